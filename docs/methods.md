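# Methods

`polyhomeo3` quantifies homeolog expression in allopolyploids from
low-coverage 3′ tag RNA-seq (Lasy-Seq/QuantSeq-style, read 1 only).  The
premise: substitutions and small indels accumulate faster in the 3′ UTR
than in the CDS of homeologous genes, so reads anchored at the poly(A) end
map uniquely to one subgenome far more often than whole-transcript reads,
and homeolog expression can be quantified by plain unique-mapping counts —
provided the annotation actually covers the 3′ UTR and counting respects
strand.  This note documents the models, parameter choices, numerical
conventions and limitations of each component.

## Synthetic allopolyploid generator

The generator (`polyhomeo3.sim`) is the package's experimental ground: it
produces genomes, annotations, reads and per-read truth labels under the
conditions the workflow is designed for.

**Genome model.** K subgenomes (default 3, labelled A/B/D after the wheat
convention) descend from a common ancestor.  Each ancestral gene is a
random CDS (default 500 bp) plus 3′ UTR (default 300 bp); each subgenome
copy receives independent per-site substitutions — `cds_divergence`
(default 0.01/site) in the CDS, `utr_divergence` (default 0.05/site,
enforced ≥ CDS rate) in the UTR — and UTR-only indels (`indel_rate`,
default 0.002 events/site, lengths 1–3).  Substitutions are uniform over
the three alternative bases.  Indels are confined to the UTR because CDS
frameshifts are irrelevant to mapping behaviour and would only complicate
bookkeeping.  Genes sit on one chromosome per subgenome (`chr1A`…),
alternating strand, separated by a 300 bp spacer that diverges at the UTR
rate; the alternating layout guarantees that annotation extension meets
both same-strand and opposite-strand neighbours.  Divergence defaults are
chosen as a plausible allopolyploid regime: ~2 % pairwise CDS and ~10 %
pairwise UTR divergence between subgenomes, preserving the CDS≪UTR
asymmetry that motivates the method.

**Read model.** A read is drawn from a gene chosen proportionally to its
expression weight among the non-excluded subgenomes (uniform weights by
default; any nonnegative vector per ancestral gene is accepted).  The read
is the sense-strand sequence ending at the gene's true 3′ end, followed by
a fixed `polya_len` (default 30) of A's; the 5′ start is jittered upstream
by Uniform{0..20} bases, the read truncated to `read_len` (default 126,
a typical single-end read-1 length) and corrupted at `error_rate` (default
0.002/base, ≈Q27).  Base qualities are constant high ("I"); quality
trimming is exercised separately with synthetically degraded tails.
`excluded_subgenomes={"D"}` gives the null-subgenome ("tetraploid") pool
used for error-rate calibration.  The poly(A) length in real 3′ tag reads
is variable and protocol-dependent; here it is a fixed parameter, which is
sufficient because only its presence (and removal) matters downstream.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: splicing and intron-spanning reads, alternative
polyadenylation, UMI structure, internal priming artefacts, expression-
dependent library biases, contamination (organellar reads appear only if
the caller adds an "other" reference), and reference mis-assembly.  Real
error rates (e.g. a few percent of reads on an absent subgenome) arise
largely from these unmodelled effects; the simulator's clean regime yields
much lower error rates, so the synthetic analyses validate the *machinery*
(estimators, counting rules, oracles), not the field error magnitude.

## Read preprocessing

Order fixed as head crop → quality trim → poly(A)/poly(T) trim → strict
length filter.

- **Head crop** (default 10 bases): removes the 5′ positions with biased
  base composition typical of tag libraries.
- **Quality trimming** keeps the longest prefix in which every full 4-base
  window has mean Phred ≥ 20 and whose final base is ≥ 20 — a simplified
  sliding-window trimmer with a defined, oracle-testable contract.
- **Poly(X) trimming** removes the longest 3′ suffix that is ≥ 10 bases
  long and composed of a single base X ∈ {A, T} with ≤ 1 non-X base.  The
  "longest qualifying suffix" reading is applied literally, so the suffix
  may absorb one boundary base as its allowed mismatch; that base is part
  of an A/T run and genuinely ambiguous, so nothing informative is lost.
  Only the 3′ end is trimmed: read 1 carries the mRNA sense sequence.
- **Length filter** is strict: reads of exactly 40 bases are dropped
  (`> min_len`).

The report satisfies `reads_in = reads_out + dropped_short` and yields NA
(not 0) retention on empty input.

## 3′-ward annotation extension

Gene annotations in polyploid references often stop at the CDS.  Every
gene's 3′ boundary is extended by a uniform L (menu 0.5–4 kb), clamped at
chromosome bounds and stopped one base before the nearest same-strand gene
in the direction of extension: for a '+' gene the smallest same-strand
start beyond its end; for a '−' gene the mirror image (largest same-strand
end below its start).  Opposite-strand genes never block extension because
counting is strand-resolved.  Two edge rules: a gene already overlapped by
a downstream same-strand gene is left unchanged (the stop rule is
unsatisfiable, so the conservative choice preserves the input), and the 5′
boundary never moves.  Extension is not idempotent once collisions
truncate, so the pipeline always extends from the original annotation.
Child features (mRNA/exon) are not rewritten; counting consumes gene-level
intervals.

## Built-in read mapper

The mapper exists so the whole workflow runs at desk scale without an
external aligner; real alignments enter through `read_sam` (primary
records only, uniqueness from NH==1 when present else MAPQ ≥ 30, both
configurable because aligners encode multi-mapping differently).

Seed-and-extend design: every 15-mer of every reference is indexed on both
strands; a read contributes seeds every 5 bases plus one at its 3′ end.
Every (reference, strand, diagonal) sharing a seed becomes a candidate;
nearby diagonals are clustered and each cluster is scored with a windowed
Smith–Waterman (match +1, mismatch −1, linear gap −2; window = diagonal
span ± 8, so gaps up to ~16 bases fit).  Alignment starts are recovered by
re-running the kernel on reversed prefixes.  The mapper is exhaustive
among seed-sharing loci, which is what the test oracles verify (a full
Smith–Waterman scan over every reference position).

**Loci, not cells.**  Optimal local alignments can end at several nearby
cells (a gap traded against mismatches); placements overlapping on the
same reference strand are therefore merged into one locus before
multiplicity is computed.  A read is *unique* iff exactly one locus
attains the best score and the margin to the second-best locus is ≥ 1 (the
default `min_margin`); ties are reported in deterministic (score,
reference, strand, position) order.  No spliced alignment, no
quality-aware scoring, no multi-mapper rescue: multi reads are simply not
counted.

## Subgenome assignment and the null-subgenome error estimate

A uniquely mapped read inherits its chromosome's subgenome (trailing
letter of the name); chloroplast-like references fall into an "other"
bucket excluded from every subgenome denominator.  Reports follow the
two-denominator convention: the attributable percentage is over all
preprocessed reads, per-subgenome shares are over uniquely assigned reads
and sum to 100 %.

The error estimate uses a null-subgenome design: in a pool that cannot
contain subgenome D, the D-assigned share of uniquely assigned reads is a
direct misclassification-rate proxy.  On simulated null pools the estimate
equals the truth-label misclassification fraction restricted to D calls by
construction (no read originates from D), and the sweep over UTR
divergence shows the scientifically relevant trend: the error rate is
non-increasing as UTR divergence grows, approaching zero by ~10 % pairwise
divergence with ~100-base reads.

## Homeolog triads

Pairs are reciprocal best hits (RBH) between subgenome transcript sets;
triads are AB pairs whose members share the same D partner in AD and BD.
The homology search is a shared-12-mer prefilter followed by banded affine
Smith–Waterman (match +1, mismatch −1, gap open −2, gap extend −1, band
± 20 around the main diagonal — homeologs are near-globally colinear and
cumulative indel drift is far below the band).  Hits below a significance
floor of 100 are rejected; random 400–800-base sequences score ≤ ~30 under
this scheme, so the floor separates homology from noise with a wide gap
while requiring transcripts ≳ 100 bases.  Score ties at the best-hit level
disqualify the query (no unique "best" exists); unpaired genes remain
subgenome-specific singletons.  The scoring scheme is a declared package
parameter validated against planted orthology on synthetic data, not a
reproduction of any specific homology tool's defaults.

## Counting, normalization, correlation

A unique read is assigned to a gene iff its alignment overlaps the gene
interval by ≥ 1 base on the same strand (a `reverse` mode exists for
antisense protocols).  Overlapping ≥ 2 same-strand genes → ambiguous,
counted for none; 0 genes → no-feature; opposite-strand overlap neither
counts nor creates ambiguity.  `assigned + no_feature + ambiguous` equals
the unique reads processed, asserted after every run.

CPM (count/total × 10⁶) is the appropriate normalization for 3′ tag data —
one fragment per transcript, so gene length does not inflate counts; TPM
(length-normalized rates scaled to 10⁶) serves conventional RNA-seq
tables.  Correlations are Pearson on log₁₀ expression restricted to genes
expressed in **both** tables (the joint filter; the per-method alternative
would correlate undefined logs).  Ternary fractions normalize each triad's
(cA, cB, cD); all-zero triads are omitted and tallied.

## Downsampling and saturation

Detection: a gene is detected iff ≥ 1 read is assigned; a triad iff ≥ 1 of
its members is detected; the gene tally counts each expressed homeolog
individually.  Downsampling draws round(rate·N) reads without replacement
(round-half-even; the convention is a package choice), with two modes:
independent draws for variance studies and nested permutation-prefix
subsets (the default), which make detection exactly monotone in rate.  The
pipeline downsamples assigned reads directly (fast mode); with a
deterministic mapper this is distribution-identical to re-mapping a read
subset, since assignment is a fixed per-read function.

The analytic companion: under without-replacement subsampling of k from N
assigned reads, E[detected] = Σ_g [1 − C(N−c_g, k)/C(N, k)], computed with
log-gamma.  The saturation trend is summarized by least squares of
detected count against ln(depth), N(d) = a + b·ln(d) — one plausible
functional form for "logarithmic saturation", exposed with its residual
sum of squares rather than asserted as the true law.

## Pipeline determinism

Every stage is a pure function of (inputs, parameters, seed); all
randomness flows through `numpy.random.default_rng` seeds carried in the
config.  The manifest records SHA-256 checksums of every output, so equal
configs produce byte-identical manifests; logs are excluded from the
manifest.  Config format is TOML; stage failures abort with the stage name
and keep partial outputs.

## Problem sizes

The packaged analyses run at desk scale by choice: demo pipeline 3 × 200
genes and 5 × 10⁴ reads; oracle comparisons 500 reads against ≤ 6 kb of
reference; triad recovery 300 planted triads; null-subgenome calibration
5 × 10⁴ reads (2 × 10⁴ per point in the divergence sweep); detection
expectation checked against 200 seeded downsamples.  These sizes give
stable statistics (binomial standard errors well below the asserted
tolerances) while keeping every analysis reproducible on a single CPU in
minutes.

## Known limitations

- The mapper is exhaustive only among seed-sharing loci; a read whose best
  locus shares no exact 15-mer (≳ 7 % divergence from its own locus, or
  dense errors) can be missed.  Irrelevant at the simulated error rates,
  relevant for degraded real data.
- Triad construction assumes 1:1:1 orthology; tandem duplicates or lost
  homeologs yield singletons or pairs, never partial triads.
- The saturation fit is descriptive; extrapolation beyond the observed
  depth range inherits the a + b·ln(d) assumption.
- Differential expression and GO enrichment are out of scope; count tables
  are exported for external DE tools.
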