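# polyhomeo3

Homeolog expression quantification for allopolyploids from **low-coverage
3′ tag RNA-seq**, with a built-in synthetic allopolyploid data generator.

## The problem

Allopolyploid species — bread wheat (*Triticum aestivum*, AABBDD) being the
canonical example — carry two or more *homeologous* copies of most genes,
one per subgenome.  Their coding sequences are so similar that conventional
RNA-seq reads often cannot be attributed to a single subgenome.  The 3′ UTR,
under weaker purifying selection, diverges much faster: 3′ tag protocols
(Lasy-Seq, QuantSeq and relatives) sequence one poly(A)-anchored fragment
per mRNA, concentrating reads exactly where homeologs differ most.  Two
practical obstacles remain:

1. **Annotation** — gene models in polyploid references frequently stop at
   the CDS, so 3′-anchored reads land outside every annotated gene;
2. **Validation** — with no ground truth, the subgenome misclassification
   rate of a mapping workflow is unknown.

`polyhomeo3` implements the full desk-scale workflow around both ideas, for
anyone building or benchmarking homeolog expression pipelines: read
preprocessing (5′ head crop, quality trim, poly(A)/poly(T) trim, strict
>40-base filter), uniform 3′-ward annotation extension that stops before
the next same-strand gene, an exhaustive seed-and-extend read mapper (plus
SAM ingest for external aligners), unique-read subgenome assignment,
reciprocal-best-hit homeolog triads, strand-specific counting with
multi-annotation exclusion, CPM/TPM normalization, ternary homeolog
fractions, and downsampling/saturation analysis.  A synthetic generator
produces allopolyploid genomes, 3′-anchored reads with truth labels, and
**null-subgenome** read pools — the synthetic analog of a tetraploid
derivative of a hexaploid cultivar — in which any read assigned to the
absent subgenome is, by construction, a classification error.

## The statistics at the core

- **Null-subgenome error rate.**  For a read pool that cannot contain
  subgenome *n*, the misclassification-rate proxy is
  `ê = N_n / Σ_s N_s`, the share of uniquely assigned reads attributed to
  the absent subgenome.  On simulated pools the package checks `ê` against
  the truth-label misclassification fraction.
- **3′ extension.**  A '+'-strand gene's annotated end is replaced by
  `min(end + L, chrom_length, next_same_strand_start − 1)` (mirrored for
  '−' genes); opposite-strand overlap is allowed because counting is
  strand-resolved.
- **Detection under subsampling.**  Drawing k of N assigned reads without
  replacement, the expected number of detected genes is
  `E = Σ_g [1 − C(N−c_g, k)/C(N, k)]`; the empirical detection-vs-depth
  curve is summarized by a least-squares fit `N(d) = a + b·ln(d)`.
- **Normalization.**  `CPM_g = c_g/Σc × 10⁶` (no length term — 3′ tag data
  yield one fragment per transcript); `TPM_g = (c_g/ℓ_g)/Σ(c/ℓ) × 10⁶` for
  conventional RNA-seq; Pearson correlation on log₁₀ values over jointly
  expressed genes.

## Worked example

Estimate the misclassification rate with a null-subgenome control
(`python examples/04_null_subgenome_error.py`):

```
reads uniquely assigned:       10000
share A / B: 50.5% / 49.5%
null-subgenome error estimate: 0.000%
truth misclassification:       0.000%
```

The pool contained no subgenome-D reads; the D-assigned share (here zero —
the simulator's clean error model separates the diverged UTRs completely)
is a direct estimate of the workflow's error rate and matches the
truth-label rate.  Mapping a balanced hexaploid pool instead
(`python examples/03_map_and_assign_subgenomes.py`) splits uniquely
assigned reads evenly:

```
uniquely assigned: 100.0% of reads
  share A: 33.4%
  share B: 33.1%
  share D: 33.5%
```

And the depth analysis (`python examples/07_depth_saturation.py`) shows
detection saturating logarithmically, with the analytic hypergeometric
expectation tracking the empirical counts:

```
rate 0.2:  142 genes (analytic expectation   143.3), 62 triads
rate 0.4:  155 genes (analytic expectation   152.5), 64 triads
rate 0.6:  160 genes (analytic expectation   156.9), 64 triads
rate 0.8:  161 genes (analytic expectation   159.4), 64 triads
rate 1.0:  161 genes (analytic expectation   161.0), 64 triads

saturation fit N(d) = 38.4 + 12.2 ln(d)
```

Each `examples/*.py` script is a short, self-contained narrative of one
capability; `examples/08_full_pipeline_demo.py` (or
`polyhomeo3 demo --outdir demo --seed 0`) runs every stage end-to-end and
prints the manifest stats.  The same stages are available as CLI
subcommands: `simulate`, `preprocess`, `extend-gff`, `map`, `count`,
`evaluate-null`, `triads`, `run`.

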