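"""Synthetic allopolyploid genomes, annotations and 3'-anchored reads.

The generator emulates the situation the package is built for: an
allopolyploid whose K subgenomes diverged from a common ancestor, with
substitution rates higher in the 3' UTR than in the CDS (purifying selection
on coding sequence), small indels restricted to the UTR, strand-specific
3' tag reads that end in a poly(A) stretch, and -- optionally -- a
"null subgenome" read pool from which one subgenome is absent, the synthetic
analog of a tetraploid derivative of a hexaploid cultivar.  Every simulated
read carries a truth label (gene and subgenome of origin), which downstream
modules use to score assignment accuracy and validate the null-subgenome
error estimate.

Layout conventions (chosen to make extension-collision geometry occur by
construction): one chromosome per subgenome named ``chr1A``/``chr1B``/...,
genes placed alternately on '+' and '-' strands, separated by a fixed
intergenic spacer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from polyhomeo3.annotation import GeneModel, write_gff3
from polyhomeo3.errors import ConfigurationError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G on byte codes


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class SimConfig:
    """Parameters of the genome generator.

    ``utr_divergence >= cds_divergence`` is enforced: the premise of 3' tag
    subgenome assignment is that UTRs diverge faster than coding sequence.
    Divergences are substitutions per site applied independently on each
    subgenome lineage; ``indel_rate`` is events per site, UTR only, with
    lengths drawn uniformly from 1-3 bases.
    """

    n_subgenomes: int = 3
    n_genes: int = 100
    cds_len: int = 500
    utr3_len: int = 300
    intergenic_len: int = 300
    cds_divergence: float = 0.01
    utr_divergence: float = 0.05
    indel_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subgenomes", "n_genes", "cds_len", "utr3_len", "intergenic_len"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("cds_divergence", "utr_divergence", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {rate}")
        if self.utr_divergence < self.cds_divergence:
            raise ConfigurationError(
                "utr_divergence must be >= cds_divergence "
                f"({self.utr_divergence} < {self.cds_divergence})"
            )
        if self.n_subgenomes > 24:
            raise ConfigurationError("at most 24 subgenomes supported")

    @property
    def labels(self) -> tuple[str, ...]:
        base = "ABDEFGHIJKLMNOPQRSTUVWXYZ"  # A, B, D first: the wheat convention
        return tuple(base[: self.n_subgenomes])


@dataclass
class GeneStructure:
    """Realized (post-mutation) structure of one gene on one subgenome."""

    gene_id: str
    ancestral_index: int
    subgenome: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive, whole gene (CDS + 3' UTR)
    end: int
    cds_start: int  # genomic span of the CDS part
    cds_end: int
    utr_len: int  # realized 3' UTR length after indels
    transcript: str  # sense-strand CDS + UTR sequence


@dataclass
class SyntheticGenomeSet:
    """References, annotations and orthology truth for one simulated polyploid."""

    config: SimConfig
    references: dict[str, str]
    structures: dict[str, list[GeneStructure]]  # per subgenome label
    ancestor_transcripts: list[str]  # per ancestral gene index

    @property
    def labels(self) -> tuple[str, ...]:
        return self.config.labels

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.references.items()}

    def genes_full(self) -> list[GeneModel]:
        """Full annotation: gene intervals covering CDS + complete 3' UTR."""
        return [
            GeneModel(s.gene_id, s.chrom, s.strand, s.start, s.end, source="full")
            for label in self.labels
            for s in self.structures[label]
        ]

    def transcripts(self, label: str) -> dict[str, str]:
        """Sense-strand transcript sequences (CDS + 3' UTR) for one subgenome."""
        return {s.gene_id: s.transcript for s in self.structures[label]}

    def orthology(self) -> pd.DataFrame:
        """Truth table of homeologous gene ids, one row per ancestral gene."""
        rows = {}
        for label in self.labels:
            rows[label] = {s.ancestral_index: s.gene_id for s in self.structures[label]}
        df = pd.DataFrame(rows)
        df.index.name = "ancestral_index"
        return df

    def gene_lookup(self) -> dict[str, GeneStructure]:
        return {s.gene_id: s for label in self.labels for s in self.structures[label]}

    # -- writers ---------------------------------------------------------

    def write_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(self.references.items())
        ]
        seqio_write(records, str(path), "fasta")

    def write_gff3(self, path, truncate_bp: int = 0) -> None:
        if truncate_bp:
            write_gff3(truncate_utr_annotation(self, truncate_bp), path)
        else:
            write_gff3(self.genes_full(), path)

    def write_transcripts(self, directory) -> dict[str, Path]:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for label in self.labels:
            recs = [
                SeqRecord(Seq(s.transcript), id=s.gene_id, description="")
                for s in self.structures[label]
            ]
            p = directory / f"transcripts_{label}.fa"
            seqio_write(recs, str(p), "fasta")
            paths[label] = p
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate``, uniformly among the
    three alternative bases."""
    out = seq.copy()
    if rate <= 0:
        return out
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alts = _BASES[_BASES != out[i]]
        out[i] = alts[rng.integers(0, 3)]
    return out


def _apply_indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply indel events (per-site rate; del/ins equiprobable; length 1-3)."""
    if rate <= 0:
        return seq
    sites = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(sites) == 0:
        return seq
    parts: list[np.ndarray] = []
    prev = 0
    for pos in sites:
        parts.append(seq[prev:pos])
        length = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # deletion starting at pos
            prev = min(pos + length, len(seq))
        else:  # insertion before pos
            parts.append(_random_seq(rng, length))
            prev = pos
    parts.append(seq[prev:])
    return np.concatenate(parts)


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_subgenomes(config: SimConfig) -> SyntheticGenomeSet:
    """Derive K subgenomes from one common ancestor.

    Each ancestral gene is a random CDS + 3' UTR; every subgenome copy
    receives independent substitutions (``cds_divergence`` in CDS,
    ``utr_divergence`` in UTR), UTR-only indels, and is placed on its own
    chromosome with alternating strands.  Intergenic spacers diverge at the
    UTR rate (neutral sequence).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    anc_cds = [_random_seq(rng, config.cds_len) for _ in range(n)]
    anc_utr = [_random_seq(rng, config.utr3_len) for _ in range(n)]
    anc_spacers = [_random_seq(rng, config.intergenic_len) for _ in range(n + 1)]
    ancestor_transcripts = [_to_str(np.concatenate([c, u])) for c, u in zip(anc_cds, anc_utr)]

    references: dict[str, str] = {}
    structures: dict[str, list[GeneStructure]] = {}
    for label in config.labels:
        chrom = f"chr1{label}"
        parts: list[str] = []
        genes: list[GeneStructure] = []
        pos = 0  # 0-based running offset
        for i in range(n):
            spacer = _mutate(anc_spacers[i], config.utr_divergence, rng)
            parts.append(_to_str(spacer))
            pos += len(spacer)
            cds = _mutate(anc_cds[i], config.cds_divergence, rng)
            utr = _apply_indels(
                _mutate(anc_utr[i], config.utr_divergence, rng), config.indel_rate, rng
            )
            transcript = _to_str(np.concatenate([cds, utr]))
            strand = "+" if i % 2 == 0 else "-"
            genomic = transcript if strand == "+" else _revcomp(transcript)
            start = pos + 1  # to 1-based
            end = pos + len(genomic)
            if strand == "+":
                cds_start, cds_end = start, start + len(cds) - 1
            else:
                cds_start, cds_end = end - len(cds) + 1, end
            genes.append(
                GeneStructure(
                    gene_id=f"g{label}{i:04d}",
                    ancestral_index=i,
                    subgenome=label,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    utr_len=len(utr),
                    transcript=transcript,
                )
            )
            parts.append(genomic)
            pos += len(genomic)
        tail = _mutate(anc_spacers[n], config.utr_divergence, rng)
        parts.append(_to_str(tail))
        references[chrom] = "".join(parts)
        structures[label] = genes
    return SyntheticGenomeSet(
        config=config,
        references=references,
        structures=structures,
        ancestor_transcripts=ancestor_transcripts,
    )


def truncate_utr_annotation(
    genomes: SyntheticGenomeSet, truncate_bp: int, seed: Optional[int] = None
) -> list[GeneModel]:
    """Annotation with each gene's 3' boundary pulled back toward the CDS.

    Emulates incomplete 3' UTR annotation: each gene loses
    ``min(truncate_bp, realized UTR length)`` bases from its 3' end,
    respecting strand.  Gene ids are unchanged.  Deterministic; the ``seed``
    parameter is accepted for interface symmetry but unused.
    """
    if truncate_bp < 0:
        raise ConfigurationError(f"truncate_bp must be >= 0, got {truncate_bp}")
    out: list[GeneModel] = []
    for label in genomes.labels:
        for s in genomes.structures[label]:
            t = min(truncate_bp, s.utr_len)
            if s.strand == "+":
                start, end = s.start, s.end - t
            else:
                start, end = s.start + t, s.end
            out.append(GeneModel(s.gene_id, s.chrom, s.strand, start, end, source="truncated"))
    return out


@dataclass
class ReadSimConfig:
    """Parameters of the 3'-anchored read generator.

    Each read is drawn from a gene chosen proportionally to its expression
    weight among non-excluded subgenomes, takes the sense-strand sequence
    ending at the gene's true 3' end followed by ``polya_len`` A's, jitters
    its 5' start upstream by Uniform{0..jitter} bases, truncates to
    ``read_len`` and applies per-base sequencing errors.  Defaults mirror a
    Lasy-Seq-style library: 126-base read 1, a long poly(A) stretch at the
    3' end, and a low substitution error rate.
    """

    n_reads: int = 50_000
    read_len: int = 126
    polya_len: int = 30
    jitter: int = 20
    error_rate: float = 0.002
    weights: Optional[Sequence[float]] = None  # per ancestral gene; None = uniform
    excluded_subgenomes: frozenset[str] = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0 or self.read_len <= 0:
            raise ConfigurationError("n_reads and read_len must be positive")
        if self.polya_len < 0 or self.jitter < 0:
            raise ConfigurationError("polya_len and jitter must be >= 0")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ConfigurationError(f"error_rate must be in [0, 1], got {self.error_rate}")
        self.excluded_subgenomes = frozenset(self.excluded_subgenomes)


def simulate_3prime_reads(
    genomes: SyntheticGenomeSet, config: ReadSimConfig
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Generate 3'-anchored reads with truth labels.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence, quality)`` (constant high quality "I") and
    ``truth`` is a DataFrame with columns
    ``read_id, gene_id, subgenome, start, end`` giving each read's origin
    gene and the 1-based inclusive genomic interval covered by its
    non-poly(A) portion.
    """
    labels = [lab for lab in genomes.labels if lab not in config.excluded_subgenomes]
    if config.excluded_subgenomes - set(genomes.labels):
        raise ConfigurationError(
            f"excluded subgenomes {sorted(config.excluded_subgenomes - set(genomes.labels))} "
            "not among simulated labels"
        )
    if not labels:
        raise ConfigurationError("all subgenomes excluded; nothing to simulate")

    n_genes = genomes.config.n_genes
    if config.weights is None:
        w = np.ones(n_genes)
    else:
        w = np.asarray(config.weights, dtype=float)
        if len(w) != n_genes or np.any(w < 0) or w.sum() <= 0:
            raise ConfigurationError(
                "weights must be nonnegative, not all zero, one per ancestral gene"
            )
    # flat pool over (subgenome, gene), same weight vector per subgenome copy
    pool = [(lab, i) for lab in labels for i in range(n_genes)]
    p = np.tile(w, len(labels))
    p = p / p.sum()

    rng = np.random.default_rng(config.seed)
    choices = rng.choice(len(pool), size=config.n_reads, p=p)
    jitters = rng.integers(0, config.jitter + 1, size=config.n_reads)

    structures = {lab: genomes.structures[lab] for lab in labels}
    reads: list[tuple[str, str, str]] = []
    rows = []
    polya = "A" * config.polya_len
    for ridx in range(config.n_reads):
        lab, gi = pool[choices[ridx]]
        s = structures[lab][gi]
        full = s.transcript + polya
        t_len = len(s.transcript)
        start_in_s = max(0, len(full) - config.read_len - int(jitters[ridx]))
        seq_arr = np.frombuffer(
            full[start_in_s : start_in_s + config.read_len].encode(), dtype=np.uint8
        ).copy()
        if config.error_rate > 0:
            hits = np.flatnonzero(rng.random(len(seq_arr)) < config.error_rate)
            for i in hits:
                alts = _BASES[_BASES != seq_arr[i]]
                seq_arr[i] = alts[rng.integers(0, 3)]
        seq = seq_arr.tobytes().decode("ascii")
        read_id = f"read{ridx:06d}"
        # genomic interval of the transcript-covered part
        t0 = min(start_in_s, t_len)
        t1 = min(start_in_s + config.read_len, t_len)
        if t1 <= t0:  # read entirely within the poly(A) tail
            t0, t1 = t_len - 1, t_len
        if s.strand == "+":
            g0, g1 = s.start + t0, s.start + t1 - 1
        else:
            g0, g1 = s.end - (t1 - 1), s.end - t0
        reads.append((read_id, seq, "I" * len(seq)))
        rows.append((read_id, s.gene_id, lab, g0, g1))
    truth = pd.DataFrame(rows, columns=["read_id", "gene_id", "subgenome", "start", "end"])
    return reads, truth


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str, "gene_id": str, "subgenome": str})
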