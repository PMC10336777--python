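"""Strand-specific read-to-gene counting, normalization and homeolog ratios.

Counting rules for 3' tag data: a uniquely mapped read is assigned to a gene
iff its alignment overlaps the gene interval by at least one base on the
same strand (tag reads carry the mRNA sense sequence; a ``reverse`` mode
exists for antisense protocols).  Reads overlapping two or more same-strand
genes are ambiguous and counted for none; opposite-strand overlap neither
counts nor creates ambiguity.  Multi-mapped reads never contribute.

CPM is the appropriate normalization for 3' tag counts (one fragment per
transcript, so gene length does not inflate counts); TPM is provided for
conventional RNA-seq tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from polyhomeo3.aligner import AlignmentRecord
from polyhomeo3.annotation import GeneModel
from polyhomeo3.errors import (
    ConfigurationError,
    UndefinedStatisticError,
    ValidationError,
)
from polyhomeo3.triads import Triad


@dataclass
class CountTable:
    """Per-gene raw counts plus assignment-category tallies.

    Invariant: ``assigned + no_feature + ambiguous_feature`` equals the
    number of uniquely mapped reads processed.
    """

    counts: pd.Series  # index: gene ids, values: int
    categories: dict = field(
        default_factory=lambda: {
            "assigned": 0,
            "no_feature": 0,
            "ambiguous_feature": 0,
            "non_unique": 0,
        }
    )
    annotation_tag: str = ""

    def check(self) -> None:
        c = self.categories
        if int(self.counts.sum()) != c["assigned"]:
            raise ValidationError("count sum differs from the assigned tally")
        if (self.counts < 0).any():
            raise ValidationError("negative counts")

    @property
    def n_unique_reads(self) -> int:
        c = self.categories
        return c["assigned"] + c["no_feature"] + c["ambiguous_feature"]

    def to_tsv(self, path) -> None:
        df = self.counts.rename("count").rename_axis("gene_id").reset_index()
        df.to_csv(path, sep="\t", index=False)

    def categories_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"annotation": self.annotation_tag, **self.categories}])


def count_reads(
    alignments: Sequence[AlignmentRecord],
    genes: Sequence[GeneModel],
    stranded: str = "sense",
    n_non_unique: int = 0,
    annotation_tag: str = "",
    return_assignments: bool = False,
) -> CountTable | tuple[CountTable, list[str]]:
    """Count uniquely mapped reads per gene with strand-resolved overlap.

    ``alignments`` must contain only unique placements (one per read);
    ``n_non_unique`` is carried into the category tally for reporting.
    With ``return_assignments`` the per-assigned-read gene ids are returned
    too (in alignment order), the unit on which fast-mode downsampling
    operates.
    """
    if stranded not in ("sense", "reverse"):
        raise ConfigurationError(f"stranded must be 'sense' or 'reverse', got {stranded!r}")
    trees: dict[str, IntervalTree] = {}
    known_chroms = {g.chrom for g in genes}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)

    counts = pd.Series(0, index=pd.Index([g.gene_id for g in genes], name="gene_id"), dtype=int)
    cats = {"assigned": 0, "no_feature": 0, "ambiguous_feature": 0, "non_unique": n_non_unique}
    flip = {"+": "-", "-": "+"}
    assignments: list[str] = []
    for rec in alignments:
        if rec.ref not in known_chroms:
            raise ConfigurationError(f"alignment on unknown chromosome {rec.ref!r}")
        want = rec.strand if stranded == "sense" else flip[rec.strand]
        # record interval [start, end) 0-based -> [start+1, end] 1-based
        overlaps = trees[rec.ref].overlap(rec.start + 1, rec.end + 1)
        gene_ids = {iv.data.gene_id for iv in overlaps if iv.data.strand == want}
        if len(gene_ids) == 0:
            cats["no_feature"] += 1
        elif len(gene_ids) == 1:
            cats["assigned"] += 1
            gene_id = next(iter(gene_ids))
            counts[gene_id] += 1
            if return_assignments:
                assignments.append(gene_id)
        else:
            cats["ambiguous_feature"] += 1
    table = CountTable(counts=counts, categories=cats, annotation_tag=annotation_tag)
    table.check()
    if return_assignments:
        return table, assignments
    return table


def compare_annotations(counts_base: CountTable, counts_ext: CountTable) -> dict:
    """Per-gene effect of an annotation change on the same alignments.

    Returns per-gene classes {same, increased, decreased}, the change in the
    assigned fraction (of uniquely mapped reads) and in the number of
    detected (count > 0) genes.
    """
    if set(counts_base.counts.index) != set(counts_ext.counts.index):
        raise ValidationError("count tables cover different gene universes")
    if counts_base.n_unique_reads != counts_ext.n_unique_reads:
        raise ValidationError("count tables derive from different alignment sets")
    base = counts_base.counts
    ext = counts_ext.counts.reindex(base.index)
    delta = ext - base
    classes = pd.Series("same", index=base.index)
    classes[delta > 0] = "increased"
    classes[delta < 0] = "decreased"
    n_reads = counts_base.n_unique_reads
    assigned_frac = lambda t: t.categories["assigned"] / n_reads if n_reads else float("nan")
    return {
        "classes": classes,
        "n_same": int((classes == "same").sum()),
        "n_increased": int((classes == "increased").sum()),
        "n_decreased": int((classes == "decreased").sum()),
        "assigned_fraction_base": assigned_frac(counts_base),
        "assigned_fraction_ext": assigned_frac(counts_ext),
        "assigned_fraction_delta": assigned_frac(counts_ext) - assigned_frac(counts_base),
        "no_feature_delta": counts_ext.categories["no_feature"]
        - counts_base.categories["no_feature"],
        "detected_base": int((base > 0).sum()),
        "detected_ext": int((ext > 0).sum()),
    }


def cpm(table: CountTable | pd.Series) -> pd.Series:
    """Counts per million: count / total * 1e6 (no length normalization)."""
    counts = table.counts if isinstance(table, CountTable) else table
    total = counts.sum()
    if total <= 0:
        raise UndefinedStatisticError("CPM undefined: zero total count")
    return counts / total * 1e6


def tpm(table: CountTable | pd.Series, gene_lengths: Mapping[str, float]) -> pd.Series:
    """Transcripts per million: length-normalized rates scaled to 1e6."""
    counts = table.counts if isinstance(table, CountTable) else table
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValidationError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    rates = counts / lengths
    total = rates.sum()
    if total <= 0:
        raise UndefinedStatisticError("TPM undefined: zero total rate")
    return rates / total * 1e6


def log_correlation(x: pd.Series, y: pd.Series) -> tuple[float, int]:
    """Pearson correlation of log10 expression over jointly expressed genes.

    Restricts to genes with x > 0 AND y > 0 (the joint "expressed" filter),
    then correlates log10(x) with log10(y).  Returns (r, n_genes_used).
    """
    common = x.index.intersection(y.index)
    if len(common) != len(x) or len(common) != len(y):
        raise ValidationError("expression tables cover different gene universes")
    xv, yv = x.loc[common], y.loc[common]
    mask = (xv > 0) & (yv > 0)
    n = int(mask.sum())
    if n < 3:
        raise UndefinedStatisticError(f"correlation undefined with n={n} jointly expressed genes")
    r = float(np.corrcoef(np.log10(xv[mask]), np.log10(yv[mask]))[0, 1])
    return r, n


@dataclass
class TernaryPoint:
    triad: Triad
    fa: float
    fb: float
    fd: float


def ternary_fractions(
    triads: Sequence[Triad],
    counts: Mapping[str, float] | pd.Series,
) -> tuple[pd.DataFrame, int]:
    """Per-triad homeolog expression fractions (fA, fB, fD).

    Triads whose three homeologs all have zero counts are omitted; the
    number omitted is returned alongside the DataFrame.
    """
    get = counts.get if hasattr(counts, "get") else counts.__getitem__
    rows = []
    n_omitted = 0
    for t in triads:
        ca, cb, cd = (float(get(g, 0.0)) for g in t)
        total = ca + cb + cd
        if total <= 0:
            n_omitted += 1
            continue
        rows.append((t.a, t.b, t.d, ca / total, cb / total, cd / total))
    df = pd.DataFrame(rows, columns=["a_id", "b_id", "d_id", "fA", "fB", "fD"])
    return df, n_omitted
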