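"""Subgenome assignment of uniquely mapped reads and the null-subgenome
error estimate.

A read that maps uniquely to one chromosome is attributed to that
chromosome's subgenome.  Reports follow the conventions of per-subgenome
proportion tables: the "attributable" percentage is taken over all
preprocessed reads, while the per-subgenome shares are taken over uniquely
assigned reads and sum to 100%.  Chloroplast or other non-subgenome
references fall into an "other" bucket that never enters either denominator.

The misclassification-rate estimate rests on a null-subgenome design: if the
read pool cannot contain one subgenome (a tetraploid derivative of a
hexaploid, or the simulator's exclusion mode), every read assigned to that
subgenome is a classification error, so the assigned fraction is a direct
error-rate proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from polyhomeo3.aligner import UniquenessCall
from polyhomeo3.annotation import DEFAULT_SUBGENOME_LABELS, subgenome_of
from polyhomeo3.errors import ConfigurationError, UndefinedStatisticError, ValidationError


def assign_subgenome(
    call: UniquenessCall,
    chrom_map: Mapping[str, str],
) -> Optional[str]:
    """Subgenome label for one uniqueness call, or None for multi/unmapped.

    ``chrom_map`` maps every reference name to a subgenome label (use
    ``"other"`` for chloroplast-like references).
    """
    if call.status != "unique" or call.record is None:
        return None
    ref = call.record.ref
    if ref not in chrom_map:
        raise ConfigurationError(f"reference {ref!r} absent from chromosome map")
    return chrom_map[ref]


def chrom_map_from_names(
    names: Iterable[str], labels: Sequence[str] = DEFAULT_SUBGENOME_LABELS
) -> dict[str, str]:
    """Build a chromosome->subgenome map from trailing-letter naming."""
    return {name: subgenome_of(name, labels) for name in names}


@dataclass
class SubgenomeTally:
    """Read counts per subgenome plus the denominators for both proportion sets."""

    counts: dict[str, int]
    n_preprocessed: int
    labels: tuple[str, ...] = DEFAULT_SUBGENOME_LABELS

    @property
    def n_other(self) -> int:
        return self.counts.get("other", 0)

    @property
    def n_subgenome_assigned(self) -> int:
        """Uniquely assigned reads on a declared subgenome (excludes "other")."""
        return sum(self.counts.get(lab, 0) for lab in self.labels)

    @property
    def attributable_pct(self) -> Optional[float]:
        """Percent of preprocessed reads uniquely assigned to a subgenome."""
        if self.n_preprocessed == 0:
            return None
        return 100.0 * self.n_subgenome_assigned / self.n_preprocessed

    @property
    def shares_pct(self) -> Optional[dict[str, float]]:
        """Per-subgenome percentages over uniquely assigned reads (sum to 100)."""
        total = self.n_subgenome_assigned
        if total == 0:
            return None
        return {lab: 100.0 * self.counts.get(lab, 0) / total for lab in self.labels}

    def to_frame(self) -> pd.DataFrame:
        shares = self.shares_pct
        row = {"attributable_pct": self.attributable_pct}
        for lab in self.labels:
            row[f"share_{lab}_pct"] = None if shares is None else shares[lab]
        row["other_reads"] = self.n_other
        return pd.DataFrame([row])


def tally(
    assignments: Iterable[Optional[str]],
    n_preprocessed: Optional[int] = None,
    labels: Sequence[str] = DEFAULT_SUBGENOME_LABELS,
) -> SubgenomeTally:
    """Tally per-read subgenome assignments (None = not uniquely assigned).

    If ``n_preprocessed`` is omitted, the assignment list is assumed to cover
    every preprocessed read.
    """
    assignments = list(assignments)
    counts: dict[str, int] = {}
    for lab in assignments:
        if lab is None:
            continue
        counts[lab] = counts.get(lab, 0) + 1
    n = len(assignments) if n_preprocessed is None else n_preprocessed
    return SubgenomeTally(counts=counts, n_preprocessed=n, labels=tuple(labels))


@dataclass
class ErrorEstimate:
    """Null-subgenome misclassification-rate estimate."""

    null_label: str
    error_rate: float  # fraction of uniquely assigned reads on the null subgenome
    breakdown: dict[str, float] = field(default_factory=dict)  # shares per label

    @property
    def error_pct(self) -> float:
        return 100.0 * self.error_rate


def estimate_null_error(t: SubgenomeTally, null_label: str) -> ErrorEstimate:
    """Error rate = reads assigned to the absent subgenome / uniquely assigned."""
    if null_label not in t.labels:
        raise ConfigurationError(f"null label {null_label!r} not among {t.labels}")
    total = t.n_subgenome_assigned
    if total == 0:
        raise UndefinedStatisticError("no uniquely assigned reads; error rate undefined")
    shares = t.shares_pct or {}
    return ErrorEstimate(
        null_label=null_label,
        error_rate=t.counts.get(null_label, 0) / total,
        breakdown=shares,
    )


def score_accuracy(
    calls: Mapping[str, Optional[str]],
    truth: pd.DataFrame,
    labels: Sequence[str] = DEFAULT_SUBGENOME_LABELS,
) -> pd.DataFrame:
    """Confusion matrix of origin subgenome (rows) vs assignment (columns).

    ``calls`` maps read id -> assigned label or None; ``truth`` must carry
    ``read_id`` and ``subgenome`` columns covering every called read.
    Columns are the subgenome labels plus "other" and "none"; row sums equal
    the per-origin read counts among the calls provided.
    """
    origin = dict(zip(truth["read_id"], truth["subgenome"]))
    cols = list(labels) + ["other", "none"]
    rows = sorted(set(origin.values()) | set(labels))
    mat = pd.DataFrame(0, index=pd.Index(rows, name="origin"), columns=cols)
    for read_id, assigned in calls.items():
        if read_id not in origin:
            raise ValidationError(f"read {read_id!r} missing from truth table")
        col = assigned if assigned in cols else ("none" if assigned is None else "other")
        mat.loc[origin[read_id], col] += 1
    return mat
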