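"""Downsampling, detection definitions and saturation of gene discovery.

Detection definitions: a gene is "detected" if one or more reads are
assigned to it; a homeolog triad is "detected" if at least one of its three
members is detected.  The gene tally counts each expressed homeolog
individually -- a triad with one, two or three expressed members contributes
one, two or three genes -- and subgenome-specific singletons count as one
gene but no triad.

Under uniform subsampling of k reads out of N without replacement, the
probability that a gene with c assigned reads retains at least one is
``1 - C(N-c, k)/C(N, k)``; summing over genes gives the analytic expectation
of the detected-gene count, computed with log-gamma for stability.  The
saturation trend is summarized by a least-squares fit of detected counts
against log depth, N(d) = a + b*ln(d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from polyhomeo3.errors import ConfigurationError, ValidationError
from polyhomeo3.expression import CountTable
from polyhomeo3.triads import Triad

DEFAULT_RATES = (0.2, 0.4, 0.6, 0.8)


def downsample(read_ids: Sequence, rate: float, seed: int) -> list:
    """Uniform sample without replacement of size round(rate * N).

    Rounding is round-half-even; the subset preserves the input order.
    """
    if not 0 < rate <= 1:
        raise ConfigurationError(f"downsampling rate must be in (0, 1], got {rate}")
    n = len(read_ids)
    size = round(rate * n)
    if rate == 1:
        return list(read_ids)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=size, replace=False))
    return [read_ids[i] for i in idx]


def nested_subsets(read_ids: Sequence, rates: Sequence[float], seed: int) -> dict[float, list]:
    """Nested subsamples built by truncating one random permutation.

    Nesting guarantees exactly monotone detection across rates; use
    independent :func:`downsample` draws for variance studies instead.
    """
    for rate in rates:
        if not 0 < rate <= 1:
            raise ConfigurationError(f"downsampling rate must be in (0, 1], got {rate}")
    n = len(read_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    out = {}
    for rate in sorted(rates):
        size = round(rate * n)
        idx = np.sort(perm[:size])
        out[rate] = [read_ids[i] for i in idx]
    return out


@dataclass
class DetectionSummary:
    depth: int  # number of reads in the (sub)sample
    n_detected_genes: int
    n_detected_triads: int
    rate: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_detected_triads > self.n_detected_genes:
            raise ValidationError("detected triads cannot exceed detected genes")


def detect(
    counts: CountTable | pd.Series | Mapping[str, int],
    triads: Sequence[Triad],
    depth: Optional[int] = None,
    rate: Optional[float] = None,
    seed: Optional[int] = None,
) -> DetectionSummary:
    """Apply the detection definitions to a count table."""
    if isinstance(counts, CountTable):
        series = counts.counts
    else:
        series = pd.Series(counts)
    detected = set(series.index[series >= 1])
    n_genes = len(detected)
    n_triads = sum(1 for t in triads if (t.a in detected or t.b in detected or t.d in detected))
    return DetectionSummary(
        depth=int(series.sum()) if depth is None else depth,
        n_detected_genes=n_genes,
        n_detected_triads=n_triads,
        rate=rate,
        seed=seed,
    )


def expected_detection(counts: pd.Series | Sequence[int], k: int) -> float:
    """Analytic expected number of detected genes after subsampling k reads.

    ``E = sum_g [1 - C(N - c_g, k) / C(N, k)]`` under without-replacement
    sampling, where N is the total assigned-read count.
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c >= 0]
    n_total = int(c.sum())
    if k < 0 or k > n_total:
        raise ValidationError(f"subsample size k={k} outside [0, {n_total}]")
    if k == 0:
        return 0.0
    # log C(N-c, k) - log C(N, k); genes with c > N - k are always detected
    expressed = c[c >= 1]
    miss = np.zeros(len(expressed))
    feasible = expressed <= n_total - k
    nc = n_total - expressed[feasible]
    log_miss = (
        gammaln(nc + 1)
        - gammaln(nc - k + 1)
        - (gammaln(n_total + 1) - gammaln(n_total - k + 1))
    )
    miss[feasible] = np.exp(log_miss)
    return float(np.sum(1.0 - miss))


@dataclass
class SaturationFit:
    """Least-squares fit of N(d) = a + b * ln(d)."""

    intercept: float
    slope: float
    rss: float

    def predict(self, depth) -> np.ndarray:
        d = np.asarray(depth, dtype=float)
        return self.intercept + self.slope * np.log(d)


def fit_saturation(summaries: Sequence[DetectionSummary] | pd.DataFrame) -> SaturationFit:
    """Fit detected-gene counts against log depth over >= 2 distinct depths."""
    if isinstance(summaries, pd.DataFrame):
        depths = summaries["depth"].to_numpy(dtype=float)
        detected = summaries["n_detected_genes"].to_numpy(dtype=float)
    else:
        depths = np.array([s.depth for s in summaries], dtype=float)
        detected = np.array([s.n_detected_genes for s in summaries], dtype=float)
    if len(np.unique(depths)) < 2:
        raise ValidationError("saturation fit requires >= 2 distinct depths")
    if np.any(depths <= 0):
        raise ValidationError("depths must be positive")
    design = np.column_stack([np.ones_like(depths), np.log(depths)])
    coef, _, _, _ = np.linalg.lstsq(design, detected, rcond=None)
    resid = detected - design @ coef
    return SaturationFit(intercept=float(coef[0]), slope=float(coef[1]), rss=float(resid @ resid))


def detection_table(summaries: Sequence[DetectionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "depth": s.depth,
                "rate": s.rate,
                "seed": s.seed,
                "n_detected_genes": s.n_detected_genes,
                "n_detected_triads": s.n_detected_triads,
            }
            for s in summaries
        ]
    )
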