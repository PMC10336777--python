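"""3' tag read preprocessing: head crop, quality trim, poly(A)/poly(T) trim,
length filter.

The order is fixed -- crop -> quality -> poly(X) -> strict length filter --
and the length filter is strict ("reads > min_len bases pass").  Poly(A) and
poly(T) are trimmed only from the 3' end: read 1 of a 3' tag library carries
the mRNA sense sequence, so the poly(A) stretch (or poly(T), if the template
strand leaked through) sits at the 3' end of the read.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Optional

from polyhomeo3.errors import ValidationError

PHRED_OFFSET = 33
_QUALITY_WINDOW = 4


@dataclass
class PreprocessParams:
    head_crop: int = 10
    quality_threshold: int = 20
    min_len: int = 40  # strict: reads must be > min_len after trimming
    polyx_min_run: int = 10
    polyx_max_mismatch: int = 1

    def __post_init__(self) -> None:
        for name in ("head_crop", "quality_threshold", "min_len", "polyx_min_run", "polyx_max_mismatch"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class PreprocessReport:
    """Per-file retention accounting.  ``reads_in = reads_out + dropped_short``."""

    reads_in: int = 0
    reads_out: int = 0
    attrition: dict = field(default_factory=lambda: {
        "head_cropped": 0,       # reads shortened by the head crop
        "quality_trimmed": 0,    # reads shortened by the quality scan
        "polyx_trimmed": 0,      # reads with a poly(A)/poly(T) tail removed
        "dropped_short": 0,      # reads removed by the strict length filter
    })

    @property
    def fraction_retained(self) -> Optional[float]:
        if self.reads_in == 0:
            return None  # undefined on empty input, not 0
        return self.reads_out / self.reads_in

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"reads_in\t{self.reads_in}\n")
            fh.write(f"reads_out\t{self.reads_out}\n")
            frac = self.fraction_retained
            fh.write(f"fraction_retained\t{'NA' if frac is None else f'{frac:.6f}'}\n")
            for key, val in self.attrition.items():
                fh.write(f"{key}\t{val}\n")


def crop_head(seq: str, qual: str, n: int) -> tuple[str, str]:
    """Remove the first ``n`` bases and qualities (5' head crop)."""
    if n < 0:
        raise ValidationError("head crop must be >= 0")
    return seq[n:], qual[n:]


def trim_quality_tail(seq: str, qual: str, threshold: int) -> tuple[str, str]:
    """Keep the longest prefix in which every full 4-base window has mean
    quality >= threshold and the final base is >= threshold.

    This is a simplified sliding-window trimmer (window 4, mean cut) followed
    by stripping of trailing sub-threshold bases, so no low-quality base ever
    survives at the 3' end.
    """
    if len(seq) != len(qual):
        raise ValidationError(
            f"quality string length {len(qual)} != sequence length {len(seq)}"
        )
    q = [ord(c) - PHRED_OFFSET for c in qual]
    n = len(q)
    limit = n
    for i in range(0, n - _QUALITY_WINDOW + 1):
        if sum(q[i : i + _QUALITY_WINDOW]) < threshold * _QUALITY_WINDOW:
            limit = i + _QUALITY_WINDOW - 1  # any prefix up to here has no failing window
            break
    while limit > 0 and q[limit - 1] < threshold:
        limit -= 1
    return seq[:limit], qual[:limit]


def trim_polyx_tail(
    seq: str, qual: str, min_run: int = 10, max_mismatch: int = 1
) -> tuple[str, str]:
    """Remove the longest 3' suffix that is >= ``min_run`` long and composed
    of a single base X in {A, T} with at most ``max_mismatch`` non-X bases.

    Applied once; the longest qualifying suffix over both X choices wins.
    """
    best = 0
    for x in ("A", "T"):
        mismatches = 0
        valid = 0
        for m in range(1, len(seq) + 1):
            if seq[-m] != x:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
            valid = m
        if valid >= min_run:
            best = max(best, valid)
    if best:
        return seq[:-best], qual[:-best]
    return seq, qual


def preprocess_read(
    seq: str, qual: str, params: PreprocessParams
) -> tuple[str, str, dict]:
    """Apply crop -> quality -> poly(X); returns trimmed read plus step flags."""
    steps = {"head_cropped": False, "quality_trimmed": False, "polyx_trimmed": False}
    s1, q1 = crop_head(seq, qual, params.head_crop)
    steps["head_cropped"] = len(s1) < len(seq)
    s2, q2 = trim_quality_tail(s1, q1, params.quality_threshold)
    steps["quality_trimmed"] = len(s2) < len(s1)
    s3, q3 = trim_polyx_tail(s2, q2, params.polyx_min_run, params.polyx_max_mismatch)
    steps["polyx_trimmed"] = len(s3) < len(s2)
    return s3, q3, steps


def _open_maybe_gzip(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def preprocess_fastq(
    in_path, out_path, params: Optional[PreprocessParams] = None
) -> PreprocessReport:
    """Stream a FASTQ file through the preprocessing cascade.

    Reads surviving with length > ``params.min_len`` (strict) are written to
    ``out_path``; the report's attrition counts satisfy
    ``reads_in = reads_out + dropped_short``.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    if params is None:
        params = PreprocessParams()
    report = PreprocessReport()
    with _open_maybe_gzip(in_path, "r") as fin, _open_maybe_gzip(out_path, "w") as fout:
        iterator = FastqGeneralIterator(fin)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise IOError(
                    f"{in_path}: malformed FASTQ near record {report.reads_in + 1}: {exc}"
                ) from exc
            report.reads_in += 1
            try:
                s, q, steps = preprocess_read(seq, qual, params)
            except ValidationError as exc:
                raise IOError(
                    f"{in_path}: record {report.reads_in} ({title.split()[0]}): {exc}"
                ) from exc
            for key, hit in steps.items():
                if hit:
                    report.attrition[key] += 1
            if len(s) > params.min_len:
                report.reads_out += 1
                fout.write(f"@{title}\n{s}\n+\n{q}\n")
            else:
                report.attrition["dropped_short"] += 1
    return report


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read a whole (small) FASTQ file into memory as (id, seq, qual) tuples."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_maybe_gzip(path, "r") as fh:
        return [(title.split()[0], seq, qual) for title, seq, qual in FastqGeneralIterator(fh)]
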