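"""Read alignment: an exhaustive seed-and-extend mapper plus SAM ingest.

The built-in mapper exists so the whole workflow runs at desk scale with no
external aligner: it indexes every k-mer of every reference (both strands),
collects all seed-sharing loci for a read, and scores each locus with a
windowed Smith-Waterman (match +1, mismatch -1, linear gap -2) that is
exhaustive among seed-sharing loci.  Contiguous (unspliced) alignment only.
Real datasets enter through :func:`read_sam` instead; both routes end in the
same :class:`UniquenessCall` contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from polyhomeo3._align_core import encode, sw_best
from polyhomeo3.errors import ValidationError

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap: int = -2  # linear, per gap base


@dataclass
class AlignmentRecord:
    """One read placement.  Reference interval is 0-based half-open
    (converted to 1-based only at SAM boundaries)."""

    read_id: str
    ref: str
    start: int
    end: int
    strand: str  # '+': read aligns to forward reference strand
    score: int
    qstart: int = 0  # aligned span on the read, 0-based half-open
    qend: int = 0
    read_len: int = 0
    n_cobest: int = 1
    margin: int = 0


@dataclass
class UniquenessCall:
    status: str  # "unique" | "multi" | "unmapped"
    record: Optional[AlignmentRecord] = None


class SeedIndex:
    """Exact k-mer index over both strands of a reference set."""

    def __init__(self, references: Mapping[str, str] | Sequence[tuple[str, str]], k: int = 15):
        if k < 8:
            raise ValidationError(f"seed length k must be >= 8, got {k}")
        items = list(references.items()) if isinstance(references, Mapping) else list(references)
        if not items:
            raise ValidationError("references must be non-empty")
        names = [name for name, _ in items]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate reference names")
        self.k = k
        self.names: list[str] = names
        self.seqs: list[str] = [seq.upper() for _, seq in items]
        self.fwd: list[np.ndarray] = [encode(s) for s in self.seqs]
        self.rev: list[np.ndarray] = [encode(revcomp(s)) for s in self.seqs]
        self._table: dict[str, list[tuple[int, int, int]]] = {}
        for ref_idx, seq in enumerate(self.seqs):
            for strand_idx, s in enumerate((seq, revcomp(seq))):
                for pos in range(0, len(s) - k + 1):
                    self._table.setdefault(s[pos : pos + k], []).append(
                        (ref_idx, strand_idx, pos)
                    )

    def lookup(self, kmer: str) -> list[tuple[str, str, int]]:
        """Occurrences of ``kmer`` as (reference name, strand, strand-local pos)."""
        return [
            (self.names[r], "+-"[si], pos) for r, si, pos in self._table.get(kmer.upper(), ())
        ]

    def n_indexed(self, ref_name: str, strand: str) -> int:
        ref_idx = self.names.index(ref_name)
        si = 0 if strand == "+" else 1
        return sum(
            1 for entries in self._table.values() for r, s, _ in entries if r == ref_idx and s == si
        )


def build_index(references, k: int = 15) -> SeedIndex:
    return SeedIndex(references, k=k)


def _seed_offsets(read_len: int, k: int, step: int) -> range | list[int]:
    offsets = list(range(0, read_len - k + 1, step))
    tail = read_len - k
    if tail >= 0 and (not offsets or offsets[-1] != tail):
        offsets.append(tail)
    return offsets


def map_read(
    index: SeedIndex,
    seq: str,
    scoring: Scoring = Scoring(),
    seed_step: int = 5,
    pad: int = 8,
    read_id: str = "",
) -> list[AlignmentRecord]:
    """All candidate placements of one read, best first.

    Candidate loci are every (reference, strand, diagonal) sharing at least
    one exact seed with the read; each is scored by Smith-Waterman inside a
    window of the reference around the seeded diagonal.  A read with zero
    seed hits is unmapped (empty list).  Records are deduplicated by
    alignment end, sorted by (score desc, reference, strand, position), and
    annotated with the co-best count and the margin to the second-best
    distinct placement (margin = best score when there is no second).
    """
    seq = seq.upper()
    n = len(seq)
    k = index.k
    if n < k:
        return []
    read_enc = encode(seq)

    # gather seed diagonals per (ref, strand)
    diags: dict[tuple[int, int], set[int]] = {}
    for off in _seed_offsets(n, k, seed_step):
        for ref_idx, strand_idx, pos in index._table.get(seq[off : off + k], ()):
            diags.setdefault((ref_idx, strand_idx), set()).add(pos - off)

    raw: dict[tuple[int, int, int], tuple[int, int, int, int, int]] = {}
    for (ref_idx, strand_idx), dset in diags.items():
        ref_enc = index.fwd[ref_idx] if strand_idx == 0 else index.rev[ref_idx]
        m = len(ref_enc)
        # cluster nearby diagonals into shared windows
        ordered = sorted(dset)
        clusters: list[list[int]] = [[ordered[0]]]
        for d in ordered[1:]:
            if d - clusters[-1][-1] <= 2 * pad:
                clusters[-1].append(d)
            else:
                clusters.append([d])
        for cluster in clusters:
            lo = max(0, cluster[0] - pad)
            hi = min(m, cluster[-1] + n + pad)
            if hi <= lo:
                continue
            window = ref_enc[lo:hi]
            hit = _window_align(read_enc, window, scoring)
            if hit is None:
                continue
            s_score, s_qstart, s_qend, s_rstart, s_rend = hit
            key = (ref_idx, strand_idx, lo + s_rend)
            prev = raw.get(key)
            if prev is None or s_score > prev[0]:
                raw[key] = (s_score, s_qstart, s_qend, lo + s_rstart, lo + s_rend)

    records: list[AlignmentRecord] = []
    for (ref_idx, strand_idx, _), (score, qstart, qend, rstart, rend) in raw.items():
        m = len(index.seqs[ref_idx])
        if strand_idx == 0:
            start, end, strand = rstart, rend, "+"
        else:
            # coordinates on the reverse strand map back to forward
            start, end, strand = m - rend, m - rstart, "-"
        records.append(
            AlignmentRecord(
                read_id=read_id,
                ref=index.names[ref_idx],
                start=start,
                end=end,
                strand=strand,
                score=score,
                qstart=qstart,
                qend=qend,
                read_len=n,
            )
        )
    records = _merge_loci(records)
    records.sort(key=lambda r: (-r.score, r.ref, r.strand, r.start))
    if records:
        best = records[0].score
        n_cobest = sum(1 for r in records if r.score == best)
        margin = best - records[1].score if len(records) > 1 else best
        records = [replace(r, n_cobest=n_cobest, margin=margin) for r in records]
    return records


def _merge_loci(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Collapse overlapping placements on the same reference strand to one
    locus, keeping the best-scoring representative.

    Path-equivalent optima (e.g. a gap traded against mismatches) can end a
    few bases apart within one locus; they are a single placement for
    assignment purposes, not genuine multi-mapping.
    """
    records = sorted(records, key=lambda r: (r.ref, r.strand, r.start, r.end))
    merged: list[AlignmentRecord] = []
    for rec in records:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.ref == rec.ref
            and prev.strand == rec.strand
            and rec.start < prev.end
        ):
            if rec.score > prev.score:
                merged[-1] = rec
            continue
        merged.append(rec)
    return merged


def _window_align(read_enc: np.ndarray, window: np.ndarray, scoring: Scoring):
    """SW of read vs window; returns (score, qstart, qend, rstart, rend) or 0."""
    score, qend, rend = sw_best(read_enc, window, scoring.match, scoring.mismatch, scoring.gap)
    if score <= 0:
        return None
    # start coordinates via reverse alignment of the optimal prefix
    score2, qlen, rlen = sw_best(
        read_enc[:qend][::-1].copy(),
        window[:rend][::-1].copy(),
        scoring.match,
        scoring.mismatch,
        scoring.gap,
    )
    qstart, rstart = qend - qlen, rend - rlen
    return (score, qstart, qend, rstart, rend)


def call_uniqueness(records: Sequence[AlignmentRecord], min_margin: int = 1) -> UniquenessCall:
    """Unique iff exactly one co-best placement and margin >= ``min_margin``."""
    if not records:
        return UniquenessCall("unmapped")
    best = records[0]
    if best.n_cobest == 1 and best.margin >= min_margin:
        return UniquenessCall("unique", best)
    return UniquenessCall("multi", best)


def map_reads(
    index: SeedIndex,
    reads: Iterable[tuple[str, str] | tuple[str, str, str]],
    scoring: Scoring = Scoring(),
    min_margin: int = 1,
    seed_step: int = 5,
) -> list[UniquenessCall]:
    """Map a batch of (id, seq[, qual]) reads and call uniqueness for each."""
    calls = []
    for read in reads:
        read_id, seq = read[0], read[1]
        records = map_read(index, seq, scoring=scoring, seed_step=seed_step, read_id=read_id)
        calls.append(call_uniqueness(records, min_margin=min_margin))
    return calls


# ---------------------------------------------------------------------------
# SAM interoperability
# ---------------------------------------------------------------------------


def write_sam(
    calls: Sequence[UniquenessCall],
    reads: Sequence[tuple[str, str] | tuple[str, str, str]],
    references: Mapping[str, str] | Mapping[str, int],
    path,
) -> None:
    """Write one primary record per read (mapped or unmapped) as plain SAM.

    ``calls`` and ``reads`` must be parallel (one call per read, same
    order).  Multi-mapping is encoded in the NH tag (number of co-best
    placements), the alignment score in AS; MAPQ is 60 for unique calls and
    1 otherwise.
    """
    import pysam

    if len(calls) != len(reads):
        raise ValidationError("calls and reads must be parallel sequences")
    lengths = {
        name: (len(v) if isinstance(v, str) else int(v)) for name, v in references.items()
    }
    names = sorted(lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": lengths[name]} for name in names],
    }
    ref_id = {name: i for i, name in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for call, read in zip(calls, reads):
            rec = call.record
            read_id, seq = read[0], read[1]
            a = pysam.AlignedSegment(out.header)
            if call.status == "unmapped" or rec is None:
                a.query_name = read_id
                a.is_unmapped = True
                a.query_sequence = seq
                out.write(a)
                continue
            a.query_name = rec.read_id
            a.reference_id = ref_id[rec.ref]
            a.reference_start = rec.start
            a.mapping_quality = 60 if (rec.n_cobest == 1 and rec.margin >= 1) else 1
            a.is_reverse = rec.strand == "-"
            oriented = seq if rec.strand == "+" else revcomp(seq)
            a.query_sequence = oriented
            # soft clips flip orientation with the read
            lead = rec.qstart if rec.strand == "+" else rec.read_len - rec.qend
            trail = rec.read_len - rec.qend if rec.strand == "+" else rec.qstart
            ref_span = rec.end - rec.start
            read_span = rec.qend - rec.qstart
            cigar = []
            if lead:
                cigar.append((4, lead))
            matched = min(ref_span, read_span)
            if matched:
                cigar.append((0, matched))
            if ref_span > matched:
                cigar.append((2, ref_span - matched))
            elif read_span > matched:
                cigar.append((1, read_span - matched))
            if trail:
                cigar.append((4, trail))
            a.cigartuples = cigar
            a.set_tag("NH", rec.n_cobest)
            a.set_tag("AS", rec.score)
            out.write(a)


def default_sam_uniqueness(aln) -> bool:
    """Default uniqueness policy for external SAM: NH == 1 when present,
    otherwise MAPQ >= 30 (covers both the NH and MAPQ multi-mapper dialects)."""
    if aln.has_tag("NH"):
        return aln.get_tag("NH") == 1
    return aln.mapping_quality >= 30


def read_sam(
    path, uniqueness_policy: Optional[Callable] = None
) -> tuple[list[AlignmentRecord], list[UniquenessCall]]:
    """Ingest externally produced SAM/BAM as records + uniqueness calls.

    Primary alignments only; coordinates converted to the internal 0-based
    half-open convention (pysam already exposes them that way).
    """
    import pysam

    if uniqueness_policy is None:
        uniqueness_policy = default_sam_uniqueness
    records: list[AlignmentRecord] = []
    calls: list[UniquenessCall] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        if not fh.header.get("SQ"):
            raise ValidationError(f"{path}: SAM lacks a sequence header (@SQ lines)")
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_unmapped:
                calls.append(UniquenessCall("unmapped"))
                continue
            if aln.reference_start is None or aln.reference_name is None:
                raise ValidationError(f"{path}: mapped record without coordinates")
            n_cobest = aln.get_tag("NH") if aln.has_tag("NH") else None
            unique = bool(uniqueness_policy(aln))
            rec = AlignmentRecord(
                read_id=aln.query_name,
                ref=aln.reference_name,
                start=aln.reference_start,
                end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                score=int(aln.get_tag("AS")) if aln.has_tag("AS") else 0,
                read_len=aln.query_length,
                n_cobest=int(n_cobest) if n_cobest is not None else (1 if unique else 2),
                margin=1 if unique else 0,
            )
            records.append(rec)
            calls.append(UniquenessCall("unique" if unique else "multi", rec))
    return records, calls
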