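"""Homeolog pairs by reciprocal best hit and A-B-D triad assembly.

Homeolog pairs between two subgenomes are reciprocal best hits (RBH) of a
local-alignment search between their transcript sets; triads are AB pairs
whose members point to the same D partner in the AD and BD pair sets.  The
search is a desk-scale homology scan: a shared-k-mer prefilter proposes
candidate targets, and a banded affine Smith-Waterman (match +1,
mismatch -1, gap open -2, gap extend -1) scores them.  Homeologs are
near-globally colinear, so the banded score is the relevant one; unrelated
sequences stay below the significance floor and are rejected.

Score ties at the best-hit level disqualify the query from RBH: a tie means
there is no unique "best", and conservative rejection prevents arbitrary
pairings.  Genes without a qualifying partner remain subgenome-specific
singletons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional

import pandas as pd

from polyhomeo3._align_core import banded_affine_score, encode
from polyhomeo3.errors import ValidationError


class Triad(NamedTuple):
    a: str
    b: str
    d: str


@dataclass(frozen=True)
class HomologyParams:
    k: int = 12  # prefilter k-mer length
    band: int = 20  # alignment band half-width (bases)
    match: int = 1
    mismatch: int = -1
    gap_open: int = 2  # penalty of the first gap base
    gap_extend: int = 1  # penalty per additional gap base
    min_score: int = 100  # significance floor; best hits below it are rejected


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1)}


def align_transcripts(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    params: HomologyParams = HomologyParams(),
    prefilter: bool = True,
) -> pd.DataFrame:
    """Score every query against candidate targets; returns a hit table.

    Candidates are targets sharing at least one exact ``params.k``-mer with
    the query (or all targets if ``prefilter`` is False).  The returned
    DataFrame has columns ``query, target, score`` and keeps only hits at or
    above the significance floor.
    """
    if not queries or not targets:
        raise ValidationError("query and target sets must be non-empty")
    for name, seq in list(queries.items()) + list(targets.items()):
        if not seq:
            raise ValidationError(f"empty sequence for {name!r}")

    enc_targets = {tid: encode(seq.upper()) for tid, seq in targets.items()}
    if prefilter:
        kmer_index: dict[str, set[str]] = {}
        for tid, seq in targets.items():
            for kmer in _kmers(seq.upper(), params.k):
                kmer_index.setdefault(kmer, set()).add(tid)

    rows = []
    for qid in sorted(queries):
        qseq = queries[qid].upper()
        qenc = encode(qseq)
        if prefilter:
            candidates: set[str] = set()
            for kmer in _kmers(qseq, params.k):
                candidates |= kmer_index.get(kmer, set())
        else:
            candidates = set(targets)
        for tid in sorted(candidates):
            score = int(
                banded_affine_score(
                    qenc,
                    enc_targets[tid],
                    params.band,
                    params.match,
                    params.mismatch,
                    params.gap_open,
                    params.gap_extend,
                )
            )
            if score >= params.min_score:
                rows.append((qid, tid, score))
    return pd.DataFrame(rows, columns=["query", "target", "score"])


def best_hits(hits: pd.DataFrame) -> dict[str, Optional[str]]:
    """Best target per query; ties map to None (query disqualified)."""
    out: dict[str, Optional[str]] = {}
    for qid, grp in hits.groupby("query"):
        top = grp["score"].max()
        winners = sorted(grp.loc[grp["score"] == top, "target"])
        out[str(qid)] = winners[0] if len(winners) == 1 else None
    return out


def reciprocal_best_hits(fwd: pd.DataFrame, rev: pd.DataFrame) -> set[tuple[str, str]]:
    """Pairs (x, y) with best(fwd, x) = y and best(rev, y) = x.

    ``fwd`` scores set-1 queries against set-2 targets; ``rev`` the reverse
    direction.  Tied queries (no unique best) never pair.
    """
    fb = best_hits(fwd)
    rb = best_hits(rev)
    pairs = set()
    for x, y in fb.items():
        if y is not None and rb.get(y) == x:
            pairs.add((x, y))
    return pairs


def build_triads(
    ab_pairs: set[tuple[str, str]],
    ad_pairs: set[tuple[str, str]],
    bd_pairs: set[tuple[str, str]],
) -> list[Triad]:
    """Assemble triads: (a, b, d) iff (a, b) in AB, (a, d) in AD and (b, d)
    in BD for the same d (the shared-D rule)."""
    ad = dict(ad_pairs)
    bd = dict(bd_pairs)
    triads = []
    for a, b in sorted(ab_pairs):
        d = ad.get(a)
        if d is not None and bd.get(b) == d:
            triads.append(Triad(a, b, d))
    seen: set[str] = set()
    for t in triads:
        for g in t:
            if g in seen:
                raise ValidationError(f"gene {g!r} occurs in more than one triad")
            seen.add(g)
    return triads


def triads_from_transcripts(
    transcripts: Mapping[str, Mapping[str, str]],
    params: HomologyParams = HomologyParams(),
    subgenomes: tuple[str, str, str] = ("A", "B", "D"),
) -> list[Triad]:
    """Convenience: full RBH + shared-D construction from three transcript sets."""
    a, b, d = subgenomes
    pair_sets = {}
    for x, y in ((a, b), (a, d), (b, d)):
        fwd = align_transcripts(transcripts[x], transcripts[y], params)
        rev = align_transcripts(transcripts[y], transcripts[x], params)
        pair_sets[(x, y)] = reciprocal_best_hits(fwd, rev)
    return build_triads(pair_sets[(a, b)], pair_sets[(a, d)], pair_sets[(b, d)])


def write_triads(triads: list[Triad], path) -> None:
    pd.DataFrame(triads, columns=["a_id", "b_id", "d_id"]).to_csv(path, sep="\t", index=False)


def read_triads(path) -> list[Triad]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [Triad(*row) for row in df.itertuples(index=False)]
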