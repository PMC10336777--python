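"""Mapper contracts: index completeness, exact and ambiguous placement,
uniqueness calls, strand handling, SAM round trips, and agreement of the
windowed alignment with independent oracles (a from-scratch full
Smith-Waterman and Biopython's PairwiseAligner)."""

import numpy as np
import pytest

from polyhomeo3 import aligner, sim
from polyhomeo3.aligner import (
    Scoring,
    build_index,
    call_uniqueness,
    map_read,
    map_reads,
    read_sam,
    revcomp,
    write_sam,
)
from polyhomeo3.errors import ValidationError


def sw_matrix(read: str, ref: str, match=1, mismatch=-1, gap=-2) -> np.ndarray:
    """Full Smith-Waterman score matrix, linear gaps (oracle; vectorized per
    row with a running-maximum unrolling of the horizontal recurrence)."""
    r = np.frombuffer(read.encode(), np.uint8)
    f = np.frombuffer(ref.encode(), np.uint8)
    n, m = len(r), len(f)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    sub = np.where(f[None, :] == r[:, None], match, mismatch)
    j2 = -gap * np.arange(1, m + 1)  # gap is negative; -gap*j grows
    for i in range(1, n + 1):
        C = np.maximum(H[i - 1, :-1] + sub[i - 1], H[i - 1, 1:] + gap)
        C = np.maximum(C, 0)
        H[i, 1:] = np.maximum(np.maximum.accumulate(C + j2) - j2, 0)
    return H


def sw_tiny(read, ref, match=1, mismatch=-1, gap=-2):
    """Textbook cell-by-cell SW (second, independent formulation)."""
    n, m = len(read), len(ref)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if read[i - 1] == ref[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
            best = max(best, H[i][j])
    return best, H


class TestOracleSelfConsistency:
    def test_vectorized_matrix_equals_textbook_dp(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            read = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 25)))
            ref = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 60)))
            best, H = sw_tiny(read, ref)
            Hv = sw_matrix(read, ref)
            assert np.array_equal(np.array(H), Hv)
            assert Hv.max() == best

    def test_oracle_agrees_with_biopython_local_aligner(self):
        from Bio.Align import PairwiseAligner

        pa = PairwiseAligner(
            mode="local", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-2,
        )
        rng = np.random.default_rng(1)
        for _ in range(20):
            read = "".join(rng.choice(list("ACGT"), size=30))
            ref = "".join(rng.choice(list("ACGT"), size=120))
            assert sw_matrix(read, ref).max() == pa.score(ref, read)


class TestBuildIndex:
    def test_positions_per_strand(self):
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), size=100))
        idx = build_index({"r1": seq}, k=15)
        assert idx.n_indexed("r1", "+") == 86
        assert idx.n_indexed("r1", "-") == 86

    def test_duplicate_names_rejected_but_duplicate_sequences_allowed(self):
        with pytest.raises(ValidationError):
            build_index([("r1", "ACGT" * 10), ("r1", "ACGT" * 10)], k=8)
        idx = build_index([("r1", "ACGT" * 10), ("r2", "ACGT" * 10)], k=8)
        assert set(idx.names) == {"r1", "r2"}

    def test_every_indexed_kmer_recovers_its_position(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        k = 15
        idx = build_index({"r1": seq}, k=k)
        for pos in range(0, len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            assert ("r1", "+", pos) in idx.lookup(kmer)

    def test_small_k_rejected(self):
        with pytest.raises(ValidationError):
            build_index({"r": "ACGTACGTACGT"}, k=4)


@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(7)
    return {
        "chr1A": "".join(rng.choice(list("ACGT"), size=2000)),
        "chr1B": "".join(rng.choice(list("ACGT"), size=2000)),
    }


@pytest.fixture(scope="module")
def index(refs):
    return build_index(refs)


class TestMapRead:
    def test_verbatim_read_maps_exactly(self, refs, index):
        read = refs["chr1A"][500:600]
        records = map_read(index, read)
        best = records[0]
        assert (best.ref, best.strand, best.start, best.end) == ("chr1A", "+", 500, 600)
        assert best.score == 100
        assert best.n_cobest == 1

    def test_reverse_complement_read_maps_minus_strand(self, refs, index):
        read = revcomp(refs["chr1A"][700:800])
        best = map_read(index, read)[0]
        assert (best.ref, best.strand, best.start, best.end) == ("chr1A", "-", 700, 800)
        assert best.score == 100

    def test_planted_duplicate_gives_two_cobest(self, refs):
        shared = refs["chr1A"][100:220]
        refs2 = {
            "chr1A": refs["chr1A"],
            "chr1B": refs["chr1B"][:900] + shared + refs["chr1B"][1020:],
        }
        index = build_index(refs2)
        records = map_read(index, shared[10:110])
        assert records[0].n_cobest == 2
        assert {r.ref for r in records[: records[0].n_cobest]} == {"chr1A", "chr1B"}
        assert call_uniqueness(records).status == "multi"

    def test_mismatched_read_scores_match_minus_mismatches(self, refs, index):
        read = list(refs["chr1A"][300:400])
        read[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[50]]
        best = map_read(index, "".join(read))[0]
        assert best.score == 98  # 99 matches - 1 mismatch

    def test_no_seed_hits_is_unmapped(self, index):
        records = map_read(index, "A" * 40)
        assert call_uniqueness(records).status == "unmapped"

    def test_short_read_unmapped(self, index):
        assert map_read(index, "ACGT") == []

    def test_margin_sweep_monotone(self, small_genomes, small_index):
        reads, _ = sim.simulate_3prime_reads(
            small_genomes, sim.ReadSimConfig(n_reads=300, polya_len=0, seed=31)
        )
        records_per_read = [map_read(small_index, seq) for _, seq, _ in reads]
        uniques = []
        for margin in (1, 3, 6, 10):
            uniques.append(
                sum(
                    call_uniqueness(r, min_margin=margin).status == "unique"
                    for r in records_per_read
                )
            )
        assert all(a >= b for a, b in zip(uniques, uniques[1:]))

    def test_deterministic_tie_order(self, refs):
        shared = refs["chr1A"][100:220]
        refs2 = {"chr1A": refs["chr1A"], "chr1B": refs["chr1B"][:900] + shared + refs["chr1B"][1020:]}
        index = build_index(refs2)
        r1 = map_read(index, shared[10:110])
        r2 = map_read(index, shared[10:110])
        assert [(r.ref, r.strand, r.start) for r in r1] == [
            (r.ref, r.strand, r.start) for r in r2
        ]
        assert r1[0].ref == "chr1A"  # reference-name order breaks the tie


def cluster_ends(ends, gap=50):
    """Group co-optimal end cells into loci: path-equivalent optima sit a few
    bases apart; genuinely distinct loci are far apart."""
    clusters = []
    for name, strand, j in sorted(ends):
        if clusters and clusters[-1][0] == (name, strand) and j - clusters[-1][1][-1] <= gap:
            clusters[-1][1].append(j)
        else:
            clusters.append([(name, strand), [j]])
    return clusters


class TestWindowedAlignmentVsOracle:
    def test_simulated_reads_match_full_scan(self, small_genomes, small_index):
        # 60 reads with errors and indel-bearing UTRs: best score and the set
        # of co-best loci must equal the exhaustive matrix scan
        reads, _ = sim.simulate_3prime_reads(
            small_genomes,
            sim.ReadSimConfig(n_reads=60, polya_len=5, error_rate=0.01, seed=33),
        )
        refs = small_genomes.references
        for _, seq, _ in reads:
            records = map_read(small_index, seq)
            oracle_best = 0
            oracle_ends = set()
            for name, ref in refs.items():
                for strand, target in (("+", ref), ("-", revcomp(ref))):
                    H = sw_matrix(seq, target)
                    top = int(H.max())
                    if top > oracle_best:
                        oracle_best, oracle_ends = top, set()
                    if top == oracle_best:
                        rows, cols = np.nonzero(H == top)
                        oracle_ends |= {(name, strand, int(j)) for j in cols}
            assert records, "read unexpectedly unmapped"
            best = records[0]
            assert best.score == oracle_best
            clusters = cluster_ends(oracle_ends)
            cobest = [r for r in records if r.score == best.score]
            assert len(cobest) == len(clusters)
            for r in cobest:
                end = r.end if r.strand == "+" else len(refs[r.ref]) - r.start
                assert any(
                    key == (r.ref, r.strand) and min(js) - 50 <= end <= max(js) + 50
                    for key, js in clusters
                )


class TestSamRoundTrip:
    def test_uniqueness_calls_survive_round_trip(self, small_genomes, small_index, tmp_path):
        reads, _ = sim.simulate_3prime_reads(
            small_genomes, sim.ReadSimConfig(n_reads=150, seed=35)
        )
        calls = map_reads(small_index, reads)
        path = tmp_path / "out.sam"
        write_sam(calls, reads, small_genomes.references, path)
        _, calls2 = read_sam(path)
        assert [c.status for c in calls2] == [c.status for c in calls]
        for a, b in zip(calls, calls2):
            if a.status == "unique":
                assert (a.record.ref, a.record.strand, a.record.start) == (
                    b.record.ref,
                    b.record.strand,
                    b.record.start,
                )

    def test_nh_tag_policy(self, tmp_path):
        path = tmp_path / "t.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1A\tLN:1000\n"
            "r1\t0\tchr1A\t10\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tNH:i:1\n"
            "r2\t0\tchr1A\t50\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tNH:i:3\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 20 + "\t*\n"
            "r4\t0\tchr1A\t90\t7\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\n"
        )
        _, calls = read_sam(path)
        assert [c.status for c in calls] == ["unique", "multi", "unmapped", "multi"]
        # r4 has no NH tag: MAPQ >= 30 rule applies
        path2 = tmp_path / "t2.sam"
        path2.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1A\tLN:1000\n"
            "r4\t0\tchr1A\t90\t44\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\n"
        )
        _, calls2 = read_sam(path2)
        assert calls2[0].status == "unique"

    def test_headerless_sam_rejected(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text("r1\t0\tchr1A\t10\t60\t20M\t*\t0\t0\tACGT\t*\n")
        with pytest.raises(Exception):
            read_sam(path)
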