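"""Strand-specific counting vs a naive double-loop oracle, annotation-change
comparison, CPM/TPM identities, log-correlation and ternary fractions."""

import random

import numpy as np
import pandas as pd
import pytest

from polyhomeo3.aligner import AlignmentRecord
from polyhomeo3.annotation import GeneModel
from polyhomeo3.errors import (
    ConfigurationError,
    UndefinedStatisticError,
    ValidationError,
)
from polyhomeo3.expression import (
    CountTable,
    compare_annotations,
    count_reads,
    cpm,
    log_correlation,
    ternary_fractions,
    tpm,
)
from polyhomeo3.triads import Triad

FLIP = {"+": "-", "-": "+"}


def oracle_count(records, genes, stranded="sense"):
    """Naive per-read x per-gene double loop (independent re-derivation)."""
    counts = {g.gene_id: 0 for g in genes}
    cats = {"assigned": 0, "no_feature": 0, "ambiguous_feature": 0}
    for rec in records:
        want = rec.strand if stranded == "sense" else FLIP[rec.strand]
        hits = set()
        for g in genes:
            if g.chrom != rec.ref or g.strand != want:
                continue
            # 1-based read interval [start+1, end] vs gene [start, end]
            if rec.start + 1 <= g.end and rec.end >= g.start:
                hits.add(g.gene_id)
        if not hits:
            cats["no_feature"] += 1
        elif len(hits) == 1:
            cats["assigned"] += 1
            counts[hits.pop()] += 1
        else:
            cats["ambiguous_feature"] += 1
    return counts, cats


def _rec(ref, start, end, strand, rid="r"):
    return AlignmentRecord(rid, ref, start, end, strand, end - start)


class TestCountReads:
    GENES = [
        GeneModel("plus1", "chr1A", "+", 101, 200),
        GeneModel("minus1", "chr1A", "-", 151, 260),
        GeneModel("plus2", "chr1A", "+", 221, 320),
    ]

    def test_read_inside_one_gene(self):
        t = count_reads([_rec("chr1A", 110, 150, "+")], self.GENES)
        assert t.counts["plus1"] == 1
        assert t.categories["assigned"] == 1

    def test_opposite_strand_overlap_resolved_by_strand(self):
        # read overlaps both a '+' and a '-' gene; strand decides, no ambiguity
        t = count_reads([_rec("chr1A", 160, 199, "+")], self.GENES)
        assert t.counts["plus1"] == 1
        assert t.counts["minus1"] == 0
        t = count_reads([_rec("chr1A", 160, 199, "-")], self.GENES)
        assert t.counts["minus1"] == 1

    def test_two_same_strand_genes_is_ambiguous(self):
        t = count_reads([_rec("chr1A", 190, 230, "+")], self.GENES)
        assert t.categories["ambiguous_feature"] == 1
        assert t.counts.sum() == 0

    def test_no_overlap_is_no_feature(self):
        t = count_reads([_rec("chr1A", 500, 560, "+")], self.GENES)
        assert t.categories["no_feature"] == 1

    def test_reverse_stranded_mode_flips(self):
        t = count_reads([_rec("chr1A", 160, 199, "-")], self.GENES, stranded="reverse")
        assert t.counts["plus1"] == 1

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ConfigurationError):
            count_reads([_rec("chrZ", 0, 10, "+")], self.GENES)

    def test_category_conservation(self):
        recs = [_rec("chr1A", s, s + 40, st) for s in range(0, 400, 13) for st in "+-"]
        t = count_reads(recs, self.GENES, n_non_unique=7)
        assert t.n_unique_reads == len(recs)
        assert t.categories["non_unique"] == 7

    def test_matches_double_loop_oracle_on_random_layouts(self):
        rng = random.Random(77)
        for layout in range(8):
            genes = []
            for i in range(rng.randint(3, 14)):
                start = rng.randint(1, 2000)
                end = start + rng.randint(10, 400)  # nested/adjacent happen freely
                genes.append(
                    GeneModel(f"g{i}", rng.choice(["chr1A", "chr1B"]),
                              rng.choice("+-"), start, end)
                )
            recs = []
            for j in range(500):
                s = rng.randint(0, 2400)
                recs.append(_rec(rng.choice(["chr1A", "chr1B"]), s,
                                 s + rng.randint(1, 120), rng.choice("+-"), f"r{j}"))
            table = count_reads(recs, genes)
            oc, ocats = oracle_count(recs, genes)
            assert dict(table.counts) == oc
            assert {k: table.categories[k] for k in ocats} == ocats


class TestCompareAnnotations:
    def _table(self, counts, no_feature=0, ambiguous=0):
        s = pd.Series(counts)
        return CountTable(
            counts=s,
            categories={
                "assigned": int(s.sum()),
                "no_feature": no_feature,
                "ambiguous_feature": ambiguous,
                "non_unique": 0,
            },
        )

    def test_identical_tables_all_same(self):
        a = self._table({"g1": 3, "g2": 0}, no_feature=2)
        b = self._table({"g1": 3, "g2": 0}, no_feature=2)
        rep = compare_annotations(a, b)
        assert rep["n_same"] == 2 and rep["n_increased"] == 0 and rep["n_decreased"] == 0
        assert rep["assigned_fraction_delta"] == 0

    def test_gains_and_losses_classified(self):
        base = self._table({"g1": 3, "g2": 5, "g3": 0}, no_feature=4)
        ext = self._table({"g1": 6, "g2": 4, "g3": 0}, no_feature=2)
        rep = compare_annotations(base, ext)
        assert rep["classes"]["g1"] == "increased"
        assert rep["classes"]["g2"] == "decreased"
        assert rep["classes"]["g3"] == "same"
        assert rep["no_feature_delta"] == -2

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValidationError):
            compare_annotations(self._table({"g1": 1}), self._table({"g2": 1}))


class TestNormalization:
    def test_cpm_arithmetic(self):
        s = pd.Series({"g1": 1, "g2": 1, "g3": 2})
        out = cpm(s)
        assert out.tolist() == [250_000.0, 250_000.0, 500_000.0]

    def test_cpm_scale_invariance_and_identity(self):
        rng = np.random.default_rng(60)
        s = pd.Series(rng.integers(0, 50, size=30), index=[f"g{i}" for i in range(30)])
        s.iloc[0] = 5
        pd.testing.assert_series_equal(cpm(s), cpm(s * 7))
        assert cpm(s).sum() == pytest.approx(1e6, rel=1e-9)

    def test_cpm_zero_total_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cpm(pd.Series({"g1": 0}))

    def test_tpm_arithmetic(self):
        s = pd.Series({"g1": 10, "g2": 10})
        out = tpm(s, {"g1": 100, "g2": 200})
        assert out["g1"] == pytest.approx(2e6 / 3)
        assert out["g2"] == pytest.approx(1e6 / 3)
        assert out.sum() == pytest.approx(1e6)

    def test_tpm_equal_counts_equal_lengths(self):
        s = pd.Series({"g1": 4, "g2": 4})
        out = tpm(s, {"g1": 500, "g2": 500})
        assert out["g1"] == out["g2"] == pytest.approx(5e5)

    def test_tpm_missing_length_rejected(self):
        with pytest.raises(ValidationError):
            tpm(pd.Series({"g1": 1}), {})


class TestLogCorrelation:
    def test_self_correlation_is_one(self):
        x = pd.Series({"g1": 10.0, "g2": 100.0, "g3": 7.0, "g4": 0.0})
        r, n = log_correlation(x, x)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert n == 3  # the zero gene is filtered out

    def test_scaling_preserves_correlation(self):
        rng = np.random.default_rng(61)
        x = pd.Series(rng.lognormal(2, 1, size=50), index=[f"g{i}" for i in range(50)])
        r, _ = log_correlation(x, 13.0 * x)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(62)
        idx = [f"g{i}" for i in range(200)]
        x = pd.Series(rng.lognormal(1, 1, size=200), index=idx)
        y = pd.Series(rng.lognormal(1, 1, size=200), index=idx)
        r, n = log_correlation(x, y)
        lx, ly = np.log10(x), np.log10(y)
        num = ((lx - lx.mean()) * (ly - ly.mean())).sum()
        den = np.sqrt(((lx - lx.mean()) ** 2).sum() * ((ly - ly.mean()) ** 2).sum())
        assert n == 200
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_too_few_genes_undefined(self):
        x = pd.Series({"g1": 1.0, "g2": 2.0})
        with pytest.raises(UndefinedStatisticError):
            log_correlation(x, x)


class TestTernaryFractions:
    TRIADS = [Triad("a1", "b1", "d1"), Triad("a2", "b2", "d2")]

    def test_balance_and_vertex(self):
        counts = {"a1": 10, "b1": 10, "d1": 10, "a2": 5, "b2": 0, "d2": 0}
        df, omitted = ternary_fractions(self.TRIADS, counts)
        assert omitted == 0
        assert df.loc[0, ["fA", "fB", "fD"]].tolist() == pytest.approx([1 / 3] * 3)
        assert df.loc[1, ["fA", "fB", "fD"]].tolist() == [1.0, 0.0, 0.0]

    def test_all_zero_triad_omitted_with_tally(self):
        counts = {"a1": 1, "b1": 0, "d1": 0, "a2": 0, "b2": 0, "d2": 0}
        df, omitted = ternary_fractions(self.TRIADS, counts)
        assert len(df) == 1 and omitted == 1

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(63)
        counts = {g: int(c) for g, c in zip(
            [g for t in self.TRIADS for g in t], rng.integers(1, 100, 6)
        )}
        df, _ = ternary_fractions(self.TRIADS, counts)
        assert np.allclose(df[["fA", "fB", "fD"]].sum(axis=1), 1.0)
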