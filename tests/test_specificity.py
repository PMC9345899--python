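import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    fisher_two_sided_enumeration,
    mann_whitney_exact_enumeration,
    paired_t_p,
)
from tsrdiv.errors import DegenerateVarianceError, DesignError, ValidationError
from tsrdiv.specificity import (
    SampleGroupDesign,
    classify_population_specific,
    enrichment_odds_ratio,
    geneset_fractions,
    leave_one_out_specificity,
    mann_whitney_u,
    misinitiation_rates,
    odds_ratio_ci,
    paired_t_test,
    tsrs_per_gene,
)
from tsrdiv.tsr import TsrAnnotationRecord


def design_5x5() -> SampleGroupDesign:
    assignments = {}
    for i in range(1, 6):
        assignments[f"hi_{i}"] = ("hi", f"ind_{i}")
        assignments[f"lo_{i}"] = ("lo", f"ind_{i}")
    return SampleGroupDesign(assignments)


def presence_row(hi, lo):
    cols = [f"hi_{i}" for i in range(1, 6)] + [f"lo_{i}" for i in range(1, 6)]
    return pd.DataFrame([list(hi) + list(lo)], index=["t"], columns=cols).astype(bool)


class TestClassify:
    @pytest.mark.parametrize(
        "hi,lo,expected",
        [
            ((1, 1, 1, 0, 0), (0, 0, 0, 0, 0), "hi_specific"),
            ((1, 0, 0, 0, 0), (0, 0, 0, 0, 0), "unreplicated"),
            ((1, 1, 0, 0, 0), (1, 0, 0, 0, 0), "shared"),
            ((0, 0, 0, 0, 0), (1, 1, 0, 0, 0), "lo_specific"),
            ((0, 0, 0, 0, 0), (0, 0, 0, 0, 0), "unreplicated"),
            ((1, 1, 1, 1, 1), (1, 1, 1, 1, 1), "shared"),
        ],
    )
    def test_rule(self, hi, lo, expected):
        labels = classify_population_specific(presence_row(hi, lo), design_5x5())
        assert labels["t"] == expected

    def test_labels_partition(self):
        gen = np.random.default_rng(0)
        pres = pd.DataFrame(
            gen.random((200, 10)) < 0.4,
            columns=[f"hi_{i}" for i in range(1, 6)] + [f"lo_{i}" for i in range(1, 6)],
        )
        labels = classify_population_specific(pres, design_5x5())
        assert set(labels.unique()) <= {
            "hi_specific", "lo_specific", "shared", "unreplicated"
        }
        # hi_specific & any lo presence impossible
        lo_cols = [f"lo_{i}" for i in range(1, 6)]
        assert not pres.loc[labels == "hi_specific", lo_cols].any(axis=None)

    def test_small_group_rejected(self):
        design = SampleGroupDesign(
            {"hi_1": ("hi", "a"), "lo_1": ("lo", "a"), "lo_2": ("lo", "b")}
        )
        pres = pd.DataFrame(
            [[True, True, True]], columns=["hi_1", "lo_1", "lo_2"], index=["t"]
        )
        with pytest.raises(DesignError):
            classify_population_specific(pres, design)

    def test_duplicate_individual_in_group_rejected(self):
        with pytest.raises(DesignError):
            SampleGroupDesign({"a": ("hi", "x"), "b": ("hi", "x")})


class TestPairedT:
    def test_worked_example(self):
        t, df, p = paired_t_test([0, 0, 0, 0, 0], [100, 100, 100, 0, 0])
        assert t == pytest.approx(2.449, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0705, abs=5e-4)
        assert round(p, 2) == 0.07

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateVarianceError):
            paired_t_test([1.0, 2.0], [1.0, 2.0])

    def test_symmetric_n2(self):
        t, df, p = paired_t_test([0.0, 0.0], [1.0, -1.0])
        assert t == 0.0
        assert df == 1
        assert p == 1.0

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        st.integers(0, 1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_and_oracle(self, xs, seed):
        gen = np.random.default_rng(seed)
        ys = [x + float(gen.normal()) for x in xs]
        if np.std(np.subtract(ys, xs), ddof=1) == 0:
            return
        t1, _, p1 = paired_t_test(xs, ys)
        t2, _, p2 = paired_t_test(ys, xs)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        assert p1 == pytest.approx(paired_t_p(xs, ys))


class TestFisherEnrichment:
    def labels_and_membership(self, a, b, c, d):
        ids = [f"t{i}" for i in range(a + b + c + d)]
        labels = pd.Series(
            ["hi_specific"] * (a + b) + ["lo_specific"] * (c + d), index=ids
        )
        member = pd.Series([True] * a + [False] * b + [True] * c + [False] * d,
                           index=ids)
        return labels, member

    def test_20_80_10_90(self):
        labels, member = self.labels_and_membership(20, 80, 10, 90)
        res = enrichment_odds_ratio(labels, member)
        assert res.table == (20, 80, 10, 90)
        assert res.odds_ratio == pytest.approx(2.25)
        assert res.p == pytest.approx(fisher_two_sided_enumeration(20, 80, 10, 90),
                                      rel=1e-9)
        assert res.ci_low < 2.25 < res.ci_high

    def test_1_0_0_1_haldane(self):
        labels, member = self.labels_and_membership(1, 0, 0, 1)
        res = enrichment_odds_ratio(labels, member)
        assert res.p == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(9.0)  # (1.5*1.5)/(0.5*0.5)

    def test_symmetric_table(self):
        labels, member = self.labels_and_membership(5, 5, 5, 5)
        res = enrichment_odds_ratio(labels, member)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_swap_groups_inverts_or(self):
        labels, member = self.labels_and_membership(12, 8, 5, 15)
        res = enrichment_odds_ratio(labels, member)
        swapped = labels.map(
            {"hi_specific": "lo_specific", "lo_specific": "hi_specific"}
        )
        res2 = enrichment_odds_ratio(swapped, member)
        assert res2.odds_ratio == pytest.approx(1 / res.odds_ratio)
        assert res2.p == pytest.approx(res.p)

    def test_empty_specific_set_rejected(self):
        labels = pd.Series(["hi_specific", "shared"], index=["a", "b"])
        member = pd.Series([True, False], index=["a", "b"])
        with pytest.raises(ValidationError):
            enrichment_odds_ratio(labels, member)

    @given(st.tuples(*[st.integers(1, 25)] * 4))
    @settings(max_examples=30, deadline=None)
    def test_p_matches_enumeration(self, table):
        a, b, c, d = table
        labels, member = self.labels_and_membership(a, b, c, d)
        res = enrichment_odds_ratio(labels, member)
        assert res.p == pytest.approx(
            fisher_two_sided_enumeration(a, b, c, d), rel=1e-6
        )

    def test_ci_contains_or_when_no_zero_cell(self):
        _, lo, hi = odds_ratio_ci((20, 80, 10, 90))
        assert lo <= 2.25 <= hi


class TestMannWhitney:
    def test_separated_groups(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_multisets(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_with_ties(self):
        x, y = [1, 1, 2, 5], [2, 2, 3, 3, 9]
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(mann_whitney_exact_enumeration(x, y), rel=1e-9)

    def test_large_n_uses_approximation(self):
        gen = np.random.default_rng(0)
        x = gen.normal(0, 1, 40)
        y = gen.normal(0.5, 1, 40)
        _, p = mann_whitney_u(x, y)
        assert 0 < p < 1


def make_annotation(genes, categories=None):
    categories = categories or {}
    return {
        tid: TsrAnnotationRecord(
            tsr_id=tid,
            category=categories.get(tid, "promoter"),
            nearest_gene_id=g,
            distance_to_tss=0,
        )
        for tid, g in genes.items()
    }


class TestGenesetFractions:
    def setup_case(self):
        design = design_5x5()
        ids = [f"t{i}" for i in range(10)]
        labels = pd.Series("hi_specific", index=ids)
        labels.iloc[5:] = "lo_specific"
        cols = design.samples("hi") + design.samples("lo")
        pres = pd.DataFrame(False, index=ids, columns=cols)
        pres.loc[ids[:5], design.samples("hi")] = True
        pres.loc[ids[5:], design.samples("lo")] = True
        annotation = make_annotation({tid: f"g{i}" for i, tid in enumerate(ids)})
        return design, labels, pres, annotation

    def test_fraction_value(self):
        design, labels, pres, annotation = self.setup_case()
        # vary presence so per-individual fractions differ (non-degenerate test)
        pres.loc["t0", "hi_1"] = False
        fr, test = geneset_fractions(
            labels, annotation, pres, design, {"g0", "g1"}
        )
        assert fr["hi_1"] == pytest.approx(0.25)  # t0 absent: 1 of 4 in set
        for s in design.samples("hi")[1:]:
            assert fr[s] == pytest.approx(0.4)  # 2 of 5 hi TSRs in set
        for s in design.samples("lo"):
            assert fr[s] == 0.0
        assert test is not None and test[2] < 0.05

    def test_disjoint_set_degenerate(self):
        design, labels, pres, annotation = self.setup_case()
        with pytest.raises(DegenerateVarianceError):
            geneset_fractions(labels, annotation, pres, design, {"nope"})


class TestTsrsPerGene:
    def test_mean(self):
        design = design_5x5()
        ids = ["a", "b", "c"]
        labels = pd.Series(["hi_specific"] * 2 + ["lo_specific"], index=ids)
        pres = pd.DataFrame(
            True, index=ids, columns=design.samples("hi") + design.samples("lo")
        )
        annotation = make_annotation({"a": "g1", "b": "g1", "c": "g2"})
        res = tsrs_per_gene(labels, annotation, pres, design, scope="population")
        assert res["mean_hi"] == pytest.approx(2.0)
        assert res["mean_lo"] == pytest.approx(1.0)

    def test_mean_one_point_five(self):
        design = design_5x5()
        ids = ["a", "b", "c", "d"]
        labels = pd.Series(["hi_specific"] * 3 + ["lo_specific"], index=ids)
        pres = pd.DataFrame(
            True, index=ids, columns=design.samples("hi") + design.samples("lo")
        )
        annotation = make_annotation({"a": "g1", "b": "g1", "c": "g2", "d": "g3"})
        res = tsrs_per_gene(labels, annotation, pres, design)
        assert res["mean_hi"] == pytest.approx(1.5)


class TestMisinitiation:
    def setup_case(self):
        design = design_5x5()
        ids = ["t1", "t2", "t3", "t4", "u1", "u2"]
        labels = pd.Series(["hi_specific"] * 4 + ["lo_specific"] * 2, index=ids)
        cols = design.samples("hi") + design.samples("lo")
        pres = pd.DataFrame(False, index=ids, columns=cols)
        pres.loc[["t1", "t2", "t3", "t4"], design.samples("hi")] = True
        pres.loc[["u1", "u2"], design.samples("lo")] = True
        cats = {"t1": "promoter", "t2": "promoter", "t3": "promoter",
                "t4": "intron", "u1": "promoter", "u2": "promoter"}
        annotation = make_annotation(
            {tid: f"g{i}" for i, tid in enumerate(ids)}, cats
        )
        return design, labels, pres, annotation

    def test_tsr_level_rate(self):
        design, labels, pres, annotation = self.setup_case()
        res = misinitiation_rates(annotation, labels, pres, design)
        for s in design.samples("hi"):
            assert res["rates"][s] == pytest.approx(0.25)

    def test_promoter_like_grouping(self):
        design, labels, pres, annotation = self.setup_case()
        annotation["t4"] = TsrAnnotationRecord("t4", "five_utr", "g3", 0)
        res = misinitiation_rates(
            annotation, labels, pres, design,
            promoter_like=("promoter", "five_utr"),
        )
        for s in design.samples("hi"):
            assert res["rates"][s] == 0.0

    def test_gene_level(self):
        design, labels, pres, annotation = self.setup_case()
        # one gene with promoter + intergenic TSRs counts as mis-initiated
        annotation["t4"] = TsrAnnotationRecord("t4", "intergenic", "g0", 0)
        res = misinitiation_rates(
            annotation, labels, pres, design, level="gene"
        )
        # genes: g0 (t1 promoter + t4 intergenic -> mis), g1, g2 (promoter only)
        for s in design.samples("hi"):
            assert res["rates"][s] == pytest.approx(1 / 3)


class TestLeaveOneOut:
    def example(self):
        pres = pd.DataFrame(
            {
                "T1": [1, 1, 0, 0],
                "T2": [0, 0, 1, 1],
                "T3": [0, 1, 0, 1],
            },
            index=["t1", "t2", "t3", "t4"],
        ).astype(bool)
        return pres

    def test_hand_worked_fractions(self):
        loo = leave_one_out_specificity(self.example())
        F = loo.fractions
        assert np.isnan(F.loc["T1", "T1"])
        assert F.loc["T1", "T2"] == 0.0
        assert F.loc["T1", "T3"] == 0.5
        assert F.loc["T2", "T1"] == 0.0
        assert F.loc["T2", "T3"] == 0.5
        assert F.loc["T3", "T1"] == 1.0
        assert F.loc["T3", "T2"] == 1.0

    def test_hand_worked_zscores(self):
        loo = leave_one_out_specificity(self.example())
        assert loo.zscores.loc["T1", "T2"] == pytest.approx(-1.0)
        assert loo.zscores.loc["T1", "T3"] == pytest.approx(1.0)

    def test_z_rows_standardized(self):
        gen = np.random.default_rng(3)
        pres = pd.DataFrame(gen.random((100, 6)) < 0.3,
                            columns=[f"T{i}" for i in range(6)])
        loo = leave_one_out_specificity(pres)
        for _, row in loo.zscores.iterrows():
            vals = row.dropna().to_numpy()
            if vals.size >= 2:
                assert vals.mean() == pytest.approx(0.0, abs=1e-12)
                assert vals.std() == pytest.approx(1.0, abs=1e-12)

    def test_all_shared_all_missing(self):
        pres = pd.DataFrame(True, index=["a", "b"], columns=["T1", "T2", "T3"])
        loo = leave_one_out_specificity(pres)
        assert loo.fractions.isna().all(axis=None)

    def test_permutation_invariance(self):
        pres = self.example()
        loo1 = leave_one_out_specificity(pres)
        perm = ["T3", "T1", "T2"]
        loo2 = leave_one_out_specificity(pres[perm])
        for u in perm:
            for t in perm:
                v1, v2 = loo1.fractions.loc[u, t], loo2.fractions.loc[u, t]
                assert (np.isnan(v1) and np.isnan(v2)) or v1 == v2

    def test_two_tissues_rejected(self):
        pres = pd.DataFrame(True, index=["a"], columns=["T1", "T2"])
        with pytest.raises(ValidationError):
            leave_one_out_specificity(pres)
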