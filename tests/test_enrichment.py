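"""Family enrichment tables, matrix assembly, clustering, co-occupancy,
activity classification and candidate shortlisting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tecre.enrichment import (
    ActivityRules,
    EnrichmentMatrix,
    build_enrichment_matrix,
    classify_family_activity,
    cluster_enrichment,
    cooccupancy_summary,
    dataset_correlation,
    family_enrichment,
    shortlist_candidates,
)

from conftest import make_peak, make_te


def small_fixture():
    """Family A: 2/2 copies overlapped; background (family B): 0/2."""
    te = [
        make_te("chr1", 100, 200, "A", "A.0"),
        make_te("chr1", 300, 400, "A", "A.1"),
        make_te("chr1", 1000, 1100, "B", "B.0"),
        make_te("chr1", 1200, 1300, "B", "B.1"),
    ]
    peaks = [make_peak("chr1", 150, 180), make_peak("chr1", 350, 380)]
    return peaks, te


def matrix_from_dict(values: dict, alpha=0.05, sig=None) -> EnrichmentMatrix:
    df = pd.DataFrame(values)
    if sig is None:
        sig = df > -np.log10(alpha)
    return EnrichmentMatrix(values=df, significant=sig, alpha=alpha)


class TestFamilyEnrichment:
    def test_hypergeometric_tail_hand_enumeration(self):
        # 2x2 table [[2,0],[0,2]]: P(both draws from the overlapped pair)
        # = C(2,2)*C(2,0)/C(4,2) = 1/6
        peaks, te = small_fixture()
        table = family_enrichment(peaks, te, min_instances=2).set_index("family")
        assert table.loc["A", "p"] == pytest.approx(1 / 6)
        assert table.loc["A", "n_overlapped"] == 2
        assert table.loc["B", "n_overlapped"] == 0

    def test_no_testable_family_raises(self):
        peaks, te = small_fixture()
        with pytest.raises(ValueError, match="no family"):
            family_enrichment(peaks, te, min_instances=3)

    def test_min_instances_marks_untested(self):
        peaks, te = small_fixture()
        te = te + [make_te("chr1", 2000, 2100, "C", "C.0")]
        table = family_enrichment(peaks, te, min_instances=2).set_index("family")
        assert not table.loc["C", "tested"] and np.isnan(table.loc["C", "p"])

    def test_fraction_mode_zero_equals_any(self, te_annotation):
        from tecre.simulate import simulate_peakset

        instances, _, _ = te_annotation
        peaks = simulate_peakset(
            instances, [("chr1", 5_000_000), ("chr2", 5_000_000)], "d", 500, seed=3
        )
        t_any = family_enrichment(peaks, instances, overlap_mode="any")
        t_frac = family_enrichment(peaks, instances, overlap_mode="frac:0")
        pd.testing.assert_frame_equal(t_any, t_frac)

    def test_bh_adjustment_matches_from_scratch(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=25)
        # from-scratch BH: p_(i) * n / i, cumulative-min from the largest rank
        order = np.argsort(p)
        n = len(p)
        stepup = p[order] * n / np.arange(1, n + 1)
        adj_sorted = np.minimum.accumulate(stepup[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(adj_sorted, 1.0)
        from statsmodels.stats.multitest import multipletests

        assert np.allclose(multipletests(p, method="fdr_bh")[1], expected)

    def test_mixed_datasets_rejected(self):
        peaks, te = small_fixture()
        peaks[0] = make_peak("chr1", 150, 180, dataset="other")
        with pytest.raises(ValueError, match="single dataset"):
            family_enrichment(peaks, te)

    def test_blacklist_mask_removes_peaks(self):
        peaks, te = small_fixture()
        from tecre.intervals import GenomicInterval

        mask = [GenomicInterval("chr1", 140, 190)]
        table = family_enrichment(
            peaks, te, min_instances=2, peak_mask=mask
        ).set_index("family")
        assert table.loc["A", "n_overlapped"] == 1


class TestBuildMatrix:
    def two_tables(self):
        peaks, te = small_fixture()
        t1 = family_enrichment(peaks, te, min_instances=2)
        t1["dataset"] = "d1"
        t2 = t1.copy()
        t2["dataset"] = "d2"
        return t1, t2

    def test_union_of_families_and_zero_fill(self):
        t1, t2 = self.two_tables()
        t2 = t2[t2["family"] == "A"].copy()
        em = build_enrichment_matrix([t1, t2])
        assert set(em.families) == {"A", "B"}
        assert em.values.loc["B", "d2"] == 0.0

    def test_duplicate_dataset_names_rejected(self):
        t1, t2 = self.two_tables()
        t2["dataset"] = "d1"
        with pytest.raises(ValueError, match="duplicated"):
            build_enrichment_matrix([t1, t2])

    def test_significant_subset_is_any_dataset_union(self):
        em = matrix_from_dict(
            {"d1": {"f1": 5.0, "f2": 0.0}, "d2": {"f1": 0.0, "f2": 6.0}}
        )
        keep = em.significant_subset()
        assert set(keep.families) == {"f1", "f2"}
        em2 = matrix_from_dict({"d1": {"f1": 5.0, "f2": 0.0}, "d2": {"f1": 0.0, "f2": 0.0}})
        assert em2.significant_subset().families == ["f1"]


class TestCluster:
    def test_separable_centroids_recovered(self):
        rows = {}
        for i in range(5):
            rows[f"hi{i}"] = [50.0, 50.0]
            rows[f"mid{i}"] = [10.0, 10.0]
            rows[f"lo{i}"] = [0.0, 0.0]
        em = matrix_from_dict(
            {"d1": {k: v[0] for k, v in rows.items()}, "d2": {k: v[1] for k, v in rows.items()}}
        )
        labels = cluster_enrichment(em, k=3, seed=0)
        # canonical relabelling: cluster 0 has the highest mean
        assert all(labels[f"hi{i}"] == 0 for i in range(5))
        assert all(labels[f"mid{i}"] == 1 for i in range(5))
        assert all(labels[f"lo{i}"] == 2 for i in range(5))

    def test_k_equals_rows_gives_singletons(self):
        em = matrix_from_dict({"d1": {"a": 1.0, "b": 5.0, "c": 9.0}, "d2": {"a": 0.0, "b": 4.0, "c": 8.0}})
        labels = cluster_enrichment(em, k=3, seed=0)
        assert sorted(labels) == [0, 1, 2]

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(4)
        em = matrix_from_dict(
            {
                "d1": {f"f{i}": float(v) for i, v in enumerate(rng.uniform(0, 20, 30))},
                "d2": {f"f{i}": float(v) for i, v in enumerate(rng.uniform(0, 20, 30))},
            }
        )
        a = cluster_enrichment(em, k=4, seed=7)
        b = cluster_enrichment(em, k=4, seed=7)
        assert a.equals(b)

    def test_k_larger_than_rows_rejected(self):
        em = matrix_from_dict({"d1": {"a": 1.0, "b": 2.0}, "d2": {"a": 1.0, "b": 2.0}})
        with pytest.raises(ValueError):
            cluster_enrichment(em, k=3)


class TestDatasetCorrelation:
    def test_duplicated_column_perfectly_correlated(self):
        em = matrix_from_dict(
            {"d1": {"a": 1.0, "b": 2.0, "c": 3.0}, "d2": {"a": 1.0, "b": 2.0, "c": 3.0}}
        )
        assert dataset_correlation(em).loc["d1", "d2"] == pytest.approx(1.0)

    def test_reversed_ranks_anticorrelated(self):
        em = matrix_from_dict(
            {"d1": {"a": 1.0, "b": 2.0, "c": 3.0}, "d2": {"a": 3.0, "b": 2.0, "c": 1.0}}
        )
        assert dataset_correlation(em).loc["d1", "d2"] == pytest.approx(-1.0)

    def test_equals_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(13)
        vals = rng.uniform(0, 30, size=(20, 5))
        em = matrix_from_dict(
            {f"d{j}": {f"f{i}": vals[i, j] for i in range(20)} for j in range(5)}
        )
        got = dataset_correlation(em)
        for i in range(5):
            for j in range(5):
                ri = stats.rankdata(vals[:, i])
                rj = stats.rankdata(vals[:, j])
                expected = np.corrcoef(ri, rj)[0, 1]
                assert got.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_yields_nan_marker(self):
        em = matrix_from_dict(
            {"d1": {"a": 1.0, "b": 2.0, "c": 3.0}, "d2": {"a": 0.0, "b": 0.0, "c": 0.0}}
        )
        corr = dataset_correlation(em)
        assert np.isnan(corr.loc["d1", "d2"]) and corr.loc["d2", "d2"] == 1.0


class TestCooccupancy:
    def make(self):
        sig = pd.DataFrame(
            {
                "GATA3": {"f1": True, "f2": True, "f3": False},
                "DLX5": {"f1": False, "f2": True, "f3": True},
                "H3K4me1": {"f1": False, "f2": True, "f3": False},
            }
        )
        vals = sig.astype(float) * 10
        return EnrichmentMatrix(values=vals, significant=sig, alpha=0.05)

    def test_set_algebra(self):
        res = cooccupancy_summary(self.make(), "GATA3", "DLX5", ["H3K4me1"])
        assert (res["A_only"], res["B_only"], res["shared"]) == (1, 1, 1)
        assert res["shared_with_enhancer_marks"] == pytest.approx(1.0)

    def test_empty_shared_fraction_undefined(self):
        em = self.make()
        em.significant.loc[:, "DLX5"] = [False, False, True]
        res = cooccupancy_summary(em, "GATA3", "DLX5", ["H3K4me1"])
        assert res["shared"] == 0 and np.isnan(res["shared_with_enhancer_marks"])

    def test_missing_dataset_named_in_error(self):
        with pytest.raises(KeyError, match="TEAD4"):
            cooccupancy_summary(self.make(), "GATA3", "TEAD4")


class TestActivityAndShortlist:
    def make(self):
        datasets = [
            "GATA3", "DLX5", "TFAP2C", "H3K4me3", "H3K4me1", "H3K27ac",
            "P300", "MED1", "H3K9me3",
        ]
        fams = ["prom", "enh", "rep", "none"]
        sig = pd.DataFrame(False, index=fams, columns=datasets)
        sig.loc["prom", ["H3K4me3", "TFAP2C", "GATA3", "DLX5"]] = True
        sig.loc["enh", ["H3K4me1", "P300"]] = True
        sig.loc["rep", "H3K9me3"] = True
        vals = sig.astype(float) * 8
        return EnrichmentMatrix(values=vals, significant=sig, alpha=0.05)

    def test_rule_application(self):
        labels = classify_family_activity(self.make())
        assert labels["prom"] == "promoter-like"
        assert labels["enh"] == "enhancer-like"
        assert labels["rep"] == "repressed"
        assert labels["none"] == "unclassified"

    def test_promoter_takes_precedence_over_enhancer(self):
        em = self.make()
        em.significant.loc["prom", ["H3K4me1", "P300"]] = True
        assert classify_family_activity(em)["prom"] == "promoter-like"

    def test_rule_referencing_absent_dataset_raises(self):
        em = self.make()
        rules = ActivityRules(promoter_marks=("H3K4me3",), pioneer=("NOTTHERE",))
        with pytest.raises(KeyError, match="NOTTHERE"):
            classify_family_activity(em, rules)

    def test_shortlist_requires_all_datasets_and_label(self):
        table = shortlist_candidates(
            self.make(),
            required=("GATA3", "DLX5", "TFAP2C"),
            allowed_labels=("promoter-like",),
        )
        assert list(table["family"]) == ["prom"]

    def test_empty_shortlist_is_valid(self):
        table = shortlist_candidates(
            self.make(), required=("GATA3", "DLX5", "TFAP2C"),
            allowed_labels=("enhancer-like",),
        )
        assert table.empty

    def test_score_ties_break_lexicographically(self):
        em = self.make()
        em.significant.loc["aaa"] = em.significant.loc["prom"]
        em.values.loc["aaa"] = em.values.loc["prom"]
        em.significant.loc["zzz"] = em.significant.loc["prom"]
        em.values.loc["zzz"] = em.values.loc["prom"]
        table = shortlist_candidates(
            em, required=("GATA3", "DLX5", "TFAP2C"), allowed_labels=("promoter-like",)
        )
        assert list(table["family"]) == ["aaa", "prom", "zzz"]
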