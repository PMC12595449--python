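"""Differential-expression cascade: normalization, contrasts, BH, filters,
set algebra and delta ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chronopain import synth
from chronopain.deg import (
    DEGSets,
    SampleInfo,
    early_late_delta_ranking,
    filter_low_expression,
    log2cpm,
    nested_late_contrast,
    overall_treatment_degs,
    phenotype_correlation_filter,
    set_algebra,
    up_down_split,
)
from statsmodels.stats.multitest import multipletests


def toy_info(n_per_cell=3, thr=None, guard=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for timing in ("early", "late"):
        for treatment in ("SAFit2", "vehicle"):
            for i in range(n_per_cell):
                rows.append((f"{timing}_{treatment}_{i}", treatment, timing))
    df = pd.DataFrame(rows, columns=["sample_id", "treatment", "timing"])
    df["threshold_log_g"] = thr if thr is not None else rng.normal(size=len(df))
    df["guarding_index"] = guard if guard is not None else rng.normal(size=len(df))
    return SampleInfo(df.set_index("sample_id"))


class TestNormalization:
    def test_cpm_values(self):
        counts = pd.DataFrame({"s1": [10, 90]}, index=["g1", "g2"])
        lc = log2cpm(counts, prior=0.0)
        assert lc.loc["g1", "s1"] == pytest.approx(np.log2(1e5))
        assert lc.loc["g2", "s1"] == pytest.approx(np.log2(9e5))

    def test_zero_count_prior(self):
        counts = pd.DataFrame({"s1": [0, 100]}, index=["g1", "g2"])
        assert log2cpm(counts, prior=0.5).loc["g1", "s1"] == pytest.approx(-1.0)

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": [5, 20, 75]}, index=list("abc"))
        doubled = counts * 2
        assert np.allclose(log2cpm(counts), log2cpm(doubled))

    def test_zero_library_dropped_with_warning(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="s2"):
            lc = log2cpm(counts)
        assert list(lc.columns) == ["s1"]


class TestLowExpressionFilter:
    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame(
            {"s1": [0, 10], "s2": [0, 10]}, index=["dead", "alive"]
        )
        assert list(filter_low_expression(counts).index) == ["alive"]

    def test_boundary_half_of_samples_kept(self):
        # gene at exactly CPM 1 in exactly half of samples: kept (inclusive)
        counts = pd.DataFrame(
            {"s1": [1, 999_999], "s2": [0, 1_000_000]},
            index=["edge", "big"],
        )
        kept = filter_low_expression(counts, min_cpm=1.0, min_frac_samples=0.5)
        assert "edge" in kept.index

    def test_toy_matches_hand_tally(self):
        counts = pd.DataFrame(
            {
                "s1": [0, 5, 50, 200, 1],
                "s2": [0, 0, 60, 150, 2],
                "s3": [1, 0, 40, 100, 0],
                "s4": [0, 0, 55, 120, 3],
            },
            index=[f"g{i}" for i in range(5)],
        )
        lib = counts.sum(axis=0)
        cpm = counts.div(lib, axis=1) * 1e6
        expected = [
            g for g in counts.index
            if (cpm.loc[g] >= 1).mean() >= 0.5
        ]
        kept = filter_low_expression(counts)
        assert list(kept.index) == expected

    def test_empty_result_rejected(self):
        counts = pd.DataFrame({"s1": [0, 1_000_000]}, index=["a", "b"])
        with pytest.raises(ValueError):
            filter_low_expression(counts, min_cpm=1e9)


class TestOverallModel:
    def test_no_signal_no_degs(self):
        info = toy_info(4)
        rng = np.random.default_rng(0)
        lc = pd.DataFrame(
            np.tile(rng.normal(5, 1, size=(50, 1)), (1, 16)),
            index=[f"g{i}" for i in range(50)],
            columns=info.table.index,
        )
        res, degs = overall_treatment_degs(lc + 1e-9 * rng.normal(size=(50, 16)), info)
        assert degs == set()

    def test_single_planted_gene_found(self):
        info = toy_info(4)
        rng = np.random.default_rng(1)
        lc = pd.DataFrame(
            rng.normal(5, 0.01, size=(40, 16)),
            index=[f"g{i}" for i in range(40)],
            columns=info.table.index,
        )
        treated = info.table["treatment"] == "SAFit2"
        lc.loc["g7", treated.values] += 1.0
        res, degs = overall_treatment_degs(lc, info)
        assert degs == {"g7"}
        assert res.stats.loc["g7", "log2fc"] == pytest.approx(1.0, abs=0.02)
        up, down = up_down_split(res, degs)
        assert up == {"g7"} and down == set()

    def test_confounded_design_rejected(self):
        rows = [("a", "SAFit2", "early", 0.1, 0.1),
                ("b", "SAFit2", "early", 0.2, 0.1),
                ("c", "vehicle", "late", 0.1, 0.2),
                ("d", "vehicle", "late", 0.0, 0.2)]
        info = SampleInfo(pd.DataFrame(
            rows, columns=["sample_id", "treatment", "timing",
                           "threshold_log_g", "guarding_index"]
        ).set_index("sample_id"))
        lc = pd.DataFrame(np.zeros((3, 4)), index=list("xyz"),
                          columns=info.table.index)
        with pytest.raises(ValueError, match="confounded"):
            overall_treatment_degs(lc, info)


class TestBenjaminiHochberg:
    @staticmethod
    def bh_oracle(pvals):
        """Step-up BH by direct definition."""
        p = np.asarray(pvals, dtype=float)
        n = p.size
        order = np.argsort(p, kind="mergesort")
        q = np.empty(n)
        prev = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * n / rank)
            q[i] = prev
        return q

    def test_hand_case(self):
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_exhaustive_grid_vs_oracle(self):
        """BH used by the pipeline equals the step-up definition on every
        p-vector of length <= 5 over a fixed grid."""
        grid = [0.001, 0.01, 0.04, 0.05, 0.2, 0.5, 1.0]
        for length in (1, 2, 3, 4, 5):
            for p in itertools.product(grid, repeat=length):
                expected = self.bh_oracle(p)
                got = multipletests(list(p), method="fdr_bh")[1]
                assert np.allclose(got, expected), p

    def test_q_at_least_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        q = multipletests(p, method="fdr_bh")[1]
        assert (q >= p - 1e-12).all()


class TestNestedLate:
    def test_identical_groups_zero_degs(self):
        info = toy_info(3)
        rng = np.random.default_rng(5)
        base = rng.normal(5, 1, size=30)
        lc = pd.DataFrame(
            np.tile(base[:, None], (1, 12)) + 0.01 * rng.normal(size=(30, 12)),
            index=[f"g{i}" for i in range(30)], columns=info.table.index,
        )
        _, degs = nested_late_contrast(lc, info)
        assert degs == set()

    def test_small_late_group_rejected(self):
        rows = [("a", "SAFit2", "late", 0.1, 0.1),
                ("b", "vehicle", "late", 0.1, 0.1),
                ("c", "vehicle", "late", 0.1, 0.1),
                ("d", "SAFit2", "early", 0.1, 0.1)]
        info = SampleInfo(pd.DataFrame(
            rows, columns=["sample_id", "treatment", "timing",
                           "threshold_log_g", "guarding_index"]
        ).set_index("sample_id"))
        lc = pd.DataFrame(np.zeros((3, 4)), index=list("xyz"),
                          columns=info.table.index)
        with pytest.raises(ValueError, match=">= 2"):
            nested_late_contrast(lc, info)

    def test_fdr_and_sensitivity_on_planted_counts(self):
        """Truth-label oracle: empirical FDR controlled and sensitivity
        high for 200 planted genes at |log2FC| 1.5, n = 8 vs 8."""
        samples = synth.default_count_samples(8, seed=13)
        p = synth.CountSimParams(n_pheno_linked=0, seed=13)
        counts, truth = synth.generate_counts(p, samples)
        from chronopain.deg import filter_low_expression, log2cpm

        lc = log2cpm(filter_low_expression(counts))
        _, degs = nested_late_contrast(lc, SampleInfo(samples.loc[lc.columns]))
        tr = truth.loc[lc.index]
        planted = set(tr.index[tr["is_treatment_deg"]])
        n_called = len(degs)
        fdr = len(degs - planted) / max(n_called, 1)
        sens = len(degs & planted) / len(planted)
        se = np.sqrt(0.05 * 0.95 / max(n_called, 1))
        assert fdr <= 0.05 + 3 * se
        assert sens > 0.8


class TestPhenotypeFilter:
    def test_exact_linear_gene_retained_guard_gene_excluded(self):
        info = toy_info(4, seed=7)
        thr = info.table["threshold_log_g"].to_numpy()
        guard = info.table["guarding_index"].to_numpy()
        lc = pd.DataFrame(
            {
                c: [2.0 * thr[i], 3.0 * guard[i], 5.0 + 0.0 * i]
                for i, c in enumerate(info.table.index)
            },
            index=["thr_gene", "guard_gene", "flat_gene"],
        )
        lc.loc["flat_gene"] += np.random.default_rng(0).normal(
            0, 1, size=lc.shape[1]
        )
        kept = phenotype_correlation_filter(
            lc, info, {"thr_gene", "guard_gene", "flat_gene"}
        )
        assert kept == {"thr_gene"}

    def test_constant_covariate_rejected(self):
        info = toy_info(3, thr=0.5)
        lc = pd.DataFrame(np.zeros((2, 12)), index=["a", "b"],
                          columns=info.table.index)
        with pytest.raises(ValueError, match="constant covariate"):
            phenotype_correlation_filter(lc, info, {"a"})

    def test_planted_recall(self):
        samples = synth.default_count_samples(8, seed=17)
        p = synth.CountSimParams(seed=17)
        counts, truth = synth.generate_counts(p, samples)
        from chronopain.deg import filter_low_expression, log2cpm

        lc = log2cpm(filter_low_expression(counts))
        tr = truth.loc[lc.index]
        pheno = set(tr.index[tr["is_pheno_linked"]])
        null = set(tr.index[~tr["is_pheno_linked"] & ~tr["is_treatment_deg"]])
        kept = phenotype_correlation_filter(lc, SampleInfo(samples), pheno | null)
        recall = len(kept & pheno) / len(pheno)
        assert recall > 0.8
        # null retention stays below the Bonferroni expectation + slack
        assert len(kept & null) <= max(3, 0.001 * len(null) + 3)


class TestSetAlgebra:
    def test_idempotent_intersection(self):
        s = DEGSets({"A": {"x", "y"}})
        assert set_algebra(s, "A & A") == {"x", "y"}

    def test_difference_cardinality(self):
        s = DEGSets({"A": {1, 2, 3, 4, 5}, "B": {4, 5, 6}})
        assert len(set_algebra(s, "A - B")) == 3

    def test_inclusion_exclusion_on_random_sets(self, rng):
        for _ in range(20):
            a = set(rng.integers(0, 50, size=rng.integers(0, 30)).tolist())
            b = set(rng.integers(0, 50, size=rng.integers(0, 30)).tolist())
            s = DEGSets({"A": a, "B": b})
            union = set_algebra(s, "A | B")
            inter = set_algebra(s, "A & B")
            assert len(union) == len(a) + len(b) - len(inter)

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError, match="unknown set"):
            set_algebra(DEGSets({"A": set()}), "A | Bogus")

    def test_parentheses(self):
        s = DEGSets({"A": {1, 2, 3}, "B": {2, 3}, "C": {3}})
        assert set_algebra(s, "A - (B - C)") == {1, 3}


class TestDeltaRanking:
    def _lc(self, info, deltas_early, deltas_late):
        genes = sorted(deltas_early)
        cols = {}
        for sid, row in info.table.iterrows():
            vals = []
            for g in genes:
                d = deltas_early[g] if row["timing"] == "early" else deltas_late[g]
                vals.append(5.0 + (d if row["treatment"] == "SAFit2" else 0.0))
            cols[sid] = vals
        return pd.DataFrame(cols, index=genes)

    def test_equal_deltas_empty(self):
        info = toy_info(2)
        lc = self._lc(info, {"a": 1.0, "b": -0.5}, {"a": 1.0, "b": -0.5})
        out = early_late_delta_ranking(lc, info, {"a", "b"})
        assert out.empty

    def test_planted_early_only_genes_ranked_first(self):
        info = toy_info(2)
        lc = self._lc(
            info,
            {"early1": 2.0, "early2": -1.5, "null": 0.0},
            {"early1": 0.0, "early2": 0.0, "null": 0.0},
        )
        out = early_late_delta_ranking(lc, info, {"early1", "early2", "null"})
        assert list(out.index) == ["early1", "early2"]

    def test_exact_ties_broken_by_gene_id(self):
        info = toy_info(2)
        lc = self._lc(info, {"zz": 1.0, "aa": 1.0}, {"zz": 0.0, "aa": 0.0})
        out = early_late_delta_ranking(lc, info, {"zz", "aa"})
        assert list(out.index) == ["aa", "zz"]

    def test_empty_candidates_warn(self):
        info = toy_info(2)
        lc = self._lc(info, {"a": 1.0}, {"a": 0.0})
        with pytest.warns(UserWarning, match="empty"):
            out = early_late_delta_ranking(lc, info, set())
        assert out.empty


def test_pipeline_invariant_to_row_and_column_order():
    samples = synth.default_count_samples(4, seed=21)
    p = synth.CountSimParams(n_genes=400, n_deg_treatment=40,
                             n_pheno_linked=10, seed=21)
    counts, _ = synth.generate_counts(p, samples)
    info = SampleInfo(samples)
    rng = np.random.default_rng(0)
    shuffled = counts.iloc[
        rng.permutation(counts.shape[0]), rng.permutation(counts.shape[1])
    ]
    lc1 = log2cpm(filter_low_expression(counts))
    lc2 = log2cpm(filter_low_expression(shuffled))
    _, d1 = nested_late_contrast(lc1, info)
    _, d2 = nested_late_contrast(lc2, info)
    assert d1 == d2
    _, o1 = overall_treatment_degs(lc1, info)
    _, o2 = overall_treatment_degs(lc2, info)
    assert o1 == o2
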