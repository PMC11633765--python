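"""Group comparison, FDR, summary tests, correlations, network overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from capdyn.stats import (
    adjust_and_compare,
    compare_metrics,
    fdr_bh,
    mann_whitney_z,
    metric_seizure_correlation,
    network_overlap,
    welch_t_from_summary,
)
from capdyn.types import ConfigurationError


def cov_table(n_per_group, rng, covs=("age",)):
    rows = []
    for g in ("patient", "control"):
        for _ in range(n_per_group):
            rows.append({"group": g} | {c: rng.normal() for c in covs})
    return pd.DataFrame(rows)


class TestWelchT:
    def test_state_anxiety_summary_row(self):
        # 38.1 (10.6) vs 31.6 (6.65), n = 14 per group
        t, df, p = welch_t_from_summary(38.1, 10.6, 14, 31.6, 6.65, 14)
        # df recomputed from the rounded printed summaries is 21.86;
        # the printed 21.87 reflects the unrounded raw data, so the
        # comparison carries printed-precision slack
        assert t == pytest.approx(1.94, abs=0.005)
        assert df == pytest.approx(21.87, abs=0.015)
        assert p == pytest.approx(0.06, abs=0.01)

    def test_identical_groups(self):
        t, _, p = welch_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == 1.0

    def test_equal_variance_equal_n_collapses_to_pooled_df(self):
        _, df, _ = welch_t_from_summary(1.0, 2.0, 12, 0.0, 2.0, 12)
        assert df == pytest.approx(22.0, abs=1e-9)


class TestFdrBH:
    def test_hand_computed_three_values(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.37]), [0.37])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        q = fdr_bh(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestMannWhitney:
    def test_identical_samples_z_zero(self):
        z, p = mann_whitney_z([1, 2, 3], [1, 2, 3])
        assert z == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_complete_separation_maximal_z(self):
        # U at its extreme for n=14/14 with continuity correction:
        # |Z| = (98 - 0.5) / sqrt(14*14*29/12) = 4.48
        z, _ = mann_whitney_z(np.arange(14) + 100.0, np.arange(14))
        assert z == pytest.approx(97.5 / np.sqrt(14 * 14 * 29 / 12.0), abs=1e-9)
        assert z == pytest.approx(4.48, abs=0.005)
        z2, _ = mann_whitney_z(np.arange(14), np.arange(14) + 100.0)
        assert z2 == pytest.approx(-z)

    def test_all_tied_data(self):
        z, p = mann_whitney_z([2.0, 2.0], [2.0, 2.0, 2.0])
        assert z == 0.0 and p == 1.0

    @pytest.mark.parametrize("seed", [0, 2, 3])
    def test_normal_approximation_matches_exhaustive_permutation(self, seed):
        # n = 8/8: all C(16, 8) relabelings as the exact reference,
        # across effect sizes spanning p ~ 0.001 to ~ 0.3
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0.8, 1, 8), rng.normal(0, 1, 8)
        z_obs, p_approx = mann_whitney_z(x, y)
        combined = np.concatenate([x, y])
        hits = total = 0
        for pick in itertools.combinations(range(16), 8):
            g1 = combined[list(pick)]
            g2 = np.delete(combined, list(pick))
            z, _ = mann_whitney_z(g1, g2)
            total += 1
            if abs(z) >= abs(z_obs) - 1e-12:
                hits += 1
        assert p_approx == pytest.approx(hits / total, abs=0.01)


class TestAdjustAndCompare:
    def test_pure_group_separation(self, rng):
        covs = cov_table(10, rng)
        metric = (covs["group"] == "patient").astype(float)
        row = adjust_and_compare(metric, covs, covariate_columns=("age",))
        assert abs(row.cohens_d) > 3 and row.p < 0.001
        assert row.adjusted_diff == pytest.approx(1.0, abs=1e-8)

    def test_sign_convention_patient_minus_control(self, rng):
        covs = cov_table(10, rng)
        metric = np.where(covs["group"] == "patient", 0.0, 5.0) + rng.normal(
            0, 0.1, len(covs)
        )
        row = adjust_and_compare(metric, covs, covariate_columns=("age",))
        assert row.adjusted_diff < 0 and row.cohens_d < 0

    def test_confound_is_removed(self):
        # metric is a pure covariate effect; adjustment shrinks the
        # apparent group difference at least 5-fold on average
        rng = np.random.default_rng(0)
        raw_diffs, adj_diffs = [], []
        for _ in range(200):
            covs = cov_table(10, rng)
            conf = rng.normal(size=len(covs)) + 0.8 * (covs["group"] == "patient")
            covs["bdi"] = conf
            metric = 2.0 * conf
            grp = covs["group"] == "patient"
            raw_diffs.append(abs(metric[grp].mean() - metric[~grp].mean()))
            row = adjust_and_compare(metric, covs, covariate_columns=("bdi",))
            adj_diffs.append(abs(row.adjusted_diff))
        assert np.mean(raw_diffs) >= 5 * np.mean(adj_diffs)

    def test_insufficient_subjects_yield_missing_row(self, rng):
        covs = cov_table(2, rng)
        row = adjust_and_compare(np.ones(len(covs)), covs, covariate_columns=("age",))
        assert row.is_missing

    def test_compare_metrics_applies_fdr_within_family(self, rng):
        covs = cov_table(10, rng)
        table = pd.DataFrame(
            {f"m{i}": rng.normal(size=len(covs)) for i in range(4)}
        )
        out = compare_metrics(table, covs, covariate_columns=("age",))
        assert np.all(out["p_fdr"] >= out["p"] - 1e-15)
        assert out.attrs["sign_convention"] == "patient - control"


class TestSeizureCorrelation:
    def test_monotone_relation_is_perfect_rank_correlation(self):
        counts = np.array([0, 1, 3, 9, 30])
        rho, _ = metric_seizure_correlation(np.sqrt(counts + 1), counts)
        assert rho == pytest.approx(1.0)

    def test_insufficient_n_refused(self):
        with pytest.raises(ConfigurationError, match="insufficient n"):
            metric_seizure_correlation([1, 2, 3], [1, 2, 3])

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(500):
            rho, p = metric_seizure_correlation(
                rng.normal(size=14), rng.poisson(5, size=14)
            )
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestNetworkOverlap:
    def test_single_network_takes_all(self):
        cap = np.zeros(100)
        atlas = np.zeros(100, dtype=int)
        atlas[:50] = 1
        atlas[50:] = 2
        cap[:30] = 2.0  # only inside network 1
        with pytest.warns(UserWarning, match="negative"):
            out = network_overlap(cap, atlas, z_thresh=1.04)
        assert out["positive"] == {1: 100.0}

    def test_standard_normal_map_tail_fraction(self):
        # |z| > 1.04 captures the ~15% extreme tail on each side
        rng = np.random.default_rng(8)
        cap = rng.normal(size=200_000)
        atlas = np.ones(200_000, dtype=int)
        n_pos = (cap > 1.04).sum()
        assert n_pos / cap.size == pytest.approx(0.149, abs=0.005)

    def test_uniform_map_splits_evenly(self):
        rng = np.random.default_rng(9)
        cap = rng.normal(size=20_000)
        atlas = np.repeat([1, 2], 10_000)
        out = network_overlap(cap, atlas, z_thresh=1.04)
        for sign in ("positive", "negative"):
            assert out[sign][1] == pytest.approx(50.0, abs=3.0)
            assert sum(out[sign].values()) == pytest.approx(100.0, abs=1e-9)

    def test_seed_voxels_removed(self):
        cap = np.full(10, 3.0)
        atlas = np.array([1] * 5 + [2] * 5)
        out = network_overlap(cap, atlas, z_thresh=1.0, exclude=np.arange(5))
        assert out["positive"] == {2: 100.0}
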