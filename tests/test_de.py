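"""The five DE models and BH adjustment: closed forms, oracles, calibration."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consensusde import SimConfig, simulate_dataset
from consensusde.data import CountMatrix, StudyDesign
from consensusde.de import (
    DispersionFit,
    bh_adjust,
    fit_dispersion,
    mann_whitney_test,
    nb_lrt_robust_test,
    nb_wald_test,
    voom_moderated_t_test,
    voom_weights,
    welch_t_test,
)


def _design(n1, n2=None):
    n2 = n1 if n2 is None else n2
    return StudyDesign(
        [f"s{j}" for j in range(n1 + n2)], ["ctl"] * n1 + ["trt"] * n2
    )


def _cm(counts):
    counts = np.asarray(counts)
    return CountMatrix(
        [f"g{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
    )


def _flat_dispersion(n, phi=0.1):
    arr = np.full(n, phi)
    return DispersionFit(raw=arr, trend=arr, final=arr, trend_a=0.0, trend_b=phi)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_brute_force(p):
    """Literal step-up: q_(i) = min_{j>=i} p_(j) * m / j, back to input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBHAdjust:
    def test_hand_step_up_example(self):
        q = bh_adjust([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04], atol=1e-12)

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7, atol=1e-15)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_q_dominates_p_and_is_monotone(self, p_list):
        p = np.asarray(p_list)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)
        np.testing.assert_allclose(q, bh_brute_force(p), atol=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def mw_enumeration_p(x_treat, y_ctl):
    """Exact two-sided p by enumerating all group assignments (tie-free)."""
    pooled = np.concatenate([x_treat, y_ctl])
    n1 = len(x_treat)
    u_obs = sum(1 for a in x_treat for b in y_ctl if a > b)
    us = []
    for comb in combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        us.append(sum(1 for a in pooled[mask] for b in pooled[~mask] if a > b))
    us = np.asarray(us)
    return min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        """(1,2,3) vs (4,5,6): U = 0 for the low group, two-sided p = 2/20."""
        vals = np.array([[4.0, 5.0, 6.0, 1.0, 2.0, 3.0]])  # treatment cols last
        res = mann_whitney_test(vals, _design(3))
        assert res.statistic[0] == 0.0
        assert res.p_value[0] == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        vals = np.array([[5.0, 7.0, 9.0, 5.0, 7.0, 9.0]])
        res = mann_whitney_test(vals, _design(3))
        assert res.p_value[0] == pytest.approx(1.0)

    def test_constant_gene_p_one(self):
        vals = np.array([[3.0] * 6])
        res = mann_whitney_test(vals, _design(3))
        assert res.p_value[0] == 1.0
        assert res.flags[0] == "constant"

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 4), (3, 3), (3, 5), (4, 4), (2, 8), (5, 5), (4, 6)])
    def test_exact_p_matches_full_enumeration(self, n1, n2, rng):
        for _ in range(5):
            vals = rng.normal(size=(1, n1 + n2))
            design = _design(n1, n2)
            res = mann_whitney_test(vals, design)
            oracle = mw_enumeration_p(vals[0, n1:], vals[0, :n1])
            assert res.p_value[0] == pytest.approx(oracle, abs=1e-12)


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------


class TestWelchT:
    def test_identical_groups(self):
        vals = np.tile(np.array([[1.0, 2.0, 3.0]]), (1, 2))
        res = welch_t_test(vals, _design(3), log_scale=False)
        assert res.statistic[0] == 0.0
        assert res.p_value[0] == 1.0

    def test_shifted_groups_match_hand_computation(self):
        from scipy import stats as sps

        vals = np.array([[1.0, 2.0, 3.0, 11.0, 12.0, 13.0]])
        res = welch_t_test(vals, _design(3), log_scale=False)
        # hand Welch: means 2 and 12, s^2 = 1 each, n = 3
        se = np.sqrt(1.0 / 3 + 1.0 / 3)
        t = 10.0 / se
        df = (1.0 / 3 + 1.0 / 3) ** 2 / ((1.0 / 3) ** 2 / 2 + (1.0 / 3) ** 2 / 2)
        assert res.statistic[0] == pytest.approx(t, rel=1e-12)
        assert res.p_value[0] == pytest.approx(2 * sps.t.sf(t, df), rel=1e-12)
        assert res.log2_fold_change[0] == pytest.approx(10.0)

    def test_degenerate_zero_variance(self):
        equal = np.array([[2.0] * 6])
        res = welch_t_test(equal, _design(3), log_scale=False)
        assert res.p_value[0] == 1.0
        shifted = np.array([[2.0, 2.0, 2.0, 5.0, 5.0, 5.0]])
        res = welch_t_test(shifted, _design(3), log_scale=False)
        assert res.p_value[0] == 0.0
        assert res.flags[0] == "degenerate"


# ---------------------------------------------------------------------------
# negative binomial models
# ---------------------------------------------------------------------------


class TestNBWald:
    def test_lfc_is_exact_log_ratio_of_group_means(self):
        counts = np.array([[18, 20, 22, 78, 80, 82], [30, 31, 32, 29, 30, 31]])
        res = nb_wald_test(_cm(counts), _design(3), _flat_dispersion(2, 0.05))
        assert res.log2_fold_change[0] == pytest.approx(2.0, abs=1e-9)

    def test_identical_groups_null(self):
        counts = np.array([[10, 20, 30, 10, 20, 30]])
        res = nb_wald_test(_cm(counts), _design(3), _flat_dispersion(1, 0.1))
        assert res.statistic[0] == pytest.approx(0.0, abs=1e-9)
        assert res.p_value[0] == pytest.approx(1.0, abs=1e-9)

    def test_zero_group_flagged_and_finite(self):
        counts = np.array([[0, 0, 0, 12, 15, 18]])
        res = nb_wald_test(_cm(counts), _design(3), _flat_dispersion(1, 0.1))
        assert np.isfinite(res.log2_fold_change[0])
        assert res.flags[0] == "zero-group"
        assert res.p_value[0] < 0.05


class TestNBLRTRobust:
    def test_identical_groups_null(self):
        counts = np.array([[10, 20, 30, 10, 20, 30]])
        res = nb_lrt_robust_test(_cm(counts), _design(3), _flat_dispersion(1, 0.1))
        assert res.statistic[0] == pytest.approx(0.0, abs=1e-9)
        assert res.p_value[0] == pytest.approx(1.0, abs=1e-9)

    def test_outlier_downweighting_reduces_significance(self):
        counts = np.array([[20, 22, 18, 21, 19, 250], [20, 21, 19, 20, 22, 21]])
        cm, design = _cm(counts), _design(3)
        disp = _flat_dispersion(2, 0.1)
        robust = nb_lrt_robust_test(cm, design, disp).p_value[0]
        plain = nb_lrt_robust_test(cm, design, disp, residual_cutoff=1e12).p_value[0]
        assert robust > plain


class TestVoom:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        block = rng.negative_binomial(5, 0.02, size=(100, 3))
        counts = np.hstack([block, block])
        res = voom_moderated_t_test(_cm(counts), _design(3))
        np.testing.assert_allclose(res.statistic, 0.0, atol=1e-9)
        np.testing.assert_allclose(res.p_value, 1.0, atol=1e-9)

    def test_small_panel_falls_back_with_warning(self):
        counts = np.array([[10, 20, 30, 40, 50, 60], [5, 6, 7, 8, 9, 10]])
        with pytest.warns(UserWarning, match="fewer than 10 genes"):
            res = voom_moderated_t_test(_cm(counts), _design(3))
        assert np.all((res.p_value >= 0) & (res.p_value <= 1))

    def test_flat_variance_data_gets_near_equal_weights(self, rng):
        # log-scale data with mean-independent variance: the trend is flat
        logmu = rng.uniform(4, 12, 2000)
        flat = np.rint(2.0 ** (logmu[:, None] + rng.normal(0, 0.3, (2000, 6)))).astype(int)
        _, w_flat = voom_weights(_cm(flat), _design(3))
        assert w_flat.max() / w_flat.min() < 1.5
        # NB counts have strongly mean-dependent log variance: wide weights
        cm_nb, design_nb, _ = simulate_dataset(SimConfig(n_genes=2000, n_per_group=3, seed=5))
        _, w_nb = voom_weights(cm_nb, design_nb)
        assert w_nb.max() / w_nb.min() > w_flat.max() / w_flat.min()


class TestDispersionFit:
    def test_poisson_counts_give_near_zero_dispersion(self):
        cfg = SimConfig(n_genes=1000, n_per_group=6, seed=42, disp_a=0.0, disp_b=0.0,
                        libsize_sdlog=0.0)
        cm, design, _ = simulate_dataset(cfg)
        fit = fit_dispersion(cm.counts, None, design)
        assert np.median(fit.final) < 0.05

    def test_constant_dispersion_recovered(self):
        cfg = SimConfig(n_genes=1000, n_per_group=6, seed=42, disp_a=0.0, disp_b=0.2,
                        libsize_sdlog=0.0)
        cm, design, _ = simulate_dataset(cfg)
        fit = fit_dispersion(cm.counts, None, design)
        assert 0.15 <= np.median(fit.final) <= 0.25

    def test_single_gene_falls_back_with_warning(self):
        counts = np.array([[10, 20, 30, 40, 50, 60]])
        with pytest.warns(UserWarning, match="positive raw dispersion"):
            fit = fit_dispersion(counts, None, _design(3))
        assert np.all(fit.final > 0)

    def test_shrunken_lies_between_raw_and_trend(self):
        cfg = SimConfig(n_genes=500, n_per_group=6, seed=9)
        cm, design, _ = simulate_dataset(cfg)
        fit = fit_dispersion(cm.counts, None, design)
        ok = np.isfinite(fit.raw) & (fit.raw > 0)
        # geometric-mean shrinkage with a small upward bias correction:
        # the final value lies between raw and trend up to that correction
        lo = np.minimum(fit.raw[ok], fit.trend[ok])
        hi = np.maximum(fit.raw[ok], fit.trend[ok])
        assert np.all(fit.final[ok] >= lo * 0.99)
        assert np.all(fit.final[ok] <= hi * 1.06)


@pytest.mark.parametrize("model", ["nb_wald", "nb_lrt_robust", "voom", "mann_whitney", "welch_t"])
def test_all_zero_genes_kept_with_unit_p(model, rng):
    """Degenerate genes stay in the universe with p = q = 1 and a flag."""
    counts = rng.negative_binomial(5, 0.02, size=(30, 6))
    counts[7] = 0
    cm, design = _cm(counts), _design(3)
    if model in ("nb_wald", "nb_lrt_robust"):
        fit = fit_dispersion(cm.counts, None, design)
        fn = nb_wald_test if model == "nb_wald" else nb_lrt_robust_test
        res = fn(cm, design, fit)
    elif model == "voom":
        res = voom_moderated_t_test(cm, design)
    elif model == "mann_whitney":
        res = mann_whitney_test(cm.counts.astype(float), design)
    else:
        res = welch_t_test(cm.counts.astype(float), design)
    assert res.p_value[7] == 1.0
    assert res.q_value[7] == 1.0
    assert res.log2_fold_change[7] == 0.0
    assert res.flags[7] == "all-zero"
    assert len(res.gene_ids) == 30
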