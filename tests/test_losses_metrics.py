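"""Survival likelihood and metric oracles.

The MTLR likelihood is checked against an independent brute-force that
enumerates all m+1 monotone label configurations explicitly; concordance
and Brier scores are checked against explicit O(n^2) pair loops and
hand-computable cases.
"""

import numpy as np
import pytest
from scipy.stats import spearmanr

from survformer.losses_metrics import (
    SurvivalDiscretization,
    TaskSpec,
    composite_loss,
    concordance_index,
    integrated_brier_score,
    make_discretization,
    mtlr_loss,
    mtlr_nll,
    mtlr_nll_t,
    mtlr_survival_curve,
    tabular_metrics,
)
from survformer.nn import Tensor


# ---------------------------------------------------------------------------
# independent enumeration oracle


def enumerate_configs(m: int) -> list[np.ndarray]:
    """All monotone 0->1 label vectors of length m (event in interval j, or none)."""
    configs = []
    for j in range(1, m + 2):  # switch index; m+1 = all-zero (survive past tau_m)
        y = np.zeros(m)
        y[j - 1 :] = 1.0 if j <= m else 0.0
        configs.append(y)
    return configs


def oracle_nll(f: np.ndarray, interval_idx: int, event: int) -> float:
    m = len(f)
    scores = np.array([np.exp(float(y @ f)) for y in enumerate_configs(m)])
    Z = scores.sum()
    if event == 1:
        return float(-np.log(scores[interval_idx - 1] / Z))
    consistent = scores[interval_idx:]  # switch index > c
    return float(-np.log(consistent.sum() / Z))


def oracle_survival(f: np.ndarray) -> np.ndarray:
    m = len(f)
    scores = np.array([np.exp(float(y @ f)) for y in enumerate_configs(m)])
    Z = scores.sum()
    return np.array([scores[k + 1 :].sum() / Z for k in range(m)])


class TestMTLRLoss:
    @pytest.mark.parametrize(
        "f,interval,event,expected",
        [
            ([0.0], 1, 1, np.log(2)),
            ([0.0, 0.0], 2, 1, np.log(3)),
            ([0.0, 0.0], 1, 0, np.log(3 / 2)),
        ],
    )
    def test_worked_values(self, f, interval, event, expected):
        got = mtlr_nll(np.array(f), np.array([interval]), np.array([event]))[0]
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("m", list(range(1, 13)))
    def test_matches_enumeration_all_m(self, m, rng):
        for _ in range(20):
            f = rng.normal(scale=2.0, size=m)
            for event in (0, 1):
                lo = 1 if event == 1 else 0
                for k in range(lo, m + 1):
                    got = mtlr_nll(f, np.array([k]), np.array([event]))[0]
                    assert got == pytest.approx(oracle_nll(f, k, event), abs=1e-8)

    def test_time_mapping(self):
        disc = SurvivalDiscretization(np.array([0.0, 1.0, 2.0]))
        f = np.zeros(2)
        # event at t=0.5 -> interval 1; censored at t=1.5 -> survived 1 interval
        assert mtlr_loss(f, 0.5, 1, disc)[0] == pytest.approx(oracle_nll(f, 1, 1))
        assert mtlr_loss(f, 1.5, 0, disc)[0] == pytest.approx(oracle_nll(f, 1, 0))

    def test_event_beyond_grid_clamped_with_warning(self):
        disc = SurvivalDiscretization(np.array([0.0, 1.0, 2.0]))
        with pytest.warns(UserWarning, match="beyond"):
            got = mtlr_loss(np.zeros(2), 5.0, 1, disc)[0]
        assert got == pytest.approx(oracle_nll(np.zeros(2), 2, 1))

    def test_gradient_matches_finite_differences(self, rng):
        for event, k in [(1, 2), (0, 1), (0, 0)]:
            f = rng.normal(size=(3, 4))
            t = Tensor(f.copy(), requires_grad=True)
            loss = mtlr_nll_t(t, np.array([k] * 3), np.array([event] * 3))
            loss.backward()
            eps = 1e-6
            for b in range(3):
                for j in range(4):
                    fp, fm = f.copy(), f.copy()
                    fp[b, j] += eps
                    fm[b, j] -= eps
                    num = (
                        mtlr_nll(fp, np.array([k] * 3), np.array([event] * 3)).mean()
                        - mtlr_nll(fm, np.array([k] * 3), np.array([event] * 3)).mean()
                    ) / (2 * eps)
                    assert t.grad[b, j] == pytest.approx(num, abs=1e-5)


class TestSurvivalCurve:
    def test_uniform_logits_m2(self):
        surv, risk = mtlr_survival_curve(np.zeros(2))
        np.testing.assert_allclose(surv, [2 / 3, 1 / 3], atol=1e-12)
        assert risk == pytest.approx((1 - 2 / 3) + (1 - 1 / 3))

    def test_m1_uniform(self):
        surv, _ = mtlr_survival_curve(np.zeros(1))
        assert surv[0] == pytest.approx(0.5)

    def test_large_first_logit_drives_survival_down(self):
        surv, _ = mtlr_survival_curve(np.array([30.0, 0.0]))
        assert surv[0] < 1e-10

    def test_matches_enumeration_and_is_monotone(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 10))
            f = rng.normal(scale=3.0, size=m)
            surv, risk = mtlr_survival_curve(f)
            np.testing.assert_allclose(surv, oracle_survival(f), atol=1e-8)
            assert np.all(np.diff(surv) <= 1e-12)
            assert np.all((surv >= 0) & (surv <= 1))
            assert risk == pytest.approx(m - surv.sum())


class TestMakeDiscretization:
    def test_quantile_grid(self):
        times = np.arange(1.0, 101.0)
        events = np.ones(100)
        disc = make_discretization(times, events, m=4)
        assert disc.boundaries[0] == 0.0
        assert disc.boundaries[-1] == 100.0
        assert disc.m == 4

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            make_discretization(np.array([1.0, 2.0]), np.array([0, 0]), m=3)


class TestCompositeLoss:
    def test_zero_weight_excluded(self):
        assert composite_loss([np.array([0.5]), np.array([9.9])], [1.0, 0.0]) == 0.5

    def test_additivity(self):
        assert composite_loss([np.array([0.2]), np.array([0.3])], [1.0, 1.0]) == pytest.approx(0.5)

    def test_masked_mean(self):
        losses = [np.array([0.4, 123.0])]
        masks = [np.array([True, False])]
        assert composite_loss(losses, [1.0], masks) == pytest.approx(0.4)

    def test_linear_in_lambda(self, rng):
        losses = [rng.uniform(size=5), rng.uniform(size=5)]
        lam = rng.uniform(size=2)
        a = composite_loss(losses, list(lam))
        b = composite_loss(losses, list(2.0 * lam))
        assert b == pytest.approx(2 * a)

    def test_all_masked_warns(self):
        with pytest.warns(UserWarning, match="masked"):
            out = composite_loss([np.array([1.0])], [1.0], [np.array([False])])
        assert out == 0.0


def oracle_cindex(risk, times, events):
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_anti_monotone(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        risk = -times
        assert concordance_index(risk, times, np.ones(4)) == 1.0

    def test_all_tied_risks(self):
        times = np.array([1.0, 2.0, 3.0])
        assert concordance_index(np.zeros(3), times, np.ones(3)) == 0.5

    def test_censored_case_matches_pair_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            times = rng.exponential(size=n)
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                continue
            risk = rng.normal(size=n)
            assert concordance_index(risk, times, events) == pytest.approx(
                oracle_cindex(risk, times, events)
            )

    def test_invariant_to_monotone_transform(self, rng):
        times = rng.exponential(size=20)
        events = rng.integers(0, 2, size=20)
        events[0] = 1
        risk = rng.normal(size=20)
        a = concordance_index(risk, times, events)
        b = concordance_index(np.exp(3 * risk), times, events)
        assert a == pytest.approx(b)

    def test_no_comparable_pairs_signalled(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index(np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.array([0, 0]))


def oracle_ibs(surv, times, events, grid):
    """Brute-force IPCW Brier integration (independent KM for censoring)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter().fit(times, 1 - np.asarray(events))

    def G(t):
        return float(kmf.predict(t))

    def G_minus(t):
        sf = kmf.survival_function_
        prior = sf[sf.index < t]
        return float(prior.iloc[-1, 0]) if len(prior) else 1.0

    n = len(times)
    bs = []
    for t in grid:
        total = 0.0
        for i in range(n):
            if times[i] <= t and events[i] == 1:
                total += surv[i] ** 2 / G_minus(times[i]) if G_minus(times[i]) > 0 else 0.0
            elif times[i] > t:
                total += (1 - surv[i]) ** 2 / G(t) if G(t) > 0 else 0.0
        bs.append(total / n)
    return np.trapezoid(bs, grid) / (grid[-1] - grid[0])


class TestIBS:
    def test_constant_half_no_censoring_is_quarter(self, rng):
        n = 40
        times = rng.exponential(size=n) + 0.1
        events = np.ones(n, dtype=int)
        grid = np.linspace(0, times.max(), 20)
        surv = np.full((n, len(grid)), 0.5)
        assert integrated_brier_score(surv, times, events, grid) == pytest.approx(0.25, abs=1e-10)

    def test_perfect_oracle_predictions_score_zero(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.ones(3, dtype=int)
        grid = np.array([0.0, 0.5, 1.5, 2.5, 3.0])
        surv = np.array([[1.0 if g < t else 0.0 for g in grid] for t in times])
        assert integrated_brier_score(surv, times, events, grid) == pytest.approx(0.0, abs=1e-12)

    def test_five_sample_censored_case_matches_brute_force(self):
        """Constant-per-sample predictions against an explicit IPCW sum."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.array([1, 0, 1, 0, 1])
        grid = np.array([0.0, 1.5, 2.5, 3.5])
        rng = np.random.default_rng(0)
        levels = rng.uniform(size=5)
        surv = np.tile(levels[:, None], (1, len(grid)))
        got = integrated_brier_score(surv, times, events, grid)
        assert got == pytest.approx(oracle_ibs(levels, times, events, grid), abs=1e-10)

    def test_grid_outside_range_rejected(self):
        times = np.array([1.0, 2.0])
        events = np.array([1, 1])
        with pytest.raises(ValueError):
            integrated_brier_score(np.ones((2, 2)), times, events, np.array([0.0, 10.0]))


class TestTabularMetrics:
    def test_perfect_classification(self):
        out = tabular_metrics(np.array([0, 1, 2]), np.array([0, 1, 2]), "classification")
        assert out["ACC"] == 1.0
        assert out["F1"] == 1.0

    def test_shifted_regression(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = tabular_metrics(y, y + 1, "regression")
        assert out["MAE"] == 1.0
        assert out["SCC"] == pytest.approx(1.0)

    def test_spearman_with_tie_matches_scipy_oracle(self):
        y_true = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y_pred = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        out = tabular_metrics(y_true, y_pred, "regression")
        assert out["SCC"] == pytest.approx(spearmanr(y_true, y_pred).statistic)

    def test_constant_predictions_flagged(self):
        out = tabular_metrics(np.array([1.0, 2.0]), np.array([3.0, 3.0]), "regression")
        assert out["SCC"] == 0.0
        assert out["SCC_undefined"] == 1.0


class TestTaskSpec:
    def test_output_dims(self):
        disc = SurvivalDiscretization(np.linspace(0, 10, 11))
        assert TaskSpec("r", "regression").output_dim == 1
        assert TaskSpec("c", "classification", classes=list("abcde")).output_dim == 5
        assert TaskSpec("s", "survival", discretization=disc).output_dim == 10

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TaskSpec("x", "magic")
        with pytest.raises(ValueError):
            TaskSpec("c", "classification")
        with pytest.raises(ValueError):
            TaskSpec("s", "survival")
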