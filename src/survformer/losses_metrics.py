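"""Task losses and evaluation metrics.

Survival is modelled with the multitask logistic regression (MTLR)
discretized-time likelihood: time is cut into m intervals
0 = tau_0 < tau_1 < ... < tau_m and the event-time distribution is encoded
by the m+1 monotone binary label vectors (all zeros = survive past tau_m;
switching to 1 at interval j = event in interval j).  A configuration y
scores exp(sum_k y_k f_k) given interval logits f, with partition function
Z summing over the m+1 valid configurations.  The negative log-likelihood
of the label configuration(s) consistent with an observation — a single
configuration for an observed event, the tail set for a censored one — is
the survival loss.

Evaluation covers Harrell's concordance index, the IPCW integrated Brier
score, and the usual tabular metrics (accuracy, macro-F1, MAE, Spearman).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.stats import spearmanr
from sklearn.metrics import accuracy_score, f1_score

from .nn import Tensor

__all__ = [
    "SurvivalDiscretization",
    "TaskSpec",
    "make_discretization",
    "mtlr_loss",
    "mtlr_nll",
    "mtlr_nll_t",
    "mtlr_survival_curve",
    "composite_loss",
    "concordance_index",
    "integrated_brier_score",
    "tabular_metrics",
]


@dataclass
class SurvivalDiscretization:
    """Interval boundaries 0 = tau_0 < tau_1 < ... < tau_m."""

    boundaries: np.ndarray

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries[0] != 0:
            raise ValueError("discretization must start at tau_0 = 0")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def m(self) -> int:
        return len(self.boundaries) - 1

    def event_interval(self, t: float) -> int:
        """1-based interval containing an event at time t: tau_{k-1} < t <= tau_k."""
        k = int(np.searchsorted(self.boundaries[1:], t, side="left")) + 1
        if k > self.m:
            warnings.warn(f"event time {t} beyond tau_m; assigned to last interval", stacklevel=2)
            k = self.m
        return k

    def intervals_survived(self, t: float) -> int:
        """Number of full intervals survived by a censoring at time t."""
        return min(int(np.searchsorted(self.boundaries[1:], t, side="right")), self.m)


@dataclass
class TaskSpec:
    """A typed prediction target with its loss weight."""

    name: str
    kind: str  # "regression" | "classification" | "survival"
    weight: float = 1.0
    classes: list[str] | None = None
    discretization: SurvivalDiscretization | None = None

    def __post_init__(self):
        if self.kind not in ("regression", "classification", "survival"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("task weight must be >= 0")
        if self.kind == "classification" and not self.classes:
            raise ValueError("classification task needs a class vocabulary")
        if self.kind == "survival" and self.discretization is None:
            raise ValueError("survival task needs a discretization")

    @property
    def output_dim(self) -> int:
        if self.kind == "regression":
            return 1
        if self.kind == "classification":
            return len(self.classes)
        return self.discretization.m


def make_discretization(times: np.ndarray, events: np.ndarray, m: int = 10) -> SurvivalDiscretization:
    """Quantile-based interval grid from training survival data.

    Interior boundaries are the i/m quantiles of the *uncensored* event
    times; tau_m is the maximum observed time (events or censorings) so
    every observation falls inside the grid.  Duplicate quantiles (heavily
    tied times) are merged, shrinking m with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    event_times = times[events == 1]
    if len(event_times) == 0:
        raise ValueError("no uncensored events to build a discretization from")
    interior = np.quantile(event_times, np.arange(1, m) / m)
    tau_max = float(times.max())
    bounds = np.concatenate([[0.0], interior, [tau_max]])
    uniq = np.unique(bounds)
    uniq = uniq[uniq <= tau_max]
    if len(uniq) - 1 < m:
        warnings.warn(f"tied event times reduced the grid to m={len(uniq) - 1}", stacklevel=2)
    if len(uniq) < 2:
        raise ValueError("degenerate discretization")
    return SurvivalDiscretization(uniq)


# ---------------------------------------------------------------------------
# MTLR likelihood


def _config_scores(logits: np.ndarray) -> np.ndarray:
    """Log-scores s_j of the m+1 monotone configurations, shape (..., m+1).

    Column j-1 (j = 1..m) is sum_{k >= j} f_k (event in interval j); the
    last column is 0 (all-zero configuration, survive past tau_m).
    """
    logits = np.asarray(logits, dtype=float)
    suffix = np.cumsum(logits[..., ::-1], axis=-1)[..., ::-1]
    zeros = np.zeros(logits.shape[:-1] + (1,))
    return np.concatenate([suffix, zeros], axis=-1)


def _logsumexp(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    return np.squeeze(m, axis) + np.log(np.exp(x - m).sum(axis=axis))


def mtlr_nll(logits: np.ndarray, interval_idx: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-sample MTLR negative log-likelihood (numpy, batched).

    For an event (event=1), `interval_idx` is the 1-based interval k
    containing the event time: the likelihood is that of the single
    configuration switching at k.  For a censored sample (event=0),
    `interval_idx` is the number c of full intervals survived: all
    configurations with event after interval c (switch index >= c+1,
    including all-zero) are consistent and their mass is summed.
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    interval_idx = np.atleast_1d(np.asarray(interval_idx, dtype=int))
    event = np.atleast_1d(np.asarray(event, dtype=int))
    m = logits.shape[-1]
    s = _config_scores(logits)  # (B, m+1)
    logZ = _logsumexp(s, axis=-1)
    B = logits.shape[0]
    out = np.empty(B)
    for b in range(B):
        if event[b] == 1:
            k = interval_idx[b]
            if not 1 <= k <= m:
                raise ValueError(f"event interval {k} outside 1..{m}")
            out[b] = logZ[b] - s[b, k - 1]
        else:
            c = interval_idx[b]
            if not 0 <= c <= m:
                raise ValueError(f"survived-interval count {c} outside 0..{m}")
            out[b] = logZ[b] - _logsumexp(s[b, c:][None, :], axis=-1)[0]
    return out


def mtlr_loss(
    logits: np.ndarray, time: float | np.ndarray, event: int | np.ndarray, disc: SurvivalDiscretization
) -> np.ndarray:
    """MTLR negative log-likelihood for observations given in time units."""
    times = np.atleast_1d(np.asarray(time, dtype=float))
    events = np.atleast_1d(np.asarray(event, dtype=int))
    if np.any(times < 0):
        raise ValueError("survival times must be nonnegative")
    idx = np.array(
        [disc.event_interval(t) if e == 1 else disc.intervals_survived(t) for t, e in zip(times, events)]
    )
    return mtlr_nll(logits, idx, events)


def mtlr_nll_t(logits: Tensor, interval_idx: np.ndarray, event: np.ndarray) -> Tensor:
    """MTLR negative log-likelihood as a differentiable node (mean over batch).

    The gradient w.r.t. logit f_k is P(y_k = 1) - P(y_k = 1 | consistent
    configurations), both computed from the configuration softmax.
    """
    data = np.atleast_2d(logits.data)
    interval_idx = np.atleast_1d(np.asarray(interval_idx, dtype=int))
    event = np.atleast_1d(np.asarray(event, dtype=int))
    B, m = data.shape
    s = _config_scores(data)
    smax = s.max(axis=-1, keepdims=True)
    pi = np.exp(s - smax)
    pi /= pi.sum(axis=-1, keepdims=True)  # (B, m+1)
    # P(y_k = 1) = sum_{j <= k} pi_j, k = 1..m
    P = np.cumsum(pi, axis=-1)[:, :m]
    T = np.empty_like(P)
    losses = mtlr_nll(data, interval_idx, event)
    for b in range(B):
        if event[b] == 1:
            k = interval_idx[b]
            T[b] = (np.arange(1, m + 1) >= k).astype(float)
        else:
            c = interval_idx[b]
            cond = pi[b, c:] / pi[b, c:].sum()
            qk = np.zeros(m)
            # consistent configs have switch index j >= c+1; y_k = 1 iff j <= k
            cum = np.cumsum(cond)  # over j = c+1..m+1
            for k in range(c + 1, m + 1):
                qk[k - 1] = cum[k - 1 - c]
            T[b] = qk
    grad_f = P - T  # (B, m)

    out = Tensor(losses.mean(), _prev=(logits,))

    def bw(g):
        logits._accumulate(np.asarray(g) * grad_f / B)

    out._backward = bw
    return out


def mtlr_survival_curve(logits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted survival probabilities S(tau_1..tau_m) and a risk score.

    S(tau_k) is the mass of configurations with event after interval k;
    the risk score is the cumulative incidence mass sum_k (1 - S(tau_k)),
    a monotone summary of how early the distribution places the event.
    Returns (survival (..., m), risk (...,)).
    """
    logits = np.asarray(logits, dtype=float)
    squeeze = logits.ndim == 1
    data = np.atleast_2d(logits)
    s = _config_scores(data)
    smax = s.max(axis=-1, keepdims=True)
    pi = np.exp(s - smax)
    pi /= pi.sum(axis=-1, keepdims=True)
    m = data.shape[-1]
    # S(tau_k) = sum_{j > k} pi_j
    surv = 1.0 - np.cumsum(pi, axis=-1)[:, :m]
    surv = np.clip(surv, 0.0, 1.0)
    risk = (1.0 - surv).sum(axis=-1)
    if squeeze:
        return surv[0], risk[0]
    return surv, risk


# ---------------------------------------------------------------------------
# composite multitask loss


def composite_loss(
    per_sample_losses: list[np.ndarray], weights: list[float], masks: list[np.ndarray] | None = None
) -> float:
    """Weighted sum over tasks of masked per-sample loss means."""
    if len(per_sample_losses) != len(weights):
        raise ValueError("one weight per task required")
    total = 0.0
    for t, (losses, lam) in enumerate(zip(per_sample_losses, weights)):
        losses = np.asarray(losses, dtype=float)
        mask = np.ones(len(losses), dtype=bool) if masks is None else np.asarray(masks[t], dtype=bool)
        if mask.sum() == 0:
            warnings.warn(f"task {t}: all samples masked; contributes 0", stacklevel=2)
            continue
        total += lam * losses[mask].mean()
    return float(total)


# ---------------------------------------------------------------------------
# survival metrics


def concordance_index(
    risk: np.ndarray, times: np.ndarray, events: np.ndarray, variant: str = "harrell"
) -> float:
    """Concordance index (default: Harrell's).

    A pair is comparable when the earlier time belongs to an observed event
    (strictly earlier).  Concordant pairs have higher risk for the earlier
    failure; risk ties count 1/2.  Raises if no pair is comparable.
    `variant="ipcw"` delegates to the inverse-probability-of-censoring
    weighted estimator (Uno's C) from scikit-survival.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if variant == "ipcw":
        from sksurv.metrics import concordance_index_ipcw

        y = np.array(list(zip(events.astype(bool), times)), dtype=[("event", bool), ("time", float)])
        return float(concordance_index_ipcw(y, y, risk)[0])
    if variant != "harrell":
        raise ValueError(f"unknown concordance variant {variant!r}")
    # comparable[i, j]: t_i < t_j and event_i = 1
    earlier = times[:, None] < times[None, :]
    comparable = earlier & (events[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs; concordance undefined")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    concordant = (comparable & higher).sum() + 0.5 * (comparable & tied).sum()
    return float(concordant / n_comp)


def _km_censoring(times: np.ndarray, events: np.ndarray):
    """Kaplan-Meier estimate of the censoring survival function G."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=1 - np.asarray(events, dtype=int))
    idx = kmf.survival_function_.index.to_numpy(dtype=float)
    vals = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def G(t: np.ndarray, left_limit: bool = False) -> np.ndarray:
        side = "left" if left_limit else "right"
        pos = np.searchsorted(idx, np.asarray(t, dtype=float), side=side) - 1
        pos = np.clip(pos, 0, len(vals) - 1)
        return vals[pos]

    return G


def integrated_brier_score(
    surv_probs: np.ndarray, times: np.ndarray, events: np.ndarray, grid: np.ndarray
) -> float:
    """IPCW Brier score integrated over `grid` by the trapezoid rule.

    `surv_probs[i, k]` is sample i's predicted S(grid[k]).  Censoring
    weights come from the Kaplan-Meier estimate of the censoring
    distribution, evaluated at t- for observed events.  The grid must lie
    within [0, max event time]; the integral is normalised by the grid span.
    """
    surv_probs = np.asarray(surv_probs, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    grid = np.asarray(grid, dtype=float)
    if surv_probs.shape != (len(times), len(grid)):
        raise ValueError("surv_probs must be (n_samples, len(grid))")
    if len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    tau = times[events == 1].max() if (events == 1).any() else times.max()
    if grid[0] < 0 or grid[-1] > tau:
        raise ValueError(f"grid must lie within [0, {tau}] (max event time)")
    G = _km_censoring(times, events)
    n = len(times)
    bs = np.empty(len(grid))
    g_event = G(times, left_limit=True)  # G(t_i-)
    for k, t in enumerate(grid):
        had_event = (times <= t) & (events == 1)
        still_at_risk = times > t
        term1 = np.where(had_event & (g_event > 0), surv_probs[:, k] ** 2 / np.where(g_event > 0, g_event, 1.0), 0.0)
        gt = G(np.array([t]))[0]
        term2 = np.where(still_at_risk, (1.0 - surv_probs[:, k]) ** 2 / (gt if gt > 0 else 1.0), 0.0)
        bs[k] = (term1 + term2).sum() / n
    return float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))


# ---------------------------------------------------------------------------
# tabular metrics


def tabular_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, kind: str
) -> dict[str, float]:
    """Standard metrics for a non-survival task.

    Classification: accuracy and macro-F1.  Regression: MAE and Spearman's
    rank correlation (average ranks for ties); a constant prediction vector
    makes the correlation undefined and is reported as 0 with a flag.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if kind == "classification":
        return {
            "ACC": float(accuracy_score(y_true, y_pred)),
            "F1": float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        }
    if kind == "regression":
        mae = float(np.mean(np.abs(y_true.astype(float) - y_pred.astype(float))))
        out = {"MAE": mae}
        if np.all(y_pred == y_pred[0]) or np.all(y_true == y_true[0]):
            out["SCC"] = 0.0
            out["SCC_undefined"] = 1.0
        else:
            rho = spearmanr(y_true, y_pred).statistic
            out["SCC"] = float(rho) if np.isfinite(rho) else 0.0
        return out
    raise ValueError(f"unknown task kind {kind!r}")
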