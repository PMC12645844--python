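"""Multitask training: gradient surgery, splits, early stopping, cluster CV.

When several task losses share an encoder, their gradients on the shared
parameters can conflict (negative cosine similarity); summing them then
lets one task undo another's progress.  Gradient surgery (PCGrad) resolves
each conflict by projecting one task's gradient onto the normal plane of
the other before summing:

    v_i <- v_i - (v_i . v_j / ||v_j||^2) v_j    whenever v_i . v_j < 0.

Projection is applied only to the shared encoder parameters; each task head
receives its own task's unmodified gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import nn
from .nn import Adam, Tensor
from .losses_metrics import (
    TaskSpec,
    concordance_index,
    integrated_brier_score,
    mtlr_nll_t,
    mtlr_nll,
    mtlr_survival_curve,
    tabular_metrics,
)
from .model_core import GeneTransformer

__all__ = [
    "SplitPlan",
    "TrainState",
    "pcgrad_project",
    "make_splits",
    "prepare_targets",
    "train",
    "evaluate",
    "cluster_cv",
]


# ---------------------------------------------------------------------------
# gradient surgery


def pcgrad_project(grads: list[np.ndarray], seed: int | np.random.Generator = 0) -> np.ndarray:
    """Merge per-task gradient vectors with PCGrad.

    Each task's gradient is projected, in seeded random task order, against
    every *original* conflicting gradient; the merged gradient is the sum of
    the projected vectors.  Zero-norm opponents are skipped (no projection
    defined); with no conflicts the result is exactly sum(grads).
    """
    if len(grads) == 0:
        raise ValueError("need at least one gradient")
    grads = [np.asarray(g, dtype=float) for g in grads]
    if len({g.shape for g in grads}) != 1:
        raise ValueError("gradient vectors must have equal shapes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sq_norms = [float(g @ g) for g in grads]
    merged = np.zeros_like(grads[0])
    for i in range(len(grads)):
        v = grads[i].copy()
        order = rng.permutation(len(grads))
        for j in order:
            if j == i or sq_norms[j] == 0.0:
                continue
            dot = float(v @ grads[j])
            if dot < 0.0:
                v -= dot / sq_norms[j] * grads[j]
        merged += v
    return merged


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitPlan:
    train: list[str]
    val: list[str]
    test: list[str]
    seed: int


def make_splits(
    sample_ids: list[str],
    proportions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    n_repeats: int = 10,
    seed: int = 0,
    events: np.ndarray | None = None,
) -> list[SplitPlan]:
    """Seeded random train/validation/test partitions, repeated n times.

    When `events` is given the split is stratified by the event indicator so
    censoring fractions stay comparable across parts.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    sample_ids = [str(s) for s in sample_ids]
    n = len(sample_ids)
    plans = []
    for r in range(n_repeats):
        rng = np.random.default_rng((seed, r))
        if events is None:
            strata = [np.arange(n)]
        else:
            ev = np.asarray(events)
            strata = [np.flatnonzero(ev == u) for u in np.unique(ev)]
        parts: list[list[int]] = [[], [], []]
        for stratum in strata:
            perm = stratum[rng.permutation(len(stratum))]
            n_train = int(np.floor(len(perm) * proportions[0]))
            n_val = int(np.floor(len(perm) * proportions[1]))
            parts[0].extend(perm[:n_train])
            parts[1].extend(perm[n_train : n_train + n_val])
            parts[2].extend(perm[n_train + n_val :])
        if any(len(p) == 0 for p in parts):
            raise ValueError(f"too few samples ({n}) for nonempty train/val/test parts")
        plans.append(
            SplitPlan(
                train=[sample_ids[i] for i in sorted(parts[0])],
                val=[sample_ids[i] for i in sorted(parts[1])],
                test=[sample_ids[i] for i in sorted(parts[2])],
                seed=seed,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# targets


def prepare_targets(tasks: list[TaskSpec], columns: dict[str, np.ndarray]) -> list[dict]:
    """Assemble per-task target arrays with missing-value masks.

    `columns` maps clinical column names to per-sample arrays; survival
    tasks expect `<name>` (time) and `<name>_event`.  Samples with a missing
    target are masked out of that task's loss only.
    """
    out = []
    for task in tasks:
        if task.kind == "survival":
            times = np.asarray(columns[task.name], dtype=float)
            events = np.asarray(columns[f"{task.name}_event"], dtype=float)
            mask = np.isfinite(times) & np.isfinite(events)
            idx = np.zeros(len(times), dtype=int)
            ev = np.zeros(len(times), dtype=int)
            for i in np.flatnonzero(mask):
                ev[i] = int(events[i])
                idx[i] = (
                    task.discretization.event_interval(times[i])
                    if ev[i] == 1
                    else task.discretization.intervals_survived(times[i])
                )
            out.append({"kind": "survival", "time": times, "event": ev, "interval_idx": idx, "mask": mask})
        elif task.kind == "classification":
            raw = np.asarray(columns[task.name])
            vocab = {c: i for i, c in enumerate(task.classes)}
            labels = np.full(len(raw), -1, dtype=int)
            for i, v in enumerate(raw):
                if isinstance(v, float) and np.isnan(v):
                    continue
                labels[i] = vocab[str(v)]
            out.append({"kind": "classification", "y": labels, "mask": labels >= 0})
        else:
            y = np.asarray(columns[task.name], dtype=float)
            out.append({"kind": "regression", "y": y, "mask": np.isfinite(y)})
    return out


def _task_loss(task: TaskSpec, output: Tensor, target: dict, idx: np.ndarray) -> Tensor | None:
    """Masked mean loss for one task on the batch rows `idx` (absolute indices)."""
    sub_mask = target["mask"][idx]
    rows = np.flatnonzero(sub_mask)
    if len(rows) == 0:
        return None
    keep = idx[rows]
    if task.kind == "regression":
        pred = output[rows].reshape(len(rows))
        diff = pred - Tensor(target["y"][keep])
        return (diff * diff).mean()
    if task.kind == "classification":
        logits = output[rows]
        lp = nn.log_softmax(logits, axis=-1)
        picked = lp[np.arange(len(rows)), target["y"][keep]]
        return -picked.mean()
    return mtlr_nll_t(output[rows], target["interval_idx"][keep], target["event"][keep])


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainState:
    epoch: int = 0
    best_epoch: int = -1
    best_val_loss: float = np.inf
    patience_left: int = 0
    history: list[dict] = field(default_factory=list)


def _flatten(params: list[Tensor], grads: dict[int, np.ndarray]) -> np.ndarray:
    return np.concatenate([grads.get(id(p), np.zeros_like(p.data)).ravel() for p in params])


def _unflatten(params: list[Tensor], flat: np.ndarray) -> None:
    pos = 0
    for p in params:
        n = p.data.size
        p.grad = flat[pos : pos + n].reshape(p.data.shape)
        pos += n


def train(
    model: GeneTransformer,
    expr: np.ndarray,
    targets: list[dict],
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    lr: float = 1e-4,
    batch_size: int = 32,
    max_epochs: int = 500,
    patience: int = 10,
    pcgrad: bool = True,
    seed: int = 0,
    verbose: bool = False,
    warmup_steps: int = 50,
    clip_norm: float | None = 5.0,
    min_epochs: int = 0,
) -> TrainState:
    """Train with Adam and early stopping on the validation composite loss.

    With `pcgrad` enabled, the shared encoder receives the PCGrad-merged
    gradient of the weighted task losses; each task head always receives its
    own task's unmodified (weighted) gradient.  A linear learning-rate
    warmup over `warmup_steps` optimizer steps and global-norm gradient
    clipping (`clip_norm`) stabilise the early epochs.  The parameters
    minimising the validation loss are restored before returning.
    """
    expr = np.asarray(expr, dtype=float)
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    tasks = model.tasks
    shared = model.shared_params()
    heads = [model.head_params(t) for t in range(len(tasks))]
    opt = Adam(model.all_params(), lr=lr)
    rng = np.random.default_rng(seed)
    dropout_rng = np.random.default_rng((seed, 1))
    state = TrainState(patience_left=patience)
    best_params: dict[str, np.ndarray] | None = None
    step = 0

    def _clip(params: list[Tensor]):
        if clip_norm is None:
            return
        total = np.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
        if total > clip_norm:
            scale = clip_norm / total
            for p in params:
                if p.grad is not None:
                    p.grad = p.grad * scale

    for epoch in range(max_epochs):
        order = train_idx[rng.permutation(len(train_idx))]
        epoch_losses = np.zeros(len(tasks))
        n_batches = 0
        for s in range(0, len(order), batch_size):
            idx = order[s : s + batch_size]
            pooled, outputs, _ = model.forward(
                expr[idx], dropout_rng=dropout_rng if model.config.dropout > 0 else None
            )
            losses = [_task_loss(task, out, tgt, idx) for task, out, tgt in zip(tasks, outputs, targets)]
            weighted = [
                None if L is None or task.weight == 0 else L * task.weight for task, L in zip(tasks, losses)
            ]
            active = [t for t, w in enumerate(weighted) if w is not None]
            if not active:
                continue
            for t, L in enumerate(losses):
                if L is not None:
                    epoch_losses[t] += float(L.data)
            n_batches += 1
            if not np.all(np.isfinite([float(losses[t].data) for t in active])):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            if pcgrad and len(active) > 1:
                task_grads = []
                head_grads: list[dict[int, np.ndarray]] = []
                for t in active:
                    weighted[t].backward()
                    task_grads.append(_flatten(shared, {id(p): p.grad for p in shared if p.grad is not None}))
                    head_grads.append({id(p): p.grad.copy() for p in heads[t] if p.grad is not None})
                merged = pcgrad_project(task_grads, rng)
                opt.zero_grad()
                _unflatten(shared, merged)
                for t, hg in zip(active, head_grads):
                    for p in heads[t]:
                        if id(p) in hg:
                            p.grad = hg[id(p)]
            else:
                total = weighted[active[0]]
                for t in active[1:]:
                    total = total + weighted[t]
                total.backward()
            _clip(model.all_params())
            step += 1
            opt.lr = lr * min(1.0, step / max(1, warmup_steps))
            opt.step()
        state.epoch = epoch
        val_loss = _composite_eval_loss(model, expr, targets, val_idx)
        state.history.append(
            {"epoch": epoch, "train_losses": (epoch_losses / max(1, n_batches)).tolist(), "val_loss": val_loss}
        )
        if verbose:
            print(f"epoch {epoch}: val composite loss {val_loss:.4f}")
        if val_loss < state.best_val_loss - 1e-12:
            state.best_val_loss = val_loss
            state.best_epoch = epoch
            state.patience_left = patience
            best_params = {n: p.data.copy() for n, p in model.params.items()}
        elif epoch >= min_epochs:
            state.patience_left -= 1
            if state.patience_left <= 0:
                break
    if best_params is not None:
        for n, p in model.params.items():
            p.data = best_params[n]
    return state


def _composite_eval_loss(model: GeneTransformer, expr: np.ndarray, targets: list[dict], idx: np.ndarray) -> float:
    idx = np.asarray(idx, dtype=int)
    total = 0.0
    _, outputs, _ = model.forward(expr[idx])
    for task, out, tgt in zip(model.tasks, outputs, targets):
        sub_mask = tgt["mask"][idx]
        rows = np.flatnonzero(sub_mask)
        if len(rows) == 0 or task.weight == 0:
            continue
        keep = idx[rows]
        if task.kind == "regression":
            pred = out.data[rows, 0]
            total += task.weight * float(np.mean((pred - tgt["y"][keep]) ** 2))
        elif task.kind == "classification":
            logits = out.data[rows]
            shifted = logits - logits.max(axis=1, keepdims=True)
            lp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
            total += task.weight * float(-lp[np.arange(len(rows)), tgt["y"][keep]].mean())
        else:
            total += task.weight * float(
                mtlr_nll(out.data[rows], tgt["interval_idx"][keep], tgt["event"][keep]).mean()
            )
    return total


# ---------------------------------------------------------------------------
# evaluation


def evaluate(model: GeneTransformer, expr: np.ndarray, targets: list[dict], idx: np.ndarray) -> dict:
    """Held-out metrics per task (C-index/IBS for survival, ACC/F1, MAE/SCC)."""
    idx = np.asarray(idx, dtype=int)
    _, outputs, _ = model.forward(expr[idx])
    report: dict[str, dict] = {}
    for t, (task, out) in enumerate(zip(model.tasks, outputs)):
        tgt = targets[t]
        rows = np.flatnonzero(tgt["mask"][idx])
        keep = idx[rows]
        if len(rows) == 0:
            report[task.name] = {}
            continue
        if task.kind == "survival":
            surv, risk = mtlr_survival_curve(out.data[rows])
            times, events = tgt["time"][keep], tgt["event"][keep]
            entry = {"C-Index": concordance_index(risk, times, events)}
            bounds = task.discretization.boundaries
            tau = times[events == 1].max() if (events == 1).any() else None
            if tau is not None:
                grid_cols = np.flatnonzero(bounds[1:] <= tau)
                if len(grid_cols) >= 1:
                    grid = np.concatenate([[0.0], bounds[1:][grid_cols]])
                    probs = np.concatenate([np.ones((len(rows), 1)), surv[:, grid_cols]], axis=1)
                    try:
                        entry["IBS"] = integrated_brier_score(probs, times, events, grid)
                    except ValueError:
                        pass
            report[task.name] = entry
        elif task.kind == "classification":
            pred = out.data[rows].argmax(axis=1)
            report[task.name] = tabular_metrics(tgt["y"][keep], pred, "classification")
        else:
            report[task.name] = tabular_metrics(tgt["y"][keep], out.data[rows, 0], "regression")
    return report


# ---------------------------------------------------------------------------
# cluster-based cross-validation


def cluster_cv(
    embeddings: np.ndarray,
    k: int = 5,
    seed: int = 0,
    val_fraction: float = 0.125,
    retry_limit: int = 5,
) -> list[dict]:
    """Cluster-based CV folds from patient embeddings.

    Samples are clustered with seeded k-means (k-means++ init); each cluster
    in turn is the test fold and the remainder is re-split into train and
    validation.  Returns one dict per fold with integer index arrays
    ``train``, ``val``, ``test`` and the cluster ``labels``.
    """
    if k < 2:
        raise ValueError("cluster CV needs k >= 2")
    embeddings = np.asarray(embeddings, dtype=float)
    n = len(embeddings)
    if k > n:
        raise ValueError("more clusters than samples")
    labels = None
    for attempt in range(retry_limit):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt)
        cand = km.fit_predict(embeddings)
        if len(np.unique(cand)) == k:
            labels = cand
            break
        warnings.warn("empty cluster; re-seeding k-means", stacklevel=2)
    if labels is None:
        raise RuntimeError("k-means failed to produce k nonempty clusters")
    rng = np.random.default_rng(seed)
    folds = []
    for c in range(k):
        test = np.flatnonzero(labels == c)
        rest = np.flatnonzero(labels != c)
        rest = rest[rng.permutation(len(rest))]
        n_val = max(1, int(len(rest) * val_fraction))
        folds.append(
            {"test": np.sort(test), "val": np.sort(rest[:n_val]), "train": np.sort(rest[n_val:]), "labels": labels}
        )
    return folds
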