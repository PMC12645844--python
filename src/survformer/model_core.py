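"""Transformer encoder over genes with expression-derived positional attention.

Genes play the role of tokens: every sample shares the same token
embeddings (pretrained on a PPI graph), and the only sample-specific signal
enters through the attention logits, where each head h adds a positional
term built from the per-gene expression values e:

    logit(i, j) = (g_i W^Q)(g_j W^K)^T / sqrt(2d)
                + (e_i u^Q)(e_j u^K)^T / sqrt(2d)

with learned projection vectors u^Q, u^K (length d, per head, shared across
layers).  Because e_i is a scalar, the positional term equals
e_i * e_j * (u^Q . u^K) / sqrt(2d) — a rank-one sample-specific modulation
of attention.  The value pathway is a standard learned projection with no
positional contribution (untied, TUPE-style).  Pre-norm residual blocks
with gene-wise feed-forward layers follow each attention block; pooling
over genes yields the sample embedding consumed by task-specific heads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .losses_metrics import TaskSpec

__all__ = ["ModelConfig", "GeneTransformer", "attention_logits", "prune_head", "unprune_head"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters."""

    n_layers: int = 2
    n_heads: int = 4
    d_model: int = 64
    d_ff: int = 128
    head_hidden: int = 32
    dropout: float = 0.1
    pooling: str = "mean"  # "mean" | "max" | "attention"
    positional_per_layer: bool = False  # default: u^Q, u^K shared across layers
    dtype: str = "float32"  # training precision; "float64" for gradient checks

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.pooling not in ("mean", "max", "attention"):
            raise ValueError(f"unknown pooling mode {self.pooling!r}")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")
        for name in ("n_layers", "n_heads", "d_model", "d_ff", "head_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


def attention_logits(
    gene_reprs: np.ndarray,
    expr: np.ndarray,
    w_q: np.ndarray,
    w_k: np.ndarray,
    u_q: np.ndarray,
    u_k: np.ndarray,
) -> np.ndarray:
    """Pre-softmax attention logits for one layer/head (reference form).

    `gene_reprs` is (n_genes, d_model) for the layer, `expr` the sample's
    per-gene (normalised) expression vector, `w_q`/`w_k` the d_model x d
    projections and `u_q`/`u_k` the length-d positional projection vectors.
    """
    gene_reprs = np.asarray(gene_reprs, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if gene_reprs.shape[0] != expr.shape[0]:
        raise ValueError("expression vector must align with gene representations")
    if w_q.shape != w_k.shape or gene_reprs.shape[1] != w_q.shape[0]:
        raise ValueError("projection shapes inconsistent with gene representations")
    d = w_q.shape[1]
    if u_q.shape != (d,) or u_k.shape != (d,):
        raise ValueError("positional projection vectors must have length d")
    scale = 1.0 / np.sqrt(2.0 * d)
    q = gene_reprs @ w_q
    k = gene_reprs @ w_k
    content = q @ k.T
    pos = np.outer(expr, u_q) @ np.outer(expr, u_k).T
    return scale * (content + pos)


class GeneTransformer:
    """Multitask transformer over gene tokens.

    Parameters live in a flat dict of named autodiff tensors; the pretrained
    gene embedding table is a fixed input projected into the model width.
    """

    def __init__(
        self,
        config: ModelConfig,
        gene_ids: list[str],
        gene_embeddings: np.ndarray,
        tasks: list[TaskSpec],
        seed: int = 0,
    ):
        gene_embeddings = np.asarray(gene_embeddings, dtype=float)
        if gene_embeddings.shape[0] != len(gene_ids):
            raise ValueError("one embedding vector per gene required")
        self.config = config
        self.np_dtype = np.float32 if config.dtype == "float32" else np.float64
        self.gene_ids = [str(g) for g in gene_ids]
        self.gene_embeddings = gene_embeddings.astype(self.np_dtype)
        self.tasks = list(tasks)
        self.rng = np.random.default_rng(seed)
        self.head_mask = np.ones((config.n_layers, config.n_heads))
        self.norm_stats: dict | None = None
        self.params: dict[str, Tensor] = {}
        self._build(seed)

    # -- parameter setup -----------------------------------------------------
    def _param(self, name: str, shape: tuple[int, ...], scale: float | None = None) -> Tensor:
        if scale is None:
            scale = 1.0 / np.sqrt(shape[0])
        t = Tensor(self.rng.normal(scale=scale, size=shape).astype(self.np_dtype), requires_grad=True, name=name)
        self.params[name] = t
        return t

    def _zeros(self, name: str, shape: tuple[int, ...]) -> Tensor:
        t = Tensor(np.zeros(shape, dtype=self.np_dtype), requires_grad=True, name=name)
        self.params[name] = t
        return t

    def _ones(self, name: str, shape: tuple[int, ...]) -> Tensor:
        t = Tensor(np.ones(shape, dtype=self.np_dtype), requires_grad=True, name=name)
        self.params[name] = t
        return t

    def _build(self, seed: int):
        cfg = self.config
        d_g = self.gene_embeddings.shape[1]
        self._param("embed_proj", (d_g, cfg.d_model))
        n_pos = cfg.n_layers if cfg.positional_per_layer else 1
        for s in range(n_pos):
            # positional projection vectors per head; modest init so the
            # positional term starts comparable to the content term
            self._param(f"u_q.{s}", (cfg.n_heads, cfg.d_head), scale=0.5)
            self._param(f"u_k.{s}", (cfg.n_heads, cfg.d_head), scale=0.5)
        for l in range(cfg.n_layers):
            for nm in ("w_q", "w_k", "w_v", "w_o"):
                self._param(f"layer{l}.{nm}", (cfg.d_model, cfg.d_model))
            self._ones(f"layer{l}.ln1_g", (cfg.d_model,))
            self._zeros(f"layer{l}.ln1_b", (cfg.d_model,))
            self._ones(f"layer{l}.ln2_g", (cfg.d_model,))
            self._zeros(f"layer{l}.ln2_b", (cfg.d_model,))
            self._param(f"layer{l}.ff1", (cfg.d_model, cfg.d_ff))
            self._zeros(f"layer{l}.ff1_b", (cfg.d_ff,))
            self._param(f"layer{l}.ff2", (cfg.d_ff, cfg.d_model))
            self._zeros(f"layer{l}.ff2_b", (cfg.d_model,))
        self._ones("ln_out_g", (cfg.d_model,))
        self._zeros("ln_out_b", (cfg.d_model,))
        if cfg.pooling == "attention":
            self._param("pool_q", (cfg.d_model,))
        for t, task in enumerate(self.tasks):
            self._param(f"head{t}.w1", (cfg.d_model, cfg.head_hidden))
            self._zeros(f"head{t}.b1", (cfg.head_hidden,))
            self._param(f"head{t}.w2", (cfg.head_hidden, task.output_dim))
            self._zeros(f"head{t}.b2", (task.output_dim,))

    def shared_params(self) -> list[Tensor]:
        return [t for n, t in self.params.items() if not n.startswith("head")]

    def head_params(self, task_index: int) -> list[Tensor]:
        return [t for n, t in self.params.items() if n.startswith(f"head{task_index}.")]

    def all_params(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward -------------------------------------------------------------
    def _positional_slot(self, layer: int) -> int:
        return layer if self.config.positional_per_layer else 0

    def encoder_forward(
        self,
        expr: np.ndarray,
        capture_attention: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, np.ndarray | None, Tensor]:
        """Run the encoder on a batch of expression vectors.

        Returns (pooled sample embeddings (B, d_model), attention tensor
        (B, n_layers, n_heads, n_genes, n_genes) if captured, final layer
        state (B, n_genes, d_model)).  `dropout_rng` enables dropout
        (training mode); inference is deterministic.
        """
        cfg = self.config
        expr = np.atleast_2d(np.asarray(expr, dtype=self.np_dtype))
        B, n_genes = expr.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(f"expression has {n_genes} genes, model expects {len(self.gene_ids)}")
        P = self.params
        g0 = Tensor(self.gene_embeddings) @ P["embed_proj"]  # (n_genes, d_model)
        x = g0.reshape(1, n_genes, cfg.d_model) + Tensor(np.zeros((B, 1, 1), dtype=self.np_dtype))
        ee = expr[:, :, None] * expr[:, None, :]  # (B, n_genes, n_genes)
        scale = 1.0 / np.sqrt(2.0 * cfg.d_head)
        captured = (
            np.empty((B, cfg.n_layers, cfg.n_heads, n_genes, n_genes)) if capture_attention else None
        )
        for l in range(cfg.n_layers):
            h = nn.layer_norm(x, P[f"layer{l}.ln1_g"], P[f"layer{l}.ln1_b"])
            q = (h @ P[f"layer{l}.w_q"]).reshape(B, n_genes, cfg.n_heads, cfg.d_head).transpose(0, 2, 1, 3)
            k = (h @ P[f"layer{l}.w_k"]).reshape(B, n_genes, cfg.n_heads, cfg.d_head).transpose(0, 2, 1, 3)
            v = (h @ P[f"layer{l}.w_v"]).reshape(B, n_genes, cfg.n_heads, cfg.d_head).transpose(0, 2, 1, 3)
            s = self._positional_slot(l)
            # per-head scalar u^Q . u^K; the positional logit term is its
            # product with e_i e_j (algebraically identical to the outer form)
            c_h = (P[f"u_q.{s}"] * P[f"u_k.{s}"]).sum(axis=1)  # (n_heads,)
            # fold the 1/sqrt(2d) scale into the small factors (q and c_h)
            # rather than scaling the full n_genes x n_genes logit tensor
            attn = nn.fused_pos_attention(q * scale, k, c_h * scale, ee)
            if np.any(~np.isfinite(attn.data)):
                raise FloatingPointError(f"non-finite attention weights at layer {l}")
            if capture_attention:
                captured[:, l] = attn.data
            ctx = attn @ v  # (B, H, n_genes, d_head)
            mask = self.head_mask[l].reshape(1, cfg.n_heads, 1, 1).astype(self.np_dtype)
            ctx = ctx * Tensor(mask)
            ctx = ctx.transpose(0, 2, 1, 3).reshape(B, n_genes, cfg.d_model)
            attn_out = ctx @ P[f"layer{l}.w_o"]
            attn_out = self._dropout(attn_out, dropout_rng)
            x = x + attn_out
            h2 = nn.layer_norm(x, P[f"layer{l}.ln2_g"], P[f"layer{l}.ln2_b"])
            ff = nn.relu(h2 @ P[f"layer{l}.ff1"] + P[f"layer{l}.ff1_b"]) @ P[f"layer{l}.ff2"] + P[f"layer{l}.ff2_b"]
            ff = self._dropout(ff, dropout_rng)
            x = x + ff
            if np.any(~np.isfinite(x.data)):
                raise FloatingPointError(f"non-finite activations after layer {l}")
        x = nn.layer_norm(x, P["ln_out_g"], P["ln_out_b"])
        if cfg.pooling == "mean":
            pooled = x.mean(axis=1)
        elif cfg.pooling == "max":
            pooled = x.max(axis=1)
        else:  # attention-weighted pooling over genes
            w = nn.softmax(x @ P["pool_q"].reshape(cfg.d_model, 1), axis=1)  # (B, n_genes, 1)
            pooled = (x * w).sum(axis=1)
        return pooled, captured, x

    def _dropout(self, t: Tensor, rng: np.random.Generator | None) -> Tensor:
        p = self.config.dropout
        if rng is None or p <= 0:
            return t
        keep = (rng.random(t.shape) >= p).astype(self.np_dtype) / np.asarray(1.0 - p, dtype=self.np_dtype)
        return t * Tensor(keep)

    def task_heads_forward(self, pooled: Tensor) -> list[Tensor]:
        """Per-task outputs: regression (B,1); classification (B,C); survival (B,m)."""
        outs = []
        for t, _task in enumerate(self.tasks):
            h = nn.relu(pooled @ self.params[f"head{t}.w1"] + self.params[f"head{t}.b1"])
            outs.append(h @ self.params[f"head{t}.w2"] + self.params[f"head{t}.b2"])
        return outs

    def forward(
        self, expr: np.ndarray, capture_attention: bool = False, dropout_rng: np.random.Generator | None = None
    ) -> tuple[Tensor, list[Tensor], np.ndarray | None]:
        pooled, attn, _ = self.encoder_forward(expr, capture_attention, dropout_rng)
        return pooled, self.task_heads_forward(pooled), attn

    def attention_tensor(self, expr: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Post-softmax attention weights (B, n_layers, n_heads, n_genes, n_genes)."""
        expr = np.atleast_2d(expr)
        parts = []
        for s in range(0, len(expr), batch_size):
            _, attn, _ = self.encoder_forward(expr[s : s + batch_size], capture_attention=True)
            parts.append(attn)
        return np.concatenate(parts, axis=0)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path, norm_stats: dict | None = None) -> None:
        path = Path(path)
        arrays = {f"param::{n}": t.data for n, t in self.params.items()}
        arrays["head_mask"] = self.head_mask
        arrays["gene_embeddings"] = self.gene_embeddings
        meta = {
            "config": asdict(self.config),
            "gene_ids": self.gene_ids,
            "tasks": [
                {
                    "name": t.name,
                    "kind": t.kind,
                    "weight": t.weight,
                    "classes": t.classes,
                    "boundaries": None if t.discretization is None else t.discretization.boundaries.tolist(),
                }
                for t in self.tasks
            ],
            "norm_stats": norm_stats,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GeneTransformer":
        from .losses_metrics import SurvivalDiscretization

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            tasks = [
                TaskSpec(
                    name=t["name"],
                    kind=t["kind"],
                    weight=t["weight"],
                    classes=t["classes"],
                    discretization=None
                    if t["boundaries"] is None
                    else SurvivalDiscretization(np.asarray(t["boundaries"])),
                )
                for t in meta["tasks"]
            ]
            model = cls(ModelConfig(**meta["config"]), meta["gene_ids"], data["gene_embeddings"], tasks)
            for name in list(model.params):
                model.params[name].data = data[f"param::{name}"].copy()
            model.head_mask = data["head_mask"].copy()
            model.norm_stats = meta.get("norm_stats")
        return model


def prune_head(model: GeneTransformer, layer: int, head: int) -> GeneTransformer:
    """Zero one attention head's output contribution at inference (in place)."""
    if not (0 <= layer < model.config.n_layers and 0 <= head < model.config.n_heads):
        raise IndexError(f"no head ({layer}, {head}) in this model")
    model.head_mask[layer, head] = 0.0
    return model


def unprune_head(model: GeneTransformer, layer: int, head: int) -> GeneTransformer:
    if not (0 <= layer < model.config.n_layers and 0 <= head < model.config.n_heads):
        raise IndexError(f"no head ({layer}, {head}) in this model")
    model.head_mask[layer, head] = 1.0
    return model
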