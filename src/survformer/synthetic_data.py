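"""Fully synthetic datasets with the statistical structure the model assumes.

The generator emulates a bulk RNA-seq survival cohort: genes are organised
into correlated co-expression modules driven by latent factors; FPKM values
are log-normal (so log2(FPKM+1) is right-skewed with a floor at zero, as in
real data); a gene graph is enriched for within-module edges on top of a
scale-free background, so graph-based embeddings carry information about
the expression structure; clinical covariates are noisy functions of the
module activities; and survival times follow an exponential hazard

    h = h0 * exp(beta . x_planted + gamma * x_a * x_b)

on standardised log-expression of a few planted genes, including one
multiplicative gene-gene interaction, with independent exponential
censoring calibrated to a target censoring fraction.  A manifest records
every piece of ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_preprocess import ClinicalTable, ExpressionMatrix, TaskColumn

__all__ = ["SyntheticSpec", "generate", "generate_attention_fixture"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort."""

    n_samples: int = 600
    n_genes: int = 120
    n_modules: int = 6
    module_size: int = 15
    loading: float = 0.9  # module factor loading on member genes
    gene_noise_sd: float = 0.45  # residual latent noise per gene
    expr_scale: float = 1.2  # latent -> log FPKM scale (controls skew)
    expr_baseline_mean: float = 1.0
    expr_baseline_sd: float = 1.0
    # survival: planted main-effect genes and one interacting pair
    beta: float = 0.6  # log-hazard per sd of each planted main-effect gene
    gamma: float = 1.5  # log-hazard of the pairwise interaction term
    n_beta_genes: int = 2
    baseline_hazard: float = 0.05  # events per time unit at risk 0
    censoring_rate: float = 0.3  # target fraction censored
    # clinical noise
    age_noise_sd: float = 5.0
    size_noise_sd: float = 4.0
    # graph
    ba_attachment: int = 2  # scale-free background attachment parameter
    within_module_edge_p: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring rate must be in [0, 1)")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module sizes must sum to at most n_genes")
        if not np.isfinite([self.beta, self.gamma]).all():
            raise ValueError("effect sizes must be finite")


def _calibrate_censoring(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with E[c / (c + h)] = target."""
    if target == 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards)))

    lo, hi = 1e-12, 1e12
    if frac(hi) < target:
        raise ValueError(f"censoring rate {target} infeasible for these hazards")
    return brentq(lambda c: frac(c) - target, lo, hi, xtol=1e-12, rtol=1e-10)


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, ClinicalTable, nx.Graph, dict]:
    """Generate (expression in FPKM-like units, clinical table, gene graph, manifest)."""
    rng = np.random.default_rng(spec.seed)
    ns, ng = spec.n_samples, spec.n_genes
    gene_ids = [f"G{i:04d}" for i in range(ng)]
    sample_ids = [f"S{i:04d}" for i in range(ns)]

    # module assignment: first n_modules * module_size genes belong to modules
    module_of = np.full(ng, -1, dtype=int)
    for m in range(spec.n_modules):
        module_of[m * spec.module_size : (m + 1) * spec.module_size] = m

    # latent expression: module factor x loading + per-gene noise
    factors = rng.normal(size=(ns, spec.n_modules))
    latent = rng.normal(scale=spec.gene_noise_sd, size=(ns, ng))
    for g in range(ng):
        if module_of[g] >= 0:
            latent[:, g] += spec.loading * factors[:, module_of[g]]

    baseline = rng.normal(loc=spec.expr_baseline_mean, scale=spec.expr_baseline_sd, size=ng)
    fpkm = np.exp(baseline + spec.expr_scale * latent)

    # the hazard sees what the model sees: standardised log2(FPKM+1)
    logx = np.log2(fpkm + 1.0)
    z = (logx - logx.mean(axis=0)) / np.where(logx.std(axis=0) == 0, 1.0, logx.std(axis=0))

    # planted survival genes: main effects in modules 0..n_beta-1, the
    # interacting pair inside one module so its members co-express
    beta_genes = [m * spec.module_size for m in range(spec.n_beta_genes)]
    pair = (spec.n_beta_genes * spec.module_size, spec.n_beta_genes * spec.module_size + 1)
    risk = spec.beta * z[:, beta_genes].sum(axis=1) + spec.gamma * z[:, pair[0]] * z[:, pair[1]]
    hazards = spec.baseline_hazard * np.exp(risk)
    event_times = rng.exponential(1.0 / hazards)
    c_rate = _calibrate_censoring(hazards, spec.censoring_rate)
    if c_rate > 0:
        censor_times = rng.exponential(1.0 / c_rate, size=ns)
        times = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    else:
        times, events = event_times, np.ones(ns, dtype=int)

    # clinical covariates as noisy functions of module activities
    age = 55.0 + 8.0 * factors[:, 0] + rng.normal(scale=spec.age_noise_sd, size=ns)
    tumor_size = 22.0 + 6.0 * factors[:, 1 % spec.n_modules] + rng.normal(scale=spec.size_noise_sd, size=ns)
    grade_latent = factors[:, 2 % spec.n_modules] + rng.normal(scale=0.6, size=ns)
    grade = np.digitize(grade_latent, [-0.6, 0.6]) + 1  # ordinal 1..3
    n_subtypes = min(4, spec.n_modules)
    subtype_scores = factors[:, :n_subtypes] + rng.normal(scale=0.8, size=(ns, n_subtypes))
    subtype = np.array([f"ST{j}" for j in subtype_scores.argmax(axis=1)])

    clin = pd.DataFrame(
        {
            "age": age,
            "tumor_size": tumor_size,
            "grade": grade.astype(str),
            "subtype": subtype,
            "survival": times,
            "survival_event": events,
        },
        index=sample_ids,
    )
    schema = [
        TaskColumn("age", "regression"),
        TaskColumn("tumor_size", "regression"),
        TaskColumn("grade", "classification", classes=["1", "2", "3"]),
        TaskColumn("subtype", "classification", classes=[f"ST{j}" for j in range(n_subtypes)]),
        TaskColumn("survival", "survival", event_col="survival_event"),
    ]
    clinical = ClinicalTable(sample_ids, clin, schema)

    # gene graph: scale-free background + dense within-module wiring
    graph = nx.barabasi_albert_graph(ng, spec.ba_attachment, seed=int(rng.integers(2**31 - 1)))
    graph = nx.relabel_nodes(graph, {i: gene_ids[i] for i in range(ng)})
    for m in range(spec.n_modules):
        members = [g for g in range(ng) if module_of[g] == m]
        for a_i, a in enumerate(members):
            for b in members[a_i + 1 :]:
                if rng.random() < spec.within_module_edge_p:
                    graph.add_edge(gene_ids[a], gene_ids[b])
    graph.remove_edges_from(nx.selfloop_edges(graph))

    manifest = {
        "gene_ids": gene_ids,
        "module_of": module_of.tolist(),
        "beta_genes": [gene_ids[g] for g in beta_genes],
        "interaction_pair": [gene_ids[pair[0]], gene_ids[pair[1]]],
        "beta": spec.beta,
        "gamma": spec.gamma,
        "oracle_risk": risk.tolist(),
        "censoring_rate_target": spec.censoring_rate,
        "censoring_rate_realized": float(1 - events.mean()),
        "censoring_exponential_rate": c_rate,
        "seed": spec.seed,
    }
    expr = ExpressionMatrix(sample_ids, gene_ids, fpkm)
    return expr, clinical, graph, manifest


def generate_attention_fixture(
    n_samples: int = 50,
    n_genes: int = 30,
    n_layers: int = 1,
    n_heads: int = 2,
    hub_gene: int | None = None,
    hub_strength: float = 20.0,
    shift_gene: int | None = None,
    shift_sigmas: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired row-stochastic attention tensors for analysis tests.

    Returns two tensors of shape (n_samples, n_layers, n_heads, n_genes,
    n_genes).  Both are independent draws from the same null distribution;
    optionally the second tensor plants a hub (one key gene whose column is
    boosted in every row) and/or shifts one gene's aggregate incoming
    attention by `shift_sigmas` null standard deviations.
    """
    rng = np.random.default_rng(seed)

    def draw() -> np.ndarray:
        raw = rng.exponential(size=(n_samples, n_layers, n_heads, n_genes, n_genes))
        return raw / raw.sum(axis=-1, keepdims=True)

    base = draw()
    other = draw()
    if hub_gene is not None:
        other[..., hub_gene] *= hub_strength
        other /= other.sum(axis=-1, keepdims=True)
    if shift_gene is not None:
        # aggregate score = mean incoming attention; estimate its null sd
        scores = base.mean(axis=(1, 2, 3))  # (n_samples, n_genes) per-key means
        sigma = scores[:, shift_gene].std()
        other[..., shift_gene] += shift_sigmas * sigma
        other = np.clip(other, 0.0, None)
        other /= other.sum(axis=-1, keepdims=True)
    return base, other
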