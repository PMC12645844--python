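"""Reading, writing and preprocessing of expression, clinical and gene-set data.

The preprocessing chain mirrors standard bulk RNA-seq practice for
attention-based models: log2(FPKM+1) transformation, per-gene
standardisation with training-set statistics, and selection of highly
variable genes restricted to a curated candidate universe (e.g. hallmark
gene sets) so that the gene vocabulary stays at a tractable size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "NormalizationStats",
    "read_expression",
    "log_transform",
    "normalize_per_gene",
    "inverse_normalize",
    "select_hvg",
    "read_gmt",
    "write_gmt",
    "read_clinical",
]


class FormatError(ValueError):
    """Malformed input file."""


class SchemaError(ValueError):
    """Clinical table violates its declared task schema."""


@dataclass
class ExpressionMatrix:
    """Samples x genes real-valued expression matrix.

    ``values[p, i]`` is the expression of gene ``gene_ids[i]`` in sample
    ``sample_ids[p]``, in whatever unit the current pipeline stage uses
    (raw FPKM, log2(FPKM+1), or per-gene z-scores).
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(list(self.sample_ids), list(genes), self.values[:, idx])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        pos = {s: p for p, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in samples]
        return ExpressionMatrix(list(samples), list(self.gene_ids), self.values[idx, :])

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep)


@dataclass
class TaskColumn:
    """Declared type of one clinical column: regression | classification | survival."""

    name: str
    kind: str  # "regression" | "classification" | "survival"
    classes: list[str] | None = None  # classification vocabulary
    event_col: str | None = None  # survival: companion 0/1 event column


@dataclass
class ClinicalTable:
    """Per-sample clinical targets aligned with an ExpressionMatrix.

    Missing values are allowed (NaN / empty); downstream losses mask them
    per task rather than dropping the sample globally.
    """

    sample_ids: list[str]
    data: pd.DataFrame
    schema: list[TaskColumn] = field(default_factory=list)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def survival_arrays(self, task: TaskColumn) -> tuple[np.ndarray, np.ndarray]:
        times = self.data[task.name].to_numpy(dtype=float)
        events = self.data[task.event_col].to_numpy(dtype=float)
        return times, events


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def union(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class NormalizationStats:
    """Per-gene mean/sd fitted on training samples, reused on held-out data."""

    gene_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"gene_ids": self.gene_ids, "mean": self.mean.tolist(), "sd": self.sd.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        d = json.loads(Path(path).read_text())
        return cls(d["gene_ids"], np.asarray(d["mean"]), np.asarray(d["sd"]))


# ---------------------------------------------------------------------------
# readers


def read_expression(path: str | Path, orientation: str = "samples_in_rows", sep: str | None = None) -> ExpressionMatrix:
    """Read a delimited expression table.

    `orientation` declares the file layout ("samples_in_rows" or
    "genes_in_rows"); the returned matrix is always samples x genes.
    Duplicate gene rows are collapsed by their mean.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # noqa: BLE001 - rewrap for a uniform error type
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no data columns found (missing header?)")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[np.argmax(bad.to_numpy())]
            raise FormatError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
    df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        raise FormatError(f"{path}: missing expression values")
    if orientation == "genes_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.columns.duplicated().any():
        df = df.T.groupby(level=0, sort=False).mean().T
    return ExpressionMatrix.from_frame(df)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (tab-separated: name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
        name, desc, *members = parts
        members = [m for m in members if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = members
        descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + list(members))
        for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_clinical(path: str | Path, task_schema: list[TaskColumn], sep: str | None = None) -> ClinicalTable:
    """Read a clinical table and validate it against the declared task schema."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.map(str)
    for task in task_schema:
        if task.name not in df.columns:
            raise SchemaError(f"missing clinical column {task.name!r}")
        if task.kind == "survival":
            if task.event_col is None or task.event_col not in df.columns:
                raise SchemaError(f"survival task {task.name!r} lacks an event indicator column")
            times = pd.to_numeric(df[task.name], errors="coerce")
            events = pd.to_numeric(df[task.event_col], errors="coerce")
            observed = times.notna()
            if (times[observed] < 0).any():
                raise SchemaError(f"survival task {task.name!r}: negative time")
            ev = events[observed].dropna()
            if not ev.isin([0, 1]).all():
                raise SchemaError(f"survival task {task.name!r}: event indicator must be 0 or 1")
        elif task.kind == "classification":
            if task.classes is not None:
                seen = set(df[task.name].dropna().astype(str))
                unknown = seen - set(task.classes)
                if unknown:
                    raise SchemaError(f"classification task {task.name!r}: labels {sorted(unknown)} not in vocabulary")
        elif task.kind == "regression":
            vals = pd.to_numeric(df[task.name], errors="coerce")
            if (df[task.name].notna() & vals.isna()).any():
                raise SchemaError(f"regression task {task.name!r}: non-numeric value")
        else:
            raise SchemaError(f"unknown task kind {task.kind!r}")
    return ClinicalTable(list(df.index), df, task_schema)


# ---------------------------------------------------------------------------
# transformations


def log_transform(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every value v by log2(v + 1). Input must be nonnegative."""
    if np.any(mat.values < 0):
        raise ValueError("log_transform requires nonnegative expression values")
    return ExpressionMatrix(list(mat.sample_ids), list(mat.gene_ids), np.log2(mat.values + 1.0))


def normalize_per_gene(
    mat: ExpressionMatrix, stats: NormalizationStats | None = None
) -> tuple[ExpressionMatrix, NormalizationStats]:
    """Standardise each gene to mean 0 / sd 1.

    When `stats` is None the statistics are fitted on `mat` (the training
    set) and returned for reuse; otherwise the provided statistics are
    applied unchanged, so validation/test data are never refit.
    Zero-variance genes get sd clamped to 1 (their values become 0) to keep
    gene indexing aligned with the embedding table.
    """
    if stats is None:
        if mat.n_samples < 2:
            raise ValueError("need at least 2 samples to fit normalization statistics")
        mean = mat.values.mean(axis=0)
        sd = mat.values.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} zero-variance gene(s); sd clamped to 1", stacklevel=2)
            sd = np.where(zero, 1.0, sd)
        stats = NormalizationStats(list(mat.gene_ids), mean, sd)
    else:
        if list(stats.gene_ids) != list(mat.gene_ids):
            raise ValueError("normalization stats gene order does not match the matrix")
    z = (mat.values - stats.mean) / stats.sd
    return ExpressionMatrix(list(mat.sample_ids), list(mat.gene_ids), z), stats


def inverse_normalize(mat: ExpressionMatrix, stats: NormalizationStats) -> ExpressionMatrix:
    """Undo `normalize_per_gene` with the stored statistics."""
    if list(stats.gene_ids) != list(mat.gene_ids):
        raise ValueError("normalization stats gene order does not match the matrix")
    return ExpressionMatrix(list(mat.sample_ids), list(mat.gene_ids), mat.values * stats.sd + stats.mean)


def select_hvg(mat: ExpressionMatrix, candidate_sets: GeneSetCollection | None, k: int) -> list[str]:
    """Top-k most variable genes within the candidate universe.

    Variance is computed on the matrix as given (conventionally
    log-transformed, not yet standardised — standardised variance is 1 by
    construction).  Ties at the cutoff break lexicographically by gene id;
    the returned list follows the matrix's gene order restricted to the
    selected genes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if candidate_sets is None:
        universe = list(mat.gene_ids)
    else:
        allowed = candidate_sets.union()
        universe = [g for g in mat.gene_ids if g in allowed]
    if not universe:
        raise ValueError("candidate universe is empty after intersecting with the matrix genes")
    if len(universe) <= k:
        if len(universe) < k:
            warnings.warn(f"only {len(universe)} candidate genes available for k={k}", stacklevel=2)
        return universe
    idx = {g: i for i, g in enumerate(mat.gene_ids)}
    var = mat.values.var(axis=0, ddof=0)
    # sort by (-variance, gene id): deterministic tie-break
    ranked = sorted(universe, key=lambda g: (-var[idx[g]], g))
    chosen = set(ranked[:k])
    return [g for g in mat.gene_ids if g in chosen]
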