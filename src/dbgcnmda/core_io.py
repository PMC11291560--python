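"""Data model and I/O for microbe-disease association networks.

The package works on three kinds of tabular artifacts, all plain UTF-8 TSV
with ``#`` comment lines:

* association edge lists — either HMDAD-style triples
  (``microbe<TAB>disease[<TAB>evidence...]``) or a labeled 0/1 matrix with a
  header row of disease names and a first column of microbe names;
* square labeled similarity matrices on one node type;
* long-format prediction tables (microbe, disease, score, rank).

Orientation is fixed throughout the package: rows are microbes, columns are
diseases.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dbgcnmda")

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "RunConfig",
    "read_association_edgelist",
    "write_association",
    "read_similarity",
    "write_similarity",
    "write_scores",
    "read_config",
    "write_config",
]


class ParseError(ValueError):
    """Raised for malformed input files, with the offending line number."""


@dataclass
class AssociationMatrix:
    """Binary bipartite adjacency between microbes (rows) and diseases (columns)."""

    microbe_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.values.shape
        if len(self.microbe_ids) != m or len(self.disease_ids) != n:
            raise ValueError("label lists do not match matrix dimensions")
        if len(set(self.microbe_ids)) != m or len(set(self.disease_ids)) != n:
            raise ValueError("entity labels must be unique")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association entries must be exactly 0 or 1")
        if self.values.sum() == 0:
            raise ValueError("association matrix has no positive entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_positives(self) -> int:
        return int(self.values.sum())

    def masked(self, pairs: Sequence[tuple[int, int]]) -> "AssociationMatrix":
        """Return a copy with the given (microbe, disease) entries zeroed.

        Used to build the training view of the network with held-out
        positives removed, so no downstream similarity or feature sees them.
        """
        values = self.values.copy()
        for i, j in pairs:
            values[i, j] = 0.0
        return AssociationMatrix(list(self.microbe_ids), list(self.disease_ids), values)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity on one node type, entries in [0, 1].

    ``kind`` records provenance: ``functional`` (biology-derived input),
    ``gapk`` (Gaussian interaction-profile kernel of association profiles) or
    ``fused`` (entrywise combination of the two).
    """

    entity_ids: list[str]
    values: np.ndarray
    kind: str = "functional"

    _KINDS = ("functional", "gapk", "fused")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square and match labels")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric (tol 1e-10)")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.entity_ids)


@dataclass
class RunConfig:
    """Hyperparameters for featurization, model architecture and training.

    Defaults follow the package's reference configuration; the paper-scale
    network (292 x 39) trains comfortably with these on one CPU.
    """

    gamma: float = 0.9               # RWR restart probability
    poly_degree: int = 2             # base degree of polynomial feature expansion
    poly_target_dim: int = 1000      # expanded disease feature width
    hidden_dims: list[int] = field(default_factory=lambda: [256, 128, 64])
    n_gcn_layers: int = 3
    alpha: float = 1.0               # positive-target enhancement in the loss
    mu: float = 5e-4                 # L2 weight decay over all trainable weights
    learning_rate: float = 1e-3
    epochs: int = 500
    patience: int = 50               # early stopping on validation AUPR
    seed: int = 0
    test_fraction: float = 0.2
    n_folds: int = 5
    gcn_activation: str = "tanh"         # nonlinearity of the GCN layers
    bandwidth_mode: str = "normalized"   # GAPK bandwidth: "normalized" or "raw"
    per_fold_features: bool = True       # recompute GAPK/RWR from the masked matrix
    standardize_features: bool = True    # column-standardize model inputs
    exclude_test_from_loss: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.poly_degree < 1 or self.poly_target_dim < 1:
            raise ValueError("poly_degree and poly_target_dim must be positive")
        if self.n_gcn_layers < 0:
            raise ValueError("n_gcn_layers must be non-negative")
        if self.bandwidth_mode not in ("normalized", "raw"):
            raise ValueError("bandwidth_mode must be 'normalized' or 'raw'")
        if self.gcn_activation not in ("tanh", "relu", "identity"):
            raise ValueError("gcn_activation must be 'tanh', 'relu' or 'identity'")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _data_lines(path: Path) -> list[tuple[int, str]]:
    lines = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            lines.append((lineno, line))
    return lines


def read_association_edgelist(path, dialect: str = "triples") -> AssociationMatrix:
    """Read an association network from TSV.

    ``triples`` expects one edge per line (microbe, disease, optional extra
    columns such as evidence); duplicate edges collapse to a single 1 and
    labels keep first-appearance order. ``matrix`` expects a labeled 0/1
    matrix with disease names in the header row and microbe names in the
    first column.
    """
    path = Path(path)
    if dialect == "triples":
        lines = _data_lines(path)
        if not lines:
            raise ParseError(f"{path}: no edges found")
        microbes: dict[str, int] = {}
        diseases: dict[str, int] = {}
        edges: list[tuple[int, int]] = []
        for lineno, line in lines:
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ParseError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
            mi = microbes.setdefault(parts[0], len(microbes))
            dj = diseases.setdefault(parts[1], len(diseases))
            edges.append((mi, dj))
        values = np.zeros((len(microbes), len(diseases)))
        for i, j in edges:
            values[i, j] = 1.0
        return AssociationMatrix(list(microbes), list(diseases), values)
    if dialect == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        values = df.to_numpy(dtype=float)
        return AssociationMatrix(
            [str(x).strip() for x in df.index],
            [str(x).strip() for x in df.columns],
            values,
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_association(A: AssociationMatrix, path, dialect: str = "matrix") -> None:
    """Write an association network as labeled matrix TSV or as triples."""
    path = Path(path)
    if dialect == "matrix":
        df = pd.DataFrame(A.values.astype(int), index=A.microbe_ids, columns=A.disease_ids)
        df.to_csv(path, sep="\t")
    elif dialect == "triples":
        with open(path, "w", encoding="utf-8") as fh:
            for i, j in zip(*np.nonzero(A.values)):
                fh.write(f"{A.microbe_ids[i]}\t{A.disease_ids[j]}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_similarity(path, kind: str = "functional") -> SimilarityMatrix:
    """Read a labeled square similarity TSV.

    Asymmetry is repaired by averaging with the transpose and out-of-range
    entries are clipped to [0, 1]; both repairs emit a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    labels = [str(x).strip() for x in df.index]
    col_labels = [str(x).strip() for x in df.columns]
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity matrix must be square, got {df.shape}")
    if labels != col_labels:
        raise ValueError(f"{path}: header labels do not match index labels")
    values = df.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-10):
        warnings.warn(f"{path}: asymmetric similarity symmetrized by averaging")
        values = (values + values.T) / 2
    if values.min() < 0 or values.max() > 1:
        warnings.warn(f"{path}: entries outside [0, 1] clipped")
        values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(labels, values, kind=kind)


def write_similarity(S: SimilarityMatrix, path) -> None:
    pd.DataFrame(S.values, index=S.entity_ids, columns=S.entity_ids).to_csv(
        Path(path), sep="\t"
    )


def write_scores(scores: np.ndarray, microbe_ids, disease_ids, path) -> pd.DataFrame:
    """Write predicted association scores as a ranked long-format TSV.

    One row per (microbe, disease) pair with the rank of the microbe within
    its disease column (descending score, ties broken by microbe label).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(microbe_ids), len(disease_ids)):
        raise ValueError("score matrix shape does not match label lists")
    rows = []
    for j, disease in enumerate(disease_ids):
        order = sorted(range(len(microbe_ids)), key=lambda i: (-scores[i, j], microbe_ids[i]))
        for rank, i in enumerate(order, start=1):
            rows.append((microbe_ids[i], disease, scores[i, j], rank))
    df = pd.DataFrame(rows, columns=["microbe", "disease", "score", "rank"])
    df.to_csv(Path(path), sep="\t", index=False)
    return df


def read_config(path) -> RunConfig:
    """Load a RunConfig from a YAML mapping of field names to values."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
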