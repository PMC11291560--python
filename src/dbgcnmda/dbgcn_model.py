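"""Dual-branch graph convolutional encoder, dense decoder and bilinear scorer.

The model embeds microbes and diseases with two complementary GCN branches:

* **Global branch** — propagation over the heterogeneous microbe-disease
  graph (block adjacency [[0, A], [A^T, 0]]), so microbe embeddings
  aggregate information from their associated diseases and vice versa.
* **Local branch** — propagation over the two homogeneous similarity
  graphs (microbe-microbe and disease-disease), refining the global
  embeddings with same-type neighborhood structure.

Every GCN layer applies the symmetric-normalized propagation with self
loops, E <- act(D^(-1/2) (I + S) D^(-1/2) E W). Three dense layers per node
type decode the embeddings, and the association score is the bilinear inner
product of the decoded microbe and disease representations. Training
minimizes a positive-enhanced Frobenius reconstruction loss: observed
training associations carry target alpha (> 0 raises their margin against
the overwhelming majority of zero targets), held-out positives are zeroed,
and an L2 penalty mu * ||W||^2 decays all trainable weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import _autodiff as ad
from .core_io import AssociationMatrix, RunConfig

__all__ = [
    "VARIANTS",
    "GcnLayerParams",
    "NormalizedGraph",
    "ModelState",
    "build_hetero_graph",
    "normalize_graph",
    "gcn_layer",
    "global_branch",
    "local_branch",
    "decode_and_score",
    "alpha_loss",
    "init_model_state",
    "forward_scores",
]

VARIANTS = ("DBGCNMDA", "FNMDA", "GlobalGCNMDA", "LocalGCNMDA")

_ACTIVATIONS = {
    "relu": lambda x: np.maximum(x, 0.0),
    "tanh": np.tanh,
    "identity": lambda x: x,
}

_ACTIVATIONS_T = {"relu": ad.relu, "tanh": ad.tanh, "identity": lambda t: t}


@dataclass
class GcnLayerParams:
    weight: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        if not np.isfinite(self.weight).all():
            raise ValueError("layer weights must be finite")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class NormalizedGraph:
    """Adjacency plus its precomputed self-loop symmetric normalization."""

    adjacency: np.ndarray
    propagation: np.ndarray

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


def normalize_graph(S: np.ndarray) -> NormalizedGraph:
    """Propagation matrix D^(-1/2) (I + S) D^(-1/2) with self loops added."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("adjacency must be square")
    S_tilde = np.eye(S.shape[0]) + S
    d = S_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    propagation = S_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
    return NormalizedGraph(adjacency=S, propagation=propagation)


def build_hetero_graph(A: AssociationMatrix) -> NormalizedGraph:
    """Normalized heterogeneous graph over the (m + n)-node block adjacency."""
    m, n = A.shape
    S = np.zeros((m + n, m + n))
    S[:m, m:] = A.values
    S[m:, :m] = A.values.T
    return normalize_graph(S)


def gcn_layer(G: NormalizedGraph, E: np.ndarray, P: GcnLayerParams) -> np.ndarray:
    """One propagation step: act(P_hat @ E @ W)."""
    E = np.asarray(E, dtype=float)
    if E.shape[0] != G.n:
        raise ValueError("embedding rows do not match graph size")
    if E.shape[1] != P.weight.shape[0]:
        raise ValueError("embedding width does not match layer input width")
    return _ACTIVATIONS[P.activation](G.propagation @ E @ P.weight)


# ---------------------------------------------------------------------------
# Trainable state


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _chain_widths(config: RunConfig) -> tuple[int, list[int]]:
    """Projection width and global-chain output widths.

    hidden_dims[0] is the common projection width; global layer k outputs
    hidden_dims[min(k, last)], so extra depth repeats the final width.
    """
    dims = config.hidden_dims
    proj = dims[0]
    widths = [dims[min(k, len(dims) - 1)] for k in range(1, config.n_gcn_layers + 1)]
    return proj, widths


@dataclass
class ModelState:
    """All trainable weights plus the configuration snapshot."""

    params: dict[str, np.ndarray]
    config: RunConfig
    variant: str = "DBGCNMDA"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        for name, arr in self.params.items():
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite parameter {name!r}")

    # Views matching the conceptual architecture -------------------------
    @property
    def microbe_proj(self) -> np.ndarray:
        return self.params["microbe_proj"]

    @property
    def disease_proj(self) -> np.ndarray:
        return self.params["disease_proj"]

    def _layers(self, prefix: str) -> list[GcnLayerParams]:
        out = []
        k = 0
        while f"{prefix}{k}" in self.params:
            out.append(
                GcnLayerParams(
                    self.params[f"{prefix}{k}"],
                    activation=self.config.gcn_activation,
                )
            )
            k += 1
        return out

    @property
    def global_layers(self) -> list[GcnLayerParams]:
        return self._layers("global_W")

    @property
    def local_microbe_layers(self) -> list[GcnLayerParams]:
        return self._layers("local_m_W")

    @property
    def local_disease_layers(self) -> list[GcnLayerParams]:
        return self._layers("local_d_W")

    def decoder_layers(self, node_type: str) -> list[tuple[np.ndarray, np.ndarray]]:
        tag = {"microbe": "m", "disease": "d"}[node_type]
        return [
            (self.params[f"dec_{tag}_W{k}"], self.params[f"dec_{tag}_b{k}"])
            for k in range(3)
        ]

    def trainable(self) -> list[str]:
        return sorted(self.params)


def init_model_state(
    m_feat_dim: int,
    d_feat_dim: int,
    config: RunConfig,
    variant: str = "DBGCNMDA",
    rng: np.random.Generator | None = None,
) -> ModelState:
    """Symmetric uniform (fan-based) initialization of every weight array."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    proj, g_widths = _chain_widths(config)
    params: dict[str, np.ndarray] = {
        "microbe_proj": _glorot(rng, m_feat_dim, proj),
        "disease_proj": _glorot(rng, d_feat_dim, proj),
    }
    width = proj
    use_global = variant in ("DBGCNMDA", "GlobalGCNMDA")
    use_local = variant in ("DBGCNMDA", "LocalGCNMDA")
    if use_global:
        for k, out in enumerate(g_widths):
            params[f"global_W{k}"] = _glorot(rng, width, out)
            width = out
    if use_local:
        for k in range(config.n_gcn_layers):
            params[f"local_m_W{k}"] = _glorot(rng, width, width)
            params[f"local_d_W{k}"] = _glorot(rng, width, width)
    # three dense decoder layers per node type, shared widths
    half = max(width // 2, 1)
    dec_dims = [(width, width), (width, half), (half, half)]
    for tag in ("m", "d"):
        for k, (fi, fo) in enumerate(dec_dims):
            params[f"dec_{tag}_W{k}"] = _glorot(rng, fi, fo)
            params[f"dec_{tag}_b{k}"] = np.zeros(fo)
    return ModelState(params=params, config=config, variant=variant)


# ---------------------------------------------------------------------------
# Forward pass (autodiff tensors; public numpy ops wrap this path)


def _forward_embeddings(
    p: dict[str, ad.Tensor],
    state: ModelState,
    G_het: NormalizedGraph | None,
    G_sm: NormalizedGraph | None,
    G_sd: NormalizedGraph | None,
    M_feat: np.ndarray,
    D_feat: np.ndarray,
) -> tuple[ad.Tensor, ad.Tensor]:
    m = M_feat.shape[0]
    act = _ACTIVATIONS_T[state.config.gcn_activation]
    Em = ad.matmul(ad.constant(M_feat), p["microbe_proj"])
    Ed = ad.matmul(ad.constant(D_feat), p["disease_proj"])
    if state.variant in ("DBGCNMDA", "GlobalGCNMDA"):
        # heterogeneous propagation in block form: rows split by node type
        Pmm = ad.constant(G_het.propagation[:m, :m])
        Pmd = ad.constant(G_het.propagation[:m, m:])
        Pdm = ad.constant(G_het.propagation[m:, :m])
        Pdd = ad.constant(G_het.propagation[m:, m:])
        k = 0
        while f"global_W{k}" in p:
            W = p[f"global_W{k}"]
            agg_m = ad.add(ad.matmul(Pmm, Em), ad.matmul(Pmd, Ed))
            agg_d = ad.add(ad.matmul(Pdm, Em), ad.matmul(Pdd, Ed))
            Em = act(ad.matmul(agg_m, W))
            Ed = act(ad.matmul(agg_d, W))
            k += 1
    if state.variant in ("DBGCNMDA", "LocalGCNMDA"):
        Psm = ad.constant(G_sm.propagation)
        Psd = ad.constant(G_sd.propagation)
        k = 0
        while f"local_m_W{k}" in p:
            Em = act(ad.matmul(ad.matmul(Psm, Em), p[f"local_m_W{k}"]))
            Ed = act(ad.matmul(ad.matmul(Psd, Ed), p[f"local_d_W{k}"]))
            k += 1
    return Em, Ed


def _forward_decoder(p: dict[str, ad.Tensor], E: ad.Tensor, tag: str) -> ad.Tensor:
    for k in range(3):
        E = ad.add_bias(ad.matmul(E, p[f"dec_{tag}_W{k}"]), p[f"dec_{tag}_b{k}"])
        if k < 2:  # last dense layer stays linear
            E = ad.relu(E)
    return E


def _forward_scores_t(
    p: dict[str, ad.Tensor],
    state: ModelState,
    G_het,
    G_sm,
    G_sd,
    M_feat,
    D_feat,
) -> ad.Tensor:
    Em, Ed = _forward_embeddings(p, state, G_het, G_sm, G_sd, M_feat, D_feat)
    Rm = _forward_decoder(p, Em, "m")
    Rd = _forward_decoder(p, Ed, "d")
    RdT = ad.Tensor(Rd.value.T, parents=(Rd,))

    def backward(g):
        if Rd.requires_grad:
            Rd.grad += g.T

    RdT._backward = backward
    return ad.matmul(Rm, RdT)


def _as_tensors(state: ModelState) -> dict[str, ad.Tensor]:
    return {k: ad.parameter(v) for k, v in state.params.items()}


def forward_scores(
    state: ModelState,
    G_het: NormalizedGraph | None,
    G_sm: NormalizedGraph | None,
    G_sd: NormalizedGraph | None,
    M_feat: np.ndarray,
    D_feat: np.ndarray,
) -> np.ndarray:
    """Deterministic forward pass returning the m x n score matrix."""
    return _forward_scores_t(
        _as_tensors(state), state, G_het, G_sm, G_sd, M_feat, D_feat
    ).value


def global_branch(
    G_het: NormalizedGraph,
    M_feat: np.ndarray,
    D_feat: np.ndarray,
    state: ModelState,
) -> tuple[np.ndarray, np.ndarray]:
    """Project per-type features and propagate over the heterogeneous graph."""
    m = np.asarray(M_feat).shape[0]
    Em = np.asarray(M_feat) @ state.microbe_proj
    Ed = np.asarray(D_feat) @ state.disease_proj
    E = np.vstack([Em, Ed])
    for layer in state.global_layers:
        E = gcn_layer(G_het, E, layer)
    return E[:m], E[m:]


def local_branch(
    Sm_graph: NormalizedGraph,
    Sd_graph: NormalizedGraph,
    global_out: tuple[np.ndarray, np.ndarray],
    state: ModelState,
) -> tuple[np.ndarray, np.ndarray]:
    """Refine embeddings with independent chains on each similarity graph."""
    Em, Ed = (np.asarray(x, dtype=float) for x in global_out)
    for layer in state.local_microbe_layers:
        Em = gcn_layer(Sm_graph, Em, layer)
    for layer in state.local_disease_layers:
        Ed = gcn_layer(Sd_graph, Ed, layer)
    return Em, Ed


def decode_and_score(
    Rm: np.ndarray, Rd: np.ndarray, state: ModelState
) -> np.ndarray:
    """Three dense layers per node type, then bilinear inner-product scores."""
    def decode(E: np.ndarray, tag: str) -> np.ndarray:
        for k, (W, b) in enumerate(state.decoder_layers(tag)):
            E = E @ W + b
            if k < 2:
                E = np.maximum(E, 0.0)
        return E

    Rm_p = decode(np.asarray(Rm, dtype=float), "microbe")
    Rd_p = decode(np.asarray(Rd, dtype=float), "disease")
    return Rm_p @ Rd_p.T


def build_loss_target(
    A: AssociationMatrix,
    holdout_pairs: Iterable[tuple[int, int]],
    alpha: float,
) -> np.ndarray:
    """Augmented label matrix: alpha at retained positives, 0 elsewhere."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    target = A.values * alpha
    for i, j in holdout_pairs:
        target[i, j] = 0.0
    return target


def alpha_loss(
    A_pred: np.ndarray,
    A: AssociationMatrix,
    test_mask: Sequence[tuple[int, int]],
    alpha: float,
    mu: float,
    state: ModelState,
    exclude_test_from_loss: bool = False,
) -> float:
    """Positive-enhanced reconstruction loss plus L2 weight decay.

    Held-out positives become zero targets by default (they are treated as
    unobserved during training); ``exclude_test_from_loss`` removes the
    held-out cells from the Frobenius sum entirely instead.
    """
    A_pred = np.asarray(A_pred, dtype=float)
    if A_pred.shape != A.shape:
        raise ValueError("prediction and association shapes differ")
    target = build_loss_target(A, test_mask, alpha)
    diff = target - A_pred
    if exclude_test_from_loss:
        mask = np.ones_like(diff)
        for i, j in test_mask:
            mask[i, j] = 0.0
        diff = diff * mask
    penalty = mu * sum(float(np.sum(v**2)) for v in state.params.values())
    return float(np.sum(diff * diff)) + penalty
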