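"""Splitting, training, cross-validation and evaluation.

The evaluation design mirrors the balanced-set protocol common in
association prediction: all known positives plus an equal number of
sampled negative pairs form the labeled universe. A fraction is held out
as an independent test set; the remainder (the benchmark set) is split
into folds. For every fold a model is trained with that fold's positives
removed from the network and evaluated on the fold's held-out positives
against its held-out negatives. Leakage control is on by default: kernel
similarities, RWR features and the heterogeneous graph are all recomputed
from the masked training matrix, so no held-out edge can influence
training in any way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import _autodiff as ad
from .core_io import AssociationMatrix, RunConfig, SimilarityMatrix
from .dbgcn_model import (
    ModelState,
    NormalizedGraph,
    _forward_scores_t,
    build_hetero_graph,
    build_loss_target,
    init_model_state,
    normalize_graph,
)
from .node_features import polynomial_expand, rwr_features
from .similarity import fuse_similarity, gapk_similarity

logger = logging.getLogger("dbgcnmda")

Pair = tuple[int, int]

__all__ = [
    "EvalSplit",
    "MetricsReport",
    "TrainResult",
    "make_split",
    "auc_score",
    "aupr_score",
    "train_model",
    "cross_validate",
]


@dataclass
class EvalSplit:
    """Balanced positive/negative pairs partitioned into folds plus a test set."""

    positives: list[Pair]
    negatives: list[Pair]
    fold_pos: list[list[Pair]]
    fold_neg: list[list[Pair]]
    test_pos: list[Pair]
    test_neg: list[Pair]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.fold_pos)

    @property
    def fold_assignments(self) -> dict[Pair, int]:
        out: dict[Pair, int] = {}
        for f, pairs in enumerate(self.fold_pos):
            out.update({p: f for p in pairs})
        for f, pairs in enumerate(self.fold_neg):
            out.update({p: f for p in pairs})
        return out

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValueError("positives and negatives overlap")
        if len(self.positives) != len(self.negatives):
            raise ValueError("split must be balanced")
        sizes = [len(x) for x in self.fold_pos]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes differ by more than 1")


def make_split(
    A: AssociationMatrix, test_fraction: float, n_folds: int, seed: int
) -> EvalSplit:
    """Sample balanced negatives and carve test/fold partitions.

    Negatives are drawn uniformly without replacement from the zero cells
    of the association matrix. All randomness flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    pos_idx = np.argwhere(A.values == 1)
    zero_idx = np.argwhere(A.values == 0)
    n_pos = len(pos_idx)
    if len(zero_idx) < n_pos:
        raise ValueError("not enough zero entries to sample balanced negatives")
    neg_idx = zero_idx[rng.choice(len(zero_idx), size=n_pos, replace=False)]

    def partition(idx: np.ndarray) -> tuple[list[Pair], list[list[Pair]]]:
        pairs = [tuple(map(int, p)) for p in idx[rng.permutation(len(idx))]]
        n_test = int(round(test_fraction * len(pairs)))
        test, bench = pairs[:n_test], pairs[n_test:]
        folds = [list(chunk) for chunk in _deal(bench, n_folds)]
        return test, folds

    test_pos, fold_pos = partition(pos_idx)
    test_neg, fold_neg = partition(neg_idx)
    return EvalSplit(
        positives=[tuple(map(int, p)) for p in pos_idx],
        negatives=[tuple(map(int, p)) for p in neg_idx],
        fold_pos=fold_pos,
        fold_neg=fold_neg,
        test_pos=test_pos,
        test_neg=test_neg,
        seed=seed,
    )


def _deal(items: list, n_folds: int) -> list[list]:
    """Split into n_folds contiguous chunks with sizes differing by at most 1."""
    out, start = [], 0
    base, extra = divmod(len(items), n_folds)
    for f in range(n_folds):
        size = base + (1 if f < extra else 0)
        out.append(items[start : start + size])
        start += size
    return out


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative (midrank ties)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))

def aupr_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve (step-wise average precision)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR requires at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Training


@dataclass
class FoldInputs:
    """Everything the model consumes, derived from one training view of A."""

    A_view: AssociationMatrix
    Sm: SimilarityMatrix
    Sd: SimilarityMatrix
    M_feat: np.ndarray
    D_feat: np.ndarray
    G_het: NormalizedGraph
    G_sm: NormalizedGraph
    G_sd: NormalizedGraph


def prepare_fold_inputs(
    A: AssociationMatrix,
    mfs: SimilarityMatrix | None,
    dfs: SimilarityMatrix | None,
    holdout_pos: Sequence[Pair],
    config: RunConfig,
) -> FoldInputs:
    """Kernel similarity, fusion, RWR features and graphs for one training view.

    With ``per_fold_features`` on (the default) every derived quantity is
    computed from the matrix with held-out positives zeroed; the static
    mode computes everything once from the full matrix.
    """
    A_view = A.masked(holdout_pos) if config.per_fold_features else A
    mgs = gapk_similarity(A_view, "microbe", mode=config.bandwidth_mode)
    dgs = gapk_similarity(A_view, "disease", mode=config.bandwidth_mode)
    Sm = fuse_similarity(mfs, mgs)
    Sd = fuse_similarity(dfs, dgs)
    M = rwr_features(Sm, config.gamma)
    D = rwr_features(Sd, config.gamma)
    D_exp = polynomial_expand(D, config.poly_degree, config.poly_target_dim)
    M_feat, D_feat = M.values, D_exp.values
    if config.standardize_features:
        # RWR entries are O(1/n); without rescaling the net starts in a
        # vanishing-gradient regime and collapses to the all-zero solution
        M_feat, D_feat = _standardize(M_feat), _standardize(D_feat)
    return FoldInputs(
        A_view=A_view,
        Sm=Sm,
        Sd=Sd,
        M_feat=M_feat,
        D_feat=D_feat,
        G_het=build_hetero_graph(A_view),
        G_sm=normalize_graph(Sm.values),
        G_sd=normalize_graph(Sd.values),
    )


def _standardize(X: np.ndarray) -> np.ndarray:
    mu, sd = X.mean(axis=0), X.std(axis=0)
    return (X - mu) / np.where(sd == 0, 1.0, sd)


@dataclass
class TrainResult:
    state: ModelState
    scores: np.ndarray          # m x n score matrix from the best state
    loss_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _fold_holdouts(split: EvalSplit, fold) -> tuple[list[Pair], list[Pair], list[Pair]]:
    """(held-out positives, validation positives, validation negatives)."""
    if fold == "final":
        return list(split.test_pos), list(split.test_pos), list(split.test_neg)
    f = int(fold)
    holdout = list(split.fold_pos[f]) + list(split.test_pos)
    return holdout, list(split.fold_pos[f]), list(split.fold_neg[f])


def _pair_scores(scores: np.ndarray, pos: list[Pair], neg: list[Pair]):
    vals = [scores[i, j] for i, j in pos] + [scores[i, j] for i, j in neg]
    labels = [1] * len(pos) + [0] * len(neg)
    return vals, labels


def train_model(
    A: AssociationMatrix,
    mfs: SimilarityMatrix | None,
    dfs: SimilarityMatrix | None,
    split: EvalSplit,
    fold,
    config: RunConfig,
    variant: str = "DBGCNMDA",
) -> TrainResult:
    """Train one model for a fold id (or "final" for the test-set model).

    Recomputes similarities and features from the training view, optimizes
    the positive-enhanced reconstruction loss with Adam, and returns the
    state with the best validation AUPR (early stopping with patience).
    """
    holdout, val_pos, val_neg = _fold_holdouts(split, fold)
    inputs = prepare_fold_inputs(A, mfs, dfs, holdout, config)
    fold_tag = config.n_folds if fold == "final" else int(fold)
    rng = np.random.default_rng([config.seed % (2**31), fold_tag])
    state = init_model_state(
        inputs.M_feat.shape[1], inputs.D_feat.shape[1], config, variant, rng
    )

    target = build_loss_target(A, holdout, config.alpha)
    mask = None
    if config.exclude_test_from_loss:
        mask = np.ones_like(target)
        for i, j in holdout:
            mask[i, j] = 0.0

    params = {k: ad.parameter(v) for k, v in state.params.items()}
    optimizer = ad.Adam(list(params.values()), lr=config.learning_rate)

    result = TrainResult(state=state, scores=np.zeros(A.shape))
    best_val, best_params, since_best = -np.inf, None, 0
    for epoch in range(config.epochs):
        scores_t = _forward_scores_t(
            params, state, inputs.G_het, inputs.G_sm, inputs.G_sd,
            inputs.M_feat, inputs.D_feat,
        )
        loss_t = ad.add(
            ad.masked_sq_error(scores_t, target, mask),
            ad.l2_penalty(list(params.values()), config.mu),
        )
        loss = float(loss_t.value)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
        result.loss_history.append(loss)

        vals, labels = _pair_scores(scores_t.value, val_pos, val_neg)
        val_aupr = aupr_score(vals, labels)
        result.val_history.append(val_aupr)
        if val_aupr > best_val:
            best_val, since_best = val_aupr, 0
            best_params = {k: t.value.copy() for k, t in params.items()}
            result.best_epoch = epoch
            result.scores = scores_t.value.copy()
        else:
            since_best += 1
            if since_best > config.patience:
                logger.debug("early stop at epoch %d (best %d)", epoch, result.best_epoch)
                break
        logger.debug("fold %s epoch %d loss %.6f val_aupr %.4f", fold, epoch, loss, val_aupr)

        loss_t.backward()
        optimizer.step()

    if best_params is not None:
        state = ModelState(params=best_params, config=config, variant=variant)
        result.state = state
    return result


@dataclass
class MetricsReport:
    """Aggregated cross-validation metrics for one model variant."""

    auc: float
    aupr: float
    per_fold: list[tuple[float, float]]
    variant: str
    n_gcn_layers: int
    test_auc: float | None = None
    test_aupr: float | None = None
    affinity_spearman: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_fold:
            mean_auc = float(np.mean([a for a, _ in self.per_fold]))
            mean_aupr = float(np.mean([p for _, p in self.per_fold]))
            if abs(mean_auc - self.auc) > 1e-12 or abs(mean_aupr - self.aupr) > 1e-12:
                raise ValueError("aggregate metrics must equal per-fold means")

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_gcn_layers": self.n_gcn_layers,
            "auc": self.auc,
            "aupr": self.aupr,
            "per_fold": [list(x) for x in self.per_fold],
            "test_auc": self.test_auc,
            "test_aupr": self.test_aupr,
            "affinity_spearman": self.affinity_spearman,
            "seed": self.seed,
        }


def cross_validate(
    A: AssociationMatrix,
    mfs: SimilarityMatrix | None,
    dfs: SimilarityMatrix | None,
    config: RunConfig,
    variant: str = "DBGCNMDA",
    evaluate_test: bool = True,
) -> MetricsReport:
    """k-fold cross-validation plus an independent-test-set evaluation.

    Each fold's metrics come from that fold's held-out positives against
    its equal-sized held-out negatives; the reported AUC/AUPR are the fold
    means. A final model trained with only the test positives held out
    provides the independent test metrics.
    """
    split = make_split(A, config.test_fraction, config.n_folds, config.seed)
    per_fold = []
    for f in range(split.n_folds):
        result = train_model(A, mfs, dfs, split, f, config, variant=variant)
        vals, labels = _pair_scores(result.scores, split.fold_pos[f], split.fold_neg[f])
        per_fold.append((auc_score(vals, labels), aupr_score(vals, labels)))
        logger.info("%s fold %d: auc %.4f aupr %.4f", variant, f, *per_fold[-1])

    test_auc = test_aupr = None
    if evaluate_test:
        final = train_model(A, mfs, dfs, split, "final", config, variant=variant)
        vals, labels = _pair_scores(final.scores, split.test_pos, split.test_neg)
        test_auc, test_aupr = auc_score(vals, labels), aupr_score(vals, labels)

    return MetricsReport(
        auc=float(np.mean([a for a, _ in per_fold])),
        aupr=float(np.mean([p for _, p in per_fold])),
        per_fold=per_fold,
        variant=variant,
        n_gcn_layers=config.n_gcn_layers,
        test_auc=test_auc,
        test_aupr=test_aupr,
        seed=config.seed,
    )
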