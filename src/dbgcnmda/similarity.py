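"""Gaussian interaction-profile kernel (GAPK) similarity and fusion.

Each microbe is described by its interaction profile -- the corresponding
row of the association matrix; each disease by the corresponding column.
Two entities are similar when their profiles are close under a Gaussian
kernel whose bandwidth is set from the mean squared profile norm, the
standard GIP-kernel convention:

    GS(i, j) = exp(-Theta * ||V_i - V_j||^2),   Theta = m / sum_i ||V_i||^2

so the exponent is dimensionless and the diagonal is exactly 1. A ``raw``
bandwidth mode (Theta = mean squared norm, not its inverse) is kept as a
sensitivity option.

Fusion with an externally supplied functional similarity FS is entrywise:
the average (FS + GS)/2 wherever FS is nonzero, GS alone elsewhere; with no
FS at all the fused matrix is simply the GAPK matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AssociationMatrix, SimilarityMatrix

__all__ = ["GapkKernel", "gapk_bandwidth", "gapk_similarity", "fuse_similarity"]


@dataclass
class GapkKernel:
    bandwidth: float
    axis: str  # "microbe" or "disease"


def _profiles(A: AssociationMatrix, axis: str) -> np.ndarray:
    if axis == "microbe":
        return A.values
    if axis == "disease":
        return A.values.T
    raise ValueError("axis must be 'microbe' or 'disease'")


def gapk_bandwidth(A: AssociationMatrix, axis: str, mode: str = "normalized") -> GapkKernel:
    """Kernel bandwidth Theta for the given node type.

    ``normalized``: Theta = (number of profiles) / (sum of squared profile
    norms) — inverse mean squared norm. ``raw``: the mean squared norm
    itself. An all-zero matrix has no defined bandwidth.
    """
    profiles = _profiles(A, axis)
    total = float((profiles**2).sum())
    if total == 0:
        raise ValueError("bandwidth undefined: association matrix is all zero")
    count = profiles.shape[0]
    if mode == "normalized":
        bandwidth = count / total
    elif mode == "raw":
        bandwidth = total / count
    else:
        raise ValueError("mode must be 'normalized' or 'raw'")
    return GapkKernel(bandwidth=bandwidth, axis=axis)


def gapk_similarity(A: AssociationMatrix, axis: str, mode: str = "normalized") -> SimilarityMatrix:
    """GAPK similarity matrix over one node type of the association network.

    Entry (i, j) is exp(-Theta * ||V_i - V_j||^2) for interaction profiles
    V; symmetric with unit diagonal. Entities with empty profiles still get
    self-similarity 1 (zero distance to themselves).
    """
    kernel = gapk_bandwidth(A, axis, mode=mode)
    profiles = _profiles(A, axis)
    sq_norms = (profiles**2).sum(axis=1)
    # ||Vi - Vj||^2 = ||Vi||^2 + ||Vj||^2 - 2 Vi.Vj, clipped against roundoff
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2 * profiles @ profiles.T
    np.clip(d2, 0.0, None, out=d2)
    values = np.exp(-kernel.bandwidth * d2)
    values = (values + values.T) / 2
    np.fill_diagonal(values, 1.0)
    ids = A.microbe_ids if axis == "microbe" else A.disease_ids
    return SimilarityMatrix(list(ids), values, kind="gapk")


def fuse_similarity(FS: SimilarityMatrix | None, GS: SimilarityMatrix) -> SimilarityMatrix:
    """Entrywise fusion of functional and GAPK similarity.

    Where the functional similarity is nonzero the fused entry is the
    average of the two; where it is zero (unknown functional relation) the
    GAPK entry is used alone. ``FS=None`` falls back to GAPK only.
    """
    if FS is None:
        return SimilarityMatrix(list(GS.entity_ids), GS.values.copy(), kind="fused")
    if FS.entity_ids != GS.entity_ids:
        raise ValueError("functional and GAPK similarity must share entity ordering")
    fused = np.where(FS.values != 0, (FS.values + GS.values) / 2, GS.values)
    return SimilarityMatrix(list(GS.entity_ids), fused, kind="fused")
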