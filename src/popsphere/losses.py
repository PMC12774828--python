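"""Contrastive losses for embedding training: triplet, N-pair, and the
centroid-based N-pair loss, plus negative selection.

Each sample in a batch acts once as the *anchor* z; its second augmented view
is the *positive* z+, and other samples' embeddings are *negatives* z-. The
triplet loss compares Euclidean distances with a margin. The N-pair loss,

    L = log(1 + sum_i exp(z.z_i^- - z.z+)),

scores similarity by inner products taken in the global frame and is therefore
sensitive to where in the embedding space the points sit. The centroid-based
variant evaluates every anchor-negative comparison in a local frame instead:
for each negative a centroid

    C_i = (z + 2 z_i^- + z+) / 4

is subtracted from all three points (the negative carries double weight since
anchor and positive are views of the same individual), the shifted vectors are
divided by the magnitude of the largest of the three, and the N-pair form is
applied to the normalized vectors. In the best case — anchor and positive
coincident, anywhere relative to the negative — the normalized inner products
are exactly +1 (anchor.positive) and -1 (anchor.negative), so exp(-2) is
subtracted inside the sum to make that configuration contribute zero loss.
Because the construction only sees differences of points, the loss is
invariant to translations (and rotations) of the embedding.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

#: Floor applied to the centroid-frame scale and to inverse-distance weights.
EPS = 1e-12

#: Best-case offset exp(z~.z~(-) - z~.z~(+)) = exp(-1 - 1).
BEST_CASE_OFFSET = float(np.exp(-2.0))


def _as2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[None, :] if x.ndim == 1 else x


# ---------------------------------------------------------------------------
# Scalar per-anchor losses
# ---------------------------------------------------------------------------

def triplet_loss(z, z_pos, z_neg, alpha: float = 0.2) -> float:
    """max(||z - z+|| - ||z - z-|| + alpha, 0)."""
    z, z_pos, z_neg = (np.asarray(a, dtype=float) for a in (z, z_pos, z_neg))
    if not z.shape == z_pos.shape == z_neg.shape:
        raise ValueError("triplet points must share a dimension")
    if alpha < 0:
        raise ValueError("margin must be >= 0")
    d_pos = np.linalg.norm(z - z_pos)
    d_neg = np.linalg.norm(z - z_neg)
    return float(max(d_pos - d_neg + alpha, 0.0))


def npair_loss(z, z_pos, negatives) -> float:
    """log(1 + sum_i exp(z.z_i^- - z.z+)) with global-frame inner products."""
    z = np.asarray(z, dtype=float)
    z_pos = np.asarray(z_pos, dtype=float)
    negatives = _as2d(negatives)
    if len(negatives) == 0:
        raise ValueError("at least one negative required")
    s = negatives @ z - z @ z_pos
    return float(np.log1p(np.exp(s).sum()))


def compute_centroid(z, z_pos, z_neg) -> np.ndarray:
    """C_i = (z + 2 z_i^- + z+) / 4 — the negative carries double weight."""
    z, z_pos, z_neg = (np.asarray(a, dtype=float) for a in (z, z_pos, z_neg))
    if not z.shape == z_pos.shape == z_neg.shape:
        raise ValueError("points must share a dimension")
    return (z + 2.0 * z_neg + z_pos) / 4.0


def scale_mu(z_c, z_c_pos, z_c_neg, squared: bool = False) -> float:
    """Scale of the centroid frame: the largest of the three magnitudes.

    With ``squared=True`` the squared magnitudes are compared *and returned*
    (a literal variant kept for comparison); the default uses the plain
    Euclidean magnitude, which is what makes the best-case normalized inner
    products equal exactly +/-1.
    """
    norms = [float(np.linalg.norm(v)) for v in (z_c, z_c_pos, z_c_neg)]
    mu = max(norms)
    if mu < EPS:
        logger.warning("degenerate centroid frame (all points coincident); "
                       "flooring scale at %g", EPS)
        return EPS
    return mu * mu if squared else mu


def centroid_npair_loss(z, z_pos, negatives, squared: bool = False) -> float:
    """Centroid-based N-pair loss over one anchor and its negatives.

    For each negative the three points are shifted by the centroid, scaled by
    the largest magnitude, and the N-pair ratio is accumulated with the
    best-case offset exp(-2) subtracted. Degenerate frames (anchor, positive
    and negative exactly coincident) are skipped with a warning.
    """
    z = np.asarray(z, dtype=float)
    z_pos = np.asarray(z_pos, dtype=float)
    negatives = _as2d(negatives)
    if len(negatives) == 0:
        raise ValueError("at least one negative required")
    total = 0.0
    for z_neg in negatives:
        c = compute_centroid(z, z_pos, z_neg)
        u, v, w = z - c, z_pos - c, z_neg - c
        if max(np.linalg.norm(u), np.linalg.norm(v),
               np.linalg.norm(w)) < EPS:
            logger.warning("skipping degenerate centroid term")
            continue
        scale = scale_mu(u, v, w, squared=squared)
        # inner products of the scale-normalized vectors = raw / scale^2
        s = (u @ w - u @ v) / scale**2
        total += np.exp(s) - BEST_CASE_OFFSET
    return float(np.log1p(total))


# ---------------------------------------------------------------------------
# Batched losses with analytic gradients (used by the training loop)
# ---------------------------------------------------------------------------

def _gather_negatives(z1: np.ndarray, neg_idx):
    """Negatives for each anchor come from the view-1 embedding pool."""
    n = len(z1)
    if neg_idx is None:
        # all other samples: (n, n-1) index grid excluding the diagonal
        grid = np.broadcast_to(np.arange(n), (n, n))
        neg_idx = grid[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    neg_idx = np.asarray(neg_idx, dtype=np.int64)
    if neg_idx.ndim != 2 or len(neg_idx) != n:
        raise ValueError("negative index array must be (n_anchors, n_neg)")
    return neg_idx


def centroid_npair_batch(z1: np.ndarray, z2: np.ndarray, neg_idx=None):
    """Batch centroid N-pair loss and its gradients.

    Parameters
    ----------
    z1, z2 : (n, d) arrays
        View-1 (anchor) and view-2 (positive) embeddings of the same samples.
    neg_idx : (n, k) int array, optional
        Per-anchor negative indices into ``z1``; default all other samples.

    Returns
    -------
    (loss, dz1, dz2)
        Total loss (sum over anchors) and gradients w.r.t. both views.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    n, d = z1.shape
    if n < 2:
        raise ValueError("batch must contain at least 2 samples")
    neg_idx = _gather_negatives(z1, neg_idx)
    zn = z1[neg_idx]                       # (n, k, d)
    z = z1[:, None, :]                     # anchors  (n, 1, d)
    p = z2[:, None, :]                     # positives

    u = (3.0 * z - p - 2.0 * zn) / 4.0     # anchor   - centroid
    v = (3.0 * p - z - 2.0 * zn) / 4.0     # positive - centroid
    w = (2.0 * zn - z - p) / 4.0           # negative - centroid

    norms = np.stack([np.linalg.norm(u, axis=-1),
                      np.linalg.norm(v, axis=-1),
                      np.linalg.norm(w, axis=-1)])      # (3, n, k)
    which = norms.argmax(axis=0)
    mu = norms.max(axis=0)
    degenerate = mu < EPS
    mu = np.maximum(mu, EPS)
    mu2 = mu * mu

    s = (np.einsum("nkd,nkd->nk", u, w)
         - np.einsum("nkd,nkd->nk", u, v)) / mu2
    term = np.exp(s) - BEST_CASE_OFFSET
    term[degenerate] = 0.0
    denom = 1.0 + term.sum(axis=1)                       # (n,)
    loss = float(np.log(denom).sum())

    # dL/ds for each (anchor, negative) pair
    g = np.exp(s) / denom[:, None]
    g[degenerate] = 0.0

    inv_mu2 = 1.0 / mu2
    gu = (w - v) * inv_mu2[..., None]
    gv = -u * inv_mu2[..., None]
    gw = u * inv_mu2[..., None]
    # chain through mu = ||argmax vector||
    coef = (-2.0 * s / mu2)[..., None]
    gu += np.where((which == 0)[..., None], coef * u, 0.0)
    gv += np.where((which == 1)[..., None], coef * v, 0.0)
    gw += np.where((which == 2)[..., None], coef * w, 0.0)
    gu *= g[..., None]
    gv *= g[..., None]
    gw *= g[..., None]

    dz1 = ((3.0 * gu - gv - gw) / 4.0).sum(axis=1)
    dz2 = ((-gu + 3.0 * gv - gw) / 4.0).sum(axis=1)
    dneg = (gw - gu - gv) / 2.0
    np.add.at(dz1, neg_idx.ravel(), dneg.reshape(-1, d))
    return loss, dz1, dz2


def npair_batch(z1: np.ndarray, z2: np.ndarray, neg_idx=None):
    """Batch N-pair loss (global frame) and gradients; same contract as
    :func:`centroid_npair_batch`."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    n, d = z1.shape
    if n < 2:
        raise ValueError("batch must contain at least 2 samples")
    neg_idx = _gather_negatives(z1, neg_idx)
    zn = z1[neg_idx]
    pos_sim = np.einsum("nd,nd->n", z1, z2)
    s = np.einsum("nd,nkd->nk", z1, zn) - pos_sim[:, None]
    denom = 1.0 + np.exp(s).sum(axis=1)
    loss = float(np.log(denom).sum())
    g = np.exp(s) / denom[:, None]
    dz1 = np.einsum("nk,nkd->nd", g, zn) - g.sum(axis=1)[:, None] * z2
    dz2 = -g.sum(axis=1)[:, None] * z1
    np.add.at(dz1, neg_idx.ravel(), (g[..., None] * z1[:, None, :]).reshape(-1, d))
    return loss, dz1, dz2


def triplet_batch(z1: np.ndarray, z2: np.ndarray, neg_idx=None,
                  alpha: float = 0.2):
    """Batch triplet loss and gradients; the per-anchor loss is the mean of
    the triplet terms over that anchor's negatives."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    n, d = z1.shape
    if n < 2:
        raise ValueError("batch must contain at least 2 samples")
    neg_idx = _gather_negatives(z1, neg_idx)
    k = neg_idx.shape[1]
    zn = z1[neg_idx]
    diff_pos = z1 - z2                                      # (n, d)
    d_pos = np.maximum(np.linalg.norm(diff_pos, axis=-1), EPS)
    diff_neg = z1[:, None, :] - zn                          # (n, k, d)
    d_neg = np.maximum(np.linalg.norm(diff_neg, axis=-1), EPS)
    term = d_pos[:, None] - d_neg + alpha
    active = term > 0
    loss = float(np.where(active, term, 0.0).mean(axis=1).sum())
    gpos = diff_pos / d_pos[:, None]                        # d d_pos / dz1
    gneg = diff_neg / d_neg[..., None]
    scale = active.astype(float) / k
    dz1 = scale.sum(axis=1)[:, None] * gpos \
        - np.einsum("nk,nkd->nd", scale, gneg)
    dz2 = -scale.sum(axis=1)[:, None] * gpos
    np.add.at(dz1, neg_idx.ravel(), (scale[..., None] * gneg).reshape(-1, d))
    return loss, dz1, dz2


_BATCH_LOSSES = {
    "centroid": centroid_npair_batch,
    "npair": npair_batch,
    "triplet": triplet_batch,
}


def batch_loss(z1, z2, neg_idx=None, kind: str = "centroid",
               alpha: float = 0.2) -> float:
    """Total batch loss: sum over anchors of the per-anchor loss."""
    return batch_loss_and_grad(z1, z2, neg_idx=neg_idx, kind=kind,
                               alpha=alpha)[0]


def batch_loss_and_grad(z1, z2, neg_idx=None, kind: str = "centroid",
                        alpha: float = 0.2):
    """Loss plus gradients w.r.t. the two embedding views."""
    if kind not in _BATCH_LOSSES:
        raise ValueError(f"unknown loss kind {kind!r}; "
                         f"choose from {sorted(_BATCH_LOSSES)}")
    if kind == "triplet":
        return triplet_batch(z1, z2, neg_idx, alpha=alpha)
    return _BATCH_LOSSES[kind](z1, z2, neg_idx)


# ---------------------------------------------------------------------------
# Negative selection
# ---------------------------------------------------------------------------

def select_negatives(embeddings: np.ndarray, anchor_index: int,
                     n_neg: int | None = None, mode: str = "all",
                     rng=None) -> np.ndarray:
    """Pick negative indices for one anchor.

    ``mode='all'`` returns every other sample. ``mode='inverse_distance'``
    draws ``n_neg`` others without replacement with weights proportional to
    1 / (embedding distance + eps), concentrating negatives near the anchor.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    n = len(embeddings)
    if n < 2:
        raise ValueError("need at least 2 samples")
    others = np.concatenate([np.arange(anchor_index),
                             np.arange(anchor_index + 1, n)])
    if mode == "all":
        return others
    if mode != "inverse_distance":
        raise ValueError(f"unknown negative-selection mode {mode!r}")
    if n_neg is None or not 1 <= n_neg <= len(others):
        raise ValueError("n_neg must satisfy 1 <= n_neg < batch size")
    if rng is None:
        rng = np.random.default_rng()
    dist = np.linalg.norm(embeddings[others] - embeddings[anchor_index],
                          axis=1)
    weights = 1.0 / (dist + EPS)
    return rng.choice(others, size=n_neg, replace=False,
                      p=weights / weights.sum())


def select_negative_matrix(embeddings: np.ndarray, n_neg: int | None,
                           mode: str, rng) -> np.ndarray | None:
    """Per-anchor negative index matrix for a whole batch (None = all)."""
    if mode == "all":
        return None
    return np.stack([
        select_negatives(embeddings, a, n_neg=n_neg, mode=mode, rng=rng)
        for a in range(len(embeddings))])
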