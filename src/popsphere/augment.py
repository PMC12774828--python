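"""Genotype data augmentation: allele-count flips, missingness masking,
and one-hot encoding.

Two augmented views of the same individual act as the anchor/positive pair in
the contrastive losses. A view is produced by first flipping each non-missing
call with per-sample probability ``pflip`` (0->1, 2->1, and 1->0 or 1->2 with
equal probability — always a single-allele change), then masking each call to
missing with probability ``pmask``, and finally one-hot encoding over four
channels: 0 -> (1,0,0,0), 1 -> (0,1,0,0), 2 -> (0,0,1,0), -1 -> (0,0,0,1).
The per-sample rates are redrawn uniformly every training batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_CHANNELS = 4


@dataclass
class AugmentationConfig:
    """Maximum flip/mask rates and the lower bound of the uniform rate draw."""

    pflip_max: float = 0.99
    pmask_max: float = 0.99
    rate_low: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate_low <= self.pflip_max <= 1.0:
            raise ValueError("need 0 <= rate_low <= pflip_max <= 1")
        if not 0.0 <= self.rate_low <= self.pmask_max <= 1.0:
            raise ValueError("need 0 <= rate_low <= pmask_max <= 1")


def draw_rates(n_samples: int, config: AugmentationConfig, rng):
    """Draw per-sample flip and mask rates ~ U(rate_low, p*_max)."""
    pflip = rng.uniform(config.rate_low, config.pflip_max, size=n_samples)
    pmask = rng.uniform(config.rate_low, config.pmask_max, size=n_samples)
    return pflip, pmask


def _check_calls(calls: np.ndarray) -> np.ndarray:
    calls = np.asarray(calls)
    if not np.isin(calls, (-1, 0, 1, 2)).all():
        raise ValueError("genotype calls must lie in {0, 1, 2, -1}")
    return calls


def flip_batch(calls: np.ndarray, pflip: np.ndarray, rng) -> np.ndarray:
    """Flip calls of a (n_samples, n_markers) batch with per-sample rates.

    Homozygotes flip to the heterozygote; heterozygotes flip to either
    homozygote with equal probability. Missing calls are never flipped.
    """
    calls = _check_calls(calls)
    pflip = np.asarray(pflip, dtype=float).reshape(-1, 1)
    out = calls.copy()
    do_flip = (rng.random(calls.shape) < pflip) & (calls >= 0)
    het_target = np.where(rng.random(calls.shape) < 0.5, 0, 2).astype(calls.dtype)
    flipped = np.where(calls == 1, het_target, 1).astype(calls.dtype)
    out[do_flip] = flipped[do_flip]
    return out


def mask_batch(calls: np.ndarray, pmask: np.ndarray, rng) -> np.ndarray:
    """Set calls of a batch to missing (-1) with per-sample probabilities."""
    calls = _check_calls(calls)
    pmask = np.asarray(pmask, dtype=float).reshape(-1, 1)
    out = calls.copy()
    out[rng.random(calls.shape) < pmask] = -1
    return out


def flip_markers(calls_row: np.ndarray, pflip: float, rng) -> np.ndarray:
    """Flip a single sample's calls with probability ``pflip`` per marker."""
    return flip_batch(np.asarray(calls_row)[None, :], np.array([pflip]),
                      rng)[0]


def mask_markers(calls_row: np.ndarray, pmask: float, rng) -> np.ndarray:
    """Mask a single sample's calls to -1 with probability ``pmask``."""
    return mask_batch(np.asarray(calls_row)[None, :], np.array([pmask]),
                      rng)[0]


def one_hot_batch(calls: np.ndarray) -> np.ndarray:
    """One-hot encode a (n_samples, n_markers) batch to (n_samples, 4,
    n_markers), channels ordered (0, 1, 2, missing)."""
    calls = _check_calls(calls)
    channel = np.where(calls < 0, 3, calls).astype(np.int64)
    eye = np.eye(N_CHANNELS, dtype=np.float32)
    return np.transpose(eye[channel], (0, 2, 1))


def one_hot(calls_row: np.ndarray) -> np.ndarray:
    """One-hot encode one sample's calls to an (n_markers, 4) matrix."""
    return one_hot_batch(np.asarray(calls_row)[None, :])[0].T


def one_hot_inverse(encoded: np.ndarray) -> np.ndarray:
    """Invert :func:`one_hot`: (n_markers, 4) back to calls in {0,1,2,-1}."""
    encoded = np.asarray(encoded)
    if encoded.ndim != 2 or encoded.shape[1] != N_CHANNELS:
        raise ValueError("expected an (n_markers, 4) one-hot matrix")
    if not np.array_equal(encoded.sum(axis=1), np.ones(len(encoded))):
        raise ValueError("rows are not one-hot")
    channel = encoded.argmax(axis=1)
    return np.where(channel == 3, -1, channel).astype(np.int8)


def augment_batch(calls: np.ndarray, pflip: np.ndarray, pmask: np.ndarray,
                  rng) -> np.ndarray:
    """Full augmentation of a batch: flip, then mask, then one-hot.

    Returns a (n_samples, 4, n_markers) float32 tensor ready for the encoder.
    """
    return one_hot_batch(mask_batch(flip_batch(calls, pflip, rng), pmask, rng))


def augment_view(calls_row: np.ndarray, pflip: float, pmask: float,
                 rng) -> np.ndarray:
    """One augmented view of a single sample as an (n_markers, 4) matrix."""
    return augment_batch(np.asarray(calls_row)[None, :], np.array([pflip]),
                         np.array([pmask]), rng)[0].T
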