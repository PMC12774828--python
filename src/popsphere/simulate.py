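"""Synthetic genotype data with known two-tier population structure.

The generator follows the Balding–Nichols drift model applied at two levels:
for each marker an ancestral allele frequency p is drawn uniformly from a
configurable range, each superpopulation draws its frequency from
Beta(p(1-F_super)/F_super, (1-p)(1-F_super)/F_super) around p, each
subpopulation drifts the same way around its superpopulation frequency with
F_sub, and diploid genotypes are Binomial(2, subpop frequency). The F
parameters are FST-like divergences: Var(population frequency) = F p(1-p).

Also provides the SNP-chip missingness design: a fraction of the samples is
split into groups, and every member of a group has the same random marker
subset set to missing — emulating cohorts genotyped on different chips —
optionally filled back in with the per-marker mode of the untouched samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, LabelSet, marker_modes

logger = logging.getLogger(__name__)


@dataclass
class PopulationDesign:
    """Hierarchical population design for the drift simulator."""

    n_super: int = 3
    n_sub_per_super: int = 3
    n_per_sub: int = 15
    n_markers: int = 1000
    fst_super: float = 0.25
    fst_sub: float = 0.03
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_super", "n_sub_per_super", "n_per_sub", "n_markers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("fst_super", "fst_sub"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        low, high = self.ancestral_maf_range
        if not 0.0 < low <= high <= 0.5:
            raise ValueError("ancestral_maf_range must satisfy 0 < low <= high <= 0.5")

    @property
    def n_samples(self) -> int:
        return self.n_super * self.n_sub_per_super * self.n_per_sub


@dataclass
class ChipMaskDesign:
    """SNP-chip masking experiment layout.

    ``fraction_masked_samples`` of the samples are split evenly into
    ``n_groups`` chip groups; each group masks its own random subset of
    ``fraction_masked_markers`` of the markers, identically for all members.
    ``fill`` is "mode" (replace masked calls with the per-marker mode of the
    untouched samples) or "none" (leave them as -1).
    """

    fraction_masked_samples: float = 0.2
    n_groups: int = 4
    fraction_masked_markers: float = 0.2
    fill: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_masked_samples", "fraction_masked_markers"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.fill not in ("mode", "none"):
            raise ValueError("fill must be 'mode' or 'none'")


def _beta_drift(p: np.ndarray, fst: float, size, rng) -> np.ndarray:
    """Draw drifted frequencies around p with Var = fst * p(1-p)."""
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale, size=size)


def simulate_hierarchical(design: PopulationDesign):
    """Simulate genotypes under two-level Balding–Nichols drift.

    Returns
    -------
    (GenotypeMatrix, LabelSet, dict)
        The genotype matrix (no missing calls), the two-tier labels, and a
        truth dict with ``ancestral``, ``super_freqs`` and ``sub_freqs``
        allele-frequency arrays.
    """
    rng = np.random.default_rng(design.seed)
    m = design.n_markers
    low, high = design.ancestral_maf_range
    ancestral = rng.uniform(low, high, size=m)

    super_freqs = _beta_drift(ancestral, design.fst_super,
                              (design.n_super, m), rng)
    sub_freqs = np.empty((design.n_super, design.n_sub_per_super, m))
    for s in range(design.n_super):
        sub_freqs[s] = _beta_drift(super_freqs[s], design.fst_sub,
                                   (design.n_sub_per_super, m), rng)
    # guard against Beta endpoint degeneracies producing exact 0/1
    sub_freqs = np.clip(sub_freqs, 1e-9, 1.0 - 1e-9)

    samples, subs, supers, blocks = [], [], [], []
    for s in range(design.n_super):
        for b in range(design.n_sub_per_super):
            geno = rng.binomial(2, sub_freqs[s, b],
                                size=(design.n_per_sub, m)).astype(np.int8)
            blocks.append(geno)
            for i in range(design.n_per_sub):
                samples.append(f"S{s}_B{b}_I{i}")
                subs.append(f"SUB_{s}_{b}")
                supers.append(f"SUPER_{s}")
    calls = np.vstack(blocks)

    markers = pd.DataFrame({
        "id": [f"snp{j}" for j in range(m)],
        "chromosome": ["1"] * m,
        "position": np.arange(1, m + 1, dtype=np.int64) * 1000,
    })
    gm = GenotypeMatrix(samples=samples, markers=markers, calls=calls)
    labels = LabelSet(table=pd.DataFrame({
        "sample_id": samples, "subpopulation": subs,
        "superpopulation": supers}))
    truth = {"ancestral": ancestral, "super_freqs": super_freqs,
             "sub_freqs": sub_freqs}
    return gm, labels, truth


def apply_chip_masking(gm: GenotypeMatrix, design: ChipMaskDesign):
    """Apply the chip-group missingness design to a complete genotype matrix.

    Returns
    -------
    (GenotypeMatrix, numpy.ndarray)
        The masked matrix and a per-sample group assignment: -1 for untouched
        samples, 0..n_groups-1 for the chip groups.
    """
    if (gm.calls == -1).any():
        raise ValueError("apply_chip_masking requires a complete matrix")
    rng = np.random.default_rng(design.seed)
    n, m = gm.n_samples, gm.n_markers
    n_masked = int(round(design.fraction_masked_samples * n))
    if n_masked < design.n_groups:
        raise ValueError(
            f"{n_masked} masked samples cannot fill {design.n_groups} groups")
    order = rng.permutation(n)
    masked_ids = order[:n_masked]
    groups = np.full(n, -1, dtype=np.int64)
    # even split; any remainder spreads over the first groups
    for g, chunk in enumerate(np.array_split(masked_ids, design.n_groups)):
        if len(chunk) == 0:
            raise ValueError("empty chip group")
        groups[chunk] = g

    n_mask_markers = int(round(design.fraction_masked_markers * m))
    calls = gm.calls.copy()
    mode_fill = marker_modes(gm.calls[groups == -1]) if design.fill == "mode" \
        else None
    for g in range(design.n_groups):
        marker_subset = rng.choice(m, size=n_mask_markers, replace=False)
        members = np.flatnonzero(groups == g)
        if design.fill == "mode":
            calls[np.ix_(members, marker_subset)] = mode_fill[marker_subset]
        else:
            calls[np.ix_(members, marker_subset)] = -1
    out = GenotypeMatrix(samples=list(gm.samples), markers=gm.markers.copy(),
                         calls=calls)
    return out, groups


def split_train_val(gm: GenotypeMatrix, labels: LabelSet | None = None,
                    val_fraction: float = 0.2, stratify: bool = False,
                    seed: int = 0):
    """Split sample ids into disjoint, exhaustive train/validation sets.

    With ``stratify`` the split is per subpopulation so validation proportions
    are preserved to rounding; subpopulations with a single sample go to the
    training set.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = gm.n_samples
    sample_arr = np.array(gm.samples)
    if stratify:
        if labels is None:
            raise ValueError("stratified split requires labels")
        subs = labels.sub_of(gm.samples)
        val_idx: list[int] = []
        for sub in pd.unique(subs):
            members = np.flatnonzero(subs == sub)
            if len(members) < 2:
                logger.info("subpopulation %s has a single sample; "
                            "kept in training set", sub)
                continue
            k = int(round(val_fraction * len(members)))
            k = min(max(k, 1), len(members) - 1)
            val_idx.extend(rng.permutation(members)[:k])
        val_idx = np.sort(np.array(val_idx, dtype=np.int64))
    else:
        k = int(round(val_fraction * n))
        val_idx = np.sort(rng.permutation(n)[:k])
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    return sample_arr[~val_mask].tolist(), sample_arr[val_mask].tolist()
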