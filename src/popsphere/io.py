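"""Genotype, label, and embedding I/O plus dataset preprocessing filters.

Genotypes are diploid alternate-allele counts: 0 (homozygous reference),
1 (heterozygous), 2 (homozygous alternate), with -1 marking a missing call.
Supported on-disk formats are the PLINK 1 binary trio (.bed/.bim/.fam,
SNP-major), the unpacked EIGENSTRAT text trio (.geno/.snp/.ind, 9 = missing),
and plain UTF-8 TSV for labels and embeddings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CALLS = frozenset({-1, 0, 1, 2})

#: Default sex-chromosome label sets per species; chromosome labels are
#: treated as opaque strings because conventions differ across tools.
SEX_CHROMOSOMES = {
    "dog": frozenset({"X", "Y", "39", "40"}),
    "human": frozenset({"X", "Y", "23", "24"}),
}


class FormatError(ValueError):
    """Raised when an on-disk genotype file is malformed or inconsistent."""


@dataclass
class GenotypeMatrix:
    """Samples x markers matrix of diploid allele counts.

    Attributes
    ----------
    samples : list of str
        Ordered unique sample identifiers (rows).
    markers : pandas.DataFrame
        One row per marker with columns ``id``, ``chromosome``, ``position``.
    calls : numpy.ndarray
        ``(n_samples, n_markers)`` integer array with values in {0, 1, 2, -1}.
    """

    samples: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError(f"invalid genotype codes present: "
                             f"{np.unique(self.calls[bad]).tolist()}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if self.markers["id"].duplicated().any():
            raise ValueError("duplicate marker ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the boolean/index marker selection."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.iloc[keep].reset_index(drop=True)
            if keep.dtype != bool
            else self.markers.loc[keep].reset_index(drop=True),
            calls=self.calls[:, keep].copy(),
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            markers=self.markers.copy(),
            calls=self.calls[idx].copy(),
        )


@dataclass
class LabelSet:
    """Two-tier population labels (subpopulation nested in superpopulation)."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample_id", "subpopulation", "superpopulation"]))

    def __post_init__(self) -> None:
        required = {"sample_id", "subpopulation", "superpopulation"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"label table must have columns {sorted(required)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(),
                                  "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in labels: {dups}")
        nesting = self.table.groupby("subpopulation")["superpopulation"].nunique()
        broken = nesting[nesting > 1]
        if len(broken):
            raise ValueError(
                "subpopulations mapped to more than one superpopulation: "
                f"{broken.index.tolist()}")

    def aligned_to(self, samples: list[str]) -> pd.DataFrame:
        """Label rows reindexed to the given sample order (NaN if unlabeled)."""
        return (self.table.set_index("sample_id")
                .reindex(samples)
                .reset_index(names="sample_id"))

    def sub_of(self, samples: list[str]) -> np.ndarray:
        return self.aligned_to(samples)["subpopulation"].to_numpy()

    def super_of(self, samples: list[str]) -> np.ndarray:
        return self.aligned_to(samples)["superpopulation"].to_numpy()


# ---------------------------------------------------------------------------
# PLINK 1 binary trio
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major PLINK 1 .bed

# 2-bit PLINK codes -> alternate-allele (A1) counts
_BED_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


def read_plink(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read a PLINK 1 binary trio into a :class:`GenotypeMatrix`.

    Calls are counts of the A1 (alternate) allele; missing calls are -1.
    Marker order follows the .bim file; sample order follows the .fam file.
    """
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise FormatError(f"{fam_path}: expected at least 2 .fam columns")
    samples = fam.iloc[:, 1].tolist()
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] < 4:
        raise FormatError(f"{bim_path}: expected at least 4 .bim columns")
    markers = pd.DataFrame({
        "id": bim.iloc[:, 1],
        "chromosome": bim.iloc[:, 0],
        "position": bim.iloc[:, 3].astype(np.int64),
    })
    n, m = len(samples), len(markers)
    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes (not SNP-major PLINK 1)")
    bytes_per_marker = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_marker * m:
        raise FormatError(
            f"{bed_path}: {body.size} data bytes, expected "
            f"{bytes_per_marker * m} for {n} samples x {m} markers")
    blocks = body.reshape(m, bytes_per_marker)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack([(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)],
                     axis=-1).reshape(m, -1)[:, :n]
    calls = _BED_DECODE[codes].T
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


def write_plink(gm: GenotypeMatrix, prefix) -> None:
    """Write ``prefix``.bed/.bim/.fam (SNP-major PLINK 1, A1 = alternate)."""
    prefix = Path(prefix)
    n, m = gm.n_samples, gm.n_markers
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in gm.samples:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for rec in gm.markers.itertuples(index=False):
            fh.write(f"{rec.chromosome} {rec.id} 0 {rec.position} A G\n")
    bytes_per_marker = (n + 3) // 4
    codes = np.empty((m, bytes_per_marker * 4), dtype=np.uint8)
    codes[:] = 0b01  # padding beyond n is ignored on read
    lut = np.zeros(4, dtype=np.uint8)
    for val, code in _BED_ENCODE.items():
        lut[val + 1] = code
    codes[:, :n] = lut[gm.calls.T + 1]
    quads = codes.reshape(m, bytes_per_marker, 4)
    packed = (quads[..., 0] | (quads[..., 1] << 2)
              | (quads[..., 2] << 4) | (quads[..., 3] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# EIGENSTRAT unpacked text trio
# ---------------------------------------------------------------------------

def read_eigenstrat(geno_path, snp_path, ind_path) -> GenotypeMatrix:
    """Read an unpacked EIGENSTRAT trio; 9 in .geno is remapped to -1.

    Each .geno line is one marker; each character one sample.
    """
    ind = pd.read_csv(ind_path, sep=r"\s+", header=None, dtype=str)
    samples = ind.iloc[:, 0].tolist()
    snp = pd.read_csv(snp_path, sep=r"\s+", header=None, dtype=str)
    if snp.shape[1] < 4:
        raise FormatError(f"{snp_path}: expected at least 4 .snp columns")
    markers = pd.DataFrame({
        "id": snp.iloc[:, 0],
        "chromosome": snp.iloc[:, 1],
        "position": snp.iloc[:, 3].astype(np.int64),
    })
    n = len(samples)
    rows = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if not line.isdigit():
                raise FormatError(
                    f"{geno_path}:{lineno}: non-digit characters in genotype row")
            if len(line) != n:
                raise FormatError(
                    f"{geno_path}:{lineno}: row length {len(line)} != "
                    f"{n} samples")
            rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    if len(rows) != len(markers):
        raise FormatError(
            f"{geno_path}: {len(rows)} genotype rows != {len(markers)} markers")
    calls = np.stack(rows).astype(np.int8).T
    bad = ~np.isin(calls, (0, 1, 2, 9))
    if bad.any():
        raise FormatError(f"{geno_path}: genotype codes outside {{0,1,2,9}}")
    calls[calls == 9] = -1
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


def write_eigenstrat(gm: GenotypeMatrix, prefix) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".ind"), "w") as fh:
        for sid in gm.samples:
            fh.write(f"{sid} U Pop\n")
    with open(prefix.with_suffix(".snp"), "w") as fh:
        for rec in gm.markers.itertuples(index=False):
            fh.write(f"{rec.id} {rec.chromosome} 0.0 {rec.position} A G\n")
    out = gm.calls.T.astype(np.int8).copy()
    out[out == -1] = 9
    with open(prefix.with_suffix(".geno"), "w") as fh:
        for row in out:
            fh.write("".join(chr(ord("0") + v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Labels and embeddings (TSV)
# ---------------------------------------------------------------------------

def read_labels(tsv_path) -> LabelSet:
    """Read a sample_id / subpopulation / superpopulation TSV."""
    table = pd.read_csv(tsv_path, sep="\t", dtype=str)
    return LabelSet(table=table[["sample_id", "subpopulation",
                                 "superpopulation"]])


def write_labels(labels: LabelSet, tsv_path) -> None:
    labels.table.to_csv(tsv_path, sep="\t", index=False)


def write_embedding(samples, coords3, coords2, labels: LabelSet | None,
                    path, header_comment: str | None = None) -> None:
    """Write per-sample 3D sphere and 2D map coordinates (plus labels) as TSV.

    Coordinates are printed with enough digits to round-trip well below 1e-9.
    """
    coords3 = np.asarray(coords3, dtype=float)
    coords2 = np.asarray(coords2, dtype=float)
    df = pd.DataFrame({
        "sample_id": list(samples),
        "x3": coords3[:, 0] if len(samples) else [],
        "y3": coords3[:, 1] if len(samples) else [],
        "z3": coords3[:, 2] if len(samples) else [],
        "x2": coords2[:, 0] if len(samples) else [],
        "y2": coords2[:, 1] if len(samples) else [],
    })
    if labels is not None:
        aligned = labels.aligned_to(list(samples))
        df["subpopulation"] = aligned["subpopulation"].fillna("")
        df["superpopulation"] = aligned["superpopulation"].fillna("")
    else:
        df["subpopulation"] = ""
        df["superpopulation"] = ""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_embedding(path):
    """Read an embedding TSV back; returns (samples, coords3, coords2, labels)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample_id": str, "subpopulation": str,
                            "superpopulation": str})
    samples = df["sample_id"].tolist()
    coords3 = df[["x3", "y3", "z3"]].to_numpy(float)
    coords2 = df[["x2", "y2"]].to_numpy(float)
    lab = df[["sample_id", "subpopulation", "superpopulation"]].dropna()
    labels = LabelSet(table=lab.reset_index(drop=True)) if len(lab) else None
    return samples, coords3, coords2, labels


# ---------------------------------------------------------------------------
# Preprocessing filters
# ---------------------------------------------------------------------------

def filter_sex_chromosomes(gm: GenotypeMatrix, sex_labels) -> GenotypeMatrix:
    """Drop markers whose chromosome label is in ``sex_labels``."""
    sex_labels = {str(c) for c in sex_labels}
    keep = ~gm.markers["chromosome"].astype(str).isin(sex_labels).to_numpy()
    if not keep.any():
        logger.warning("sex-chromosome filter removed every marker")
    return gm.subset_markers(keep)


def minor_allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Per-marker MAF over non-missing calls; NaN where all calls are missing."""
    calls = gm.calls.astype(float)
    obs = calls >= 0
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(obs, calls, 0.0).sum(axis=0) / (2.0 * n_obs)
    maf = np.minimum(f, 1.0 - f)
    maf[n_obs == 0] = np.nan
    return maf


def maf_filter(gm: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop markers with minor-allele frequency below ``threshold``.

    MAF is min(f, 1-f) with f the alternate-allele frequency over
    non-missing calls. Markers with every call missing are removed.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    maf = minor_allele_frequencies(gm)
    all_missing = np.isnan(maf)
    if all_missing.any():
        logger.info("maf_filter: removing %d all-missing markers",
                    int(all_missing.sum()))
    keep = ~all_missing & (maf >= threshold)
    return gm.subset_markers(keep)


def drop_monomorphic(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Remove markers with zero minor-allele frequency (noninformative sites)."""
    maf = minor_allele_frequencies(gm)
    return gm.subset_markers(~np.isnan(maf) & (maf > 0))


def marker_modes(calls: np.ndarray) -> np.ndarray:
    """Per-marker most common non-missing genotype; ties go to the smaller
    value; all-missing markers fall back to 0."""
    counts = np.stack([(calls == g).sum(axis=0) for g in (0, 1, 2)])
    modes = counts.argmax(axis=0).astype(np.int8)  # argmax takes first = smallest
    all_missing = counts.sum(axis=0) == 0
    if all_missing.any():
        logger.info("mode imputation: %d markers all-missing in reference, "
                    "imputing 0", int(all_missing.sum()))
        modes[all_missing] = 0
    return modes


def mode_impute(gm: GenotypeMatrix,
                reference: GenotypeMatrix | None = None) -> GenotypeMatrix:
    """Replace missing calls with the per-marker modal genotype.

    The mode is computed over non-missing calls of ``reference`` (default:
    ``gm`` itself); ties are broken toward the smaller genotype value.
    """
    ref = reference if reference is not None else gm
    if ref.n_markers != gm.n_markers:
        raise ValueError("reference marker count differs from target")
    modes = marker_modes(ref.calls)
    calls = gm.calls.copy()
    missing = calls == -1
    calls[missing] = np.broadcast_to(modes, calls.shape)[missing]
    return GenotypeMatrix(samples=list(gm.samples), markers=gm.markers.copy(),
                          calls=calls)
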