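"""Genotype container and PLINK 1 binary (bed/bim/fam) input/output.

Dosages are counts of the *counted* allele — bim column 5 (allele1) — coded
0/1/2 with ``MISSING`` (-1) as the missing sentinel, stored as ``int8`` so a
biobank-scale matrix stays memory-friendly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MISSING", "GenotypeDataset", "read_plink", "write_plink"]

MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# PLINK 2-bit codes (within a byte, sample index increases from the low bits):
# 00 -> homozygous allele1 (dosage 2), 01 -> missing, 10 -> het, 11 -> hom allele2.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "allele1", "allele2"]
SAMPLE_COLUMNS = ["fid", "iid", "sex", "phenotype"]


class PlinkFormatError(ValueError):
    """Raised when a bed/bim/fam triplet is malformed or an unsupported dialect."""


@dataclass
class GenotypeDataset:
    """Samples x variants dosage matrix with variant and sample metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` int8 array of counted-allele dosages in
        {0, 1, 2} with ``MISSING`` for no-calls.
    variants
        DataFrame with columns ``variant_id, chrom, pos, allele1, allele2``
        (1-based positions, as in bim files).
    samples
        DataFrame with columns ``fid, iid, sex, phenotype``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError(
                f"dosage matrix is {n}x{m} but metadata describe "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        # int8 values in [-1, 2] are exactly {missing, 0, 1, 2}
        if self.dosages.size and (
            int(self.dosages.min()) < MISSING or int(self.dosages.max()) > 2
        ):
            bad = np.unique(self.dosages[(self.dosages < MISSING) | (self.dosages > 2)])
            raise ValueError(f"dosages contain values outside {{0,1,2,missing}}: {bad}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.variants["variant_id"])

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosages_imputed(self) -> np.ndarray:
        """Dosages as float64 with missing entries replaced by the per-variant mean.

        A variant with no observed genotypes imputes to 0.
        """
        x = self.dosages.astype(np.float64)
        miss = self.dosages == MISSING
        if miss.any():
            x[miss] = np.nan
            with np.errstate(invalid="ignore"):
                col_means = np.nanmean(x, axis=0)
            col_means = np.where(np.isfinite(col_means), col_means, 0.0)
            idx = np.nonzero(miss)
            x[idx] = col_means[idx[1]]
        return x

    def allele_frequency(self) -> np.ndarray:
        """Per-variant frequency of the counted allele among non-missing calls (NaN if none)."""
        x = self.dosages.astype(np.float64)
        x[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(x, axis=0) / 2.0

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeDataset":
        d = self.dosages
        samples = self.samples
        variants = self.variants
        copied = False
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]  # fancy indexing copies
            samples = samples.iloc[sample_idx]
            copied = True
        if variant_idx is not None:
            variant_idx = np.asarray(variant_idx)
            d = d[:, variant_idx]
            variants = variants.iloc[variant_idx]
            copied = True
        if not copied:
            d = d.copy()
        return GenotypeDataset(np.ascontiguousarray(d), variants.copy(), samples.copy())


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK 1 binary triplet ``prefix.bed/.bim/.fam`` (SNP-major only)."""
    prefix = Path(prefix)
    paths = {ext: prefix.with_suffix(prefix.suffix + ext) for ext in (".bed", ".bim", ".fam")}
    for ext, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK file: {p}")

    bim = pd.read_csv(
        paths[".bim"],
        sep=r"\s+",
        header=None,
        names=["chrom", "variant_id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "variant_id": str, "allele1": str, "allele2": str},
    )
    variants = bim[["variant_id", "chrom", "pos", "allele1", "allele2"]].copy()

    fam = pd.read_csv(
        paths[".fam"],
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    samples = fam[["fid", "iid", "sex", "phenotype"]].copy()

    raw = np.fromfile(paths[".bed"], dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise PlinkFormatError(f"{paths['.bed']}: bad magic bytes, not a PLINK 1 bed file")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{paths['.bed']}: individual-major bed layout is not supported (flag byte {raw[2]:#04x})"
        )
    n, m = len(samples), len(variants)
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{paths['.bed']}: size {len(raw)} inconsistent with {n} samples x {m} variants "
            f"(expected {expected} bytes)"
        )
    body = raw[3:].reshape(m, bytes_per_variant)
    # unpack 2-bit codes, low bits first within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_variant * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T  # (n, m)
    return GenotypeDataset(np.ascontiguousarray(dosages), variants, samples)


def write_plink(ds: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``ds`` as a PLINK 1 SNP-major bed/bim/fam triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = ds.dosages.shape

    code_lut = np.empty(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        code_lut[dosage % 4] = code  # MISSING=-1 -> index 3
    codes = code_lut[ds.dosages.T % 4]  # (m, n)

    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    codes = codes.reshape(m, -1, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(prefix.suffix + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        packed.tofile(fh)

    bim = pd.DataFrame(
        {
            "chrom": ds.variants["chrom"],
            "variant_id": ds.variants["variant_id"],
            "cm": 0,
            "pos": ds.variants["pos"],
            "allele1": ds.variants["allele1"],
            "allele2": ds.variants["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(prefix.suffix + ".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": ds.samples["fid"],
            "iid": ds.samples["iid"],
            "father": 0,
            "mother": 0,
            "sex": ds.samples["sex"],
            "phenotype": ds.samples["phenotype"],
        }
    )
    fam.to_csv(prefix.with_suffix(prefix.suffix + ".fam"), sep="\t", header=False, index=False)
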