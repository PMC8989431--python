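"""Variant and sample quality control.

Filters mirror standard GWAS pre-processing: per-sample call rate, then
minor-allele frequency, an exact Hardy-Weinberg equilibrium test, per-variant
missingness, and duplicate removal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .genotype import GenotypeDataset

__all__ = ["QCReport", "hwe_exact_test", "qc_filter"]


@dataclass
class QCReport:
    n_variants_in: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    n_removed_missingness: int = 0
    n_removed_duplicate: int = 0
    n_samples_removed_call_rate: int = 0
    n_variants_out: int = 0
    n_samples_out: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def log_lines(self) -> list[str]:
        return [
            f"samples removed (call rate): {self.n_samples_removed_call_rate}",
            f"variants removed (MAF): {self.n_removed_maf}",
            f"variants removed (HWE): {self.n_removed_hwe}",
            f"variants removed (missingness): {self.n_removed_missingness}",
            f"variants removed (duplicate): {self.n_removed_duplicate}",
            f"retained: {self.n_samples_out} samples, {self.n_variants_out} variants",
        ]


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Conditional on the observed allele counts, the p-value sums the
    probabilities of all heterozygote counts no more probable than the
    observed one (the standard exact HWE test).

    Parameters are the three genotype counts (either homozygote first).
    """
    for c in (n_hom1, n_het, n_hom2):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")

    # work with the rarer allele
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if rare == 0:
        return 1.0

    # P(n_het | rare allele count) via the standard recurrence, normalized at the end
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid % 2) != (rare % 2):
        mid += 1
    probs[mid] = 1.0
    # going down: P(h-2)/P(h) = h(h-1) / ((r-h+2)/2 * (n-... ) ) in genotype terms
    h = mid
    while h > 1:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mid
    while h <= rare - 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    probs /= probs.sum()
    obs = probs[n_het]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _first_fail_attribution(masks: list[np.ndarray]) -> list[np.ndarray]:
    """Attribute each removed variant to the first rule that fails it."""
    taken = np.zeros_like(masks[0])
    out = []
    for mask in masks:
        eff = mask & ~taken
        out.append(eff)
        taken |= mask
    return out


def qc_filter(
    ds: GenotypeDataset,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    variant_missing_max: float = 0.05,
    sample_call_rate_min: float = 0.95,
    drop_duplicates: bool = True,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply sample call-rate filtering, then variant filters, tallying each rule.

    Variants failing several rules are counted once, under the first failing
    rule in the order MAF, HWE, missingness, duplicate. Returns the filtered
    dataset (possibly empty) and a :class:`QCReport`.
    """
    if ds.n_variants == 0 or ds.n_samples == 0:
        raise ValueError("qc_filter requires a non-empty dataset")
    report = QCReport(n_variants_in=ds.n_variants)

    miss = ds.missing_mask()
    call_rate = 1.0 - miss.mean(axis=1)
    keep_samples = call_rate >= sample_call_rate_min
    report.n_samples_removed_call_rate = int((~keep_samples).sum())
    if not keep_samples.all():
        ds = ds.subset(sample_idx=np.flatnonzero(keep_samples))
        miss = ds.missing_mask()
    report.n_samples_out = ds.n_samples

    if ds.n_samples == 0:
        empty = ds.subset(variant_idx=np.array([], dtype=int))
        return empty, report

    d = ds.dosages
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, np.where(miss, 0, d).sum(axis=0) / (2.0 * n_obs), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    fail_maf = ~(maf >= maf_min)  # NaN (all-missing variant) fails too

    hwe_p = np.ones(ds.n_variants)
    n_hom1 = ((d == 2) & ~miss).sum(axis=0)
    n_het = ((d == 1) & ~miss).sum(axis=0)
    n_hom2 = ((d == 0) & ~miss).sum(axis=0)
    for j in range(ds.n_variants):
        if n_obs[j] > 0:
            hwe_p[j] = hwe_exact_test(int(n_hom1[j]), int(n_het[j]), int(n_hom2[j]))
    fail_hwe = hwe_p < hwe_p_min

    fail_missing = miss.mean(axis=0) > variant_missing_max

    if drop_duplicates:
        dup_id = ds.variants["variant_id"].duplicated(keep="first").to_numpy()
        alleles = ds.variants[["allele1", "allele2"]].astype(str)
        dup_locus = ds.variants.assign(
            _amin=alleles.min(axis=1), _amax=alleles.max(axis=1)
        )[["chrom", "pos", "_amin", "_amax"]].duplicated(keep="first").to_numpy()
        fail_dup = dup_id | dup_locus
    else:
        fail_dup = np.zeros(ds.n_variants, dtype=bool)

    eff_maf, eff_hwe, eff_miss, eff_dup = _first_fail_attribution(
        [fail_maf, fail_hwe, fail_missing, fail_dup]
    )
    report.n_removed_maf = int(eff_maf.sum())
    report.n_removed_hwe = int(eff_hwe.sum())
    report.n_removed_missingness = int(eff_miss.sum())
    report.n_removed_duplicate = int(eff_dup.sum())

    keep = ~(fail_maf | fail_hwe | fail_missing | fail_dup)
    out = ds.subset(variant_idx=np.flatnonzero(keep))
    report.n_variants_out = out.n_variants
    return out, report
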