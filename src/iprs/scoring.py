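"""Polygenic score construction.

Two scores are supported:

* the traditional PRS, ``PRS_i = sum_j wM_j * g_ij`` with marginal-effect
  weights, and
* the interaction PRS (iPRS),
  ``iPRS_i = sum_j wM_j * g_ij + sum_j wI_j * g_ij * e_i``
  whose main-effect weights come from the G×E interaction model and whose
  second sum carries the per-variant interaction weights.

All weights are expressed on the risk-allele scale: ``flip_to_risk`` swaps
the counted allele of any variant with a negative main weight (dosage
``g -> 2 - g``), negating both weights, so every main weight is non-negative.
Setting every interaction weight to zero makes the iPRS collapse to the PRS
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeDataset

__all__ = [
    "WeightSet",
    "ScoreVector",
    "flip_to_risk",
    "compute_prs",
    "compute_iprs",
    "weights_from_scan",
]

WEIGHT_COLUMNS = [
    "variant_id",
    "risk_allele",
    "other_allele",
    "beta_main",
    "beta_gxe",
    "exposure_name",
]


@dataclass
class WeightSet:
    """Per-variant (risk allele, main weight, interaction weight) triples."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in WEIGHT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"weight table lacks columns {missing}")
        if self.table["variant_id"].duplicated().any():
            raise ValueError("weight table has duplicated variant ids")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    def write(self, path) -> None:
        self.table[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "WeightSet":
        return cls(pd.read_csv(path, sep="\t", dtype={"variant_id": str}))


@dataclass
class ScoreVector:
    """One score per sample, in log-odds units."""

    table: pd.DataFrame  # columns fid, iid, score

    def __post_init__(self) -> None:
        if not np.isfinite(self.table["score"].to_numpy(dtype=float)).all():
            raise ValueError("scores contain non-finite values")

    @property
    def values(self) -> np.ndarray:
        return self.table["score"].to_numpy(dtype=float)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def standardized(self) -> "ScoreVector":
        v = self.values
        sd = v.std()
        if sd == 0:
            raise ValueError("cannot standardize a constant score")
        out = self.table.copy()
        out["score"] = (v - v.mean()) / sd
        return ScoreVector(out)


def weights_from_scan(stats_table: pd.DataFrame, exposure_name: str = "E") -> WeightSet:
    """Build a WeightSet from a scan table (converged rows only).

    For a marginal scan the interaction weight column is absent or NaN and is
    stored as zero, representing a traditional PRS.
    """
    t = stats_table[stats_table["converged"].astype(bool)].copy()
    gxe = t["beta_gxe"].to_numpy(dtype=float) if "beta_gxe" in t else np.zeros(len(t))
    gxe = np.where(np.isfinite(gxe), gxe, 0.0)
    other = t["other_allele"] if "other_allele" in t else ""
    return WeightSet(
        pd.DataFrame(
            {
                "variant_id": t["variant_id"].to_numpy(),
                "risk_allele": t["risk_allele"].to_numpy(),
                "other_allele": other,
                "beta_main": t["beta_main"].to_numpy(dtype=float),
                "beta_gxe": gxe,
                "exposure_name": exposure_name,
            }
        )
    )


def _weight_variant_indices(weights: WeightSet, ds: GenotypeDataset) -> np.ndarray:
    pos = ds.variant_ids.get_indexer(weights.table["variant_id"])
    if (pos < 0).any():
        absent = weights.table.loc[pos < 0, "variant_id"].tolist()
        raise KeyError(f"weights reference variants absent from the dataset: {absent}")
    return pos


def flip_to_risk(weights: WeightSet, ds: GenotypeDataset) -> tuple[WeightSet, GenotypeDataset]:
    """Flip variants with negative main weight onto the risk-allele scale.

    For each such variant the counted allele and dosage are swapped
    (``g -> 2 - g``, missing untouched) and both weights are negated; a zero
    main weight counts as already risk-oriented. Returns new objects; the
    dataset is restricted to the weight variants, in weight order.
    """
    pos = _weight_variant_indices(weights, ds)
    identity = len(pos) == ds.n_variants and np.array_equal(pos, np.arange(ds.n_variants))
    sub = ds if identity else ds.subset(variant_idx=pos)
    wt = weights.table.copy()
    flip = wt["beta_main"].to_numpy(dtype=float) < 0
    if flip.any():
        d = sub.dosages
        # single vectorized pass: flip dosage on flipped columns, keep missing
        flipped_vals = np.where(d == MISSING, d, (2 - d).astype(d.dtype))
        d = np.where(flip[None, :], flipped_vals, d)
        variants = sub.variants.copy()
        a1 = variants["allele1"].to_numpy().copy()
        a2 = variants["allele2"].to_numpy().copy()
        a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
        variants["allele1"], variants["allele2"] = a1, a2
        sub = GenotypeDataset(d, variants, sub.samples)
        wt.loc[flip, ["beta_main", "beta_gxe"]] *= -1.0
        ra = wt["risk_allele"].to_numpy().copy()
        oa = wt["other_allele"].to_numpy().copy()
        ra[flip], oa[flip] = oa[flip].copy(), ra[flip].copy()
        wt["risk_allele"], wt["other_allele"] = ra, oa
    return WeightSet(wt), sub


def _aligned_dosages(ds: GenotypeDataset, weights: WeightSet) -> np.ndarray:
    pos = _weight_variant_indices(weights, ds)
    if not ds.missing_mask().any():  # gather narrow int8 first, convert after
        return ds.dosages[:, pos].astype(np.float64)
    return ds.dosages_imputed()[:, pos]


def compute_prs(ds: GenotypeDataset, weights: WeightSet) -> ScoreVector:
    """Traditional PRS: dosage-weighted sum of main weights (missing mean-imputed)."""
    if len(weights) == 0:
        raise ValueError("empty weight set")
    G = _aligned_dosages(ds, weights)
    score = G @ weights.table["beta_main"].to_numpy(dtype=float)
    return ScoreVector(
        pd.DataFrame({"fid": ds.samples["fid"], "iid": ds.samples["iid"], "score": score})
    )


def compute_iprs(ds: GenotypeDataset, e, weights: WeightSet) -> ScoreVector:
    """Interaction PRS: main-weight sum plus exposure-scaled interaction sum."""
    if len(weights) == 0:
        raise ValueError("empty weight set")
    e = np.asarray(e, dtype=np.float64).ravel()
    if len(e) != ds.n_samples:
        raise ValueError("exposure vector length does not match samples")
    if not np.isfinite(e).all():
        raise ValueError("exposure missing (non-finite) for a scored sample")
    G = _aligned_dosages(ds, weights)
    w_m = weights.table["beta_main"].to_numpy(dtype=float)
    w_i = weights.table["beta_gxe"].to_numpy(dtype=float)
    score = G @ w_m + (G @ w_i) * e
    return ScoreVector(
        pd.DataFrame({"fid": ds.samples["fid"], "iid": ds.samples["iid"], "score": score})
    )
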