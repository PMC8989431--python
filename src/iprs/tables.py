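"""Phenotype/exposure/covariate tables and sample alignment."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype import GenotypeDataset

__all__ = ["read_phenotypes", "align_phenotypes"]

REQUIRED = ["FID", "IID", "outcome", "exposure"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read a whitespace/tab separated phenotype file.

    Expected header columns: FID, IID, outcome (0/1), exposure, then any
    covariate columns.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype file lacks columns {missing}")
    bad = set(df["outcome"].unique()) - {0, 1}
    if bad:
        raise ValueError(f"{path}: outcome must be coded 0/1, found {sorted(bad)}")
    return df


def align_phenotypes(
    ds: GenotypeDataset, pheno: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Align a phenotype table to the genotype samples by (FID, IID).

    Returns ``(y, e, c)`` in genotype sample order; ``c`` is None when the
    table has no covariate columns. Samples present on one side only raise an
    error listing the offending ids.
    """
    key_geno = list(zip(ds.samples["fid"], ds.samples["iid"]))
    key_pheno = list(zip(pheno["FID"], pheno["IID"]))
    geno_set, pheno_set = set(key_geno), set(key_pheno)
    only_geno = sorted(geno_set - pheno_set)
    only_pheno = sorted(pheno_set - geno_set)
    if only_geno or only_pheno:
        raise ValueError(
            "sample id mismatch between genotype and phenotype files; "
            f"genotype-only: {only_geno[:10]}, phenotype-only: {only_pheno[:10]}"
        )
    indexed = pheno.set_index(pd.MultiIndex.from_tuples(key_pheno))
    ordered = indexed.loc[pd.MultiIndex.from_tuples(key_geno)]
    y = ordered["outcome"].to_numpy(dtype=float)
    e = ordered["exposure"].to_numpy(dtype=float)
    cov_cols = [c for c in ordered.columns if c not in ("FID", "IID", "outcome", "exposure")]
    c = ordered[cov_cols].to_numpy(dtype=float) if cov_cols else None
    return y, e, c
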