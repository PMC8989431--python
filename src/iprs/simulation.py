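"""Synthetic case-control data with gene-environment interactions.

Two generators mirror the two classical PRS regimes:

* ``simulate_sparse`` — a handful of pre-identified SNPs (default 10, six
  with non-zero main effects, four of those interacting with a binary
  exposure), phenotype from a logistic model, and quota sampling until a
  preset number of cases and controls is reached.  Interaction signs follow a
  scenario: all antagonistic (opposite the main effect), all synergistic, or
  half/half.
* ``simulate_polygenic`` — every causal variant has a small effect drawn
  from N(0, h2/n_causal) where h2 is the variance budget of the genetic
  predictor; a tiny fraction of variants additionally interact with the
  exposure, most of them antagonistically.

Genotypes are independent biallelic dosages ``Binomial(2, MAF)`` with MAF
uniform in a configurable range; the exposure is Bernoulli(0.5).  Every
dataset carries a truth record sufficient to recompute each sample's exact
outcome probability.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .evaluation import evaluate_predictions
from .genotype import GenotypeDataset, write_plink
from .prediction import run_fold

__all__ = [
    "SparseSimConfig",
    "PolygenicSimConfig",
    "StudySettings",
    "TruthRecord",
    "SimulatedDataset",
    "synthesize_genotypes",
    "simulate_sparse",
    "simulate_polygenic",
    "run_simulation_study",
    "load_config",
    "export_dataset",
]

LOG_OR_15 = math.log(1.5)

SCENARIOS = ("all_antagonistic", "all_synergistic", "half_half")


@dataclass
class SparseSimConfig:
    """Sparse design: few SNPs, fixed effects, case/control quota sampling."""

    n_snps: int = 10
    maf_low: float = 0.1
    maf_high: float = 0.5
    n_causal_main: int = 6
    n_interacting: int = 4
    interacting_require_main: bool = True
    scenario: str = "all_antagonistic"
    beta_main_mag: float = LOG_OR_15
    beta_int_mag: float = LOG_OR_15
    beta_e: float = LOG_OR_15
    alpha: float = math.log(0.1 / 0.9)  # baseline prevalence ~10%
    n_cases: int = 1000
    n_controls: int = 1000
    max_draws: int = 2_000_000
    seed: int = 0

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; valid: {SCENARIOS}")
        if not (0 <= self.n_causal_main <= self.n_snps):
            raise ValueError("n_causal_main must be within [0, n_snps]")
        if self.n_interacting > self.n_snps:
            raise ValueError("n_interacting cannot exceed n_snps")
        if self.interacting_require_main and self.n_interacting > self.n_causal_main:
            raise ValueError("interacting SNPs must be a subset of causal SNPs")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("MAF range must satisfy 0 < low <= high <= 0.5")


@dataclass
class PolygenicSimConfig:
    """Polygenic design: all causal variants with small normal effects."""

    m: int = 40_000
    n_samples: int = 5_000
    causal_fraction: float = 0.01
    h2: float = 0.3
    interacting_fraction: float = 1e-4
    antagonistic_proportion: float = 0.7
    beta_int_mag: float = LOG_OR_15
    beta_e: float = LOG_OR_15
    alpha: float = math.log(0.1 / 0.9)
    maf_low: float = 0.05
    maf_high: float = 0.5
    interacting_subset_of_causal: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.m < 1 or self.n_samples < 1:
            raise ValueError("m and n_samples must be positive")
        if not 0.0 <= self.antagonistic_proportion <= 1.0:
            raise ValueError("antagonistic_proportion must lie in [0, 1]")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("MAF range must satisfy 0 < low <= high <= 0.5")

    @property
    def n_causal(self) -> int:
        return max(1, round(self.causal_fraction * self.m))

    @property
    def n_interacting(self) -> int:
        return round(self.interacting_fraction * self.m)


@dataclass
class TruthRecord:
    """Everything needed to recompute each sample's true outcome probability."""

    design: str
    alpha: float
    beta_e: float
    beta_main: np.ndarray
    beta_int: np.ndarray
    maf: np.ndarray
    causal_ids: list
    interacting_ids: list
    scenario: str | None = None
    n_draws_total: int = 0
    n_cases_seen: int = 0

    def linear_predictor(self, dosages: np.ndarray, e: np.ndarray) -> np.ndarray:
        g = np.asarray(dosages, dtype=float)
        e = np.asarray(e, dtype=float)
        return self.alpha + g @ self.beta_main + (g @ self.beta_int) * e + self.beta_e * e

    def probability(self, dosages: np.ndarray, e: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(dosages, e)))

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("beta_main", "beta_int", "maf"):
            d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d, indent=2)


@dataclass
class SimulatedDataset:
    genotypes: GenotypeDataset
    exposure: np.ndarray
    outcome: np.ndarray
    truth: TruthRecord


def _binomial2(rng: np.random.Generator, maf: np.ndarray, n: int) -> np.ndarray:
    """Dosages ~ Binomial(2, maf_j) as the sum of two Bernoulli draws.

    Equivalent in distribution to ``rng.binomial(2, maf)`` but several times
    faster at genome scale.
    """
    m = len(maf)
    p32 = maf.astype(np.float32)[None, :]
    d = (rng.random((n, m), dtype=np.float32) < p32).astype(np.int8)
    d += rng.random((n, m), dtype=np.float32) < p32
    return d


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _variant_frame(m: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [f"snp{j + 1}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1),
            "allele1": "A",
            "allele2": "B",
        }
    )


def _sample_frame(n: int, start: int = 0) -> pd.DataFrame:
    ids = [f"S{start + i + 1}" for i in range(n)]
    return pd.DataFrame({"fid": ids, "iid": ids, "sex": 0, "phenotype": -9})


def synthesize_genotypes(
    n_samples: int,
    m: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed=0,
) -> GenotypeDataset:
    """Independent biallelic dosages, ``g ~ Binomial(2, MAF_j)``, no missingness."""
    if n_samples < 1 or m < 1:
        raise ValueError("n_samples and m must be positive")
    rng = _rng(seed)
    maf = rng.uniform(maf_low, maf_high, size=m)
    d = _binomial2(rng, maf, n_samples)
    return GenotypeDataset(d, _variant_frame(m), _sample_frame(n_samples))


def _interaction_signs(n_int: int, scenario: str, rng: np.random.Generator) -> np.ndarray:
    """-1 antagonistic, +1 synergistic, per interacting SNP."""
    if scenario == "all_antagonistic":
        return -np.ones(n_int)
    if scenario == "all_synergistic":
        return np.ones(n_int)
    signs = np.array([-1.0, 1.0] * ((n_int + 1) // 2))[:n_int]
    return rng.permutation(signs)


def sparse_effects(cfg: SparseSimConfig, rng: np.random.Generator) -> TruthRecord:
    """Draw the sparse design's per-SNP effect configuration."""
    cfg.validate()
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_snps)
    causal = np.sort(rng.choice(cfg.n_snps, size=cfg.n_causal_main, replace=False))
    beta_main = np.zeros(cfg.n_snps)
    beta_main[causal] = cfg.beta_main_mag  # risk direction, per the scenario design

    pool = causal if cfg.interacting_require_main else np.arange(cfg.n_snps)
    interacting = np.sort(rng.choice(pool, size=cfg.n_interacting, replace=False))
    signs = _interaction_signs(cfg.n_interacting, cfg.scenario, rng)
    beta_int = np.zeros(cfg.n_snps)
    # antagonistic = opposite the SNP's risk direction (mains here are positive;
    # for an interaction-only SNP the sign is taken against beta_I's own risk
    # direction, i.e. antagonistic = negative)
    beta_int[interacting] = signs * cfg.beta_int_mag

    ids = [f"snp{j + 1}" for j in range(cfg.n_snps)]
    return TruthRecord(
        design="sparse",
        alpha=cfg.alpha,
        beta_e=cfg.beta_e,
        beta_main=beta_main,
        beta_int=beta_int,
        maf=maf,
        causal_ids=[ids[j] for j in causal],
        interacting_ids=[ids[j] for j in interacting],
        scenario=cfg.scenario,
    )


def simulate_sparse(cfg: SparseSimConfig, seed=None) -> SimulatedDataset:
    """Quota-sample the sparse design until exactly the configured case and
    control counts are reached (excess draws discarded)."""
    cfg.validate()
    rng = _rng(cfg.seed if seed is None else seed)
    truth = sparse_effects(cfg, rng)

    need_cases, need_controls = cfg.n_cases, cfg.n_controls
    kept_g, kept_e, kept_y = [], [], []
    drawn = 0
    batch = max(1024, 2 * (cfg.n_cases + cfg.n_controls))
    while need_cases > 0 or need_controls > 0:
        if drawn >= cfg.max_draws:
            raise RuntimeError(
                f"quota sampling exceeded the draw budget ({cfg.max_draws}); "
                "the intercept alpha makes one class too rare"
            )
        b = min(batch, cfg.max_draws - drawn)
        g = rng.binomial(2, truth.maf[None, :], size=(b, cfg.n_snps)).astype(np.int8)
        e = rng.binomial(1, 0.5, size=b)
        p = truth.probability(g, e)
        y = rng.random(b) < p
        drawn += b
        truth.n_cases_seen += int(y.sum())
        take_case = np.flatnonzero(y)[:need_cases]
        take_ctrl = np.flatnonzero(~y)[:need_controls]
        take = np.concatenate([take_case, take_ctrl])
        if len(take):
            kept_g.append(g[take])
            kept_e.append(e[take])
            kept_y.append(y[take])
            need_cases -= len(take_case)
            need_controls -= len(take_ctrl)
    truth.n_draws_total = drawn

    g = np.concatenate(kept_g)
    e = np.concatenate(kept_e)
    y = np.concatenate(kept_y).astype(int)
    order = rng.permutation(len(y))  # shuffle cases/controls together
    g, e, y = g[order], e[order], y[order]
    ds = GenotypeDataset(g, _variant_frame(cfg.n_snps), _sample_frame(len(y)))
    return SimulatedDataset(ds, e.astype(float), y, truth)


def polygenic_effects(cfg: PolygenicSimConfig, rng: np.random.Generator) -> TruthRecord:
    cfg.validate()
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.m)
    n_causal = cfg.n_causal
    causal = np.sort(rng.choice(cfg.m, size=n_causal, replace=False))
    beta_main = np.zeros(cfg.m)
    beta_main[causal] = rng.normal(0.0, math.sqrt(cfg.h2 / n_causal), size=n_causal)

    n_int = cfg.n_interacting
    beta_int = np.zeros(cfg.m)
    interacting = np.array([], dtype=int)
    if n_int > 0:
        pool = causal if cfg.interacting_subset_of_causal else np.arange(cfg.m)
        interacting = np.sort(rng.choice(pool, size=n_int, replace=False))
        n_ant = round(cfg.antagonistic_proportion * n_int)
        signs = np.concatenate([-np.ones(n_ant), np.ones(n_int - n_ant)])
        signs = rng.permutation(signs)
        # antagonistic opposes the SNP's own risk direction (sign of its main
        # effect; a zero-main SNP's risk direction is taken as positive)
        risk_dir = np.where(beta_main[interacting] >= 0, 1.0, -1.0)
        beta_int[interacting] = signs * risk_dir * cfg.beta_int_mag

    ids = [f"snp{j + 1}" for j in range(cfg.m)]
    return TruthRecord(
        design="polygenic",
        alpha=cfg.alpha,
        beta_e=cfg.beta_e,
        beta_main=beta_main,
        beta_int=beta_int,
        maf=maf,
        causal_ids=[ids[j] for j in causal],
        interacting_ids=[ids[j] for j in interacting],
    )


def simulate_polygenic(cfg: PolygenicSimConfig, seed=None) -> SimulatedDataset:
    """Population sample of the polygenic design (no quota sampling)."""
    cfg.validate()
    rng = _rng(cfg.seed if seed is None else seed)
    truth = polygenic_effects(cfg, rng)
    g = _binomial2(rng, truth.maf, cfg.n_samples)
    e = rng.binomial(1, 0.5, size=cfg.n_samples).astype(float)
    p = truth.probability(g, e)
    y = (rng.random(cfg.n_samples) < p).astype(int)
    ds = GenotypeDataset(g, _variant_frame(cfg.m), _sample_frame(cfg.n_samples))
    return SimulatedDataset(ds, e, y, truth)


@dataclass
class StudySettings:
    """Analysis settings applied to every replicate of a study.

    ``test_fraction="auto"`` evaluates the sparse design in-sample (each
    replicate is one simulated study; a ten-SNP panel barely overfits) and the
    polygenic design on a stratified held-out half (with far more variants
    than samples, in-sample evaluation of an estimated genome-wide score is
    vacuous). Pass ``None`` for in-sample or a fraction for a held-out split.
    """

    p_threshold: float | None = None  # None = use all variants (no selection)
    selection_rule: str = "main_or_interaction"
    test_fraction: float | str | None = "auto"
    ci_reps: int = 200  # bootstrap reps for the per-replicate Brier CI


METRIC_COLUMNS = [
    "replicate",
    "auc_iprs",
    "auc_prs",
    "auc_diff",
    "delong_p",
    "brier_iprs",
    "brier_prs",
    "prev_high_iprs",
    "prev_high_prs",
    "prev_low_iprs",
    "prev_low_prs",
    "prevalence_chisq_p",
    "spiegelhalter_p_iprs",
    "spiegelhalter_p_prs",
    "cox_slope_iprs",
    "cox_slope_prs",
    "n_selected_iprs",
    "n_selected_prs",
    "failed",
]


def _replicate_metrics(
    sim: SimulatedDataset, settings: StudySettings, rng_seed: int, test_fraction
):
    y = sim.outcome
    e = sim.exposure
    idx = np.arange(len(y))
    if test_fraction is None:
        tr = te = idx
    else:
        tr, te = train_test_split(
            idx,
            test_size=test_fraction,
            stratify=y,
            random_state=rng_seed % (2**31),
        )
    preds, art = run_fold(
        sim.genotypes,
        y.astype(float),
        e,
        tr,
        te,
        p_threshold=settings.p_threshold,
        selection_rule=settings.selection_rule,
        second_stage_on_test=test_fraction is not None,
    )
    rep = evaluate_predictions(
        preds["y"],
        preds["p_iprs_model"],
        preds["p_prs_model"],
        ci_reps=settings.ci_reps,
        seed=rng_seed % (2**31),
    )
    return {
        "auc_iprs": rep.auc_iprs,
        "auc_prs": rep.auc_prs,
        "auc_diff": rep.auc_iprs - rep.auc_prs,
        "delong_p": rep.delong.p_value,
        "brier_iprs": rep.calibration_iprs.brier,
        "brier_prs": rep.calibration_prs.brier,
        "prev_high_iprs": rep.stratification_iprs.prevalence[2],
        "prev_high_prs": rep.stratification_prs.prevalence[2],
        "prev_low_iprs": rep.stratification_iprs.prevalence[0],
        "prev_low_prs": rep.stratification_prs.prevalence[0],
        "prevalence_chisq_p": rep.prevalence_test.p_value,
        "spiegelhalter_p_iprs": rep.calibration_iprs.spiegelhalter_p,
        "spiegelhalter_p_prs": rep.calibration_prs.spiegelhalter_p,
        "cox_slope_iprs": rep.calibration_iprs.cox_slope,
        "cox_slope_prs": rep.calibration_prs.cox_slope,
        "n_selected_iprs": len(art.selected_iprs),
        "n_selected_prs": len(art.selected_prs),
    }


def run_simulation_study(
    design: str,
    cfg,
    n_replicates: int,
    settings: StudySettings | None = None,
    seed: int = 0,
    only_replicates=None,
) -> tuple[pd.DataFrame, dict]:
    """Generate/analyze/evaluate ``n_replicates`` datasets; aggregate the metrics.

    Each replicate draws a fresh effect configuration and dataset from its own
    child seed (reproducible in isolation), fits both prediction models on a
    stratified training half and evaluates on the held-out half.  Failed
    replicates (e.g. a degenerate fit) are recorded and excluded from the
    aggregate means.
    """
    if design not in ("sparse", "polygenic"):
        raise ValueError(f"unknown design {design!r}")
    settings = settings or StudySettings()
    test_fraction = settings.test_fraction
    if isinstance(test_fraction, str):
        if test_fraction != "auto":
            raise ValueError(f"unknown test_fraction {test_fraction!r}")
        test_fraction = None if design == "sparse" else 0.5
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    wanted = set(range(n_replicates)) if only_replicates is None else set(only_replicates)
    rows = []
    for r, child in enumerate(children):
        if r not in wanted:
            continue
        rng = np.random.default_rng(child)
        eval_seed = int(child.generate_state(1)[0] % (2**31))
        row = {"replicate": r, "failed": False}
        try:
            if design == "sparse":
                sim = simulate_sparse(cfg, seed=rng)
            else:
                sim = simulate_polygenic(cfg, seed=rng)
            row.update(_replicate_metrics(sim, settings, eval_seed, test_fraction))
        except (RuntimeError, ValueError) as err:
            row["failed"] = True
            row["error"] = str(err)
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(columns=["replicate", "failed"])
    ok = table[~table["failed"].astype(bool)]
    numeric = [c for c in METRIC_COLUMNS if c in ok.columns and c not in ("replicate", "failed")]
    aggregate = {f"mean_{c}": float(ok[c].mean()) for c in numeric}
    aggregate["n_replicates"] = n_replicates
    aggregate["n_failed"] = int(table["failed"].sum())
    if len(ok):
        aggregate["frac_auc_diff_positive"] = float((ok["auc_diff"] > 0).mean())
    return table, aggregate


# ---------------------------------------------------------------------------
# config files and dataset export
# ---------------------------------------------------------------------------

_CONFIG_KINDS = {"sparse": SparseSimConfig, "polygenic": PolygenicSimConfig}


def _parse_value(text: str):
    t = text.strip()
    if t.lower() in ("true", "false"):
        return t.lower() == "true"
    for cast in (int, float):
        try:
            return cast(t)
        except ValueError:
            continue
    return t


def load_config(path, kind: str):
    """Load a flat ``key = value`` config file into a simulation config."""
    if kind not in _CONFIG_KINDS:
        raise ValueError(f"unknown config kind {kind!r}; valid: {sorted(_CONFIG_KINDS)}")
    cls = _CONFIG_KINDS[kind]
    valid = set(cls.__dataclass_fields__)
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in valid:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r} for {kind}")
        kwargs[key] = _parse_value(value)
    cfg = cls(**kwargs)
    cfg.validate()
    return cfg


def export_dataset(sim: SimulatedDataset, outdir) -> dict:
    """Write a simulated dataset as PLINK triplet + phenotype table + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = outdir / "genotypes"
    write_plink(sim.genotypes, prefix)
    pheno = pd.DataFrame(
        {
            "FID": sim.genotypes.samples["fid"],
            "IID": sim.genotypes.samples["iid"],
            "outcome": sim.outcome.astype(int),
            "exposure": sim.exposure,
        }
    )
    pheno_path = outdir / "pheno.tsv"
    pheno.to_csv(pheno_path, sep="\t", index=False)
    truth_path = outdir / "truth.json"
    truth_path.write_text(sim.truth.to_json())
    return {
        "bed": str(prefix) + ".bed",
        "bim": str(prefix) + ".bim",
        "fam": str(prefix) + ".fam",
        "pheno": str(pheno_path),
        "truth": str(truth_path),
    }
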