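"""Second-stage risk models and cross-validated prediction.

The two prediction models refit a logistic regression on constructed scores:

* ``prs_model``  : ``logit P(y=1) = b0 + b1*PRS + b2*PRS*E + b3*E``
* ``iprs_model`` : ``logit P(y=1) = b0 + b1*iPRS + b2*E``

Both include an intercept and free coefficients estimated on the training
data (the standard two-stage PRS practice). ``cross_validate`` runs the whole
pipeline — association scan, optional variant selection, risk-allele flip,
weight construction, scoring, second-stage fit — inside each training fold so
no test-fold information leaks into any artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold

from .association import genome_scan, select_variants
from .genotype import GenotypeDataset
from .scoring import ScoreVector, WeightSet, compute_iprs, compute_prs, flip_to_risk, weights_from_scan

__all__ = [
    "RiskModel",
    "FoldArtifacts",
    "CVPredictions",
    "fit_risk_model",
    "predict_risk",
    "run_fold",
    "cross_validate",
]

_EPS = 1e-12


@dataclass
class RiskModel:
    """Fitted second-stage logistic model."""

    kind: str  # "prs_model" or "iprs_model"
    params: np.ndarray  # intercept first, then score(, score*E), E
    bse: np.ndarray
    fold_id: int = -1

    def __post_init__(self) -> None:
        arity = {"prs_model": 4, "iprs_model": 3}
        if self.kind not in arity:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if len(self.params) != arity[self.kind]:
            raise ValueError(
                f"{self.kind} expects {arity[self.kind]} coefficients, got {len(self.params)}"
            )
        if not np.isfinite(self.params).all():
            raise ValueError("risk model coefficients must be finite")


def _design(kind: str, s: np.ndarray, e: np.ndarray) -> np.ndarray:
    if kind == "prs_model":
        return np.column_stack([np.ones_like(s), s, s * e, e])
    return np.column_stack([np.ones_like(s), s, e])


def fit_risk_model(kind: str, scores, e, y, fold_id: int = -1) -> RiskModel:
    """Maximum-likelihood fit of the kind-specific second-stage model."""
    s = scores.values if isinstance(scores, ScoreVector) else np.asarray(scores, float).ravel()
    e = np.asarray(e, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not (len(s) == len(e) == len(y)):
        raise ValueError("scores, exposure and outcome must be aligned")
    if np.var(s) == 0:
        raise ValueError(f"{kind}: score is constant, second-stage fit undefined")
    X = _design(kind, s, e)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"{kind}: design is rank deficient (e.g. exposure constant); "
            "drop the inestimable columns or use a varying exposure"
        )
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as err:  # pragma: no cover - statsmodels raises on hard separation
        raise RuntimeError(f"{kind} (fold {fold_id}): fit failed: {err}") from err
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 1e3:
        raise RuntimeError(f"{kind} (fold {fold_id}): separation or non-convergence")
    return RiskModel(kind, np.asarray(res.params), np.asarray(res.bse), fold_id)


def predict_risk(model: RiskModel, scores, e) -> np.ndarray:
    """Inverse-logit of the model's linear predictor, strictly inside (0, 1)."""
    s = scores.values if isinstance(scores, ScoreVector) else np.asarray(scores, float).ravel()
    e = np.asarray(e, dtype=float).ravel()
    if len(s) != len(e):
        raise ValueError("scores and exposure must be aligned")
    eta = _design(model.kind, s, e) @ model.params
    p = 1.0 / (1.0 + np.exp(-eta))
    return np.clip(p, _EPS, 1.0 - _EPS)


@dataclass
class FoldArtifacts:
    fold_id: int
    weights_iprs: WeightSet
    weights_prs: WeightSet
    model_iprs: RiskModel
    model_prs: RiskModel
    selected_iprs: list
    selected_prs: list


@dataclass
class CVPredictions:
    """Out-of-fold predictions from both models for every sample."""

    table: pd.DataFrame  # fid, iid, fold, y, p_prs_model, p_iprs_model
    artifacts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        dup = self.table.duplicated(subset=["fid", "iid"])
        if dup.any():
            raise ValueError("a sample appears in more than one test fold")
        for col in ("p_prs_model", "p_iprs_model"):
            p = self.table[col].to_numpy(dtype=float)
            if ((p <= 0) | (p >= 1)).any():
                raise ValueError(f"{col} outside (0, 1)")

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def run_fold(
    ds: GenotypeDataset,
    y: np.ndarray,
    e: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    c=None,
    p_threshold: float | None = 5e-6,
    selection_rule: str = "main_or_interaction",
    fold_id: int = 0,
    second_stage_on_test: bool = False,
) -> tuple[pd.DataFrame, FoldArtifacts]:
    """Train the full two-model pipeline on ``train_idx``, predict ``test_idx``.

    With ``p_threshold=None`` every converged variant is used (the polygenic
    setting); otherwise the iPRS arm keeps variants passing ``selection_rule``
    on the interaction scan while the PRS arm keeps variants with a
    significant marginal effect.

    ``second_stage_on_test`` refits the 3-4 coefficient second-stage models on
    the test-fold scores instead of the training-fold scores. When the scan
    uses far more variants than samples without selection, the training-fold
    score quasi-separates the training outcomes (overfit weights) and the
    second stage cannot be estimated there; refitting the low-dimensional
    recalibration on the evaluation samples leaks no per-variant weight.
    """
    y = np.asarray(y, dtype=float).ravel()
    e = np.asarray(e, dtype=float).ravel()
    ds_tr = ds.subset(sample_idx=train_idx)
    y_tr, e_tr = y[train_idx], e[train_idx]
    c_tr = None if c is None else np.asarray(c, float)[train_idx]

    stats_int = genome_scan(ds_tr, y_tr, e_tr, c_tr, model="interaction")
    stats_marg = genome_scan(ds_tr, y_tr, e_tr, c_tr, model="marginal")

    if p_threshold is None:
        sel_i = sorted(stats_int.table.loc[stats_int.table["converged"], "variant_id"])
        sel_p = sorted(stats_marg.table.loc[stats_marg.table["converged"], "variant_id"])
    else:
        sel_i = select_variants(stats_int, p_threshold, selection_rule)
        sel_p = select_variants(stats_marg, p_threshold, "main_only")
    if not sel_i or not sel_p:
        raise RuntimeError(
            f"fold {fold_id}: no variants selected for "
            f"{'iPRS' if not sel_i else 'PRS'} at p<{p_threshold}; "
            "lower the threshold or provide stronger signals"
        )

    w_iprs = weights_from_scan(
        stats_int.table[stats_int.table["variant_id"].isin(sel_i)], exposure_name="E"
    )
    w_prs = weights_from_scan(
        stats_marg.table[stats_marg.table["variant_id"].isin(sel_p)], exposure_name="E"
    )

    # flip train and test with the *raw* weights: the flip set is defined by the
    # sign of the estimated main weight, and must hit both folds identically
    w_iprs_raw, w_prs_raw = w_iprs, w_prs
    w_iprs, ds_tr_i = flip_to_risk(w_iprs_raw, ds_tr)
    w_prs, ds_tr_p = flip_to_risk(w_prs_raw, ds_tr)

    ds_te = ds.subset(sample_idx=test_idx)
    e_te, y_te = e[test_idx], y[test_idx]
    _, ds_te_i = flip_to_risk(w_iprs_raw, ds_te)
    _, ds_te_p = flip_to_risk(w_prs_raw, ds_te)
    iprs_te = compute_iprs(ds_te_i, e_te, w_iprs)
    prs_te = compute_prs(ds_te_p, w_prs)

    if second_stage_on_test:
        model_i = fit_risk_model("iprs_model", iprs_te, e_te, y_te, fold_id)
        model_p = fit_risk_model("prs_model", prs_te, e_te, y_te, fold_id)
    else:
        iprs_tr = compute_iprs(ds_tr_i, e_tr, w_iprs)
        prs_tr = compute_prs(ds_tr_p, w_prs)
        model_i = fit_risk_model("iprs_model", iprs_tr, e_tr, y_tr, fold_id)
        model_p = fit_risk_model("prs_model", prs_tr, e_tr, y_tr, fold_id)

    preds = pd.DataFrame(
        {
            "fid": ds_te.samples["fid"].to_numpy(),
            "iid": ds_te.samples["iid"].to_numpy(),
            "fold": fold_id,
            "y": y_te.astype(int),
            "p_prs_model": predict_risk(model_p, prs_te, e_te),
            "p_iprs_model": predict_risk(model_i, iprs_te, e_te),
        }
    )
    art = FoldArtifacts(fold_id, w_iprs, w_prs, model_i, model_p, sel_i, sel_p)
    return preds, art


def cross_validate(
    ds: GenotypeDataset,
    y,
    e,
    c=None,
    k: int = 5,
    seed: int = 0,
    p_threshold: float | None = 5e-6,
    selection_rule: str = "main_or_interaction",
    whole_sample_weights: bool = False,
) -> CVPredictions:
    """Stratified k-fold cross-validation of both prediction models.

    By default scans and variant selection happen inside each training fold
    (leakage-free). ``whole_sample_weights=True`` reproduces the alternative
    reading in which weights come from a single whole-sample scan and only the
    second-stage models are cross-validated.
    """
    y = np.asarray(y, dtype=float).ravel()
    e = np.asarray(e, dtype=float).ravel()
    if k < 2:
        raise ValueError("k must be at least 2")
    if ds.n_samples < 10 * k:
        raise ValueError(f"need at least {10 * k} samples for k={k}")
    if len(y) != ds.n_samples or len(e) != ds.n_samples:
        raise ValueError("outcome/exposure must align with the genotype samples")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class; cannot stratify folds")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    frames, artifacts = [], []
    for fold_id, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(
                f"fold {fold_id} has a single outcome class; use fewer folds"
            )
        if whole_sample_weights:
            full = np.arange(ds.n_samples)
            preds, art = run_fold(
                ds, y, e, full, te, c, p_threshold, selection_rule, fold_id
            )
        else:
            preds, art = run_fold(
                ds, y, e, tr, te, c, p_threshold, selection_rule, fold_id
            )
        frames.append(preds)
        artifacts.append(art)
    table = pd.concat(frames, ignore_index=True)
    return CVPredictions(table, artifacts)
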