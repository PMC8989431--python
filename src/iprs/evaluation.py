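"""Discrimination, risk-stratification and calibration metrics.

Covers the full battery used to compare the two risk models: AUC with
DeLong's test for paired ROC curves, 5%/90%/5% risk stratification with a
prevalence chi-square, the Brier score with a bootstrap CI, a quantile-binned
calibration curve, Spiegelhalter's z and the Cox logistic recalibration
slope/intercept.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "auc",
    "delong_test",
    "DeLongResult",
    "stratify",
    "StratificationTable",
    "prevalence_chisq",
    "brier",
    "calibration_curve",
    "spiegelhalter_z",
    "cox_calibration",
    "CalibrationReport",
    "evaluate_predictions",
    "EvaluationReport",
]


def _check_xy(y, p) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if len(y) != len(p):
        raise ValueError("y and predictions have different lengths")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    return y, p


def auc(y, p) -> float:
    """Mann-Whitney AUC: probability a random case outscores a random control.

    Ties count one half. Requires both classes present.
    """
    y, p = _check_xy(y, p)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both cases and controls")
    ranks = sps.rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _midrank_placements(y: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placements: per-case and per-control structural components."""
    cases = p[y == 1]
    controls = p[y == 0]
    n1, n0 = len(cases), len(controls)
    all_r = sps.rankdata(np.concatenate([cases, controls]))
    case_r = sps.rankdata(cases)
    ctrl_r = sps.rankdata(controls)
    v10 = (all_r[:n1] - case_r) / n0  # per case
    v01 = 1.0 - (all_r[n1:] - ctrl_r) / n1  # per control
    a = (all_r[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return v10, v01, a


@dataclass
class DeLongResult:
    auc1: float
    auc2: float
    z: float
    p_value: float
    degenerate: bool = False


def delong_test(y, p1, p2) -> DeLongResult:
    """DeLong's test for two correlated (paired) AUCs.

    The variance of the AUC difference comes from the empirical covariance of
    the per-case and per-control placement values. A zero variance (e.g.
    identical predictions) is flagged degenerate with p = 1.
    """
    y, p1 = _check_xy(y, p1)
    _, p2 = _check_xy(y, p2)
    v10_1, v01_1, a1 = _midrank_placements(y, p1)
    v10_2, v01_2, a2 = _midrank_placements(y, p2)
    n1, n0 = len(v10_1), len(v01_1)
    s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1) if n0 > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    )
    if var <= 0:
        return DeLongResult(a1, a2, 0.0, 1.0, degenerate=True)
    z = (a1 - a2) / np.sqrt(var)
    return DeLongResult(a1, a2, float(z), float(2 * sps.norm.sf(abs(z))))


@dataclass
class StratificationTable:
    """Low / intermediate / high risk groups cut at score percentiles."""

    cuts: tuple[float, float]
    bounds: tuple[float, float]  # score values at the cut percentiles
    n: np.ndarray  # per group, ordered low/intermediate/high
    n_cases: np.ndarray
    prevalence: np.ndarray
    degenerate: bool = False
    groups = ("low", "intermediate", "high")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "n": self.n,
                "n_cases": self.n_cases,
                "prevalence": self.prevalence,
            }
        )


def stratify(scores, y, cuts: tuple[float, float] = (0.05, 0.95)) -> StratificationTable:
    """Partition samples at the score quantiles into low/intermediate/high risk.

    Default cuts at the 5th and 95th percentiles: bottom 5% low risk, top 5%
    high risk. Quantiles are the empirical linear-interpolation (type 7)
    quantiles; samples tied with a bound fall in the lower group.
    """
    y, s = _check_xy(y, scores)
    if len(s) < 20:
        raise ValueError("stratification needs at least 20 samples")
    lo_q, hi_q = cuts
    lo, hi = np.quantile(s, [lo_q, hi_q])
    degenerate = lo == hi
    low = s < lo
    high = s > hi
    mid = ~(low | high)
    n = np.array([low.sum(), mid.sum(), high.sum()], dtype=int)
    n_cases = np.array([y[low].sum(), y[mid].sum(), y[high].sum()], dtype=int)
    with np.errstate(invalid="ignore"):
        prev = np.where(n > 0, n_cases / np.maximum(n, 1), np.nan)
    return StratificationTable((lo_q, hi_q), (float(lo), float(hi)), n, n_cases, prev, degenerate)


@dataclass
class ChisqResult:
    chi2: float
    df: int
    p_value: float
    low_expected: bool = False


def prevalence_chisq(table_a: StratificationTable, table_b: StratificationTable) -> ChisqResult:
    """Pearson chi-square comparing case counts across risk groups of two models.

    The contingency table is 2 models x 3 groups of case counts. Note the two
    stratifications usually come from the same samples; the test treats them
    as independent, as in common practice, which is anti-conservative under
    strong pairing.
    """
    obs = np.stack([table_a.n_cases, table_b.n_cases]).astype(float)
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    if obs.shape[1] < 2 or obs.sum() == 0:
        return ChisqResult(0.0, 0, 1.0, low_expected=True)
    expected = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return ChisqResult(chi2, df, p, low_expected=bool((expected < 1).any()))


def brier(y, p, ci_reps: int = 2000, seed: int | None = 0) -> tuple[float, float, float]:
    """Brier score (mean squared forecast error) with a percentile bootstrap 95% CI."""
    y, p = _check_xy(y, p)
    sq = (y - p) ** 2
    score = float(sq.mean())
    if ci_reps <= 0 or len(y) < 2:
        return score, np.nan, np.nan
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(y), size=(ci_reps, len(y)))
    boot = sq[idx].mean(axis=1)
    lo, hi = np.quantile(boot, [0.025, 0.975])
    return score, float(lo), float(hi)


def calibration_curve(y, p, n_bins: int = 10) -> pd.DataFrame:
    """Observed vs predicted risk in quantile bins of the predictions.

    Returns a frame with columns ``mean_predicted, observed, n`` (deciles by
    default; duplicate bin edges are merged, empty bins omitted).
    """
    y, p = _check_xy(y, p)
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        return pd.DataFrame(
            {"mean_predicted": [p.mean()], "observed": [y.mean()], "n": [len(y)]}
        )
    bins = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = bins == b
        if mask.any():
            rows.append((p[mask].mean(), y[mask].mean(), int(mask.sum())))
    return pd.DataFrame(rows, columns=["mean_predicted", "observed", "n"])


def spiegelhalter_z(y, p) -> tuple[float, float]:
    """Spiegelhalter's calibration test.

    ``z = sum (y-p)(1-2p) / sqrt(sum (1-2p)^2 p (1-p))``; a well-calibrated
    forecaster gives z ~ N(0,1). If every prediction is exactly 0.5 the
    statistic is 0 by convention (two-sided p = 1).
    """
    y, p = _check_xy(y, p)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("predictions must be strictly inside (0, 1)")
    num = ((y - p) * (1 - 2 * p)).sum()
    den = ((1 - 2 * p) ** 2 * p * (1 - p)).sum()
    if den == 0:
        return 0.0, 1.0
    z = float(num / np.sqrt(den))
    return z, float(2 * sps.norm.sf(abs(z)))


def cox_calibration(y, p) -> tuple[float, float]:
    """Cox recalibration: logistic regression of outcomes on logit(predictions).

    Returns (slope, intercept); (1, 0) indicates perfect calibration.
    """
    y, p = _check_xy(y, p)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("predictions must be strictly inside (0, 1)")
    lp = np.log(p / (1 - p))
    X = sm.add_constant(lp)
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("Cox recalibration fit did not converge (separation?)")
    return float(res.params[1]), float(res.params[0])


@dataclass
class CalibrationReport:
    brier: float
    brier_ci: tuple[float, float]
    curve: list
    spiegelhalter_z: float
    spiegelhalter_p: float
    cox_slope: float
    cox_intercept: float


@dataclass
class EvaluationReport:
    """Joint evaluation of the two prediction models on the same samples."""

    auc_iprs: float
    auc_prs: float
    delong: DeLongResult
    stratification_iprs: StratificationTable
    stratification_prs: StratificationTable
    prevalence_test: ChisqResult
    calibration_iprs: CalibrationReport
    calibration_prs: CalibrationReport
    n: int

    def to_dict(self) -> dict:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, np.generic):
                return o.item()
            raise TypeError(f"cannot serialize {type(o)}")

        d = asdict(self)
        return json.loads(json.dumps(d, default=conv))

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def evaluate_predictions(
    y, p_iprs, p_prs, cuts=(0.05, 0.95), ci_reps: int = 2000, seed: int | None = 0
) -> EvaluationReport:
    """Run the full metric battery for the two models on paired predictions."""
    y, p_iprs = _check_xy(y, p_iprs)
    _, p_prs = _check_xy(y, p_prs)

    def calib(p):
        b, lo, hi = brier(y, p, ci_reps=ci_reps, seed=seed)
        zs, zp = spiegelhalter_z(y, p)
        try:
            slope, intercept = cox_calibration(y, p)
        except RuntimeError:
            slope, intercept = np.nan, np.nan
        curve = calibration_curve(y, p)
        return CalibrationReport(
            brier=b,
            brier_ci=(lo, hi),
            curve=curve.to_dict("records"),
            spiegelhalter_z=zs,
            spiegelhalter_p=zp,
            cox_slope=slope,
            cox_intercept=intercept,
        )

    strat_i = stratify(p_iprs, y, cuts)
    strat_p = stratify(p_prs, y, cuts)
    return EvaluationReport(
        auc_iprs=auc(y, p_iprs),
        auc_prs=auc(y, p_prs),
        delong=delong_test(y, p_iprs, p_prs),
        stratification_iprs=strat_i,
        stratification_prs=strat_p,
        prevalence_test=prevalence_chisq(strat_i, strat_p),
        calibration_iprs=calib(p_iprs),
        calibration_prs=calib(p_prs),
        n=len(y),
    )
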