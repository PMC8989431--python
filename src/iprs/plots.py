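"""ROC, risk-stratification and calibration figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.metrics import roc_curve

from .evaluation import EvaluationReport

__all__ = ["plot_roc", "plot_prevalence", "plot_calibration", "save_report_figures"]


def _save(fig, stem: Path) -> list[str]:
    paths = []
    for ext in ("svg", "png"):
        p = stem.with_suffix(f".{ext}")
        fig.savefig(p, dpi=150, bbox_inches="tight")
        paths.append(str(p))
    plt.close(fig)
    return paths


def plot_roc(y, p_iprs, p_prs, report: EvaluationReport, stem) -> list[str]:
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, p, a in (
        ("iPRS model", p_iprs, report.auc_iprs),
        ("PRS model", p_prs, report.auc_prs),
    ):
        fpr, tpr, _ = roc_curve(y, p)
        ax.plot(fpr, tpr, label=f"{label} (AUC={a:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"DeLong p = {report.delong.p_value:.3g}")
    ax.legend(loc="lower right")
    return _save(fig, Path(stem))


def plot_prevalence(report: EvaluationReport, stem) -> list[str]:
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = report.stratification_iprs.groups
    x = np.arange(len(groups))
    width = 0.38
    ax.bar(x - width / 2, report.stratification_iprs.prevalence, width, label="iPRS model")
    ax.bar(x + width / 2, report.stratification_prs.prevalence, width, label="PRS model")
    ax.set_xticks(x, [g.capitalize() for g in groups])
    ax.set_ylabel("Prevalence")
    ax.set_title(f"Risk stratification (chi-square p = {report.prevalence_test.p_value:.3g})")
    ax.legend()
    return _save(fig, Path(stem))


def plot_calibration(report: EvaluationReport, stem) -> list[str]:
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, calib in (
        ("iPRS model", report.calibration_iprs),
        ("PRS model", report.calibration_prs),
    ):
        pts = calib.curve
        xs = [c["mean_predicted"] for c in pts]
        ys = [c["observed"] for c in pts]
        lo, hi = calib.brier_ci
        ax.plot(xs, ys, "o-", label=f"{label} (Brier {calib.brier:.4f} [{lo:.4f}, {hi:.4f}])")
    lim = ax.get_xlim()
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlim(lim)
    ax.set_xlabel("Mean predicted risk")
    ax.set_ylabel("Observed frequency")
    ax.legend(loc="upper left", fontsize=8)
    return _save(fig, Path(stem))


def save_report_figures(y, p_iprs, p_prs, report: EvaluationReport, outdir) -> list[str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    paths += plot_roc(y, p_iprs, p_prs, report, outdir / "roc")
    paths += plot_prevalence(report, outdir / "prevalence")
    paths += plot_calibration(report, outdir / "calibration")
    return paths
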