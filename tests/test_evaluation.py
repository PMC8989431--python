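"""Discrimination, stratification and calibration metrics against oracles."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from iprs.evaluation import (
    auc,
    brier,
    calibration_curve,
    cox_calibration,
    delong_test,
    evaluate_predictions,
    prevalence_chisq,
    spiegelhalter_z,
    stratify,
)


def auc_pair_oracle(y, p):
    """Enumerate every case-control pair; ties count one half."""
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    cases = p[y == 1]
    controls = p[y == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


def test_auc_known_values():
    assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5
    assert auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        auc([1, 1, 1], [0.1, 0.2, 0.3])


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_auc_matches_pair_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(20, 200)
    y = rng.binomial(1, 0.4, n)
    if len(np.unique(y)) < 2:
        y[0], y[1] = 0, 1
    p = np.round(rng.random(n), 2)  # rounding forces ties
    assert auc(y, p) == pytest.approx(auc_pair_oracle(y, p), abs=1e-12)


def test_delong_identical_predictions_degenerate():
    rng = np.random.default_rng(5)
    y = rng.binomial(1, 0.5, 50)
    p = rng.random(50)
    res = delong_test(y, p, p)
    assert res.degenerate
    assert res.p_value == 1.0
    assert res.auc1 == res.auc2


def test_delong_antisymmetric_in_arm_order():
    rng = np.random.default_rng(6)
    y = rng.binomial(1, 0.4, 200)
    p1 = rng.random(200) + 0.3 * y
    p2 = rng.random(200) + 0.1 * y
    r12 = delong_test(y, p1, p2)
    r21 = delong_test(y, p2, p1)
    assert r12.z == pytest.approx(-r21.z, abs=1e-12)
    assert r12.p_value == pytest.approx(r21.p_value, abs=1e-12)


def test_delong_invariant_to_monotone_transform():
    rng = np.random.default_rng(7)
    y = rng.binomial(1, 0.4, 150)
    p1 = rng.random(150) + 0.4 * y
    p2 = rng.random(150) + 0.2 * y
    a = delong_test(y, p1, p2)
    b = delong_test(y, np.exp(2 * p1), np.exp(2 * p2))
    assert a.z == pytest.approx(b.z, abs=1e-10)
    assert a.auc1 == pytest.approx(b.auc1, abs=1e-12)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_delong_matches_pROC_reference():
    rng = np.random.default_rng(8)
    n = 150
    y = rng.binomial(1, 0.4, n)
    if len(np.unique(y)) < 2:
        y[:2] = [0, 1]
    p1 = rng.random(n) + 0.5 * y
    p2 = rng.random(n) + 0.2 * y
    res = delong_test(y, p1, p2)
    df = pd.DataFrame({"y": y, "p1": p1, "p2": p2})
    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        csv = os.path.join(td, "d.csv")
        df.to_csv(csv, index=False)
        rcode = (
            "suppressMessages(library(pROC));"
            f"d <- read.csv('{csv}');"
            "r1 <- roc(d$y, d$p1, quiet=TRUE);"
            "r2 <- roc(d$y, d$p2, quiet=TRUE);"
            "t <- roc.test(r1, r2, method='delong', paired=TRUE);"
            "cat(sprintf('%.15g %.15g %.15g %.15g', t$statistic, t$p.value, auc(r1), auc(r2)))"
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        )
        z_r, p_r, auc1_r, auc2_r = map(float, out.stdout.split())
    assert res.auc1 == pytest.approx(auc1_r, abs=1e-10)
    assert res.auc2 == pytest.approx(auc2_r, abs=1e-10)
    assert abs(res.z) == pytest.approx(abs(z_r), abs=1e-6)
    assert res.p_value == pytest.approx(p_r, abs=1e-6)


def test_stratification_group_sizes_five_ninety_five():
    rng = np.random.default_rng(9)
    s = rng.permutation(1000).astype(float)  # all distinct
    y = rng.binomial(1, 0.3, 1000)
    table = stratify(s, y)
    np.testing.assert_array_equal(table.n, [50, 900, 50])
    assert table.n.sum() == 1000


def test_stratification_all_cases_gives_unit_prevalence():
    s = np.linspace(0, 1, 100)
    table = stratify(s, np.ones(100))
    np.testing.assert_allclose(table.prevalence, 1.0)


def test_stratification_matches_groupby_oracle():
    rng = np.random.default_rng(10)
    s = rng.normal(size=500)
    y = rng.binomial(1, 0.25, 500)
    table = stratify(s, y)
    lo, hi = np.quantile(s, [0.05, 0.95])
    df = pd.DataFrame({"s": s, "y": y})
    df["grp"] = np.where(df.s < lo, "low", np.where(df.s > hi, "high", "mid"))
    oracle = df.groupby("grp")["y"].agg(["size", "sum", "mean"])
    for i, g in [(0, "low"), (1, "mid"), (2, "high")]:
        assert table.n[i] == oracle.loc[g, "size"]
        assert table.n_cases[i] == oracle.loc[g, "sum"]
        assert table.prevalence[i] == pytest.approx(oracle.loc[g, "mean"])


def test_tied_scores_flagged_degenerate():
    table = stratify(np.ones(50), np.r_[np.ones(10), np.zeros(40)])
    assert table.degenerate
    assert table.n[1] == 50  # everyone intermediate


def test_prevalence_chisq_identical_tables():
    rng = np.random.default_rng(11)
    s = rng.normal(size=200)
    y = rng.binomial(1, 0.3, 200)
    t = stratify(s, y)
    res = prevalence_chisq(t, t)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0


def test_prevalence_chisq_matches_hand_computation():
    ta = stratify(np.arange(100.0), np.r_[np.zeros(50), np.ones(50)])
    tb = stratify(np.arange(100.0), np.r_[np.ones(50), np.zeros(50)])
    res = prevalence_chisq(ta, tb)
    # hand computation on the 2x3 case-count table, written out independently
    obs = np.array([ta.n_cases, tb.n_cases], dtype=float)
    chi2 = 0.0
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    tot = obs.sum()
    for i in range(2):
        for j in range(3):
            exp = row[i] * col[j] / tot
            chi2 += (obs[i, j] - exp) ** 2 / exp
    assert res.chi2 == pytest.approx(chi2, abs=1e-10)
    assert res.df == 2


def test_prevalence_chisq_invariant_to_consistent_group_permutation():
    rng = np.random.default_rng(12)
    s1, s2 = rng.normal(size=(2, 300))
    y = rng.binomial(1, 0.3, 300)
    ta, tb = stratify(s1, y), stratify(s2, y)
    base = prevalence_chisq(ta, tb)
    import dataclasses

    perm = [2, 0, 1]
    ta_p = dataclasses.replace(
        ta, n=ta.n[perm], n_cases=ta.n_cases[perm], prevalence=ta.prevalence[perm]
    )
    tb_p = dataclasses.replace(
        tb, n=tb.n[perm], n_cases=tb.n_cases[perm], prevalence=tb.prevalence[perm]
    )
    assert prevalence_chisq(ta_p, tb_p).chi2 == pytest.approx(base.chi2, abs=1e-12)


def test_brier_hand_values():
    assert brier([1, 0], [1.0, 0.0], ci_reps=0)[0] == 0.0
    assert brier([1, 0, 1, 0], [0.5] * 4, ci_reps=0)[0] == pytest.approx(0.25)
    assert brier([1, 0], [0.8, 0.3], ci_reps=0)[0] == pytest.approx(0.065)


def test_brier_bootstrap_ci_brackets_point_estimate():
    rng = np.random.default_rng(13)
    y = rng.binomial(1, 0.3, 500)
    p = np.clip(rng.normal(0.3, 0.1, 500), 0.01, 0.99)
    score, lo, hi = brier(y, p, ci_reps=500, seed=0)
    assert lo <= score <= hi
    assert brier(y, p, ci_reps=500, seed=0) == (score, lo, hi)  # seeded determinism


def test_calibration_curve_on_calibrated_data_lies_on_diagonal():
    rng = np.random.default_rng(14)
    p = rng.uniform(0.05, 0.95, 100_000)
    y = (rng.random(100_000) < p).astype(float)
    curve = calibration_curve(y, p)
    assert len(curve) == 10
    assert (curve["mean_predicted"] - curve["observed"]).abs().max() < 0.02


def test_calibration_curve_degenerate_single_bin():
    y = np.array([0, 1, 0, 1.0])
    p = np.full(4, 0.4)
    curve = calibration_curve(y, p)
    assert len(curve) == 1
    assert curve["n"].iloc[0] == 4


def test_calibration_curve_perfect_forecast_on_diagonal():
    y = np.r_[np.zeros(50), np.ones(50)]
    p = np.r_[np.full(50, 0.001), np.full(50, 0.999)]
    curve = calibration_curve(y, p)
    np.testing.assert_allclose(curve["mean_predicted"], curve["observed"], atol=1e-3)


def test_spiegelhalter_z_zero_at_one_half():
    y = np.array([0, 1, 1, 0.0])
    z, p = spiegelhalter_z(y, np.full(4, 0.5))
    assert z == 0.0
    assert p == 1.0


def test_spiegelhalter_detects_shrunk_probabilities():
    rng = np.random.default_rng(15)
    n = 10_000
    reported = rng.uniform(0.1, 0.9, n)
    truth = np.clip(0.5 + 1.8 * (reported - 0.5), 0.01, 0.99)
    y = (rng.random(n) < truth).astype(float)
    z, p = spiegelhalter_z(y, reported)
    assert abs(z) > 1.96


def test_spiegelhalter_requires_open_interval():
    with pytest.raises(ValueError):
        spiegelhalter_z([0, 1], [0.0, 1.0])


def test_cox_refit_fixed_point_gives_slope_one_intercept_zero():
    rng = np.random.default_rng(16)
    import statsmodels.api as sm

    n = 5_000
    x = rng.normal(size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
    p = sm.Logit(y, sm.add_constant(x)).fit(disp=0).predict()
    slope, intercept = cox_calibration(y, p)
    assert slope == pytest.approx(1.0, abs=1e-4)
    assert intercept == pytest.approx(0.0, abs=1e-4)


def test_cox_detects_doubled_logit_scale():
    rng = np.random.default_rng(17)
    n = 50_000
    lp = rng.normal(0, 1, n)
    p_true = 1 / (1 + np.exp(-lp))
    y = (rng.random(n) < p_true).astype(float)
    p_over = 1 / (1 + np.exp(-2 * lp))  # logit doubled
    slope, _ = cox_calibration(y, p_over)
    assert slope == pytest.approx(0.5, abs=0.05)


def test_cox_slope_near_zero_for_shuffled_outcomes():
    rng = np.random.default_rng(18)
    n = 50_000
    lp = rng.normal(0, 1, n)
    p = 1 / (1 + np.exp(-lp))
    y = (rng.random(n) < p).astype(float)
    rng.shuffle(y)
    slope, _ = cox_calibration(y, p)
    assert abs(slope) < 0.05


def test_evaluate_predictions_assembles_full_report():
    rng = np.random.default_rng(19)
    n = 400
    y = rng.binomial(1, 0.3, n)
    p1 = np.clip(0.3 + 0.3 * (y - 0.3) + rng.normal(0, 0.15, n), 0.01, 0.99)
    p2 = np.clip(0.3 + 0.15 * (y - 0.3) + rng.normal(0, 0.15, n), 0.01, 0.99)
    rep = evaluate_predictions(y, p1, p2, ci_reps=100, seed=0)
    assert 0.5 < rep.auc_iprs <= 1.0
    assert rep.n == n
    d = rep.to_dict()
    assert set(d["calibration_iprs"]) >= {"brier", "spiegelhalter_z", "cox_slope"}
    assert isinstance(rep.to_json(), str)
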