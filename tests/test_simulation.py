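"""Generators: quota sampling, scenario contracts, polygenic effect draws."""

import json
import math

import numpy as np
import pytest

from iprs.association import fit_interaction
from iprs.simulation import (
    PolygenicSimConfig,
    SparseSimConfig,
    StudySettings,
    export_dataset,
    load_config,
    polygenic_effects,
    run_simulation_study,
    simulate_polygenic,
    simulate_sparse,
    sparse_effects,
    synthesize_genotypes,
)


@pytest.mark.parametrize("n_cases,n_controls", [(1000, 1000), (150, 350)])
def test_quota_sampler_emits_exact_counts(n_cases, n_controls):
    cfg = SparseSimConfig(n_cases=n_cases, n_controls=n_controls)
    sim = simulate_sparse(cfg, seed=3)
    assert int(sim.outcome.sum()) == n_cases
    assert int((1 - sim.outcome).sum()) == n_controls
    assert sim.genotypes.n_samples == n_cases + n_controls


def test_quota_sampler_deterministic_given_seed():
    cfg = SparseSimConfig(n_cases=200, n_controls=200)
    a = simulate_sparse(cfg, seed=11)
    b = simulate_sparse(cfg, seed=11)
    np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
    np.testing.assert_array_equal(a.outcome, b.outcome)
    assert a.truth.to_json() == b.truth.to_json()


def test_null_model_raw_case_fraction_near_half():
    cfg = SparseSimConfig(
        n_cases=2000,
        n_controls=2000,
        beta_main_mag=0.0,
        beta_int_mag=0.0,
        beta_e=0.0,
        alpha=0.0,
    )
    sim = simulate_sparse(cfg, seed=5)
    frac = sim.truth.n_cases_seen / sim.truth.n_draws_total
    se = math.sqrt(0.25 / sim.truth.n_draws_total)
    assert abs(frac - 0.5) < 3 * se + 1e-9


def test_extreme_alpha_exhausts_draw_budget():
    cfg = SparseSimConfig(n_cases=100, n_controls=100, alpha=-30.0, max_draws=10_000)
    with pytest.raises(RuntimeError, match="draw budget"):
        simulate_sparse(cfg, seed=0)


@pytest.mark.parametrize(
    "scenario,expected_signs",
    [
        ("all_antagonistic", {-1.0}),
        ("all_synergistic", {1.0}),
        ("half_half", {-1.0, 1.0}),
    ],
)
def test_scenario_fixes_interaction_signs(scenario, expected_signs):
    cfg = SparseSimConfig(scenario=scenario)
    truth = sparse_effects(cfg, np.random.default_rng(0))
    ids = [f"snp{j + 1}" for j in range(cfg.n_snps)]
    int_idx = [ids.index(v) for v in truth.interacting_ids]
    main_signs = np.sign(truth.beta_main[int_idx])
    assert set(main_signs) == {1.0}  # interacting SNPs all causal risk SNPs
    rel = set(np.sign(truth.beta_int[int_idx]) * main_signs)
    assert rel == expected_signs
    if scenario == "half_half":
        assert (np.sign(truth.beta_int[int_idx]) < 0).sum() == 2


def test_truth_probability_recomputes_outcome_model():
    cfg = SparseSimConfig(n_cases=100, n_controls=100)
    sim = simulate_sparse(cfg, seed=9)
    g = sim.genotypes.dosages.astype(float)
    t = sim.truth
    lp = t.alpha + g @ t.beta_main + (g @ t.beta_int) * sim.exposure + t.beta_e * sim.exposure
    np.testing.assert_allclose(t.probability(g, sim.exposure), 1 / (1 + np.exp(-lp)))


def test_interacting_snps_subset_of_causal_when_required():
    cfg = SparseSimConfig(interacting_require_main=True)
    for seed in range(5):
        truth = sparse_effects(cfg, np.random.default_rng(seed))
        assert set(truth.interacting_ids) <= set(truth.causal_ids)


def test_interaction_only_snps_possible_when_not_required():
    cfg = SparseSimConfig(interacting_require_main=False, n_interacting=6)
    seen_interaction_only = False
    for seed in range(20):
        truth = sparse_effects(cfg, np.random.default_rng(seed))
        only = set(truth.interacting_ids) - set(truth.causal_ids)
        seen_interaction_only |= bool(only)
    assert seen_interaction_only


def test_sparse_truth_recovered_by_interaction_refit():
    """Effect recovery from a large quota sample (betas are consistent under
    case-control sampling; only the intercept shifts)."""
    cfg = SparseSimConfig(n_cases=10_000, n_controls=10_000)
    sim = simulate_sparse(cfg, seed=21)
    g = sim.genotypes.dosages.astype(float)
    ids = sim.genotypes.variant_ids.tolist()
    for vid in sim.truth.interacting_ids[:2] + sim.truth.causal_ids[:2]:
        j = ids.index(vid)
        fit = fit_interaction(sim.outcome.astype(float), g[:, j], sim.exposure)
        k = ids.index(vid)
        assert abs(fit.beta_g_main - sim.truth.beta_main[k]) < 3 * fit.se_g
        assert abs(fit.beta_gxe - sim.truth.beta_int[k]) < 3 * fit.se_gxe


def test_polygenic_counts_follow_fractions():
    cfg = PolygenicSimConfig(m=40_000)
    assert cfg.n_causal == 400
    assert cfg.n_interacting == 4
    truth = polygenic_effects(cfg, np.random.default_rng(0))
    assert len(truth.causal_ids) == 400
    assert len(truth.interacting_ids) == 4
    int_idx = [int(v[3:]) - 1 for v in truth.interacting_ids]
    main_dir = np.where(truth.beta_main[int_idx] >= 0, 1.0, -1.0)
    antagonistic = (np.sign(truth.beta_int[int_idx]) * main_dir) < 0
    assert antagonistic.sum() == 3  # round(0.7 * 4)


def test_polygenic_effect_variance_matches_h2_over_m():
    cfg = PolygenicSimConfig(m=40_000)
    truth = polygenic_effects(cfg, np.random.default_rng(1))
    idx = [int(v[3:]) - 1 for v in truth.causal_ids]
    effects = truth.beta_main[idx]
    target = cfg.h2 / cfg.n_causal
    # sample variance of k normal draws has sd ~ sigma^2 * sqrt(2/(k-1))
    tol = 3 * target * math.sqrt(2 / (len(effects) - 1))
    assert abs(effects.var(ddof=1) - target) < tol


def test_polygenic_interacting_subset_flag():
    cfg = PolygenicSimConfig(m=10_000, interacting_subset_of_causal=True)
    truth = polygenic_effects(cfg, np.random.default_rng(2))
    assert set(truth.interacting_ids) <= set(truth.causal_ids)


def test_zero_interacting_count_proceeds_without_interactions():
    cfg = PolygenicSimConfig(m=1_000, n_samples=50)  # round(1e-4 * 1000) = 0
    sim = simulate_polygenic(cfg, seed=0)
    assert len(sim.truth.interacting_ids) == 0
    assert np.all(sim.truth.beta_int == 0)


def test_synthesized_genotypes_deterministic_and_frequency_consistent():
    a = synthesize_genotypes(10_000, 40, seed=4)
    b = synthesize_genotypes(10_000, 40, seed=4)
    np.testing.assert_array_equal(a.dosages, b.dosages)
    freq = a.dosages.mean(axis=0) / 2.0
    # drawn MAF is recoverable within 3 binomial standard errors
    maf_se = np.sqrt(freq * (1 - freq) / (2 * 10_000))
    drawn = np.random.default_rng(4).uniform(0.05, 0.5, 40)
    assert np.all(np.abs(freq - drawn) < 3 * maf_se + 1e-6)


def test_degenerate_maf_range_gives_expected_dosage_one():
    ds = synthesize_genotypes(2_000, 5, maf_low=0.5, maf_high=0.5, seed=6)
    np.testing.assert_allclose(ds.dosages.mean(axis=0), 1.0, atol=0.1)


def test_study_aggregate_matches_replicate_table():
    cfg = SparseSimConfig(n_cases=150, n_controls=150)
    table, agg = run_simulation_study("sparse", cfg, 4, seed=42)
    ok = table[~table["failed"]]
    assert len(table) == 4
    assert agg["n_failed"] == int(table["failed"].sum())
    assert agg["mean_auc_iprs"] == pytest.approx(ok["auc_iprs"].mean())
    assert agg["mean_auc_diff"] == pytest.approx(
        (ok["auc_iprs"] - ok["auc_prs"]).mean()
    )


def test_study_replicates_reproducible_in_isolation():
    cfg = SparseSimConfig(n_cases=150, n_controls=150)
    full, _ = run_simulation_study("sparse", cfg, 3, seed=7)
    part, _ = run_simulation_study("sparse", cfg, 3, seed=7, only_replicates=[2])
    row_full = full[full["replicate"] == 2].iloc[0]
    row_part = part.iloc[0]
    assert row_full["auc_iprs"] == pytest.approx(row_part["auc_iprs"], abs=1e-12)
    assert row_full["brier_prs"] == pytest.approx(row_part["brier_prs"], abs=1e-12)


def test_config_file_roundtrip(tmp_path):
    path = tmp_path / "sparse.cfg"
    path.write_text(
        "scenario = all_synergistic\n"
        "n_cases = 120  # small run\n"
        "n_controls = 130\n"
        "beta_e = 0.2\n"
    )
    cfg = load_config(path, "sparse")
    assert cfg.scenario == "all_synergistic"
    assert cfg.n_cases == 120
    assert cfg.beta_e == pytest.approx(0.2)


def test_config_unknown_key_named_in_error(tmp_path):
    path = tmp_path / "bad.cfg"
    path.write_text("n_casez = 5\n")
    with pytest.raises(ValueError, match="n_casez"):
        load_config(path, "sparse")


def test_export_dataset_writes_triplet_and_truth(tmp_path):
    cfg = SparseSimConfig(n_cases=50, n_controls=50)
    sim = simulate_sparse(cfg, seed=13)
    paths = export_dataset(sim, tmp_path / "out")
    from iprs.genotype import read_plink

    back = read_plink(str(tmp_path / "out" / "genotypes"))
    np.testing.assert_array_equal(back.dosages, sim.genotypes.dosages)
    truth = json.loads((tmp_path / "out" / "truth.json").read_text())
    assert truth["design"] == "sparse"
    assert len(truth["beta_main"]) == cfg.n_snps
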