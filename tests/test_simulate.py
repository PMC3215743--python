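"""Synthetic cohort generator: calibration, matching, parameter recovery."""

import numpy as np
import pytest
from scipy.special import expit, logit

from hwematch.exact import GenotypeCounts, hwe_exact_pvalue
from hwematch.likelihood import PopulationParams
from hwematch.simulate import (
    SimulationScenario,
    build_population,
    calibrate_intercepts,
    draw_matched_blocks,
    estimate_joint_probs,
    perturb_population_params,
    phenotype_genotype_cells,
    sample_frequency_matched,
    sample_unmatched,
    simulate_population,
)


def test_pure_bernoulli_prevalences_without_effects():
    """With every log-odds zero and intercepts at logit(f), T and D are plain
    Bernoulli draws at the target rates."""
    scn = SimulationScenario(
        alpha_snp=(0, 0, 0, 0), beta_snp=(0, 0, 0, 0),
        alpha_sex=0, alpha_ethn=0, alpha_age=0,
        beta_sex=0, beta_ethn=0, beta_age=0, beta_trait=0,
        alpha0=float(logit(0.3)), beta0=float(logit(0.2)),
    )
    pop = simulate_population(scn, 100_000, np.random.default_rng(1))
    se_t = np.sqrt(0.3 * 0.7 / len(pop))
    se_d = np.sqrt(0.2 * 0.8 / len(pop))
    assert abs(pop["T"].mean() - 0.3) < 3 * se_t
    assert abs(pop["D"].mean() - 0.2) < 3 * se_d


def test_calibration_self_consistency():
    """Calibrated intercepts reproduce the target prevalences on a fresh pool."""
    scn = SimulationScenario(pool_size=400_000)
    a0, b0 = calibrate_intercepts(scn, rng=np.random.default_rng(7))
    scn2 = SimulationScenario(pool_size=400_000, alpha0=a0, beta0=b0)
    pop = simulate_population(scn2, 400_000, np.random.default_rng(8))
    assert abs(pop["T"].mean() - 0.3) < 0.003
    assert abs(pop["D"].mean() - 0.3) < 0.003


def test_calibration_zero_effects_symmetric_logistic():
    scn = SimulationScenario(
        alpha_snp=(0, 0, 0, 0), beta_snp=(0, 0, 0, 0),
        alpha_sex=0, alpha_ethn=0, alpha_age=0,
        beta_sex=0, beta_ethn=0, beta_age=0, beta_trait=0,
        f_t=0.5, f_d=0.5, pool_size=200_000,
    )
    a0, b0 = calibrate_intercepts(scn, rng=np.random.default_rng(3))
    assert abs(a0) < 0.02 and abs(b0) < 0.02


def test_calibration_monotone_in_target():
    scn = SimulationScenario(pool_size=100_000)
    rng_seed = 11
    _, b_low = calibrate_intercepts(scn, f_d=0.2, rng=np.random.default_rng(rng_seed))
    _, b_high = calibrate_intercepts(scn, f_d=0.5, rng=np.random.default_rng(rng_seed))
    assert b_high > b_low


def test_trait_disease_odds_ratio_matches_coefficient(small_pool):
    """beta_trait = 1.0983 should yield an empirical OR of D on T near 3."""
    pool, _, _ = small_pool
    tab = pool.groupby(["T", "D"]).size().unstack()
    odds_ratio = (tab.loc[1, 1] * tab.loc[0, 0]) / (tab.loc[1, 0] * tab.loc[0, 1])
    # the marginal OR is attenuated relative to the conditional one by the
    # shared covariates, but with these effect sizes stays within ~5% of 3
    assert odds_ratio == pytest.approx(3.0, rel=0.05)


def test_population_genotypes_in_hwp(small_pool):
    """Exact-test rejection across null SNPs stays near the nominal level."""
    pool, _, _ = small_pool
    rng = np.random.default_rng(12)
    rejected = 0
    trials = 200
    for _ in range(trials):
        sub = pool.sample(2000, random_state=rng.integers(2**31))
        counts = np.bincount(sub["snp4"].to_numpy(), minlength=3)
        if hwe_exact_pvalue(GenotypeCounts(*map(int, counts))) <= 0.05:
            rejected += 1
    assert rejected / trials <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / trials)


def test_estimate_joint_probs_cell_fractions():
    import pandas as pd

    df = pd.DataFrame(
        {"T": [0] * 40 + [1] * 20 + [0] * 25 + [1] * 15,
         "D": [0] * 60 + [1] * 40}
    )
    pop = estimate_joint_probs(df)
    assert pop.as_array().tolist() == pytest.approx([0.40, 0.20, 0.25, 0.15])
    assert pop.f_d == pytest.approx(pop.k01 + pop.k11)


def test_matching_inequality_holds_over_many_seeds(small_pool):
    """|q0_realised - q1| <= c + rounding slack on every generated dataset."""
    pool, _, scn = small_pool
    n_cases, n_controls, c = 400, 400, 0.02
    for seed in range(100):
        rng = np.random.default_rng(seed)
        study = sample_frequency_matched(pool, n_cases, n_controls, c, rng)
        cases = study[study["D"] == 1]
        controls = study[study["D"] == 0]
        assert len(cases) == n_cases and len(controls) == n_controls
        q1 = cases["T"].mean()
        q0 = controls["T"].mean()
        assert abs(q0 - q1) <= c + 1.0 / n_controls


def test_matching_with_zero_tolerance(small_pool):
    pool, _, _ = small_pool
    rng = np.random.default_rng(77)
    study = sample_frequency_matched(pool, 500, 500, 0.0, rng)
    q1 = study[study["D"] == 1]["T"].mean()
    n_t1 = int(study[study["D"] == 0]["T"].sum())
    assert n_t1 == round(q1 * 500)


def test_matched_sampler_insufficient_stratum_is_named():
    import pandas as pd

    pool = pd.DataFrame(
        {"T": [1] * 50 + [0] * 5, "D": [1] * 50 + [0] * 5,
         "snp1": 1, "snp2": 1, "snp3": 1, "snp4": 1,
         "sex": 0, "ethn": 0, "age": 0}
    )
    with pytest.raises(ValueError, match="stratum T="):
        sample_frequency_matched(pool, 40, 40, 0.02, np.random.default_rng(0))


def test_unmatched_sampler_ignores_trait(small_pool):
    pool, _, _ = small_pool
    rng = np.random.default_rng(5)
    study = sample_unmatched(pool, 1000, 1000, rng)
    assert (study["D"] == 1).sum() == 1000 and (study["D"] == 0).sum() == 1000
    pool_rate = pool[pool["D"] == 0]["T"].mean()
    got = study[study["D"] == 0]["T"].mean()
    assert abs(got - pool_rate) < 3 * np.sqrt(pool_rate * (1 - pool_rate) / 1000)


def test_count_level_matched_draw_satisfies_matching(small_pool):
    """The fast hypergeometric replicate sampler honours the matching rule."""
    pool, _, scn = small_pool
    cc, ctl = phenotype_genotype_cells(pool, "snp1")
    for seed in range(50):
        blocks = draw_matched_blocks(cc, ctl, 2000, 2000, 0.02,
                                     np.random.default_rng(seed))
        sizes = blocks.block_sizes  # (0,0),(1,0),(0,1),(1,1)
        q1 = sizes[3] / (sizes[2] + sizes[3])
        q0 = sizes[1] / (sizes[0] + sizes[1])
        assert abs(q0 - q1) <= 0.02 + 1.0 / 2000
        assert blocks.n_total == 4000


def test_perturbation_identity_and_bounds(pop_mid):
    rng = np.random.default_rng(2)
    assert perturb_population_params(pop_mid, 0.0, rng) is pop_mid
    for _ in range(50):
        pert = perturb_population_params(pop_mid, 0.2, rng)
        assert pert.as_array().sum() == pytest.approx(1.0)
        assert abs(pert.f_d - pop_mid.f_d) <= 0.2 * pop_mid.f_d + 1e-12
        t_case = pert.k11 / pert.f_d
        true_t_case = pop_mid.k11 / pop_mid.f_d
        assert abs(t_case - true_t_case) <= 0.2 * true_t_case + 1e-12


def test_logistic_coefficient_recovery(small_pool):
    """Refitting the two logistic models on the pool recovers the generative
    log-odds within 5% relative error (dominant coding, additive age)."""
    sm = pytest.importorskip("statsmodels.api")
    pool, _, scn = small_pool
    X = np.column_stack(
        [(pool[f"snp{i}"] >= 1).astype(float) for i in (1, 3)]
        + [pool["sex"], pool["ethn"]]
    )
    fit_t = sm.Logit(pool["T"], sm.add_constant(X)).fit(disp=0)
    got = fit_t.params[1:5]
    expect = [0.4055, 0.4055, 0.6931, 0.4055]
    assert np.allclose(got, expect, rtol=0.05)

    Xd = np.column_stack(
        [(pool[f"snp{i}"] >= 1).astype(float) for i in (1, 2)]
        + [pool["ethn"], pool["age"], pool["T"]]
    )
    fit_d = sm.Logit(pool["D"], sm.add_constant(Xd)).fit(disp=0)
    got_d = fit_d.params[1:6]
    expect_d = [0.4055, 0.4055, 0.4055, 0.4055, 1.0983]
    assert np.allclose(got_d, expect_d, rtol=0.05)


def test_unreachable_prevalence_raises():
    scn = SimulationScenario(pool_size=10_000)
    with pytest.raises(ValueError, match="unreachable"):
        calibrate_intercepts(scn, f_t=1e-12, rng=np.random.default_rng(0))
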