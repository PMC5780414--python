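"""Forward simulator: determinism, inverse identity, recovery statistics."""

import numpy as np
import pandas as pd
import pytest

from darkcarbon import (
    InvalidInputError,
    NoiseModel,
    analyze_campaign,
    estimate_isotope_dilution,
    integrate_profile,
    make_scenario,
    recovery_report,
    simulate_campaign,
)
from darkcarbon.simulate import MEDITERRANEAN_ENVELOPES

ZERO_NOISE = NoiseModel(replicate_cv=0.0)


class TestMakeScenario:
    def test_same_seed_same_scenario(self):
        a = make_scenario("mediterranean-deep", seed=7)
        b = make_scenario("mediterranean-deep", seed=7)
        assert a == b

    def test_uniform_template_is_constant(self):
        sc = make_scenario("uniform", seed=0)
        assert len(set(sc.true_abd)) == 1
        assert len(set(sc.true_pr)) == 1

    def test_unknown_template_rejected(self):
        with pytest.raises(InvalidInputError):
            make_scenario("hadal-trench")

    def test_mediterranean_draws_stay_inside_envelopes(self):
        """Many seeds, every drawn true value inside the stated envelope."""
        for seed in range(100):
            sc = make_scenario("mediterranean-deep", seed=seed)
            for var, values in (
                ("php", sc.true_php), ("pr", sc.true_pr),
                ("abd", sc.true_abd), ("pa", sc.true_pa),
            ):
                lo, hi = MEDITERRANEAN_ENVELOPES[var]
                assert all(lo <= v <= hi for v in values), (seed, var)


class TestSimulateCampaign:
    def test_seed_reproducibility(self):
        sc = make_scenario("mediterranean-deep", seed=11)
        a = simulate_campaign(sc)
        b = simulate_campaign(sc)
        for z in a.depths:
            assert a.leucine[z].replicate_dpm == b.leucine[z].replicate_dpm
            assert a.bicarbonate[z].blank_dpm == b.bicarbonate[z].blank_dpm

    def test_zero_noise_forward_inverse_identity(self):
        """At zero noise the pipeline recovers every true rate and the
        depth integral to better than 1e-10 relative."""
        sc = make_scenario(
            "mediterranean-deep", overrides={"noise": ZERO_NOISE}, seed=5
        )
        est = analyze_campaign(simulate_campaign(sc))
        truth = sc.true_profile()
        for t, e in zip(truth.samples, est.samples):
            assert abs(e.php - t.php) <= 1e-10 * t.php
            assert abs(e.pr - t.pr) <= 1e-10 * t.pr
            assert abs(e.abd - t.abd) <= 1e-10 * t.abd
            assert abs(e.pa - t.pa) <= 1e-10 * t.pa
        ti = integrate_profile(truth, "abd").value
        ei = integrate_profile(est, "abd").value
        assert abs(ei - ti) <= 1e-10 * ti

    def test_zero_noise_dilution_series_recovers_configured_id(self):
        sc = make_scenario("uniform", overrides={"noise": ZERO_NOISE}, seed=0)
        obs = simulate_campaign(sc)
        fit = estimate_isotope_dilution(obs.dilution_series)
        assert fit.isotope_dilution == pytest.approx(1.28, abs=1e-9)

    def test_blanks_have_positive_mean(self):
        sc = make_scenario("uniform", seed=2)
        obs = simulate_campaign(sc)
        blanks = [v for z in obs.depths for v in obs.leucine[z].blank_dpm]
        assert np.mean(blanks) > 0

    def test_poisson_counting_model(self):
        sc = make_scenario(
            "uniform",
            overrides={"noise": NoiseModel(counting_model="poisson")},
            seed=3,
        )
        obs = simulate_campaign(sc)
        counts = obs.leucine[200.0].replicate_dpm
        assert all(float(c).is_integer() for c in counts)


@pytest.fixture(scope="module")
def mc_reports():
    """200 seeds of the default 5% replicate-CV noise on a constant profile."""
    reports = []
    for seed in range(200):
        sc = make_scenario("uniform", seed=seed)
        est = analyze_campaign(simulate_campaign(sc, with_dilution_series=False))
        reports.append(recovery_report(sc, est))
    return reports


class TestMonteCarloRecovery:
    def test_rates_unbiased_within_one_percent(self, mc_reports):
        bias = pd.concat([r["relative_bias"] for r in mc_reports], axis=1).mean(axis=1)
        for var in ("php", "pr", "abd", "pa"):
            assert abs(bias[var]) < 0.01, f"{var}: mean relative bias {bias[var]:.4f}"

    def test_estimate_scatter_tracks_replicate_cv(self, mc_reports):
        """sd of the per-seed ABD estimates ≈ replicate CV / sqrt(3 replicates)."""
        rmse = pd.concat([r["relative_rmse"] for r in mc_reports], axis=1).mean(axis=1)
        assert 0.4 * 0.05 < rmse["abd"] < 1.5 * 0.05

    def test_integral_recovery_within_mc_error(self, mc_reports):
        bias = np.mean([r.loc["abd_integral", "relative_bias"] for r in mc_reports])
        assert abs(bias) < 0.01

    def test_two_sd_coverage_near_nominal(self, mc_reports):
        """±2 sd intervals from triplicate scatter cover the truth at a rate
        consistent with the heavy-tailed t distribution of n=3 replicates."""
        coverage = np.mean([r.loc["abd", "coverage_2sd"] for r in mc_reports])
        assert 0.80 <= coverage <= 0.99


class TestRecoveryReport:
    def test_perfect_estimates(self):
        sc = make_scenario("uniform", overrides={"noise": ZERO_NOISE}, seed=0)
        report = recovery_report(sc, sc.true_profile())
        assert report.loc["abd", "relative_bias"] == 0.0
        assert report.loc["abd", "relative_rmse"] == 0.0

    def test_ten_percent_inflation_reported(self):
        sc = make_scenario("uniform", overrides={"noise": ZERO_NOISE}, seed=0)
        inflated = sc.true_profile()
        for s in inflated.samples:
            s.abd *= 1.1
        report = recovery_report(sc, inflated)
        assert report.loc["abd", "relative_bias"] == pytest.approx(0.1, rel=1e-9)

    def test_mismatched_grids_rejected(self):
        sc = make_scenario("uniform", seed=0)
        other = make_scenario("mediterranean-deep", seed=0)
        with pytest.raises(InvalidInputError):
            recovery_report(sc, other.true_profile())
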