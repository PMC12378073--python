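"""Simulation engine: truncation, reproducibility, analytic quantile
recovery and rank-correlation sensitivity."""

import math

import numpy as np
import pytest

from bmrisk.data import DEFAULT_SPECS, MEL, ValidationError
from bmrisk.montecarlo import (
    ConfigurationError,
    DistributionSpec,
    SimulationConfig,
    fit_distribution,
    percentile_bootstrap_se,
    risk_verdict,
    sample,
    sensitivity_analysis,
    simulate_hq,
)


class TestFit:
    def test_normal_moments_recovered(self):
        rng = np.random.default_rng(7)
        x = rng.normal(730.0, 26.0, size=100_000)
        spec = fit_distribution(x, "normal")
        assert spec.loc == pytest.approx(730.0, abs=3 * 26.0 / math.sqrt(100_000))
        assert spec.scale == pytest.approx(26.0, rel=0.02)

    def test_lognormal_log_moments(self):
        rng = np.random.default_rng(8)
        x = rng.lognormal(1.5, 0.4, size=50_000)
        spec = fit_distribution(x, "lognormal")
        assert spec.loc == pytest.approx(1.5, abs=0.01)
        assert spec.scale == pytest.approx(0.4, rel=0.05)

    def test_degenerate_lognormal(self):
        spec = fit_distribution([3.0, 3.0, 3.0], "lognormal")
        assert spec.scale == 0.0
        assert sample(spec, 5, seed=0) == pytest.approx([3.0] * 5)

    def test_errors(self):
        with pytest.raises(ValidationError):
            fit_distribution([1.0], "normal")
        with pytest.raises(ValidationError):
            fit_distribution([1.0, -2.0], "lognormal")


class TestSample:
    def test_point_mass(self):
        assert sample(DistributionSpec("point", 5.0), 5, seed=1).tolist() == [5.0] * 5

    def test_seed_reproducibility(self):
        spec = DistributionSpec("normal", 0.0, 1.0, lower=0.0)
        a = sample(spec, 1000, seed=42)
        b = sample(spec, 1000, seed=42)
        assert np.array_equal(a, b)

    def test_truncated_normal_matches_half_normal_mean(self):
        # normal(0,1) truncated at 0 is half-normal with mean sqrt(2/pi)
        spec = DistributionSpec("normal", 0.0, 1.0, lower=0.0)
        x = sample(spec, 10_000, seed=3)
        assert np.all(x >= 0)
        se = math.sqrt(1 - 2 / math.pi) / math.sqrt(10_000)
        assert x.mean() == pytest.approx(math.sqrt(2 / math.pi), abs=3 * se)


class TestSimulateHq:
    def test_point_mass_collapses_to_deterministic(self):
        cfg = SimulationConfig(
            concentration={"MEL": DistributionSpec("point", 72.60 / 0.1)},
            fir=DistributionSpec("point", 0.1),
            n_iterations=10_000,
            seed=5,
        )
        res = simulate_hq(cfg, DEFAULT_SPECS)
        expected = 72.60 / 3150.0
        s = res.per_analyte["MEL"]
        assert s.degenerate
        for v in s.percentiles.values():
            assert v == expected
        assert s.p95 == expected
        assert s.sd == 0.0

    def test_lognormal_p95_matches_closed_form(self):
        # C ~ LogNormal(mu, sigma), FIR point f: P95(HQ) = exp(mu+1.6449 sigma) f / TDI
        mu, sigma, f = 5.0, 0.5, 2.0
        cfg = SimulationConfig(
            concentration={"MEL": DistributionSpec("lognormal", mu, sigma)},
            fir=DistributionSpec("point", f),
            n_iterations=10_000,
            seed=11,
        )
        res = simulate_hq(cfg, DEFAULT_SPECS)
        analytic = math.exp(mu + 1.6449 * sigma) * f / 3150.0
        se = percentile_bootstrap_se(res.hq_draws["MEL"], 95.0, seed=0)
        assert res.per_analyte["MEL"].p95 == pytest.approx(analytic, abs=3 * se)

    def test_bit_identical_reruns(self):
        cfg = SimulationConfig(
            concentration={
                "MEL": DistributionSpec("normal", 109.0, 26.0),
                "CYA": DistributionSpec("normal", 138.0, 38.0),
            },
            fir=DistributionSpec("lognormal", -0.7, 0.5),
            n_iterations=2_000,
            seed=77,
        )
        r1 = simulate_hq(cfg, DEFAULT_SPECS)
        r2 = simulate_hq(cfg, DEFAULT_SPECS)
        for a in r1.hq_draws:
            assert np.array_equal(r1.hq_draws[a], r2.hq_draws[a])
        assert r1.hi.percentiles == r2.hi.percentiles
        assert r1.per_analyte["MEL"].sensitivity == r2.per_analyte["MEL"].sensitivity

    def test_percentile_table_non_decreasing_and_exceedance_consistent(self):
        cfg = SimulationConfig(
            concentration={"MEL": DistributionSpec("lognormal", 8.0, 1.0)},
            fir=DistributionSpec("lognormal", 0.0, 0.5),
            n_iterations=4_000,
            seed=13,
        )
        res = simulate_hq(cfg, DEFAULT_SPECS)
        s = res.per_analyte["MEL"]
        ordered = [s.percentiles[p] for p in sorted(s.percentiles)]
        assert ordered == sorted(ordered)
        # exceedance prob consistent with where the draws cross 1
        assert s.exceedance_prob == pytest.approx(
            float(np.mean(res.hq_draws["MEL"] > 1.0))
        )

    def test_location_scaling_monotone(self):
        base = SimulationConfig(
            concentration={"MEL": DistributionSpec("lognormal", 3.0, 0.4)},
            fir=DistributionSpec("lognormal", 0.0, 0.3),
            n_iterations=4_000,
            seed=21,
        )
        k = 1.7  # scaling a lognormal's natural-scale location = +log k in log-space
        scaled = SimulationConfig(
            concentration={"MEL": DistributionSpec("lognormal", 3.0 + math.log(k), 0.4)},
            fir=DistributionSpec("lognormal", 0.0, 0.3),
            n_iterations=4_000,
            seed=21,
        )
        r0 = simulate_hq(base, DEFAULT_SPECS)
        r1 = simulate_hq(scaled, DEFAULT_SPECS)
        for p in r0.per_analyte["MEL"].percentiles:
            assert r1.per_analyte["MEL"].percentiles[p] == pytest.approx(
                k * r0.per_analyte["MEL"].percentiles[p]
            )

    def test_single_iteration_degenerate(self):
        cfg = SimulationConfig(
            concentration={"MEL": DistributionSpec("normal", 100.0, 10.0)},
            fir=DistributionSpec("point", 1.0),
            n_iterations=1,
            seed=1,
        )
        res = simulate_hq(cfg, DEFAULT_SPECS)
        s = res.per_analyte["MEL"]
        assert s.sd == 0.0 and s.degenerate
        assert len(set(s.percentiles.values())) == 1

    def test_missing_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(concentration={"MEL": DistributionSpec("point", 1.0)})
        cfg = SimulationConfig(
            concentration={"XX": DistributionSpec("point", 1.0)},
            fir=DistributionSpec("point", 1.0),
        )
        with pytest.raises(ConfigurationError):
            simulate_hq(cfg, DEFAULT_SPECS)

    def test_intake_bw_parameterization(self):
        # FIR = intake/bw per draw; with point masses HQ is exact
        cfg = SimulationConfig(
            concentration={"MEL": DistributionSpec("point", 100.0)},
            intake=DistributionSpec("point", 750.0),  # mL/day
            bw=DistributionSpec("point", 5.0),  # kg
            n_iterations=100,
            seed=2,
        )
        res = simulate_hq(cfg, DEFAULT_SPECS)
        assert res.per_analyte["MEL"].p95 == pytest.approx(100.0 * 150.0 / 3150.0)


class TestSensitivity:
    def test_identity_dependence_ranked_first(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        noise = rng.normal(size=500)
        ranked = sensitivity_analysis({"x": x, "noise": noise}, x)
        assert ranked[0].variable == "x"
        assert ranked[0].rank_correlation == pytest.approx(1.0)
        assert ranked[0].contribution > 0.9

    def test_higher_cv_input_dominates_product(self):
        # HQ = C*FIR/t with CV(C) = 4x CV(FIR): C must rank first
        rng = np.random.default_rng(1)
        c = rng.lognormal(0.0, 0.8, size=5_000)
        f = rng.lognormal(0.0, 0.2, size=5_000)
        out = c * f
        ranked = sensitivity_analysis({"c": c, "f": f}, out)
        assert ranked[0].variable == "c"
        assert ranked[0].contribution > ranked[1].contribution

    def test_symmetric_inputs_equal_contribution(self):
        rng = np.random.default_rng(2)
        a = rng.lognormal(0.0, 0.5, size=20_000)
        b = rng.lognormal(0.0, 0.5, size=20_000)
        ranked = sensitivity_analysis({"a": a, "b": b}, a * b)
        assert ranked[0].contribution == pytest.approx(0.5, abs=0.02)
        assert sum(e.contribution for e in ranked) <= 1.0 + 1e-9

    def test_constant_output_degenerate(self):
        ranked = sensitivity_analysis(
            {"x": np.arange(20.0)}, np.ones(20)
        )
        assert ranked[0].rank_correlation == 0.0
        assert ranked[0].contribution == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            sensitivity_analysis({"x": np.arange(5.0)}, np.arange(5.0))


class TestVerdict:
    def _result(self, p95):
        cfg = SimulationConfig(
            concentration={"MEL": DistributionSpec("point", p95 * 3150.0)},
            fir=DistributionSpec("point", 1.0),
            n_iterations=100,
            seed=0,
        )
        return simulate_hq(cfg, DEFAULT_SPECS)

    def test_below_threshold(self):
        v = risk_verdict(self._result(0.00561))
        assert v["classification"] == "below threshold"

    def test_potential_concern(self):
        assert risk_verdict(self._result(1.5))["classification"] == "potential concern"

    def test_boundary_is_concern(self):
        assert risk_verdict(self._result(1.0))["classification"] == "potential concern"
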