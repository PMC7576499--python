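"""Estimator chain: rate/slope fits, permeability formulas, Arrhenius,
strain comparison, pipeline aggregation."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nipflow.errors import (
    FitDegenerateError,
    InsufficientDesignError,
    InvalidComparisonError,
    InvalidParameterError,
    NoReswellingError,
)
from nipflow.kinetics import (
    ArrheniusResult,
    CellGeometry,
    PermeabilityEstimate,
    RateFit,
    ShockConditions,
    ShockTrace,
    SlopeFit,
    activation_energy,
    compare_strains,
    fit_reswelling_slope,
    fit_shrinkage_rate,
    glycerol_permeability,
    percent_reduction,
    run_kinetics_pipeline,
    scaled_trace,
    shrinkage_rate_constant,
    water_permeability,
)
from nipflow.synthetic_data import (
    default_simulation_params,
    simulate_arrhenius_series,
    simulate_shock,
)

from conftest import NIP11


def _trace_from_exponential(k, n=600, duration=None, shock_kind="water"):
    duration = duration or 8.0 / k
    t = np.linspace(0, duration, n)
    v_inf = 1.4 / 2.1
    v = v_inf + (1 - v_inf) * np.exp(-k * t)
    return ShockTrace(
        time=t, signal=v, temperature=23.0, shock_kind=shock_kind,
        conditions=ShockConditions(shock_solute="sorbitol"),
    )


class TestShrinkageRateFit:
    def test_noiseless_round_trip_is_exact(self):
        fit = fit_shrinkage_rate(_trace_from_exponential(2.0))
        assert fit.k == pytest.approx(2.0, rel=1e-6)
        assert fit.baseline == pytest.approx(1.4 / 2.1, rel=1e-6)

    def test_constant_trace_is_degenerate(self):
        trace = ShockTrace(
            time=np.linspace(0, 5, 100), signal=np.full(100, 0.8),
            temperature=23.0, shock_kind="water",
            conditions=ShockConditions(),
        )
        with pytest.raises(FitDegenerateError):
            fit_shrinkage_rate(trace)

    def test_noisy_monte_carlo_mean_within_two_percent(self, water_params):
        """Mean fitted k over 50 noisy replicates tracks the generating k."""
        params = replace(water_params, noise_sd=0.01)
        k_true = shrinkage_rate_constant(
            NIP11["pf_true"], params.geometry, params.conditions
        )
        ks = []
        for r in range(50):
            trace = simulate_shock(replace(params, seed=100 + r), 23.0)
            ks.append(fit_shrinkage_rate(trace).k)
        assert np.mean(ks) == pytest.approx(k_true, rel=0.02)

    def test_glycerol_trace_uses_only_shrinkage_phase(self, glycerol_params):
        trace = simulate_shock(glycerol_params, 23.0)
        fit = fit_shrinkage_rate(trace)
        k_true = shrinkage_rate_constant(
            NIP11["pf_true"], glycerol_params.geometry, glycerol_params.conditions
        )
        assert fit.k == pytest.approx(k_true, rel=1e-3)


class TestWaterPermeability:
    def test_zero_rate_gives_zero(self, geometry, water_conditions):
        est = water_permeability(
            RateFit(k=1e-300, amplitude=0.3, baseline=0.6, rmse=0.0),
            geometry, water_conditions,
        )
        assert est.value == pytest.approx(0.0, abs=1e-290)

    def test_formula_at_documented_defaults(self, geometry, water_conditions):
        """k=0.309/s, V0/A=8.3e-5 cm, Vw=18.07, 2.1 osmol/L -> ~6.8e-4 cm/s."""
        fit = RateFit(k=0.309, amplitude=0.3, baseline=0.6, rmse=0.0)
        est = water_permeability(fit, geometry, water_conditions)
        expected = 0.309 * 8.3e-5 / (18.07 * 2.1e-3)
        assert est.value == pytest.approx(expected, rel=1e-12)
        assert est.value == pytest.approx(6.8e-4, rel=0.01)

    def test_linear_in_geometry(self, geometry, water_conditions):
        fit = RateFit(k=0.3, amplitude=0.3, baseline=0.6, rmse=0.0)
        base = water_permeability(fit, geometry, water_conditions).value
        doubled = water_permeability(
            fit, CellGeometry(v0_over_a=2 * geometry.v0_over_a),
            water_conditions,
        ).value
        assert doubled == pytest.approx(2 * base, rel=1e-12)


class TestReswellingSlope:
    def test_noiseless_round_trip_is_exact(self, geometry):
        """Generator slope m = Pgly * (A/V0) is recovered to 1e-6 relative."""
        pgly = 5e-4 * geometry.v0_over_a  # makes m exactly 5e-4 / s
        params = default_simulation_params(
            pf_true=NIP11["pf_true"], pgly_true=pgly,
            ea_water=9.8, ea_glycerol=6.9, shock_solute="glycerol",
        )
        trace = simulate_shock(params, 23.0)
        fit = fit_reswelling_slope(trace)
        assert fit.m == pytest.approx(5e-4, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_water_only_trace_has_no_reswelling(self, water_params):
        trace = simulate_shock(water_params, 23.0)
        trace = replace_kind(trace)
        with pytest.raises(NoReswellingError):
            fit_reswelling_slope(trace)

    def test_flat_recovery_rejected_with_noise(self, glycerol_params):
        """pgly=0 plus noise: plateau must not masquerade as re-swelling."""
        params = replace(glycerol_params, pgly_true=0.0, noise_sd=0.01)
        for seed in range(5):
            trace = simulate_shock(replace(params, seed=seed), 23.0)
            with pytest.raises(NoReswellingError):
                fit_reswelling_slope(trace)

    def test_noisy_monte_carlo_mean_within_five_percent(self, glycerol_params):
        params = replace(glycerol_params, noise_sd=0.01)
        m_true = NIP11["pgly_true"] / params.geometry.v0_over_a
        ms = []
        for r in range(50):
            trace = simulate_shock(replace(params, seed=500 + r), 23.0)
            ms.append(fit_reswelling_slope(trace).m)
        assert np.mean(ms) == pytest.approx(m_true, rel=0.05)


def replace_kind(trace):
    """Clone a water-shock trace labelled as glycerol (no recovery phase)."""
    return ShockTrace(
        time=trace.time, signal=trace.signal, temperature=trace.temperature,
        shock_kind="glycerol",
        conditions=replace(trace.conditions, shock_solute="glycerol"),
        signal_baseline=trace.signal_baseline, signal_span=trace.signal_span,
    )


class TestGlycerolPermeability:
    def test_zero_slope_gives_zero(self, geometry):
        fit = SlopeFit(m=0.0, window=(10, 100), r2=1.0)
        assert glycerol_permeability(fit, geometry).value == 0.0

    def test_formula_direct_evaluation(self, geometry):
        fit = SlopeFit(m=5e-4, window=(10, 100), r2=1.0)
        est = glycerol_permeability(fit, geometry)
        assert est.value == pytest.approx(4.15e-8, rel=1e-10)

    def test_negative_slope_flagged_not_raised(self, geometry):
        fit = SlopeFit(m=-1e-4, window=(10, 100), r2=0.9)
        est = glycerol_permeability(fit, geometry)
        assert "reverse_flux" in est.flags
        assert est.value < 0

    def test_exponential_mode_inverse_pair(self, glycerol_params):
        """simulate -> estimate recovers any Pgly exactly at zero noise."""
        trace = simulate_shock(glycerol_params, 23.0)
        fit = fit_reswelling_slope(trace)
        est = glycerol_permeability(fit, glycerol_params.geometry)
        assert est.value == pytest.approx(NIP11["pgly_true"], rel=1e-6)


class TestActivationEnergy:
    @staticmethod
    def _exact_points(ea, p_ref=24.5e-8, t_ref=23.0, kind="Pgly"):
        from nipflow.constants import arrhenius_factor

        return [
            (
                float(t),
                PermeabilityEstimate(
                    kind=kind, value=p_ref * arrhenius_factor(ea, t, t_ref),
                    temperature=float(t),
                ),
            )
            for t in (10, 15, 20, 25, 30, 35)
        ]

    def test_exact_arrhenius_input_recovered(self):
        result = activation_energy(self._exact_points(6.93))
        assert result.ea == pytest.approx(6.93, rel=1e-6)
        assert result.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_permeability_gives_zero(self):
        result = activation_energy(self._exact_points(0.0))
        assert result.ea == pytest.approx(0.0, abs=1e-12)

    def test_prefactor_back_substitution(self):
        """The fitted line reproduces P at the reference temperature."""
        result = activation_energy(self._exact_points(6.93))
        assert result.permeability_at(23.0) == pytest.approx(24.5e-8, rel=1e-6)

    def test_closed_form_ols_agreement(self):
        """Slope matches an independent closed-form OLS computation."""
        from nipflow.constants import R_KCAL, celsius_to_kelvin

        pts = self._exact_points(8.60, p_ref=12.8e-8)
        x = np.array([1 / celsius_to_kelvin(t) for t, _ in pts])
        y = np.array([math.log(e.value) for _, e in pts])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        result = activation_energy(pts)
        assert result.ea == pytest.approx(-slope * R_KCAL, rel=1e-12)

    def test_input_validation(self):
        pts = self._exact_points(6.93)
        with pytest.raises(InsufficientDesignError):
            activation_energy(pts[:2])
        bad = pts[:2] + [
            (30.0, PermeabilityEstimate(kind="Pgly", value=0.0, flags=()))
        ]
        with pytest.raises(InvalidParameterError):
            activation_energy(bad)


class TestPercentReduction:
    @pytest.mark.parametrize(
        "native,mutant,expected",
        [
            (24.5, 3.58, 85.4),  # double mutant, reported as ~85%
            (12.8, 2.57, 79.9),  # single mutant, reported bound ~79%
            (24.5, 7.84, 68.0),  # single mutant, reported as ~68%
        ],
    )
    def test_printed_permeability_pairs(self, native, mutant, expected):
        a = PermeabilityEstimate(kind="Pgly", value=native * 1e-8)
        b = PermeabilityEstimate(kind="Pgly", value=mutant * 1e-8)
        assert percent_reduction(a, b) == pytest.approx(expected, abs=0.05)

    def test_identity_gives_zero(self):
        est = PermeabilityEstimate(kind="Pf", value=6.78e-4)
        assert percent_reduction(est, est) == 0.0

    def test_mismatched_kinds_rejected(self):
        a = PermeabilityEstimate(kind="Pf", value=6.78e-4)
        b = PermeabilityEstimate(kind="Pgly", value=24.5e-8)
        with pytest.raises(InvalidComparisonError):
            percent_reduction(a, b)


class TestCompareStrains:
    def test_identical_groups_not_significant(self):
        res = compare_strains([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.significance_label == "ns"

    def test_large_shift_highly_significant(self):
        res = compare_strains([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p_value < 0.001
        assert res.significance_label == "***"

    def test_welch_p_value_matches_permutation_oracle(self):
        """Welch p agrees with an exhaustive permutation test at small n."""
        rng = np.random.default_rng(7)
        a = [3.1, 2.4, 2.9, 3.6]
        b = [4.0, 4.4, 3.8, 4.9]
        res = compare_strains(a, b)
        # exhaustive two-sample permutation distribution of the t statistic
        perm = stats.permutation_test(
            (a, b),
            lambda x, y, axis=None: stats.ttest_ind(
                x, y, axis=axis, equal_var=False
            ).statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        assert res.p_value == pytest.approx(perm.pvalue, abs=0.05)

    def test_zero_variance_equal_means(self):
        res = compare_strains([2.0] * 3, [2.0] * 3)
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestScaleEquivariance:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 10.0))
    def test_signal_scale_leaves_estimates_unchanged(self, c):
        """Multiplying the signal by c>0 changes neither k nor m."""
        params = default_simulation_params(
            **NIP11, shock_solute="glycerol", noise_sd=0.0, n_samples=400
        )
        trace = simulate_shock(params, 23.0)
        scaled = scaled_trace(trace, c)
        m0 = fit_reswelling_slope(trace).m
        m1 = fit_reswelling_slope(scaled).m
        assert m1 == pytest.approx(m0, rel=1e-9)
        k0 = fit_shrinkage_rate(trace).k
        k1 = fit_shrinkage_rate(scaled).k
        assert k1 == pytest.approx(k0, rel=1e-6)


class TestOdeModeRecovery:
    def test_water_permeability_within_ten_percent(self):
        """Mechanistic-mode Pf estimate carries only the documented
        exponential-approximation bias (<10%) at the 1.4->2.1 shock."""
        params = default_simulation_params(**NIP11, shock_solute="sorbitol",
                                           mode="ode")
        trace = simulate_shock(params, 23.0)
        est = water_permeability(
            fit_shrinkage_rate(trace), params.geometry, params.conditions
        )
        assert est.value == pytest.approx(NIP11["pf_true"], rel=0.10)


@pytest.fixture(scope="module")
def cohort():
    traces = []
    for name, pgly in (("nativelike", NIP11["pgly_true"]), ("waterless", 0.0)):
        for solute in ("sorbitol", "glycerol"):
            params = default_simulation_params(
                pf_true=NIP11["pf_true"], pgly_true=pgly,
                ea_water=NIP11["ea_water"], ea_glycerol=NIP11["ea_glycerol"],
                shock_solute=solute, noise_sd=0.01,
                seed=11 if name == "nativelike" else 17,
                strain=name, n_samples=800,
            )
            traces.extend(
                simulate_arrhenius_series(
                    params, [10, 15, 20, 23, 25, 30, 35], 3
                )
            )
    return traces


class TestKineticsPipeline:
    def test_report_is_deterministic(self, cohort):
        r1 = run_kinetics_pipeline(cohort)
        r2 = run_kinetics_pipeline(cohort)
        assert r1 == r2

    def test_recovers_generating_activation_energy(self, cohort):
        report = run_kinetics_pipeline(cohort)
        block = report["strains"]["nativelike"]
        assert block["water"]["activation_energy"]["ea"] == pytest.approx(
            NIP11["ea_water"], rel=0.05
        )
        assert block["glycerol"]["activation_energy"]["ea"] == pytest.approx(
            NIP11["ea_glycerol"], rel=0.05
        )
        assert block["water"]["permeability"]["value"] == pytest.approx(
            NIP11["pf_true"], rel=0.05
        )

    def test_zero_pgly_strain_reports_no_reswelling(self, cohort):
        report = run_kinetics_pipeline(cohort)
        gly = report["strains"]["waterless"]["glycerol"]
        assert gly["no_reswelling_traces"] == 21  # 7 temperatures x 3 reps
        assert gly["by_temperature"] == {}

    def test_comparison_separates_the_strains(self, cohort):
        report = run_kinetics_pipeline(cohort)
        cmp_ = report["comparisons"]["nativelike|waterless|water"]
        assert cmp_["label"] in ("ns", "**", "***")
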