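"""Voltage-clamp generator self-consistency and fitter recovery."""

import numpy as np
import pytest

from lysoquant.ephys import (
    GatingParams,
    InhibitionModel,
    VoltageProtocol,
    family_metrics,
    fit_dose_response,
    fit_exponential,
    inhibition_ratio,
    simulate_family,
)

GATING = GatingParams()
INHIB = InhibitionModel()
FAST = VoltageProtocol(step_voltages=(80.0, 140.0), pre_s=0.05, pulse_s=2.0,
                       tail_s=0.4, dt=0.001)


def analytic_pulse_end(g: GatingParams, v: float, s: float = 1.0,
                       pulse_s: float = 2.0) -> float:
    act = g.i_inst_frac + (1 - g.i_inst_frac) * (1 - np.exp(-pulse_s / g.tau_act(v)))
    return s * g.g_max * g.p_inf(v) * (v - g.v_rev) * act


class TestSimulate:
    def test_no_lipid_families_identical_over_time(self):
        early = simulate_family(GATING, INHIB, 0.0, 30.0, FAST)
        late = simulate_family(GATING, INHIB, 0.0, 180.0, FAST)
        np.testing.assert_array_equal(early.sweeps, late.sweeps)

    def test_full_inhibition_limit(self):
        full = InhibitionModel(f_ceiling=1.0, f_ceiling_tail=1.0)
        fam = simulate_family(GATING, full, 1e9, 1e9, FAST)
        assert np.max(np.abs(fam.sweeps)) < 1e-6

    def test_hill_midpoint_scales_pulse_current(self):
        inh = InhibitionModel(f_ceiling=0.8, f_ceiling_tail=0.8, ec50_um=30.0)
        t = 1e6  # >> tau_wash: steady state
        ref = simulate_family(GATING, inh, 0.0, t, FAST)
        mid = simulate_family(GATING, inh, 30.0, t, FAST)
        p = FAST
        sl = slice(p.n_pre, p.n_pre + p.n_pulse)
        np.testing.assert_allclose(mid.sweeps[:, sl],
                                   (1 - 0.8 / 2) * ref.sweeps[:, sl], rtol=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_family(GATING, INHIB, -1.0, 30.0, FAST)
        with pytest.raises(ValueError):
            simulate_family(GATING, INHIB, 0.0, -1.0, FAST)

    def test_noise_deterministic_per_seed(self):
        a = simulate_family(GATING, INHIB, 50.0, 30.0, FAST, noise_sd_pa=5.0, seed=3)
        b = simulate_family(GATING, INHIB, 50.0, 30.0, FAST, noise_sd_pa=5.0, seed=3)
        c = simulate_family(GATING, INHIB, 50.0, 30.0, FAST, noise_sd_pa=5.0, seed=4)
        np.testing.assert_array_equal(a.sweeps, b.sweeps)
        assert (a.sweeps != c.sweeps).any()


class TestFitExponential:
    def test_noiseless_decay_exact(self):
        t = np.arange(0, 0.25, 0.001)
        y = 10.0 + 100.0 * np.exp(-t / 0.05)
        fit = fit_exponential(t, y, kind="decay")
        assert fit.converged
        assert fit.amplitude == pytest.approx(100.0, abs=1e-6)
        assert fit.tau == pytest.approx(0.05, abs=1e-6)
        assert fit.offset == pytest.approx(10.0, abs=1e-6)

    def test_noiseless_activation_exact(self):
        t = np.arange(0, 1.0, 0.002)
        y = -5.0 + 250.0 * (1 - np.exp(-t / 0.2))
        fit = fit_exponential(t, y, kind="activation")
        assert fit.converged
        assert fit.amplitude == pytest.approx(250.0, abs=1e-6)
        assert fit.tau == pytest.approx(0.2, abs=1e-6)

    def test_tau_recovered_at_snr_20(self):
        t = np.arange(0, 0.25, 0.001)
        clean = 10.0 + 100.0 * np.exp(-t / 0.05)
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = fit_exponential(t, clean + rng.normal(0, 5.0, t.size), "decay")
            assert fit.converged
            errors.append(abs(fit.tau - 0.05) / 0.05)
        assert np.median(errors) < 0.02

    def test_constant_trace_not_converged(self):
        t = np.arange(0, 0.1, 0.001)
        fit = fit_exponential(t, np.full(t.size, 42.0), kind="decay")
        assert not fit.converged

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_exponential(np.arange(5), np.arange(5.0), "decay")
        with pytest.raises(ValueError):
            fit_exponential(np.zeros(30), np.arange(30.0), "decay")


class TestFamilyMetrics:
    def test_noiseless_i_max_matches_closed_form(self):
        fam = simulate_family(GATING, INHIB, 0.0, 30.0, FAST)
        m = family_metrics(fam, v_ref=140.0)
        assert m.i_max_pa == pytest.approx(analytic_pulse_end(GATING, 140.0),
                                           rel=0.005)
        assert m.tau_act_s == pytest.approx(GATING.tau_act(140.0), rel=1e-6)
        assert m.tau_deact_s == pytest.approx(GATING.tau_deact, rel=1e-6)

    def test_no_slow_gating_flags_fit(self):
        g = GatingParams(i_inst_frac=1.0)
        fam = simulate_family(g, INHIB, 0.0, 30.0, FAST)
        m = family_metrics(fam, v_ref=140.0)
        assert (not m.activation_fit.converged) or abs(m.activation_fit.amplitude) < 1e-6

    def test_linearity_in_conductance(self):
        m1 = family_metrics(simulate_family(GATING, INHIB, 0.0, 30.0, FAST), 140.0)
        g2 = GatingParams(g_max=2 * GATING.g_max)
        m2 = family_metrics(simulate_family(g2, INHIB, 0.0, 30.0, FAST), 140.0)
        assert m2.i_max_pa == pytest.approx(2 * m1.i_max_pa, rel=1e-9)
        assert m2.i_tail_pa == pytest.approx(2 * m1.i_tail_pa, rel=1e-6)
        assert m2.tau_act_s == pytest.approx(m1.tau_act_s, rel=1e-6)

    def test_missing_reference_voltage_errors(self):
        fam = simulate_family(GATING, INHIB, 0.0, 30.0, FAST)
        with pytest.raises(ValueError, match="not in protocol"):
            family_metrics(fam, v_ref=60.0)


class TestInhibitionRatio:
    def test_stability_control_unity(self):
        early = simulate_family(GATING, INHIB, 0.0, 30.0, FAST)
        late = simulate_family(GATING, INHIB, 0.0, 180.0, FAST)
        max_ratio, tail_ratio = inhibition_ratio(late, early, 140.0)
        assert max_ratio == pytest.approx(1.0, abs=1e-9)
        assert tail_ratio == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("conc", [25.0, 50.0, 100.0])
    def test_noiseless_ratio_equals_analytic_scale_ratio(self, conc):
        early = simulate_family(GATING, INHIB, conc, 30.0, FAST)
        late = simulate_family(GATING, INHIB, conc, 180.0, FAST)
        max_ratio, tail_ratio = inhibition_ratio(late, early, 140.0)
        assert max_ratio == pytest.approx(
            INHIB.scale(conc, 180.0) / INHIB.scale(conc, 30.0), abs=1e-9)
        assert tail_ratio == pytest.approx(
            INHIB.scale_tail(conc, 180.0) / INHIB.scale_tail(conc, 30.0), abs=1e-9)

    def test_default_conditions_reproduce_observed_inhibition(self):
        """At 100 uM the generator's own 3min/30s ratios sit near 0.61 (max)
        and 0.34 (tail) — i.e. ~39% and ~66% current decreases — and survive
        measurement noise at 5% of i_max (50 cells)."""
        i_max0 = analytic_pulse_end(GATING, 140.0)
        noise_sd = 0.05 * i_max0
        max_ratios, tail_ratios = [], []
        for seed in range(50):
            early = simulate_family(GATING, INHIB, 100.0, 30.0, FAST,
                                    noise_sd_pa=noise_sd, seed=2 * seed)
            late = simulate_family(GATING, INHIB, 100.0, 180.0, FAST,
                                   noise_sd_pa=noise_sd, seed=2 * seed + 1)
            mr, tr = inhibition_ratio(late, early, 140.0)
            max_ratios.append(mr)
            tail_ratios.append(tr)
        assert np.mean(max_ratios) == pytest.approx(0.61, abs=0.05)
        assert np.mean(tail_ratios) == pytest.approx(0.34, abs=0.05)

    def test_mutant_like_no_inhibition(self):
        """A transporter insensitive to the lipid (inhibition ceiling 0)
        behaves exactly like the no-lipid control."""
        insensitive = InhibitionModel(f_ceiling=0.0, f_ceiling_tail=0.0)
        early = simulate_family(GATING, insensitive, 100.0, 30.0, FAST)
        late = simulate_family(GATING, insensitive, 100.0, 180.0, FAST)
        max_ratio, tail_ratio = inhibition_ratio(late, early, 140.0)
        assert max_ratio == pytest.approx(1.0, abs=1e-9)
        assert tail_ratio == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_concentration_and_time(self):
        i_max = lambda conc, t: family_metrics(
            simulate_family(GATING, INHIB, conc, t, FAST), 140.0).i_max_pa
        by_conc = [i_max(c, 120.0) for c in (0.0, 10.0, 30.0, 100.0)]
        assert np.all(np.diff(by_conc) < 0)
        by_time = [i_max(50.0, t) for t in (0.0, 30.0, 120.0, 600.0)]
        assert np.all(np.diff(by_time) < 0)

    def test_ordering_validation(self):
        early = simulate_family(GATING, INHIB, 0.0, 30.0, FAST)
        late = simulate_family(GATING, INHIB, 0.0, 180.0, FAST)
        with pytest.raises(ValueError):
            inhibition_ratio(early, late, 140.0)


class TestDoseResponse:
    TRUTH = dict(ec50=30.0, hill_n=1.5, floor=0.0, ceiling=0.7)

    @staticmethod
    def response(c, ec50=30.0, hill_n=1.5, floor=0.0, ceiling=0.7):
        c = np.asarray(c, dtype=float)
        return floor + (ceiling - floor) * c**hill_n / (c**hill_n + ec50**hill_n)

    def test_noiseless_recovery_exact(self):
        c = np.array([5.0, 10.0, 25.0, 50.0, 100.0, 200.0])
        fit = fit_dose_response(c, self.response(c))
        assert fit.ec50 == pytest.approx(30.0, abs=1e-4)
        assert fit.hill_n == pytest.approx(1.5, abs=1e-4)
        assert fit.floor == pytest.approx(0.0, abs=1e-4)
        assert fit.ceiling == pytest.approx(0.7, abs=1e-4)

    def test_fitted_curve_midpoint_identity(self):
        c = np.array([5.0, 10.0, 25.0, 50.0, 100.0, 200.0])
        fit = fit_dose_response(c, self.response(c))
        assert fit.predict(fit.ec50) == pytest.approx((fit.floor + fit.ceiling) / 2)

    def test_ec50_recovered_near_information_limit(self):
        """With one noisy point per concentration the Cramer-Rao bound for
        this 6-point design puts the median relative EC50 error near 11%;
        the fit should sit at that floor, not above it."""
        c = np.array([5.0, 10.0, 25.0, 50.0, 100.0, 200.0])
        clean = self.response(c)
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = fit_dose_response(c, clean + rng.normal(0, 0.03, c.size))
            errors.append(abs(fit.ec50 - 30.0) / 30.0)
        assert np.median(errors) < 0.15

    def test_ec50_recovered_with_replicates(self):
        c = np.repeat([5.0, 10.0, 25.0, 50.0, 100.0, 200.0], 5)
        clean = self.response(c)
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = fit_dose_response(c, clean + rng.normal(0, 0.03, c.size))
            errors.append(abs(fit.ec50 - 30.0) / 30.0)
        assert np.median(errors) < 0.10

    def test_non_bracketing_design_errors(self):
        c = np.array([100.0, 200.0, 400.0, 800.0])  # all above the midpoint
        with pytest.raises(ValueError, match="bracketing"):
            fit_dose_response(c, self.response(c))

    def test_too_few_concentrations(self):
        c = np.array([10.0, 30.0, 90.0])
        with pytest.raises(ValueError, match="distinct"):
            fit_dose_response(c, self.response(c))
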