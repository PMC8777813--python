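"""Shell-model bubble dynamics: closed-form oracles, fixed points,
backend cross-checks and sweep/weighting behaviour."""

import numpy as np
import pandas as pd
import pytest

from sonobubble.agents import AGENTS, MOUSE_BLOOD, Medium, ShellParameters
from sonobubble.bubble import (BubbleModel, RadiusTrajectory, SweepResult,
                               damping_coefficient, equilibrium_gas_pressure,
                               natural_frequency, oscillation_amplitude,
                               radiated_pressure, weight_sweep)
from sonobubble.pulses import synthesize_tone_burst
from sonobubble.sizing import SizeSummary


class TestEquilibriumPressure:
    def test_hand_arithmetic(self):
        shell = ShellParameters("x", chi=0.0, gamma=1.1, sigma=0.052)
        med = Medium(p0=101325.0, pv=6267.0)
        assert equilibrium_gas_pressure(1e-6, shell, med) == pytest.approx(199058.0)

    def test_laplace_term_vanishes(self):
        shell = ShellParameters("x", chi=0.0, gamma=1.1, sigma=0.0)
        med = Medium(p0=101325.0, pv=1e-30)
        assert equilibrium_gas_pressure(1e-6, shell, med) == pytest.approx(101325.0)

    def test_large_bubble_asymptote(self):
        shell = ShellParameters("x", chi=0.0, gamma=1.1, sigma=0.05)
        med = MOUSE_BLOOD
        assert equilibrium_gas_pressure(1.0, shell, med) == \
            pytest.approx(med.p0 - med.pv, rel=1e-4)

    def test_unphysical_rejected(self):
        shell = ShellParameters("x", chi=0.0, gamma=1.1, sigma=0.05)
        with pytest.raises(ValueError, match="unphysical"):
            equilibrium_gas_pressure(1e-6, shell, Medium(p0=1.0, pv=200000.0))


class TestDamping:
    def test_closed_form_sum(self):
        med = MOUSE_BLOOD
        omega = 2 * np.pi * 1.8e6
        expected = 4 * med.mu / (med.rho * omega * 1e-12) + omega * 1e-6 / med.c
        val = damping_coefficient(omega, 1e-6, med)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(2.01, abs=0.01)

    def test_scaling_law(self):
        med = MOUSE_BLOOD
        omega = 2 * np.pi * 1e6
        visc = lambda r0: 4 * med.mu / (med.rho * omega * r0 ** 2)
        rad = lambda r0: omega * r0 / med.c
        d1 = damping_coefficient(omega, 1e-6, med)
        d2 = damping_coefficient(omega, 2e-6, med)
        assert d2 == pytest.approx(visc(1e-6) / 4 + rad(1e-6) * 2, rel=1e-12)
        assert d1 == pytest.approx(visc(1e-6) + rad(1e-6), rel=1e-12)


class TestNaturalFrequency:
    def test_matches_symbolic_linearization(self):
        """Independent oracle: differentiate the RHS symbolically and
        compare omega0 = sqrt(-f'(R0)) with the closed form."""
        sympy = pytest.importorskip("sympy")
        R, R0, rho, pg, pv, p0, sigma, chi, gamma = sympy.symbols(
            "R R0 rho pg pv p0 sigma chi gamma", positive=True)
        bracket = (pg * (R0 / R) ** (3 * gamma) + pv - p0 - 2 * sigma / R
                   - 2 * chi * (1 / R0 - 1 / R))
        f = bracket / (rho * R)
        eq = {pg: p0 + 2 * sigma / R0 - pv}
        fprime = sympy.diff(f, R).subs(R, R0).subs(eq)
        for name, shell in AGENTS.items():
            for r0 in (1e-6, 2e-6, 5e-6):
                subs = {R0: r0, rho: MOUSE_BLOOD.rho, p0: MOUSE_BLOOD.p0,
                        pv: MOUSE_BLOOD.pv, sigma: shell.sigma,
                        chi: shell.chi, gamma: shell.gamma}
                w0_sym = float(sympy.sqrt(-fprime.subs(subs)))
                f0_sym = w0_sym / (2 * np.pi)
                assert natural_frequency(r0, shell, MOUSE_BLOOD) == \
                    pytest.approx(f0_sym, rel=1e-10), name


class TestSimulation:
    @pytest.mark.parametrize("agent", list(AGENTS))
    @pytest.mark.parametrize("r0_um", [0.5, 1.0, 2.0, 5.0])
    def test_fixed_point_without_forcing(self, agent, r0_um, zero_pulse):
        model = BubbleModel(AGENTS[agent], MOUSE_BLOOD, zero_pulse)
        traj = model.simulate(r0_um * 1e-6)
        assert not traj.collapsed
        assert np.abs(traj.R - r0_um * 1e-6).max() / (r0_um * 1e-6) < 1e-6

    def test_backends_agree(self, treatment_pulse):
        r0 = 2e-6
        a = BubbleModel(AGENTS["SonoVue"], MOUSE_BLOOD, treatment_pulse,
                        backend="numba").simulate(r0)
        b = BubbleModel(AGENTS["SonoVue"], MOUSE_BLOOD, treatment_pulse,
                        backend="scipy").simulate(r0)
        assert oscillation_amplitude(a)[1] == \
            pytest.approx(oscillation_amplitude(b)[1], abs=0.05)

    def test_collapse_flagged_not_silent(self):
        pulse = synthesize_tone_burst(1.8e6, 10e-6, 3e6, "rectangular", 100e6)
        model = BubbleModel(AGENTS["SonoVue"], MOUSE_BLOOD, pulse)
        traj = model.simulate(2e-6)
        assert traj.collapsed
        assert traj.R.min() <= 0.011 * 2e-6

    def test_amplitude_monotone_in_pnp_low_drive(self, agents):
        for shell in agents.values():
            last = -1.0
            for pnp in (1e3, 5e3, 20e3, 50e3):
                pulse = synthesize_tone_burst(1.8e6, 10e-6, pnp,
                                              "rectangular", 60e6)
                traj = BubbleModel(shell, MOUSE_BLOOD, pulse).simulate(2e-6)
                pct = oscillation_amplitude(traj)[1]
                assert pct > last, shell.name
                last = pct

    def test_grid_convergence_at_treatment_amplitude(self, treatment_pulse):
        r0 = 2e-6
        coarse = BubbleModel(AGENTS["SonoVue"], MOUSE_BLOOD, treatment_pulse,
                             rtol=1e-8).simulate(r0)
        fine = BubbleModel(AGENTS["SonoVue"], MOUSE_BLOOD, treatment_pulse,
                           rtol=5e-9).simulate(r0)
        assert oscillation_amplitude(coarse)[1] == \
            pytest.approx(oscillation_amplitude(fine)[1], abs=0.1)

    def test_r0_out_of_range_rejected(self, zero_pulse):
        model = BubbleModel(AGENTS["SonoVue"], MOUSE_BLOOD, zero_pulse)
        with pytest.raises(ValueError, match="range"):
            model.simulate(60e-6)


class TestOscillationAmplitude:
    def test_constant_radius_zero(self):
        t = np.linspace(0, 1e-5, 100)
        traj = RadiusTrajectory(t=t, R=np.full_like(t, 2e-6),
                                Rdot=np.zeros_like(t), R0=2e-6)
        assert oscillation_amplitude(traj) == (0.0, 0.0)

    def test_sinusoidal_closed_form(self):
        # R = R0 (1 + eps sin wt): diameter excursion Dmax - Dmin = 4 eps R0,
        # i.e. 2 eps of the equilibrium diameter -> 20% for eps = 0.1
        t = np.linspace(0, 1e-5, 4001)
        R0, eps, om = 2e-6, 0.1, 2 * np.pi * 1e6
        R = R0 * (1 + eps * np.sin(om * t))
        traj = RadiusTrajectory(t=t, R=R, Rdot=R0 * eps * om * np.cos(om * t),
                                R0=R0)
        a, pct = oscillation_amplitude(traj)
        assert a == pytest.approx(4 * eps * R0, rel=1e-3)
        assert pct == pytest.approx(2 * eps * 100, rel=1e-3)


class TestRadiatedPressure:
    def _prescribed(self, eps=1e-4):
        R0, om = 2e-6, 2 * np.pi * 1e6
        t = np.linspace(0, 4e-6, 2001)
        R = R0 * (1 + eps * np.sin(om * t))
        traj = RadiusTrajectory(
            t=t, R=R, Rdot=R0 * eps * om * np.cos(om * t), R0=R0,
            Rddot=-R0 * eps * om ** 2 * np.sin(om * t))
        return traj, R0, om, eps, t

    def test_static_bubble_radiates_nothing(self):
        t = np.linspace(0, 1e-5, 50)
        traj = RadiusTrajectory(t=t, R=np.full_like(t, 1e-6),
                                Rdot=np.zeros_like(t), R0=1e-6,
                                Rddot=np.zeros_like(t))
        p, (pnp, ppp) = radiated_pressure(traj, 7e-6)
        assert np.all(p == 0.0) and pnp == 0.0 and ppp == 0.0

    def test_small_amplitude_analytic_oracle(self):
        traj, R0, om, eps, t = self._prescribed()
        r = 7e-6
        rho = Medium().rho
        p, _ = radiated_pressure(traj, r)
        expected = -rho * R0 ** 3 * eps * om ** 2 * np.sin(om * t) / r
        assert np.allclose(p, expected, atol=10 * eps * np.abs(expected).max())

    def test_one_over_r_law_exact(self):
        traj = self._prescribed(eps=0.05)[0]
        p1, (pnp1, _) = radiated_pressure(traj, 7e-6)
        p2, (pnp2, _) = radiated_pressure(traj, 14e-6)
        np.testing.assert_allclose(p1, 2 * p2, rtol=1e-14)
        assert pnp1 == pytest.approx(2 * pnp2, rel=1e-14)

    def test_rejects_point_inside_bubble(self):
        traj = self._prescribed(eps=0.05)[0]
        with pytest.raises(ValueError, match="inside"):
            radiated_pressure(traj, 1e-6)


def _summary_from_bins(centers_um, percents):
    """Minimal SizeSummary carrying just a count histogram."""
    hist = pd.DataFrame({"bin_center_um": centers_um, "percent": percents})
    return SizeSummary(count_hist=hist, volume_hist=hist, percentiles={},
                       geometric_mean_um=0, mean_um=0, sem_um=0,
                       mean_roundness=1, concentration_per_ml=0,
                       n_particles=1, diameters_um=np.array([1.0]),
                       roundness=np.array([1.0]))


class TestSweepAndWeighting:
    def test_default_grid_has_194_points(self, zero_pulse):
        model = BubbleModel(AGENTS["SonoVue"], MOUSE_BLOOD, zero_pulse)
        sweep = model.sweep()
        assert sweep.r0_grid.size == 194
        assert np.all(sweep.osc_amp_pct[~sweep.collapsed] == 0.0)
        assert not sweep.collapsed.any()

    def test_weight_constant_metric_auc_is_constant(self):
        grid = np.linspace(0.5e-6, 5e-6, 10)
        sweep = SweepResult(r0_grid=grid, osc_amp_abs=np.zeros(10),
                            osc_amp_pct=np.full(10, 7.5),
                            pnp_at_7um=np.zeros(10), ppp_at_7um=np.zeros(10),
                            collapsed=np.zeros(10, bool))
        dist = _summary_from_bins([2.0, 4.0, 6.0], [20.0, 30.0, 50.0])
        for norm in ("count", "volume"):
            assert weight_sweep(sweep, dist, norm).auc == pytest.approx(7.5)

    def test_point_mass_and_two_bin_hand_arithmetic(self):
        grid = np.array([0.5e-6, 1.0e-6, 1.5e-6])
        sweep = SweepResult(r0_grid=grid, osc_amp_abs=np.zeros(3),
                            osc_amp_pct=np.array([1.0, 2.0, 3.0]),
                            pnp_at_7um=np.zeros(3), ppp_at_7um=np.zeros(3),
                            collapsed=np.zeros(3, bool))
        point = _summary_from_bins([2.0], [100.0])     # d=2 um -> R0=1 um
        assert weight_sweep(sweep, point).auc == pytest.approx(2.0)
        two = _summary_from_bins([1.0, 2.0], [25.0, 75.0])  # metrics 1 and 2
        assert weight_sweep(sweep, two).auc == pytest.approx(1.75)

    def test_mass_outside_grid_rejected(self):
        grid = np.array([0.5e-6, 1.0e-6])
        sweep = SweepResult(r0_grid=grid, osc_amp_abs=np.zeros(2),
                            osc_amp_pct=np.ones(2), pnp_at_7um=np.zeros(2),
                            ppp_at_7um=np.zeros(2), collapsed=np.zeros(2, bool))
        bad = _summary_from_bins([2.0, 10.0], [90.0, 10.0])  # 10% at R0=5 um
        with pytest.raises(ValueError, match="outside"):
            weight_sweep(sweep, bad)

    def test_sweep_saves_text_outputs(self, tmp_path, zero_pulse):
        model = BubbleModel(AGENTS["SonoVue"], MOUSE_BLOOD, zero_pulse)
        sweep = model.sweep(r0_min=1e-6, r0_max=2e-6, step=0.5e-6)
        out = tmp_path / "sweep.csv"
        sweep.save(out)
        assert out.exists() and out.with_suffix(".csv.json").exists()
        data = np.loadtxt(out, delimiter=",", skiprows=1)
        assert data.shape == (3, 5)
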