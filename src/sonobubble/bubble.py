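"""Shell-model Rayleigh-Plesset bubble dynamics.

The dynamic model is a modified Rayleigh-Plesset equation for a gas bubble
stabilised by a thin elastic shell:

    R*Rddot = (1/rho) * [ -(3/2)*rho*Rdot^2 + pg*(R0/R)^(3*gamma) + pv - p0
                          - 2*sigma/R - 2*chi*(1/R0 - 1/R)
                          - delta_t*omega*rho*R*Rdot - pac(t) ]

with the ambient term -p0 included so that R = R0 is a rest state, and the
initial gas pressure closed by the equilibrium condition
pg = p0 + 2*sigma/R0 - pv.  The damping coefficient delta_t combines viscous
and re-radiation losses (thermal damping is not modelled); omega is the
angular center frequency of the driving pulse.

The radiated pressure a distance r from the bubble centre follows the
incompressible near-field expression p(r,t) = rho*(R^2*Rddot + 2*R*Rdot^2)/r,
with Rddot evaluated from the model right-hand side.

`BubbleModel` bundles an agent's shell parameters, the surrounding medium and
a driving pulse; `simulate` integrates one bubble, `sweep` scans a grid of
equilibrium radii, and `weight_sweep` folds a sweep with a measured size
distribution.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .agents import Medium, ShellParameters
from .pulses import PressurePulse

__all__ = [
    "RadiusTrajectory", "SweepResult", "WeightedSummary", "BubbleModel",
    "equilibrium_gas_pressure", "damping_coefficient", "natural_frequency",
    "simulate_bubble", "oscillation_amplitude", "radiated_pressure",
    "sweep_radii", "weight_sweep",
]

logger = logging.getLogger(__name__)

#: integration halts and flags collapse when R drops below this fraction of R0
COLLAPSE_FRACTION = 0.01

_R0_RANGE = (0.1e-6, 50e-6)


def equilibrium_gas_pressure(R0: float, shell: ShellParameters,
                             medium: Medium) -> float:
    """Initial gas pressure making R(t) = R0 a fixed point of the unforced
    model: pg = p0 + 2*sigma/R0 - pv (Pa)."""
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    pg = medium.p0 + 2.0 * shell.sigma / R0 - medium.pv
    if pg <= 0:
        raise ValueError(
            f"unphysical parameter set: equilibrium gas pressure {pg:.3g} Pa <= 0")
    return pg


def damping_coefficient(omega: float, R0: float, medium: Medium) -> float:
    """Dimensionless damping: viscous 4*mu/(rho*omega*R0^2) plus
    re-radiation omega*R0/c.  Thermal damping is not modelled."""
    if omega <= 0 or R0 <= 0:
        raise ValueError("omega and R0 must be positive")
    visc = 4.0 * medium.mu / (medium.rho * omega * R0 ** 2)
    rad = omega * R0 / medium.c
    return visc + rad


def natural_frequency(R0: float, shell: ShellParameters, medium: Medium) -> float:
    """Undamped linear resonance frequency (Hz) of the implemented model.

    Linearising the right-hand side about R = R0 gives
    omega0^2 = (3*gamma*pg - 2*sigma/R0 + 2*chi/R0) / (rho*R0^2).
    """
    pg = equilibrium_gas_pressure(R0, shell, medium)
    k = (3.0 * shell.gamma * pg - 2.0 * shell.sigma / R0
         + 2.0 * shell.chi / R0)
    if k <= 0:
        raise ValueError("negative linear stiffness: parameter set unstable")
    return float(np.sqrt(k / (medium.rho * R0 ** 2)) / (2.0 * np.pi))


@dataclass
class RadiusTrajectory:
    """One bubble's R(t) solution on the solver's accepted-step grid."""

    t: np.ndarray           # s
    R: np.ndarray           # m
    Rdot: np.ndarray        # m/s
    R0: float               # m
    label: str = ""
    collapsed: bool = False
    Rddot: np.ndarray | None = None   # m/s^2, from the model RHS

    def __post_init__(self) -> None:
        if np.any(self.R <= 0):
            raise ValueError("trajectory contains non-positive radii")


@dataclass
class SweepResult:
    """Oscillation and radiated-pressure metrics over an R0 grid."""

    r0_grid: np.ndarray        # m, strictly increasing
    osc_amp_abs: np.ndarray    # m, Dmax - Dmin
    osc_amp_pct: np.ndarray    # % of equilibrium diameter
    pnp_at_7um: np.ndarray     # Pa
    ppp_at_7um: np.ndarray     # Pa
    collapsed: np.ndarray      # bool mask; metrics there are NaN
    agent: str = ""
    pulse_label: str = ""

    def max_osc_pct(self) -> tuple[float, float]:
        """(R0 attaining max, max percent amplitude); smallest R0 on ties."""
        ok = ~self.collapsed
        if not ok.any():
            raise ValueError("all sweep points collapsed")
        vals = np.where(ok, self.osc_amp_pct, -np.inf)
        best = float(np.nanmax(vals))
        i = int(np.argmax(vals >= best - 0.0))  # first index at the max
        i = int(np.flatnonzero(vals == best)[0])
        return float(self.r0_grid[i]), best

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arr = np.column_stack([
            self.r0_grid * 1e6, self.osc_amp_abs * 1e6, self.osc_amp_pct,
            self.pnp_at_7um / 1e6, self.ppp_at_7um / 1e6,
        ])
        np.savetxt(path, arr, delimiter=",",
                   header="r0_um,osc_amp_um,osc_amp_pct,pnp7_mpa,ppp7_mpa",
                   comments="")
        r0max, pmax = self.max_osc_pct()
        summary = {
            "agent": self.agent, "pulse": self.pulse_label,
            "n_points": int(self.r0_grid.size),
            "n_collapsed": int(self.collapsed.sum()),
            "max_osc_amp_pct": pmax, "r0_at_max_um": r0max * 1e6,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(summary, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SweepResult":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        osc_pct = arr[:, 2]
        return cls(r0_grid=arr[:, 0] * 1e-6, osc_amp_abs=arr[:, 1] * 1e-6,
                   osc_amp_pct=osc_pct, pnp_at_7um=arr[:, 3] * 1e6,
                   ppp_at_7um=arr[:, 4] * 1e6,
                   collapsed=~np.isfinite(osc_pct),
                   agent=meta.get("agent", ""), pulse_label=meta.get("pulse", ""))


@dataclass
class WeightedSummary:
    """A sweep metric folded with a size distribution on histogram bins."""

    diameters: np.ndarray       # bin centers, m
    weights: np.ndarray         # sum to 1
    weighted_metric: np.ndarray  # w(d) * metric(d)
    normalization: str          # "count" | "volume"
    metric_name: str = ""
    agent: str = ""

    @property
    def auc(self) -> float:
        """Distribution-weighted mean of the metric (sum over bins)."""
        return float(self.weighted_metric.sum())


class BubbleModel:
    """Encapsulated-bubble dynamics for one agent, medium and driving pulse.

    Parameters
    ----------
    shell, medium : agent and fluid constants.
    pulse : driving pressure waveform; its center frequency sets the
        angular frequency in the damping term.
    rtol, atol_r, atol_v : solver tolerances (relative; absolute on R in m
        and on Rdot in m/s).
    backend : "numba" (compiled RK45, default) or "scipy" (solve_ivp RK45
        with LSODA fallback) — both integrate the identical right-hand side.
    """

    def __init__(self, shell: ShellParameters, medium: Medium,
                 pulse: PressurePulse, *, rtol: float = 1e-8,
                 atol_r: float = 1e-12, atol_v: float = 1e-6,
                 points_per_period: int = 32, backend: str = "numba"):
        self.shell = shell
        self.medium = medium
        self.pulse = pulse
        self.rtol = rtol
        self.atol_r = atol_r
        self.atol_v = atol_v
        self.points_per_period = points_per_period
        if backend not in ("numba", "scipy"):
            raise ValueError("backend must be 'numba' or 'scipy'")
        self.backend = backend
        self.omega = 2.0 * np.pi * pulse.center_frequency

    # -- right-hand side ---------------------------------------------------
    def _params(self, R0: float) -> dict:
        pg = equilibrium_gas_pressure(R0, self.shell, self.medium)
        dt_coef = damping_coefficient(self.omega, R0, self.medium) * self.omega
        return dict(rho=self.medium.rho, p0=self.medium.p0, pv=self.medium.pv,
                    sigma=self.shell.sigma, chi=self.shell.chi,
                    gamma=self.shell.gamma, pg=pg, dcoef=dt_coef, R0=R0)

    def rhs_acceleration(self, t, R, Rdot, R0: float) -> np.ndarray:
        """Model Rddot at given state(s); vectorised over arrays."""
        q = self._params(R0)
        pac = np.interp(t, self.pulse.t, self.pulse.p, left=0.0, right=0.0)
        bracket = (-1.5 * q["rho"] * Rdot ** 2
                   + q["pg"] * (R0 / R) ** (3.0 * q["gamma"])
                   + q["pv"] - q["p0"]
                   - 2.0 * q["sigma"] / R
                   - 2.0 * q["chi"] * (1.0 / R0 - 1.0 / R)
                   - q["dcoef"] * q["rho"] * R * Rdot
                   - pac)
        return bracket / (q["rho"] * R)

    # -- integration -------------------------------------------------------
    def simulate(self, R0: float, t_end: float | None = None) -> RadiusTrajectory:
        """Integrate the bubble from rest; halts flagged on collapse
        (R < R0/100), never silently returned as converged."""
        if not _R0_RANGE[0] <= R0 <= _R0_RANGE[1]:
            raise ValueError(f"R0 = {R0:.3g} m outside supported range "
                             f"[{_R0_RANGE[0]:.1e}, {_R0_RANGE[1]:.1e}] m")
        if t_end is None:
            t_end = self.pulse.duration
        period = 1.0 / self.pulse.center_frequency
        max_step = period / self.points_per_period
        if self.backend == "numba":
            traj = self._simulate_numba(R0, t_end, max_step)
        else:
            traj = self._simulate_scipy(R0, t_end, max_step)
        traj.Rddot = self.rhs_acceleration(traj.t, traj.R, traj.Rdot, R0)
        return traj

    def _simulate_numba(self, R0, t_end, max_step):
        from ._rp_kernel import integrate_rp, COLLAPSE, STEP_FAILURE, MAXSTEPS
        q = self._params(R0)
        t, R, Rd, m, status = integrate_rp(
            t_end, R0, self.pulse.p, float(self.pulse.t[0]), self.pulse.dt,
            q["rho"], q["p0"], q["pv"], q["sigma"], q["chi"], q["gamma"],
            q["pg"], q["dcoef"], self.rtol, self.atol_r, self.atol_v,
            max_step, COLLAPSE_FRACTION, 4_000_000)
        if status == STEP_FAILURE or status == MAXSTEPS:
            raise RuntimeError(f"integration failed (status {status}) at R0={R0:.3g} m")
        return RadiusTrajectory(t=t, R=R, Rdot=Rd, R0=R0,
                                label=self.pulse.label,
                                collapsed=(status == COLLAPSE))

    def _simulate_scipy(self, R0, t_end, max_step):
        q = self._params(R0)
        tp, pp = self.pulse.t, self.pulse.p
        g3 = 3.0 * q["gamma"]

        def rhs(t, y):
            R, Rd = y
            pac = np.interp(t, tp, pp, left=0.0, right=0.0)
            bracket = (-1.5 * q["rho"] * Rd * Rd
                       + q["pg"] * (R0 / R) ** g3
                       + q["pv"] - q["p0"]
                       - 2.0 * q["sigma"] / R
                       - 2.0 * q["chi"] * (1.0 / R0 - 1.0 / R)
                       - q["dcoef"] * q["rho"] * R * Rd
                       - pac)
            return [Rd, bracket / (q["rho"] * R)]

        def collapse_event(t, y):
            return y[0] - COLLAPSE_FRACTION * R0
        collapse_event.terminal = True

        sol = solve_ivp(rhs, (0.0, t_end), [R0, 0.0], method="RK45",
                        rtol=self.rtol, atol=[self.atol_r, self.atol_v],
                        max_step=max_step, events=collapse_event)
        if not sol.success and sol.status != 1:
            # stiff-solver fallback on step failure
            sol = solve_ivp(rhs, (0.0, t_end), [R0, 0.0], method="LSODA",
                            rtol=self.rtol, atol=[self.atol_r, self.atol_v],
                            max_step=max_step, events=collapse_event)
            if not sol.success and sol.status != 1:
                raise RuntimeError(f"integration failed at R0={R0:.3g} m: {sol.message}")
        return RadiusTrajectory(t=sol.t, R=sol.y[0], Rdot=sol.y[1], R0=R0,
                                label=self.pulse.label,
                                collapsed=(sol.status == 1))

    # -- metrics over an R0 grid -------------------------------------------
    def sweep(self, r0_min: float = 0.35e-6, r0_max: float = 10e-6,
              step: float = 50e-9, r_radiated: float = 7e-6) -> SweepResult:
        """Simulate each R0 on [r0_min, r0_max] (inclusive, uniform step) and
        collect oscillation-amplitude and radiated-pressure metrics.
        Collapse-flagged points carry NaN metrics under a mask."""
        npts = int(round((r0_max - r0_min) / step)) + 1
        grid = r0_min + step * np.arange(npts)
        amp_abs = np.full(npts, np.nan)
        amp_pct = np.full(npts, np.nan)
        pnp7 = np.full(npts, np.nan)
        ppp7 = np.full(npts, np.nan)
        mask = np.zeros(npts, dtype=bool)
        for i, r0 in enumerate(grid):
            traj = self.simulate(float(r0))
            if traj.collapsed:
                mask[i] = True
                logger.debug("sweep point %d (R0=%.3g m): collapse", i, r0)
                continue
            a, pct = oscillation_amplitude(traj)
            amp_abs[i] = a
            amp_pct[i] = pct
            if r_radiated > traj.R.max():
                _, pk = radiated_pressure(traj, r_radiated, medium=self.medium)
                pnp7[i], ppp7[i] = pk
            logger.debug("sweep point %d: R0=%.3g m amp=%.2f%%", i, r0, pct)
        if mask.any():
            logger.info("sweep: %d/%d points collapse-flagged", mask.sum(), npts)
        return SweepResult(r0_grid=grid, osc_amp_abs=amp_abs, osc_amp_pct=amp_pct,
                           pnp_at_7um=pnp7, ppp_at_7um=ppp7, collapsed=mask,
                           agent=self.shell.name, pulse_label=self.pulse.label)


# -- free-function views matching the toolkit surface ------------------------

def simulate_bubble(R0: float, shell: ShellParameters, medium: Medium,
                    pulse: PressurePulse, **solver_opts) -> RadiusTrajectory:
    return BubbleModel(shell, medium, pulse, **solver_opts).simulate(R0)


def oscillation_amplitude(traj: RadiusTrajectory) -> tuple[float, float]:
    """(absolute diameter excursion Dmax - Dmin in m, percent of the
    equilibrium diameter)."""
    if traj.t.size == 0:
        raise ValueError("empty trajectory")
    absolute = 2.0 * float(traj.R.max() - traj.R.min())
    percent = absolute / (2.0 * traj.R0) * 100.0
    return absolute, percent


def radiated_pressure(traj: RadiusTrajectory, r: float,
                      medium: Medium | None = None):
    """Radiated pressure time series at distance r and its (PNP, PPP) peaks.

    p(r,t) = rho*(R^2*Rddot + 2*R*Rdot^2)/r, with Rddot taken from the model
    right-hand side stored on the trajectory (never numerical differencing).
    """
    if r <= traj.R.max():
        raise ValueError(f"r = {r:.3g} m lies inside the bubble "
                         f"(max R = {traj.R.max():.3g} m)")
    if traj.Rddot is None:
        raise ValueError("trajectory carries no model acceleration (Rddot)")
    rho = (medium or Medium()).rho
    p = rho * (traj.R ** 2 * traj.Rddot + 2.0 * traj.R * traj.Rdot ** 2) / r
    pnp = float(max(0.0, -p.min()))
    ppp = float(max(0.0, p.max()))
    return p, (pnp, ppp)


def sweep_radii(shell: ShellParameters, medium: Medium, pulse: PressurePulse,
                r0_min: float = 0.35e-6, r0_max: float = 10e-6,
                step: float = 50e-9, **solver_opts) -> SweepResult:
    return BubbleModel(shell, medium, pulse, **solver_opts).sweep(
        r0_min=r0_min, r0_max=r0_max, step=step)


def weight_sweep(sweep: SweepResult, dist, normalization: str = "count",
                 metric: str = "osc_amp_pct") -> WeightedSummary:
    """Fold a sweep metric with a size distribution.

    ``dist`` is a :class:`sonobubble.sizing.SizeSummary`; its count- or
    volume-normalized histogram supplies weights on diameter bin centers
    (diameter d maps to R0 = d/2).  The metric is linearly interpolated from
    the sweep grid onto the bin centers; the AUC is the weighted sum.
    """
    if normalization not in ("count", "volume"):
        raise ValueError("normalization must be 'count' or 'volume'")
    hist = dist.count_hist if normalization == "count" else dist.volume_hist
    d = np.asarray(hist["bin_center_um"], float) * 1e-6     # m
    w = np.asarray(hist["percent"], float) / 100.0
    keep = w > 0
    d, w = d[keep], w[keep]
    r0 = d / 2.0
    lo, hi = sweep.r0_grid[0], sweep.r0_grid[-1]
    outside = w[(r0 < lo) | (r0 > hi)].sum()
    if outside > 0.01:
        raise ValueError(
            f"{outside * 100:.1f}% of the distribution mass lies outside the "
            f"sweep grid [{lo * 1e6:.2f}, {hi * 1e6:.2f}] um radius")
    vals = np.asarray(getattr(sweep, metric), float)
    ok = ~sweep.collapsed & np.isfinite(vals)
    m = np.interp(r0, sweep.r0_grid[ok], vals[ok])
    inside = (r0 >= lo) & (r0 <= hi)
    m[~inside] = 0.0
    return WeightedSummary(diameters=d, weights=w, weighted_metric=w * m,
                           normalization=normalization, metric_name=metric,
                           agent=sweep.agent)
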