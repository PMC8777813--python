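"""Attenuation spectroscopy and cavitation-threshold analysis.

Two signal chains from pulse-echo / passive-cavitation-detector recordings:

* **Attenuation**: per-replicate periodograms averaged within each role,
  baseline (no bubbles) minus sample in dB, divided by the acoustic path
  (default 8 cm = twice the sample chamber thickness) to give dB/cm.  The
  frequency of maximum attenuation is the bulk resonance of the suspension.

* **Cavitation threshold**: for each mechanical index (MI), the
  background-subtracted spectrum yields the subharmonic magnitude (band peak,
  400-600 kHz, in dB over background) and the spectral integral (trapezoidal
  integral of the linear-power excess, 0.2-10 MHz, reported in dB).  A
  four-parameter logistic (4PL)

      Y(x) = d + (a - d) / (1 + (x/c)^b)

  is fitted to metric-vs-MI data; the inflection MI ``c`` is the cavitation
  threshold.  When several agents are fitted jointly the plateaus a and d can
  be shared across datasets.  Confidence intervals come from the parameter
  covariance of the nonlinear least-squares fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "WaveformSet", "AttenuationSpectrum", "CavitationResponse",
    "averaged_power_spectrum", "attenuation_spectrum", "resonance_peak",
    "band_metrics", "four_param_logistic", "CavitationThresholdModel",
    "CavitationThresholdResults", "fit_4pl", "classify_regimes",
]

#: acoustic path through the sample chamber (2 x 4 cm thickness), cm
DEFAULT_PATH_CM = 8.0

SUBHARMONIC_BAND = (400e3, 600e3)
INTEGRAL_BAND = (0.2e6, 10e6)

#: linear-power floor guarding log of a zero spectral excess
_POWER_FLOOR = 1e-30


@dataclass
class WaveformSet:
    """Replicate recordings sharing one role and acquisition setting.

    waveforms : (n_replicates, n_samples) pressure-proportional voltage
    sampling_rate : Hz
    role : "baseline" or "sample"
    mi : MI label for cavitation runs; concentration : ppmL for attenuation.
    """

    waveforms: np.ndarray
    sampling_rate: float
    role: str = "sample"
    mi: float | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        w = np.atleast_2d(np.asarray(self.waveforms, float))
        self.waveforms = w
        if w.shape[0] < 1 or w.shape[1] < 2:
            raise ValueError("need at least one replicate of length >= 2")
        if self.role not in ("baseline", "sample"):
            raise ValueError("role must be 'baseline' or 'sample'")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, w in enumerate(self.waveforms):
            np.savetxt(directory / f"trace_{i:03d}.csv", w, delimiter=",")
        manifest = {"sampling_rate": self.sampling_rate, "role": self.role,
                    "mi": self.mi, "concentration": self.concentration,
                    "n_replicates": int(self.waveforms.shape[0])}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "WaveformSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        traces = [np.loadtxt(p, delimiter=",")
                  for p in sorted(directory.glob("trace_*.csv"))]
        return cls(np.vstack(traces), manifest["sampling_rate"],
                   manifest["role"], manifest.get("mi"),
                   manifest.get("concentration"))


@dataclass
class AttenuationSpectrum:
    """Frequency-dependent attenuation in dB/cm over a stated path."""

    frequency: np.ndarray   # Hz, strictly increasing
    attenuation: np.ndarray  # dB/cm
    path_cm: float = DEFAULT_PATH_CM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(self.attenuation)):
            raise ValueError("attenuation must be finite")


def averaged_power_spectrum(wset: WaveformSet):
    """Mean rectangular-window periodogram across replicates.

    Returns (frequency Hz, mean linear power).  The dB conventions applied
    downstream (re baseline) are recorded by the consumers in metadata.
    """
    f, p = _signal.periodogram(wset.waveforms, fs=wset.sampling_rate,
                               window="boxcar", axis=-1)
    return f, p.mean(axis=0)


def attenuation_spectrum(baseline: WaveformSet, sample: WaveformSet,
                         path_cm: float = DEFAULT_PATH_CM) -> AttenuationSpectrum:
    """Baseline-minus-sample spectral loss converted to dB/cm.

    A(f) = [P_baseline(f) - P_sample(f)] in dB / path_cm.
    """
    if baseline.waveforms.shape[1] != sample.waveforms.shape[1] or \
            baseline.sampling_rate != sample.sampling_rate:
        raise ValueError("baseline and sample grids do not match")
    f, pb = averaged_power_spectrum(baseline)
    _, ps = averaged_power_spectrum(sample)
    keep = f > 0
    f, pb, ps = f[keep], pb[keep], ps[keep]
    att_db = 10.0 * np.log10(np.maximum(pb, _POWER_FLOOR)
                             / np.maximum(ps, _POWER_FLOOR))
    return AttenuationSpectrum(frequency=f, attenuation=att_db / path_cm,
                               path_cm=path_cm,
                               meta={"db_reference": "baseline power spectrum",
                                     "n_baseline": int(baseline.waveforms.shape[0]),
                                     "n_sample": int(sample.waveforms.shape[0])})


def resonance_peak(spec: AttenuationSpectrum,
                   band: tuple[float, float]) -> tuple[float, float]:
    """(frequency, attenuation) of the attenuation maximum within ``band``;
    ties resolve to the lowest frequency."""
    lo, hi = band
    m = (spec.frequency >= lo) & (spec.frequency <= hi)
    if not m.any():
        raise ValueError("band contains no spectral samples")
    f, a = spec.frequency[m], spec.attenuation[m]
    i = int(np.argmax(a))          # first occurrence = lowest frequency
    return float(f[i]), float(a[i])


def band_metrics(freq: np.ndarray, power_sample: np.ndarray,
                 power_background: np.ndarray,
                 subharmonic_band: tuple[float, float] = SUBHARMONIC_BAND,
                 integral_band: tuple[float, float] = INTEGRAL_BAND,
                 subharmonic_stat: str = "peak") -> tuple[float, float]:
    """Cavitation metrics from background-subtracted spectra.

    Subharmonic magnitude: peak (or mean) of the dB excess over background in
    the subharmonic band.  Spectral integral: trapezoidal integral of the
    linear-power excess over the integral band, reported in dB
    (10*log10, floored for non-positive excess).
    """
    freq = np.asarray(freq, float)
    for band in (subharmonic_band, integral_band):
        if band[0] < freq[0] or band[1] > freq[-1]:
            raise ValueError(f"band {band} outside the spectral grid")
    excess_db = 10.0 * np.log10(np.maximum(power_sample, _POWER_FLOOR)
                                / np.maximum(power_background, _POWER_FLOOR))
    m_sub = (freq >= subharmonic_band[0]) & (freq <= subharmonic_band[1])
    if subharmonic_stat == "peak":
        sub_db = float(excess_db[m_sub].max())
    elif subharmonic_stat == "mean":
        sub_db = float(excess_db[m_sub].mean())
    else:
        raise ValueError("subharmonic_stat must be 'peak' or 'mean'")

    m_int = (freq >= integral_band[0]) & (freq <= integral_band[1])
    lin_excess = power_sample[m_int] - power_background[m_int]
    integral = np.trapezoid(lin_excess, freq[m_int])
    integral_db = float(10.0 * np.log10(max(integral, _POWER_FLOOR)))
    return sub_db, integral_db


# ---------------------------------------------------------------------------
# 4PL cavitation-threshold model
# ---------------------------------------------------------------------------

def four_param_logistic(x, a, d, b, c):
    """Y = d + (a - d) / (1 + (x/c)^b); a is the low-x plateau, d the
    high-x plateau, c the inflection point, b the Hill slope."""
    x = np.asarray(x, float)
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass
class CavitationResponse:
    """Metric-vs-MI curve for one agent (replicates allowed)."""

    mi: np.ndarray                 # (n_mi,), strictly increasing
    response: np.ndarray           # (n_reps, n_mi) or (n_mi,), dB-scaled
    label: str = ""

    def __post_init__(self) -> None:
        self.mi = np.asarray(self.mi, float)
        self.response = np.atleast_2d(np.asarray(self.response, float))
        if np.any(np.diff(self.mi) <= 0):
            raise ValueError("mi grid must be strictly increasing")
        if np.unique(self.mi).size < 4:
            raise ValueError("need >= 4 distinct MI values to fit a 4PL")
        if self.response.shape[1] != self.mi.size:
            raise ValueError("response shape does not match mi grid")

    @property
    def x_flat(self) -> np.ndarray:
        return np.tile(self.mi, self.response.shape[0])

    @property
    def y_flat(self) -> np.ndarray:
        return self.response.ravel()


class CavitationThresholdModel:
    """Joint 4PL threshold model over one or more agents.

    Parameters
    ----------
    responses : mapping of agent label to :class:`CavitationResponse`.
    share_plateaus : if True (default), the plateaus a and d are common to
        all datasets in a joint fit; slope b and inflection c stay per agent.
    """

    def __init__(self, responses: dict[str, CavitationResponse],
                 share_plateaus: bool = True):
        if not responses:
            raise ValueError("no responses supplied")
        self.responses = dict(responses)
        self.share_plateaus = share_plateaus

    def _start(self, resp: CavitationResponse):
        y = resp.response.mean(axis=0)
        a0, d0 = float(y[0]), float(y[-1])
        # midpoint crossing as c start
        mid = 0.5 * (a0 + d0)
        idx = int(np.argmin(np.abs(y - mid)))
        c0 = float(resp.mi[max(idx, 1)])
        return a0, d0, 4.0, c0

    def fit(self, max_nfev: int = 20000) -> "CavitationThresholdResults":
        labels = list(self.responses)
        starts = {k: self._start(v) for k, v in self.responses.items()}
        if self.share_plateaus:
            a0 = float(np.mean([s[0] for s in starts.values()]))
            d0 = float(np.mean([s[1] for s in starts.values()]))
            theta0 = [a0, d0]
            for k in labels:
                theta0 += [starts[k][2], starts[k][3]]

            def unpack(theta):
                out = {}
                for i, k in enumerate(labels):
                    out[k] = (theta[0], theta[1],
                              theta[2 + 2 * i], theta[3 + 2 * i])
                return out
        else:
            theta0 = []
            for k in labels:
                theta0 += list(starts[k])

            def unpack(theta):
                return {k: tuple(theta[4 * i:4 * i + 4])
                        for i, k in enumerate(labels)}

        def residuals(theta):
            p = unpack(theta)
            res = []
            for k in labels:
                r = self.responses[k]
                res.append(four_param_logistic(r.x_flat, *p[k]) - r.y_flat)
            return np.concatenate(res)

        lower = np.full(len(theta0), -np.inf)
        upper = np.full(len(theta0), np.inf)
        # c must stay positive
        c_idx = ([3 + 2 * i for i in range(len(labels))]
                 if self.share_plateaus else [4 * i + 3 for i in range(len(labels))])
        for i in c_idx:
            lower[i] = 1e-12
        sol = least_squares(residuals, theta0, bounds=(lower, upper),
                            max_nfev=max_nfev)
        if not sol.success:
            raise RuntimeError(
                f"4PL fit failed to converge: {sol.message}; best residual "
                f"{np.sqrt(2 * sol.cost):.4g} from start {theta0}")
        n_obs = sol.fun.size
        n_par = len(theta0)
        dof = max(n_obs - n_par, 1)
        s2 = 2.0 * sol.cost / dof
        JtJ = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(JtJ)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        tcrit = stats.t.ppf(0.975, dof)

        params, cis, flagged = {}, {}, {}
        p = unpack(sol.x)
        se_map = unpack(se)
        for k in labels:
            a, d, b, c = p[k]
            params[k] = {"a": a, "d": d, "b": b, "c": c}
            se_c = se_map[k][3]
            cis[k] = {"c": (c - tcrit * se_c, c + tcrit * se_c),
                      "b": (p[k][2] - tcrit * se_map[k][2],
                            p[k][2] + tcrit * se_map[k][2])}
            mi = self.responses[k].mi
            flagged[k] = not (mi[0] <= c <= mi[-1])
        return CavitationThresholdResults(
            params=params, conf_ints=cis, flagged=flagged, cov=cov,
            residual_rms=float(np.sqrt(np.mean(sol.fun ** 2))), dof=dof,
            share_plateaus=self.share_plateaus, model=self)


@dataclass
class CavitationThresholdResults:
    """Fitted 4PL parameters, CIs and regime boundaries per agent."""

    params: dict
    conf_ints: dict
    flagged: dict
    cov: np.ndarray
    residual_rms: float
    dof: int
    share_plateaus: bool
    model: CavitationThresholdModel = field(repr=False)

    def threshold(self, agent: str) -> float:
        """Cavitation threshold = fitted inflection MI c."""
        return self.params[agent]["c"]

    def conf_int(self, agent: str, param: str = "c") -> tuple[float, float]:
        return self.conf_ints[agent][param]

    def regimes(self, agent: str) -> tuple[float, float]:
        return classify_regimes(self.params[agent]["b"], self.params[agent]["c"])

    def summary(self) -> str:
        lines = ["4PL cavitation-threshold fit "
                 f"(plateaus {'shared' if self.share_plateaus else 'per agent'}; "
                 f"residual RMS {self.residual_rms:.3g} dB, dof {self.dof})",
                 f"{'agent':<12}{'a':>8}{'d':>9}{'b':>8}{'c (MI)':>9}"
                 f"{'95% CI(c)':>22}{'regimes':>22}"]
        for k, p in self.params.items():
            lo, hi = self.conf_ints[k]["c"]
            s_lo, s_hi = self.regimes(k)
            flag = "  [c outside data range]" if self.flagged[k] else ""
            lines.append(f"{k:<12}{p['a']:>8.2f}{p['d']:>9.2f}{p['b']:>8.2f}"
                         f"{p['c']:>9.3f}   ({lo:.3f}, {hi:.3f})"
                         f"   ({s_lo:.3f}, {s_hi:.3f}){flag}")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        out = {k: {"params": self.params[k],
                   "ci_c": list(self.conf_ints[k]["c"]),
                   "regime_bounds": list(self.regimes(k)),
                   "flagged": self.flagged[k]}
               for k in self.params}
        out["_meta"] = {"share_plateaus": self.share_plateaus,
                        "residual_rms": self.residual_rms, "dof": self.dof,
                        "ci_kind": "parameter-covariance (t-based, 95%)"}
        Path(path).write_text(json.dumps(out, indent=1))


def fit_4pl(responses: dict[str, CavitationResponse] | CavitationResponse,
            share_plateaus: bool = True) -> CavitationThresholdResults:
    """Convenience wrapper: joint 4PL fit over agents (see
    :class:`CavitationThresholdModel`)."""
    if isinstance(responses, CavitationResponse):
        responses = {responses.label or "agent": responses}
    return CavitationThresholdModel(responses, share_plateaus).fit()


def classify_regimes(b: float, c: float, q: float = 0.05) -> tuple[float, float]:
    """Regime boundaries from a fitted 4PL.

    The stable/transitional boundary is the MI where the curve has completed
    a fraction q of the a-to-d transition, the transitional/inertial boundary
    where it has completed 1-q:  x_f = c * (f/(1-f))^(1/b).  Returned as
    (stable_upper_mi, inertial_lower_mi), sorted.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    x_lo = c * (q / (1.0 - q)) ** (1.0 / b)
    x_hi = c * ((1.0 - q) / q) ** (1.0 / b)
    return (min(x_lo, x_hi), max(x_lo, x_hi))
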