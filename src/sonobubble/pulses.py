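"""Tone-burst synthesis and acoustic-output metrics.

A :class:`PressurePulse` is a uniformly sampled acoustic pressure waveform
p(t) in pascal.  The metrics computed here are the regulatory quantities used
to characterise diagnostic and therapeutic exposures:

* PNP / PPP — peak-negative / peak-positive pressure (Pa),
* MI — mechanical index, PNP[MPa] / sqrt(f[MHz]),
* I_SPPA — spatial-peak pulse-average intensity, (1/T) ∫ p²/(ρc) dt (W/cm²),
* I_SPTA — spatial-peak temporal-average intensity, I_SPPA × duty (mW/cm²).

Sign convention: positive pressure denotes compression; PNP is the magnitude
of the most negative sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal.windows import tukey as _tukey

__all__ = [
    "PressurePulse",
    "PulseMetrics",
    "synthesize_tone_burst",
    "pulse_metrics",
]

#: minimum samples per carrier period accepted anywhere in this module
NYQUIST_MARGIN = 16


@dataclass(frozen=True)
class PressurePulse:
    """Uniformly sampled pressure waveform.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, uniform grid.
    p : ndarray
        Acoustic pressure in Pa (positive = compression).
    center_frequency : float
        Carrier frequency in Hz.  For externally supplied waveforms this is
        the peak of the magnitude spectrum (see :meth:`from_waveform`).
    label : str
        Free-text tag.
    """

    t: np.ndarray
    p: np.ndarray
    center_frequency: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "p", p)
        if t.ndim != 1 or t.size < 2 or p.shape != t.shape:
            raise ValueError("t and p must be 1-D arrays of equal length >= 2")
        if not (np.isfinite(t).all() and np.isfinite(p).all()):
            raise ValueError("waveform contains non-finite samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-12, atol=0.0):
            raise ValueError("sampling interval is not uniform")
        if self.center_frequency > 0:
            fs = 1.0 / dt[0]
            if fs < NYQUIST_MARGIN * self.center_frequency * (1 - 1e-9):
                raise ValueError(
                    f"undersampled waveform: need >= {NYQUIST_MARGIN} samples per "
                    f"period of {self.center_frequency:g} Hz, got {fs / self.center_frequency:.1f}"
                )

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Span of the waveform including the trailing sample interval."""
        return float(self.t[-1] - self.t[0]) + self.dt

    @property
    def pnp(self) -> float:
        """Peak negative pressure magnitude, Pa."""
        return float(max(0.0, -self.p.min()))

    @property
    def ppp(self) -> float:
        """Peak positive pressure, Pa."""
        return float(max(0.0, self.p.max()))

    @classmethod
    def from_waveform(cls, t: np.ndarray, p: np.ndarray, label: str = "") -> "PressurePulse":
        """Wrap a recorded waveform, inferring the center frequency from the
        peak of its rectangular-windowed magnitude spectrum."""
        t = np.asarray(t, float)
        p = np.asarray(p, float)
        dt = t[1] - t[0]
        spec = np.abs(np.fft.rfft(p))
        freqs = np.fft.rfftfreq(p.size, dt)
        spec[0] = 0.0  # ignore DC
        fc = float(freqs[int(np.argmax(spec))])
        return cls(t=t, p=p, center_frequency=fc, label=label)

    # -- plain-text I/O ----------------------------------------------------
    def save(self, path: str | Path, prf: float | None = None) -> None:
        """Write 2-column CSV (`time_s,pressure_pa`) plus a JSON sidecar."""
        path = Path(path)
        arr = np.column_stack([self.t, self.p])
        np.savetxt(path, arr, delimiter=",", header="time_s,pressure_pa", comments="")
        meta = {"center_frequency_hz": self.center_frequency, "label": self.label}
        if prf is not None:
            meta["prf_hz"] = prf
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PressurePulse":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            return cls(arr[:, 0], arr[:, 1], meta["center_frequency_hz"],
                       meta.get("label", ""))
        return cls.from_waveform(arr[:, 0], arr[:, 1])


@dataclass(frozen=True)
class PulseMetrics:
    pnp: float            # Pa
    ppp: float            # Pa
    mi: float             # dimensionless
    duration: float       # s
    duty_cycle: float     # fraction
    i_sppa: float         # W/cm^2
    i_spta: float         # mW/cm^2

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("pnp", "ppp", "mi", "duration", "duty_cycle", "i_sppa", "i_spta")}


def synthesize_tone_burst(
    center_frequency: float,
    duration: float,
    pnp: float,
    envelope: str = "tukey(0.25)",
    sampling_rate: float | None = None,
    label: str = "",
) -> PressurePulse:
    """Synthesize a tone burst with a given peak negative pressure.

    Parameters
    ----------
    center_frequency : Hz
    duration : s — must cover at least one carrier cycle.
    pnp : Pa — target peak negative pressure of the enveloped burst.
        The waveform is scaled so min(p) = −pnp (exact for pnp > 0).
    envelope : ``"rectangular"`` or ``"tukey(alpha)"``.
    sampling_rate : Hz, default 64 × center frequency.
    """
    if duration * center_frequency < 1:
        raise ValueError("duration must cover at least one carrier period")
    if sampling_rate is None:
        sampling_rate = 64.0 * center_frequency
    if sampling_rate < NYQUIST_MARGIN * center_frequency:
        raise ValueError(
            f"sampling_rate below the Nyquist margin rule: need >= "
            f"{NYQUIST_MARGIN}x the center frequency "
            f"({NYQUIST_MARGIN * center_frequency:g} Hz), got {sampling_rate:g} Hz"
        )
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    carrier = np.sin(2.0 * np.pi * center_frequency * t)
    env = _make_envelope(envelope, n)
    p = carrier * env
    if pnp < 0:
        raise ValueError("pnp must be non-negative")
    if pnp == 0.0:
        p = np.zeros_like(p)
    else:
        # rescale so the enveloped minimum hits exactly -pnp
        p *= pnp / (-p.min())
    return PressurePulse(t=t, p=p, center_frequency=center_frequency, label=label)


def _make_envelope(envelope: str, n: int) -> np.ndarray:
    env = envelope.strip().lower()
    if env in ("rect", "rectangular"):
        return np.ones(n)
    if env.startswith("tukey"):
        alpha = 0.25
        if "(" in env:
            alpha = float(env[env.index("(") + 1:env.rindex(")")])
        return _tukey(n, alpha)
    raise ValueError(f"unknown envelope {envelope!r}")


def pulse_metrics(
    pulse: PressurePulse,
    prf: float = 0.0,
    rho: float = 1000.0,
    c: float = 1480.0,
    duty_cycle: float | None = None,
) -> PulseMetrics:
    """Acoustic-output metrics of a single pulse fired at repetition rate prf.

    ``duty_cycle`` may be supplied explicitly (scanner-reported duty values do
    not always follow from cycles × PRF); otherwise it is duration × prf.

    MI uses the standard convention PNP[MPa] / sqrt(f[MHz]).  I_SPPA is the
    pulse-average of p²/(ρc) converted to W/cm²; I_SPTA = I_SPPA × duty × 1000
    in mW/cm².
    """
    duration = pulse.duration
    if duty_cycle is None:
        duty_cycle = duration * prf
    if not 0.0 <= duty_cycle <= 1.0:
        raise ValueError(f"duty cycle {duty_cycle:.4g} outside [0, 1] "
                         "(prf x duration must not exceed 1)")
    pnp = pulse.pnp
    ppp = pulse.ppp
    if pulse.center_frequency > 0 and pnp > 0:
        mi = (pnp / 1e6) / np.sqrt(pulse.center_frequency / 1e6)
    else:
        mi = 0.0
    # time integral of instantaneous intensity over the burst, W/m^2 -> W/cm^2
    energy_flux = np.trapezoid(pulse.p ** 2, pulse.t) / (rho * c)   # W/m^2 * s
    i_sppa = energy_flux / duration / 1e4
    i_spta = i_sppa * duty_cycle * 1e3
    return PulseMetrics(pnp=pnp, ppp=ppp, mi=float(mi), duration=duration,
                        duty_cycle=float(duty_cycle), i_sppa=float(i_sppa),
                        i_spta=float(i_spta))


def mi_to_pnp(mi: float, center_frequency: float) -> float:
    """Peak negative pressure (Pa) giving mechanical index ``mi`` at
    ``center_frequency`` (Hz)."""
    return mi * np.sqrt(center_frequency / 1e6) * 1e6
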