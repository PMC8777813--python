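"""Seeded generators emulating the statistical structure of the lab data.

Each generator produces inputs with the structure its matching analysis
stage assumes, with known ground truth, so the whole pipeline is testable
without any external measurement:

* particle populations — lognormal diameters parameterised by the median and
  the d90/d10 polydispersity index (matching the published per-agent
  summaries);
* pulse-echo waveform pairs — a broadband deterministic baseline and a
  sample filtered so the spectral power deficit equals a requested
  frequency-dependent attenuation profile over the acoustic path;
* MI-response curves — 4PL evaluations plus Gaussian dB noise per replicate;
* dose-response surfaces — saturating Hill responses in concentration whose
  EC50 decreases with acoustic intensity.

All randomness flows from an integer seed through ``numpy.random.default_rng``;
identical arguments give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .sizing import ParticleTable, DEFAULT_FOV_VOLUME_ML
from .spectra import WaveformSet, CavitationResponse, four_param_logistic
from .mapping import ResponseTable

__all__ = [
    "psd_to_lognormal_sigma", "gen_population", "gen_waveform_set",
    "gen_mi_response", "gen_response_surface", "HillSurface",
    "TABLE_SIZE_SCENARIOS",
]

#: z(0.90) - z(0.10) of the standard normal = 2 * 1.2816
_Z_SPAN = 2.0 * 1.2816

#: published per-agent count-normalized size summaries
#: (median diameter µm, d90/d10, fresh concentration particles/mL)
TABLE_SIZE_SCENARIOS = {
    "SonoVue": {"median_um": 1.7, "psd": 2.46, "concentration": 0.239e9},
    "Sonazoid": {"median_um": 1.9, "psd": 2.06, "concentration": 1.269e9},
    "Optison": {"median_um": 3.3, "psd": 2.15, "concentration": 0.607e9},
}


def psd_to_lognormal_sigma(psd: float) -> float:
    """ln-scale sigma of a lognormal with a given d90/d10 ratio:
    sigma = ln(psd) / 2.5631."""
    if psd < 1:
        raise ValueError("psd (d90/d10) must be >= 1")
    return float(np.log(psd) / _Z_SPAN)


def gen_population(median_diameter: float, psd_d90_d10: float, n: int,
                   seed: int, minutes: float = 0.5, dilution: float = 100.0,
                   mean_roundness: float = 0.94, roundness_sd: float = 0.02,
                   fov_volume_ml: float = DEFAULT_FOV_VOLUME_ML) -> ParticleTable:
    """Lognormal bubble population as a per-particle optical-sizing table.

    Diameters are lognormal(median, sigma(psd)); projected areas are
    back-computed as pi*d^2/4 and the maximum diameter is d divided by a
    per-particle roundness draw (truncated normal on (0.5, 1]).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = psd_to_lognormal_sigma(psd_d90_d10)
    d = median_diameter * np.exp(sigma * rng.standard_normal(n))
    rnd = np.clip(rng.normal(mean_roundness, roundness_sd, n), 0.5, 1.0)
    df = pd.DataFrame({
        "area_um2": np.pi * d ** 2 / 4.0,
        "max_diam_um": d / rnd,
        "minutes": np.full(n, float(minutes)),
        "dilution": np.full(n, float(dilution)),
    })
    return ParticleTable(df, fov_volume_ml=fov_volume_ml)


def _broadband_baseline(n_samples: int, fs: float) -> np.ndarray:
    """Deterministic broadband click, designed in the frequency domain so
    its power spectrum is strictly positive and null-free up to ~12 MHz."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    mag = np.exp(-0.5 * ((freqs - 4e6) / 5e6) ** 2) + 0.1
    # zero phase -> symmetric click; roll it into the record
    w = np.fft.irfft(mag, n_samples)
    return np.roll(w, n_samples // 4)


def gen_waveform_set(attenuation_profile: Callable[[np.ndarray], np.ndarray],
                     noise_db: float, n_replicates: int, seed: int,
                     fs: float = 50e6, n_samples: int = 4096,
                     path_cm: float = 8.0) -> tuple[WaveformSet, WaveformSet]:
    """(baseline, sample) waveform sets with a known attenuation imprint.

    ``attenuation_profile(f_hz) -> dB/cm`` (>= 0).  The sample replicates are
    the baseline filtered in the frequency domain so that the power-spectral
    deficit equals profile x path_cm dB.  ``noise_db`` sets additive white
    noise per replicate, in dB below the baseline peak amplitude
    (np.inf = noiseless).
    """
    rng = np.random.default_rng(seed)
    base = _broadband_baseline(n_samples, fs)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    prof = np.asarray(attenuation_profile(freqs), float)
    if np.any(prof < 0):
        raise ValueError("attenuation profile must be >= 0 dB/cm")
    h = 10.0 ** (-prof * path_cm / 20.0)      # amplitude filter
    filtered = np.fft.irfft(np.fft.rfft(base) * h, n_samples)

    if np.isinf(noise_db):
        noise_rms = 0.0
    else:
        noise_rms = np.abs(base).max() * 10.0 ** (-noise_db / 20.0)
    b = np.tile(base, (n_replicates, 1))
    s = np.tile(filtered, (n_replicates, 1))
    if noise_rms > 0:
        b = b + noise_rms * rng.standard_normal(b.shape)
        s = s + noise_rms * rng.standard_normal(s.shape)
    return (WaveformSet(b, fs, role="baseline"),
            WaveformSet(s, fs, role="sample"))


def gen_mi_response(a: float, d: float, b: float, c: float,
                    mi_grid: np.ndarray, noise_db: float, n_reps: int,
                    seed: int, label: str = "") -> CavitationResponse:
    """4PL curve on an MI grid plus Gaussian noise (sd ``noise_db``) per
    replicate."""
    mi_grid = np.asarray(mi_grid, float)
    rng = np.random.default_rng(seed)
    clean = four_param_logistic(mi_grid, a, d, b, c)
    resp = clean[None, :] + noise_db * rng.standard_normal((n_reps, mi_grid.size))
    return CavitationResponse(mi=mi_grid, response=resp, label=label)


@dataclass(frozen=True)
class HillSurface:
    """Saturating dose-response ground truth for one agent.

    percent_positive(I, C) = emax * C / (C + EC50(I)), with
    EC50(I) = ec50_ref * (i_ref / I)^intensity_gain — the half-maximal
    concentration falls as intensity rises.
    """

    emax: float
    ec50_ref: float        # particles/mL at the reference intensity
    i_ref: float           # mW/cm^2
    intensity_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.emax > 100:
            raise ValueError("emax cannot exceed 100%")

    def ec50(self, intensity) -> np.ndarray:
        return self.ec50_ref * (self.i_ref / np.asarray(intensity, float)) \
            ** self.intensity_gain

    def __call__(self, intensity, conc) -> np.ndarray:
        c = np.asarray(conc, float)
        return self.emax * c / (c + self.ec50(intensity))


def gen_response_surface(agent_params: dict[str, HillSurface],
                         intensities: np.ndarray, concentrations: np.ndarray,
                         noise_sd: float, seed: int,
                         n_reps: int = 3) -> ResponseTable:
    """Sample Hill surfaces on a factorial design into a long-format
    response table; noise is Gaussian in percentage points, clipped to
    [0, 100]."""
    rng = np.random.default_rng(seed)
    rows = []
    for agent, surf in agent_params.items():
        for i in np.asarray(intensities, float):
            for c in np.asarray(concentrations, float):
                y = float(surf(i, c))
                for rep in range(n_reps):
                    val = np.clip(y + noise_sd * rng.standard_normal(), 0, 100)
                    rows.append((agent, i, c, float(val), rep))
    return ResponseTable(pd.DataFrame(
        rows, columns=["agent", "i_spta_mw_cm2", "conc_ppml",
                       "pct_positive", "rep"]))
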