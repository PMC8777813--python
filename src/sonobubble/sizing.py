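"""Optical-sizing analytics for microbubble populations.

Consumes per-particle tables from optical microscopy (projected area and
maximum diameter per detected particle) and produces the population
summaries used to characterise an agent: equivalent diameters, roundness,
count- and volume-normalized 0.1-µm histograms, d10/d50/d90 percentiles and
the d90/d10 polydispersity index, geometric/arithmetic means, and the
suspension concentration from the imaging volume and dilution factor.

Count normalization weights every particle equally; volume normalization
weights each particle by d³, emphasising the few large bubbles that carry
most of the gas volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParticleTable", "SizeSummary", "particle_metrics",
    "summarize_population", "stability_compare", "area_matched_concentration",
    "DEFAULT_FOV_VOLUME_ML",
]

#: optical imaging volume of one field of view, mL
DEFAULT_FOV_VOLUME_ML = 6.2e-6

#: detection cutoff, µm (30% above the objective resolution)
DEFAULT_MIN_DIAMETER_UM = 0.7


@dataclass
class ParticleTable:
    """Per-particle measurements from one or more pooled images.

    ``data`` columns: ``area_um2``, ``max_diam_um``, ``minutes`` (time since
    preparation), ``dilution`` (dilution factor of the imaged sample).
    """

    data: pd.DataFrame
    fov_volume_ml: float = DEFAULT_FOV_VOLUME_ML

    REQUIRED = ("area_um2", "max_diam_um", "minutes", "dilution")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"particle table missing columns {missing}")
        if (self.data["area_um2"] <= 0).any():
            raise ValueError("particle areas must be positive")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def load(cls, path: str | Path,
             fov_volume_ml: float = DEFAULT_FOV_VOLUME_ML) -> "ParticleTable":
        return cls(pd.read_csv(path), fov_volume_ml=fov_volume_ml)

    def save(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def particle_metrics(area: float | np.ndarray,
                     max_diameter: float | np.ndarray):
    """Equivalent diameter and roundness of a detected particle.

    d_eq = 2*sqrt(area/pi) — the diameter of the circle with the particle's
    area; roundness = d_eq / max_diameter, capped at 1.
    """
    area = np.asarray(area, float)
    max_diameter = np.asarray(max_diameter, float)
    if np.any(area <= 0) or np.any(max_diameter <= 0):
        raise ValueError("area and max_diameter must be positive")
    d_eq = 2.0 * np.sqrt(area / np.pi)
    roundness = np.minimum(d_eq / max_diameter, 1.0)
    if d_eq.ndim == 0:
        return float(d_eq), float(roundness)
    return d_eq, roundness


def _weighted_percentile(d: np.ndarray, w: np.ndarray, q: float) -> float:
    """Linear interpolation of the weighted empirical CDF (midpoint rule)."""
    order = np.argsort(d, kind="stable")
    d, w = d[order], w[order]
    cw = np.cumsum(w)
    cdf = (cw - 0.5 * w) / cw[-1]
    return float(np.interp(q, cdf, d))


@dataclass
class SizeSummary:
    """Dual-normalized summary of one sized population."""

    count_hist: pd.DataFrame       # bin_center_um, percent (sums to 100)
    volume_hist: pd.DataFrame
    percentiles: dict              # {"count": {"d10","d50","d90","psd"}, "volume": ...}
    geometric_mean_um: float
    mean_um: float
    sem_um: float
    mean_roundness: float
    concentration_per_ml: float
    n_particles: int
    diameters_um: np.ndarray = field(repr=False)   # surviving particles
    roundness: np.ndarray = field(repr=False)
    bin_width_um: float = 0.1

    def psd(self, normalization: str = "count") -> float:
        return self.percentiles[normalization]["psd"]

    def to_json(self, path: str | Path) -> None:
        out = {
            "percentiles": self.percentiles,
            "geometric_mean_um": self.geometric_mean_um,
            "mean_um": self.mean_um, "sem_um": self.sem_um,
            "mean_roundness": self.mean_roundness,
            "concentration_per_ml": self.concentration_per_ml,
            "n_particles": self.n_particles,
            "bin_width_um": self.bin_width_um,
            "count_hist": self.count_hist.to_dict(orient="list"),
            "volume_hist": self.volume_hist.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(out, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SizeSummary":
        d = json.loads(Path(path).read_text())
        return cls(
            count_hist=pd.DataFrame(d["count_hist"]),
            volume_hist=pd.DataFrame(d["volume_hist"]),
            percentiles=d["percentiles"],
            geometric_mean_um=d["geometric_mean_um"],
            mean_um=d["mean_um"], sem_um=d["sem_um"],
            mean_roundness=d["mean_roundness"],
            concentration_per_ml=d["concentration_per_ml"],
            n_particles=d["n_particles"],
            diameters_um=np.array([]), roundness=np.array([]),
            bin_width_um=d.get("bin_width_um", 0.1),
        )


def _histogram(d: np.ndarray, w: np.ndarray, bin_um: float) -> pd.DataFrame:
    """Left-closed [k*bin, (k+1)*bin) histogram in percent, labelled by center."""
    # epsilon guards bin edges against float division (2.0/0.1 -> 19.999...)
    k = np.floor(d / bin_um + 1e-9).astype(int)
    edges_lo = 0
    edges_hi = int(k.max()) + 1
    counts = np.bincount(k - edges_lo, weights=w, minlength=edges_hi)
    centers = (np.arange(edges_hi) + 0.5) * bin_um
    pct = counts / counts.sum() * 100.0
    return pd.DataFrame({"bin_center_um": centers, "percent": pct})


def summarize_population(table: ParticleTable,
                         min_diameter: float = DEFAULT_MIN_DIAMETER_UM,
                         bin_um: float = 0.1) -> SizeSummary:
    """Summarise a particle table after applying the diameter cutoff.

    Count weights are uniform; volume weights are proportional to d³.
    Percentiles interpolate the weighted empirical CDF.  Concentration is
    (surviving count / imaging volume) × dilution factor.
    """
    d_all, rnd_all = particle_metrics(table.data["area_um2"].to_numpy(),
                                      table.data["max_diam_um"].to_numpy())
    keep = d_all >= min_diameter
    if not keep.any():
        raise ValueError(f"no particles survive the {min_diameter} um cutoff")
    d = d_all[keep]
    rnd = rnd_all[keep]
    dilution = float(np.median(table.data["dilution"].to_numpy()[keep]))

    w_count = np.ones_like(d)
    w_vol = d ** 3
    percentiles = {}
    for norm, w in (("count", w_count), ("volume", w_vol)):
        p = {f"d{q}": _weighted_percentile(d, w, q / 100) for q in (10, 50, 90)}
        p["psd"] = p["d90"] / p["d10"]
        percentiles[norm] = p

    conc = d.size / table.fov_volume_ml * dilution
    return SizeSummary(
        count_hist=_histogram(d, w_count, bin_um),
        volume_hist=_histogram(d, w_vol, bin_um),
        percentiles=percentiles,
        geometric_mean_um=float(stats.gmean(d)),
        mean_um=float(d.mean()),
        sem_um=float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else 0.0,
        mean_roundness=float(rnd.mean()),
        concentration_per_ml=float(conc),
        n_particles=int(d.size),
        diameters_um=d,
        roundness=rnd,
        bin_width_um=bin_um,
    )


def stability_compare(fresh: SizeSummary, aged: SizeSummary) -> dict:
    """Fresh vs aged comparison: percent changes and a Welch two-sample test
    on the diameter distributions."""
    if fresh.bin_width_um != aged.bin_width_um:
        raise ValueError("summaries use different binnings")

    def pct_change(a, b):
        return (b - a) / a * 100.0

    t, p = stats.ttest_ind(fresh.diameters_um, aged.diameters_um,
                           equal_var=False)
    return {
        "concentration_change_pct": pct_change(fresh.concentration_per_ml,
                                               aged.concentration_per_ml),
        "mean_diameter_change_pct": pct_change(fresh.mean_um, aged.mean_um),
        "roundness_change_pct": pct_change(fresh.mean_roundness,
                                           aged.mean_roundness),
        "diameter_welch_t": float(t),
        "diameter_p_value": float(p),
        "fresh_mean_um": fresh.mean_um,
        "aged_mean_um": aged.mean_um,
    }


def area_matched_concentration(ref_dist: SizeSummary, ref_conc: float,
                               other_dist: SizeSummary) -> float:
    """Concentration of ``other`` presenting the same total cross-sectional
    area as ``ref`` at ``ref_conc``: ref_conc * <d²>_ref / <d²>_other with
    count-weighted mean squared diameters."""
    msd_ref = float(np.mean(ref_dist.diameters_um ** 2))
    msd_other = float(np.mean(other_dist.diameters_um ** 2))
    return ref_conc * msd_ref / msd_other
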