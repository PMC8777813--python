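"""Dose-response surfaces and the "best agent" map.

Calcein-uptake responses measured on a coarse (acoustic intensity x
microbubble concentration) design are interpolated per agent with a
separable cubic spline.  Both axes are taken on a log10 scale: the measured
concentrations span more than a decade and the intensities are close to
decade-spaced, so low-order splines on the logarithmic axes track the
saturating response shape where a linear intensity axis cannot.  The winning
agent (largest percent-positive) is reported per grid cell together with
its margin over the runner-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline

__all__ = ["ResponseTable", "BestAgentMap", "interpolate_surface",
           "best_agent_map"]

_COLS = ("agent", "i_spta_mw_cm2", "conc_ppml", "pct_positive", "rep")


@dataclass
class ResponseTable:
    """Long-format calcein dose-response measurements.

    Columns: agent, i_spta_mw_cm2, conc_ppml, pct_positive (0-100), rep.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLS if c not in self.data.columns]
        if missing:
            raise ValueError(f"response table missing columns {missing}")
        pct = self.data["pct_positive"]
        if ((pct < 0) | (pct > 100)).any():
            raise ValueError("pct_positive outside [0, 100]")
        for agent, grp in self.data.groupby("agent"):
            if grp["i_spta_mw_cm2"].nunique() < 2 or grp["conc_ppml"].nunique() < 2:
                raise ValueError(
                    f"agent {agent!r} needs >= 2 intensity and >= 2 "
                    "concentration levels")

    @property
    def agents(self) -> list[str]:
        return sorted(self.data["agent"].unique())

    @classmethod
    def load(cls, path: str | Path) -> "ResponseTable":
        return cls(pd.read_csv(path))

    def save(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def interpolate_surface(table: ResponseTable, agent: str,
                        intensity_grid: np.ndarray,
                        conc_grid: np.ndarray) -> np.ndarray:
    """Replicate-mean response for one agent interpolated onto a grid.

    Separable spline on (log10 intensity, log10 concentration), cubic where
    the design allows (order limited to n_levels - 1), no smoothing, clipped
    to [0, 100].  Queries outside the measured ranges are rejected.
    """
    sub = table.data[table.data["agent"] == agent]
    if sub.empty:
        raise KeyError(f"agent {agent!r} not in table")
    means = (sub.groupby(["i_spta_mw_cm2", "conc_ppml"])["pct_positive"]
             .mean().unstack())
    if means.isna().any().any():
        raise ValueError(f"agent {agent!r}: incomplete factorial design")
    ivals = np.log10(means.index.to_numpy(float))
    cvals = np.log10(means.columns.to_numpy(float))
    gi = np.log10(np.asarray(intensity_grid, float))
    gc = np.log10(np.asarray(conc_grid, float))
    if gi.min() < ivals.min() - 1e-12 or gi.max() > ivals.max() + 1e-12:
        raise ValueError("intensity grid extends outside the measured range "
                         f"[{10 ** ivals.min():g}, {10 ** ivals.max():g}] mW/cm^2")
    if gc.min() < cvals.min() - 1e-12 or gc.max() > cvals.max() + 1e-12:
        raise ValueError("concentration grid extends outside the measured range")
    kx = min(3, ivals.size - 1)
    ky = min(3, cvals.size - 1)
    spl = RectBivariateSpline(ivals, cvals, means.to_numpy(), kx=kx, ky=ky, s=0)
    return np.clip(spl(gi, gc), 0.0, 100.0)


@dataclass
class BestAgentMap:
    """Winning agent and margin per (intensity, concentration) cell."""

    intensity_grid: np.ndarray
    conc_grid: np.ndarray
    surfaces: dict                     # agent -> (ni, nc) response
    winner: np.ndarray                 # (ni, nc) object array of str
    margin: np.ndarray                 # percentage points, >= 0
    ties: np.ndarray = field(repr=False)  # (ni, nc) object array of tuples

    def save(self, path: str | Path) -> None:
        """Delimited winner grid plus a JSON legend."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("i_spta_mw_cm2,conc_ppml,winner,margin_pp\n")
            for i, iv in enumerate(self.intensity_grid):
                for j, cv in enumerate(self.conc_grid):
                    fh.write(f"{iv:g},{cv:g},{self.winner[i, j]},"
                             f"{self.margin[i, j]:.4f}\n")
        legend = {"agents": sorted(self.surfaces),
                  "n_intensity": int(self.intensity_grid.size),
                  "n_concentration": int(self.conc_grid.size)}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(legend, indent=1))


def best_agent_map(table: ResponseTable, intensity_grid: np.ndarray,
                   conc_grid: np.ndarray, tie_tol: float = 1e-9) -> BestAgentMap:
    """Per-cell argmax over the interpolated agent surfaces.

    Margin is best minus second best; exact ties (within ``tie_tol``
    percentage points) are listed, not broken by agent order.
    """
    agents = table.agents
    surfaces = {a: interpolate_surface(table, a, intensity_grid, conc_grid)
                for a in agents}
    stack = np.stack([surfaces[a] for a in agents])    # (na, ni, nc)
    order = np.argsort(-stack, axis=0, kind="stable")
    best_idx = order[0]
    best = np.take_along_axis(stack, best_idx[None], axis=0)[0]
    if len(agents) > 1:
        second = np.take_along_axis(stack, order[1][None], axis=0)[0]
    else:
        second = np.full_like(best, -np.inf)
    margin = np.where(np.isfinite(second), best - second, 0.0)

    ni, nc = best.shape
    winner = np.empty((ni, nc), dtype=object)
    ties = np.empty((ni, nc), dtype=object)
    for i in range(ni):
        for j in range(nc):
            tied = tuple(a for k, a in enumerate(agents)
                         if stack[k, i, j] >= best[i, j] - tie_tol)
            ties[i, j] = tied
            winner[i, j] = agents[best_idx[i, j]] if len(tied) == 1 \
                else "|".join(tied)
    return BestAgentMap(intensity_grid=np.asarray(intensity_grid, float),
                        conc_grid=np.asarray(conc_grid, float),
                        surfaces=surfaces, winner=winner,
                        margin=np.maximum(margin, 0.0), ties=ties)
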