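"""Constant-rate-infusion pharmacokinetics of circulating microbubbles.

One-compartment model with first-order elimination: during infusion at rate
k0 into a distribution volume Vd, the circulating concentration is

    C(t) = (k0 / CL) * (1 - exp(-ke * t)) * Cbub

with ke = 0.6931 / t_half and clearance CL = ke * Vd.  The plateau is
(k0/CL) * Cbub and is approached monotonically; "steady state" is defined as
reaching a configurable fraction of the plateau (default 99.8%, about nine
half-lives).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InfusionModel", "STEADY_STATE_FRACTION", "pump_delivered_rate"]

#: fraction of plateau defining "steady state" (~9 half-lives)
STEADY_STATE_FRACTION = 0.998

#: ln 2 as used in the elimination-rate definition
_LN2 = 0.6931

#: delivered-flow multiplier of the infusion pump fitted with a 1 mL syringe
SYRINGE_FLOW_MULTIPLIER = 0.058


@dataclass(frozen=True)
class InfusionModel:
    """Microbubble infusion into the blood pool.

    k0 : infusion rate, mL/s
    vd : volume of distribution (blood volume), mL
    t_half : circulating bubble half-life, s
    cbub : stock bubble concentration, particles/mL
    """

    k0: float
    vd: float
    t_half: float
    cbub: float

    def __post_init__(self) -> None:
        for name in ("k0", "vd", "t_half", "cbub"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_ul_per_min(cls, k0_ul_min: float, vd_ml: float, t_half_s: float,
                        cbub: float) -> "InfusionModel":
        return cls(k0=k0_ul_min / 1e3 / 60.0, vd=vd_ml, t_half=t_half_s, cbub=cbub)

    # derived rates are recomputed, never stored
    @property
    def ke(self) -> float:
        """Elimination rate constant, 1/s."""
        return _LN2 / self.t_half

    @property
    def clearance(self) -> float:
        """Clearance, mL/s."""
        return self.ke * self.vd

    @property
    def plateau(self) -> float:
        """Steady-state concentration, particles/mL."""
        return self.k0 / self.clearance * self.cbub

    def plasma_concentration(self, t) -> np.ndarray | float:
        """C(t), particles/mL; monotone non-decreasing in t (t >= 0, s)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        c = self.plateau * (1.0 - np.exp(-self.ke * t))
        return float(c) if c.ndim == 0 else c

    def time_to_fraction(self, fraction: float = STEADY_STATE_FRACTION) -> float:
        """Time (s) to reach a given fraction of the plateau:
        t = -ln(1 - fraction) / ke."""
        if not 0.0 < fraction < 1.0:
            raise ValueError("fraction must lie strictly inside (0, 1)")
        return float(-np.log(1.0 - fraction) / self.ke)

    def concentration_window(self, t_start: float, t_end: float) -> tuple[float, float]:
        """(C(t_start), C(t_end)) — min and max over the window, by
        monotonicity."""
        if not 0 <= t_start < t_end:
            raise ValueError("need 0 <= t_start < t_end")
        return (self.plasma_concentration(t_start),
                self.plasma_concentration(t_end))


def pump_delivered_rate(pump_setting_ml_min: float,
                        multiplier: float = SYRINGE_FLOW_MULTIPLIER) -> int:
    """Actual delivered rate in µL/min for a pump setting in mL/min.

    The oscillating perfusion pump fitted with a 1 mL syringe delivers
    ``multiplier`` times the set rate; the result is rounded to the nearest
    integer µL/min for reporting.
    """
    return int(round(pump_setting_ml_min * multiplier * 1e3))
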