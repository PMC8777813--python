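"""Shell and medium parameter sets for the three clinical contrast agents.

The shipped defaults are literature physicochemical properties of
SonoVue (lipid-shelled SF6), Sonazoid (lipid-shelled C4F10) and Optison
(albumin-shelled C3F8), with mouse blood as the surrounding fluid.

Ambient pressure, vapour pressure (water at 37 degC) and blood sound speed
are declared assumptions, overridable per instance or via a JSON parameter
file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

__all__ = ["ShellParameters", "Medium", "AGENTS", "MOUSE_BLOOD",
           "load_agents", "dump_agents"]


@dataclass(frozen=True)
class ShellParameters:
    """Physicochemical constants of an encapsulated microbubble.

    chi    -- shell stiffness (N/m), restoring term 2*chi*(1/R0 - 1/R)
    gamma  -- polytropic exponent of the core gas (dimensionless)
    sigma  -- interfacial tension (N/m)
    kappa  -- gas compressibility (m^2/N); stored for reference, not used
              by the dynamic model
    """

    name: str
    chi: float
    gamma: float
    sigma: float
    kappa: float | None = None

    def __post_init__(self) -> None:
        if self.chi < 0:
            raise ValueError("shell stiffness chi must be >= 0")
        if self.gamma < 1:
            raise ValueError("specific heat ratio gamma must be >= 1")
        if self.sigma < 0:
            raise ValueError("interfacial tension sigma must be >= 0")


@dataclass(frozen=True)
class Medium:
    """Surrounding-fluid constants.

    rho -- density (kg/m^3); mu -- dynamic viscosity (Pa s);
    c -- sound speed (m/s); p0 -- ambient pressure (Pa);
    pv -- vapour pressure (Pa).
    """

    rho: float = 1057.0
    mu: float = 5.996e-3
    c: float = 1570.0
    p0: float = 101_325.0
    pv: float = 6_267.0

    def __post_init__(self) -> None:
        for name in ("rho", "mu", "c", "p0", "pv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"medium parameter {name} must be > 0")

    def with_(self, **kw) -> "Medium":
        return replace(self, **kw)


#: mouse blood at 37 degC
MOUSE_BLOOD = Medium()

#: shipped agent defaults
AGENTS: dict[str, ShellParameters] = {
    "SonoVue": ShellParameters("SonoVue", chi=0.22, gamma=1.0934,
                               sigma=0.052, kappa=9.173e-6),
    "Sonazoid": ShellParameters("Sonazoid", chi=0.53, gamma=1.0699,
                                sigma=0.042, kappa=6.537e-6),
    "Optison": ShellParameters("Optison", chi=4.00, gamma=1.0731,
                               sigma=0.9, kappa=7.458e-6),
}


def load_agents(path: str | Path) -> dict[str, ShellParameters]:
    """Read a JSON agent parameter file: {name: {chi, gamma, sigma[, kappa]}}."""
    data = json.loads(Path(path).read_text())
    out = {}
    for name, d in data.items():
        out[name] = ShellParameters(name=name, chi=d["chi"], gamma=d["gamma"],
                                    sigma=d["sigma"], kappa=d.get("kappa"))
    return out


def dump_agents(agents: dict[str, ShellParameters], path: str | Path) -> None:
    data = {
        n: {"chi": a.chi, "gamma": a.gamma, "sigma": a.sigma, "kappa": a.kappa}
        for n, a in agents.items()
    }
    Path(path).write_text(json.dumps(data, indent=1))
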