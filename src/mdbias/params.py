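"""Physiological and probe parameters with unit handling.

All model mathematics runs in strict SI (m, s, mol·m⁻³).  Conventional
physiological units (mL/100 mL/min for perfusion, µmol/100 mL/min for
metabolic rate, mM for concentration) are accepted only at the I/O boundary
through :func:`to_si` / :func:`from_si`.  mM and mol·m⁻³ are numerically
identical and treated as the same unit.

Defaults are the basal resting-muscle values used throughout the model:
arterial glucose 5 mM, blood flow 4 mL/100 mL/min, glucose uptake
0.8 µmol/100 mL/min, an endothelial diffusion coefficient of
4.50e-14 m²/s calibrated against tracer equilibration kinetics, and a
16 mm × 0.5 mm microdialysis probe perfused at 2 µL/min (3.33e-11 m³/s)
with 50% relative recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "PhysiologyParams",
    "ProbeParams",
    "TracerParams",
    "to_si",
    "from_si",
    "derived_beta",
    "derived_cv",
    "load_config",
]

# conversion factors: conventional -> SI
_FLOW = 1.0 / (100.0 * 60.0)            # mL/100mL/min -> s^-1
_METABOLISM = 1e-6 / (1e-4 * 60.0)      # umol/100mL/min -> mol m^-3 s^-1

_KINDS = {"flow": _FLOW, "metabolism": _METABOLISM, "concentration": 1.0}


def to_si(value: float, kind: str) -> float:
    """Convert a conventional-unit quantity to SI.

    ``flow``: mL/100 mL/min → s⁻¹; ``metabolism``: µmol/100 mL/min →
    mol·m⁻³·s⁻¹; ``concentration``: mM → mol·m⁻³ (identity).
    """
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {value!r}")
    try:
        factor = _KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown unit kind {kind!r}; expected one of {sorted(_KINDS)}"
        ) from None
    return value * factor


def from_si(value: float, kind: str) -> float:
    """Inverse of :func:`to_si` (exact round trip)."""
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {value!r}")
    try:
        factor = _KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown unit kind {kind!r}; expected one of {sorted(_KINDS)}"
        ) from None
    return value / factor


@dataclass(frozen=True)
class PhysiologyParams:
    """Tissue-side parameters, stored in SI.

    Parameters
    ----------
    F : float
        Blood flow per tissue volume, s⁻¹ (basal: 4 mL/100 mL/min).
    M : float
        Glucose metabolism per tissue volume, mol·m⁻³·s⁻¹
        (basal: 0.8 µmol/100 mL/min).
    Ca : float
        Arterial glucose concentration, mM (≡ mol·m⁻³).
    Vi : float
        Interstitial volume fraction (dimensionless).
    Di, Dp, Dw : float
        Glucose diffusion coefficients of interstitial fluid, plasma and
        endothelium, m²·s⁻¹.
    rp, rw : float
        Capillary plasma radius and outer wall radius, m.
    rt_a, rt_v : float
        Tissue cone radii at the arterial and venous ends, m.
    """

    F: float = to_si(4.0, "flow")
    M: float = to_si(0.8, "metabolism")
    Ca: float = 5.0
    Vi: float = 0.2
    Di: float = 9.2e-10
    Dp: float = 9.2e-10
    Dw: float = 4.50e-14
    rp: float = 2.5e-6
    rw: float = 3.1e-6
    rt_a: float = 28e-6
    rt_v: float = 22e-6

    def __post_init__(self) -> None:
        for name in ("F", "M", "Ca", "Vi", "Di", "Dp", "Dw", "rp", "rw",
                     "rt_a", "rt_v"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not self.rp < self.rw < self.rt_v <= self.rt_a:
            raise ValueError(
                "radii must satisfy rp < rw < rt_v <= rt_a, got "
                f"rp={self.rp}, rw={self.rw}, rt_v={self.rt_v}, rt_a={self.rt_a}"
            )
        if self.Vi > 1:
            raise ValueError(f"Vi must be <= 1, got {self.Vi}")

    @property
    def rt_mid(self) -> float:
        """Representative (axially averaged) tissue cone radius, m."""
        return 0.5 * (self.rt_a + self.rt_v)

    @property
    def Cv(self) -> float:
        """Venous concentration from the steady mass balance, mM."""
        return derived_cv(self)

    @classmethod
    def from_conventional(cls, *, F: float | None = None, M: float | None = None,
                          **kwargs: float) -> "PhysiologyParams":
        """Build from flow in mL/100 mL/min and metabolism in µmol/100 mL/min."""
        if F is not None:
            kwargs["F"] = to_si(F, "flow")
        if M is not None:
            kwargs["M"] = to_si(M, "metabolism")
        return cls(**kwargs)

    def with_(self, **kwargs: float) -> "PhysiologyParams":
        """Copy with selected fields replaced (SI values)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ProbeParams:
    """Microdialysis probe geometry, perfusion and recovery.

    ``R0`` is the true relative recovery, ``f`` the perfusate flow (m³/s),
    ``L`` the membrane length (m), ``r1`` the probe radius (m) and ``Cp``
    the glucose concentration of the perfusate (mM).
    """

    R0: float = 0.5
    # 2 uL/min; the tabulated 3.33e-11 m3/s is this value rounded
    f: float = 2e-9 / 60.0
    L: float = 16e-3
    r1: float = 250e-6
    Cp: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.R0 <= 1):
            raise ValueError(f"R0 must be in (0, 1], got {self.R0}")
        for name in ("f", "L", "r1"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.Cp < 0:
            raise ValueError(f"Cp must be non-negative, got {self.Cp}")

    @property
    def S_probe(self) -> float:
        """Membrane exchange surface 2π·r1·L, m²."""
        return 2.0 * math.pi * self.r1 * self.L

    @property
    def beta(self) -> float:
        """Mass-transfer coefficient β = R0·f/S_probe, m·s⁻¹."""
        return derived_beta(self)

    def with_(self, **kwargs: float) -> "ProbeParams":
        return replace(self, **kwargs)

    def with_beta_multiplier(self, c: float) -> "ProbeParams":
        """Scale β by ``c`` via the perfusate flow (β depends only on R0·f)."""
        if c <= 0:
            raise ValueError("beta multiplier must be positive")
        return replace(self, f=self.f * c)


@dataclass(frozen=True)
class TracerParams:
    """Glucose tracer added to the perfusate for internal-reference calibration."""

    Cp_star: float = 1.0
    include_metabolism_term: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Cp_star) and self.Cp_star > 0):
            raise ValueError(f"Cp_star must be strictly positive, got {self.Cp_star}")


def derived_beta(probe: ProbeParams) -> float:
    """β = R0·f/(2π·r1·L) in m·s⁻¹ (≈6.63e-7 for the default probe)."""
    return probe.R0 * probe.f / (2.0 * math.pi * probe.r1 * probe.L)


def derived_cv(phys: PhysiologyParams, measured: float | None = None,
               rtol: float = 0.05) -> float:
    """Venous glucose concentration Cv = Ca − M/F from the steady mass balance.

    If ``measured`` is given, the derived value is validated against it to
    relative tolerance ``rtol``.
    """
    extraction = phys.M / phys.F
    if extraction >= phys.Ca:
        raise ValueError(
            f"complete extraction exceeded: M/F = {extraction:.3g} mM >= Ca = {phys.Ca} mM"
        )
    cv = phys.Ca - extraction
    if measured is not None and abs(cv - measured) > rtol * measured:
        raise ValueError(
            f"derived Cv = {cv:.4g} mM inconsistent with measured {measured:.4g} mM"
        )
    return cv


_PHYS_KEYS = {
    # config key -> (dataclass field, unit kind or None for SI/dimensionless)
    "F": ("F", "flow"),
    "M": ("M", "metabolism"),
    "Ca": ("Ca", None),
    "Vi": ("Vi", None),
    "Di": ("Di", None),
    "Dp": ("Dp", None),
    "Dw": ("Dw", None),
    "rp": ("rp", None),
    "rw": ("rw", None),
    "rt_a": ("rt_a", None),
    "rt_v": ("rt_v", None),
}
_PROBE_KEYS = {"R": "R0", "R0": "R0", "f": "f", "L": "L", "r1": "r1", "Cp": "Cp"}


def load_config(path: str | Path) -> tuple[PhysiologyParams, ProbeParams]:
    """Load a YAML/JSON config with ``physiology`` and ``probe`` sections.

    Keys are named after the model symbols; flow and metabolism are given in
    conventional units (mL/100 mL/min, µmol/100 mL/min), everything else in
    SI / mM.  Unknown keys raise ``ValueError``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg: dict[str, Any] = json.loads(text)
    else:
        cfg = yaml.safe_load(text) or {}
    unknown_sections = set(cfg) - {"physiology", "probe"}
    if unknown_sections:
        raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")

    phys_kwargs: dict[str, float] = {}
    for key, value in (cfg.get("physiology") or {}).items():
        if key not in _PHYS_KEYS:
            raise ValueError(f"unknown physiology key {key!r}")
        fld, kind = _PHYS_KEYS[key]
        phys_kwargs[fld] = to_si(float(value), kind) if kind else float(value)

    probe_kwargs: dict[str, float] = {}
    for key, value in (cfg.get("probe") or {}).items():
        if key not in _PROBE_KEYS:
            raise ValueError(f"unknown probe key {key!r}")
        probe_kwargs[_PROBE_KEYS[key]] = float(value)

    return PhysiologyParams(**phys_kwargs), ProbeParams(**probe_kwargs)
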