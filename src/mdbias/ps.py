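"""Apparent endothelial permeability–surface area (PS) product.

The Renkin–Crone expression infers an exchange capacity from flow and the
arterial, venous and interstitial concentrations:

    PS = −F·ln[(Cv − Ci)/(Ca − Ci)]

in s⁻¹ (≡ mL·mL⁻¹·s⁻¹).  It is strictly increasing in the interstitial
concentration Ci on (0, Cv): underestimating the IGC therefore
underestimates PS.  ``ps_measured`` applies the microdialysis bias map
Ci,0 → Ci,eff before evaluating the expression, giving the PS value an
experiment relying on microdialysis IGC would report; because the bias is
relatively larger at rest than under high-metabolism conditions, the biased
PS_m rises more steeply between conditions than the true PS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import PhysiologyParams, ProbeParams, derived_cv
from .steady import solve_steady

__all__ = ["PSResult", "ps_true", "ps_measured", "format_ps"]


@dataclass(frozen=True)
class PSResult:
    """PS product (s⁻¹) with the inputs it was computed from."""

    ps: float
    variant: str  # "true" | "measured"
    F: float
    Ca: float
    Cv: float
    Ci: float

    @property
    def ps_conventional(self) -> float:
        """PS in units of 1e-4 mL/mL/s (the scale typical of muscle glucose)."""
        return self.ps / 1e-4

    def summary(self) -> dict:
        return {"variant": self.variant, "ps_per_s": self.ps,
                "ps_1e-4_mL_per_mL_s": self.ps_conventional,
                "F_per_s": self.F, "Ca_mM": self.Ca, "Cv_mM": self.Cv,
                "Ci_mM": self.Ci}


def ps_true(F: float, Ca: float, Cv: float, Ci: float,
            variant: str = "true") -> PSResult:
    """PS = −F·ln[(Cv−Ci)/(Ca−Ci)]; F in s⁻¹, concentrations in mM.

    Raises for Ci ≥ Cv ("elevated extraction"), where the logarithm is
    undefined and the single-barrier model cannot assign a finite PS.
    """
    if Ca <= Cv:
        raise ValueError(f"arterial concentration must exceed venous (Ca={Ca}, Cv={Cv})")
    if Ci >= Cv:
        raise ValueError(
            f"elevated extraction: Ci={Ci} mM >= Cv={Cv} mM, PS undefined"
        )
    if Ci < 0:
        raise ValueError("Ci must be non-negative")
    ratio = (Cv - Ci) / (Ca - Ci)
    return PSResult(ps=-F * math.log(ratio), variant=variant, F=F, Ca=Ca,
                    Cv=Cv, Ci=Ci)


def ps_measured(phys: PhysiologyParams, probe: ProbeParams,
                Ci0: float) -> PSResult:
    """PS as it would be inferred from a microdialysis-biased IGC.

    Maps Ci,0 to Ci,eff through the steady bias model, then applies the
    Renkin–Crone expression with the biased concentration.
    """
    sol = solve_steady(phys, probe, Ci0)
    cv = derived_cv(phys)
    return ps_true(phys.F, phys.Ca, cv, sol.Ci_eff, variant="measured")


def format_ps(result: PSResult) -> str:
    """Human-readable PS in ×10⁻⁴ mL/mL/s."""
    return f"{result.ps_conventional:.3g}e-4 mL/mL/s ({result.variant})"
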