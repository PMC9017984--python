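"""Steady-state interstitial glucose field around a microdialysis probe.

The probe (an infinite cylinder of radius r1 and membrane length L) removes
glucose at rate R0·f·(Ci(r1) − Cp).  On the tissue scale the capillary bed
acts as a distributed source that resupplies the deficit Ci,0 − Ci(r) with a
first-order rate constant 1/A, where the resupply timescale

    A = 1/(2F) + (rt² − rw²)·ln(rw/rp)/(2·Dw)

combines the fall in plasma concentration from the extra extraction (1/(2F))
with the extra trans-endothelial gradient (wall term).  The field obeys the
modified Helmholtz equation

    Di·Vi·(1/r)·d/dr(r·dCi/dr) = (Ci − Ci,0)/A

with a Robin condition at the probe wall, Di·Vi·dCi/dr|r1 = β·(Ci(r1) − Cp),
β = R0·f/S_probe, and Ci → Ci,0 far away.  The decaying axisymmetric
solution is Ci(r) = Ci,0 + B·K0(r/λ) with screening length λ = √(Di·Vi·A);
the modified Bessel closed form is the primary solution path, and a
finite-difference discretisation on a log-spaced grid is kept as an
independent numerical oracle.

By linearity, the probe-wall deficit is proportional to the driving
difference: Ci,0 − Ci,eff = α·(Ci,0 − Cp), with α depending only on probe
and tissue parameters — so one solve characterises the bias for any
(Ci,0, Cp) pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.special import k0, k1

from .params import PhysiologyParams, ProbeParams

__all__ = [
    "SinkTimescale",
    "BiasSolution",
    "sink_timescale",
    "solve_steady",
    "solve_steady_fd",
    "alpha",
    "bias_curve",
    "field_map",
]

ISOCONTOUR_LEVELS = (0.99, 0.95, 0.90, 0.80, 0.70)


@dataclass(frozen=True)
class SinkTimescale:
    """Capillary resupply timescale A (s) and screening length λ (m).

    ``plasma_part`` = 1/(2F) and ``wall_part`` = (rt²−rw²)·ln(rw/rp)/(2·Dw)
    are the contributions of the plasma-concentration drop and of the extra
    endothelial gradient; A is their sum.
    """

    plasma_part: float
    wall_part: float
    diffusivity: float  # effective Di*Vi, m^2/s

    @property
    def A(self) -> float:
        return self.plasma_part + self.wall_part

    @property
    def screening_length(self) -> float:
        return float(np.sqrt(self.diffusivity * self.A))


def sink_timescale(phys: PhysiologyParams, rt: float | None = None) -> SinkTimescale:
    """Resupply timescale of the distributed capillary source (basal ≈2.2e3 s)."""
    if rt is None:
        rt = phys.rt_mid
    plasma = 1.0 / (2.0 * phys.F)
    wall = (rt * rt - phys.rw ** 2) * np.log(phys.rw / phys.rp) / (2.0 * phys.Dw)
    return SinkTimescale(plasma_part=plasma, wall_part=float(wall),
                         diffusivity=phys.Di * phys.Vi)


@dataclass(frozen=True)
class BiasSolution:
    """Steady radial field around the probe and derived bias quantities.

    Attributes
    ----------
    r : ndarray
        Radial grid from the probe wall r1 outward, m.
    Ci : ndarray
        Interstitial glucose concentration on ``r``, mM.
    Ci0, Cp : float
        Far-field interstitial and perfusate concentrations, mM.
    alpha : float
        Bias amplitude; Ci,0 − Ci,eff = α·(Ci,0 − Cp).
    Ci_eff : float
        Effective concentration at the probe wall Ci(r1), mM.
    removal_rate : float
        Probe glucose removal R0·f·(Ci_eff − Cp), mol·s⁻¹.
    flux_r1 : float
        Diffusive flux density into the probe at r1, mol·m⁻²·s⁻¹.
    timescale : SinkTimescale
    probe : ProbeParams
    """

    r: np.ndarray
    Ci: np.ndarray
    Ci0: float
    Cp: float
    alpha: float
    Ci_eff: float
    removal_rate: float
    flux_r1: float
    timescale: SinkTimescale
    probe: ProbeParams

    @property
    def relative_underestimation(self) -> float:
        """(Ci,0 − Ci,eff)/Ci,0, dimensionless."""
        return (self.Ci0 - self.Ci_eff) / self.Ci0

    def gamma(self) -> np.ndarray:
        """Local capillary resupply rate γ(r) = (Ci,0 − Ci(r))/A, mol·m⁻³·s⁻¹."""
        return (self.Ci0 - self.Ci) / self.timescale.A

    def summary(self) -> dict:
        return {
            "Ci0_mM": self.Ci0,
            "Cp_mM": self.Cp,
            "alpha": self.alpha,
            "ci_eff_mM": self.Ci_eff,
            "relative_underestimation_pct": 100.0 * self.relative_underestimation,
            "removal_rate_mol_per_s": self.removal_rate,
            "screening_length_m": self.timescale.screening_length,
            "sink_timescale_s": self.timescale.A,
        }


def _check_converged(phys: PhysiologyParams, probe: ProbeParams, r2: float,
                     lam: float) -> None:
    # K0 decays like exp(-r/lam): r2 must leave a negligible tail
    if r2 / lam < 8.0:
        raise ValueError(
            f"outer boundary r2={r2:.3g} m too small: solution not converged "
            f"(r2/lambda = {r2 / lam:.2f} < 8); increase r2"
        )


def solve_steady(phys: PhysiologyParams, probe: ProbeParams, Ci0: float,
                 r2: float | None = None, n: int = 400,
                 rt: float | None = None) -> BiasSolution:
    """Solve the steady probe-bias problem via the modified Bessel closed form.

    Parameters
    ----------
    phys, probe : parameter sets.
    Ci0 : float
        Unperturbed far-field interstitial concentration, mM.
    r2 : float, optional
        Outer boundary where Ci = Ci,0 is imposed; default 50·r1 with a
        convergence check that the screened tail is negligible there.
    n : int
        Number of (log-spaced) radial output nodes.
    rt : float, optional
        Tissue radius in the sink term; defaults to the cone midpoint.
    """
    if Ci0 < 0 or probe.Cp < 0:
        raise ValueError("concentrations must be non-negative")
    ts = sink_timescale(phys, rt)
    lam = ts.screening_length
    if r2 is None:
        r2 = 50.0 * probe.r1
    _check_converged(phys, probe, r2, lam)

    beta = probe.beta
    DiVi = phys.Di * phys.Vi
    r1 = probe.r1
    # Ci(r) = Ci0 + B K0(r/lam); Robin: DiVi dCi/dr|r1 = beta (Ci(r1) - Cp)
    # dCi/dr = -B K1(r/lam)/lam
    # => -DiVi B K1(x1)/lam = beta (Ci0 - Cp + B K0(x1))
    x1 = r1 / lam
    B = -beta * (Ci0 - probe.Cp) / (DiVi * k1(x1) / lam + beta * k0(x1))

    r = np.geomspace(r1, r2, n)
    Ci = Ci0 + B * k0(r / lam)
    Ci_eff = float(Ci[0])
    denom = Ci0 - probe.Cp
    a = (Ci0 - Ci_eff) / denom if denom != 0 else 0.0
    if np.any(Ci < 0):
        warnings.warn(
            "steady bias field goes negative: the linear resupply model is "
            "outside its validity range for these parameters",
            RuntimeWarning, stacklevel=2,
        )
    removal = probe.R0 * probe.f * (Ci_eff - probe.Cp)
    flux = removal / probe.S_probe
    return BiasSolution(r=r, Ci=Ci, Ci0=Ci0, Cp=probe.Cp, alpha=float(a),
                        Ci_eff=Ci_eff, removal_rate=float(removal),
                        flux_r1=float(flux), timescale=ts, probe=probe)


def solve_steady_fd(phys: PhysiologyParams, probe: ProbeParams, Ci0: float,
                    r2: float | None = None, n: int = 3000,
                    rt: float | None = None) -> BiasSolution:
    """Finite-difference solution of the same problem (independent oracle).

    Conservative finite-volume discretisation of
    Di·Vi·(1/r)(r·Ci')' = (Ci − Ci,0)/A on a log-spaced grid with the Robin
    condition at r1 and Ci(r2) = Ci,0.  Used to validate the Bessel closed
    form; not the primary solution path.
    """
    if Ci0 < 0 or probe.Cp < 0:
        raise ValueError("concentrations must be non-negative")
    ts = sink_timescale(phys, rt)
    lam = ts.screening_length
    if r2 is None:
        r2 = 50.0 * probe.r1
    _check_converged(phys, probe, r2, lam)

    DiVi = phys.Di * phys.Vi
    beta = probe.beta
    r = np.geomspace(probe.r1, r2, n)
    # faces between nodes
    rf = np.sqrt(r[:-1] * r[1:])
    dr = np.diff(r)
    # control volume of node i: [rf[i-1], rf[i]]
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    rhs = np.full(n, 0.0)
    vol = np.empty(n)
    vol[0] = 0.5 * (rf[0] ** 2 - r[0] ** 2)
    vol[1:-1] = 0.5 * (rf[1:] ** 2 - rf[:-1] ** 2)
    vol[-1] = 0.5 * (r[-1] ** 2 - rf[-1] ** 2)

    # interior flux coefficients: F_i+1/2 = DiVi * rf * (C[i+1]-C[i])/dr
    cond = DiVi * rf / dr
    for i in range(1, n - 1):
        main[i] = -(cond[i - 1] + cond[i]) - vol[i] * DiVi / lam ** 2
        lower[i - 1] = cond[i - 1]
        upper[i] = cond[i]
        rhs[i] = -vol[i] * DiVi / lam ** 2 * Ci0
    # node 0: Robin. inward face flux = r1 * beta (C0 - Cp)
    main[0] = -cond[0] - vol[0] * DiVi / lam ** 2 - r[0] * beta
    upper[0] = cond[0]
    rhs[0] = -vol[0] * DiVi / lam ** 2 * Ci0 - r[0] * beta * probe.Cp
    # node n-1: Dirichlet
    main[-1] = 1.0
    lower[-1] = 0.0
    rhs[-1] = Ci0

    A = sparse.diags([lower, main, upper], [-1, 0, 1], format="csc")
    Ci = spsolve(A, rhs)
    Ci_eff = float(Ci[0])
    denom = Ci0 - probe.Cp
    a = (Ci0 - Ci_eff) / denom if denom != 0 else 0.0
    removal = probe.R0 * probe.f * (Ci_eff - probe.Cp)
    return BiasSolution(r=r, Ci=Ci, Ci0=Ci0, Cp=probe.Cp, alpha=float(a),
                        Ci_eff=Ci_eff, removal_rate=float(removal),
                        flux_r1=float(removal / probe.S_probe), timescale=ts,
                        probe=probe)


def alpha(phys: PhysiologyParams, probe: ProbeParams,
          rt: float | None = None) -> float:
    """Bias amplitude α from a single solve (independent of the Ci,0/Cp pair)."""
    sol = solve_steady(phys, probe, Ci0=probe.Cp + 1.0, rt=rt)
    return sol.alpha


def bias_curve(phys: PhysiologyParams, probe: ProbeParams, Ci0_grid,
               rt: float | None = None):
    """Bias curve over a grid of true concentrations.

    Returns a dict of arrays ``Ci0``, ``Ci_eff`` and ``underestimation_pct``
    (the line Ci_eff = (1−α)·Ci0 + α·Cp through (Cp, Cp)).
    """
    Ci0_grid = np.asarray(Ci0_grid, dtype=float)
    a = alpha(phys, probe, rt=rt)
    Ci_eff = (1.0 - a) * Ci0_grid + a * probe.Cp
    with np.errstate(divide="ignore", invalid="ignore"):
        under = np.where(Ci0_grid > 0,
                         100.0 * (Ci0_grid - Ci_eff) / Ci0_grid, 0.0)
    return {"Ci0": Ci0_grid, "Ci_eff": Ci_eff, "underestimation_pct": under,
            "alpha": a}


def field_map(phys: PhysiologyParams, probe: ProbeParams, Ci0: float,
              extent: float | None = None, n: int = 201,
              levels=ISOCONTOUR_LEVELS):
    """Axisymmetric 2-D expansion of the radial solution with isocontour radii.

    Returns ``(x, y, C, contours)`` where ``C[i, j]`` is the concentration at
    (x[j], y[i]) on a square grid of half-width ``extent`` (default 2 mm)
    centred on the probe (NaN inside the probe), and ``contours`` maps each
    requested fraction of Ci,0 to the radius (m) at which Ci first reaches
    it, or None when the level lies below Ci_eff/Ci,0 (contour absent).
    """
    if extent is None:
        extent = 2e-3
    sol = solve_steady(phys, probe, Ci0, r2=max(50.0 * probe.r1, 4.0 * extent))
    x = np.linspace(-extent, extent, n)
    y = np.linspace(-extent, extent, n)
    X, Y = np.meshgrid(x, y)
    Rg = np.hypot(X, Y)
    C = np.full_like(Rg, np.nan)
    outside = Rg >= probe.r1
    C[outside] = np.interp(Rg[outside], sol.r, sol.Ci, right=Ci0)

    contours: dict[float, float | None] = {}
    frac = sol.Ci / Ci0 if Ci0 > 0 else np.ones_like(sol.Ci)
    for level in levels:
        if frac[0] > level:
            contours[level] = None  # field never drops to this level
        else:
            idx = np.searchsorted(frac, level)  # frac increases with r
            contours[level] = float(np.interp(level, frac[max(idx - 1, 0):idx + 1],
                                              sol.r[max(idx - 1, 0):idx + 1]))
    return x, y, C, contours
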