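"""Named scenarios, figure-data reproduction and fixture sweeps.

A :class:`Scenario` bundles physiology overrides, probe overrides and a
metabolism multiplier into a reproducible parameter set.  The immutable
presets cover the basal resting state, the four interstitial-concentration
quarters of the probe-field illustration, a 15-fold hyperinsulinemic
metabolism increase, and the Gudbjörnsdóttir-style probe (R=0.3,
f=4.17e-11 m³/s, Cp=1.5 mM) used as a literature-comparison demonstrator
(its per-condition flow and metabolism are study inputs the user must
supply).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import compartment, steady, transient
from .params import PhysiologyParams, ProbeParams, to_si

__all__ = ["Scenario", "PRESETS", "get_scenario", "run_scenario",
           "reproduce", "generate_fixtures"]


@dataclass(frozen=True)
class Scenario:
    """A fully resolvable parameter set for one model run."""

    name: str
    description: str = ""
    physiology: Mapping[str, float] = field(default_factory=dict)
    probe: Mapping[str, float] = field(default_factory=dict)
    metabolism_multiplier: float = 1.0
    Ci0: float | None = None  # override; default = compartment-model value

    def resolve(self) -> tuple[PhysiologyParams, ProbeParams, float]:
        """Materialise (PhysiologyParams, ProbeParams, Ci0)."""
        phys = PhysiologyParams(**dict(self.physiology))
        if self.metabolism_multiplier != 1.0:
            phys = phys.with_(M=phys.M * self.metabolism_multiplier)
        probe = ProbeParams(**dict(self.probe))
        ci0 = self.Ci0 if self.Ci0 is not None else compartment.igc_quick_estimate(phys)
        return phys, probe, ci0

    def metadata(self) -> dict:
        phys, probe, ci0 = self.resolve()
        return {"scenario": self.name, "description": self.description,
                "F_per_s": phys.F, "M_mol_m3_s": phys.M, "Ca_mM": phys.Ca,
                "Dw_m2_s": phys.Dw, "R0": probe.R0, "f_m3_s": probe.f,
                "Cp_mM": probe.Cp, "beta_m_s": probe.beta, "Ci0_mM": ci0}


def _freeze(d: dict) -> Mapping[str, float]:
    return MappingProxyType(dict(d))


PRESETS: Mapping[str, Scenario] = MappingProxyType({
    "basal": Scenario("basal", "Resting muscle, basal insulin; default probe."),
    # quarters of the probe-field illustration: same flow, rising metabolism
    # (illustrative multipliers spanning resting to insulin-stimulated states)
    "figure1-quarter-A": Scenario("figure1-quarter-A",
                                  "Resting metabolism (M0).", metabolism_multiplier=1.0),
    "figure1-quarter-B": Scenario("figure1-quarter-B",
                                  "Moderately elevated metabolism (3x M0).",
                                  metabolism_multiplier=3.0),
    "figure1-quarter-C": Scenario("figure1-quarter-C",
                                  "Elevated metabolism (5x M0).",
                                  metabolism_multiplier=5.0),
    "figure1-quarter-D": Scenario("figure1-quarter-D",
                                  "Strongly elevated metabolism (7x M0).",
                                  metabolism_multiplier=7.0),
    "hyperinsulinemia-15x": Scenario("hyperinsulinemia-15x",
                                     "15-fold metabolic increase at unchanged flow.",
                                     metabolism_multiplier=15.0),
    "gudbjornsdottir-probe": Scenario(
        "gudbjornsdottir-probe",
        "Literature probe demonstrator: R=0.3, f=4.17e-11 m3/s, Cp=1.5 mM; "
        "per-condition flow/metabolism must be supplied by the user.",
        probe=_freeze({"R0": 0.3, "f": 4.17e-11, "Cp": 1.5})),
})


def get_scenario(name: str, **overrides: Any) -> Scenario:
    """Fetch a preset by name, optionally with field overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"presets: {sorted(PRESETS)}") from None
    if not overrides:
        return base
    data = {"name": base.name, "description": base.description,
            "physiology": dict(base.physiology), "probe": dict(base.probe),
            "metabolism_multiplier": base.metabolism_multiplier,
            "Ci0": base.Ci0}
    data.update(overrides)
    return Scenario(**data)


def _metadata_header(meta: dict) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in meta.items())


def run_scenario(scenario: Scenario, outputs=("steady",),
                 out_dir: str | Path | None = None) -> dict:
    """Run the requested computations for a scenario.

    ``outputs`` may contain ``steady``, ``transient``, ``compartment`` and
    ``ps``; returns a dict of result objects/tables and, when ``out_dir`` is
    given, writes CSV/JSON files carrying the resolved parameters as header
    metadata.  Requesting ``ps`` for a scenario whose venous concentration
    cannot be derived raises with the missing inputs listed.
    """
    phys, probe, ci0 = scenario.resolve()
    meta = scenario.metadata()
    results: dict[str, Any] = {"metadata": meta}
    for kind in outputs:
        if kind == "steady":
            results["steady"] = steady.solve_steady(phys, probe, ci0)
        elif kind == "transient":
            results["transient"] = transient.solve_transient(phys, probe, ci0)
        elif kind == "compartment":
            xi = np.linspace(0.0, 1.0, 101)
            results["compartment"] = pd.DataFrame({
                "xi": xi,
                "C_plasma_mM": compartment.axial_plasma_profile(xi, phys),
                "rt_m": compartment.cone_radius(xi, phys),
            })
        elif kind == "ps":
            from .ps import ps_measured, ps_true
            from .params import derived_cv
            missing = []
            try:
                cv = derived_cv(phys)
            except ValueError as exc:
                raise ValueError(f"scenario incomplete for PS: {exc}") from exc
            results["ps"] = {"true": ps_true(phys.F, phys.Ca, cv, ci0),
                             "measured": ps_measured(phys, probe, ci0)}
        else:
            raise ValueError(f"unknown output kind {kind!r}")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = _metadata_header(meta)
        if "steady" in results:
            sol = results["steady"]
            df = pd.DataFrame({"r_m": sol.r, "Ci_mM": sol.Ci})
            path = out_dir / f"{scenario.name}_steady.csv"
            path.write_text(header + df.to_csv(index=False,
                                               float_format="%.6g"))
            (out_dir / f"{scenario.name}_steady.json").write_text(
                json.dumps(sol.summary(), indent=2))
        if "transient" in results:
            sol = results["transient"]
            df = pd.DataFrame({"t_s": sol.t, "Ci_eff_mM": sol.Ci_eff,
                               "alpha_t": sol.alpha_t})
            path = out_dir / f"{scenario.name}_transient.csv"
            path.write_text(header + df.to_csv(index=False,
                                               float_format="%.6g"))
        if "compartment" in results:
            path = out_dir / f"{scenario.name}_compartment.csv"
            path.write_text(header + results["compartment"].to_csv(
                index=False, float_format="%.6g"))
        if "ps" in results:
            (out_dir / f"{scenario.name}_ps.json").write_text(json.dumps(
                {k: v.summary() for k, v in results["ps"].items()}, indent=2))
    return results


def reproduce(figure_id: str, out_dir: str | Path | None = None) -> dict:
    """Recompute the numeric data behind the headline figures/examples.

    ``figure_id`` ∈ {fig1, fig2, fig3, fig6, worked-examples}.  Returns the
    data as DataFrames / dicts and optionally writes CSV/JSON.
    """
    phys = PhysiologyParams()
    probe = ProbeParams()
    out: dict[str, Any] = {}
    if figure_id == "fig1":
        rows = []
        for q in ("A", "B", "C", "D"):
            sc = PRESETS[f"figure1-quarter-{q}"]
            p, pr, ci0 = sc.resolve()
            _, _, _, contours = steady.field_map(p, pr, ci0)
            for level, radius in contours.items():
                rows.append({"quarter": q, "Ci0_mM": ci0, "level": level,
                             "contour_radius_m": radius})
        out["data"] = pd.DataFrame(rows)
    elif figure_id == "fig2":
        grid = np.linspace(probe.Cp, 8.0, 61)
        curve = steady.bias_curve(phys, probe, grid)
        out["data"] = pd.DataFrame({"Ci0_mM": curve["Ci0"],
                                    "Ci_eff_mM": curve["Ci_eff"],
                                    "underestimation_pct":
                                        curve["underestimation_pct"]})
        out["alpha"] = curve["alpha"]
    elif figure_id == "fig3":
        rows = []
        for F_conv in (1.0, 4.0, 40.0):
            p = phys.with_(F=to_si(F_conv, "flow"))
            for mult in (0.25, 0.5, 1.0, 2.0, 4.0):
                pr = probe.with_beta_multiplier(mult)
                a = steady.alpha(p, pr)
                for diff in np.linspace(0.0, 6.0, 13):
                    rows.append({"F_mL_100mL_min": F_conv,
                                 "beta_multiplier": mult, "alpha": a,
                                 "Ci0_minus_Cp_mM": diff,
                                 "Ci_eff_minus_Cp_mM": (1.0 - a) * diff})
        out["data"] = pd.DataFrame(rows)
    elif figure_id == "fig6":
        ci0 = compartment.igc_quick_estimate(phys)
        frames = []
        for mult in (0.25, 1.0, 4.0):
            pr = probe.with_beta_multiplier(mult)
            sol = transient.solve_transient(phys, pr, ci0)
            frames.append(pd.DataFrame({
                "beta_multiplier": mult, "t_s": sol.t,
                "Ci_eff_mM": sol.Ci_eff, "alpha_t": sol.alpha_t,
                "alpha_t_normalized": sol.alpha_t / sol.alpha_steady}))
        out["data"] = pd.concat(frames, ignore_index=True)
    elif figure_id == "worked-examples":
        ci0 = compartment.igc_quick_estimate(phys)
        sol = steady.solve_steady(phys, probe, ci0)
        sol6 = steady.solve_steady(phys, probe, 6.0)
        sol_cp33 = steady.solve_steady(phys, probe.with_(Cp=3.3), ci0)
        out["data"] = {
            "ci0_mM": ci0,
            "ci0_full_chain_mM": compartment.igc_full(phys),
            "endothelial_gradient_mM":
                compartment.endothelial_gradient(phys.rt_mid, phys),
            "interstitial_drop_mM":
                compartment.interstitial_drop(phys.rt_a, phys.rt_a, phys),
            "alpha": sol.alpha,
            "ci_eff_mM": sol.Ci_eff,
            "relative_underestimation_pct":
                100.0 * sol.relative_underestimation,
            "removal_rate_mol_per_s": sol.removal_rate,
            "underestimation_at_6mM_pct":
                100.0 * sol6.relative_underestimation,
            "absolute_difference_at_6mM_mM": 6.0 - sol6.Ci_eff,
            "ci_eff_at_cp_3.3_mM": sol_cp33.Ci_eff,
        }
    else:
        raise ValueError(f"unknown figure id {figure_id!r}; expected "
                         "fig1, fig2, fig3, fig6 or worked-examples")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if isinstance(out["data"], pd.DataFrame):
            (out_dir / f"{figure_id}.csv").write_text(
                out["data"].to_csv(index=False, float_format="%.6g"))
        else:
            (out_dir / f"{figure_id}.json").write_text(
                json.dumps(out["data"], indent=2))
    return out


FIXTURE_RANGES = {
    "Ci0_mM": (2.0, 8.0),
    "Cp_mM": (0.0, 4.0),
    "beta_multiplier": (0.25, 4.0),
    "F_mL_100mL_min": (1.0, 40.0),
    "M_multiplier": (1.0, 15.0),
}


def generate_fixtures(seed: int, n: int,
                      out_path: str | Path | None = None) -> pd.DataFrame:
    """Seeded Latin-hypercube sweep over (Ci0, Cp, β, F, M) spanning the
    physiological ranges of the bias-model illustrations; every row resolves
    to valid parameter sets (used for property-based testing)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(FIXTURE_RANGES), seed=seed)
    unit = sampler.random(n)
    lows = np.array([lo for lo, _ in FIXTURE_RANGES.values()])
    highs = np.array([hi for _, hi in FIXTURE_RANGES.values()])
    df = pd.DataFrame(qmc.scale(unit, lows, highs),
                      columns=list(FIXTURE_RANGES))
    # validation pass: each row must build valid parameter objects
    for _, row in df.iterrows():
        PhysiologyParams.from_conventional(
            F=row["F_mL_100mL_min"]).with_(
            M=PhysiologyParams().M * row["M_multiplier"])
        ProbeParams(Cp=row["Cp_mM"]).with_beta_multiplier(
            row["beta_multiplier"])
    if out_path is not None:
        Path(out_path).write_text(df.to_csv(index=False, float_format="%.6g"))
    return df
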