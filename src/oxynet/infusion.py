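"""Infusion scenarios: hemodilution, HBOC loading, and boundary
recalibration.

Seven treatment conditions are shipped: an unsupplemented baseline and
{top-load, exchange} x {non-carrying control, 35:1 T-State PolyhHb,
30:1 R-State PolyhHb}. Each scenario fixes the systemic hematocrit
(hemodilution), plasma viscosity, HBOC dose and O2 affinity, and the
shear-stimulus scaling ``k_s`` (NO scavenging).

Because the simulated bed sits downstream of unmodeled arteries whose
tissue keeps consuming the same O2 after an infusion, the radius-
dependent boundary inlet model must be recalibrated: the O2 *extracted*
upstream, ``OE(r) = C(p_max) - C(p_in(r))``, is held equal between the
baseline and the modified blood, and the resulting per-radius inlet pO2
values are refitted to a linear-in-radius model (p_max held fixed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import yaml

from .carriers import (
    BloodComposition,
    OxygenCarrier,
    blood_o2_content,
    hboc_mass_to_heme_molar,
)
from .oxygen import BoundaryModel, boundary_inlet_po2

__all__ = [
    "InfusionScenario",
    "SCENARIOS",
    "scenario_names",
    "get_scenario",
    "apply_scenario",
    "upstream_extraction",
    "recalibrate_boundary",
    "ExtractionInfeasibleError",
]


class ExtractionInfeasibleError(ValueError):
    """The modified blood cannot supply the baseline upstream extraction."""


@dataclass(frozen=True)
class InfusionScenario:
    """One treatment condition (a column of the infusion parameter grid)."""

    name: str
    hct: float
    plasma_viscosity: float
    c_hboc_mass: float                     # mg/mL
    hboc_p50: Optional[float] = None
    hboc_n: Optional[float] = None
    k_s: float = 1.0
    reference_bc: Optional[tuple[float, float]] = None  # published (p0, slope)
    bc_override: Optional[BoundaryModel] = None

    def __post_init__(self) -> None:
        if self.c_hboc_mass > 0 and (self.hboc_p50 is None or self.hboc_n is None):
            raise ValueError("HBOC dose requires hboc_p50 and hboc_n")
        if self.c_hboc_mass == 0 and self.hboc_p50 is not None:
            raise ValueError("control scenarios must not define an HBOC carrier")

    @property
    def carries_o2(self) -> bool:
        return self.c_hboc_mass > 0


def _load_presets() -> dict[str, InfusionScenario]:
    text = (importlib.resources.files("oxynet") / "data" / "scenarios.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, row in raw.items():
        ref = row.get("reference_bc")
        # the published recalibrated boundary coefficients ship as each
        # preset's boundary model: exact reproduction of the published
        # pairs by recalibrate_boundary depends on the (unpublished)
        # in-RBC heme concentration, so the printed values are taken as
        # part of the scenario definition, while recalibrate_boundary
        # remains the computed path for custom compositions
        out[name] = InfusionScenario(
            name=name,
            hct=float(row["hct"]),
            plasma_viscosity=float(row["plasma_viscosity"]),
            c_hboc_mass=float(row["c_hboc_mass"]),
            hboc_p50=None if row["hboc_p50"] is None else float(row["hboc_p50"]),
            hboc_n=None if row["hboc_n"] is None else float(row["hboc_n"]),
            k_s=float(row["k_s"]),
            reference_bc=None if ref is None else (float(ref["p0"]), float(ref["slope"])),
            bc_override=(None if (ref is None or name == "baseline")
                         else BoundaryModel(p0=float(ref["p0"]),
                                            slope=float(ref["slope"]))),
        )
    return out


SCENARIOS: dict[str, InfusionScenario] = _load_presets()


def scenario_names() -> list[str]:
    return list(SCENARIOS)


def get_scenario(name: str) -> InfusionScenario:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; shipped scenarios: {scenario_names()}"
        ) from None


def apply_scenario(baseline: BloodComposition, scenario: InfusionScenario) -> BloodComposition:
    """Blood composition after an infusion scenario.

    The baseline must be the unsupplemented state (no HBOC); the returned
    composition carries the scenario hematocrit, plasma viscosity and
    HBOC load (mass dose converted to heme molarity). The baseline
    scenario returns its input unchanged.
    """
    if baseline.c_hboc != 0 or baseline.hboc_carrier is not None:
        raise ValueError("baseline composition must be unsupplemented (no HBOC)")
    if scenario.name == "baseline":
        return baseline
    carrier = None
    c_hboc = 0.0
    if scenario.carries_o2:
        carrier = OxygenCarrier(
            name=f"hboc_{scenario.name}", p50=scenario.hboc_p50,
            n_hill=scenario.hboc_n,
        )
        c_hboc = hboc_mass_to_heme_molar(scenario.c_hboc_mass)
    return baseline.with_(
        hct=scenario.hct,
        plasma_viscosity=scenario.plasma_viscosity,
        c_hboc=c_hboc,
        hboc_carrier=carrier,
    )


def upstream_extraction(radius: float, bc: BoundaryModel, comp: BloodComposition) -> float:
    """O2 extracted upstream of a boundary inflow of given radius, mol/m^3.

    ``OE(r) = C(p_max) - C(p_in(r))``: the content drop between fully
    arterial blood and the blood arriving at the network boundary. Zero
    when the linear boundary model is capped at p_max.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return float(
        blood_o2_content(bc.pmax, comp)
        - blood_o2_content(boundary_inlet_po2(radius, bc), comp)
    )


def _solve_po2_for_content(target: float, comp: BloodComposition,
                           pmax: float, tol: float = 1e-6) -> float:
    """Invert the monotone content function C(p) = target on [0, pmax]."""
    if target < -1e-12:
        raise ExtractionInfeasibleError(
            "required blood O2 content is negative: the modified blood cannot "
            "conserve the baseline upstream extraction"
        )
    lo, hi = 0.0, float(pmax)
    if blood_o2_content(hi, comp) <= target:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if blood_o2_content(mid, comp) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def recalibrate_boundary(
    baseline_comp: BloodComposition,
    new_comp: BloodComposition,
    baseline_bc: BoundaryModel,
    radii_sample: Optional[Sequence[float]] = None,
    tol: float = 1e-6,
) -> BoundaryModel:
    """Refit the boundary inlet model to conserve upstream O2 extraction.

    For each sampled radius the inlet pO2 of the modified blood solves
    ``OE_baseline(r) = C_new(p_max) - C_new(p)`` by bisection on the
    monotone content function; a least-squares line through the solved
    (r, p) pairs gives the new (p0, slope), with p_max held fixed.

    The default radius sample spans the uncapped range of the baseline
    model (below the radius where the min() cap engages).
    """
    if radii_sample is None:
        r_cap = (baseline_bc.pmax - baseline_bc.p0) / baseline_bc.slope
        radii_sample = np.linspace(1.0, 0.98 * r_cap, 25)
    radii = np.asarray(radii_sample, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")

    c_new_max = blood_o2_content(baseline_bc.pmax, new_comp)
    solved = np.empty_like(radii)
    for i, r in enumerate(radii):
        oe = upstream_extraction(float(r), baseline_bc, baseline_comp)
        solved[i] = _solve_po2_for_content(c_new_max - oe, new_comp,
                                           baseline_bc.pmax, tol=tol)

    a = np.column_stack([np.ones_like(radii), radii])
    (p0, slope), *_ = np.linalg.lstsq(a, solved, rcond=None)
    return BoundaryModel(p0=float(p0), slope=float(slope), pmax=baseline_bc.pmax)
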