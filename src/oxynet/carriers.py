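"""Oxygen equilibrium curves and blood oxygen content.

Blood in this model carries oxygen in three pools: dissolved in plasma,
bound to hemoglobin inside red blood cells (RBCs), and bound to a
cell-free hemoglobin-based oxygen carrier (HBOC) circulating in plasma.
Each hemoglobin species is described by a Hill oxygen equilibrium curve
(OEC) with half-saturation pressure ``P50`` and cooperativity ``n``:

    Y(P) = P^n / (P^n + P50^n)

Binding is assumed to be at local equilibrium everywhere (offloading
kinetics are fast compared with vascular residence time), so saturation
is a pure function of the local pO2 and no kinetic state is stored.

Package-wide units: pressure mm Hg, length um, concentration mol/m^3
(1 uM = 1e-3 mol/m^3), volumetric flow um^3/s, viscosity cP.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "OxygenCarrier",
    "BloodComposition",
    "hill_saturation",
    "hill_slope",
    "blood_o2_content",
    "o2_capacitance",
    "per_heme_delivery_deficit",
    "o2_offloading",
    "hboc_mass_to_heme_molar",
    "get_carrier",
    "CARRIERS",
    "ALPHA_PLASMA",
    "ALPHA_TISSUE",
    "C_HB_RBC_DEFAULT",
    "PLASMA_VISCOSITY_BASELINE",
]

# O2 solubilities, mol/(m^3 mm Hg)
ALPHA_PLASMA = 1.71e-3
ALPHA_TISSUE = 1.54e-3

# Heme concentration inside RBCs, mol heme/m^3 of RBC.
# MCHC 0.34 g/mL over 64,450 g/mol per tetramer, times 4 hemes.
C_HB_RBC_DEFAULT = 21.1

# HBOC mass-to-molar conversion (polymerized Hb, per tetramer basis).
HBOC_TETRAMER_MW = 64_500.0  # g/mol
HEMES_PER_TETRAMER = 4

PLASMA_VISCOSITY_BASELINE = 1.26  # cP


@dataclass(frozen=True)
class OxygenCarrier:
    """One O2-binding hemoglobin species with a Hill equilibrium curve.

    Parameters
    ----------
    name : str
        Label used in configs and outputs.
    p50 : float
        pO2 at half saturation, mm Hg. Lower P50 means higher O2 affinity.
    n_hill : float
        Hill cooperativity coefficient (dimensionless). Tetrameric Hb in
        RBCs is cooperative (n ~ 2-3); polymerized Hb is effectively
        non-cooperative (n = 1).
    per_heme : bool
        Concentrations paired with this carrier are on a per-heme basis.
    """

    name: str
    p50: float
    n_hill: float
    per_heme: bool = True

    def __post_init__(self) -> None:
        if not self.p50 > 0:
            raise ValueError(f"p50 must be positive, got {self.p50}")
        if not self.n_hill > 0:
            raise ValueError(f"n_hill must be positive, got {self.n_hill}")


#: Shipped carrier parameter sets (murine/human RBC Hb measured in the host
#: species; 35:1 T-State and 30:1 R-State polymerized human Hb).
CARRIERS: dict[str, OxygenCarrier] = {
    "mouse_rbc": OxygenCarrier("mouse_rbc", p50=42.1, n_hill=2.2),
    "human_rbc": OxygenCarrier("human_rbc", p50=29.3, n_hill=2.9),
    "t_state_35": OxygenCarrier("t_state_35", p50=34.0, n_hill=1.0),
    "r_state_30": OxygenCarrier("r_state_30", p50=1.3, n_hill=1.0),
}


def get_carrier(name: str) -> OxygenCarrier:
    """Look up a shipped carrier by name."""
    try:
        return CARRIERS[name]
    except KeyError:
        raise KeyError(
            f"unknown carrier {name!r}; shipped carriers: {sorted(CARRIERS)}"
        ) from None


@dataclass(frozen=True)
class BloodComposition:
    """Composition of flowing blood with respect to O2 carriage.

    ``c_hboc`` is the HBOC heme concentration in whole blood (mol/m^3);
    ``c_hb_rbc`` is the heme concentration inside RBCs, so the RBC-bound
    pool scales with hematocrit ``hct``.
    """

    hct: float
    rbc_carrier: OxygenCarrier
    c_hb_rbc: float = C_HB_RBC_DEFAULT
    c_hboc: float = 0.0
    hboc_carrier: Optional[OxygenCarrier] = None
    alpha_plasma: float = ALPHA_PLASMA
    plasma_viscosity: float = PLASMA_VISCOSITY_BASELINE

    def __post_init__(self) -> None:
        if not 0.0 <= self.hct < 1.0:
            raise ValueError(f"hct must be in [0, 1), got {self.hct}")
        if self.c_hb_rbc < 0 or self.c_hboc < 0:
            raise ValueError("concentrations must be non-negative")
        if self.hboc_carrier is None and self.c_hboc != 0.0:
            raise ValueError("c_hboc must be 0 when no HBOC carrier is present")
        if self.alpha_plasma <= 0 or self.plasma_viscosity <= 0:
            raise ValueError("alpha_plasma and plasma_viscosity must be positive")

    def with_(self, **kwargs) -> "BloodComposition":
        return replace(self, **kwargs)


def _check_po2(po2):
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("pO2 must be non-negative")
    return po2


def hill_saturation(po2, carrier: OxygenCarrier):
    """Equilibrium O2 saturation Y(pO2) = pO2^n / (pO2^n + P50^n).

    Accepts scalars or arrays; returns a value in [0, 1], strictly
    increasing in pO2, with Y(P50) = 0.5 exactly.
    """
    po2 = _check_po2(po2)
    # evaluate in ratio form for numerical symmetry around P50
    x = (po2 / carrier.p50) ** carrier.n_hill
    y = x / (1.0 + x)
    return y if y.ndim else float(y)


def hill_slope(po2, carrier: OxygenCarrier):
    """Analytic dY/dpO2 of the Hill curve, mm Hg^-1.

    dY/dP = n P50^n P^(n-1) / (P^n + P50^n)^2; strictly positive for
    pO2 > 0. At pO2 = 0 the limit is 1/P50 for n = 1, 0 for n > 1 and
    +inf for n < 1.
    """
    po2 = _check_po2(po2)
    n, p50 = carrier.n_hill, carrier.p50
    with np.errstate(divide="ignore"):
        x = (po2 / p50) ** n
        out = np.where(
            po2 > 0,
            n * x / np.where(po2 > 0, po2, 1.0) / (1.0 + x) ** 2,
            (1.0 / p50) if n == 1 else (0.0 if n > 1 else np.inf),
        )
    return out if out.ndim else float(out)


def blood_o2_content(po2, comp: BloodComposition):
    """Total blood O2 concentration C(pO2), mol O2 / m^3 blood.

    Sum of dissolved plasma O2, RBC-Hb-bound O2 and HBOC-bound O2:
    ``alpha_plasma*pO2 + HCT*C_Hb,RBC*Y_Hb(pO2) + C_HBOC*Y_HBOC(pO2)``.
    """
    po2 = _check_po2(po2)
    c = comp.alpha_plasma * po2
    c = c + comp.hct * comp.c_hb_rbc * hill_saturation(po2, comp.rbc_carrier)
    if comp.hboc_carrier is not None:
        c = c + comp.c_hboc * hill_saturation(po2, comp.hboc_carrier)
    return c if np.ndim(c) else float(c)


def o2_capacitance(po2, comp: BloodComposition):
    """dC/dpO2 of total blood O2 content, mol/(m^3 mm Hg).

    This effective O2 capacitance divides the transvascular flux in the
    axial pO2 equation; it is always >= alpha_plasma and peaks near the
    P50 of the dominant carrier when that carrier is cooperative.
    """
    po2 = _check_po2(po2)
    k = np.full_like(po2, comp.alpha_plasma, dtype=float)
    k = k + comp.hct * comp.c_hb_rbc * hill_slope(po2, comp.rbc_carrier)
    if comp.hboc_carrier is not None:
        k = k + comp.c_hboc * hill_slope(po2, comp.hboc_carrier)
    return k if k.ndim else float(k)


def content_functions(comp: BloodComposition):
    """Fast scalar ``(content, capacitance)`` evaluators for one composition.

    Pure-Python closures equivalent to :func:`blood_o2_content` and
    :func:`o2_capacitance` for scalar pO2 >= 0; used in the solver inner
    loops where per-call numpy overhead dominates. Cached per composition
    (compositions are frozen/hashable).
    """
    return _content_functions_cached(comp)


def _make_content_functions(comp: BloodComposition):
    from math import pow as fpow

    a = comp.alpha_plasma
    w_hb = comp.hct * comp.c_hb_rbc
    n1, p1 = comp.rbc_carrier.n_hill, comp.rbc_carrier.p50
    w_hboc = comp.c_hboc if comp.hboc_carrier is not None else 0.0
    if comp.hboc_carrier is not None:
        n2, p2 = comp.hboc_carrier.n_hill, comp.hboc_carrier.p50
    else:
        n2, p2 = 1.0, 1.0

    def content(p: float) -> float:
        c = a * p
        if w_hb:
            x = fpow(p / p1, n1)
            c += w_hb * x / (1.0 + x)
        if w_hboc:
            x = fpow(p / p2, n2)
            c += w_hboc * x / (1.0 + x)
        return c

    def capacitance(p: float) -> float:
        k = a
        if w_hb:
            if p > 0.0:
                x = fpow(p / p1, n1)
                k += w_hb * n1 * x / (p * (1.0 + x) ** 2)
            elif n1 == 1.0:
                k += w_hb / p1
        if w_hboc:
            if p > 0.0:
                x = fpow(p / p2, n2)
                k += w_hboc * n2 * x / (p * (1.0 + x) ** 2)
            elif n2 == 1.0:
                k += w_hboc / p2
        return k

    return content, capacitance


from functools import lru_cache as _lru_cache  # noqa: E402


@_lru_cache(maxsize=256)
def _content_functions_cached(comp: BloodComposition):
    return _make_content_functions(comp)


def per_heme_delivery_deficit(
    carrier_a: OxygenCarrier,
    carrier_b: OxygenCarrier,
    p_hi: float = 100.0,
    p_lo: float = 50.0,
) -> float:
    """Percent less O2 released by carrier_a than carrier_b per heme.

    Compares the saturation drop dY = Y(p_hi) - Y(p_lo) over a fixed pO2
    window and returns ``100*(1 - dY_a/dY_b)``. The default window
    [50, 100] mm Hg is the span of the radius-dependent boundary inlet
    model, i.e. the upstream arterial/arteriolar operating range.
    """
    if not p_hi > p_lo >= 0:
        raise ValueError("require p_hi > p_lo >= 0")
    dy_a = hill_saturation(p_hi, carrier_a) - hill_saturation(p_lo, carrier_a)
    dy_b = hill_saturation(p_hi, carrier_b) - hill_saturation(p_lo, carrier_b)
    if dy_b == 0:
        raise ZeroDivisionError("reference carrier releases no O2 over the window")
    return 100.0 * (1.0 - dy_a / dy_b)


def o2_offloading(po2, carrier: OxygenCarrier, mode: str = "slope", window: float = 5.0):
    """Candidate 'O2 offloading' measures for carrier comparison plots.

    ``mode='slope'`` returns dY/dpO2; ``mode='window'`` returns the
    saturation released over a finite downward step
    ``Y(pO2) - Y(max(pO2-window, 0))``. Both are plausible readings of an
    offloading-vs-pO2 curve; neither is asserted against published plots.
    """
    if mode == "slope":
        return hill_slope(po2, carrier)
    if mode == "window":
        po2 = _check_po2(po2)
        lo = np.maximum(po2 - window, 0.0)
        out = hill_saturation(po2, carrier) - hill_saturation(lo, carrier)
        return out if np.ndim(out) else float(out)
    raise ValueError(f"unknown offloading mode {mode!r}")


def hboc_mass_to_heme_molar(mg_per_ml: float, tetramer_mw: float = HBOC_TETRAMER_MW) -> float:
    """Convert an HBOC mass concentration (mg/mL) to heme molarity (mol/m^3).

    mg/mL equals kg/m^3; dividing by the tetramer molar mass and
    multiplying by 4 hemes per tetramer gives mol heme/m^3.
    """
    if mg_per_ml < 0:
        raise ValueError("mass concentration must be non-negative")
    return mg_per_ml * 1000.0 / tetramer_mw * HEMES_PER_TETRAMER
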