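"""Bulk, clinically analogous summaries of a converged simulation.

These are the tissue-averaged quantities a low-resolution modality
(optical mammography, PET, MRI) could report: microvascular density
(MVD, vessel length per volume), regional blood volume fraction (RBV),
regional blood flow per tissue mass (RBF), tissue Hb/HBOC concentrations
and saturations, oxygen extraction fractions by carrier species (OEF),
the metabolic rate of O2 consumption (MRO2), and hypoxic volume
fractions. Standard stereological definitions are used for the vascular
summaries; segment-region intersections are by clipped length.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Union

import numpy as np
import pandas as pd

from .carriers import BloodComposition, hill_saturation
from .hemodynamics import FlowSolution
from .netgen import TissueGrid, VascularNetwork
from .oxygen import OxygenSolution, _segment_samples

__all__ = [
    "BulkMetrics",
    "OEFBreakdown",
    "region_mask",
    "vascular_bulk_metrics",
    "oef_breakdown",
    "mro2",
    "hypoxic_fractions",
    "percent_change",
    "metrics_row",
]

REGIONS = ("whole", "tumor", "host", "boundary")


@dataclass
class BulkMetrics:
    region: str
    mvd: float               # mm/mm^3
    rbv: float               # fraction
    rbf: float               # mL/(g min); tissue density 1 g/mL
    c_hb_tis: float          # uM heme
    c_oxyhb_tis: float       # uM heme
    s_hb_tis: float          # fraction
    c_hboc_tis: float        # uM heme
    c_oxyhboc_tis: float     # uM heme
    s_hboc_tis: float        # fraction
    mean_tissue_po2: float   # mm Hg
    mean_blood_po2: float    # mm Hg

    def __post_init__(self) -> None:
        for s in (self.s_hb_tis, self.s_hboc_tis):
            if not -1e-9 <= s <= 1 + 1e-9:
                raise ValueError(f"saturation {s} outside [0, 1]")
        if not 0 <= self.rbv < 1:
            raise ValueError(f"rbv {self.rbv} outside [0, 1)")


@dataclass
class OEFBreakdown:
    """Oxygen extraction fractions, total and per carrier species.

    ``oef_total * j_in_total == sum_s oef_s * j_in_s`` holds exactly
    (each side equals the total molar O2 flow extracted). Species with
    zero inflow carry ``nan`` and are listed in ``undefined``.
    """

    oef_total: float
    oef_plas: float
    oef_hb: float
    oef_hboc: float
    j_in: dict[str, float]   # molar O2 inflow by species, (mol/m^3)*um^3/s
    j_out: dict[str, float]
    undefined: list[str]


def region_mask(grid: TissueGrid, region: str) -> np.ndarray:
    """Boolean voxel mask for a named region.

    ``tumor`` includes the necrotic core (the gross tumor volume);
    ``boundary`` is the viable tumor rim (tumor fraction > 0, necrotic
    fraction = 0); ``host`` is untransformed tissue.
    """
    if region == "whole":
        return np.ones(grid.shape, dtype=bool)
    if region == "tumor":
        return (grid.phi_tumor > 0) | (grid.phi_necrotic > 0)
    if region == "host":
        return (grid.phi_normal > 0) & (grid.phi_tumor == 0) & (grid.phi_necrotic == 0)
    if region == "boundary":
        return (grid.phi_tumor > 0) & (grid.phi_necrotic == 0)
    raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")


def _as_mask(grid: TissueGrid, region: Union[str, np.ndarray]) -> np.ndarray:
    mask = region_mask(grid, region) if isinstance(region, str) else np.asarray(region, bool)
    if mask.shape != grid.shape:
        raise ValueError("region mask shape must match the grid")
    return mask


def _segment_in_fraction(network: VascularNetwork, grid: TissueGrid,
                         mask: np.ndarray):
    """Per segment: fraction of its length inside the mask, plus the
    per-sample inside flags (for flow-crossing detection)."""
    pos = network.nodes[["x", "y", "z"]]
    fractions = np.empty(len(network.segments))
    inside_flags = []
    for i, (_, row) in enumerate(network.segments.iterrows()):
        pts = _segment_samples(pos.loc[row["a"]].to_numpy(float),
                               pos.loc[row["b"]].to_numpy(float), grid.spacing)
        idx = np.clip((pts / grid.spacing).astype(int), 0,
                      np.asarray(grid.shape) - 1)
        flags = mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        fractions[i] = flags.mean()
        inside_flags.append(flags)
    return fractions, inside_flags


def vascular_bulk_metrics(
    network: VascularNetwork,
    flow: FlowSolution,
    oxygen: OxygenSolution,
    grid: TissueGrid,
    region: Union[str, np.ndarray] = "whole",
    comp: Optional[BloodComposition] = None,
) -> BulkMetrics:
    """Stereological vascular summaries over a tissue region."""
    mask = _as_mask(grid, region)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty region")
    vol = n_vox * grid.voxel_volume  # um^3

    seg = network.segments
    frac, flags = _segment_in_fraction(network, grid, mask)
    length_in = seg["length"].to_numpy(float) * frac
    radius = seg["radius"].to_numpy(float)
    hct = (flow.segment_hct.reindex(seg.index).fillna(0.0).to_numpy(float)
           if flow.segment_hct is not None else np.zeros(len(seg)))
    chboc = (flow.segment_c_hboc.reindex(seg.index).fillna(0.0).to_numpy(float)
             if flow.segment_c_hboc is not None else np.zeros(len(seg)))
    mean_po2 = oxygen.segment_mean_po2.reindex(seg.index).to_numpy(float)

    mvd = length_in.sum() / vol / 1e-6                      # mm/mm^3
    seg_vol = np.pi * radius**2 * length_in                 # um^3
    rbv = seg_vol.sum() / vol

    # blood inflow crossing into the region (plus source-segment inflow)
    oriented = flow.oriented(network)
    q = oriented["q"].to_numpy(float)
    a_ids = seg["a"].to_numpy(int)
    u_ids = oriented["u"].to_numpy(int)
    kinds = network.nodes["kind"]
    inflow = 0.0
    for i in range(len(seg)):
        f = flags[i]
        if q[i] <= 0 or not f.any():
            continue
        fl = f if a_ids[i] == u_ids[i] else f[::-1]  # walk along the flow
        entries = int(fl[0]) + int((fl[1:] & ~fl[:-1]).sum())
        if fl[0] and kinds.loc[u_ids[i]] != "arterial_root" \
                and len(oriented[oriented["v"] == u_ids[i]]) > 0:
            entries -= 1  # fed from upstream segments, not an entry point
        inflow += entries * q[i]
    rbf = inflow * 60.0 / vol  # mL/(g min) at 1 g/mL

    c_hb_rbc = 21.1
    y_hb = np.zeros(len(seg))
    y_hboc = np.zeros(len(seg))
    if comp is not None:
        c_hb_rbc = comp.c_hb_rbc
        y_hb = hill_saturation(np.clip(mean_po2, 0, None), comp.rbc_carrier)
        if comp.hboc_carrier is not None:
            y_hboc = hill_saturation(np.clip(mean_po2, 0, None), comp.hboc_carrier)

    c_hb = (seg_vol * hct).sum() * c_hb_rbc / vol           # mol/m^3
    c_oxyhb = (seg_vol * hct * y_hb).sum() * c_hb_rbc / vol
    c_hboc_t = (seg_vol * chboc).sum() / vol
    c_oxyhboc = (seg_vol * chboc * y_hboc).sum() / vol

    blood_w = seg_vol.sum()
    mean_blood = float((seg_vol * mean_po2).sum() / blood_w) if blood_w > 0 else 0.0

    return BulkMetrics(
        region=region if isinstance(region, str) else "custom",
        mvd=float(mvd),
        rbv=float(rbv),
        rbf=float(rbf),
        c_hb_tis=float(c_hb * 1e3),          # mol/m^3 -> uM
        c_oxyhb_tis=float(c_oxyhb * 1e3),
        s_hb_tis=float(c_oxyhb / c_hb) if c_hb > 0 else 0.0,
        c_hboc_tis=float(c_hboc_t * 1e3),
        c_oxyhboc_tis=float(c_oxyhboc * 1e3),
        s_hboc_tis=float(c_oxyhboc / c_hboc_t) if c_hboc_t > 0 else 0.0,
        mean_tissue_po2=float(oxygen.tissue_po2[mask].mean()),
        mean_blood_po2=mean_blood,
    )


def _species_flux(q, hct, chboc, po2, comp: BloodComposition):
    plas = comp.alpha_plasma * q * po2
    hb = comp.c_hb_rbc * q * hct * hill_saturation(max(po2, 0.0), comp.rbc_carrier)
    hboc = 0.0
    if comp.hboc_carrier is not None:
        hboc = q * chboc * hill_saturation(max(po2, 0.0), comp.hboc_carrier)
    return plas, hb, hboc


def oef_breakdown(
    network: VascularNetwork,
    flow: FlowSolution,
    oxygen: OxygenSolution,
    comp: BloodComposition,
) -> OEFBreakdown:
    """Oxygen extraction fraction per species across the whole network.

    Inlet segments are those fed by a source node of the flow-oriented
    graph (arterial roots); outlet segments drain into a sink node
    (venous roots). Species molar flows use the partitioned per-segment
    hematocrit and HBOC concentration with the segment inlet/outlet pO2.
    """
    oriented = flow.oriented(network)
    active = oriented[oriented["q"] > 0]
    sources = set(active["u"]) - set(active["v"])
    sinks = set(active["v"]) - set(active["u"])

    hct = (flow.segment_hct if flow.segment_hct is not None
           else pd.Series(comp.hct, index=network.segments.index))
    chb = (flow.segment_c_hboc if flow.segment_c_hboc is not None
           else pd.Series(comp.c_hboc, index=network.segments.index))

    j_in = {"plasma": 0.0, "hb": 0.0, "hboc": 0.0}
    j_out = {"plasma": 0.0, "hb": 0.0, "hboc": 0.0}
    for sid, row in active.iterrows():
        if row["u"] in sources:
            p, h, b = _species_flux(row["q"], hct.loc[sid], chb.loc[sid],
                                    float(oxygen.segment_inlet_po2.loc[sid]), comp)
            j_in["plasma"] += p
            j_in["hb"] += h
            j_in["hboc"] += b
        if row["v"] in sinks:
            p, h, b = _species_flux(row["q"], hct.loc[sid], chb.loc[sid],
                                    float(oxygen.segment_outlet_po2.loc[sid]), comp)
            j_out["plasma"] += p
            j_out["hb"] += h
            j_out["hboc"] += b

    undefined = []

    def oef(species):
        if j_in[species] == 0.0:
            undefined.append(species)
            return float("nan")
        return (j_in[species] - j_out[species]) / j_in[species]

    oef_p, oef_h, oef_b = oef("plasma"), oef("hb"), oef("hboc")
    tot_in = sum(j_in.values())
    oef_t = (tot_in - sum(j_out.values())) / tot_in if tot_in > 0 else float("nan")
    return OEFBreakdown(
        oef_total=oef_t, oef_plas=oef_p, oef_hb=oef_h, oef_hboc=oef_b,
        j_in=j_in, j_out=j_out, undefined=undefined,
    )


def mro2(grid: TissueGrid, tissue_po2: np.ndarray,
         region: Union[str, np.ndarray] = "whole") -> float:
    """Region-averaged metabolic rate of O2 consumption, uM/s.

    Volume average of the Michaelis-Menten uptake
    ``V_M * P / (K_M + P)`` over the region; bounded by the regional
    maximum V_M, and zero over purely necrotic regions (V_M = 0 there).
    """
    mask = _as_mask(grid, region)
    p = np.clip(tissue_po2[mask], 0.0, None)
    return float(np.mean(grid.v_m[mask] * p / (grid.k_m[mask] + p)))


def hypoxic_fractions(grid: TissueGrid, tissue_po2: np.ndarray,
                      threshold: float = 5.0) -> tuple[float, float]:
    """Hypoxic volume fractions below a pO2 threshold (default 5 mm Hg).

    The total fraction is taken over non-necrotic (normal + tumor)
    voxels only — necrotic tissue is dead and excluded from the hypoxic
    volume. The boundary fraction covers the viable tumor rim
    (tumor fraction > 0, necrotic fraction = 0).
    """
    viable = (grid.phi_normal > 0) | (grid.phi_tumor > 0)
    viable &= grid.phi_necrotic == 0
    hyp = tissue_po2 < threshold
    total = float(hyp[viable].mean()) if viable.any() else 0.0
    bnd_mask = region_mask(grid, "boundary")
    boundary = float(hyp[bnd_mask].mean()) if bnd_mask.any() else 0.0
    return total, boundary


def percent_change(value: float, baseline: float) -> float:
    """Percent change vs a baseline: ``100 * (V - V_BL) / V_BL``.

    Returns nan (the undefined flag) for a zero baseline.
    """
    if baseline == 0:
        return float("nan")
    return 100.0 * (value - baseline) / baseline


def metrics_row(
    network: VascularNetwork,
    flow: FlowSolution,
    oxygen: OxygenSolution,
    grid: TissueGrid,
    comp: BloodComposition,
    scenario: str = "baseline",
    hypoxia_threshold: float = 5.0,
) -> pd.DataFrame:
    """Tidy table: one row per region with every bulk metric.

    OEF and its decomposition are network-wide quantities and repeat on
    every region row; hypoxic fractions follow their own region rules.
    """
    oef = oef_breakdown(network, flow, oxygen, comp)
    hyp_total, hyp_boundary = hypoxic_fractions(grid, oxygen.tissue_po2,
                                                hypoxia_threshold)
    rows = []
    for region in REGIONS:
        if not region_mask(grid, region).any():
            continue
        bulk = vascular_bulk_metrics(network, flow, oxygen, grid, region, comp=comp)
        row = {"scenario": scenario, **asdict(bulk)}
        row["mro2"] = mro2(grid, oxygen.tissue_po2, region)
        row["oef_total"] = oef.oef_total
        row["oef_plas"] = oef.oef_plas
        row["oef_hb"] = oef.oef_hb
        row["oef_hboc"] = oef.oef_hboc
        row["hypoxic_fraction"] = hyp_total
        row["boundary_hypoxic_fraction"] = hyp_boundary
        rows.append(row)
    return pd.DataFrame(rows)
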