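"""Krogh tissue cylinder (KTC) with an HBOC-laden lumen.

A single vessel of radius ``r_c`` is surrounded by a concentric tissue
annulus out to ``r_t``. The lumen carries blood (plasma + RBC Hb + HBOC
in local equilibrium) by axial convection with a Poiseuille velocity
profile and radial diffusion of dissolved O2; the annulus has radial
diffusion with Michaelis-Menten consumption; pO2 and flux are matched at
the wall (finite-volume faces, so the discrete wall flux is single-
valued). Axial diffusion is neglected (convection-dominated lumen,
quasi-static tissue slices).

The resolved wall flux is reduced to an effective Sherwood number

    Sh_eff = 2 r_c j_wall / (D_plasma alpha_plasma (P_mixed - P_tissue))

and a linear correlation Sh_eff ~ 1/r, HCT, C_HBOC fitted over a
parametric sweep; the network oxygen solver accepts either the constant
classical value or such a fitted correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .carriers import BloodComposition, o2_capacitance
from .oxygen import TransportParams

__all__ = [
    "KTCConfig",
    "KTCResult",
    "SherwoodFit",
    "solve_ktc",
    "effective_sherwood",
    "fit_sherwood",
    "run_sweep",
    "krogh_annulus_po2",
]


@dataclass
class KTCConfig:
    vessel_radius: float           # um
    tissue_radius: float           # um
    comp: BloodComposition
    v_m: float = 45.0              # uM/s
    k_m: float = 5.0               # mm Hg
    inlet_po2: float = 80.0        # mm Hg
    flow: float = 5e4              # um^3/s
    length: float = 400.0          # um
    n_radial: int = 32             # tissue annulus cells
    n_axial: int = 60
    n_lumen: int = 24

    def __post_init__(self) -> None:
        if not self.tissue_radius > self.vessel_radius:
            raise ValueError("tissue_radius must exceed vessel_radius")
        if min(self.n_radial, self.n_axial, self.n_lumen) < 8:
            raise ValueError("grid counts must be >= 8")


@dataclass
class KTCResult:
    r_centers: np.ndarray          # all cells, lumen then tissue (um)
    z_centers: np.ndarray
    po2: np.ndarray                # (n_axial, n_cells)
    wall_flux: np.ndarray          # per z, (mol/m^3)*um/s outward
    wall_flux_tissue: np.ndarray   # from the tissue-side discrete balance
    mixed_po2: np.ndarray          # flow-weighted lumen mean per z
    tissue_mean_po2: np.ndarray    # annulus volume mean per z
    wall_po2: np.ndarray           # tissue pO2 adjacent to the wall per z
    outlet_po2: float
    n_lumen: int


def _radial_mesh(cfg: KTCConfig, with_tissue: bool):
    dr_l = cfg.vessel_radius / cfg.n_lumen
    faces = [i * dr_l for i in range(cfg.n_lumen + 1)]
    if with_tissue:
        dr_t = (cfg.tissue_radius - cfg.vessel_radius) / cfg.n_radial
        faces += [cfg.vessel_radius + (i + 1) * dr_t for i in range(cfg.n_radial)]
    faces = np.asarray(faces)
    centers = 0.5 * (faces[1:] + faces[:-1])
    widths = np.diff(faces)
    return faces, centers, widths


def solve_ktc(
    cfg: KTCConfig,
    params: Optional[TransportParams] = None,
    wall_po2: Optional[float] = None,
    newton_tol: float = 1e-10,
    max_iter: int = 60,
) -> KTCResult:
    """March the KTC axially, solving each radial slice implicitly.

    ``wall_po2`` switches to a prescribed-wall-pO2 mode (lumen only, no
    tissue annulus) used to verify the discretization against the
    classical constant-wall asymptote.
    """
    params = params or TransportParams()
    comp = cfg.comp
    dirichlet = wall_po2 is not None
    faces, centers, widths = _radial_mesh(cfg, with_tissue=not dirichlet)
    n_lum = cfg.n_lumen
    n_cells = len(centers)

    d_alpha = np.empty(n_cells)
    d_alpha[:n_lum] = params.d_plasma_um2 * comp.alpha_plasma
    if not dirichlet:
        d_alpha[n_lum:] = params.d_tissue_um2 * params.alpha_tissue

    # face conductances between neighbouring cells (harmonic in D*alpha)
    k_face = np.zeros(n_cells + 1)
    for i in range(1, n_cells):
        k_face[i] = 1.0 / (0.5 * widths[i - 1] / d_alpha[i - 1]
                           + 0.5 * widths[i] / d_alpha[i])
    k_wall_dir = d_alpha[n_lum - 1] / (0.5 * widths[n_lum - 1])  # Dirichlet mode

    v_bar = cfg.flow / (np.pi * cfg.vessel_radius**2)
    v = np.zeros(n_cells)
    v[:n_lum] = 2.0 * v_bar * (1.0 - (centers[:n_lum] / cfg.vessel_radius) ** 2)

    vm = np.zeros(n_cells)
    km = np.ones(n_cells)
    if not dirichlet:
        vm[n_lum:] = cfg.v_m * 1e-3   # uM/s -> mol/(m^3 s)
        km[n_lum:] = cfg.k_m

    dz = cfg.length / cfg.n_axial
    rdr = centers * widths
    z_centers = (np.arange(cfg.n_axial) + 0.5) * dz

    po2 = np.empty((cfg.n_axial, n_cells))
    wall_flux = np.empty(cfg.n_axial)
    wall_flux_tissue = np.empty(cfg.n_axial)
    mixed = np.empty(cfg.n_axial)
    tissue_mean = np.empty(cfg.n_axial)
    wall_val = np.empty(cfg.n_axial)

    p_prev = np.full(n_cells, float(cfg.inlet_po2))
    if not dirichlet:
        p_prev[n_lum:] = cfg.inlet_po2  # slice solve relaxes this immediately

    flow_weight = v[:n_lum] * rdr[:n_lum]

    from scipy.linalg import solve_banded

    # pure-diffusion tridiagonal stencil (constant over the march)
    lower = np.zeros(n_cells)
    upper = np.zeros(n_cells)
    diag_diff = np.zeros(n_cells)
    b_const = np.zeros(n_cells)
    for i in range(n_cells):
        if i > 0:
            c = k_face[i] * faces[i]
            lower[i] = c
            diag_diff[i] -= c
        if i < n_cells - 1:
            c = k_face[i + 1] * faces[i + 1]
            upper[i] = c
            diag_diff[i] -= c
    if dirichlet:
        c = k_wall_dir * faces[n_lum]
        diag_diff[n_lum - 1] -= c
        b_const[n_lum - 1] += c * wall_po2

    def diffusion(pv):
        out = diag_diff * pv + b_const
        out[1:] += lower[1:] * pv[:-1]
        out[:-1] += upper[:-1] * pv[1:]
        return out

    for kz in range(cfg.n_axial):
        p = p_prev.copy()
        for _ in range(max_iter):
            kappa = np.ones(n_cells)
            kappa[:n_lum] = o2_capacitance(np.clip(p[:n_lum], 0.0, None), comp)
            adv = v * kappa * rdr / dz  # zero in tissue (v = 0)
            mm = vm * p / (km + p)
            dmm = vm * km / (km + p) ** 2

            res = diffusion(p) - adv * (p - p_prev) - mm * rdr
            ab = np.zeros((3, n_cells))
            ab[0, 1:] = upper[:-1]
            ab[1, :] = diag_diff - adv - dmm * rdr
            ab[2, :-1] = lower[1:]
            dp = solve_banded((1, 1), ab, -res)
            p = np.clip(p + dp, 0.0, None)
            if np.abs(dp).max() < newton_tol * max(1.0, np.abs(p).max()):
                break

        po2[kz] = p
        if dirichlet:
            wall_flux[kz] = k_wall_dir * (p[n_lum - 1] - wall_po2)
            wall_flux_tissue[kz] = wall_flux[kz]
            tissue_mean[kz] = wall_po2
            wall_val[kz] = wall_po2
        else:
            wall_flux[kz] = k_face[n_lum] * (p[n_lum - 1] - p[n_lum])
            # tissue-side: total consumption in the slice / wall area
            cons = float((vm[n_lum:] * p[n_lum:] / (km[n_lum:] + p[n_lum:])
                          * rdr[n_lum:]).sum())
            wall_flux_tissue[kz] = cons / cfg.vessel_radius
            tissue_mean[kz] = float((p[n_lum:] * rdr[n_lum:]).sum()
                                    / rdr[n_lum:].sum())
            # extrapolate the tissue-side profile to the wall face
            wall_val[kz] = float(p[n_lum] + wall_flux[kz] * 0.5 * widths[n_lum]
                                 / d_alpha[n_lum])
        mixed[kz] = float((p[:n_lum] * flow_weight).sum() / flow_weight.sum())
        p_prev = p

    return KTCResult(
        r_centers=centers, z_centers=z_centers, po2=po2,
        wall_flux=wall_flux, wall_flux_tissue=wall_flux_tissue,
        mixed_po2=mixed, tissue_mean_po2=tissue_mean, wall_po2=wall_val,
        outlet_po2=float(mixed[-1]), n_lumen=n_lum,
    )


def effective_sherwood(cfg: KTCConfig, result: KTCResult,
                       params: Optional[TransportParams] = None,
                       z_index: Optional[int] = None) -> float:
    """Reduce a resolved KTC wall flux to an effective Sherwood number.

    The driving difference is mixed-mean lumen pO2 minus the *wall* pO2:
    the number lumps only the intravascular radial resistance (like the
    classical constant-wall value), leaving the extravascular resistance
    to the tissue solver. Uses the mid-length slice by default (past the
    concentration entrance region, before outlet depletion).
    """
    params = params or TransportParams()
    kz = len(result.z_centers) // 2 if z_index is None else z_index
    dp = result.mixed_po2[kz] - result.wall_po2[kz]
    if abs(dp) < 1e-12:
        raise ValueError("driving pO2 difference is zero; Sh undefined")
    d_alpha = params.d_plasma_um2 * cfg.comp.alpha_plasma
    return float(2.0 * cfg.vessel_radius * result.wall_flux[kz] / (d_alpha * dp))


@dataclass
class SherwoodFit:
    """Linear Sherwood correlation Sh = c0 + c1/r + c2*HCT + c3*C_HBOC.

    Callable with ``(radius, hct, c_hboc)`` so it can be plugged directly
    into :class:`~oxynet.oxygen.TransportParams.sherwood`. Predictors
    that were constant across the sweep are dropped (coefficient 0).
    """

    intercept: float
    coefficients: dict[str, float]
    r_squared: float
    n_points: int

    def __call__(self, radius: float, hct: float = 0.0, c_hboc: float = 0.0) -> float:
        value = self.intercept
        value += self.coefficients.get("inv_radius", 0.0) / radius
        value += self.coefficients.get("hct", 0.0) * hct
        value += self.coefficients.get("c_hboc", 0.0) * c_hboc
        return value

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SherwoodFit":
        return cls(intercept=float(doc["intercept"]),
                   coefficients={k: float(v) for k, v in doc["coefficients"].items()},
                   r_squared=float(doc["r_squared"]),
                   n_points=int(doc["n_points"]))


def fit_sherwood(sweep: Sequence[tuple[KTCConfig, float]],
                 min_points: int = 10) -> SherwoodFit:
    """Least-squares fit of effective Sh against (1/r, HCT, C_HBOC).

    ``sweep`` pairs each configuration with its measured effective
    Sherwood number. Constant predictor columns are dropped so a sweep of
    identical points reduces to an exact intercept-only fit; a design
    that is rank-deficient after dropping raises.
    """
    if len(sweep) < min_points:
        raise ValueError(f"need >= {min_points} sweep points, got {len(sweep)}")
    names = ["inv_radius", "hct", "c_hboc"]
    cols = {
        "inv_radius": np.array([1.0 / cfg.vessel_radius for cfg, _ in sweep]),
        "hct": np.array([cfg.comp.hct for cfg, _ in sweep]),
        "c_hboc": np.array([cfg.comp.c_hboc for cfg, _ in sweep]),
    }
    y = np.array([sh for _, sh in sweep], dtype=float)

    active = [n for n in names if np.ptp(cols[n]) > 1e-12]
    x = np.column_stack([np.ones(len(y))] + [cols[n] for n in active])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient Sherwood design matrix; widen the sweep")
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    pred = x @ beta
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    coefs = {n: float(b) for n, b in zip(active, beta[1:])}
    return SherwoodFit(intercept=float(beta[0]), coefficients=coefs,
                       r_squared=r2, n_points=len(y))


def run_sweep(configs: Sequence[KTCConfig],
              params: Optional[TransportParams] = None) -> list[tuple[KTCConfig, float]]:
    """Solve each KTC configuration and extract its effective Sh."""
    params = params or TransportParams()
    out = []
    for cfg in configs:
        res = solve_ktc(cfg, params=params)
        out.append((cfg, effective_sherwood(cfg, res, params=params)))
    return out


def krogh_annulus_po2(r, r_vessel: float, r_tissue: float, p_wall: float,
                      m0: float, alpha_d: float):
    """Closed-form zeroth-order Krogh annulus profile.

    Solves ``alpha D (1/r)(r P')' = M0`` with P(r_vessel) = p_wall and
    zero flux at r_tissue:

        P(r) = P_w + (M0/(alpha D)) [ (r^2 - r_c^2)/4
                                      - (r_t^2/2) ln(r/r_c) ]

    ``m0`` in mol/(m^3 s), ``alpha_d`` in mol/(m^3 mm Hg) * um^2/s,
    radii in um.
    """
    r = np.asarray(r, dtype=float)
    return p_wall + (m0 / alpha_d) * (
        (r**2 - r_vessel**2) / 4.0
        - (r_tissue**2 / 2.0) * np.log(r / r_vessel)
    )
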