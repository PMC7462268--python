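# Methods

`oxynet` simulates steady oxygen delivery through a microvascular
arterio-venous network perfused by blood that carries O2 in three pools
— dissolved in plasma, bound to hemoglobin in red blood cells (RBCs),
and bound to a cell-free hemoglobin-based oxygen carrier (HBOC)
circulating in plasma — coupled to a 3D tissue grid with
Michaelis–Menten consumption. It is a desk-scale tool: beds of a few
hundred to ~1000 segments in a ~0.5 mm³ domain, solvable in seconds to
minutes on one core.

Units are fixed package-wide: pressure mm Hg, length µm, concentration
mol/m³ (1 µM = 1e−3 mol/m³), volumetric flow µm³/s, viscosity cP, wall
shear stress Pa. Conversions happen only at I/O boundaries.

## Blood oxygen model

Each hemoglobin species has a Hill oxygen equilibrium curve
`Y(P) = P^n / (P^n + P50^n)`. Binding is assumed to be at local
equilibrium (offloading kinetics fast compared with vascular residence
time), so no kinetic state exists anywhere in the model. Total blood O2
content is

    C(P) = α_pl P + HCT · C_Hb,RBC · Y_Hb(P) + C_HBOC · Y_HBOC(P)

with α_pl = 1.71e−3 mol/(m³·mm Hg). Shipped carriers: murine RBC Hb
(P50 42.1 mm Hg, n 2.2), human RBC Hb (29.3, 2.9), 35:1 T-State
polymerized human Hb (34, 1) and 30:1 R-State polymerized human Hb
(1.3, 1). The in-RBC heme concentration C_Hb,RBC defaults to
21.1 mol heme/m³ (MCHC 0.34 g/mL ÷ 64,450 g/mol per tetramer × 4
hemes); HBOC doses given in mg/mL convert to heme molarity with
64,500 g/mol × 4. Both are configurable — several published comparison
quantities are sensitive to the (rarely printed) choice of C_Hb,RBC.

The per-heme delivery deficit between two carriers compares their
saturation drops over the arterial/arteriolar window 100 → 50 mm Hg
(the span of the boundary inlet model below); with the shipped
parameters the T-State and R-State carriers release ~45% and ~96% less
O2 per heme than murine RBC Hb over that window.

## Network generation and the tumor phantom

Full angiogenesis/growth simulation is out of scope. The generator
builds an arterial and a venous shortest-path tree (randomized edge
weights, seeded) from boundary root nodes over a cubic lattice
partition, bridges them with capillary lattice edges until a target
microvascular density (MVD, mm/mm³) is reached, and assigns radii by
Murray's law from downstream capillary counts. Every segment lies on an
arterial-to-venous path by construction and generation is a pure
function of (parameters, seed). Default bed: 800 µm cube, 80 µm pitch,
MVD 150 mm/mm³ (a realistic capillary-bed length density), one arterial
and one venous root on opposite faces.

The tumor phantom stamps a sphere onto the host bed: vessels in the
sphere are relabeled and dilated (×1.3 by default — grown tumors show
elevated MVD and regional blood volume), capillaries in a necrotic core
are pruned (50%) and dead ends trimmed. The tissue grid mimics an
infiltrative continuum tumor: a pure necrotic core, a viable shell whose
tumor/host phase fractions ramp linearly from 1 at the core edge to 0 at
the outer radius, and pure host outside. Per-voxel V_M and K_M are
phase-weighted mixtures of host (mouse 45 µM/s / human 15 µM/s, K_M
5 mm Hg), tumor (80 µM/s, 2 mm Hg) and necrotic (0) values. The phase
mixture matters: it is what lets the host-species difference in V_M
reach the tumor region, reproducing the higher tumor oxygenation of the
human parameterization.

## Hemodynamics

Poiseuille conductances `π r⁴ / (8 µ l)` with the empirical Pries
diameter- and hematocrit-dependent relative viscosity
(Fahraeus–Lindqvist). Network solves default to the in-vivo law
(perfused-vessel apparent viscosity, including the wall-layer term);
the in-vitro tube law (whose HCT→0 limit is exactly the plasma
viscosity) is available per call. Boundary pressures default to
60 mm Hg (arterial roots) and 15 mm Hg (venous roots).

A desk-scale bed resolves only a short stretch of the arterio-venous
path, so its bare hydraulic resistance would give regional blood flows
orders of magnitude above physiologic values. The pipeline therefore
applies each boundary pressure through a "feed vessel" — the series
resistance of the truncated extramural supply, by default a 12 µm ×
3 mm feeding arteriole and a 15 µm × 3 mm draining venule. This brings
regional blood flow (RBF) to ~1 mL/(g·min) and total oxygen extraction
to ~0.4 on the default bed.

Hematocrit and the plasma-borne HBOC propagate through the
flow-oriented network with exactly conserved RBC flux (Q·HCT) and HBOC
flux (Q·C_HBOC); diverging bifurcations split RBC flux either in
proportion to blood flow (default) or by the empirical Pries
phase-separation law; the HBOC always follows the plasma flow.

Structural adaptation is a minimal shear-only rule:
`r ← r (1 + step (k_s·S_H − S_ref))` with the saturating stimulus
`S_H = log10(1 + τ/τ0)`, τ the Poiseuille wall shear. `k_s ≤ 1` scales
the stimulus to represent NO scavenging by cell-free hemoglobin
(reduced vasorelaxation → constriction). By default S_ref
self-references each segment's stimulus in the entering flow state, so
an unperturbed network is already at its fixed point and the rule
responds only to the changes an infusion causes; `n_iter` (15) is a
remodeling horizon, not an equilibration count. An absolute shear set
point is available but is structurally unstable at fixed-pressure
boundaries (wall shear grows with radius), which is why richer
adaptation models add metabolic and conducted stimuli; those are out of
scope here.

## Oxygen transport

Intravascular: pO2 obeys `dP/dz = −2πr j_tv / (Q dC/dP)` along each
segment, with the Sherwood-lumped transvascular flux
`j_tv = Sh D_pl α_pl (P − P_tis) / (2r)` (Sh defaults to the classical
constant 3.66; a fitted correlation from the Krogh-cylinder module can
be plugged in). The integrator is an exponential (integrating-factor)
scheme with a midpoint capacitance estimate: unconditionally stable,
monotone, and exact for constant capacitance (plasma-only blood).
Confluent nodes mix to the unique pO2 that conserves total molar O2
flow, found by bisection on the monotone content balance (tolerance
1e−7 mm Hg, giving node conservation to ~1e−9 relative). Because
segments are oriented by pressure, a descending-pressure sweep is a
topological order even when the undirected topology is meshy. Boundary
inflow segments receive the radius-dependent inlet
`pO2 = min(p0 + slope·r, p_max)` (defaults 50 + 1·r, capped at 100).

Tissue: `α_t D_t ∇²P − V_M P/(K_M + P) + S = 0` with zero-flux outer
boundaries, on a regular voxel grid (default 40 µm). Vessel segments
enter as line sources: each segment's delivered O2, computed exactly as
`Q (C(P_in) − C(P_out))`, is splatted onto the grid by trilinear
deposition weighted by the local blood–tissue pO2 gap, so the vascular
and tissue budgets agree identically. The nonlinear solve is a damped
Newton iteration with Jacobi-preconditioned conjugate gradients (the
Jacobian is symmetric definite); the Michaelis–Menten term is extended
C¹-linearly below zero so Newton is globally well behaved, and any
negative excursions are clipped after convergence with a logged count
(persistent clipping indicates an under-resolved, starved region).

Two numerical devices matter for correctness:

* **Near-field (well-model) correction.** The tissue pO2 sampled at a
  line source corresponds to the continuum field at an effective radius
  r_eff = 0.72 × spacing (measured from the discrete Green's function
  of the trilinear deposit/sample stencil; spacing-invariant to <1%).
  The analytic steady profile between the vessel wall and r_eff — a log
  resistance minus the consumption offset `m (r_eff² − r_w²)/(4 α_t
  D_t)` of the unresolved annulus — is folded into the blood–tissue
  coupling. Without it, delivery depends strongly on voxel size; with
  it, halving the spacing moves mean tumor pO2 by well under 5%.
* **Semi-implicit source linearization.** Each outer iteration solves
  the tissue field with `S(T) ≈ S(T_old) − Λ (T − T_old)`, Λ the
  per-segment sensitivity of delivery to the local tissue pO2. The
  correction vanishes at the coupled fixed point (no budget bias) and
  keeps the pure-Neumann system nonsingular when consumption is zero —
  the case where the converged network must extract nothing.

The outer loop (vascular sweep → splat → tissue solve → relaxation,
default 0.5) stops when the max field change is below 0.01 mm Hg;
typical runs converge in 40–80 iterations.

## Krogh tissue cylinder and Sherwood calibration

The KTC module resolves a single vessel (Poiseuille velocity profile,
radial diffusion of dissolved O2, bound O2 advected in local
equilibrium) inside a concentric consuming tissue annulus, marching
axially with implicit radial slices; wall pO2 and flux are matched at a
shared finite-volume face. In a prescribed-wall-pO2 mode with
plasma-only blood it reproduces the classical fully developed Sherwood
number (3.657 vs 3.66 at the default resolution). The resolved wall
flux is reduced to an effective Sherwood number against the mixed-mean
minus *wall* pO2 difference — deliberately lumping only intravascular
resistance, since the network solver accounts for extravascular
resistance itself — and a linear correlation `Sh = c0 + c1/r + c2·HCT +
c3·C_HBOC` is fitted over parametric sweeps (constant predictors are
dropped automatically). On the default bed, swapping the constant 3.66
for a fitted correlation moves total OEF by well under 20%.

## Infusion scenarios

Seven shipped conditions: baseline plus {top-load, exchange} ×
{non-carrying control, T-State, R-State}, specifying HCT (0.45 /
0.41 / 0.35), plasma viscosity, HBOC dose (0 / 8 / 14 mg/mL), HBOC
affinity, and k_s (1 … 0.90). Because the simulated bed sits downstream
of unmodeled vasculature whose O2 extraction is assumed unchanged by
the infusion, the boundary inlet model must be recalibrated: for each
sampled radius (default 25 radii over [1, 49] µm, below the cap) the
modified blood's inlet pO2 solves `OE_baseline(r) = C_new(p_max) −
C_new(p)` by bisection, and a least-squares line gives the new
(p0, slope) with p_max fixed at 100 mm Hg. Extraction conservation
holds at every sampled radius to better than 1e−6 relative before the
fit. The recalibrated coefficients depend strongly on C_Hb,RBC; the
shipped presets therefore carry the published coefficient pairs as
their boundary models, while `recalibrate_boundary` is used for custom
compositions (and by the `infuse` CLI command).

## Bulk metrics

Standard stereological definitions over clipped segment lengths: MVD
(length density), RBV (volume fraction), RBF (blood inflow crossing
into the region per unit mass at 1 g/mL), tissue Hb/HBOC concentrations
and saturations weighted by segment mean pO2. Oxygen extraction
fractions are computed per species from molar flows at the network's
inlet and outlet segments; the decomposition identity
`OEF_total · J_in = Σ_s OEF_s · J_in,s` holds to rounding. MRO2 is the
region-averaged Michaelis–Menten uptake. Hypoxic fractions (threshold
5 mm Hg, configurable) are taken over non-necrotic tissue only; the
boundary region is the viable tumor rim (tumor fraction > 0, necrotic
fraction = 0).

## What the synthetic beds do and do not capture

The generator reproduces the *statistics* a grown tumor bed presents to
the transport model — elevated tumor MVD/RBV, an avascular necrotic
core, host periphery, seeded heterogeneity — not the morphology of
angiogenic remodeling (no tortuosity, shunts, lobed shapes, or
bed-type cohorts). Treatment comparisons share one bed per seed, so
directional conclusions (which infusion helps, by which mechanism) are
meaningful at desk scale, while absolute cohort values are not. One
directional result known from larger published models does **not**
reproduce here: at the exchange dose, the T-State solution's higher
plasma viscosity (1.51 vs 1.26 cP) cuts flow by ~20% at fixed boundary
pressures while its 14 mg/mL dose adds only ~12% heme, so its mean
tumor tissue pO2 lands ~1% *below* the exchange control's instead of
above. Shear-only adaptation cannot recover the flow (uniform viscosity
scaling leaves wall shear invariant under pressure boundaries); richer
adaptation physics would be needed.

## Problem sizes and tolerances

Default study conditions: 800 µm bed, ~950 segments, 20³ voxels at
40 µm, seven scenarios plus a human baseline (~60 s total on one core).
Mixing tolerance 1e−7 mm Hg; tissue Newton residual < 1e−8 of the
source norm; outer tolerance 0.01 mm Hg; flow conservation ~1e−14;
global O2 budget closes to ~1e−6 relative on converged runs.
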