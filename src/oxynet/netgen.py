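"""Seeded generation of desk-scale synthetic arterio-venous networks.

A full angiogenesis/remodeling growth simulation is out of scope here;
instead this module builds networks whose *statistics* emulate a grown
tumor bed: an arterial tree and a venous tree grown on a cubic lattice,
bridged by capillaries, with a parametric spherical tumor phantom
(dilated vessels in the viable rim, pruned capillaries in the necrotic
core, and matching tissue phase-fraction fields).

Networks are plain node/segment tables (pandas) with CSV/JSON round
trips; tissue grids are regular 3D arrays stored in HDF5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "GenerationError",
    "VesselNode",
    "VesselSegment",
    "VascularNetwork",
    "TissueGrid",
    "NetworkReport",
    "generate_av_network",
    "apply_tumor_phantom",
    "validate_network",
    "HOST_TISSUE_PARAMS",
]

NODE_KINDS = ("interior", "arterial_root", "venous_root")
WALL_TYPES = ("artery", "arteriole", "capillary", "venule", "vein")

#: Tissue consumption parameters by host species: maximum Michaelis-Menten
#: rate V_M (uM/s) and Michaelis constant K_M (mm Hg). Tumor tissue is the
#: same for both hosts; necrotic tissue does not consume O2 (V_M = 0).
HOST_TISSUE_PARAMS = {
    "mouse": {"v_m_host": 45.0, "k_m_host": 5.0},
    "human": {"v_m_host": 15.0, "k_m_host": 5.0},
}
V_M_TUMOR = 80.0
K_M_TUMOR = 2.0


class GenerationError(RuntimeError):
    """Raised when a network cannot be generated under the given constraints."""


@dataclass(frozen=True)
class VesselNode:
    id: int
    position: tuple[float, float, float]
    kind: str = "interior"


@dataclass(frozen=True)
class VesselSegment:
    id: int
    node_a: int
    node_b: int
    radius: float
    length: float
    wall_type: str = "capillary"
    region: str = "host"


class VascularNetwork:
    """Directed-capable vascular graph stored as node/segment tables.

    ``nodes``: DataFrame indexed by node id with columns x, y, z, kind.
    ``segments``: DataFrame indexed by segment id with columns a, b,
    radius, length, wall_type, region. Segment orientation is decided by
    the flow solver; (a, b) order carries no meaning.
    """

    def __init__(self, nodes: pd.DataFrame, segments: pd.DataFrame,
                 domain_size: tuple[float, float, float]):
        self.nodes = nodes
        self.segments = segments
        self.domain_size = tuple(float(d) for d in domain_size)
        self._validate_tables()

    def _validate_tables(self) -> None:
        missing = set(self.segments["a"]).union(self.segments["b"]) - set(self.nodes.index)
        if missing:
            raise ValueError(f"segments reference unknown nodes: {sorted(missing)[:5]}")
        if (self.segments["radius"] <= 0).any() or (self.segments["length"] <= 0).any():
            raise ValueError("segment radii and lengths must be positive")

    # -- convenience accessors -------------------------------------------------
    def copy(self) -> "VascularNetwork":
        return VascularNetwork(self.nodes.copy(), self.segments.copy(), self.domain_size)

    @property
    def positions(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(float)

    def root_ids(self, kind: str) -> list[int]:
        return list(self.nodes.index[self.nodes["kind"] == kind])

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes.index)
        for sid, row in self.segments.iterrows():
            g.add_edge(int(row["a"]), int(row["b"]), key=int(sid))
        return g

    def segment_midpoints(self) -> np.ndarray:
        pa = self.nodes.loc[self.segments["a"], ["x", "y", "z"]].to_numpy(float)
        pb = self.nodes.loc[self.segments["b"], ["x", "y", "z"]].to_numpy(float)
        return 0.5 * (pa + pb)

    def total_length(self) -> float:
        return float(self.segments["length"].sum())

    def mvd(self) -> float:
        """Microvascular density of the whole domain, mm/mm^3."""
        vol = float(np.prod(self.domain_size))  # um^3
        return self.total_length() / vol / 1e-6

    # -- I/O -------------------------------------------------------------------
    def to_csv(self, directory) -> None:
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        nodes = self.nodes.reset_index(names="id")
        nodes.to_csv(d / "nodes.csv", index=False)
        seg = self.segments.reset_index(names="id")
        seg[["id", "a", "b", "radius", "wall_type", "region"]].to_csv(
            d / "segments.csv", index=False
        )
        with open(d / "domain.json", "w") as fh:
            json.dump({"domain_size": list(self.domain_size)}, fh)

    @classmethod
    def from_csv(cls, directory) -> "VascularNetwork":
        import pathlib

        d = pathlib.Path(directory)
        nodes = pd.read_csv(d / "nodes.csv").set_index("id")
        seg = pd.read_csv(d / "segments.csv").set_index("id")
        pa = nodes.loc[seg["a"], ["x", "y", "z"]].to_numpy(float)
        pb = nodes.loc[seg["b"], ["x", "y", "z"]].to_numpy(float)
        seg["length"] = np.linalg.norm(pa - pb, axis=1)
        domain_file = d / "domain.json"
        if domain_file.exists():
            with open(domain_file) as fh:
                domain = tuple(json.load(fh)["domain_size"])
        else:
            domain = tuple(nodes[c].max() for c in ("x", "y", "z"))
        return cls(nodes, seg[["a", "b", "radius", "length", "wall_type", "region"]], domain)

    def to_json(self, path) -> None:
        doc = {
            "domain_size": list(self.domain_size),
            "nodes": self.nodes.reset_index(names="id").to_dict(orient="records"),
            "segments": self.segments.reset_index(names="id")[
                ["id", "a", "b", "radius", "wall_type", "region"]
            ].to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "VascularNetwork":
        with open(path) as fh:
            doc = json.load(fh)
        nodes = pd.DataFrame(doc["nodes"]).set_index("id")
        seg = pd.DataFrame(doc["segments"]).set_index("id")
        pa = nodes.loc[seg["a"], ["x", "y", "z"]].to_numpy(float)
        pb = nodes.loc[seg["b"], ["x", "y", "z"]].to_numpy(float)
        seg["length"] = np.linalg.norm(pa - pb, axis=1)
        return cls(nodes, seg[["a", "b", "radius", "length", "wall_type", "region"]],
                   tuple(doc["domain_size"]))

    def to_vtk(self, path) -> None:
        """Write the network as legacy ASCII VTK polylines (for viewers)."""
        idx = {nid: i for i, nid in enumerate(self.nodes.index)}
        pos = self.positions
        lines = [
            "# vtk DataFile Version 3.0",
            "oxynet vascular network",
            "ASCII",
            "DATASET POLYDATA",
            f"POINTS {len(pos)} float",
        ]
        lines += [f"{x:.6g} {y:.6g} {z:.6g}" for x, y, z in pos]
        nseg = len(self.segments)
        lines.append(f"LINES {nseg} {3 * nseg}")
        for _, row in self.segments.iterrows():
            lines.append(f"2 {idx[int(row['a'])]} {idx[int(row['b'])]}")
        lines.append(f"CELL_DATA {nseg}")
        lines.append("SCALARS radius float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{r:.6g}" for r in self.segments["radius"]]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class TissueGrid:
    """Regular 3D tissue grid of phase volume fractions and consumption.

    Voxel centers sit at ``origin + (i + 0.5) * spacing`` (0-based voxel
    indexing). ``v_m`` is the per-voxel maximum Michaelis-Menten O2
    consumption rate in uM/s and ``k_m`` the Michaelis constant in mm Hg;
    both are assembled from the phase fractions so that necrotic tissue
    does not consume O2.
    """

    spacing: float
    phi_normal: np.ndarray
    phi_tumor: np.ndarray
    phi_necrotic: np.ndarray
    v_m: np.ndarray
    k_m: np.ndarray
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.phi_normal, self.phi_tumor,
                                    self.phi_necrotic, self.v_m, self.k_m)}
        if len(shapes) != 1:
            raise ValueError("all grid arrays must share one shape")
        total = self.phi_normal + self.phi_tumor + self.phi_necrotic
        if (total > 1.0 + 1e-12).any() or (self.phi_normal < 0).any() \
                or (self.phi_tumor < 0).any() or (self.phi_necrotic < 0).any():
            raise ValueError("phase fractions must be >= 0 and sum to <= 1 per voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.phi_normal.shape

    @property
    def voxel_volume(self) -> float:
        return float(self.spacing**3)

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[ax] + (np.arange(self.shape[ax]) + 0.5) * self.spacing
            for ax in range(3)
        )

    def to_hdf5(self, path, extra: Optional[dict[str, np.ndarray]] = None) -> None:
        with h5py.File(path, "w") as fh:
            for name in ("phi_normal", "phi_tumor", "phi_necrotic", "v_m", "k_m"):
                fh.create_dataset(name, data=getattr(self, name))
            if extra:
                for name, arr in extra.items():
                    fh.create_dataset(name, data=arr)
            fh.attrs["spacing"] = self.spacing
            fh.attrs["origin"] = np.asarray(self.origin, float)

    @classmethod
    def from_hdf5(cls, path) -> "TissueGrid":
        with h5py.File(path, "r") as fh:
            kwargs = {
                name: fh[name][...]
                for name in ("phi_normal", "phi_tumor", "phi_necrotic", "v_m", "k_m")
            }
            spacing = float(fh.attrs["spacing"])
            origin = tuple(np.asarray(fh.attrs["origin"], float))
        return cls(spacing=spacing, origin=origin, **kwargs)


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

def _place_roots(shape: tuple[int, int, int], n_roots: int, preset: str,
                 rng: np.random.Generator) -> tuple[list, list]:
    """Pick arterial/venous root lattice indices (i, j, k) per placement preset."""
    nx_, ny_, nz_ = shape
    n_art = (n_roots + 1) // 2
    n_ven = n_roots - n_art

    def face_sites(i_fixed):
        return [(i_fixed, j, k) for j in range(1, ny_ - 1) for k in range(1, nz_ - 1)]

    if preset == "opposite_faces":
        art_pool, ven_pool = face_sites(0), face_sites(nx_ - 1)
    elif preset == "same_face":
        pool = face_sites(0)
        half = len(pool) // 2
        art_pool, ven_pool = pool[:half], pool[half:]
    elif preset == "corners":
        art_pool = [(i, j, k) for (i, j, k) in face_sites(0) if j + k <= (ny_ + nz_) // 2]
        ven_pool = [(i, j, k) for (i, j, k) in face_sites(nx_ - 1) if j + k >= (ny_ + nz_) // 2]
    else:
        raise ValueError(f"unknown root preset {preset!r}")

    art = [art_pool[i] for i in rng.choice(len(art_pool), size=n_art, replace=False)]
    ven = [ven_pool[i] for i in rng.choice(len(ven_pool), size=n_ven, replace=False)]
    return art, ven


def generate_av_network(
    domain_size: Sequence[float] = (800.0, 800.0, 800.0),
    lattice_pitch: float = 80.0,
    n_roots: int = 2,
    target_mvd: float = 80.0,
    seed: int = 0,
    root_preset: str = "opposite_faces",
    capillary_radius: float = 3.5,
    max_radius: float = 30.0,
) -> VascularNetwork:
    """Generate a connected arterio-venous network on a cubic lattice.

    An arterial and a venous shortest-path tree (randomized edge weights)
    are grown from boundary root nodes over a lattice partition;
    capillaries are lattice edges bridging the two trees, added until the
    microvascular density reaches ``target_mvd`` (mm/mm^3). Every segment
    lies on an arterial-root -> venous-root path by construction, and the
    output is a pure function of the arguments.

    Radii follow Murray's law from the number of capillaries drained
    downstream of each tree edge; the venous tree is slightly wider than
    the arterial tree at matched capillary count.
    """
    domain_size = tuple(float(d) for d in domain_size)
    n_cells = [int(round(d / lattice_pitch)) for d in domain_size]
    if min(n_cells) < 8:
        raise GenerationError(
            f"domain {domain_size} um holds {n_cells} lattice cells at pitch "
            f"{lattice_pitch}; need >= 8 cells per axis"
        )
    if n_roots < 2:
        raise GenerationError("need at least one arterial and one venous root")

    rng = np.random.default_rng(seed)
    shape = tuple(n + 1 for n in n_cells)  # lattice nodes per axis
    n_nodes = int(np.prod(shape))

    def nid(i, j, k):
        return (i * shape[1] + j) * shape[2] + k

    # lattice edges along the three axes, with seeded random weights
    edges = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if i + 1 < shape[0]:
                    edges.append((nid(i, j, k), nid(i + 1, j, k)))
                if j + 1 < shape[1]:
                    edges.append((nid(i, j, k), nid(i, j + 1, k)))
                if k + 1 < shape[2]:
                    edges.append((nid(i, j, k), nid(i, j, k + 1)))
    edges = np.asarray(edges)
    weights = lattice_pitch * rng.uniform(0.5, 1.5, size=len(edges))

    adj = coo_matrix(
        (np.concatenate([weights, weights]),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n_nodes, n_nodes),
    ).tocsr()

    art_idx, ven_idx = _place_roots(shape, n_roots, root_preset, rng)
    art_roots = [nid(*s) for s in art_idx]
    ven_roots = [nid(*s) for s in ven_idx]

    dist_a, pred_a = dijkstra(adj, indices=art_roots, min_only=True,
                              return_predecessors=True)[:2]
    dist_v, pred_v = dijkstra(adj, indices=ven_roots, min_only=True,
                              return_predecessors=True)[:2]
    side_arterial = dist_a <= dist_v  # ties go to the arterial side

    crossing = [tuple(e) for e in edges
                if side_arterial[e[0]] != side_arterial[e[1]]]
    order = rng.permutation(len(crossing))

    vol = float(np.prod(domain_size))                # um^3
    target_length = target_mvd * 1e-6 * vol          # um of vessel

    active_tree: dict[tuple[int, int], int] = {}     # tree edge -> capillary count
    cap_edges: list[tuple[int, int]] = []
    total_length = 0.0

    def walk_to_root(node, pred, on_art_side):
        """Yield tree edges from a node up to its root."""
        path = []
        cur = node
        while pred[cur] >= 0:
            nxt = int(pred[cur])
            path.append((min(cur, nxt), max(cur, nxt)))
            cur = nxt
        return path

    for ci in order:
        u, v = crossing[ci]
        if not side_arterial[u]:
            u, v = v, u
        new_edges = walk_to_root(u, pred_a, True) + walk_to_root(v, pred_v, False)
        for e in new_edges:
            if e not in active_tree:
                active_tree[e] = 0
                total_length += lattice_pitch
            active_tree[e] += 1
        cap_edges.append((u, v))
        total_length += lattice_pitch
        if total_length >= target_length:
            break
    else:
        if total_length < 0.8 * target_length:
            raise GenerationError(
                f"target MVD {target_mvd} mm/mm^3 infeasible: reached only "
                f"{total_length / vol / 1e-6:.1f} mm/mm^3 using every "
                f"lattice crossing; lower target_mvd or lattice_pitch"
            )

    # node table (only nodes touched by active edges), deterministic order
    used = sorted({n for e in list(active_tree) + cap_edges for n in e})
    remap = {old: new for new, old in enumerate(used)}
    coords = np.empty((len(used), 3))
    kinds = []
    art_set, ven_set = set(art_roots), set(ven_roots)
    for old in used:
        i, rem = divmod(old, shape[1] * shape[2])
        j, k = divmod(rem, shape[2])
        coords[remap[old]] = (i * lattice_pitch, j * lattice_pitch, k * lattice_pitch)
        kinds.append("arterial_root" if old in art_set
                     else "venous_root" if old in ven_set else "interior")

    nodes = pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2], "kind": kinds},
        index=pd.Index(range(len(used)), name="id"),
    )

    rows = []
    for (a, b), count in sorted(active_tree.items()):
        on_art = bool(side_arterial[a])
        factor = 1.0 if on_art else 1.2
        radius = min(capillary_radius * factor * count ** (1.0 / 3.0), max_radius)
        if on_art:
            wall = "artery" if radius >= 12.0 else "arteriole"
        else:
            wall = "vein" if radius >= 12.0 else "venule"
        rows.append((remap[a], remap[b], radius, lattice_pitch, wall, "host"))
    for a, b in sorted(cap_edges):
        rows.append((remap[a], remap[b], capillary_radius, lattice_pitch,
                     "capillary", "host"))
    segments = pd.DataFrame(
        rows, columns=["a", "b", "radius", "length", "wall_type", "region"],
        index=pd.Index(range(len(rows)), name="id"),
    )
    return VascularNetwork(nodes, segments, domain_size)


# ---------------------------------------------------------------------------
# tumor phantom
# ---------------------------------------------------------------------------

def _trim_dead_ends(network: VascularNetwork) -> VascularNetwork:
    """Iteratively remove degree-1 non-root nodes and their segments."""
    seg = network.segments.copy()
    nodes = network.nodes
    roots = set(network.root_ids("arterial_root")) | set(network.root_ids("venous_root"))
    while True:
        counts = pd.concat([seg["a"], seg["b"]]).value_counts()
        dead = [n for n, c in counts.items() if c == 1 and n not in roots]
        if not dead:
            break
        dead = set(dead)
        seg = seg[~(seg["a"].isin(dead) | seg["b"].isin(dead))]
    used = set(seg["a"]).union(seg["b"]) | roots
    return VascularNetwork(nodes.loc[sorted(used)], seg, network.domain_size)


def apply_tumor_phantom(
    network: VascularNetwork,
    center: Sequence[float],
    radius: float,
    necrotic_radius: float,
    dilation_factor: float = 1.3,
    prune_fraction: float = 0.5,
    seed: int = 0,
    grid_spacing: float = 40.0,
    host: str = "mouse",
    max_attempts: int = 5,
) -> tuple[VascularNetwork, TissueGrid]:
    """Stamp a spherical tumor phantom onto a host network.

    Segments with midpoints inside the tumor sphere are relabeled
    ``region='tumor'`` and dilated by ``dilation_factor`` (grown tumors
    show elevated microvascular density and regional blood volume);
    capillaries inside the necrotic core are pruned at ``prune_fraction``
    and the resulting dead ends trimmed.

    The returned tissue grid mimics an infiltrative continuum tumor: the
    necrotic core is pure, while the viable shell is a tumor/host phase
    mixture ramping linearly from pure tumor at the core edge to pure
    host at the outer radius. Per-voxel V_M / K_M maps are assembled as
    the phase-fraction-weighted mixtures (necrotic tissue consumes no
    O2).
    """
    if not necrotic_radius < radius:
        raise ValueError("necrotic_radius must be smaller than the tumor radius")
    center = np.asarray(center, float)
    if host not in HOST_TISSUE_PARAMS:
        raise ValueError(f"unknown host {host!r}; expected {sorted(HOST_TISSUE_PARAMS)}")

    last_error = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        net = network.copy()
        mid = net.segment_midpoints()
        dist = np.linalg.norm(mid - center, axis=1)
        in_tumor = dist < radius
        in_core = dist < necrotic_radius

        seg = net.segments
        seg.loc[in_tumor, "region"] = "tumor"
        if dilation_factor != 1.0:
            seg.loc[in_tumor, "radius"] *= dilation_factor

        if prune_fraction > 0.0:
            cap = (seg["wall_type"] == "capillary").to_numpy()
            candidates = np.flatnonzero(cap & in_core)
            drop = candidates[rng.random(len(candidates)) < prune_fraction]
            seg = seg.drop(index=seg.index[drop])
            net = VascularNetwork(net.nodes, seg, net.domain_size)
            net = _trim_dead_ends(net)

        g = net.graph()
        art = net.root_ids("arterial_root")
        ven = net.root_ids("venous_root")
        ok = any(nx.has_path(g, a, v) for a in art for v in ven)
        if ok:
            break
        last_error = (
            f"pruning (fraction {prune_fraction}, attempt {attempt + 1}) "
            "disconnected every arterial-to-venous path"
        )
    else:
        raise GenerationError(last_error)

    # tissue phase fields on the voxel grid
    shape = tuple(int(np.ceil(d / grid_spacing)) for d in network.domain_size)
    axes = [
        (np.arange(shape[ax]) + 0.5) * grid_spacing for ax in range(3)
    ]
    xg, yg, zg = np.meshgrid(*axes, indexing="ij")
    r_vox = np.sqrt((xg - center[0]) ** 2 + (yg - center[1]) ** 2 + (zg - center[2]) ** 2)

    phi_necrotic = (r_vox < necrotic_radius).astype(float)
    shell = (r_vox >= necrotic_radius) & (r_vox < radius)
    ramp = np.clip((radius - r_vox) / (radius - necrotic_radius), 0.0, 1.0)
    phi_tumor = np.where(shell, ramp, 0.0)
    phi_normal = 1.0 - phi_necrotic - phi_tumor

    params = HOST_TISSUE_PARAMS[host]
    v_m = phi_normal * params["v_m_host"] + phi_tumor * V_M_TUMOR  # necrotic: 0
    k_m = (phi_normal * params["k_m_host"] + phi_tumor * K_M_TUMOR
           + phi_necrotic * params["k_m_host"])

    grid = TissueGrid(spacing=float(grid_spacing), phi_normal=phi_normal,
                      phi_tumor=phi_tumor, phi_necrotic=phi_necrotic,
                      v_m=v_m, k_m=k_m)
    return net, grid


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class NetworkReport:
    n_nodes: int
    n_segments: int
    n_arterial_roots: int
    n_venous_roots: int
    connected: bool
    orphan_segments: list[int] = field(default_factory=list)
    radius_violations: list[int] = field(default_factory=list)
    length_mismatches: list[int] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return (self.connected and not self.orphan_segments
                and not self.length_mismatches)


def validate_network(network: VascularNetwork) -> NetworkReport:
    """Audit a network; reports problems instead of raising.

    Orphan segments are those not on any arterial-root -> venous-root
    path: dead-end branches (removed by iterative degree-1 peeling) plus
    segments in components lacking both root kinds. Radius monotonicity
    is checked along shortest paths from each root: a segment whose
    radius exceeds its parent segment's radius on the path away from the
    root is flagged (capillaries exempt).
    """
    g = network.graph()
    art = set(network.root_ids("arterial_root"))
    ven = set(network.root_ids("venous_root"))

    # components must contain both root kinds
    orphan = set()
    good_nodes = set()
    for comp in nx.connected_components(g):
        if comp & art and comp & ven:
            good_nodes |= comp
        else:
            for sid, row in network.segments.iterrows():
                if row["a"] in comp or row["b"] in comp:
                    orphan.add(int(sid))
    connected = len(good_nodes) == len(network.nodes)

    # dead-end peeling inside good components
    seg = network.segments[~network.segments.index.isin(orphan)]
    roots = art | ven
    while True:
        counts = pd.concat([seg["a"], seg["b"]]).value_counts()
        dead = {n for n, c in counts.items() if c == 1 and n not in roots}
        if not dead:
            break
        gone = seg.index[seg["a"].isin(dead) | seg["b"].isin(dead)]
        orphan.update(int(s) for s in gone)
        seg = seg.drop(index=gone)

    # radius monotonicity away from roots (tree sides only)
    radius_violations: set[int] = set()
    non_cap = network.segments[network.segments["wall_type"] != "capillary"]
    sub = nx.Graph()
    for sid, row in non_cap.iterrows():
        sub.add_edge(int(row["a"]), int(row["b"]), sid=int(sid),
                     radius=float(row["radius"]))
    for root in roots:
        if root not in sub:
            continue
        for u, v in nx.bfs_edges(sub, root):
            child = sub.edges[u, v]
            for w in sub.neighbors(v):
                if w == u:
                    continue
                grand = sub.edges[v, w]
                if grand["radius"] > child["radius"] * (1 + 1e-9):
                    radius_violations.add(grand["sid"])

    pa = network.nodes.loc[network.segments["a"], ["x", "y", "z"]].to_numpy(float)
    pb = network.nodes.loc[network.segments["b"], ["x", "y", "z"]].to_numpy(float)
    euclid = np.linalg.norm(pa - pb, axis=1)
    mism = np.abs(euclid - network.segments["length"].to_numpy(float)) > 1e-6 * np.maximum(euclid, 1.0)
    length_mismatches = [int(s) for s in network.segments.index[mism]]

    return NetworkReport(
        n_nodes=len(network.nodes),
        n_segments=len(network.segments),
        n_arterial_roots=len(art),
        n_venous_roots=len(ven),
        connected=connected,
        orphan_segments=sorted(orphan),
        radius_violations=sorted(radius_violations),
        length_mismatches=length_mismatches,
    )
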