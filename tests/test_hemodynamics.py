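"""Poiseuille network flow, viscosity laws, partitioning, adaptation."""

import numpy as np
import pytest

import oxynet as ox
from oxynet.hemodynamics import (
    CP_TO_PA_S,
    MMHG_TO_PA,
    check_mass_conservation,
    wall_shear_stress,
)

from conftest import build_network


class TestEffectiveViscosity:
    def test_zero_hct_limit_is_plasma(self):
        for r in (3.0, 10.0, 40.0):
            assert ox.effective_viscosity(r, 0.0, 1.26) == pytest.approx(1.26, rel=1e-9)

    def test_monotone_in_hct(self):
        for law in ("pries_invitro", "pries_invivo"):
            for r in (4.0, 12.0, 30.0):
                mus = [ox.effective_viscosity(r, h, 1.26, law=law)
                       for h in np.linspace(0.0, 0.6, 13)]
                assert np.all(np.diff(mus) > 0)

    def test_plasma_viscosity_scales_proportionally(self):
        # exchange T-State raises plasma viscosity 1.26 -> 1.51 cP
        lo = ox.effective_viscosity(8.0, 0.0, 1.26)
        hi = ox.effective_viscosity(8.0, 0.0, 1.51)
        assert hi / lo == pytest.approx(1.51 / 1.26, rel=1e-12)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            ox.effective_viscosity(0.0, 0.4, 1.26)


class TestSolveFlow:
    def test_single_tube_poiseuille(self, single_tube, mouse_blood):
        fl = ox.solve_flow(single_tube, root_pressures={"arterial_root": 60.0,
                                                        "venous_root": 20.0},
                           blood=mouse_blood)
        mu = ox.effective_viscosity(10.0, 0.45, mouse_blood.plasma_viscosity,
                                    law="pries_invivo")
        expected = (np.pi * 10.0**4 * 40.0 * MMHG_TO_PA
                    / (8.0 * mu * CP_TO_PA_S * 400.0))
        assert fl.segment_flow.loc[0] == pytest.approx(expected, rel=1e-12)
        assert fl.segment_shear.loc[0] == pytest.approx(
            wall_shear_stress(10.0, expected, mu), rel=1e-12)

    def test_symmetric_bifurcation_splits_evenly(self, y_bifurcation, mouse_blood):
        fl = ox.solve_flow(y_bifurcation, blood=mouse_blood)
        q1, q2 = abs(fl.segment_flow.loc[1]), abs(fl.segment_flow.loc[2])
        assert q1 == pytest.approx(q2, rel=1e-12)
        assert check_mass_conservation(y_bifurcation, fl) < 1e-9

    def test_random_tree_matches_dense_solve(self, mouse_blood):
        rng = np.random.default_rng(5)
        # random binary tree, 50 segments
        nodes = [(0, 0.0, 0.0, 0.0, "arterial_root")]
        segments = []
        next_node = 1
        frontier = [0]
        while len(segments) < 49:
            parent = int(rng.choice(frontier))
            pos = tuple(rng.uniform(0, 800, size=3))
            nodes.append((next_node, *pos, "interior"))
            segments.append((len(segments), parent, next_node,
                             float(rng.uniform(3, 15))))
            frontier.append(next_node)
            next_node += 1
        # close onto a venous root
        nodes.append((next_node, 800.0, 800.0, 800.0, "venous_root"))
        leaf = next_node - 1
        segments.append((len(segments), leaf, next_node, 8.0))
        net = build_network(nodes, segments, domain=(800.0,) * 3)

        fl = ox.solve_flow(net, blood=mouse_blood)
        # dense reference solve with the same conductances
        seg = net.segments
        mu = ox.effective_viscosity(seg["radius"].to_numpy(), 0.45,
                                    mouse_blood.plasma_viscosity,
                                    law="pries_invivo")
        g = (np.pi * seg["radius"].to_numpy() ** 4 * MMHG_TO_PA
             / (8.0 * mu * CP_TO_PA_S * seg["length"].to_numpy()))
        n = len(net.nodes)
        lap = np.zeros((n, n))
        for (a, b), gv in zip(seg[["a", "b"]].to_numpy(int), g):
            lap[a, a] += gv
            lap[b, b] += gv
            lap[a, b] -= gv
            lap[b, a] -= gv
        p = np.zeros(n)
        p[0], p[next_node] = 60.0, 15.0
        free = np.ones(n, bool)
        free[[0, next_node]] = False
        p[free] = np.linalg.solve(lap[np.ix_(free, free)],
                                  -lap[np.ix_(free, ~free)] @ p[~free])
        q_ref = g * (p[seg["a"].to_numpy(int)] - p[seg["b"].to_numpy(int)])
        # dead-end branches carry exactly zero flow up to roundoff of the
        # dominant path flow; compare with a correspondingly scaled atol
        assert np.allclose(fl.segment_flow.to_numpy(), q_ref, rtol=1e-10,
                           atol=1e-11 * np.abs(q_ref).max())

    def test_global_balance_on_generated_network(self, mouse_blood):
        net = ox.generate_av_network(seed=4)
        fl = ox.solve_flow(net, blood=mouse_blood)
        assert check_mass_conservation(net, fl) < 1e-9
        oriented = fl.oriented(net)
        art = set(net.root_ids("arterial_root"))
        ven = set(net.root_ids("venous_root"))
        inflow = oriented[oriented["u"].isin(art)]["q"].sum()
        outflow = oriented[oriented["v"].isin(ven)]["q"].sum()
        assert inflow == pytest.approx(outflow, rel=1e-9)

    def test_hemodilution_increases_flow(self, mouse_blood):
        net = ox.generate_av_network(seed=4)
        q45 = ox.solve_flow(net, blood=mouse_blood).segment_flow.abs().sum()
        q35 = ox.solve_flow(net, blood=mouse_blood.with_(hct=0.35)
                            ).segment_flow.abs().sum()
        assert q35 > q45

    def test_feed_vessels_reduce_flow(self, single_tube, mouse_blood):
        free = ox.solve_flow(single_tube, blood=mouse_blood)
        fed = ox.solve_flow(single_tube, blood=mouse_blood,
                            feed_vessels={"arterial_root":
                                          {"radius": 8.0, "length": 2000.0}})
        assert abs(fed.segment_flow.loc[0]) < abs(free.segment_flow.loc[0])

    def test_disconnected_component_raises(self, mouse_blood):
        net = build_network(
            nodes=[(0, 0, 0, 0, "arterial_root"), (1, 100, 0, 0, "venous_root"),
                   (2, 0, 200, 0, "interior"), (3, 100, 200, 0, "interior")],
            segments=[(0, 0, 1, 5.0), (1, 2, 3, 5.0)],
        )
        with pytest.raises(ValueError):
            ox.solve_flow(net, blood=mouse_blood)


class TestPartition:
    def test_chain_carries_composition_unchanged(self, mouse_blood):
        net = build_network(
            nodes=[(0, 0, 0, 0, "arterial_root"), (1, 100, 0, 0, "interior"),
                   (2, 200, 0, 0, "interior"), (3, 300, 0, 0, "venous_root")],
            segments=[(0, 0, 1, 6.0), (1, 1, 2, 6.0), (2, 2, 3, 6.0)],
        )
        fl = ox.solve_flow(net, blood=mouse_blood)
        fl = ox.partition_hematocrit_and_hboc(net, fl, 0.45, 0.6)
        assert np.allclose(fl.segment_hct, 0.45, atol=1e-12)
        assert np.allclose(fl.segment_c_hboc, 0.6, atol=1e-12)

    @pytest.mark.parametrize("rule", ["proportional", "pries"])
    def test_rbc_and_hboc_flux_conserved(self, rule, mouse_blood):
        net = ox.generate_av_network(seed=4)
        fl = ox.solve_flow(net, blood=mouse_blood)
        fl = ox.partition_hematocrit_and_hboc(net, fl, 0.45, 0.5, rule=rule)
        oriented = fl.oriented(net)
        for nid, kind in net.nodes["kind"].items():
            if kind != "interior":
                continue
            ins = oriented[(oriented["v"] == nid) & (oriented["q"] > 0)]
            outs = oriented[(oriented["u"] == nid) & (oriented["q"] > 0)]
            if not len(ins) or not len(outs):
                continue
            for field in ("segment_hct", "segment_c_hboc"):
                fin = (ins["q"] * getattr(fl, field).loc[ins.index]).sum()
                fout = (outs["q"] * getattr(fl, field).loc[outs.index]).sum()
                assert fout == pytest.approx(fin, rel=1e-10)

    def test_convergent_node_flux_weighted_mixing(self, mouse_blood):
        # two parents of unequal flow merging into one child: the child
        # hct must equal (Q1 H1 + Q2 H2) / (Q1 + Q2); here the parents
        # have equal hct, so mixing is exact regardless of flow split
        net = build_network(
            nodes=[(0, 0, 0, 0, "arterial_root"), (1, 0, 200, 0, "arterial_root"),
                   (2, 150, 100, 0, "interior"), (3, 350, 100, 0, "venous_root")],
            segments=[(0, 0, 2, 9.0), (1, 1, 2, 5.0), (2, 2, 3, 8.0)],
        )
        fl = ox.solve_flow(net, blood=mouse_blood)
        fl = ox.partition_hematocrit_and_hboc(net, fl, 0.45, 0.4)
        oriented = fl.oriented(net)
        q0, q1 = oriented.loc[0, "q"], oriented.loc[1, "q"]
        expected = (q0 * 0.45 + q1 * 0.45) / (q0 + q1)
        assert fl.segment_hct.loc[2] == pytest.approx(expected, rel=1e-12)
        assert fl.segment_c_hboc.loc[2] == pytest.approx(0.4, rel=1e-10)


class TestAdaptation:
    def test_zero_step_is_identity(self, mouse_blood):
        net = ox.generate_av_network(seed=4)
        fl = ox.solve_flow(net, blood=mouse_blood)
        params = ox.AdaptationParams(step=0.0)
        out, _ = ox.adapt_radii(net, fl, params, mouse_blood)
        assert out.segments["radius"].equals(net.segments["radius"])

    def test_self_referenced_baseline_is_fixed_point(self, mouse_blood):
        net = ox.generate_av_network(seed=4)
        fl = ox.solve_flow(net, blood=mouse_blood)
        out, _ = ox.adapt_radii(net, fl, ox.AdaptationParams(k_s=1.0),
                                mouse_blood)
        assert np.allclose(out.segments["radius"], net.segments["radius"],
                           rtol=1e-6)

    def test_lower_k_s_constricts(self, mouse_blood):
        net = ox.generate_av_network(seed=4)
        fl = ox.solve_flow(net, blood=mouse_blood)
        r1, _ = ox.adapt_radii(net, fl, ox.AdaptationParams(k_s=1.0), mouse_blood)
        r090, _ = ox.adapt_radii(net, fl, ox.AdaptationParams(k_s=0.90), mouse_blood)
        assert np.all(r090.segments["radius"].to_numpy()
                      <= r1.segments["radius"].to_numpy() + 1e-12)
        assert r090.segments["radius"].sum() < r1.segments["radius"].sum()

    def test_rerun_on_own_output_is_stable(self, mouse_blood):
        net = ox.generate_av_network(seed=4)
        fl = ox.solve_flow(net, blood=mouse_blood)
        params = ox.AdaptationParams(k_s=0.95)
        once, fl1 = ox.adapt_radii(net, fl, params, mouse_blood)
        # k_s relative to the adapted state: no further stimulus change
        twice, _ = ox.adapt_radii(once, fl1, ox.AdaptationParams(k_s=1.0),
                                  mouse_blood)
        assert np.allclose(twice.segments["radius"], once.segments["radius"],
                           rtol=1e-6)

    def test_invalid_k_s(self):
        with pytest.raises(ValueError):
            ox.AdaptationParams(k_s=0.0)
        with pytest.raises(ValueError):
            ox.AdaptationParams(k_s=1.2)
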