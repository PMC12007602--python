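import itertools

import numpy as np
import pandas as pd
import pytest

import ierpkit as ik


def brute_force_geodesics(mesh, source):
    """All-simple-paths shortest distances (exponential; tiny meshes only)."""
    edges = mesh.edge_lengths()
    adj = {i: [] for i in range(mesh.n_nodes)}
    for (i, j), w in edges.items():
        adj[i].append((j, w))
        adj[j].append((i, w))
    best = {source: 0.0}

    def walk(node, dist, visited):
        for nxt, w in adj[node]:
            if nxt in visited:
                continue
            d = dist + w
            if d < best.get(nxt, np.inf):
                best[nxt] = d
            walk(nxt, d, visited | {nxt})

    walk(source, 0.0, {source})
    return best


class TestGeodesics:
    def test_strip_chain_sum(self, strip_mesh):
        d = ik.geodesic_distances(strip_mesh, 0)
        assert d[5] == pytest.approx(5.0)
        assert d[17] == pytest.approx(17.0)

    def test_matches_brute_force_on_small_mesh(self):
        mesh = ik.make_mesh("sphere", 10, 2.0)
        for source in range(10):
            want = brute_force_geodesics(mesh, source)
            got = ik.geodesic_distances(mesh, source)
            assert set(got) == set(want)
            for node in want:
                assert got[node] == pytest.approx(want[node], abs=1e-9)

    def test_truncation_drops_far_nodes(self, strip_mesh):
        d = ik.geodesic_distances(strip_mesh, 0, max_mm=5.0)
        assert set(d) == set(range(6))

    def test_disconnected_component_absent(self):
        pos = np.array(
            [
                [0, 0, 0], [1, 0, 0], [0, 1, 0],
                [10, 10, 0], [11, 10, 0], [10, 11, 0],
            ],
            dtype=float,
        )
        tris = np.array([[0, 1, 2], [3, 4, 5]])
        mesh = ik.CorticalMesh(pos, tris)
        d = ik.geodesic_distances(mesh, 0)
        assert set(d) == {0, 1, 2}

    def test_source_out_of_range(self, strip_mesh):
        with pytest.raises(ValueError, match="out of range"):
            ik.geodesic_distances(strip_mesh, 99)


class TestNodeWeight:
    def test_midpoint_is_exactly_half(self):
        assert ik.node_weight(7.5) == 0.5

    def test_closed_form_at_5mm(self):
        assert ik.node_weight(5.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-5.0)), abs=1e-12
        )

    def test_strictly_decreasing(self):
        assert ik.node_weight(4.0) > ik.node_weight(9.0)
        d = np.linspace(0, 15, 100)
        w = ik.node_weight(d)
        assert np.all(np.diff(w) < 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            ik.node_weight(-1.0)


class TestNeighbourhood:
    def test_strip_disk_has_21_members(self, strip_mesh):
        nb = ik.build_neighbourhood(strip_mesh, 15)
        assert len(nb.members) == 21
        assert 15 in nb.members

    def test_symmetric_weights_for_symmetric_geometry(self, strip_mesh):
        nb = ik.build_neighbourhood(strip_mesh, 15)
        w = dict(zip(nb.members, nb.weights))
        assert w[12] == pytest.approx(w[18])  # +-3 mm
        assert w[15] == pytest.approx(ik.node_weight(0.0))

    def test_isolated_node_is_its_own_neighbourhood(self):
        pos = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [50, 50, 50]], dtype=float
        )
        mesh = ik.CorticalMesh(pos, np.array([[0, 1, 2]]))
        nb = ik.build_neighbourhood(mesh, 3)
        np.testing.assert_array_equal(nb.members, [3])
        assert nb.weights[0] == pytest.approx(ik.node_weight(0.0))


def flags_frame(rows):
    return pd.DataFrame(rows).set_index("lead_id")


class TestComputeMap:
    def test_single_responsive_lead_gives_100_percent(self, grid_mesh):
        leads, assignment = ik.make_leads(grid_mesh, 1, seed=0)
        flags = flags_frame(
            [{"lead_id": "L000", "responsive": True, "selective": False}]
        )
        m = ik.compute_map("overall", grid_mesh, assignment, flags)
        assert np.all(m.values[m.mask] == pytest.approx(100.0))
        assert m.mask.any()

    def test_threshold_masks_8_keeps_12_percent(self, grid_mesh, config):
        """2/25 = 8 % is masked out, 3/25 = 12 % survives the display cut."""
        cfg = config.replace(nodes_per_lead=1)
        centre = 55
        assignment = {f"L{i:03d}": np.array([centre]) for i in range(25)}
        for n_resp, should_show in ((2, False), (3, True)):
            flags = flags_frame(
                [
                    {
                        "lead_id": f"L{i:03d}",
                        "responsive": i < n_resp,
                        "selective": False,
                    }
                    for i in range(25)
                ]
            )
            m = ik.compute_map("overall", grid_mesh, assignment, flags, cfg)
            assert m.mask[centre] == should_show
            expected = 100.0 * n_resp / 25
            assert m.values[centre] == pytest.approx(expected)

    def test_density_single_lead_closed_form(self):
        """One lead in a large flat plane: density ~= 1/pi leads per cm^2."""
        mesh = ik.make_mesh("grid", 1600, 1.0)
        centre_node = 20 * 40 + 20
        lead_pos = mesh.node_positions[centre_node]
        d = np.linalg.norm(mesh.node_positions - lead_pos, axis=1)
        assignment = {"L000": np.argsort(d, kind="stable")[:7]}
        m = ik.compute_map("density", mesh, assignment, None)
        assert m.values[centre_node] == pytest.approx(1 / np.pi, rel=1e-3)

    def test_matches_recomputation_from_definitions(self, strip_mesh, config):
        """Map values equal a per-node recomputation from the raw rules."""
        assignment = {
            "A": np.arange(0, 7),
            "B": np.arange(7, 14),
            "C": np.arange(14, 21),
        }
        flags = flags_frame(
            [
                {"lead_id": "A", "responsive": True, "selective": True},
                {"lead_id": "B", "responsive": True, "selective": False},
                {"lead_id": "C", "responsive": False, "selective": False},
            ]
        )
        got = ik.compute_map("overall", strip_mesh, assignment, flags, config)
        got_rel = ik.compute_map(
            "relative", strip_mesh, assignment, flags, config
        )
        for node in range(strip_mesh.n_nodes):
            nb = ik.build_neighbourhood(strip_mesh, node, config)
            w = dict(zip(nb.members, nb.weights))
            explored = sum(
                w.get(m, 0.0) for nodes in assignment.values() for m in nodes
            )
            responsive = sum(
                w.get(m, 0.0)
                for lead in ("A", "B")
                for m in assignment[lead]
            )
            selective = sum(w.get(m, 0.0) for m in assignment["A"])
            if explored > 0:
                assert got.values[node] == pytest.approx(
                    100 * responsive / explored, abs=1e-9
                )
            if responsive > 0:
                assert got_rel.values[node] == pytest.approx(
                    100 * selective / responsive, abs=1e-9
                )

    def test_percent_maps_bounded(self, sphere_mesh):
        rng = np.random.default_rng(4)
        leads, assignment = ik.make_leads(sphere_mesh, 10, seed=4)
        resp = rng.random(10) < 0.6
        sel = resp & (rng.random(10) < 0.5)
        flags = flags_frame(
            [
                {
                    "lead_id": lid,
                    "responsive": bool(resp[i]),
                    "selective": bool(sel[i]),
                }
                for i, lid in enumerate(leads.lead_ids)
            ]
        )
        for kind in ("overall", "relative"):
            m = ik.compute_map(kind, sphere_mesh, assignment, flags)
            shown = m.values[m.mask]
            assert np.all(shown <= 100 + 1e-9)
            assert np.all(shown >= 0)

    def test_node_permutation_invariance(self, grid_mesh):
        leads, assignment = ik.make_leads(grid_mesh, 3, seed=2)
        flags = flags_frame(
            [
                {"lead_id": lid, "responsive": i < 2, "selective": i < 1}
                for i, lid in enumerate(leads.lead_ids)
            ]
        )
        base = ik.compute_map("overall", grid_mesh, assignment, flags)
        rng = np.random.default_rng(0)
        perm = rng.permutation(grid_mesh.n_nodes)  # new index of old node
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        permuted_mesh = ik.CorticalMesh(
            grid_mesh.node_positions[inv], perm[grid_mesh.triangles]
        )
        permuted_assignment = {
            k: np.sort(perm[v]) for k, v in assignment.items()
        }
        permuted = ik.compute_map(
            "overall", permuted_mesh, permuted_assignment, flags
        )
        np.testing.assert_allclose(
            permuted.values[perm], base.values, atol=1e-9
        )

    def test_selective_without_responsive_rejected(self, grid_mesh):
        leads, assignment = ik.make_leads(grid_mesh, 1, seed=0)
        flags = flags_frame(
            [{"lead_id": "L000", "responsive": False, "selective": True}]
        )
        with pytest.raises(ValueError, match="inconsistent"):
            ik.compute_map("relative", grid_mesh, assignment, flags)

    def test_relative_with_no_responsive_warns_fully_masked(self, grid_mesh):
        leads, assignment = ik.make_leads(grid_mesh, 1, seed=0)
        flags = flags_frame(
            [{"lead_id": "L000", "responsive": False, "selective": False}]
        )
        with pytest.warns(UserWarning, match="fully masked"):
            m = ik.compute_map("relative", grid_mesh, assignment, flags)
        assert not m.mask.any()

    def test_unknown_kind_rejected(self, grid_mesh):
        leads, assignment = ik.make_leads(grid_mesh, 1, seed=0)
        with pytest.raises(ValueError, match="kind"):
            ik.compute_map("weird", grid_mesh, assignment, None)
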