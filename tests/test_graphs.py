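"""Graph construction: schemas, KNN correctness, invariance of features."""

import numpy as np
import pytest

from conftest import random_rotation
from loopforge.fixtures import make_loop_task
from loopforge.graphs import (
    EDGE_LOOP_LOOP,
    EDGE_LOOP_RES,
    EDGE_RES_RES,
    build_atom_graph,
    build_interaction_graph,
    build_residue_graph,
)
from loopforge.pocketing import init_loop_reconstruction, select_surface_pocket
from loopforge.structio import LoopSpec, parse_pdb


@pytest.fixture(scope="module")
def task_pieces():
    structure, spec, truth = make_loop_task(8, 6, 8, seed=5)
    pocket = select_surface_pocket(structure, spec)
    return structure, spec, truth, pocket


class TestAtomGraph:
    def test_counts_match_selected_residues(self, task_pieces):
        structure, spec, _, pocket = task_pieces
        g = build_atom_graph(structure, pocket, spec)
        wanted = set(pocket.residue_ids) | {
            (spec.chain_id, i) for i in range(spec.start, spec.end + 1)
        }
        expected = sum(
            len(r.atoms) for r in structure.residues() if (r.chain_id, r.index) in wanted
        )
        assert g.node_scalars.shape[0] == expected == len(g.coords)

    def test_feature_width_constant_and_onehot(self, task_pieces):
        structure, spec, _, pocket = task_pieces
        g = build_atom_graph(structure, pocket, spec)
        assert g.node_scalars.shape[1] == 31
        # element block rows sum to one
        assert np.all(g.node_scalars[:, :5].sum(axis=1) == 1.0)

    def test_edges_symmetric_directed(self, task_pieces):
        structure, spec, _, pocket = task_pieces
        g = build_atom_graph(structure, pocket, spec)
        pairs = {(a, b) for a, b in g.edges}
        assert all((b, a) in pairs for a, b in pairs)
        assert all(a != b for a, b in pairs)

    def test_single_ala_subgraph(self):
        """One selected ALA residue: 5 atom nodes, 4 undirected bonds."""
        from loopforge.fixtures import ChainRecipe, build_chain
        from loopforge.pocketing import PocketSelection

        s = build_chain(ChainRecipe(segments=[("helix", 3)], seed=0))
        pocket = PocketSelection(residue_ids=set(), midpoint=np.zeros(3), radius=1.0)
        spec = LoopSpec(chain_id="A", start=1, end=1)  # anchors are residues 0 and 2
        g = build_atom_graph(s, pocket, spec)
        assert g.node_scalars.shape[0] == 5
        assert len(g.edges) == 8  # peptide bonds to unselected residues drop out


class TestResidueGraph:
    def test_knn_degree(self, task_pieces):
        structure, spec, _, pocket = task_pieces
        g = build_residue_graph(structure, pocket, K=30, spec=spec)
        P = len(g.residue_ids)
        in_deg = np.bincount(g.edges[:, 1], minlength=P)
        assert np.all(in_deg == min(30, P - 1))

    def test_knn_matches_bruteforce(self, task_pieces):
        structure, spec, _, pocket = task_pieces
        K = 4
        g = build_residue_graph(structure, pocket, K=K, spec=spec)
        ca = g.coords
        for i in range(len(ca)):
            d = np.linalg.norm(ca - ca[i], axis=1)
            d[i] = np.inf
            brute = set(np.argsort(d, kind="stable")[:K])
            mine = {s for s, t in g.edges if t == i}
            assert mine == brute

    def test_scalar_features_rotation_invariant(self, task_pieces):
        structure, spec, _, pocket = task_pieces
        g1 = build_residue_graph(structure, pocket, spec=spec)
        Q, t = random_rotation(1), np.array([3.0, -2.0, 7.0])
        s2 = structure.copy()
        s2.set_atom_coords(structure.atom_coords() @ Q.T + t)
        g2 = build_residue_graph(s2, pocket, spec=spec)
        assert np.abs(g1.node_scalars - g2.node_scalars).max() < 1e-5
        assert np.abs(g1.edge_scalars - g2.edge_scalars).max() < 1e-5

    def test_vector_features_rotate(self, task_pieces):
        structure, spec, _, pocket = task_pieces
        g1 = build_residue_graph(structure, pocket, spec=spec)
        Q = random_rotation(2)
        s2 = structure.copy()
        s2.set_atom_coords(structure.atom_coords() @ Q.T)
        g2 = build_residue_graph(s2, pocket, spec=spec)
        assert np.abs(g2.node_vectors - g1.node_vectors @ Q.T).max() < 1e-5
        assert np.abs(g2.edge_vectors - g1.edge_vectors @ Q.T).max() < 1e-5

    def test_bad_k_rejected(self, task_pieces):
        structure, spec, _, pocket = task_pieces
        with pytest.raises(ValueError):
            build_residue_graph(structure, pocket, K=0, spec=spec)


class TestInteractionGraph:
    @pytest.fixture()
    def graphs(self, task_pieces):
        structure, spec, truth, pocket = task_pieces
        ag = build_atom_graph(structure, pocket, spec)
        rg = build_residue_graph(structure, pocket, spec=spec)
        init = init_loop_reconstruction(structure, spec, seed=0)
        ig = build_interaction_graph(ag, rg, init)
        return ag, rg, init, ig

    def test_bipartite_edge_count(self, graphs):
        ag, rg, init, ig = graphs
        L, P = ig.n_loop_atoms, ig.n_residues
        n_loop_res = (ig.edge_type == EDGE_LOOP_RES).sum()
        assert n_loop_res == 2 * L * P

    def test_loop_res_distance_is_minus_one_at_construction(self, graphs):
        *_, ig = graphs
        feats = ig.edge_features()
        assert np.all(feats[ig.edge_type == EDGE_LOOP_RES, 3] == -1.0)

    def test_res_res_distances_match_ca(self, graphs):
        ag, rg, init, ig = graphs
        feats = ig.edge_features()
        sel = ig.edge_type == EDGE_RES_RES
        src = ig.edges[sel, 0] - ig.n_loop_atoms
        dst = ig.edges[sel, 1] - ig.n_loop_atoms
        d = np.linalg.norm(rg.coords[src] - rg.coords[dst], axis=1)
        assert np.abs(feats[sel, 3] - d).max() < 1e-5

    def test_loop_loop_distances_from_init(self, graphs):
        ag, rg, init, ig = graphs
        feats = ig.edge_features()
        sel = ig.edge_type == EDGE_LOOP_LOOP
        d = np.linalg.norm(
            init.coords[ig.edges[sel, 0]] - init.coords[ig.edges[sel, 1]], axis=1
        )
        assert np.abs(feats[sel, 3] - d).max() < 1e-8

    def test_refreshed_features_fill_loop_res(self, graphs):
        *_, ig = graphs
        feats = ig.edge_features(refreshed=True)
        assert np.all(feats[:, 3] >= 0.0)

    def test_init_shape_mismatch_rejected(self, graphs):
        ag, rg, init, _ = graphs
        from loopforge.pocketing import LoopInit

        bad = LoopInit(coords=init.coords[:-1], mode="reconstruction", sd=1.75, seed=0)
        with pytest.raises(ValueError):
            build_interaction_graph(ag, rg, bad)
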