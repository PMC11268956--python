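"""Encoder properties: GT permutation behaviour, GVP equivariance, merge."""

import numpy as np
import pytest

from conftest import random_rotation
from loopforge import nn
from loopforge.encoders import (
    FeatureMerge,
    GTConfig,
    GTEncoder,
    GVP,
    GVPConfig,
    GVPEncoder,
    extract_loop_embeddings,
)
from loopforge.graphs import build_residue_graph
from loopforge.nn import Tensor
from loopforge.pocketing import select_surface_pocket


@pytest.fixture(scope="module")
def atom_graph(prepared_task):
    return prepared_task.atom_graph


@pytest.fixture(scope="module")
def gt_small():
    return GTConfig(n_layers=2, n_heads=2, d=16, dropout=0.0)


class TestGTEncoder:
    def test_output_shapes(self, atom_graph, gt_small):
        enc = GTEncoder(31, 2, gt_small, np.random.default_rng(0))
        enc.eval()
        h, e = enc(atom_graph)
        assert h.shape == (atom_graph.node_scalars.shape[0], 16)
        assert e.shape == (len(atom_graph.edges), 16)

    def test_coordinate_free(self, prepared_task, gt_small):
        """The atom encoder ignores coordinates entirely."""
        import copy

        enc = GTEncoder(31, 2, gt_small, np.random.default_rng(0))
        enc.eval()
        g1 = prepared_task.atom_graph
        h1, _ = enc(g1)
        g2 = copy.deepcopy(g1)
        g2.coords = g2.coords + 100.0
        h2, _ = enc(g2)
        assert np.array_equal(h1.data, h2.data)

    def test_permutation_equivariance(self, atom_graph, gt_small):
        import copy

        enc = GTEncoder(31, 2, gt_small, np.random.default_rng(0))
        enc.eval()
        h1, _ = enc(atom_graph)
        n = atom_graph.node_scalars.shape[0]
        rng = np.random.default_rng(4)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        g2 = copy.deepcopy(atom_graph)
        g2.node_scalars = g2.node_scalars[perm]
        g2.edges = inv[g2.edges]
        h2, _ = enc(g2)
        # batch-norm statistics are permutation invariant, so embeddings map back
        assert np.abs(h2.data[inv] - h1.data).max() < 1e-5

    def test_width_must_divide_heads(self):
        with pytest.raises(ValueError):
            GTConfig(n_heads=3, d=16)


class TestGVPUnit:
    def test_zero_vectors_contribute_zero_norms(self):
        rng = np.random.default_rng(0)
        gvp = GVP(4, 2, 4, 2, rng)
        s = Tensor(rng.normal(size=(5, 4)))
        v = Tensor(np.zeros((5, 2, 3)))
        s_out, v_out = gvp(s, v)
        # scalar path sees exactly zero norms: same as concatenating zeros
        expected = gvp.W_sv(nn.concat([s, Tensor(np.zeros((5, 2)))], axis=-1))
        assert np.abs(s_out.data - expected.data).max() < 1e-12
        assert np.abs(v_out.data).max() < 1e-12

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        gvp = GVP(4, 3, 5, 2, rng, activations=True)
        s = Tensor(rng.normal(size=(6, 4)))
        v = rng.normal(size=(6, 3, 3))
        Q = random_rotation(7)
        s1, v1 = gvp(s, Tensor(v))
        s2, v2 = gvp(s, Tensor(v @ Q.T))
        assert np.abs(s1.data - s2.data).max() < 1e-10
        assert np.abs(v2.data - v1.data @ Q.T).max() < 1e-10


class TestGVPEncoder:
    @pytest.fixture(scope="class")
    def encoder(self):
        cfg = GVPConfig(d_scalar=16, n_vector=3, d_seq=4, n_conv_layers=1, dropout=0.0)
        enc = GVPEncoder((29, 3, 19, 1), cfg, np.random.default_rng(0))
        enc.eval()
        return enc

    def test_rigid_motion_invariance_of_scalars(self, prepared_task, encoder):
        task = prepared_task
        g1 = task.residue_graph
        hs1, hv1 = encoder(g1)
        Q, t = random_rotation(3), np.array([1.0, -4.0, 2.0])
        s2 = task.structure.copy()
        s2.set_atom_coords(task.structure.atom_coords() @ Q.T + t)
        g2 = build_residue_graph(s2, task.pocket, spec=task.spec)
        hs2, hv2 = encoder(g2)
        assert np.abs(hs1.data - hs2.data).max() < 1e-4
        assert np.abs(hv2.data - hv1.data @ Q.T).max() < 1e-4

    def test_translation_alone_is_exactly_invariant(self, prepared_task, encoder):
        task = prepared_task
        hs1, hv1 = encoder(task.residue_graph)
        s2 = task.structure.copy()
        s2.set_atom_coords(task.structure.atom_coords() + 11.0)
        g2 = build_residue_graph(s2, task.pocket, spec=task.spec)
        hs2, hv2 = encoder(g2)
        assert np.abs(hs1.data - hs2.data).max() < 1e-9
        assert np.abs(hv1.data - hv2.data).max() < 1e-9


class TestFeatureMerge:
    def test_opposite_embeddings_cancel(self):
        rng = np.random.default_rng(0)
        merge = FeatureMerge(4, 3, 5, rng)
        res_emb = Tensor(rng.normal(size=(1, 4)))
        e = rng.normal(size=(1, 3))
        atoms = Tensor(np.concatenate([e, -e]))
        out = merge(res_emb, atoms, np.array([0, 0]), np.array([0]))
        zero_atoms = merge(res_emb, Tensor(np.zeros((2, 3))), np.array([0, 0]), np.array([0]))
        assert np.abs(out.data - zero_atoms.data).max() < 1e-12

    def test_atom_order_irrelevant(self):
        rng = np.random.default_rng(1)
        merge = FeatureMerge(4, 3, 5, rng)
        res_emb = Tensor(rng.normal(size=(2, 4)))
        atoms = rng.normal(size=(6, 3))
        a2r = np.array([0, 0, 0, 1, 1, 1])
        out1 = merge(res_emb, Tensor(atoms), a2r, np.array([0, 1]))
        perm = np.array([2, 0, 1, 5, 3, 4])
        out2 = merge(res_emb, Tensor(atoms[perm]), a2r, np.array([0, 1]))
        assert np.abs(out1.data - out2.data).max() < 1e-12

    def test_vectorised_equals_python_loop(self):
        rng = np.random.default_rng(2)
        merge = FeatureMerge(4, 3, 5, rng)
        res_emb = rng.normal(size=(3, 4))
        atoms = rng.normal(size=(10, 3))
        a2r = np.array([0, 0, 1, 1, 1, 2, 2, 2, 2, 2])
        out = merge(Tensor(res_emb), Tensor(atoms), a2r, np.arange(3)).data
        for i in range(3):
            summed = atoms[a2r == i].sum(axis=0)
            x = np.concatenate([res_emb[i], summed])[None, :]
            h = x @ merge.lin1.weight.data + merge.lin1.bias.data
            h = np.where(h > 0, h, 0.01 * h)
            expected = h @ merge.lin2.weight.data + merge.lin2.bias.data
            assert np.abs(out[i] - expected[0]).max() < 1e-6

    def test_empty_residue_rejected(self):
        rng = np.random.default_rng(3)
        merge = FeatureMerge(4, 3, 5, rng)
        with pytest.raises(ValueError):
            merge(Tensor(np.zeros((2, 4))), Tensor(np.zeros((2, 3))), np.array([0, 0]), np.array([0, 1]))


class TestExtractLoopEmbeddings:
    def test_selection_matches_gather(self):
        rng = np.random.default_rng(0)
        h = Tensor(rng.normal(size=(8, 4)))
        mask = np.array([0, 1, 1, 0, 0, 1, 0, 0], dtype=bool)
        out = extract_loop_embeddings(h, mask)
        assert np.array_equal(out.data, h.data[mask])

    def test_all_true_identity(self):
        h = Tensor(np.arange(12.0).reshape(4, 3))
        out = extract_loop_embeddings(h, np.ones(4, dtype=bool))
        assert np.array_equal(out.data, h.data)

    def test_empty_mask_rejected(self):
        h = Tensor(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            extract_loop_embeddings(h, np.zeros(4, dtype=bool))
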