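"""Encoders: graph-transformer atom encoder, GVP residue encoder, feature merge.

The atom encoder is an edge-featured multi-head attention network on the
covalent graph.  It never sees coordinates, so its embeddings are rigid-motion
invariant by construction.  Attention gates are computed per feature channel:
the elementwise query-key product is scaled by 1/sqrt(d_k), gated by the edge
embedding, and normalised by a softmax over each node's in-neighbours.

The residue encoder is a stack of geometric vector perceptron (GVP) layers on
the KNN residue graph.  Each gvp unit mixes scalar channels with the row
norms of linearly transformed vector channels, and gates vector rows by a
function of their norms, so scalars stay rotation-invariant and vectors stay
rotation-equivariant.

The feature-merging block fuses the two levels: each pocket residue's atom
embeddings are summed, concatenated to its residue embedding, and passed
through a two-layer MLP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .graphs import AtomGraph, ResidueGraph
from .nn import Tensor, concat, gather, segment_softmax, segment_sum


@dataclass
class GTConfig:
    n_layers: int = 6
    n_heads: int = 4
    d: int = 128
    dropout: float = 0.1

    def __post_init__(self):
        if self.d % self.n_heads:
            raise ValueError("model width must be divisible by the head count")

    @property
    def d_k(self) -> int:
        return self.d // self.n_heads


@dataclass
class GVPConfig:
    d_scalar: int = 128
    n_vector: int = 16
    d_seq: int = 16
    n_conv_layers: int = 3
    dropout: float = 0.1

    def __post_init__(self):
        if self.n_vector < 1:
            raise ValueError("vector multiplicity must be >= 1")


class GTLayer(nn.Module):
    def __init__(self, cfg: GTConfig, rng):
        super().__init__()
        d = cfg.d
        self.cfg = cfg
        self.norm_h = nn.BatchNorm(d)
        self.norm_e = nn.BatchNorm(d)
        self.W_Q = nn.Linear(d, d, rng, bias=False)
        self.W_K = nn.Linear(d, d, rng, bias=False)
        self.W_V = nn.Linear(d, d, rng, bias=False)
        self.W_E = nn.Linear(d, d, rng, bias=False)
        self.W_h0 = nn.Linear(d, d, rng)
        self.W_e0 = nn.Linear(d, d, rng)
        self.drop_h = nn.Dropout(cfg.dropout)
        self.drop_e = nn.Dropout(cfg.dropout)
        self.ff_norm_h = nn.BatchNorm(d)
        self.W_h1 = nn.Linear(d, 2 * d, rng)
        self.W_h2 = nn.Linear(2 * d, d, rng)
        self.ff_drop_h = nn.Dropout(cfg.dropout)
        self.ff_norm_e = nn.BatchNorm(d)
        self.W_e1 = nn.Linear(d, 2 * d, rng)
        self.W_e2 = nn.Linear(2 * d, d, rng)
        self.ff_drop_e = nn.Dropout(cfg.dropout)

    def __call__(self, h: Tensor, e: Tensor, edges: np.ndarray) -> tuple[Tensor, Tensor]:
        cfg = self.cfg
        n_nodes = h.shape[0]
        src, dst = edges[:, 0], edges[:, 1]
        hn, en = self.norm_h(h), self.norm_e(e)
        q = gather(self.W_Q(hn), dst).reshape(-1, cfg.n_heads, cfg.d_k)
        k = gather(self.W_K(hn), src).reshape(-1, cfg.n_heads, cfg.d_k)
        v = gather(self.W_V(hn), src).reshape(-1, cfg.n_heads, cfg.d_k)
        eh = self.W_E(en).reshape(-1, cfg.n_heads, cfg.d_k)
        logits = (q * k) * (1.0 / np.sqrt(cfg.d_k)) * eh
        w = segment_softmax(logits, dst, n_nodes)  # per channel over in-neighbours
        agg = segment_sum(w * v, dst, n_nodes).reshape(n_nodes, cfg.d)
        h_hat = h + self.W_h0(self.drop_h(agg))
        e_hat = e + self.W_e0(self.drop_e(w.reshape(-1, cfg.d)))
        h_out = h_hat + self.W_h2(self.ff_drop_h(nn.silu(self.W_h1(self.ff_norm_h(h_hat)))))
        e_out = e_hat + self.W_e2(self.ff_drop_e(nn.silu(self.W_e1(self.ff_norm_e(e_hat)))))
        return h_out, e_out


class GTEncoder(nn.Module):
    """Coordinate-free atom encoder on the covalent graph."""

    def __init__(self, d_node_in: int, d_edge_in: int, cfg: GTConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.proj_h = nn.Linear(d_node_in, cfg.d, rng)
        self.proj_e = nn.Linear(d_edge_in, cfg.d, rng)
        self.layers = nn.ModuleList(GTLayer(cfg, rng) for _ in range(cfg.n_layers))

    def __call__(self, graph: AtomGraph) -> tuple[Tensor, Tensor]:
        h = self.proj_h(Tensor(graph.node_scalars))
        e = self.proj_e(Tensor(graph.edge_scalars))
        for layer in self.layers:
            h, e = layer(h, e, graph.edges)
        return h, e


# -- GVP ---------------------------------------------------------------------


class GVP(nn.Module):
    """One geometric vector perceptron unit.

    Scalars: concat(s, ||W_v0 v||_row) -> linear -> optional activation.
    Vectors: W_v1 W_v0 v, rows gated by sigmoid of their norms when an
    activation is requested, passed through unchanged otherwise.
    """

    def __init__(
        self,
        ds_in: int,
        dv_in: int,
        ds_out: int,
        dv_out: int,
        rng,
        activations: bool = False,
    ):
        super().__init__()
        dv_mid = max(dv_in, dv_out)
        self.W_v0 = Tensor(rng.normal(0, np.sqrt(1.0 / dv_in), (dv_mid, dv_in)), requires_grad=True)
        self.W_v1 = Tensor(rng.normal(0, np.sqrt(1.0 / dv_mid), (dv_out, dv_mid)), requires_grad=True)
        self.W_sv = nn.Linear(ds_in + dv_mid, ds_out, rng)
        self.activations = activations

    def __call__(self, s: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
        v1 = _vec_linear(self.W_v0, v)
        v2 = _vec_linear(self.W_v1, v1)
        s_v1 = nn.safe_norm(v1, axis=-1)
        s_v2 = nn.safe_norm(v2, axis=-1)
        s_out = self.W_sv(concat([s, s_v1], axis=-1))
        if self.activations:
            s_out = nn.relu(s_out)
            v_out = v2 * nn.sigmoid(s_v2).reshape(v2.shape[0], v2.shape[1], 1)
        else:
            v_out = v2
        return s_out, v_out


def _vec_linear(W: Tensor, v: Tensor) -> Tensor:
    """[m_out, m_in] x [N, m_in, 3] -> [N, m_out, 3] along the multiplicity axis."""
    return (v.transpose(0, 2, 1) @ W.transpose(1, 0)).transpose(0, 2, 1)


class GVPConv(nn.Module):
    """Message passing with three gvp stages and mean aggregation."""

    def __init__(self, ds: int, dv: int, des: int, dev: int, dropout: float, rng):
        super().__init__()
        self.msg1 = GVP(2 * ds + des, 2 * dv + dev, ds, dv, rng, activations=True)
        self.msg2 = GVP(ds, dv, ds, dv, rng, activations=True)
        self.msg3 = GVP(ds, dv, ds, dv, rng, activations=False)
        self.norm1 = nn.LayerNorm(ds)
        self.drop_s1 = nn.Dropout(dropout)
        self.drop_v1 = nn.Dropout(dropout)
        self.ff1 = GVP(ds, dv, 4 * ds, 2 * dv, rng, activations=True)
        self.ff2 = GVP(4 * ds, 2 * dv, ds, dv, rng, activations=False)
        self.norm2 = nn.LayerNorm(ds)
        self.drop_s2 = nn.Dropout(dropout)
        self.drop_v2 = nn.Dropout(dropout)

    def __call__(self, hs, hv, es, ev, edges, n_nodes):
        src, dst = edges[:, 0], edges[:, 1]
        ms = concat([gather(hs, src), es, gather(hs, dst)], axis=-1)
        mv = concat([gather(hv, src), ev, gather(hv, dst)], axis=1)
        ms, mv = self.msg1(ms, mv)
        ms, mv = self.msg2(ms, mv)
        ms, mv = self.msg3(ms, mv)
        counts = np.maximum(np.bincount(dst, minlength=n_nodes), 1).astype(float)
        inv = Tensor(1.0 / counts[:, None])
        agg_s = segment_sum(ms, dst, n_nodes) * inv
        agg_v = segment_sum(mv, dst, n_nodes) * inv.reshape(n_nodes, 1, 1)
        hs = self.norm1(hs + self.drop_s1(agg_s))
        hv = hv + self.drop_v1(agg_v)
        fs, fv = self.ff1(hs, hv)
        fs, fv = self.ff2(fs, fv)
        hs = self.norm2(hs + self.drop_s2(fs))
        hv = hv + self.drop_v2(fv)
        return hs, hv


class GVPEncoder(nn.Module):
    """Rotation-aware residue encoder over the KNN graph.

    Layer normalisation is applied to scalar channels only; normalising
    vector components across channels would break equivariance.
    """

    def __init__(self, graph_dims: tuple[int, int, int, int], cfg: GVPConfig, rng):
        super().__init__()
        ds_in, dv_in, des_in, dev_in = graph_dims
        ds, dv = cfg.d_scalar, cfg.n_vector
        self.cfg = cfg
        self.seq_embed = nn.Embedding(21, cfg.d_seq, rng)
        self.node_norm = nn.LayerNorm(ds_in + cfg.d_seq)
        self.node_init = GVP(ds_in + cfg.d_seq, dv_in, ds, dv, rng, activations=False)
        self.edge_norm = nn.LayerNorm(des_in)
        self.edge_init = GVP(des_in, dev_in, ds, dv, rng, activations=False)
        self.convs = nn.ModuleList(
            GVPConv(ds, dv, ds, dv, cfg.dropout, rng) for _ in range(cfg.n_conv_layers)
        )

    def __call__(self, graph: ResidueGraph) -> tuple[Tensor, Tensor]:
        hs = concat(
            [Tensor(graph.node_scalars), self.seq_embed(graph.sequence)], axis=-1
        )
        hv = Tensor(graph.node_vectors)
        hs, hv = self.node_init(self.node_norm(hs), hv)
        es, ev = self.edge_init(self.edge_norm(Tensor(graph.edge_scalars)), Tensor(graph.edge_vectors))
        n = graph.coords.shape[0]
        for conv in self.convs:
            hs, hv = conv(hs, hv, es, ev, graph.edges, n)
        return hs, hv


# -- hierarchical merge ------------------------------------------------------


class FeatureMerge(nn.Module):
    """Fuse summed atom embeddings into residue embeddings (two-layer MLP)."""

    def __init__(self, d_residue: int, d_atom: int, d_out: int, rng):
        super().__init__()
        self.lin1 = nn.Linear(d_residue + d_atom, d_out, rng)
        self.lin2 = nn.Linear(d_out, d_out, rng)

    def __call__(
        self,
        residue_embeddings: Tensor,
        atom_embeddings: Tensor,
        atom_residue: np.ndarray,
        residue_rows: np.ndarray,
    ) -> Tensor:
        """``residue_rows[i]`` maps residue-graph node i to its row in the
        atom graph's residue list; every merged residue must own >= 1 atom."""
        n_res_atomgraph = int(max(atom_residue.max(), np.max(residue_rows))) + 1
        counts = np.bincount(atom_residue, minlength=n_res_atomgraph)
        if np.any(counts[residue_rows] == 0):
            raise ValueError("cannot merge a residue that has no atoms")
        summed = segment_sum(atom_embeddings, atom_residue, n_res_atomgraph)
        merged = concat([residue_embeddings, gather(summed, residue_rows)], axis=-1)
        return self.lin2(nn.leaky_relu(self.lin1(merged)))


def extract_loop_embeddings(atom_embeddings: Tensor, mask: np.ndarray) -> Tensor:
    """Rows of the atom embedding matrix belonging to loop atoms, in order."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != atom_embeddings.shape[0]:
        raise ValueError("mask length must equal the atom count")
    if not mask.any():
        raise ValueError("loop mask selects no atoms")
    return gather(atom_embeddings, np.flatnonzero(mask))
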