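"""Attention-augmented E(n)-equivariant generator for loop coordinates.

Eight stacked EGNN layers move the loop atoms; pocket-residue nodes provide
context but their coordinates are frozen.  Every geometric quantity entering
the network is either a squared inter-node distance (invariant) or a unit
difference vector (equivariant), so the predicted loop coordinates transform
exactly with any rigid motion applied to the inputs.

A recycling scheme reruns the layer stack on its own output: at each recycle
boundary the node embeddings are gate-combined with the raw (first-pass)
embeddings, and the loop-incident edge distance features are refreshed from
the current coordinates.  During training, gradients only flow through the
final recycle (earlier recycles run on detached state), bounding memory the
way iterative-refinement folding models do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .graphs import InteractionGraph
from .nn import Tensor, concat, gather, segment_softmax, segment_sum

EPS_NORM = 1e-8  # guards normalisation of coincident-node difference vectors

#: squared distances enter the edge message in scaled units so pocket-scale
#: separations map to O(1)-O(10) inputs and the coordinate feedback loop stays
#: numerically stable at initialisation while short-range geometry keeps
#: usable resolution
DIST_FEATURE_SCALE = 0.1

#: the coordinate-update output layers start small so early iterations make
#: gentle moves instead of amplifying their own distance features
COORD_INIT_SCALE = 0.1


@dataclass
class EGNNConfig:
    n_layers: int = 8
    n_heads: int = 4
    d_h: int = 128
    recycles: int = 3
    dropout: float = 0.1
    #: stop gradients at recycle boundaries (bounds memory at scale); at desk
    #: scale full backpropagation through recycles trains markedly better
    truncate_recycle_gradients: bool = True

    def __post_init__(self):
        if self.d_h % self.n_heads:
            raise ValueError("width must be divisible by the head count")
        if self.recycles < 1:
            raise ValueError("need at least one recycle")
        if self.d_k < 2:
            raise ValueError("per-head width must be >= 2")

    @property
    def d_k(self) -> int:
        return self.d_h // self.n_heads


class GateBlock(nn.Module):
    """g = sigmoid(W [h_new, h_old, h_new - h_old]); out = GraphNorm(g*h_new + h_old)."""

    def __init__(self, d: int, dropout: float, rng):
        super().__init__()
        self.lin = nn.Linear(3 * d, d, rng)
        self.drop = nn.Dropout(dropout)
        self.norm = nn.GraphNorm(d)

    def __call__(self, h_new: Tensor, h_old: Tensor) -> Tensor:
        g = nn.sigmoid(self.drop(self.lin(concat([h_new, h_old, h_new - h_old], axis=-1))))
        return self.norm(g * h_new + h_old)


class EGNNLayer(nn.Module):
    def __init__(self, cfg: EGNNConfig, rng):
        super().__init__()
        d, dk = cfg.d_h, cfg.d_k
        self.cfg = cfg
        self.W_Q = nn.Linear(d, d, rng)
        self.W_K = nn.Linear(d, d, rng)
        self.W_V = nn.Linear(d, d, rng)
        self.W_m1 = nn.Linear(d + 1, d, rng)
        self.W_m2 = nn.Linear(d, d, rng)
        self.drop_m = nn.Dropout(cfg.dropout)
        self.W_h = nn.Linear(d, d, rng)
        self.drop_h = nn.Dropout(cfg.dropout)
        self.gate = GateBlock(d, cfg.dropout, rng)
        self.W_e = nn.Linear(d, d, rng)
        self.W_x1 = nn.Linear(dk, dk // 2, rng)
        self.W_x2 = nn.Linear(dk // 2, 1, rng)
        self.W_x2.weight.data *= COORD_INIT_SCALE
        self.drop_x = nn.Dropout(cfg.dropout)
        self.W_heads = nn.Linear(cfg.n_heads, 1, rng, bias=False)
        self.W_heads.weight.data *= COORD_INIT_SCALE

    def __call__(
        self,
        h: Tensor,
        e: Tensor,
        x: Tensor,
        edges: np.ndarray,
        update_mask: np.ndarray,
    ) -> tuple[Tensor, Tensor, Tensor]:
        cfg = self.cfg
        n_nodes = h.shape[0]
        src, dst = edges[:, 0], edges[:, 1]
        E = len(edges)

        q = gather(self.W_Q(h), dst).reshape(E, cfg.n_heads, cfg.d_k)
        k = gather(self.W_K(h), src).reshape(E, cfg.n_heads, cfg.d_k)
        v = gather(self.W_V(h), src).reshape(E, cfg.n_heads, cfg.d_k)

        diff = gather(x, dst) - gather(x, src)  # x_i - x_j for edge (j -> i)
        sq_dist = (diff**2).sum(axis=-1, keepdims=True) * DIST_FEATURE_SCALE
        m = self.W_m2(nn.leaky_relu(self.drop_m(self.W_m1(concat([e, sq_dist], axis=-1)))))
        k_gated = k * m.reshape(E, cfg.n_heads, cfg.d_k)
        w = q * k_gated * (1.0 / np.sqrt(cfg.d_k))  # [E, H, d_k]
        alpha = segment_softmax(w**2, dst, n_nodes)

        agg = segment_sum(w * v, dst, n_nodes).reshape(n_nodes, cfg.d_h)
        h_hat = self.drop_h(self.W_h(agg))
        h_out = self.gate(h_hat, h)
        e_out = self.W_e(alpha.reshape(E, cfg.d_h))

        # coordinate update: per-head scalars scale the unit difference vectors
        norm = nn.safe_norm(diff, axis=-1, keepdims=True, eps=EPS_NORM) + EPS_NORM
        unit = diff / norm
        scal = self.W_x2(nn.leaky_relu(self.drop_x(self.W_x1(w))))  # [E, H, 1]
        combined = self.W_heads(scal.reshape(E, cfg.n_heads))  # [E, 1]
        dx = segment_sum(unit * combined, dst, n_nodes)
        x_out = x + dx * Tensor(update_mask[:, None].astype(float))
        return h_out, e_out, x_out


class Generator(nn.Module):
    """Initial normalisation, the EGNN stack, and the recycling driver."""

    def __init__(self, d_edge_in: int, cfg: EGNNConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.graph_norm = nn.GraphNorm(cfg.d_h)
        self.edge_init = nn.Linear(d_edge_in, cfg.d_h, rng)
        self.layers = nn.ModuleList(EGNNLayer(cfg, rng) for _ in range(cfg.n_layers))
        self.recycle_gate = GateBlock(cfg.d_h, cfg.dropout, rng)
        #: per-layer loop coordinates of every recycle, kept with gradients
        #: inside their own recycle segment (for deep supervision)
        self.layer_coords: list[Tensor] = []

    def init_state(self, node_embeddings: Tensor, edge_features: np.ndarray):
        h = self.graph_norm(node_embeddings)
        e = self.edge_init(Tensor(edge_features))
        return h, e

    def __call__(
        self,
        node_embeddings: Tensor,
        graph: InteractionGraph,
        loop_coords: np.ndarray | None = None,
    ) -> tuple[Tensor, list[np.ndarray], Tensor]:
        """Run all recycles; returns (final loop coords, per-recycle coords, h).

        Only loop-atom nodes are moved; residue coordinates pass through
        bit-identical.
        """
        cfg = self.cfg
        L = graph.n_loop_atoms
        update_mask = np.zeros(graph.n_nodes, dtype=bool)
        update_mask[:L] = True

        h_raw = self.graph_norm(node_embeddings)
        x = Tensor(graph.all_coords(loop_coords))
        h = h_raw
        trajectory: list[np.ndarray] = []
        self.layer_coords = []
        for r in range(cfg.recycles):
            last = r == cfg.recycles - 1
            if r > 0:
                if cfg.truncate_recycle_gradients:
                    # truncated backprop, as in iterative-refinement folding
                    # models with many recycles
                    h = self.recycle_gate(h.detach(), h_raw if last else h_raw.detach())
                    x = x.detach()
                else:
                    h = self.recycle_gate(h, h_raw)
            e = self.edge_init(Tensor(graph.edge_features(x.data[:L], refreshed=r > 0)))
            for layer in self.layers:
                h, e, x = layer(h, e, x, graph.edges, update_mask)
                self.layer_coords.append(x[np.arange(L)])
            trajectory.append(x.data[:L].copy())
        return x[np.arange(L)], trajectory, h
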