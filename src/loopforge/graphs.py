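"""Graph construction: atom covalent graph, residue KNN graph, interaction graph.

Three views of the same pocket feed the model:

* an **atom graph** over all pocket + loop heavy atoms, with covalent bonds as
  edges — purely topological (no coordinates), so the atom encoder is
  coordinate-free by construction;
* a **residue graph** over the nonloop pocket residues, a directed K-nearest-
  neighbour graph on CA positions carrying rotation-invariant scalar features
  and rotation-equivariant unit-vector features;
* an **interaction graph** whose nodes are loop atoms plus pocket residues:
  loop-residue pairs are fully connected, loop-loop pairs fully connected,
  and residue-residue edges reuse the KNN topology.  Edge features encode the
  edge type and a distance: the actual distance where geometry is known
  (residue-residue, and loop-loop from the initialised coordinates), and -1
  for loop-residue edges whose true separation is unknown at initialisation.

All scalar features are invariant under rigid motions of the input; all
vector features rotate with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .pocketing import LoopInit, PocketSelection
from .structio import LoopSpec, ProteinStructure, Residue, derive_covalent_bonds

KNN_K = 30

ELEMENT_CLASSES = ("C", "N", "O", "S")  # + other
RESIDUE_TYPES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()
_RES_INDEX = {name: i for i, name in enumerate(RESIDUE_TYPES)}

MAX_DEGREE = 4
RBF_BINS = 16
RBF_RANGE = 20.0
SEQ_SEP_CAP = 32

ATOM_FEATURE_DIM = len(ELEMENT_CLASSES) + 1 + len(RESIDUE_TYPES) + 1 + (MAX_DEGREE + 1)
BOND_FEATURE_DIM = 2  # intra-residue, peptide
RESIDUE_SCALAR_DIM = len(RESIDUE_TYPES) + 6 + 3  # one-hot + dihedral sin/cos + validity
RESIDUE_EDGE_SCALAR_DIM = RBF_BINS + 3

EDGE_LOOP_LOOP, EDGE_RES_RES, EDGE_LOOP_RES = 0, 1, 2


def dump_edges_tsv(edges: np.ndarray, path: str, extra: np.ndarray | None = None):
    """Debug dump: one `src<TAB>dst[<TAB>value]` row per directed edge."""
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(edges):
            row = f"{a}\t{b}"
            if extra is not None:
                row += "\t" + "\t".join(f"{v:.6g}" for v in np.atleast_1d(extra[i]))
            fh.write(row + "\n")


def element_class(element: str) -> int:
    try:
        return ELEMENT_CLASSES.index(element.capitalize())
    except ValueError:
        return len(ELEMENT_CLASSES)


def residue_type_index(name: str) -> int:
    return _RES_INDEX.get(name, len(RESIDUE_TYPES))


@dataclass
class AtomGraph:
    node_scalars: np.ndarray  # [N, ATOM_FEATURE_DIM]
    edges: np.ndarray  # [E, 2] directed (src, dst)
    edge_scalars: np.ndarray  # [E, BOND_FEATURE_DIM]
    coords: np.ndarray  # [N, 3]
    atom_residue: np.ndarray  # [N] local residue index
    residue_ids: list  # ordered (chain_id, residue index) covered by the graph
    is_loop_atom: np.ndarray  # [N] bool
    atom_names: list


@dataclass
class ResidueGraph:
    node_scalars: np.ndarray  # [P, RESIDUE_SCALAR_DIM]
    node_vectors: np.ndarray  # [P, 3, 3]
    edge_scalars: np.ndarray  # [E, RESIDUE_EDGE_SCALAR_DIM]
    edge_vectors: np.ndarray  # [E, 1, 3]
    sequence: np.ndarray  # [P] residue-type codes
    coords: np.ndarray  # [P, 3] CA positions
    edges: np.ndarray  # [E, 2] directed (src, dst)
    residue_ids: list


@dataclass
class InteractionGraph:
    """Nodes: loop atoms (first) then pocket residues."""

    n_loop_atoms: int
    n_residues: int
    edges: np.ndarray  # [E, 2] directed
    edge_type: np.ndarray  # [E] in {loop-loop, res-res, loop-res}
    residue_coords: np.ndarray  # [P, 3] fixed CA coords
    loop_coords: np.ndarray  # [L, 3] mutable

    @property
    def n_nodes(self) -> int:
        return self.n_loop_atoms + self.n_residues

    def node_kind(self) -> np.ndarray:
        return np.concatenate(
            [np.zeros(self.n_loop_atoms, dtype=int), np.ones(self.n_residues, dtype=int)]
        )

    def all_coords(self, loop_coords: np.ndarray | None = None) -> np.ndarray:
        loop = self.loop_coords if loop_coords is None else loop_coords
        return np.concatenate([loop, self.residue_coords], axis=0)

    def edge_features(
        self, loop_coords: np.ndarray | None = None, refreshed: bool = False
    ) -> np.ndarray:
        """Type one-hot plus a distance channel.

        ``refreshed=False`` applies the construction-time convention: actual
        distances for loop-loop and residue-residue edges, -1 for loop-residue
        edges.  ``refreshed=True`` fills loop-residue edges with the actual
        distances from the current loop coordinates (used at recycle
        boundaries once a conformation exists).
        """
        coords = self.all_coords(loop_coords)
        feats = np.zeros((len(self.edges), 4))
        feats[np.arange(len(self.edges)), self.edge_type] = 1.0
        d = np.linalg.norm(coords[self.edges[:, 0]] - coords[self.edges[:, 1]], axis=1)
        dist = np.where(self.edge_type == EDGE_LOOP_RES, -1.0 if not refreshed else d, d)
        feats[:, 3] = dist
        return feats


# -- atom graph --------------------------------------------------------------


def _select_residues(
    structure: ProteinStructure, pocket: PocketSelection, spec: LoopSpec
) -> list[Residue]:
    """Pocket plus loop residues, in structure order."""
    wanted = set(pocket.residue_ids) | {
        (spec.chain_id, i) for i in range(spec.start, spec.end + 1)
    }
    return [res for res in structure.residues() if (res.chain_id, res.index) in wanted]


def build_atom_graph(
    structure: ProteinStructure, pocket: PocketSelection, spec: LoopSpec
) -> AtomGraph:
    spec.validate(structure)
    residues = _select_residues(structure, pocket, spec)
    selected_ids = {(r.chain_id, r.index) for r in residues}

    # restrict full-structure covalent bonds to the selected atoms
    global_index: dict[int, int] = {}
    local = 0
    gidx = 0
    atom_residue, coords, is_loop, names, elements, res_types, backbone = (
        [], [], [], [], [], [], [])
    res_local = {(r.chain_id, r.index): i for i, r in enumerate(residues)}
    for res in structure.residues():
        sel = (res.chain_id, res.index) in selected_ids
        for atom in res.atoms:
            if sel:
                global_index[gidx] = local
                atom_residue.append(res_local[(res.chain_id, res.index)])
                coords.append(atom.coords)
                is_loop.append(
                    res.chain_id == spec.chain_id and spec.start <= res.index <= spec.end
                )
                names.append(atom.name)
                elements.append(element_class(atom.element))
                res_types.append(residue_type_index(res.name))
                backbone.append(atom.is_backbone)
                local += 1
            gidx += 1

    bonds = [
        (global_index[a], global_index[b])
        for a, b in derive_covalent_bonds(structure)
        if a in global_index and b in global_index
    ]
    edges = np.array(
        [(a, b) for a, b in bonds] + [(b, a) for a, b in bonds], dtype=int
    ).reshape(-1, 2)
    atom_residue = np.array(atom_residue)
    degree = np.zeros(local, dtype=int)
    for a, b in bonds:
        degree[a] += 1
        degree[b] += 1

    scalars = np.zeros((local, ATOM_FEATURE_DIM))
    col = 0
    scalars[np.arange(local), np.array(elements)] = 1.0
    col += len(ELEMENT_CLASSES) + 1
    rt = np.array(res_types)
    known = rt < len(RESIDUE_TYPES)
    scalars[np.flatnonzero(known), col + rt[known]] = 1.0
    col += len(RESIDUE_TYPES)
    scalars[:, col] = np.array(backbone, dtype=float)
    col += 1
    scalars[np.arange(local), col + np.minimum(degree, MAX_DEGREE)] = 1.0

    edge_scalars = np.zeros((len(edges), BOND_FEATURE_DIM))
    if len(edges):
        same_res = atom_residue[edges[:, 0]] == atom_residue[edges[:, 1]]
        edge_scalars[same_res, 0] = 1.0
        edge_scalars[~same_res, 1] = 1.0

    return AtomGraph(
        node_scalars=scalars,
        edges=edges,
        edge_scalars=edge_scalars,
        coords=np.array(coords).reshape(-1, 3),
        atom_residue=atom_residue,
        residue_ids=[(r.chain_id, r.index) for r in residues],
        is_loop_atom=np.array(is_loop, dtype=bool),
        atom_names=names,
    )


# -- residue graph -----------------------------------------------------------


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def _backbone_dihedrals(
    chain: list[Residue], i: int, loop_range: tuple | None
) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi, omega) sin/cos and validity flags for residue ``chain[i]``.

    A dihedral is valid only if the required neighbouring residues exist and
    are not loop residues — loop coordinates are unknown at inference time and
    must not leak into nonloop features.
    """

    def usable(j):
        if j < 0 or j >= len(chain):
            return None
        if loop_range is not None and loop_range[0] <= j <= loop_range[1]:
            return None
        return chain[j]

    res = chain[i]
    prev_res, next_res = usable(i - 1), usable(i + 1)
    angles = np.zeros(3)
    valid = np.zeros(3)
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if prev_res is not None and prev_res.atom("C") is not None and None not in (n, ca, c):
        angles[0] = _dihedral(prev_res.atom("C").coords, n.coords, ca.coords, c.coords)
        valid[0] = 1.0
    if next_res is not None and next_res.atom("N") is not None and None not in (n, ca, c):
        angles[1] = _dihedral(n.coords, ca.coords, c.coords, next_res.atom("N").coords)
        valid[1] = 1.0
    if (
        prev_res is not None
        and prev_res.atom("CA") is not None
        and prev_res.atom("C") is not None
        and None not in (n, ca)
    ):
        angles[2] = _dihedral(
            prev_res.atom("CA").coords, prev_res.atom("C").coords, n.coords, ca.coords
        )
        valid[2] = 1.0
    sincos = np.concatenate([np.sin(angles) * valid, np.cos(angles) * valid])
    return sincos, valid


def _rbf(d: np.ndarray, bins: int = RBF_BINS, r_max: float = RBF_RANGE) -> np.ndarray:
    centers = np.linspace(0.0, r_max, bins)
    sigma = r_max / bins
    return np.exp(-(((d[:, None] - centers[None, :]) / sigma) ** 2))


def build_residue_graph(
    structure: ProteinStructure,
    pocket: PocketSelection,
    K: int = KNN_K,
    spec: LoopSpec | None = None,
) -> ResidueGraph:
    if K < 1:
        raise ValueError("K must be >= 1")
    residues = pocket.residues(structure)
    if len(residues) < 2:
        raise ValueError("residue graph needs at least 2 pocket residues")
    P = len(residues)
    ca = np.array([r.ca() for r in residues])
    index_in_chain = np.array([r.index for r in residues])

    # KNN by CA distance, ties broken by lower residue index
    d = cdist(ca, ca)
    np.fill_diagonal(d, np.inf)
    k_eff = min(K, P - 1)
    edges = []
    for i in range(P):
        order = np.lexsort((index_in_chain, d[i]))[:k_eff]
        edges.extend((int(j), i) for j in order)
    # canonical (dst, src) order: row order independent of coordinate roundoff
    edges = np.array(sorted(edges, key=lambda e: (e[1], e[0])), dtype=int)

    loop_range = (spec.start, spec.end) if spec is not None else None
    scalars = np.zeros((P, RESIDUE_SCALAR_DIM))
    vectors = np.zeros((P, 3, 3))
    sequence = np.zeros(P, dtype=int)
    for i, res in enumerate(residues):
        rt = residue_type_index(res.name)
        if rt < len(RESIDUE_TYPES):
            scalars[i, rt] = 1.0
        chain = structure.chains[res.chain_id]
        this_loop_range = loop_range if (spec is not None and res.chain_id == spec.chain_id) else None
        sincos, valid = _backbone_dihedrals(chain, res.index, this_loop_range)
        scalars[i, len(RESIDUE_TYPES) : len(RESIDUE_TYPES) + 6] = sincos
        scalars[i, len(RESIDUE_TYPES) + 6 :] = valid
        sequence[i] = rt

        def unit_to(other: Residue | None):
            if other is None or other.atom("CA") is None:
                return np.zeros(3)
            v = other.ca() - res.ca()
            n = np.linalg.norm(v)
            return v / n if n > 1e-9 else np.zeros(3)

        def neighbour(j):
            if j < 0 or j >= len(chain):
                return None
            if this_loop_range is not None and this_loop_range[0] <= j <= this_loop_range[1]:
                return None
            return chain[j]

        vectors[i, 0] = unit_to(neighbour(res.index + 1))
        vectors[i, 1] = unit_to(neighbour(res.index - 1))
        side = [a.coords for a in res.atoms if not a.is_backbone]
        if side:
            v = np.mean(side, axis=0) - res.ca()
            n = np.linalg.norm(v)
            vectors[i, 2] = v / n if n > 1e-9 else 0.0

    src, dst = edges[:, 0], edges[:, 1]
    dvec = ca[src] - ca[dst]  # CA(j) -> CA(i) points toward the receiver? no:
    # edge (src=j, dst=i): displacement from receiver i to sender j
    dist = np.linalg.norm(dvec, axis=1)
    edge_vectors = (dvec / np.maximum(dist[:, None], 1e-9))[:, None, :]

    same_chain = np.array(
        [residues[a].chain_id == residues[b].chain_id for a, b in edges], dtype=float
    )
    sep = index_in_chain[src] - index_in_chain[dst]
    edge_scalars = np.concatenate(
        [
            _rbf(dist),
            same_chain[:, None],
            np.sign(sep)[:, None] * same_chain[:, None],
            (np.minimum(np.abs(sep), SEQ_SEP_CAP) / SEQ_SEP_CAP)[:, None] * same_chain[:, None],
        ],
        axis=1,
    )
    return ResidueGraph(
        node_scalars=scalars,
        node_vectors=vectors,
        edge_scalars=edge_scalars,
        edge_vectors=edge_vectors,
        sequence=sequence,
        coords=ca,
        edges=edges,
        residue_ids=[(r.chain_id, r.index) for r in residues],
    )


# -- interaction graph -------------------------------------------------------


def build_interaction_graph(
    atom_graph: AtomGraph,
    residue_graph: ResidueGraph,
    loop_init: LoopInit,
) -> InteractionGraph:
    """Loop atoms + pocket residues; bipartite loop-residue edges are complete."""
    loop_idx = np.flatnonzero(atom_graph.is_loop_atom)
    L = len(loop_idx)
    P = len(residue_graph.residue_ids)
    if loop_init.coords.shape[0] != L:
        raise ValueError(
            f"loop init has {loop_init.coords.shape[0]} atoms, graph has {L}"
        )

    edges, etypes = [], []
    # loop-loop: all ordered pairs
    for a in range(L):
        for b in range(L):
            if a != b:
                edges.append((a, b))
                etypes.append(EDGE_LOOP_LOOP)
    # res-res: inherit KNN topology (offset by L)
    for s, t in residue_graph.edges:
        edges.append((L + int(s), L + int(t)))
        etypes.append(EDGE_RES_RES)
    # loop-res: complete bipartite, both directions
    for a in range(L):
        for p in range(P):
            edges.append((a, L + p))
            etypes.append(EDGE_LOOP_RES)
            edges.append((L + p, a))
            etypes.append(EDGE_LOOP_RES)

    return InteractionGraph(
        n_loop_atoms=L,
        n_residues=P,
        edges=np.array(edges, dtype=int),
        edge_type=np.array(etypes, dtype=int),
        residue_coords=residue_graph.coords.copy(),
        loop_coords=np.asarray(loop_init.coords, dtype=np.float64).copy(),
    )
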