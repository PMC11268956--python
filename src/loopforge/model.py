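"""End-to-end loop model: featurisation, forward pass, checkpointing.

A :class:`LoopTask` bundles everything derived from one (structure, loop)
pair: the pocket, the three graphs, ground-truth loop coordinates and the
training labels.  :class:`LoopModel` owns the encoder/generator/scoring
parameters and runs the full pipeline:

    atom graph --GT--> atom embeddings --mask--> loop-atom embeddings
    residue graph --GVP--> residue embeddings --merge w/ atom sums--> pocket embeddings
    (loop embeddings + pocket embeddings) --EGNN recycles--> loop coordinates
    (loop embeddings x pocket embeddings) --MDN--> distance mixtures -> score
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .encoders import (
    FeatureMerge,
    GTConfig,
    GTEncoder,
    GVPConfig,
    GVPEncoder,
    extract_loop_embeddings,
)
from .generator import EGNNConfig, Generator
from .graphs import (
    RESIDUE_EDGE_SCALAR_DIM,
    RESIDUE_SCALAR_DIM,
    AtomGraph,
    ResidueGraph,
    build_atom_graph,
    build_interaction_graph,
    build_residue_graph,
)
from .nn import Tensor
from .pocketing import (
    LoopInit,
    PocketSelection,
    init_loop_reconstruction,
    select_refinement_pocket,
    select_surface_pocket,
)
from .scoring import MDNHead, MDNOutput, mdn_score, pair_min_distances
from .structio import LoopSpec, ProteinStructure

CHECKPOINT_VERSION = 1
N_ELEMENT_CLASSES = 5
N_BOND_CLASSES = 2


@dataclass
class ModelConfig:
    gt: GTConfig = field(default_factory=GTConfig)
    gvp: GVPConfig = field(default_factory=GVPConfig)
    egnn: EGNNConfig = field(default_factory=EGNNConfig)
    d_pair: int = 64
    mdn_dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.gt.d != self.egnn.d_h:
            raise ValueError("atom-encoder width must equal the generator width")

    @staticmethod
    def small(seed: int = 0, d: int = 32, heads: int = 2, recycles: int = 2) -> "ModelConfig":
        """Reduced-width configuration for desk-scale experiments."""
        return ModelConfig(
            gt=GTConfig(n_layers=2, n_heads=heads, d=d, dropout=0.0),
            gvp=GVPConfig(d_scalar=d, n_vector=4, d_seq=8, n_conv_layers=1, dropout=0.0),
            egnn=EGNNConfig(
                n_layers=4,
                n_heads=heads,
                d_h=d,
                recycles=recycles,
                dropout=0.0,
                truncate_recycle_gradients=False,
            ),
            d_pair=d,
            mdn_dropout=0.0,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return {
            "gt": asdict(self.gt),
            "gvp": asdict(self.gvp),
            "egnn": asdict(self.egnn),
            "d_pair": self.d_pair,
            "mdn_dropout": self.mdn_dropout,
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        return ModelConfig(
            gt=GTConfig(**d["gt"]),
            gvp=GVPConfig(**d["gvp"]),
            egnn=EGNNConfig(**d["egnn"]),
            d_pair=d["d_pair"],
            mdn_dropout=d.get("mdn_dropout", 0.1),
            seed=d["seed"],
        )


@dataclass
class LoopTask:
    structure: ProteinStructure
    spec: LoopSpec
    pocket: PocketSelection
    atom_graph: AtomGraph
    residue_graph: ResidueGraph
    residue_rows: np.ndarray  # residue-graph node -> row in atom graph residue list
    truth_loop_coords: np.ndarray | None
    truth_distances: np.ndarray | None  # [L, P] min distances at the true loop
    atom_labels: np.ndarray  # element class per atom node
    bond_labels: np.ndarray  # bond class per directed edge
    task_id: str = ""

    @property
    def n_loop_atoms(self) -> int:
        return int(self.atom_graph.is_loop_atom.sum())

    def pocket_residues(self):
        by_id = {(r.chain_id, r.index): r for r in self.structure.residues()}
        return [by_id[rid] for rid in self.residue_graph.residue_ids]


def prepare_task(
    structure: ProteinStructure,
    spec: LoopSpec,
    truth_loop_coords: np.ndarray | None = None,
    pocket: PocketSelection | None = None,
    mode: str = "reconstruction",
    raw_loop_coords: np.ndarray | None = None,
    task_id: str = "",
) -> LoopTask:
    """Build the graphs and labels for one loop-modeling task."""
    spec.validate(structure)
    if pocket is None:
        if mode == "refinement":
            if raw_loop_coords is None:
                raise ValueError("refinement mode needs raw loop coordinates")
            pocket = select_refinement_pocket(structure, spec, raw_loop_coords)
        else:
            pocket = select_surface_pocket(structure, spec)
    atom_graph = build_atom_graph(structure, pocket, spec)
    residue_graph = build_residue_graph(structure, pocket, spec=spec)
    row_of = {rid: i for i, rid in enumerate(atom_graph.residue_ids)}
    residue_rows = np.array([row_of[rid] for rid in residue_graph.residue_ids], dtype=int)

    atom_labels = atom_graph.node_scalars[:, : N_ELEMENT_CLASSES].argmax(axis=1)
    bond_labels = atom_graph.edge_scalars.argmax(axis=1) if len(atom_graph.edges) else np.zeros(0, int)

    truth_distances = None
    if truth_loop_coords is not None:
        by_id = {(r.chain_id, r.index): r for r in structure.residues()}
        residues = [by_id[rid] for rid in residue_graph.residue_ids]
        truth_distances = pair_min_distances(truth_loop_coords, residues)
    return LoopTask(
        structure=structure,
        spec=spec,
        pocket=pocket,
        atom_graph=atom_graph,
        residue_graph=residue_graph,
        residue_rows=residue_rows,
        truth_loop_coords=truth_loop_coords,
        truth_distances=truth_distances,
        atom_labels=atom_labels,
        bond_labels=bond_labels,
        task_id=task_id,
    )


@dataclass
class ModelOutputs:
    loop_coords: Tensor | None  # [L, 3]
    trajectory: list | None
    mdn: MDNOutput
    atom_logits: Tensor
    bond_logits: Tensor
    loop_embeddings: Tensor
    pocket_embeddings: Tensor
    layer_coords: list | None = None  # per-EGNN-layer loop coords (all recycles)


class LoopModel(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        from .graphs import ATOM_FEATURE_DIM, BOND_FEATURE_DIM

        self.gt = GTEncoder(ATOM_FEATURE_DIM, BOND_FEATURE_DIM, config.gt, rng)
        self.gvp = GVPEncoder(
            (RESIDUE_SCALAR_DIM, 3, RESIDUE_EDGE_SCALAR_DIM, 1), config.gvp, rng
        )
        self.merge = FeatureMerge(config.gvp.d_scalar, config.gt.d, config.egnn.d_h, rng)
        self.generator = Generator(4, config.egnn, rng)
        self.mdn = MDNHead(config.egnn.d_h, rng, d_pair=config.d_pair, dropout=config.mdn_dropout)
        self.atom_head = nn.Linear(config.gt.d, N_ELEMENT_CLASSES, rng)
        self.bond_head = nn.Linear(config.gt.d, N_BOND_CLASSES, rng)
        self._encoder_cache: dict = {}

    # -- pieces --------------------------------------------------------------
    def encode(self, task: LoopTask):
        h_atoms, e_atoms = self.gt(task.atom_graph)
        hs_res, _ = self.gvp(task.residue_graph)
        pocket_emb = self.merge(
            hs_res, h_atoms, task.atom_graph.atom_residue, task.residue_rows
        )
        loop_emb = extract_loop_embeddings(h_atoms, task.atom_graph.is_loop_atom)
        return h_atoms, e_atoms, loop_emb, pocket_emb

    def encode_frozen(self, task: LoopTask):
        """Encoder outputs detached from the graph and cached per task.

        Valid only while the encoder parameters are held fixed (the cache is
        cleared by :meth:`clear_encoder_cache`)."""
        key = task.task_id or id(task)
        if key not in self._encoder_cache:
            h_atoms, e_atoms, loop_emb, pocket_emb = self.encode(task)
            self._encoder_cache[key] = tuple(
                t.detach() for t in (h_atoms, e_atoms, loop_emb, pocket_emb)
            )
        return self._encoder_cache[key]

    def clear_encoder_cache(self):
        self._encoder_cache = {}

    def encoder_parameters(self):
        """Parameters of the encoder stage (GT, GVP, merge, auxiliary heads)."""
        mods = [self.gt, self.gvp, self.merge, self.atom_head, self.bond_head]
        return [p for m in mods for p in m.parameters()]

    # -- full forward --------------------------------------------------------
    def __call__(
        self,
        task: LoopTask,
        loop_init: LoopInit | None = None,
        run_generator: bool = True,
        frozen_encoders: bool = False,
    ) -> ModelOutputs:
        if frozen_encoders:
            h_atoms, e_atoms, loop_emb, pocket_emb = self.encode_frozen(task)
        else:
            h_atoms, e_atoms, loop_emb, pocket_emb = self.encode(task)
        coords, trajectory, layer_coords = None, None, None
        if run_generator:
            if loop_init is None:
                raise ValueError("generator needs an initial loop conformation")
            igraph = build_interaction_graph(task.atom_graph, task.residue_graph, loop_init)
            node_emb = nn.concat([loop_emb, pocket_emb], axis=0)
            coords, trajectory, _ = self.generator(node_emb, igraph)
            layer_coords = list(self.generator.layer_coords)
        return ModelOutputs(
            loop_coords=coords,
            trajectory=trajectory,
            mdn=self.mdn(loop_emb, pocket_emb),
            atom_logits=self.atom_head(h_atoms),
            bond_logits=self.bond_head(e_atoms),
            loop_embeddings=loop_emb,
            pocket_embeddings=pocket_emb,
            layer_coords=layer_coords,
        )

    def predict(
        self,
        task: LoopTask,
        seed: int = 0,
        sd: float | None = None,
        mode: str = "reconstruction",
        raw_loop_coords: np.ndarray | None = None,
    ) -> tuple[np.ndarray, float]:
        """Inference: initialise, generate, and score one conformation."""
        was_training = self.training
        self.eval()
        try:
            if mode == "refinement":
                from .pocketing import init_loop_refinement

                if raw_loop_coords is None:
                    raise ValueError("refinement mode needs raw loop coordinates")
                init = init_loop_refinement(
                    raw_loop_coords, seed=seed, **({"sd": sd} if sd else {})
                )
            else:
                kwargs = {"sd": sd} if sd else {}
                init = init_loop_reconstruction(task.structure, task.spec, seed=seed, mode=mode, **kwargs)
            out = self(task, loop_init=init)
            coords = out.loop_coords.data
            dists = pair_min_distances(coords, task.pocket_residues())
            score = mdn_score(out.mdn, dists)
        finally:
            self.train(was_training)
        return coords, score

    def load_state_dict(self, state):
        super().load_state_dict(state)
        self.clear_encoder_cache()

    # -- checkpointing -------------------------------------------------------
    def save(self, path: str) -> str:
        if not str(path).endswith(".npz"):
            path = str(path) + ".npz"
        state = self.state_dict()
        meta = json.dumps({"version": CHECKPOINT_VERSION, "config": self.config.to_dict()})
        np.savez(path, __meta__=np.array(meta), **state)
        return str(path)

    @staticmethod
    def load(path: str) -> "LoopModel":
        if not str(path).endswith(".npz"):
            path = str(path) + ".npz"
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        model = LoopModel(ModelConfig.from_dict(meta["config"]))
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model
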