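"""Two-stage training: MDN pretraining, then joint coordinate training.

Stage 1 trains the encoders and the mixture-density head to fit the
distribution of loop-atom/pocket-residue distances observed in the true
conformations, with two small auxiliary cross-entropy losses (element class
per atom node, bond class per covalent edge) keeping the atom encoder's
embeddings chemically grounded:

    L = L_MDN + 0.001 * L_atom + 0.001 * L_bond

Stage 2 starts from a stage-1 checkpoint, adds the generator, and appends a
coordinate loss — the RMSD between predicted and true loop coordinates in
the shared frame — with coefficient 1:

    L = L_RMSD + L_MDN + 0.001 * L_atom + 0.001 * L_bond

Both stages use Adam; stage 1 runs at lr 1e-3 with weight decay 1e-5,
stage 2 at lr 1e-4 without weight decay.  Early stopping monitors the
validation loss with a no-improvement patience (default 70 epochs) and the
best-validation parameters are retained.  Train/validation splits are
stratified by loop length in a 9:1 ratio.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass

import numpy as np

from .model import LoopModel, LoopTask, ModelConfig, ModelOutputs
from .nn import Adam, Tensor, gather
from .pocketing import SD_RECONSTRUCTION, init_loop_reconstruction
from .scoring import mdn_nll

AUX_COEF = 0.001
RMSD_COEF = 1.0


@dataclass
class TrainConfig:
    stage: int = 1
    batch_size: int = 64
    learning_rate: float | None = None  # default depends on stage
    weight_decay: float | None = None
    patience: int = 70
    max_epochs: int = 1000
    seed: int = 0
    aux_coef: float = AUX_COEF
    rmsd_coef: float = RMSD_COEF
    init_sd: float = SD_RECONSTRUCTION
    #: supervise every EGNN layer's coordinates (stage 2), not only the final
    #: ones; the reported L_rmsd is still the final-coordinate RMSD
    deep_supervision: bool = False
    #: one optimiser step per task instead of one per batch
    step_per_task: bool = False
    #: 'constant' or 'cosine' (annealed to lr/30 across max_epochs)
    lr_schedule: str = "constant"
    #: evaluate the validation loss every n epochs (patience counts checks)
    val_every: int = 1
    #: clip the global gradient norm before each step (None disables); full
    #: backpropagation through recycles needs this to stay stable
    grad_clip: float | None = None
    #: stage 2: hold the encoder stage fixed and train only the generator and
    #: the mixture-density head; encoder outputs are computed once per task
    freeze_encoders: bool = False

    def __post_init__(self):
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate is None:
            self.learning_rate = 1e-3 if self.stage == 1 else 1e-4
        if self.weight_decay is None:
            self.weight_decay = 1e-5 if self.stage == 1 else 0.0
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class LossReport:
    mdn: float = 0.0
    atom: float = 0.0
    bond: float = 0.0
    rmsd: float = 0.0
    total: float = 0.0


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under row-wise softmax logits."""
    labels = np.asarray(labels, dtype=np.int64)
    if logits.shape[0] != labels.shape[0]:
        raise ValueError("label count must match logit rows")
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    lse = ((logits - shift).exp().sum(axis=-1, keepdims=True)).log() + shift
    rows = np.arange(len(labels))
    picked = logits[rows, labels]
    return (lse.reshape(-1) - picked).mean()


def auxiliary_losses(
    atom_logits: Tensor,
    bond_logits: Tensor,
    atom_labels: np.ndarray,
    bond_labels: np.ndarray,
) -> tuple[Tensor, Tensor]:
    return cross_entropy(atom_logits, atom_labels), cross_entropy(bond_logits, bond_labels)


def rmsd_loss(pred_coords: Tensor, true_coords: np.ndarray) -> Tensor:
    """RMSD in the shared frame (no superposition): sqrt(mean |dx|^2)."""
    true_coords = np.asarray(true_coords, dtype=np.float64)
    if pred_coords.shape != true_coords.shape:
        raise ValueError("coordinate arrays must have identical shapes")
    return ((pred_coords - Tensor(true_coords)) ** 2).sum(axis=-1).mean().sqrt()


def compute_losses(outputs: ModelOutputs, task: LoopTask, config: TrainConfig) -> tuple[Tensor, LossReport]:
    if task.truth_distances is None:
        raise ValueError("training tasks need ground-truth loop coordinates")
    l_mdn = mdn_nll(outputs.mdn, task.truth_distances)
    l_atom, l_bond = auxiliary_losses(
        outputs.atom_logits, outputs.bond_logits, task.atom_labels, task.bond_labels
    )
    total = l_mdn + config.aux_coef * l_atom + config.aux_coef * l_bond
    report = LossReport(
        mdn=float(l_mdn.data), atom=float(l_atom.data), bond=float(l_bond.data)
    )
    if config.stage == 2:
        if outputs.loop_coords is None:
            raise ValueError("stage 2 requires generator outputs")
        l_rmsd = rmsd_loss(outputs.loop_coords, task.truth_loop_coords)
        if config.deep_supervision and outputs.layer_coords:
            per_layer = [rmsd_loss(c, task.truth_loop_coords) for c in outputs.layer_coords]
            coord_term = sum(per_layer[1:], per_layer[0]) * (1.0 / len(per_layer))
        else:
            coord_term = l_rmsd
        total = total + config.rmsd_coef * coord_term
        report.rmsd = float(l_rmsd.data)
        report.total = (
            config.rmsd_coef * report.rmsd
            + report.mdn
            + config.aux_coef * report.atom
            + config.aux_coef * report.bond
        )
    else:
        report.total = (
            report.mdn + config.aux_coef * report.atom + config.aux_coef * report.bond
        )
    return total, report


def stratified_split(
    tasks: list[LoopTask], fraction: float = 0.9, seed: int = 0
) -> tuple[list[LoopTask], list[LoopTask]]:
    """Split by loop length so both sides see the same length distribution."""
    rng = np.random.default_rng(seed)
    by_len: dict[int, list[LoopTask]] = {}
    for t in tasks:
        by_len.setdefault(t.spec.length, []).append(t)
    train, val = [], []
    for group in by_len.values():
        order = rng.permutation(len(group))
        n_train = max(1, int(round(fraction * len(group))))
        for pos, j in enumerate(order):
            (train if pos < n_train else val).append(group[j])
    return train, val or train  # tiny datasets validate on the training set


def _task_loss(model: LoopModel, task: LoopTask, config: TrainConfig):
    frozen = config.freeze_encoders and config.stage == 2
    if config.stage == 2:
        # one fixed initialisation per task (crc of its id): the generator
        # learns a deterministic init -> truth mapping
        init = init_loop_reconstruction(
            task.structure,
            task.spec,
            sd=config.init_sd,
            seed=zlib.crc32(task.task_id.encode()) % (2**31),
        )
        outputs = model(task, loop_init=init, frozen_encoders=frozen)
    else:
        outputs = model(task, run_generator=False)
    return compute_losses(outputs, task, config)


@dataclass
class TrainLogEntry:
    epoch: int
    train_loss: float
    val_loss: float
    report: LossReport


def train(
    tasks: list[LoopTask],
    config: TrainConfig,
    model: LoopModel | None = None,
    model_config: ModelConfig | None = None,
    val_tasks: list[LoopTask] | None = None,
    log_path: str | None = None,
    progress: bool = False,
) -> tuple[LoopModel, list[TrainLogEntry]]:
    """Optimise a model on loop tasks; returns the best-validation model state.

    ``model`` may be a fresh model (stage 1) or a stage-1 checkpointed model
    (stage 2).  Stage-2 training without a starting model is refused.
    """
    if not tasks:
        raise ValueError("training dataset is empty")
    if model is None:
        if config.stage == 2:
            raise ValueError("stage 2 must start from a stage-1 model")
        model = LoopModel(model_config or ModelConfig())
    if val_tasks is None:
        tasks, val_tasks = stratified_split(tasks, seed=config.seed)

    model.train()
    if config.freeze_encoders and config.stage == 2:
        model.clear_encoder_cache()
        frozen_ids = {id(p) for p in model.encoder_parameters()}
        train_params = [p for p in model.parameters() if id(p) not in frozen_ids]
    else:
        train_params = model.parameters()
    optim = Adam(train_params, lr=config.learning_rate, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    log: list[TrainLogEntry] = []
    best_val = np.inf
    best_state = model.state_dict()
    epochs_since_best = 0

    base_lr = config.learning_rate
    for epoch in range(1, config.max_epochs + 1):
        if config.lr_schedule == "cosine":
            floor = base_lr / 30.0
            optim.lr = floor + 0.5 * (base_lr - floor) * (
                1.0 + np.cos(np.pi * epoch / config.max_epochs)
            )
        order = rng.permutation(len(tasks))
        epoch_losses = []
        last_report = LossReport()
        step_size = 1 if config.step_per_task else config.batch_size
        for start in range(0, len(order), step_size):
            batch = [tasks[i] for i in order[start : start + step_size]]
            optim.zero_grad()
            batch_total = None
            for task in batch:
                total, last_report = _task_loss(model, task, config)
                batch_total = total if batch_total is None else batch_total + total
                epoch_losses.append(float(total.data))
            (batch_total * (1.0 / len(batch))).backward()
            if config.grad_clip is not None:
                norm = np.sqrt(
                    sum(float((p.grad**2).sum()) for p in model.parameters() if p.grad is not None)
                )
                if norm > config.grad_clip:
                    scale = config.grad_clip / norm
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad *= scale
            optim.step()

        if epoch % config.val_every and epoch != config.max_epochs:
            continue
        model.eval()
        val_losses = [float(_task_loss(model, t, config)[0].data) for t in val_tasks]
        model.train()
        val_loss = float(np.mean(val_losses))
        entry = TrainLogEntry(epoch, float(np.mean(epoch_losses)), val_loss, last_report)
        log.append(entry)
        if progress:
            print(f"epoch {epoch}: train {entry.train_loss:.4f} val {val_loss:.4f}")

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.state_dict()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break

    model.load_state_dict(best_state)
    model.eval()
    if log_path:
        with open(log_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_loss"])
            for entry in log:
                writer.writerow([entry.epoch, entry.train_loss, entry.val_loss])
    return model, log
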