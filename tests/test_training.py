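"""Loss definitions, loss composition, early stopping, gradient agreement."""

import numpy as np
import pytest

from loopforge.fixtures import make_loop_task
from loopforge.model import LoopModel, ModelConfig, prepare_task
from loopforge.nn import Tensor
from loopforge.pocketing import init_loop_reconstruction
from loopforge.scoring import mdn_nll
from loopforge.training import (
    LossReport,
    TrainConfig,
    auxiliary_losses,
    compute_losses,
    cross_entropy,
    rmsd_loss,
    stratified_split,
    train,
)

RNG = np.random.default_rng(0)


class TestCrossEntropy:
    def test_uniform_logits_give_log_c(self):
        for C in (2, 5, 10):
            logits = Tensor(np.zeros((7, C)))
            labels = RNG.integers(0, C, size=7)
            assert abs(float(cross_entropy(logits, labels).data) - np.log(C)) < 1e-12

    def test_confident_correct_logits_vanish(self):
        labels = np.array([0, 2, 1])
        logits = np.full((3, 3), -50.0)
        logits[np.arange(3), labels] = 50.0
        assert float(cross_entropy(Tensor(logits), labels).data) < 1e-12

    def test_hand_computed_toy_batch(self):
        logits = np.array([[1.0, 0.0], [0.0, 2.0], [0.5, 0.5]])
        labels = np.array([0, 1, 1])
        expected = np.mean(
            [
                -np.log(np.exp(1.0) / (np.exp(1.0) + 1.0)),
                -np.log(np.exp(2.0) / (np.exp(2.0) + 1.0)),
                -np.log(0.5),
            ]
        )
        assert abs(float(cross_entropy(Tensor(logits), labels).data) - expected) < 1e-12


class TestRMSDLoss:
    def test_identical_zero(self):
        x = RNG.normal(size=(9, 3))
        assert float(rmsd_loss(Tensor(x), x).data) == 0.0

    def test_uniform_unit_offset(self):
        x = RNG.normal(size=(9, 3))
        shifted = x + np.array([1.0, 0.0, 0.0])
        assert abs(float(rmsd_loss(Tensor(shifted), x).data) - 1.0) < 1e-12

    def test_matches_scalar_loop_oracle(self):
        a, b = RNG.normal(size=(11, 3)), RNG.normal(size=(11, 3))
        vec = float(rmsd_loss(Tensor(a), b).data)
        acc = sum(np.sum((a[i] - b[i]) ** 2) for i in range(11))
        assert abs(vec - np.sqrt(acc / 11)) < 1e-9


class TestLossComposition:
    @pytest.fixture(scope="class")
    def task_and_model(self):
        structure, spec, truth = make_loop_task(6, 4, 6, seed=0)
        task = prepare_task(structure, spec, truth_loop_coords=truth, task_id="t")
        model = LoopModel(ModelConfig.small(seed=0, recycles=1))
        model.eval()
        return task, model

    def test_stage1_composition(self, task_and_model):
        task, model = task_and_model
        outputs = model(task, run_generator=False)
        config = TrainConfig(stage=1)
        total, report = compute_losses(outputs, task, config)
        recombined = report.mdn + 0.001 * report.atom + 0.001 * report.bond
        assert abs(report.total - recombined) < 1e-12
        assert report.rmsd == 0.0

    def test_stage2_adds_exactly_rmsd(self, task_and_model):
        task, model = task_and_model
        init = init_loop_reconstruction(task.structure, task.spec, seed=0)
        outputs = model(task, loop_init=init)
        _, r1 = compute_losses(outputs, task, TrainConfig(stage=1))
        _, r2 = compute_losses(outputs, task, TrainConfig(stage=2))
        assert abs((r2.total - r1.total) - r2.rmsd) < 1e-12
        recombined = r2.rmsd + r2.mdn + 0.001 * r2.atom + 0.001 * r2.bond
        assert abs(r2.total - recombined) < 1e-12

    def test_stage2_without_generator_output_rejected(self, task_and_model):
        task, model = task_and_model
        outputs = model(task, run_generator=False)
        with pytest.raises(ValueError):
            compute_losses(outputs, task, TrainConfig(stage=2))


class TestAuxiliaryLosses:
    def test_perfect_and_uniform(self):
        labels = np.array([0, 1, 1, 0])
        perfect = np.full((4, 2), -40.0)
        perfect[np.arange(4), labels] = 40.0
        l_atom, l_bond = auxiliary_losses(
            Tensor(perfect), Tensor(np.zeros((6, 2))), labels, np.zeros(6, dtype=int)
        )
        assert float(l_atom.data) < 1e-12
        assert abs(float(l_bond.data) - np.log(2)) < 1e-12


class TestStratifiedSplit:
    def test_ratio_and_strata(self):
        tasks = []
        for length in (4, 6):
            for seed in range(10):
                s, spec, truth = make_loop_task(4, length, 4, seed=seed)
                tasks.append(prepare_task(s, spec, truth_loop_coords=truth, task_id=f"{length}-{seed}"))
        train_set, val_set = stratified_split(tasks, fraction=0.9, seed=0)
        assert len(train_set) == 18 and len(val_set) == 2
        assert {t.spec.length for t in val_set} == {4, 6}


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def tiny_tasks(self):
        tasks = []
        for seed in range(2):
            s, spec, truth = make_loop_task(5, 4, 5, seed=seed)
            tasks.append(prepare_task(s, spec, truth_loop_coords=truth, task_id=f"t{seed}"))
        return tasks

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig(stage=1))

    def test_stage2_requires_model(self, tiny_tasks):
        with pytest.raises(ValueError):
            train(tiny_tasks, TrainConfig(stage=2))

    def test_early_stopping_patience_one(self, tiny_tasks):
        cfg = TrainConfig(stage=1, patience=1, max_epochs=50, learning_rate=10.0, seed=0)
        _, log = train(
            tiny_tasks, cfg, model_config=ModelConfig.small(seed=0), val_tasks=tiny_tasks
        )
        # a divergent learning rate raises validation loss immediately
        assert len(log) < 50

    def test_fixed_seed_reproducible_first_epoch(self, tiny_tasks):
        cfg = TrainConfig(stage=1, max_epochs=1, seed=3)
        _, log_a = train(tiny_tasks, cfg, model_config=ModelConfig.small(seed=1), val_tasks=tiny_tasks)
        _, log_b = train(tiny_tasks, cfg, model_config=ModelConfig.small(seed=1), val_tasks=tiny_tasks)
        assert log_a[0].train_loss == log_b[0].train_loss
        assert log_a[0].val_loss == log_b[0].val_loss


class TestGradientAgreement:
    def test_backprop_matches_finite_difference(self):
        """Total stage-2 loss gradient vs central differences on sampled weights."""
        structure, spec, truth = make_loop_task(5, 4, 5, seed=1)
        task = prepare_task(structure, spec, truth_loop_coords=truth, task_id="g")
        model = LoopModel(ModelConfig.small(seed=2, recycles=1))
        model.train()
        init = init_loop_reconstruction(structure, spec, seed=0)
        config = TrainConfig(stage=2)

        def loss_value():
            outputs = model(task, loop_init=init)
            total, _ = compute_losses(outputs, task, config)
            return total

        model.zero_grad()
        loss_value().backward()
        params = dict(model.named_parameters())
        rng = np.random.default_rng(0)
        for name in ["gt.layers.0.W_V.weight", "gvp.convs.0.msg2.W_sv.weight",
                     "generator.layers.0.W_m1.weight", "mdn.lin_pi.weight"]:
            p = params[name]
            idx = tuple(rng.integers(0, s) for s in p.data.shape)
            bp = p.grad[idx]
            eps, old = 1e-5, p.data[idx]
            p.data[idx] = old + eps
            lp = float(loss_value().data)
            p.data[idx] = old - eps
            lm = float(loss_value().data)
            p.data[idx] = old
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - bp) / max(abs(fd), abs(bp), 1e-6) < 1e-3, name
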