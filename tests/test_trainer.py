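import numpy as np
import pytest

from paleoseg.annotation import AnnotationPlan
from paleoseg.exceptions import GeometryError, ScheduleError
from paleoseg.stack_io import MaskStack, SliceStack
from paleoseg.trainer import (
    DiceScore,
    TrainConfig,
    bce_loss,
    build_network,
    dice,
    evaluate,
    initial_learning_rate,
    learning_rate_at,
    train,
)


def _brute_force_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Independent set-counting oracle for the Dice coefficient."""
    A = {tuple(p) for p in np.argwhere(a)}
    B = {tuple(p) for p in np.argwhere(b)}
    if not A and not B:
        return 1.0
    return 2 * len(A & B) / (len(A) + len(B))


class TestLearningRateHeuristic:
    @pytest.mark.parametrize(
        "batch,expected", [(8, 0.0003125), (256, 0.01), (16, 0.000625)]
    )
    def test_linear_scaling(self, batch, expected):
        assert initial_learning_rate(batch) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_batch(self):
        with pytest.raises(ValueError):
            initial_learning_rate(0)


class TestSchedule:
    def setup_method(self):
        self.cfg = TrainConfig(epochs=110, warmup_epochs=10, batch_size=8)
        self.lr0 = initial_learning_rate(8)

    def test_starts_at_zero(self):
        assert learning_rate_at(0, self.cfg) == 0.0

    def test_warmup_endpoint_reaches_lr0(self):
        assert learning_rate_at(10, self.cfg) == pytest.approx(self.lr0)

    def test_cosine_midpoint_is_half(self):
        mid = 10 + (110 - 10) // 2
        assert learning_rate_at(mid, self.cfg) == pytest.approx(self.lr0 / 2)

    def test_continuous_at_warmup_boundary(self):
        before = learning_rate_at(9, self.cfg)
        at = learning_rate_at(10, self.cfg)
        assert abs(at - before) <= self.lr0 / 10 + 1e-12

    def test_nonnegative_and_cosine_tail_vanishes(self):
        rates = [learning_rate_at(e, self.cfg) for e in range(110)]
        assert min(rates) >= 0.0
        assert rates[-1] < self.lr0 * 1e-3

    def test_out_of_range_epoch_rejected(self):
        with pytest.raises(ValueError):
            learning_rate_at(110, self.cfg)


class TestDice:
    def test_identical_masks_score_one(self, rng):
        m = (rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8)
        assert dice(m, m).value == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0], b[2] = 1, 1
        assert dice(a, b).value == 0.0

    def test_both_empty_score_one(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert dice(z, z).value == 1.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a.flat[:4], b.flat[2:6] = 1, 1
        assert dice(a, b).value == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            a = rng.uniform(size=(8, 8)) > rng.uniform(0.2, 0.9)
            b = rng.uniform(size=(8, 8)) > rng.uniform(0.2, 0.9)
            assert dice(a, b).value == pytest.approx(_brute_force_dice(a, b))

    def test_symmetric(self, rng):
        a = rng.uniform(size=(8, 8)) > 0.6
        b = rng.uniform(size=(8, 8)) > 0.6
        assert dice(a, b).value == dice(b, a).value

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            dice(np.zeros((4, 4)), np.zeros((4, 5)))


class TestBCELoss:
    def test_perfect_prediction_vanishes(self):
        y = np.ones((8, 8))
        assert bce_loss(np.full((8, 8), 1 - 1e-9), y) < 1e-6

    def test_half_probability_is_ln2(self, rng):
        y = (rng.uniform(size=(8, 8)) > 0.5).astype(float)
        assert bce_loss(np.full((8, 8), 0.5), y) == pytest.approx(np.log(2))

    def test_confident_wrong_is_large_but_finite(self):
        loss = bce_loss(np.zeros((4, 4)), np.ones((4, 4)))
        assert np.isfinite(loss) and loss > 10


class _TinySetup:
    """A minimal solvable training problem: bright square on dark slices."""

    def __init__(self, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.normal(0.3, 0.02, size=(8, 32, 32)).clip(0, 1)
        self.mask = np.zeros((32, 32), dtype=np.uint8)
        self.mask[8:24, 8:24] = 1
        for i in range(2, 6):
            data[i][self.mask > 0] += 0.4
        self.stack = SliceStack(data.clip(0, 1))
        self.annotations = MaskStack(
            {i: (self.mask if 2 <= i < 6 else np.zeros_like(self.mask))
             for i in range(8)}
        )
        self.plan = AnnotationPlan(
            [2, 3, 4, 5], step=1, validation_index=5,
            negative_ranges=[(0, 2), (6, 8)],
        )

    def config(self, **kw):
        base = dict(
            crop_size=16, batch_size=4, epochs=12, warmup_epochs=2,
            encoder_name="tiny", decoder_channels=[16, 8], seed=0,
        )
        base.update(kw)
        return TrainConfig(**base)


class TestTrainLoop:
    def test_single_epoch_reports_epoch_zero(self):
        s = _TinySetup()
        model = train(s.stack, s.annotations, s.plan, s.config(epochs=2, warmup_epochs=1))
        assert model.best_epoch in (0, 1)
        assert 0.0 <= model.best_val_dice <= 1.0
        assert len(model.history) == 2

    def test_best_dice_is_running_maximum(self):
        s = _TinySetup()
        model = train(s.stack, s.annotations, s.plan, s.config())
        observed = [h["val_dice"] for h in model.history]
        assert model.best_val_dice == max(observed)
        assert observed[model.best_epoch] == model.best_val_dice

    def test_deterministic_given_seed(self):
        s = _TinySetup()
        m1 = train(s.stack, s.annotations, s.plan, s.config(seed=3))
        m2 = train(s.stack, s.annotations, s.plan, s.config(seed=3))
        assert m1.best_val_dice == m2.best_val_dice
        for k, v in m1.network.state_dict().items():
            np.testing.assert_array_equal(v, m2.network.state_dict()[k])

    def test_empty_plan_rejected(self):
        s = _TinySetup()
        bad = AnnotationPlan([5], step=1, validation_index=5)
        with pytest.raises(ScheduleError):
            train(s.stack, s.annotations, bad, s.config())

    def test_checkpoint_round_trip(self, tmp_path):
        from paleoseg.trainer import TrainedModel

        s = _TinySetup()
        model = train(s.stack, s.annotations, s.plan, s.config(epochs=3, warmup_epochs=1))
        model.save(tmp_path / "ckpt.npz")
        back = TrainedModel.load(tmp_path / "ckpt.npz")
        assert back.best_val_dice == model.best_val_dice
        x = np.random.default_rng(0).uniform(size=(1, 1, 16, 16))
        np.testing.assert_array_equal(
            back.network.forward(x), model.network.forward(x)
        )


class TestEvaluate:
    def _oracle_model(self, mask):
        """A stand-in model whose network always predicts `mask`."""

        class _Net:
            dtype = np.float64

            def forward(self, x, train=False):
                logits = np.where(mask > 0, 20.0, -20.0)
                return np.broadcast_to(
                    logits, (x.shape[0], 1) + mask.shape
                ).copy()

        from paleoseg.trainer import TrainedModel

        return TrainedModel(_Net(), 1.0, 0, TrainConfig(epochs=2, warmup_epochs=1))

    def test_perfect_model_scores_one(self):
        s = _TinySetup()
        model = self._oracle_model(s.mask)
        rep = evaluate(model, s.stack, s.annotations, indices=[2, 3])
        assert rep["mean_dice"] == 1.0 and rep["pooled_dice"] == 1.0

    def test_zero_predictor_on_nonempty_truth_scores_zero(self):
        s = _TinySetup()
        model = self._oracle_model(np.zeros((32, 32)))
        rep = evaluate(model, s.stack, s.annotations, indices=[2])
        assert rep["mean_dice"] == 0.0

    def test_zero_predictor_on_empty_truth_scores_one(self):
        s = _TinySetup()
        model = self._oracle_model(np.zeros((32, 32)))
        rep = evaluate(model, s.stack, s.annotations, indices=[0])
        assert rep["mean_dice"] == 1.0
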