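import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wbcnet.dataset_io import CLASS_NAMES, LabeledDataset
from wbcnet.models import (ArchitectureSpec, LayerSpec, build_from_spec,
                           save_checkpoint)
from wbcnet.synthetic_cells import SyntheticConfig, generate_dataset
from wbcnet.preprocess import preprocess_pipeline
from wbcnet.training import (TrainingConfig, adam_step, equivalent_iterations,
                             fine_tune, hinge_loss,
                             multiclass_hinge, scheduled_steps,
                             softmax_cross_entropy, train_model)


def _small_cnn(seed=0):
    """A few-thousand-parameter CNN on 128x128x3 inputs for fast loop tests."""
    spec = ArchitectureSpec(
        (LayerSpec("conv", kernel=(3, 3), filters=4),
         LayerSpec("activation", activation="relu"),
         LayerSpec("maxpool", kernel=(2, 2), stride=2),
         LayerSpec("maxpool", kernel=(2, 2), stride=2),
         LayerSpec("maxpool", kernel=(2, 2), stride=2),
         LayerSpec("maxpool", kernel=(2, 2), stride=2),
         LayerSpec("maxpool", kernel=(2, 2), stride=2),
         LayerSpec("flatten"),
         LayerSpec("dense", filters=5)),
        input_shape=(128, 128, 3))
    return build_from_spec(spec, seed=seed)


class TestSoftmaxCrossEntropy:
    def test_uniform_logits_give_log5(self):
        assert np.isclose(softmax_cross_entropy(np.zeros(5), 2), np.log(5))

    def test_saturated_case_near_zero(self):
        logits = np.array([1000.0, 0, 0, 0, 0])
        assert softmax_cross_entropy(logits, 0) < 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 4))
    def test_matches_unshifted_formula_oracle(self, seed, true_class):
        logits = np.random.default_rng(seed).normal(0, 2, size=5)
        q = np.exp(logits) / np.exp(logits).sum()  # safe at low magnitudes
        oracle = -np.log(q[true_class])
        assert abs(softmax_cross_entropy(logits, true_class) - oracle) < 1e-9
        assert softmax_cross_entropy(logits, true_class) >= 0

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            softmax_cross_entropy(np.zeros(5), 7)


class TestHingeLoss:
    @pytest.mark.parametrize("score,target,expected", [
        (1.0, 1, 0.0), (0.5, 1, 0.5), (-1.0, -1, 0.0), (0.0, -1, 1.0)])
    def test_binary_formula(self, score, target, expected):
        assert hinge_loss(score, target) == expected

    def test_target_must_be_plus_minus_one(self):
        with pytest.raises(ValueError):
            hinge_loss(0.5, 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 4))
    def test_multiclass_sum_matches_per_class_oracle(self, seed, true_class):
        scores = np.random.default_rng(seed).normal(0, 2, size=5)
        oracle = sum(
            hinge_loss(scores[k], 1 if k == true_class else -1)
            for k in range(5))
        assert abs(multiclass_hinge(scores, true_class) - oracle) < 1e-12


class TestAdamStep:
    def test_zero_gradient_is_noop(self):
        params = {"w": np.array([1.0, 2.0])}
        grads = {"w": np.zeros(2)}
        new, state = adam_step(params, grads, None, TrainingConfig())
        np.testing.assert_array_equal(new["w"], params["w"])

    def test_first_step_moves_by_learning_rate(self):
        """Bias-corrected first step with g=1: delta ~= -lr."""
        cfg = TrainingConfig(learning_rate=0.1)
        new, _ = adam_step({"w": np.array([5.0])}, {"w": np.array([1.0])},
                           None, cfg)
        assert abs(new["w"][0] - (5.0 - 0.1)) < 1e-6

    def test_two_steps_match_scalar_recursion_oracle(self):
        cfg = TrainingConfig(learning_rate=0.01)
        b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_epsilon
        g = 0.3
        theta, m, v = 2.0, 0.0, 0.0
        params, state = {"w": np.array([2.0])}, None
        for t in (1, 2):
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            theta -= 0.01 * (m / (1 - b1 ** t)) / np.sqrt(v / (1 - b2 ** t) + eps)
            params, state = adam_step(params, {"w": np.array([g])}, state, cfg)
            assert abs(params["w"][0] - theta) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adam_step({"w": np.zeros(3)}, {"w": np.zeros(2)}, None,
                      TrainingConfig())


class TestTrainModel:
    def test_zero_epochs_is_identity(self, tiny_preprocessed_dataset):
        model = _small_cnn()
        before = {k: v.copy() for k, v in model.parameters.items()}
        model, trace = train_model(model, tiny_preprocessed_dataset,
                                   TrainingConfig(epochs=0))
        assert trace == []
        for k, v in model.parameters.items():
            np.testing.assert_array_equal(v, before[k])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_model(_small_cnn(), LabeledDataset([]), TrainingConfig())

    def test_loss_decreases_on_separable_data(self):
        counts = {c: 5 for c in CLASS_NAMES}
        ds = preprocess_pipeline(generate_dataset(
            SyntheticConfig(counts=counts, seed=21)))
        finals, firsts = [], []
        for seed in (0, 1, 2):
            model = _small_cnn(seed=seed)
            _, trace = train_model(model, ds, TrainingConfig(
                epochs=6, learning_rate=1e-3, seed=seed))
            firsts.append(trace[0])
            finals.append(trace[-1])
        assert np.median(finals) < np.median(firsts)

    def test_bit_reproducible_with_same_seed(self, tiny_preprocessed_dataset):
        results = []
        for _ in range(2):
            model = _small_cnn(seed=3)
            model, trace = train_model(model, tiny_preprocessed_dataset,
                                       TrainingConfig(epochs=2, seed=9))
            results.append((trace, {k: v.copy()
                                    for k, v in model.parameters.items()}))
        assert results[0][0] == results[1][0]
        for k in results[0][1]:
            np.testing.assert_array_equal(results[0][1][k], results[1][1][k])

    def test_hinge_loss_training_runs(self, tiny_preprocessed_dataset):
        model = _small_cnn()
        _, trace = train_model(model, tiny_preprocessed_dataset,
                               TrainingConfig(epochs=1, loss="hinge"))
        assert len(trace) == 1 and np.isfinite(trace[0])


class TestSchedule:
    def test_fine_tune_schedule_arithmetic(self):
        """254 images at batch 5 for 4000 epochs -> 254*4000/5 = 203,200
        full-batch-equivalent iterations; the actual loop keeps the short
        final batch of each epoch, so it runs ceil-based steps."""
        assert equivalent_iterations(254, 4000, 5) == 203_200
        assert scheduled_steps(254, 4000, 5) == 4000 * 51

    def test_short_final_batch_is_kept(self):
        assert scheduled_steps(7, 3, 5) == 6


class TestFineTune:
    def test_zero_epoch_finetune_reproduces_checkpoint(
            self, tmp_path, tiny_preprocessed_dataset):
        model = _small_cnn(seed=5)
        save_checkpoint(model, tmp_path / "ckpt.npz")
        x = tiny_preprocessed_dataset.pixel_stack().astype(np.float32)
        tuned, trace = fine_tune(tmp_path / "ckpt.npz",
                                 tiny_preprocessed_dataset,
                                 TrainingConfig(epochs=0),
                                 model=_small_cnn(seed=99))
        assert trace == []
        np.testing.assert_array_equal(tuned.forward(x), model.forward(x))

    def test_incompatible_checkpoint_rejected(self, tmp_path,
                                              tiny_preprocessed_dataset):
        save_checkpoint(_small_cnn(), tmp_path / "ckpt.npz")
        from wbcnet.models import build_wnet
        with pytest.raises(ValueError, match="incompatible"):
            fine_tune(tmp_path / "ckpt.npz", tiny_preprocessed_dataset,
                      TrainingConfig(epochs=0), model=build_wnet())


def test_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(learning_rate=0)
    with pytest.raises(ValueError):
        TrainingConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainingConfig(loss="l2")
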