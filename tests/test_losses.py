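import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readerbias import (
    LossConfig,
    cross_entropy,
    kl_divergence,
    make_augmented_pair,
    preprocess,
    psdr_loss,
    total_loss,
)
from readerbias.exceptions import ConfigurationError, ValidationError
from readerbias.losses import random_flips


class TestPreprocess:
    def test_mean_centering_identity(self):
        out = preprocess(np.full((16, 16), 0.5), 16)
        assert np.allclose(out, 0.0)

    def test_one_sd_above_mean(self):
        out = preprocess(np.full((16, 16), 0.7365), 16)
        assert np.allclose(out, 1.0, atol=1e-12)

    def test_resize_and_channel_replication(self):
        out = preprocess(np.random.default_rng(0).random((32, 32)), 224)
        assert out.shape == (3, 224, 224)
        assert np.array_equal(out[0], out[1]) and np.array_equal(out[1], out[2])

    def test_same_size_input_keeps_values(self):
        img = np.random.default_rng(1).random((32, 32))
        out = preprocess(img, 32)
        assert out.shape == (3, 32, 32)
        assert np.allclose(out[0], (img - 0.5) / 0.2365)

    def test_non_finite_rejected(self):
        img = np.full((8, 8), np.nan)
        with pytest.raises(ValidationError, match="non-finite"):
            preprocess(img, 8)


class TestAugmentation:
    def test_no_op_probabilities_identity(self):
        img = np.random.default_rng(0).random((3, 8, 8))
        cfg = LossConfig(horizontal_flip_p=0.0, vertical_flip_p=0.0)
        a, b = make_augmented_pair(img, cfg, np.random.default_rng(1))
        assert np.array_equal(a, img) and np.array_equal(b, img)

    def test_certain_flips_give_identical_rotated_views(self):
        img = np.random.default_rng(0).random((3, 8, 8))
        cfg = LossConfig(horizontal_flip_p=1.0, vertical_flip_p=1.0)
        a, b = make_augmented_pair(img, cfg, np.random.default_rng(1))
        rotated = img[:, ::-1, ::-1]
        assert np.array_equal(a, rotated) and np.array_equal(b, rotated)

    def test_orientation_frequencies(self):
        """Each of the 4 flip orientations appears ~25% of the time."""
        img = np.arange(4, dtype=float).reshape(1, 2, 2)
        cfg = LossConfig(horizontal_flip_p=0.5, vertical_flip_p=0.5)
        rng = np.random.default_rng(7)
        orientations = {
            tuple(img.ravel()): 0,
            tuple(img[:, :, ::-1].ravel()): 0,
            tuple(img[:, ::-1, :].ravel()): 0,
            tuple(img[:, ::-1, ::-1].ravel()): 0,
        }
        for _ in range(1000):
            a, _ = make_augmented_pair(img, cfg, rng)
            orientations[tuple(a.ravel())] += 1
        for count in orientations.values():
            assert abs(count / 1000 - 0.25) < 0.05

    def test_batch_flips_are_per_image(self):
        batch = np.random.default_rng(0).random((50, 1, 4, 4))
        cfg = LossConfig(horizontal_flip_p=0.5, vertical_flip_p=0.0)
        out = random_flips(batch, cfg, np.random.default_rng(2))
        flipped = [
            np.array_equal(out[i], batch[i][:, :, ::-1]) for i in range(50)
        ]
        same = [np.array_equal(out[i], batch[i]) for i in range(50)]
        assert any(flipped) and any(same)
        assert all(f or s for f, s in zip(flipped, same))


class TestKL:
    def test_identical_distributions(self):
        assert kl_divergence([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_closed_form_half_vs_quarter(self):
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(expected)

    def test_degenerate_p_clamped(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5], epsilon=1e-8) == pytest.approx(
            np.log(2), abs=1e-6
        )

    @pytest.mark.parametrize(
        "p, q", [([0.5, 0.6], [0.5, 0.5]), ([0.5, 0.5], [1.0]), ([-0.1, 1.1], [0.5, 0.5])]
    )
    def test_invalid_vectors_rejected(self, p, q):
        with pytest.raises(ValidationError):
            kl_divergence(p, q)

    @given(
        a=st.floats(min_value=1e-6, max_value=1 - 1e-6),
        b=st.floats(min_value=1e-6, max_value=1 - 1e-6),
    )
    @settings(deadline=None)
    def test_gibbs_inequality(self, a, b):
        p, q = np.array([a, 1 - a]), np.array([b, 1 - b])
        kl = kl_divergence(p, q)
        assert kl >= 0.0
        if abs(a - b) > 1e-9:
            assert kl > 0.0


class TestPSDRAndTotal:
    def test_invariant_model_zero(self):
        pairs = [(np.array([0.3, 0.7]), np.array([0.3, 0.7]))] * 5
        assert psdr_loss(pairs) == 0.0

    def test_single_pair_equals_kl(self):
        pairs = [(np.array([0.5, 0.5]), np.array([0.25, 0.75]))]
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert psdr_loss(pairs) == pytest.approx(expected)

    def test_mean_invariant_under_duplication(self):
        pairs = [
            (np.array([0.5, 0.5]), np.array([0.25, 0.75])),
            (np.array([0.9, 0.1]), np.array([0.8, 0.2])),
        ]
        assert psdr_loss(pairs) == pytest.approx(psdr_loss(pairs * 2))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValidationError):
            psdr_loss([])

    def test_alpha_zero_reduces_to_cross_entropy(self):
        logits = np.array([[2.0, -1.0], [0.5, 1.5]])
        labels = np.array([0, 1])
        assert total_loss(logits, labels, psdr_value=0.7, alpha=0.0) == pytest.approx(
            cross_entropy(logits, labels)
        )

    def test_arithmetic_combination(self):
        # logits giving exactly ln(2) cross-entropy: equal logits, any labels
        logits = np.zeros((4, 2))
        labels = np.array([0, 1, 0, 1])
        psdr = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        expected = np.log(2) + 2 * psdr
        assert total_loss(logits, labels, psdr, alpha=2.0) == pytest.approx(expected)

    def test_monotone_in_alpha(self):
        logits = np.array([[1.0, 0.0]])
        labels = np.array([0])
        losses = [total_loss(logits, labels, 0.3, a) for a in (0, 0.5, 1, 2)]
        assert losses == sorted(losses)

    def test_bad_labels_rejected(self):
        with pytest.raises(ValidationError):
            total_loss(np.zeros((1, 2)), np.array([2]), 0.0, 1.0)

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError):
            LossConfig(alpha=-1.0)
        with pytest.raises(ConfigurationError):
            LossConfig(horizontal_flip_p=1.5)
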