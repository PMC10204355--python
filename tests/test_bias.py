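import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readerbias import BiasSpec, error_report, inject_bias, n_flips
from readerbias.exceptions import ConfigurationError, ValidationError
from readerbias.synthetic import manifest_rows
from readerbias import DatasetSpec


def make_manifest(n0, n1):
    spec = DatasetSpec(n_train_per_class=max(n0, n1), n_val_per_class=1, n_test=(1, 1))
    m = manifest_rows(spec)
    keep0 = m[(m.split == "train") & (m.true_label == 0)].index[:n0]
    keep1 = m[(m.split == "train") & (m.true_label == 1)].index[:n1]
    other = m[m.split != "train"].index
    return m.loc[keep0.union(keep1).union(other)].reset_index(drop=True)


class TestNFlips:
    @pytest.mark.parametrize(
        "rate, n, expected",
        [
            (0.10, 500, 50),
            (0.0, 123, 0),
            (0.15, 7, 1),  # 1.05 rounds down
            (0.15, 10, 2),  # 1.5 rounds half up
            (1.0, 9, 9),
        ],
    )
    def test_round_half_up(self, rate, n, expected):
        assert n_flips(rate, n) == expected

    def test_rate_domain(self):
        with pytest.raises(ConfigurationError):
            n_flips(1.2, 10)

    @given(
        rate=st.floats(min_value=0, max_value=1, allow_nan=False),
        n=st.integers(min_value=0, max_value=10_000),
    )
    @settings(deadline=None)
    def test_bounds(self, rate, n):
        k = n_flips(rate, n)
        assert 0 <= k <= n


class TestInjectBias:
    def test_false_positive_table_mapping(self, balanced_labels):
        """Overall 5% on a balanced split = 10% of negatives, 0 positives."""
        out = inject_bias(
            balanced_labels, BiasSpec("false_positive", 0.05, seed=42)
        )
        report = error_report(out)
        assert report.loc["train", "fp_count"] == 50
        assert report.loc["train", "fn_count"] == 0
        assert report.loc["train", "fp_rate"] == pytest.approx(0.10)
        assert report.loc["train", "overall_error_rate"] == pytest.approx(0.05)

    def test_false_negative_at_max_level(self, balanced_labels):
        """Overall 25% flips half the positives."""
        out = inject_bias(
            balanced_labels, BiasSpec("false_negative", 0.25, seed=42)
        )
        report = error_report(out)
        assert report.loc["train", "fn_count"] == 250
        assert report.loc["train", "fn_rate"] == pytest.approx(0.50)
        assert report.loc["train", "fp_count"] == 0

    def test_random_error_mixture(self):
        """Random at 25% on 100/100 flips exactly 25 in each class."""
        m = make_manifest(100, 100)
        out = inject_bias(m, BiasSpec("random", 0.25, seed=0))
        report = error_report(out)
        assert report.loc["train", "fp_count"] == 25
        assert report.loc["train", "fn_count"] == 25
        assert report.loc["train", "overall_error_rate"] == pytest.approx(0.25)

    def test_zero_level_is_identity(self, balanced_labels):
        out = inject_bias(balanced_labels, BiasSpec("random", 0.0, seed=1))
        assert (out["biased_label"] == out["true_label"]).all()
        assert (error_report(out) == 0).all(axis=None)

    def test_untargeted_splits_copied_clean(self, balanced_labels):
        out = inject_bias(
            balanced_labels,
            BiasSpec("random", 0.2, seed=1, apply_to_splits=("train",)),
        )
        for split in ("val", "test"):
            rows = out[out["split"] == split]
            assert (rows["biased_label"] == rows["true_label"]).all()

    def test_conservation_and_true_labels_untouched(self, balanced_labels):
        out = inject_bias(balanced_labels, BiasSpec("random", 0.15, seed=5))
        pd.testing.assert_frame_equal(
            out.drop(columns="biased_label"),
            balanced_labels.drop(columns="biased_label"),
        )

    def test_determinism_and_idempotence(self, balanced_labels):
        spec = BiasSpec("false_negative", 0.10, seed=9)
        once = inject_bias(balanced_labels, spec)
        again = inject_bias(balanced_labels, spec)
        pd.testing.assert_frame_equal(once, again)
        # re-injecting into an already-biased manifest never compounds
        twice = inject_bias(once, spec)
        pd.testing.assert_frame_equal(once, twice)

    @given(
        bias_type=st.sampled_from(["random", "false_positive", "false_negative"]),
        level=st.sampled_from([0.05, 0.10, 0.15, 0.20, 0.25]),
        n0=st.integers(min_value=4, max_value=60),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(deadline=None, max_examples=25)
    def test_exact_flip_counts_property(self, bias_type, level, n0, seed):
        """Realized per-class flips equal n_flips exactly, never in expectation;
        on a balanced split every bias type realizes the overall level."""
        m = make_manifest(n0, n0)
        out = inject_bias(m, BiasSpec(bias_type, level, seed=seed))
        report = error_report(out)
        if bias_type == "random":
            expected_fp = expected_fn = n_flips(level, n0)
        elif bias_type == "false_positive":
            expected_fp, expected_fn = n_flips(2 * level, n0), 0
        else:
            expected_fp, expected_fn = 0, n_flips(2 * level, n0)
        assert report.loc["train", "fp_count"] == expected_fp
        assert report.loc["train", "fn_count"] == expected_fn

    def test_invalid_specs(self):
        with pytest.raises(ConfigurationError):
            BiasSpec("typo", 0.1)
        with pytest.raises(ConfigurationError):
            BiasSpec("random", 0.5)
        with pytest.raises(ConfigurationError):
            BiasSpec("random", 0.1, apply_to_splits=("test",))


class TestErrorReport:
    def test_requires_biased_label(self, balanced_labels):
        with pytest.raises(ValidationError, match="biased_label"):
            error_report(balanced_labels)

    def test_random_recount(self):
        m = make_manifest(200, 200)
        out = inject_bias(m, BiasSpec("random", 0.15, seed=3))
        report = error_report(out)
        assert report.loc["train", "fp_count"] == 30
        assert report.loc["train", "fn_count"] == 30
        assert report.loc["train", "overall_error_rate"] == pytest.approx(0.15)
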