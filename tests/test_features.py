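"""Time-domain features against brute-force oracles, and normalization."""

import math

import numpy as np
import pytest

from eegemotion import ValidationError, differential_entropy, extract_all, normalize_trial
from eegemotion.features import (
    DE_FLOOR,
    FEATURE_NAMES,
    SegmentFeatures,
    mean,
    mean_first_diff,
    mean_second_diff,
    std,
    variance,
)

DE_UNIT_VARIANCE = 0.5 * math.log(2 * math.pi * math.e)  # ~1.41894


# -- independent brute-force oracles (plain loops, no numpy reductions) -----

def _oracle_features(x):
    n = len(x)
    mu = sum(x) / n
    d1 = sum(x[i + 1] - x[i] for i in range(n - 1)) / (n - 1)
    d2 = sum(x[i + 2] - x[i] for i in range(n - 2)) / (n - 2)
    var = sum((v - mu) ** 2 for v in x) / n
    de = 0.5 * math.log(2 * math.pi * math.e * var)
    return {"de": de, "mean": mu, "mean_d1": d1, "mean_d2": d2,
            "std": math.sqrt(var), "var": var}


class TestClosedForms:
    def test_de_unit_variance(self):
        assert differential_entropy([1, -1, 1, -1]) == pytest.approx(DE_UNIT_VARIANCE, abs=1e-12)

    def test_de_scaling_adds_log_c(self, rng):
        x = rng.normal(size=500)
        c = 3.7
        assert differential_entropy(c * x) - differential_entropy(x) == pytest.approx(
            math.log(c), abs=1e-9
        )

    def test_de_monte_carlo_consistency(self):
        x = np.random.default_rng(42).standard_normal(100_000)
        assert differential_entropy(x) == pytest.approx(DE_UNIT_VARIANCE, abs=0.01)

    def test_de_histogram_estimator_close_to_gaussian_form(self):
        x = np.random.default_rng(7).standard_normal(100_000)
        h = differential_entropy(x, method="histogram", bins=128)
        assert h == pytest.approx(DE_UNIT_VARIANCE, abs=0.05)

    def test_simple_sequences(self):
        assert mean([1, 3, 6]) == pytest.approx(10 / 3)
        assert mean_first_diff([1, 3, 6]) == pytest.approx(2.5)  # telescopes to (6-1)/2
        assert mean_second_diff([1, 3, 6, 10]) == pytest.approx(6.0)
        assert variance([2, 2, 2]) == 0.0
        assert std([2, 2, 2]) == 0.0

    def test_constant_segment_de_floored_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert differential_entropy([3.0, 3.0, 3.0, 3.0]) == DE_FLOOR

    def test_short_segments_rejected(self):
        with pytest.raises(ValidationError):
            mean([1.0, 2.0])
        with pytest.raises(ValidationError):
            differential_entropy([1.0])


class TestOracleEquivalence:
    def test_hundred_random_segments_match_loop_oracle(self, rng):
        """Each vectorized feature equals the loop oracle to 1e-12 relative."""
        segments = rng.normal(size=(100, 64)) * rng.uniform(0.1, 50, size=(100, 1))
        feats = extract_all({"raw": segments[:, None, :]})
        for i, f in enumerate(feats):
            expected = _oracle_features(list(segments[i]))
            for j, name in enumerate(FEATURE_NAMES):
                got = f.values[0, 0, j]
                assert got == pytest.approx(expected[name], rel=1e-12, abs=1e-12), name


class TestInvariances:
    def test_shift_invariance(self, rng):
        x = rng.normal(size=256)
        shifted = x + 11.0
        assert mean(shifted) == pytest.approx(mean(x) + 11.0, rel=1e-9)
        for fn in (mean_first_diff, mean_second_diff, std, variance, differential_entropy):
            assert fn(shifted) == pytest.approx(fn(x), rel=1e-6, abs=1e-9)

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=256)
        c = 2.5
        assert std(c * x) == pytest.approx(c * std(x), rel=1e-9)
        assert variance(c * x) == pytest.approx(c * c * variance(x), rel=1e-9)


class TestExtractAll:
    def test_cardinality_four_bands(self, rng):
        bands = {b: rng.normal(size=(10, 32, 96)) for b in ("theta", "alpha", "beta", "gamma")}
        feats = extract_all(bands, subject_id=1, trial_id=2, label=1)
        assert len(feats) == 10
        assert all(f.values.shape == (32, 4, 6) for f in feats)
        total = sum(f.values.size for f in feats)
        assert total == 10 * 32 * 4 * 6

    def test_cardinality_raw(self, rng):
        feats = extract_all({"raw": rng.normal(size=(10, 32, 96))})
        assert all(f.values.shape == (32, 1, 6) for f in feats)

    def test_deterministic(self, rng):
        bands = {"alpha": rng.normal(size=(3, 4, 64))}
        a = extract_all(bands)
        b = extract_all(bands)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.values, fb.values)

    def test_mismatched_band_shapes_rejected(self, rng):
        with pytest.raises(ValidationError):
            extract_all({"a": rng.normal(size=(3, 4, 64)), "b": rng.normal(size=(3, 4, 32))})


def _features_from(values, n_seg=3):
    """Wrap an array (n_seg, C, B, F) as SegmentFeatures list."""
    return [
        SegmentFeatures(
            values=values[i],
            band_names=tuple(f"b{j}" for j in range(values.shape[2])),
            feature_names=tuple(f"f{j}" for j in range(values.shape[3])),
            subject_id=1, trial_id=1, segment_index=i,
        )
        for i in range(n_seg)
    ]


class TestNormalization:
    def test_min_max_forced_values(self):
        vals = np.zeros((3, 1, 1, 1))
        vals[:, 0, 0, 0] = [2.0, 4.0, 6.0]
        out = normalize_trial(_features_from(vals))
        got = [f.values[0, 0, 0] for f in out]
        assert got == [0.0, 0.5, 1.0]

    def test_constant_group_zeroed_with_warning(self):
        vals = np.full((3, 2, 1, 1), 3.0)
        with pytest.warns(RuntimeWarning):
            out = normalize_trial(_features_from(vals))
        assert all((f.values == 0.0).all() for f in out)

    def test_output_bounds_and_extremes(self, rng):
        vals = rng.normal(size=(4, 8, 2, 6)) * 100
        out = normalize_trial(_features_from(vals, n_seg=4))
        stack = np.stack([f.values for f in out])
        assert stack.min() == 0.0 and stack.max() == 1.0
        # each (band, feature) group spans exactly [0, 1]
        assert np.allclose(stack.min(axis=(0, 1)), 0.0)
        assert np.allclose(stack.max(axis=(0, 1)), 1.0)

    def test_idempotent(self, rng):
        vals = rng.normal(size=(3, 4, 2, 6))
        once = normalize_trial(_features_from(vals))
        twice = normalize_trial(once)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.values, b.values, atol=1e-15)

    def test_mixed_trials_rejected(self, rng):
        feats = _features_from(rng.normal(size=(2, 2, 1, 1)), n_seg=2)
        feats[1].trial_id = 9
        with pytest.raises(ValidationError):
            normalize_trial(feats)

    def test_per_trial_grouping_single_scale(self, rng):
        vals = rng.normal(size=(3, 4, 2, 6))
        out = normalize_trial(_features_from(vals), grouping="per_trial")
        stack = np.stack([f.values for f in out])
        assert stack.min() == 0.0 and stack.max() == 1.0
        # one global group: only one cell attains 0 and one attains 1
        assert (stack == 0.0).sum() == 1 and (stack == 1.0).sum() == 1
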