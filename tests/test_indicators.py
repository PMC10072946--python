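"""Unit tests for indicator extraction and preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latticeews.indicators import (
    CHANNEL_NAMES,
    CoarseGrainSpec,
    RunTooShortError,
    WindowSpec,
    coarse_grain,
    featurize_dataset,
    featurize_run,
    gaussian_detrend,
    spatial_autocorrelation,
    spatial_moments,
    subset_channels,
    temporal_indicators,
    truncate_pad_normalize,
)
from latticeews.systems import FieldRun


def _field_run(rng, n_steps=260, side=40, label="transition", idx=200, seed=3):
    field = rng.normal(size=(n_steps, side, side)).astype(np.float32)
    return FieldRun(
        field=field,
        mask=np.ones((side, side), dtype=bool),
        forcing=np.linspace(0, 1, n_steps),
        label=label,
        system="synthetic",
        transition_index=idx if label == "transition" else None,
        seed=seed,
    )


class TestCoarseGrain:
    def test_uniform_field_is_preserved(self):
        field = np.ones((3, 36, 36))
        out = coarse_grain(field, None, CoarseGrainSpec(spatial_factor=4))
        assert out.shape == (3, 9, 9)
        assert np.allclose(out, 1.0)

    def test_checkerboard_cancels_under_even_factor(self):
        side = 36
        cb = (-1.0) ** np.add.outer(np.arange(side), np.arange(side))
        out = coarse_grain(cb[None], None, CoarseGrainSpec(spatial_factor=4))
        assert np.allclose(out, 0.0)

    def test_matches_explicit_loop_oracle(self, rng):
        field = rng.normal(size=(2, 90, 90))
        out = coarse_grain(field, None, CoarseGrainSpec(spatial_factor=10),
                           periodic=False)
        expected = np.empty((2, 9, 9))
        for t in range(2):
            for a in range(9):
                for b in range(9):
                    expected[t, a, b] = field[
                        t, 10 * a : 10 * (a + 1), 10 * b : 10 * (b + 1)
                    ].mean()
        assert np.allclose(out, expected, atol=1e-12)

    def test_masked_blocks_use_live_sites_and_impute_missing(self, rng):
        field = rng.normal(size=(1, 18, 18))
        mask = np.ones((18, 18), dtype=bool)
        mask[0, 0] = False          # partially masked block
        mask[2:4, 2:4] = False      # fully masked block (factor 2)
        out = coarse_grain(field, mask, CoarseGrainSpec(spatial_factor=2),
                           periodic=False)
        blk = field[0, :2, :2][mask[:2, :2]]
        assert out[0, 0, 0] == pytest.approx(blk.mean())
        valid = np.ones((9, 9), dtype=bool)
        valid[1, 1] = False
        assert out[0, 1, 1] == pytest.approx(out[0][valid].mean())

    def test_temporal_factor_averages_snapshots(self, rng):
        field = rng.normal(size=(6, 18, 18))
        out = coarse_grain(field, None,
                           CoarseGrainSpec(spatial_factor=2, temporal_factor=3),
                           periodic=False)
        direct = coarse_grain(field, None, CoarseGrainSpec(spatial_factor=2),
                              periodic=False)
        assert out.shape[0] == 2
        assert np.allclose(out[0], direct[:3].mean(axis=0))

    def test_nonperiodic_overflow_raises(self):
        with pytest.raises(ValueError):
            coarse_grain(np.ones((1, 36, 36)), None,
                         CoarseGrainSpec(spatial_factor=5), periodic=False)


class TestSpatialMoments:
    def test_constant_frame_degenerate_convention(self):
        assert spatial_moments(np.full((9, 9), 2.5)) == (0.0, 0.0, 0.0)

    def test_half_half_binary_frame(self):
        frame = np.ones(100); frame[:50] = -1
        var, skew, kurt = spatial_moments(frame.reshape(10, 10))
        assert (var, skew, kurt) == pytest.approx((1.0, 0.0, 1.0))

    def test_symmetric_frame_has_zero_skew(self, rng):
        half = rng.normal(size=50)
        frame = np.concatenate([half, -half]).reshape(10, 10)
        _, skew, _ = spatial_moments(frame)
        assert skew == pytest.approx(0.0, abs=1e-12)


class TestSpatialAutocorrelation:
    def test_checkerboard_alternation(self):
        cb = (-1.0) ** np.add.outer(np.arange(9), np.arange(9))
        assert spatial_autocorrelation(cb, 1) == pytest.approx(-1.0)
        assert spatial_autocorrelation(cb, 2) == pytest.approx(1.0)

    def test_linear_gradient_fully_correlated(self):
        grad = np.tile(np.arange(9.0), (9, 1))
        assert spatial_autocorrelation(grad, 1) == pytest.approx(1.0)

    def test_iid_noise_uncorrelated_on_average(self, rng):
        frames = rng.normal(size=(3000, 9, 9))
        assert abs(spatial_autocorrelation(frames, 1).mean()) < 0.02

    def test_lag_bounds(self):
        with pytest.raises(ValueError):
            spatial_autocorrelation(np.ones((9, 9)), 9)


class TestGaussianDetrend:
    def test_constant_series_zero_residual(self):
        assert np.allclose(gaussian_detrend(np.full(50, 3.3), 5.0), 0.0, atol=1e-12)

    def test_huge_bandwidth_removes_only_the_mean(self, rng):
        x = rng.normal(size=200)
        resid = gaussian_detrend(x, bandwidth=1e5)
        assert np.allclose(resid, x - x.mean(), atol=1e-6)

    def test_fast_oscillation_survives_wide_kernel(self):
        t = np.arange(400)
        sine = np.sin(2 * np.pi * t / 20)
        resid = gaussian_detrend(sine + 0.5, bandwidth=40.0)
        assert np.corrcoef(resid, sine)[0, 1] > 0.99


class TestTemporalIndicators:
    def test_matches_sliding_window_oracle(self, rng):
        x = rng.normal(size=(90, 7))
        w = 25
        out = temporal_indicators(x, w)
        assert np.isnan(out[: w - 1]).all()
        for t in (w - 1, 47, 89):
            win = x[t - w + 1 : t + 1]
            mu = win.mean(0)
            d = win - mu
            m2 = (d**2).mean(0)
            expected = [
                m2.mean(),
                ((d**3).mean(0) / m2**1.5).mean(),
                ((d**4).mean(0) / m2**2).mean(),
            ]
            for k in (1, 2, 3):
                rs = [np.corrcoef(win[k:, c], win[:-k, c])[0, 1] for c in range(7)]
                expected.append(np.mean(rs))
            assert np.allclose(out[t], expected, atol=1e-9)

    def test_ar1_cells_recover_coefficient(self, rng):
        phi, T, n = 0.8, 500, 81
        x = np.zeros((T, n))
        for t in range(1, T):
            x[t] = phi * x[t - 1] + rng.normal(size=n) * np.sqrt(1 - phi**2)
        out = temporal_indicators(x, 250)
        assert abs(out[-1, 3] - phi) < 0.05

    def test_identical_cells_average_is_identity(self, rng):
        x = rng.normal(size=(60, 1))
        tiled = np.tile(x, (1, 81))
        assert np.allclose(
            temporal_indicators(x, 20)[19:], temporal_indicators(tiled, 20)[19:]
        )

    def test_white_noise_autocorrelation_near_zero(self, rng):
        x = rng.normal(size=(400, 81))
        out = temporal_indicators(x, 200)
        assert abs(out[-1, 3]) < 0.03


class TestTruncatePadNormalize:
    def test_padding_arithmetic_and_normalization(self, rng):
        series = rng.normal(size=(250, 12))
        values, pad = truncate_pad_normalize(series, 100)
        assert values.shape == (600, 12)
        assert pad == 500
        assert np.all(values[:pad] == 0.0)
        tail = values[pad:]
        assert np.allclose(tail.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(tail.std(axis=0), 1.0, atol=1e-10)

    def test_constant_channel_zeroed(self):
        series = np.ones((150, 2))
        values, _ = truncate_pad_normalize(series, 120)
        assert np.all(values == 0.0)

    def test_too_short_raises(self):
        with pytest.raises(RunTooShortError):
            truncate_pad_normalize(np.zeros((50, 12)), 100)

    @given(st.integers(100, 600), st.integers(100, 500))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_retained_length_never_exceeds_available(self, target, avail):
        series = np.random.default_rng(1).normal(size=(avail, 3))
        values, pad = truncate_pad_normalize(series, target)
        assert 600 - pad == min(target, avail)


class TestFeaturizeRun:
    def test_no_lookahead(self, rng):
        """Indicators depend only on data up to the truncation point."""
        run = _field_run(rng)
        full = featurize_run(run, lead=20, dataset_seed=11)
        cut = run.transition_index - 20
        chopped = FieldRun(
            field=run.field[:cut].copy(),
            mask=run.mask,
            forcing=run.forcing[:cut],
            label=run.label,
            system=run.system,
            transition_index=run.transition_index,
            seed=run.seed,
        )
        again = featurize_run(chopped, lead=20, dataset_seed=11)
        assert np.array_equal(full.values, again.values)
        assert full.pad_length == again.pad_length

    def test_channel_subsets_are_column_selections(self, rng):
        run = _field_run(rng)
        s = featurize_run(run, lead=0, dataset_seed=1)
        X = s.values[None]
        assert np.array_equal(subset_channels(X, "spatial"), X[..., :6])
        assert np.array_equal(subset_channels(X, "temporal"), X[..., 6:])
        assert subset_channels(X, "full") is X

    def test_lead_zero_ends_at_transition(self, rng):
        run = _field_run(rng)
        s = featurize_run(run, lead=0, dataset_seed=1)
        assert s.meta["raw_end"] == run.transition_index

    def test_deterministic_given_seeds(self, rng):
        run = _field_run(rng)
        a = featurize_run(run, lead=10, dataset_seed=4)
        b = featurize_run(run, lead=10, dataset_seed=4)
        assert np.array_equal(a.values, b.values)


class TestFeaturizeDataset:
    def test_null_lengths_drawn_from_transition_distribution(self, rng):
        runs = [_field_run(rng, label="transition", idx=210, seed=i) for i in range(6)]
        runs += [
            _field_run(rng, n_steps=900, label="null", seed=100 + i) for i in range(6)
        ]
        fs = featurize_dataset(runs, lead=0, seed=9)
        trans_lengths = set(fs.lengths[fs.y == 1].tolist())
        assert set(fs.lengths[fs.y == 0.].tolist()) <= trans_lengths
        assert fs.X.shape == (12, 600, 12)
        assert tuple(fs.channel_names) == CHANNEL_NAMES

    def test_window_spec_validation(self):
        with pytest.raises(ValueError):
            WindowSpec(window_fraction=0.0)
        with pytest.raises(ValueError):
            WindowSpec(detrend_bandwidth=-1.0)
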