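"""Critical-slowing-down indicator extraction.

Converts a raw lattice run into a 12-channel indicator time series: variance,
skewness, kurtosis and lag-1/2/3 autocorrelation computed in the spatial
domain (per snapshot, over the 9x9 coarse-grained observation grid) and in
the temporal domain (per grid cell over a trailing sliding window of
Gaussian-detrended residuals, then averaged over cells).

Preprocessing follows the early-warning-signal training recipe: the raw run
is truncated a fixed lead time before the transition *first*, so nothing
downstream (detrending included) can leak post-transition information; the
retained length is randomized, left-padded with zeros to a fixed 600 steps,
and each channel is normalized to zero mean / unit variance over the
unpadded span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "CHANNEL_NAMES",
    "SPATIAL_CHANNELS",
    "TEMPORAL_CHANNELS",
    "CoarseGrainSpec",
    "WindowSpec",
    "IndicatorSeries",
    "FeatureSet",
    "RunTooShortError",
    "coarse_grain",
    "spatial_moments",
    "spatial_autocorrelation",
    "gaussian_detrend",
    "temporal_indicators",
    "truncate_pad_normalize",
    "featurize_coarse_field",
    "featurize_run",
    "featurize_dataset",
    "subset_channels",
]

CHANNEL_NAMES: tuple[str, ...] = (
    "spatial_variance",
    "spatial_skewness",
    "spatial_kurtosis",
    "spatial_ac1",
    "spatial_ac2",
    "spatial_ac3",
    "temporal_variance",
    "temporal_skewness",
    "temporal_kurtosis",
    "temporal_ac1",
    "temporal_ac2",
    "temporal_ac3",
)
SPATIAL_CHANNELS = tuple(range(0, 6))
TEMPORAL_CHANNELS = tuple(range(6, 12))

_DEGENERATE_VAR = 1e-12


class RunTooShortError(ValueError):
    """Raised when a run cannot yield the minimum retained indicator length."""


@dataclass(frozen=True)
class CoarseGrainSpec:
    """Block-averaging of the source lattice onto the 9x9 observation grid.

    A subregion of side ``9 * spatial_factor`` anchored at
    ``subregion_origin`` is block-averaged (over live sites only) to 9x9;
    ``temporal_factor`` consecutive snapshots are averaged together.  For
    periodic lattices the subregion may wrap around the boundary.
    """

    spatial_factor: int
    temporal_factor: int = 1
    subregion_origin: tuple[int, int] = (0, 0)
    target_grid: int = 9

    def __post_init__(self) -> None:
        if self.spatial_factor < 1:
            raise ValueError("spatial_factor must be >= 1")
        if self.temporal_factor < 1:
            raise ValueError("temporal_factor must be >= 1")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window and detrending parameters for the temporal indicators.

    ``window_fraction`` is the trailing-window width as a fraction of the
    truncated series length (at least 10 samples); ``detrend_bandwidth`` is
    the Gaussian smoothing sigma as a fraction of the series length.
    """

    window_fraction: float = 0.25
    detrend_bandwidth: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.window_fraction <= 1.0:
            raise ValueError("window_fraction must be in (0, 1]")
        if self.detrend_bandwidth <= 0:
            raise ValueError("detrend_bandwidth must be > 0")

    def window_length(self, n_steps: int) -> int:
        return min(n_steps, max(10, int(round(self.window_fraction * n_steps))))


@dataclass
class IndicatorSeries:
    """Fixed-length, normalized 12-channel indicator series for one run."""

    values: np.ndarray  # (total_len, 12) float
    pad_length: int
    label: Literal["transition", "null"]
    order: str
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.values.shape[0] - self.pad_length


@dataclass
class FeatureSet:
    """A featurized dataset: stacked indicator series plus labels."""

    X: np.ndarray        # (n_runs, total_len, 12)
    y: np.ndarray        # (n_runs,) int, 1 = transition
    orders: np.ndarray   # (n_runs,) unicode
    lengths: np.ndarray  # (n_runs,) unpadded lengths
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.X.shape[0]


def coarse_grain(
    field_: np.ndarray,
    mask: Optional[np.ndarray],
    spec: CoarseGrainSpec,
    *,
    periodic: bool = True,
) -> np.ndarray:
    """Block-average a (T, L, L) field to (T', g, g) over live sites.

    Cells whose block contains no live site are imputed with the frame mean
    of the valid cells (the observation grid shape must stay fixed for the
    classifier).  With ``periodic=False`` the subregion must fit inside the
    lattice.
    """
    field_ = np.asarray(field_)
    T, L = field_.shape[0], field_.shape[1]
    g, f = spec.target_grid, spec.spatial_factor
    side = g * f
    i0, j0 = spec.subregion_origin
    if periodic:
        rows = (i0 + np.arange(side)) % L
        cols = (j0 + np.arange(side)) % L
    else:
        if i0 < 0 or j0 < 0 or i0 + side > L or j0 + side > field_.shape[2]:
            raise ValueError(
                f"subregion of side {side} at origin {(i0, j0)} does not fit "
                f"a non-periodic {L}x{field_.shape[2]} lattice"
            )
        rows = i0 + np.arange(side)
        cols = j0 + np.arange(side)

    sub = field_[:, rows][:, :, cols].astype(np.float64)
    if mask is None:
        msub = np.ones((side, side), dtype=bool)
    else:
        msub = mask[rows][:, cols]
    counts = msub.reshape(g, f, g, f).sum(axis=(1, 3))
    sums = (sub * msub).reshape(T, g, f, g, f).sum(axis=(2, 4))
    valid = counts > 0
    cells = np.zeros((T, g, g))
    np.divide(sums, counts, out=cells, where=valid)
    if not valid.all():
        frame_mean = cells[:, valid].mean(axis=1)
        cells[:, ~valid] = frame_mean[:, None]

    tf = spec.temporal_factor
    if tf > 1:
        T2 = T // tf
        cells = cells[: T2 * tf].reshape(T2, tf, g, g).mean(axis=1)
    return cells


def _standardized_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population variance, skewness, non-excess kurtosis along the last axis.

    Degenerate samples (zero variance) yield 0 for all three by convention so
    no NaN ever reaches the classifier.
    """
    mu = x.mean(axis=-1, keepdims=True)
    d = x - mu
    m2 = (d**2).mean(axis=-1)
    m3 = (d**3).mean(axis=-1)
    m4 = (d**4).mean(axis=-1)
    ok = m2 > _DEGENERATE_VAR
    skew = np.zeros_like(m2)
    kurt = np.zeros_like(m2)
    np.divide(m3, m2**1.5, out=skew, where=ok)
    np.divide(m4, m2**2, out=kurt, where=ok)
    var = np.where(ok, m2, 0.0)
    return var, skew, kurt


def spatial_moments(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Variance, skewness and (non-excess) kurtosis over the cells of each frame.

    Accepts a single (g, g) frame or a stack (T, g, g); returns scalars or
    length-T arrays accordingly.
    """
    frames = np.asarray(frames, dtype=np.float64)
    single = frames.ndim == 2
    flat = frames.reshape(1, -1) if single else frames.reshape(frames.shape[0], -1)
    var, skew, kurt = _standardized_moments(flat)
    if single:
        return float(var[0]), float(skew[0]), float(kurt[0])
    return var, skew, kurt


def _pearson_flat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Population Pearson correlation along the last axis; degenerate -> 0."""
    am = a - a.mean(axis=-1, keepdims=True)
    bm = b - b.mean(axis=-1, keepdims=True)
    cov = (am * bm).mean(axis=-1)
    va = (am**2).mean(axis=-1)
    vb = (bm**2).mean(axis=-1)
    denom = np.sqrt(va * vb)
    out = np.zeros_like(cov)
    ok = denom > _DEGENERATE_VAR
    np.divide(cov, denom, out=out, where=ok)
    return out


def spatial_autocorrelation(frames: np.ndarray, lag: int) -> np.ndarray | float:
    """Axis-shift Pearson autocorrelation of each frame at the given lag.

    The correlation between the frame and its copy shifted by ``lag`` cells
    is computed over the cropped (non-periodic) overlap along each of the two
    axes, then the two axis values are averaged.
    """
    frames = np.asarray(frames, dtype=np.float64)
    single = frames.ndim == 2
    if single:
        frames = frames[None]
    if not 1 <= lag < frames.shape[-1]:
        raise ValueError(f"lag must be in [1, {frames.shape[-1] - 1}], got {lag}")
    T = frames.shape[0]
    r_col = _pearson_flat(
        frames[:, :, :-lag].reshape(T, -1), frames[:, :, lag:].reshape(T, -1)
    )
    r_row = _pearson_flat(
        frames[:, :-lag, :].reshape(T, -1), frames[:, lag:, :].reshape(T, -1)
    )
    out = 0.5 * (r_col + r_row)
    return float(out[0]) if single else out


def gaussian_detrend(series: np.ndarray, bandwidth: float) -> np.ndarray:
    """Residuals after removing a Gaussian-kernel moving average.

    ``bandwidth`` is the kernel sigma in samples.  The kernel is truncated at
    the series edges with its weights renormalized, so the trend estimate is
    unbiased at the boundaries of a constant series.  Works along axis 0 for
    2-d input (series per column).
    """
    series = np.asarray(series, dtype=np.float64)
    if series.shape[0] < 5:
        raise ValueError("series must have length >= 5")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    weights = gaussian_filter1d(
        np.ones(series.shape[0]), bandwidth, mode="constant"
    )
    smooth = gaussian_filter1d(series, bandwidth, axis=0, mode="constant")
    if series.ndim == 2:
        weights = weights[:, None]
    return series - smooth / weights


def _rolling_window_sums(c: np.ndarray, w: int) -> np.ndarray:
    """Sums over trailing windows of width w, for windows ending at w-1..T-1.

    ``c`` is a zero-padded cumulative sum of shape (T + 1, ...).
    """
    return c[w:] - c[:-w]


def temporal_indicators(
    cells: np.ndarray,
    window_length: int,
    *,
    lags: Sequence[int] = (1, 2, 3),
) -> np.ndarray:
    """Trailing-window temporal statistics, averaged over grid cells.

    ``cells`` is (T, n_cells) of detrended residuals.  For each cell and each
    time t >= window_length - 1, variance, skewness, kurtosis and the lag-k
    autocorrelations of the window ``[t - w + 1, t]`` are computed; rows are
    then averaged over cells.  Rows with incomplete windows (t < w - 1) are
    returned as NaN and must be treated as padding by the caller.

    Windows are strictly trailing (causal): the value at time t uses no data
    after t.
    """
    x = np.asarray(cells, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("cells must be 2-d (time, n_cells)")
    T, n_cells = x.shape
    w = int(window_length)
    if w < max(lags) + 2:
        raise ValueError(f"window_length must be >= {max(lags) + 2}")
    if T < w:
        raise ValueError("series shorter than the window")

    out = np.full((T, 3 + len(lags)), np.nan)
    zeros = np.zeros((1, n_cells))
    c1 = np.concatenate([zeros, np.cumsum(x, axis=0)])
    c2 = np.concatenate([zeros, np.cumsum(x**2, axis=0)])
    c3 = np.concatenate([zeros, np.cumsum(x**3, axis=0)])
    c4 = np.concatenate([zeros, np.cumsum(x**4, axis=0)])

    s1 = _rolling_window_sums(c1, w)
    s2 = _rolling_window_sums(c2, w)
    s3 = _rolling_window_sums(c3, w)
    s4 = _rolling_window_sums(c4, w)
    mu = s1 / w
    m2 = s2 / w - mu**2
    m3 = s3 / w - 3 * mu * s2 / w + 2 * mu**3
    m4 = s4 / w - 4 * mu * s3 / w + 6 * mu**2 * s2 / w - 3 * mu**4
    ok = m2 > _DEGENERATE_VAR
    skew = np.zeros_like(m2)
    kurt = np.zeros_like(m2)
    np.divide(m3, m2**1.5, out=skew, where=ok)
    np.divide(m4, m2**2, out=kurt, where=ok)
    var = np.where(ok, m2, 0.0)
    out[w - 1 :, 0] = var.mean(axis=1)
    out[w - 1 :, 1] = skew.mean(axis=1)
    out[w - 1 :, 2] = kurt.mean(axis=1)

    for col, k in enumerate(lags, start=3):
        n = w - k
        # products x[i] * x[i-k]; zero-filled for i < k (never inside a window)
        prod = np.zeros_like(x)
        prod[k:] = x[k:] * x[:-k]
        cp = np.concatenate([zeros, np.cumsum(prod, axis=0)])
        # windows end at t = w-1 .. T-1
        s_ab = cp[w:] - cp[k : T - w + k + 1]
        s_a = c1[w:] - c1[k : T - w + k + 1]
        s_b = c1[w - k : T - k + 1] - c1[: T - w + 1]
        s_a2 = c2[w:] - c2[k : T - w + k + 1]
        s_b2 = c2[w - k : T - k + 1] - c2[: T - w + 1]
        cov = s_ab - s_a * s_b / n
        va = s_a2 - s_a**2 / n
        vb = s_b2 - s_b**2 / n
        denom = np.sqrt(np.clip(va * vb, 0.0, None))
        r = np.zeros_like(cov)
        okr = denom > _DEGENERATE_VAR
        np.divide(cov, denom, out=r, where=okr)
        out[w - 1 :, col] = r.mean(axis=1)
    return out


def truncate_pad_normalize(
    series: np.ndarray,
    target_length: int,
    *,
    total_length: int = 600,
    min_length: int = 100,
) -> tuple[np.ndarray, int]:
    """Keep the trailing ``target_length`` rows, normalize, left-pad with zeros.

    Each channel is normalized to zero mean and unit (population) variance
    over the retained span *before* padding; channels that are constant over
    the span are set to zero.  Returns ``(values, pad_length)`` with values
    of shape ``(total_length, n_channels)``.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.shape[0] < min_length:
        raise RunTooShortError(
            f"only {series.shape[0]} valid indicator steps; need >= {min_length}"
        )
    keep = min(int(target_length), series.shape[0], total_length)
    tail = series[series.shape[0] - keep :]
    mu = tail.mean(axis=0)
    sd = tail.std(axis=0)
    normed = np.where(sd > _DEGENERATE_VAR, (tail - mu) / np.where(sd == 0, 1, sd), 0.0)
    out = np.zeros((total_length, series.shape[1]))
    out[total_length - keep :] = normed
    return out, total_length - keep


def featurize_coarse_field(
    coarse: np.ndarray,
    *,
    window_spec: WindowSpec = WindowSpec(),
    target_length: Optional[int] = None,
    total_length: int = 600,
    min_length: int = 100,
) -> tuple[np.ndarray, int]:
    """Indicator series for an already-coarse (T, g, g) observation field.

    Computes the 6 spatial per-frame indicators and the 6 trailing-window
    temporal indicators on Gaussian-detrended cell residuals, drops the
    window warm-up rows, then truncates/normalizes/pads.  Returns
    ``(values, pad_length)``.
    """
    coarse = np.asarray(coarse, dtype=np.float64)
    T = coarse.shape[0]
    w = window_spec.window_length(T)
    var, skew, kurt = spatial_moments(coarse)
    spatial = np.stack(
        [var, skew, kurt] + [spatial_autocorrelation(coarse, k) for k in (1, 2, 3)],
        axis=1,
    )
    cells = coarse.reshape(T, -1)
    resid = gaussian_detrend(cells, bandwidth=window_spec.detrend_bandwidth * T)
    temporal = temporal_indicators(resid, w)
    raw = np.concatenate([spatial, temporal], axis=1)[w - 1 :]
    if target_length is None:
        target_length = total_length
    return truncate_pad_normalize(
        raw, target_length, total_length=total_length, min_length=min_length
    )


def _run_rng(dataset_seed: int, run_seed: int) -> np.random.Generator:
    """Per-run generator stable across lead times and dataset composition."""
    return np.random.default_rng(np.random.SeedSequence([dataset_seed, run_seed]))


def featurize_run(
    run,
    *,
    lead: int = 100,
    target_length: Optional[int] = None,
    dataset_seed: int = 0,
    factor_range: tuple[int, int] = (4, 15),
    window_fraction_range: tuple[float, float] = (0.10, 0.40),
    detrend_bandwidth: float = 0.10,
    total_length: int = 600,
    min_length: int = 100,
) -> IndicatorSeries:
    """Featurize one run into a normalized 12-channel indicator series.

    The raw field is truncated ``lead`` snapshots before the transition
    (null runs keep their full span) before any statistic -- including the
    Gaussian detrend -- touches it.  The coarse-graining factor, subregion
    origin, window width and retained length are randomized per run, but
    drawn from a generator keyed on (dataset_seed, run seed) so they are
    identical across different lead times of the same run.
    """
    rng = _run_rng(dataset_seed, run.seed)
    L = run.field.shape[1]
    periodic = getattr(run, "system", "ising") == "ising"
    f_hi = min(factor_range[1], L // 9)
    f_lo = min(factor_range[0], f_hi)
    factor = int(rng.integers(f_lo, f_hi + 1))
    if periodic:
        origin = tuple(int(v) for v in rng.integers(0, L, size=2))
    else:
        origin = tuple(int(v) for v in rng.integers(0, L - 9 * factor + 1, size=2))
    wf = float(rng.uniform(*window_fraction_range))
    drawn_length = int(rng.integers(min_length, total_length + 1))
    if target_length is None:
        target_length = drawn_length

    if run.label == "transition":
        if run.transition_index is None:
            raise ValueError("transition run lacks a transition_index")
        end = int(run.transition_index) - int(lead)
    else:
        end = run.field.shape[0]
    if end < min_length:
        raise RunTooShortError(
            f"run ends {end} steps after start at lead {lead}; need >= {min_length}"
        )

    cg = CoarseGrainSpec(spatial_factor=factor, subregion_origin=origin)
    coarse = coarse_grain(run.field[:end], run.mask, cg, periodic=periodic)
    wspec = WindowSpec(window_fraction=wf, detrend_bandwidth=detrend_bandwidth)
    w = wspec.window_length(coarse.shape[0])
    values, pad = featurize_coarse_field(
        coarse,
        window_spec=wspec,
        target_length=target_length,
        total_length=total_length,
        min_length=min_length,
    )
    return IndicatorSeries(
        values=values.astype(np.float32),
        pad_length=pad,
        label=run.label,
        order=run.order,
        meta={
            "factor": factor,
            "origin": origin,
            "window_fraction": wf,
            "window_length": w,
            "lead": lead,
            "raw_end": end,
        },
    )


def featurize_dataset(
    runs: Sequence,
    *,
    lead: int = 100,
    seed: int = 0,
    total_length: int = 600,
    min_length: int = 100,
    **kwargs,
) -> FeatureSet:
    """Featurize a collection of runs into a stacked, labelled feature set.

    Transition runs are truncated ``lead`` steps before their transition with
    randomized retained lengths; null runs are then truncated to lengths
    resampled from the realized transition-run length distribution, so length
    carries no class information.  Runs too short to featurize are dropped
    with a warning.
    """
    transition_runs = [r for r in runs if r.label == "transition"]
    null_runs = [r for r in runs if r.label != "transition"]

    entries: list[tuple[IndicatorSeries, object]] = []
    dropped = 0
    for run in transition_runs:
        try:
            s = featurize_run(
                run, lead=lead, dataset_seed=seed, total_length=total_length,
                min_length=min_length, **kwargs,
            )
        except RunTooShortError:
            dropped += 1
            continue
        entries.append((s, run))
    trans_lengths = np.array([s.length for s, _ in entries], dtype=int)
    if trans_lengths.size == 0 and transition_runs:
        raise RunTooShortError("no transition run survived truncation")

    for run in null_runs:
        if trans_lengths.size:
            u = float(_run_rng(seed, run.seed).uniform())
            target = int(np.quantile(trans_lengths, u, method="nearest"))
        else:
            target = None
        try:
            s = featurize_run(
                run, lead=lead, target_length=target, dataset_seed=seed,
                total_length=total_length, min_length=min_length, **kwargs,
            )
        except RunTooShortError:
            dropped += 1
            continue
        entries.append((s, run))
    if dropped:
        warnings.warn(f"dropped {dropped} runs too short to featurize", stacklevel=2)

    X = np.stack([s.values for s, _ in entries])
    y = np.array([1 if s.label == "transition" else 0 for s, _ in entries], dtype=np.int8)
    orders = np.array([s.order for s, _ in entries])
    lengths = np.array([s.length for s, _ in entries], dtype=int)
    manifest = {
        "lead": lead,
        "seed": seed,
        "total_length": total_length,
        "n_transition": int(y.sum()),
        "n_null": int((1 - y).sum()),
        "dropped": dropped,
        "run_seeds": [int(r.seed) for _, r in entries],
    }
    return FeatureSet(X=X, y=y, orders=orders, lengths=lengths, manifest=manifest)


def subset_channels(
    X: np.ndarray, subset: Literal["full", "spatial", "temporal"]
) -> np.ndarray:
    """Project stacked features onto a channel subset by column selection."""
    if subset == "full":
        return X
    if subset == "spatial":
        return X[..., list(SPATIAL_CHANNELS)]
    if subset == "temporal":
        return X[..., list(TEMPORAL_CHANNELS)]
    raise ValueError(f"unknown channel subset {subset!r}")
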