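"""Out-of-sample phase-transition test systems.

Two lattice models used only for transfer testing (never training):

* A coupled vegetation--water model: logistic biomass growth limited by soil
  water, water recharge from rainfall with vegetation-enhanced infiltration,
  diffusive spatial coupling and additive noise.  The local kinetics have a
  fold bifurcation in rainfall R, so ramping R downward through the fold
  produces an abrupt desertification collapse.

* A sea-ice-style site-percolation model: each step a fraction of sites
  re-samples its occupancy at the current probability p(t); ramping p through
  the square-lattice site-percolation threshold (~0.5927) produces the
  spanning-cluster phase transition.  The observed field is the local
  fraction of sites belonging to the largest cluster, smoothed over a small
  radius so the indicator statistics are informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Literal, Optional

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .lattice import NoTransitionError, TransitionNotReachedError, detect_transition_time

__all__ = [
    "VegetationParams",
    "VegetationSpec",
    "PercolationSpec",
    "FieldRun",
    "vegetation_equilibria",
    "vegetation_fold_rainfall",
    "simulate_vegetation",
    "percolation_clusters",
    "simulate_percolation",
    "generate_vegetation_dataset",
    "generate_percolation_dataset",
]

#: square-lattice site-percolation threshold (infinite lattice)
SITE_PERCOLATION_THRESHOLD = 0.592746


@dataclass
class FieldRun:
    """Real-valued lattice trajectory in the same shape the featurizer uses."""

    field: np.ndarray           # (T, L, L) float32
    mask: np.ndarray            # (L, L) bool
    forcing: np.ndarray         # (T,) control value per snapshot
    label: Literal["transition", "null"]
    system: str
    transition_index: Optional[int]
    seed: int
    order: str = "n/a"
    extras: dict = dc_field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.field.shape[0]


# ---------------------------------------------------------------- vegetation


@dataclass(frozen=True)
class VegetationParams:
    """Local kinetics of the coupled vegetation (V) -- soil water (W) model.

    dV/dt = growth * V * W/(W + half_sat) * (1 - V/capacity) - mortality * V
    dW/dt = R * (V + infil_ref * bare_infil)/(V + infil_ref)
            - water_loss * W - uptake * V * W

    Vegetation increases infiltration (bare soil captures only ``bare_infil``
    of rainfall), the positive feedback that creates bistability and a fold
    in R.  Defaults give a fold near R ~ 0.57 and desert stability up to
    R ~ 1.29 (dimensionless model units).
    """

    growth: float = 1.0
    half_sat: float = 2.0
    capacity: float = 10.0
    mortality: float = 0.3
    water_loss: float = 0.3
    uptake: float = 0.05
    bare_infil: float = 0.2
    infil_ref: float = 1.0


@dataclass(frozen=True)
class VegetationSpec:
    """One vegetation--water run: geometry, rainfall ramp, noise, kinetics."""

    grid_side: int = 64
    rainfall_start: float = 1.0
    rainfall_end: float = 0.3
    n_steps: int = 600
    noise_sd: float = 0.05
    diffusion_v: float = 0.2
    diffusion_w: float = 0.5
    dt: float = 0.1
    substeps: int = 5
    params: VegetationParams = VegetationParams()
    run_class: Literal["transition", "null"] = "transition"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_side < 9:
            raise ValueError("grid_side must be >= 9")
        if self.n_steps < 5:
            raise ValueError("n_steps must be >= 5")
        max_rate = 4 * max(self.diffusion_v, self.diffusion_w) * self.dt
        if max_rate >= 1.0:
            raise ValueError("dt too large for stable diffusion (4 D dt >= 1)")


def vegetation_equilibria(R: float, params: VegetationParams = VegetationParams()):
    """Stable/unstable positive vegetation equilibria of the local kinetics.

    Returns the sorted list of positive-V fixed points (empty below the
    fold).  V = 0 (desert) is always a fixed point; it is stable whenever
    vegetation cannot invade the bare-soil water level.
    """
    p = params

    def w_of_v(V: float) -> float:
        den = p.growth * (1.0 - V / p.capacity) - p.mortality
        return p.half_sat * p.mortality / den if den > 1e-12 else np.inf

    def residual(V: float) -> float:
        W = w_of_v(V)
        if not np.isfinite(W):
            return -1e12
        infil = (V + p.infil_ref * p.bare_infil) / (V + p.infil_ref)
        return R * infil - p.water_loss * W - p.uptake * V * W

    v_max = p.capacity * (1.0 - p.mortality / p.growth) * 0.999999
    grid = np.linspace(1e-9, v_max, 600)
    vals = np.array([residual(v) for v in grid])
    roots = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(brentq(residual, a, b)))
    return sorted(roots)


def vegetation_fold_rainfall(
    params: VegetationParams = VegetationParams(),
    lo: float = 0.01,
    hi: float = 5.0,
    tol: float = 1e-6,
) -> float:
    """Rainfall at the fold: smallest R with a vegetated equilibrium."""
    if vegetation_equilibria(hi, params):
        pass
    else:
        raise ValueError("no vegetated state below hi; widen the bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if vegetation_equilibria(mid, params):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _laplacian(z: np.ndarray) -> np.ndarray:
    """5-point Laplacian with zero-flux (Neumann) boundaries."""
    out = -4.0 * z
    out += np.roll(z, 1, axis=0)
    out += np.roll(z, -1, axis=0)
    out += np.roll(z, 1, axis=1)
    out += np.roll(z, -1, axis=1)
    # undo the periodic wrap at the edges: reflect instead
    out[0, :] += z[0, :] - z[-1, :]
    out[-1, :] += z[-1, :] - z[0, :]
    out[:, 0] += z[:, 0] - z[:, -1]
    out[:, -1] += z[:, -1] - z[:, 0]
    return out


def simulate_vegetation(spec: VegetationSpec) -> FieldRun:
    """Integrate the vegetation--water lattice under a linear rainfall ramp.

    Euler--Maruyama integration with ``spec.substeps`` steps of size
    ``spec.dt`` per recorded snapshot; the observed field is the vegetation
    biomass V.  Transition runs locate their transition at the inflection of
    the spatial-mean biomass.  Blow-up (non-finite or absurdly large fields)
    raises a RuntimeError naming the step size.
    """
    p = spec.params
    rng = np.random.default_rng(spec.seed)
    L = spec.grid_side
    rainfall = np.linspace(spec.rainfall_start, spec.rainfall_end, spec.n_steps)

    eq = vegetation_equilibria(spec.rainfall_start, p)
    if not eq:
        raise ValueError(
            f"no vegetated equilibrium at rainfall_start={spec.rainfall_start}; "
            "runs must start on the vegetated branch"
        )
    v_star = eq[-1]
    w_star = p.half_sat * p.mortality / (
        p.growth * (1.0 - v_star / p.capacity) - p.mortality
    )
    V = np.full((L, L), v_star) + rng.normal(0, max(spec.noise_sd, 1e-3), (L, L))
    W = np.full((L, L), w_star)
    np.clip(V, 0.0, None, out=V)

    bound = 100.0 * p.capacity
    record = np.empty((spec.n_steps, L, L), dtype=np.float32)
    sqrt_dt = np.sqrt(spec.dt)
    # burn-in at the initial rainfall so the field starts in quasi-equilibrium
    n_relax = 20 * spec.substeps
    for step in range(n_relax + spec.n_steps * spec.substeps):
        R = rainfall[0] if step < n_relax else rainfall[(step - n_relax) // spec.substeps]
        growth = p.growth * V * W / (W + p.half_sat) * (1.0 - V / p.capacity)
        infil = (V + p.infil_ref * p.bare_infil) / (V + p.infil_ref)
        dV = growth - p.mortality * V + spec.diffusion_v * _laplacian(V)
        dW = R * infil - p.water_loss * W - p.uptake * V * W + spec.diffusion_w * _laplacian(W)
        V = V + spec.dt * dV
        W = W + spec.dt * dW
        if spec.noise_sd > 0:
            V = V + spec.noise_sd * sqrt_dt * rng.standard_normal((L, L))
        np.clip(V, 0.0, None, out=V)
        np.clip(W, 0.0, None, out=W)
        if not np.isfinite(V).all() or V.max() > bound:
            raise RuntimeError(
                f"vegetation integration blew up (dt={spec.dt}); reduce dt"
            )
        if step >= n_relax and (step - n_relax + 1) % spec.substeps == 0:
            record[(step - n_relax) // spec.substeps] = V

    transition_index: Optional[int] = None
    if spec.run_class == "transition":
        mean_v = record.mean(axis=(1, 2)).astype(float)
        if mean_v[-1] > 0.5 * v_star:
            raise TransitionNotReachedError(
                "vegetation never collapsed during the rainfall ramp"
            )
        transition_index = detect_transition_time(mean_v)

    return FieldRun(
        field=record,
        mask=np.ones((L, L), dtype=bool),
        forcing=rainfall,
        label=spec.run_class,
        system="vegetation",
        transition_index=transition_index,
        seed=spec.seed,
        extras={"v_star": float(v_star), "w_star": float(w_star)},
    )


# --------------------------------------------------------------- percolation


@dataclass(frozen=True)
class PercolationSpec:
    """One site-percolation run: occupancy ramp and refresh dynamics."""

    grid_side: int = 64
    occupancy_start: float = 0.25
    occupancy_end: float = 0.85
    n_steps: int = 600
    refresh_fraction: float = 0.1
    smoothing_radius: int = 3
    run_class: Literal["transition", "null"] = "transition"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.occupancy_start, self.occupancy_end):
            if not 0.0 <= p <= 1.0:
                raise ValueError("occupancy probabilities must lie in [0, 1]")
        if not 0.0 < self.refresh_fraction <= 1.0:
            raise ValueError("refresh_fraction must lie in (0, 1]")


_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def percolation_clusters(
    occupancy: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """4-connected cluster labelling of a boolean occupancy grid.

    Returns ``(labels, largest_cluster_mask, spanning)``; ``spanning`` is
    True when some cluster touches both opposite edges along either axis.
    """
    occ = np.asarray(occupancy, dtype=bool)
    labels, n = ndimage.label(occ, structure=_FOUR_CONNECTED)
    if n == 0:
        return labels, np.zeros_like(occ), False
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = labels == sizes.argmax()
    spanning = bool(
        np.intersect1d(labels[0, labels[0] > 0], labels[-1, labels[-1] > 0]).size
        or np.intersect1d(labels[:, 0][labels[:, 0] > 0], labels[:, -1][labels[:, -1] > 0]).size
    )
    return labels, largest, spanning


def simulate_percolation(spec: PercolationSpec) -> FieldRun:
    """Simulate a site-percolation run under a linear occupancy ramp.

    Each step, a fraction ``refresh_fraction`` of sites re-draws its
    occupancy as Bernoulli(p(t)).  The observed field is the local fraction
    of sites belonging to the largest cluster within ``smoothing_radius``
    cells.  The transition index of a transition run is the first step at
    which a cluster spans the grid.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.grid_side
    p_t = np.linspace(spec.occupancy_start, spec.occupancy_end, spec.n_steps)
    occ = rng.random((L, L)) < p_t[0]
    size = 2 * spec.smoothing_radius + 1

    record = np.empty((spec.n_steps, L, L), dtype=np.float32)
    first_span: Optional[int] = None
    for t in range(spec.n_steps):
        refresh = rng.random((L, L)) < spec.refresh_fraction
        occ = np.where(refresh, rng.random((L, L)) < p_t[t], occ)
        _, largest, spanning = percolation_clusters(occ)
        record[t] = ndimage.uniform_filter(
            largest.astype(np.float32), size=size, mode="nearest"
        )
        if spanning and first_span is None:
            first_span = t

    transition_index: Optional[int] = None
    if spec.run_class == "transition":
        if first_span is None:
            raise TransitionNotReachedError(
                "occupancy ramp never produced a spanning cluster"
            )
        transition_index = first_span

    return FieldRun(
        field=record,
        mask=np.ones((L, L), dtype=bool),
        forcing=p_t,
        label=spec.run_class,
        system="percolation",
        transition_index=transition_index,
        seed=spec.seed,
    )


# ----------------------------------------------------------------- datasets


def _generate_dataset(make_spec, simulate, n_transition, n_null, seed,
                      min_transition_index=250, max_attempts_factor=30):
    rng = np.random.default_rng(seed)
    runs = []
    discarded = 0
    for run_class, n_wanted in (("transition", n_transition), ("null", n_null)):
        got, attempts = 0, 0
        max_attempts = max_attempts_factor * max(n_wanted, 1)
        while got < n_wanted:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not generate {n_wanted} valid {run_class} runs"
                )
            try:
                run = simulate(make_spec(run_class, rng))
            except (TransitionNotReachedError, NoTransitionError):
                discarded += 1
                continue
            if run.label == "transition" and run.transition_index < min_transition_index:
                discarded += 1
                continue
            runs.append(run)
            got += 1
    if discarded:
        warnings.warn(f"discarded and resampled {discarded} runs", stacklevel=3)
    return runs


def generate_vegetation_dataset(
    n_transition: int,
    n_null: int,
    *,
    grid_side: int = 64,
    n_steps_range: tuple[int, int] = (500, 900),
    noise_sd: float = 0.05,
    params: VegetationParams = VegetationParams(),
    min_transition_index: int = 250,
    seed: int = 0,
) -> list[FieldRun]:
    """Vegetation--water runs: rainfall ramps through (transition) or held
    above (null) the desertification fold, with randomized rates."""
    fold = vegetation_fold_rainfall(params)

    def make_spec(run_class: str, rng: np.random.Generator) -> VegetationSpec:
        n_steps = int(rng.integers(n_steps_range[0], n_steps_range[1] + 1))
        if run_class == "transition":
            start = fold + rng.uniform(0.35, 0.6)
            end = fold - rng.uniform(0.2, 0.4)
        else:
            # stay on the vegetated branch, margin above the fold
            start, end = fold + rng.uniform(0.35, 0.65, size=2)
        return VegetationSpec(
            grid_side=grid_side,
            rainfall_start=float(start),
            rainfall_end=float(end),
            n_steps=n_steps,
            noise_sd=noise_sd,
            params=params,
            run_class=run_class,  # type: ignore[arg-type]
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    return _generate_dataset(make_spec, simulate_vegetation, n_transition, n_null, seed,
                             min_transition_index=min_transition_index)


def generate_percolation_dataset(
    n_transition: int,
    n_null: int,
    *,
    grid_side: int = 64,
    n_steps_range: tuple[int, int] = (500, 900),
    refresh_fraction: float = 0.1,
    min_transition_index: int = 250,
    seed: int = 0,
) -> list[FieldRun]:
    """Site-percolation runs: occupancy ramps through (transition) or stays
    bounded away from (null) the spanning threshold, on either side."""

    def make_spec(run_class: str, rng: np.random.Generator) -> PercolationSpec:
        n_steps = int(rng.integers(n_steps_range[0], n_steps_range[1] + 1))
        if run_class == "transition":
            start = rng.uniform(0.15, 0.35)
            end = rng.uniform(0.75, 0.95)
        elif rng.random() < 0.5:
            start, end = rng.uniform(0.10, 0.45, size=2)
        else:
            start, end = rng.uniform(0.72, 0.95, size=2)
        return PercolationSpec(
            grid_side=grid_side,
            occupancy_start=float(start),
            occupancy_end=float(end),
            n_steps=n_steps,
            refresh_fraction=refresh_fraction,
            run_class=run_class,  # type: ignore[arg-type]
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    return _generate_dataset(make_spec, simulate_percolation, n_transition, n_null, seed,
                             min_transition_index=min_transition_index)
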