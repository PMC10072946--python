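"""Disordered two-dimensional Ising simulator for phase-transition training data.

Generates trajectories of a ferromagnetic Ising model on a periodic square
lattice whose symmetries have been deliberately broken: nearest-neighbour
couplings are drawn from a (truncated) normal distribution and sites inside
randomly placed elliptical regions are deleted.  Runs come in two classes:

* ``transition`` runs ramp a control parameter linearly through its critical
  regime -- temperature through the order/disorder threshold (second order),
  or the external field through zero at fixed low temperature (first order,
  magnetization overturning by nucleation);
* ``null`` runs ramp the same control but stay far from criticality.

Spin states evolve by single-site Metropolis dynamics; a snapshot of the full
lattice is recorded every fixed budget of attempted flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "LatticeSpec",
    "ForcingProtocol",
    "IsingRun",
    "LatticeDeletionError",
    "TransitionNotReachedError",
    "NoTransitionError",
    "critical_temperature",
    "sample_lattice",
    "metropolis_update",
    "net_magnetization",
    "detect_transition_time",
    "simulate_run",
    "generate_ising_dataset",
]

#: 2 / ln(1 + sqrt(2)) -- Onsager's exact order/disorder threshold for the
#: homogeneous square lattice at unit coupling.
ONSAGER_FACTOR = 2.0 / np.log(1.0 + np.sqrt(2.0))


class LatticeDeletionError(ValueError):
    """Raised when elliptical deletions would remove >= 50% of the lattice."""


class TransitionNotReachedError(RuntimeError):
    """Raised when a nominal transition run never actually overturns."""


class NoTransitionError(ValueError):
    """Raised when no transition point can be located in a series."""


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry and quenched disorder of one lattice realization.

    Couplings J_ij are sampled i.i.d. from N(coupling_mean, coupling_sd^2)
    truncated at zero (ferromagnetic bonds only).  ``n_deletion_ellipses``
    elliptical regions, with semi-axes drawn uniformly from
    ``deletion_axis_range`` and random centres/orientations, are removed from
    the lattice (their sites never flip and carry no effective coupling).
    """

    side_length: int = 128
    coupling_mean: float = 1.0
    coupling_sd: float = 0.2
    n_deletion_ellipses: int = 3
    deletion_axis_range: tuple[float, float] = (4.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side_length < 16:
            raise ValueError(f"side_length must be >= 16, got {self.side_length}")
        if self.coupling_sd < 0:
            raise ValueError("coupling_sd must be >= 0")
        if self.coupling_mean <= 0:
            raise ValueError("coupling_mean must be > 0 (ferromagnetic)")


@dataclass(frozen=True)
class ForcingProtocol:
    """Linear ramp of the control parameter over one run.

    ``order='second'`` ramps temperature at zero field; ``order='first'``
    ramps the external field h at fixed temperature ``fixed_T`` below the
    critical temperature.
    """

    order: Literal["first", "second"]
    control: Literal["T", "h"]
    start_value: float
    end_value: float
    n_steps: int
    run_class: Literal["transition", "null"] = "transition"
    fixed_T: Optional[float] = None

    def __post_init__(self) -> None:
        if self.order == "second" and self.control != "T":
            raise ValueError("second-order protocols ramp temperature")
        if self.order == "first":
            if self.control != "h":
                raise ValueError("first-order protocols ramp the external field")
            if self.fixed_T is None or self.fixed_T <= 0:
                raise ValueError("first-order protocols need fixed_T > 0")
        if self.n_steps < 5:
            raise ValueError("n_steps must be >= 5")

    def values(self) -> np.ndarray:
        """Control value at each snapshot."""
        return np.linspace(self.start_value, self.end_value, self.n_steps)


@dataclass
class IsingRun:
    """One simulated lattice trajectory.

    ``spins`` is int8 with values in {-1, +1} on live sites and 0 on deleted
    sites; all statistics must respect ``mask`` (True = live).  ``couplings``
    stacks the rightward and downward bond fields as shape (2, L, L).
    ``transition_index`` is the snapshot at which the transition is deemed to
    occur (present only for transition runs).
    """

    spins: np.ndarray          # (T, L, L) int8
    mask: np.ndarray           # (L, L) bool
    couplings: np.ndarray      # (2, L, L) float64
    forcing: np.ndarray        # (T,) control value per snapshot
    label: Literal["transition", "null"]
    order: Literal["first", "second"]
    transition_index: Optional[int]
    seed: int
    system: str = "ising"
    extras: dict = field(default_factory=dict)

    @property
    def field(self) -> np.ndarray:
        """Observed scalar field (alias used by the indicator pipeline)."""
        return self.spins

    @property
    def n_steps(self) -> int:
        return self.spins.shape[0]

    def magnetization_series(self) -> np.ndarray:
        """Net magnetization m(t): mean spin over live sites per snapshot."""
        live = self.mask.sum()
        return self.spins[:, self.mask].sum(axis=1) / live


def critical_temperature(mean_coupling: float) -> float:
    """Onsager critical temperature 2 J / ln(1 + sqrt(2)) at coupling J."""
    if mean_coupling <= 0:
        raise ValueError(f"mean coupling must be > 0, got {mean_coupling}")
    return ONSAGER_FACTOR * mean_coupling


def sample_lattice(spec: LatticeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw the quenched disorder: bond couplings and the site mask.

    Returns ``(couplings, mask)`` with couplings of shape (2, L, L):
    ``couplings[0, i, j]`` bonds (i, j)-(i, j+1) and ``couplings[1, i, j]``
    bonds (i, j)-(i+1, j), indices periodic.  Raises
    :class:`LatticeDeletionError` if the ellipses delete half the lattice.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.side_length
    couplings = rng.normal(spec.coupling_mean, spec.coupling_sd, size=(2, L, L))
    np.clip(couplings, 0.0, None, out=couplings)

    mask = np.ones((L, L), dtype=bool)
    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    lo, hi = spec.deletion_axis_range
    for _ in range(spec.n_deletion_ellipses):
        ci, cj = rng.uniform(0, L, size=2)
        a, b = rng.uniform(lo, hi, size=2)
        theta = rng.uniform(0, np.pi)
        # periodic displacement so ellipses wrap cleanly at the edges
        di = (ii - ci + L / 2) % L - L / 2
        dj = (jj - cj + L / 2) % L - L / 2
        u = di * np.cos(theta) + dj * np.sin(theta)
        v = -di * np.sin(theta) + dj * np.cos(theta)
        mask &= (u / a) ** 2 + (v / b) ** 2 > 1.0

    deleted = 1.0 - mask.mean()
    if deleted >= 0.5:
        raise LatticeDeletionError(
            f"deletion ellipses removed {deleted:.1%} of sites (>= 50%); "
            "resample with a new seed or smaller/fewer ellipses"
        )
    return couplings, mask


@njit(cache=True)
def _metropolis_kernel(spins, j_right, j_down, sites_i, sites_j, uniforms, T, h):
    """Attempt one single-site flip per entry of ``sites_i``/``uniforms``.

    Deleted sites hold spin 0, so bonds incident to them contribute nothing;
    callers must only propose flips at live sites.
    """
    L = spins.shape[0]
    n = sites_i.shape[0]
    for k in range(n):
        i = sites_i[k]
        j = sites_j[k]
        s = spins[i, j]
        jp = j + 1 if j + 1 < L else 0
        jm = j - 1 if j > 0 else L - 1
        ip = i + 1 if i + 1 < L else 0
        im = i - 1 if i > 0 else L - 1
        nb = (
            j_right[i, j] * spins[i, jp]
            + j_right[i, jm] * spins[i, jm]
            + j_down[i, j] * spins[ip, j]
            + j_down[im, j] * spins[im, j]
        )
        dE = 2.0 * s * (nb + h)
        if dE <= 0.0 or uniforms[k] < np.exp(-dE / T):
            spins[i, j] = -s


def metropolis_update(
    spins: np.ndarray,
    couplings: np.ndarray,
    live_i: np.ndarray,
    live_j: np.ndarray,
    rng: np.random.Generator,
    T: float,
    h: float,
    n_flips: int,
) -> None:
    """Attempt ``n_flips`` Metropolis single-site flips in place.

    Each attempt picks a uniformly random live site and flips it with
    probability min(1, exp(-dE / T)).  The state after the call is a pure
    function of (state before, rng state).
    """
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    if n_flips < 1:
        raise ValueError("n_flips must be >= 1")
    idx = rng.integers(0, live_i.shape[0], size=n_flips)
    uniforms = rng.random(n_flips)
    _metropolis_kernel(
        spins, couplings[0], couplings[1], live_i[idx], live_j[idx], uniforms, T, h
    )


def net_magnetization(frame: np.ndarray, mask: np.ndarray) -> float:
    """Mean spin over live sites of one snapshot; lies in [-1, 1]."""
    n_live = int(mask.sum())
    if n_live == 0:
        raise ValueError("mask has no live sites")
    return float(frame[mask].sum() / n_live)


def detect_transition_time(m_series: np.ndarray, smooth_frac: float = 0.02) -> int:
    """Locate a transition as the steepest point of a smoothed series.

    The series is smoothed with a Gaussian kernel (sigma = ``smooth_frac`` of
    the series length, edge-renormalized), and the index just after the
    largest absolute first difference is returned; ties break to the earliest
    index.  A constant series raises :class:`NoTransitionError`.
    """
    m = np.asarray(m_series, dtype=float)
    if m.ndim != 1 or m.size < 5:
        raise ValueError("need a 1-d series of length >= 5")
    if np.ptp(m) == 0.0:
        raise NoTransitionError("series is constant; no transition to locate")
    sigma = max(1.0, smooth_frac * m.size)
    ones = np.ones_like(m)
    smooth = gaussian_filter1d(m, sigma, mode="constant") / gaussian_filter1d(
        ones, sigma, mode="constant"
    )
    jumps = np.abs(np.diff(smooth))
    return int(np.argmax(jumps)) + 1


def _initial_spins(
    order: str, start_control: float, t_c: float, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Equilibrium-appropriate initial state far from criticality."""
    L = mask.shape[0]
    if order == "second":
        if start_control > t_c:  # disordered start
            spins = rng.choice(np.array([-1, 1], dtype=np.int8), size=(L, L))
        else:  # ordered start, random polarity
            sign = rng.choice(np.array([-1, 1], dtype=np.int8))
            spins = np.full((L, L), sign, dtype=np.int8)
    else:
        # first order: aligned with the initial field (its metastable basin
        # once the field reverses)
        sign = np.int8(1 if start_control >= 0 else -1)
        spins = np.full((L, L), sign, dtype=np.int8)
    spins[~mask] = 0
    return spins


def simulate_run(
    spec: LatticeSpec,
    protocol: ForcingProtocol,
    *,
    flips_per_snapshot: int = 10_000,
    burn_in_intervals: int = 50,
    seed: int = 0,
) -> IsingRun:
    """Simulate one Ising trajectory under a linear forcing protocol.

    A snapshot of the lattice is recorded after every ``flips_per_snapshot``
    attempted flips, with the control parameter updated between snapshots
    along ``protocol.values()``.  Before recording, ``burn_in_intervals``
    snapshot intervals are run at the initial control value.

    For second-order transition runs the transition index is the first
    snapshot whose temperature is below the Onsager estimate built from the
    mean live-bond coupling; for first-order runs it is located from the
    inflection of the net magnetization, and a run whose magnetization never
    overturns raises :class:`TransitionNotReachedError`.
    """
    couplings, mask = sample_lattice(spec)
    rng = np.random.default_rng(seed)
    controls = protocol.values()
    t_c = critical_temperature(_mean_live_coupling(couplings, mask))

    spins = _initial_spins(protocol.order, controls[0], t_c, mask, rng)
    live_i, live_j = (a.astype(np.int64) for a in np.nonzero(mask))
    live_i = np.ascontiguousarray(live_i)
    live_j = np.ascontiguousarray(live_j)

    if protocol.order == "second":
        T_vals = controls
        h_vals = np.zeros_like(controls)
    else:
        T_vals = np.full_like(controls, float(protocol.fixed_T))
        h_vals = controls

    for _ in range(burn_in_intervals):
        metropolis_update(
            spins, couplings, live_i, live_j, rng, T_vals[0], h_vals[0], flips_per_snapshot
        )

    record = np.empty((protocol.n_steps, spec.side_length, spec.side_length), dtype=np.int8)
    for t in range(protocol.n_steps):
        metropolis_update(
            spins, couplings, live_i, live_j, rng, T_vals[t], h_vals[t], flips_per_snapshot
        )
        record[t] = spins

    transition_index: Optional[int] = None
    if protocol.run_class == "transition":
        if protocol.order == "second":
            below = np.nonzero(controls < t_c)[0]
            if below.size == 0:
                raise TransitionNotReachedError(
                    "second-order transition protocol never crosses T_c"
                )
            transition_index = int(below[0])
        else:
            m = record[:, mask].mean(axis=1)
            if np.sign(m[-1]) == np.sign(m[0]) or abs(m[-1]) < 0.5:
                raise TransitionNotReachedError(
                    "magnetization never overturned during the field ramp"
                )
            transition_index = detect_transition_time(m)

    return IsingRun(
        spins=record,
        mask=mask,
        couplings=couplings,
        forcing=controls,
        label=protocol.run_class,
        order=protocol.order,
        transition_index=transition_index,
        seed=seed,
        extras={"t_c": t_c, "flips_per_snapshot": flips_per_snapshot},
    )


def _mean_live_coupling(couplings: np.ndarray, mask: np.ndarray) -> float:
    """Mean coupling over bonds whose both endpoints are live."""
    right_live = mask & np.roll(mask, -1, axis=1)
    down_live = mask & np.roll(mask, -1, axis=0)
    total = couplings[0][right_live].sum() + couplings[1][down_live].sum()
    n = right_live.sum() + down_live.sum()
    return float(total / n)


# ---------------------------------------------------------------------------
# dataset generation


def _sample_protocol(
    order: str,
    run_class: str,
    t_c_nominal: float,
    coupling_mean: float,
    n_steps: int,
    first_order_T: float,
    rng: np.random.Generator,
) -> ForcingProtocol:
    """Draw a randomized forcing protocol of the requested class.

    Second order: transition runs ramp T from U(1.3, 1.8) Tc down to
    U(0.4, 0.7) Tc; null runs ramp within [1.3, 2.5] Tc (hot side) or
    [0.3, 0.7] Tc (cold side).  First order (fixed T < Tc): transition runs
    ramp h from -h0 to +h0 with h0 ~ U(0.2, 0.5) J; null runs ramp within
    [-h0, -0.1 J].  First-order protocols are sign-symmetrized.
    """
    if order == "second":
        if run_class == "transition":
            start = rng.uniform(1.3, 1.8) * t_c_nominal
            end = rng.uniform(0.4, 0.7) * t_c_nominal
        else:
            if rng.random() < 0.5:
                start, end = rng.uniform(1.3, 2.5, size=2) * t_c_nominal
            else:
                start, end = rng.uniform(0.3, 0.7, size=2) * t_c_nominal
        return ForcingProtocol(
            order="second", control="T", start_value=float(start), end_value=float(end),
            n_steps=n_steps, run_class=run_class,  # type: ignore[arg-type]
        )
    if run_class == "transition":
        # below h0 ~ 0.3 J nucleation is too slow to overturn within the ramp
        h0 = rng.uniform(0.3, 0.5) * coupling_mean
        start, end = -h0, h0
    else:
        h0 = rng.uniform(0.2, 0.5) * coupling_mean
        start, end = rng.uniform(-h0, -0.1 * coupling_mean, size=2)
    if rng.random() < 0.5:
        start, end = -start, -end
    return ForcingProtocol(
        order="first", control="h", start_value=float(start), end_value=float(end),
        n_steps=n_steps, run_class=run_class,  # type: ignore[arg-type]
        fixed_T=first_order_T * coupling_mean,
    )


def generate_ising_dataset(
    order: Literal["first", "second"],
    n_transition: int,
    n_null: int,
    *,
    side_length: int = 128,
    flips_per_snapshot: int = 10_000,
    n_steps_range: tuple[int, int] = (500, 900),
    min_transition_index: int = 250,
    coupling_mean: float = 1.0,
    coupling_sd: float = 0.2,
    max_deletion_ellipses: int = 5,
    deletion_axis_range: tuple[float, float] = (4.0, 20.0),
    first_order_T: float = 1.8,
    burn_in_intervals: int = 50,
    seed: int = 0,
    max_attempts_factor: int = 30,
) -> list[IsingRun]:
    """Generate a labelled set of transition and null Ising runs.

    Each run gets fresh quenched disorder (couplings, deletions), a fresh
    randomized protocol and ramp length (``n_steps`` uniform over
    ``n_steps_range``, which randomizes the forcing rate).  Transition runs
    whose transition cannot be located, arrives before
    ``min_transition_index`` (leaving no room for truncated training series),
    or whose lattice fails the deletion bound, are discarded and resampled;
    discards emit a warning summary.  Fully deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    t_c_nominal = critical_temperature(coupling_mean)
    runs: list[IsingRun] = []
    wanted = [("transition", n_transition), ("null", n_null)]
    n_discarded = 0
    for run_class, n_wanted in wanted:
        got = 0
        attempts = 0
        max_attempts = max_attempts_factor * max(n_wanted, 1)
        while got < n_wanted:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"failed to generate {n_wanted} valid {run_class} runs in "
                    f"{max_attempts} attempts"
                )
            run_seed = int(rng.integers(0, 2**31 - 1))
            spec = LatticeSpec(
                side_length=side_length,
                coupling_mean=coupling_mean,
                coupling_sd=coupling_sd,
                n_deletion_ellipses=int(rng.integers(1, max_deletion_ellipses + 1)),
                deletion_axis_range=deletion_axis_range,
                seed=run_seed,
            )
            n_steps = int(rng.integers(n_steps_range[0], n_steps_range[1] + 1))
            protocol = _sample_protocol(
                order, run_class, t_c_nominal, coupling_mean, n_steps, first_order_T, rng
            )
            try:
                run = simulate_run(
                    spec,
                    protocol,
                    flips_per_snapshot=flips_per_snapshot,
                    burn_in_intervals=burn_in_intervals,
                    seed=run_seed,
                )
            except (LatticeDeletionError, TransitionNotReachedError, NoTransitionError):
                n_discarded += 1
                continue
            if (
                run.label == "transition"
                and run.transition_index is not None
                and run.transition_index < min_transition_index
            ):
                n_discarded += 1
                continue
            runs.append(run)
            got += 1
    if n_discarded:
        warnings.warn(
            f"discarded and resampled {n_discarded} runs "
            f"(early/failed transitions or over-deleted lattices)",
            stacklevel=2,
        )
    return runs
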