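"""Two-state Poisson (telegraph) simulation of single-molecule FRET trajectories.

A two-domain enzyme switching between a low-FRET state S1 and a high-FRET
state S2 with exponential dwell times (rates k1: S1->S2 and k2: S2->S1) is a
random telegraph process.  Its stationary occupancy of S2 is k1/(k1+k2) and
its autocorrelation decays as exp(-(k1+k2)*t), which is what lets histogram
areas and correlation decays be combined into rate estimates downstream.

Simulation is continuous-time: exponential waiting times are drawn and the
hidden chain is sampled onto the frame grid, so the sampled chain is exact at
any frame interval.  The observation in a frame is the state occupying the
frame's *start* time; optional Gaussian observation noise (per-state sigma)
is applied i.i.d. per frame and is NOT clipped to [0, 1] by default, keeping
Gaussian histogram fits unbiased.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TwoStateParams",
    "FretTrajectory",
    "simulate_trajectory",
    "simulate_ensemble",
    "sigma_from_gaussian_width",
    "gaussian_width_from_sigma",
]


def sigma_from_gaussian_width(c: float) -> float:
    """Convert a fitted Gaussian width ``c`` to an observation-noise SD.

    The histogram model uses exp(-(x-b)^2 / c^2) (no factor 2 in the
    denominator), so the standard deviation of the underlying Gaussian is
    ``c / sqrt(2)``.  This helper is the single place the convention lives.
    """
    return float(c) / math.sqrt(2.0)


def gaussian_width_from_sigma(sigma: float) -> float:
    """Inverse of :func:`sigma_from_gaussian_width`: ``c = sqrt(2)*sigma``."""
    return float(sigma) * math.sqrt(2.0)


@dataclass(frozen=True)
class TwoStateParams:
    """Hidden two-state process parameters shared by simulator and estimator.

    Attributes
    ----------
    S1, S2 : float
        FRET values of the low and high state, ``0 <= S1 < S2 <= 1``.
    k1 : float
        Switching rate S1 -> S2 in 1/s.
    k2 : float
        Switching rate S2 -> S1 in 1/s.
    sigma1, sigma2 : float
        Per-state Gaussian observation-noise standard deviations
        (dimensionless FRET units).
    """

    S1: float
    S2: float
    k1: float
    k2: float
    sigma1: float = 0.0
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.S1 < self.S2 <= 1.0):
            raise ValueError(
                f"require 0 <= S1 < S2 <= 1, got S1={self.S1}, S2={self.S2}"
            )
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError(f"rates must be positive, got k1={self.k1}, k2={self.k2}")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def rate_sum(self) -> float:
        """k1 + k2, the autocorrelation decay rate in 1/s."""
        return self.k1 + self.k2

    @property
    def rate_ratio(self) -> float:
        """k1/k2, equal to the stationary occupancy ratio P(S2)/P(S1)."""
        return self.k1 / self.k2

    @property
    def stationary_p1(self) -> float:
        """Stationary probability of state 1 (the low-FRET state)."""
        return self.k2 / (self.k1 + self.k2)

    @classmethod
    def from_histogram_widths(
        cls, S1: float, S2: float, k1: float, k2: float, c1: float, c2: float
    ) -> "TwoStateParams":
        """Build parameters from fitted Gaussian widths (``sigma = c/sqrt(2)``)."""
        return cls(
            S1=S1,
            S2=S2,
            k1=k1,
            k2=k2,
            sigma1=sigma_from_gaussian_width(c1),
            sigma2=sigma_from_gaussian_width(c2),
        )


@dataclass
class FretTrajectory:
    """An ordered series of FRET observations with sampling interval ``dt`` (s)."""

    values: np.ndarray
    dt: float
    hidden_states: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.hidden_states is not None:
            self.hidden_states = np.asarray(self.hidden_states, dtype=int)
            if self.hidden_states.shape != self.values.shape:
                raise ValueError("hidden_states must match values in length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


def _switch_times(params: TwoStateParams, start_state: int, total: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Cumulative switching times of the hidden chain on [0, total].

    Dwell rates alternate deterministically given the start state, so
    exponential dwells are drawn in vectorized chunks until the chain has
    left the observation window.
    """
    rates = np.array([params.k1, params.k2])  # rate of *leaving* state 1, 2
    # generous first chunk: expected number of switches plus 10 sd
    exp_n = total * max(params.k1, params.k2)
    chunk = max(16, int(exp_n + 10.0 * math.sqrt(exp_n + 1.0)))
    out: list[np.ndarray] = []
    t_end = 0.0
    state_parity = 0 if start_state == 1 else 1
    while t_end < total:
        scales = 1.0 / rates[(np.arange(chunk) + state_parity) % 2]
        cum = t_end + np.cumsum(rng.exponential(scales))
        out.append(cum)
        t_end = cum[-1]
        state_parity = (state_parity + chunk) % 2
        chunk = max(16, chunk // 2)
    cum_all = np.concatenate(out)
    return cum_all[cum_all < total]


def simulate_trajectory(
    params: TwoStateParams,
    n_frames: int,
    dt: float,
    with_noise: bool = True,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    start_state: int | None = None,
    clip: bool = False,
) -> FretTrajectory:
    """Simulate one smFRET trajectory from the telegraph process.

    Parameters
    ----------
    params : TwoStateParams
    n_frames : int
        Number of frames (>= 1).
    dt : float
        Frame interval in seconds.
    with_noise : bool
        Add per-state Gaussian observation noise.
    seed, rng
        Either a seed or an existing generator; ``rng`` wins if both given.
    start_state : int, optional
        Force the initial state (1 or 2).  By default the initial state is
        drawn from the stationary distribution, which removes equilibration
        transients.
    clip : bool
        Clip observations to [0, 1] (off by default; Gaussian tails are kept
        so that histogram fits remain unbiased).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    if max(params.k1, params.k2) * dt > 10.0:
        warnings.warn(
            "expected dwell time is shorter than dt/10; sampled dynamics "
            "will be aliased",
            RuntimeWarning,
            stacklevel=2,
        )

    if start_state is None:
        start_state = 1 if rng.random() < params.stationary_p1 else 2
    elif start_state not in (1, 2):
        raise ValueError("start_state must be 1 or 2")

    total = n_frames * dt
    switches = _switch_times(params, start_state, total, rng)
    frame_times = np.arange(n_frames) * dt
    n_before = np.searchsorted(switches, frame_times, side="right")
    states = np.where(n_before % 2 == 0, start_state, 3 - start_state)

    values = np.where(states == 1, params.S1, params.S2).astype(float)
    if with_noise and (params.sigma1 > 0 or params.sigma2 > 0):
        sig = np.where(states == 1, params.sigma1, params.sigma2)
        values = values + rng.standard_normal(n_frames) * sig
    if clip:
        values = np.clip(values, 0.0, 1.0)

    return FretTrajectory(
        values=values,
        dt=dt,
        hidden_states=states,
        meta={"with_noise": bool(with_noise), "start_state": int(start_state)},
    )


def simulate_ensemble(
    params: TwoStateParams,
    n_traj: int,
    n_frames: int,
    dt: float,
    with_noise: bool = True,
    seed: int | None = None,
) -> list[FretTrajectory]:
    """Simulate ``n_traj`` independent trajectories with per-trajectory seeds.

    Seeds are spawned from the master seed via ``numpy.random.SeedSequence``,
    so the ensemble is bit-reproducible given the master seed and trajectories
    are mutually independent.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_traj)
    out = []
    for i, child in enumerate(children):
        traj = simulate_trajectory(
            params, n_frames, dt, with_noise=with_noise,
            rng=np.random.default_rng(child),
        )
        traj.meta["trajectory_index"] = i
        out.append(traj)
    return out


def dwell_times(traj: FretTrajectory, state: int) -> np.ndarray:
    """Observed (frame-resolution) dwell durations of ``state``, in seconds.

    The first and last dwells are censored by the observation window and are
    excluded.
    """
    if traj.hidden_states is None:
        raise ValueError("trajectory carries no hidden states")
    s = traj.hidden_states
    change = np.flatnonzero(np.diff(s) != 0) + 1
    if change.size < 2:
        return np.empty(0)
    bounds = change
    starts, ends = bounds[:-1], bounds[1:]
    mask = s[starts] == state
    return (ends[mask] - starts[mask]) * traj.dt
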