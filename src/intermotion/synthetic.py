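"""Synthetic intermittent-locomotion trajectories in an annular arena.

The generator emulates 8 h recordings of a single juvenile insect walking in
a ring-shaped arena (outer wall radius 40 cm, central dome radius 17.5 cm)
sampled at 5 Hz.  Motion alternates *move* bouts (frame displacement above
the 0.3 cm classification threshold, travelling along the annulus mid-radius
circle clockwise or anti-clockwise) and *pause* bouts (sub-threshold
micro-motion).  The statistical structure the downstream analysis assumes is
built in and recorded in a ground-truth ledger:

* move and pause durations follow a power law with a stretched-exponential
  tail (model i of :mod:`intermotion.distfit`), snapped to the 0.2 s grid;
* the probability that the travel direction flips across a pause is a
  configured function of the pause length;
* within pauses, the instantaneous rotation sign switches at a configured
  per-frame rate ("fidgeting"); within moves it never switches;
* bout pairs are drawn under a slowly drifting two-regime schedule —
  *relocation* (long moves, short pauses) vs *local search* (long pauses,
  short moves) — realised as regime blocks whose occupancy probability is
  interpolated from schedule knots.

All randomness flows from one master seed through ``numpy`` SeedSequence
spawning, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distfit import GRID_DT, CandidateModel, sample_durations, stretch_pl_quantile

__all__ = [
    "BoutLawParams",
    "PiecewiseLogCurve",
    "GeneratorConfig",
    "Trajectory",
    "GroundTruthBout",
    "GroundTruth",
    "sample_bout_lengths",
    "simulate_bout_sequence",
    "simulate_trajectory",
    "generate_cohort",
    "default_turn_curve",
]

MID_RADIUS_FRACTION = 0.5  # moves follow the circle midway between dome and wall


@dataclass(frozen=True)
class BoutLawParams:
    """Parameters of the stretched-tail power law for one bout type.

    mu is the Levy exponent (must lie in (1, 3] for a Levy walk and for the
    sampling envelope), beta the tail stretch in (0, 1], theta the tail-onset
    scale in seconds and xmin the grid floor.
    """

    mu: float
    beta: float
    theta: float
    xmin: float = GRID_DT

    def __post_init__(self) -> None:
        if not (1.0 < self.mu <= 3.0):
            raise ValueError(f"mu must be in (1, 3], got {self.mu}")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.theta <= 0 or self.xmin <= 0:
            raise ValueError("theta and xmin must be positive")

    def as_dict(self) -> dict[str, float]:
        return {"mu": self.mu, "beta": self.beta, "theta": self.theta}

    @property
    def model(self) -> CandidateModel:
        return CandidateModel("pl_stretched_tail", (self.xmin, np.inf))


@dataclass(frozen=True)
class PiecewiseLogCurve:
    """Probability curve p(d) linearly interpolated in log10 duration.

    Used for the pause-length-dependent probability of changing travel
    direction after a pause; values are clipped to [0, 1] and held constant
    outside the knot range.
    """

    knots_x: tuple[float, ...]
    knots_p: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.knots_x) != len(self.knots_p) or len(self.knots_x) < 1:
            raise ValueError("need matching, non-empty knot arrays")
        if np.any(np.diff(self.knots_x) <= 0):
            raise ValueError("knot durations must increase")
        if np.any((np.asarray(self.knots_p) < 0) | (np.asarray(self.knots_p) > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def __call__(self, d) -> np.ndarray:
        x = np.log10(np.asarray(d, dtype=float))
        p = np.interp(x, np.log10(self.knots_x), self.knots_p)
        return np.clip(p, 0.0, 1.0)


def default_turn_curve() -> PiecewiseLogCurve:
    """Default turn-after-pause curve: rising to ~0.25 by 6 s, flat to 100 s,
    rising again for the very long reorientation pauses."""
    return PiecewiseLogCurve((0.2, 6.0, 100.0, 1000.0), (0.05, 0.25, 0.25, 0.55))


@dataclass
class GeneratorConfig:
    """Full parameterisation of one synthetic individual."""

    frame_dt: float = GRID_DT
    duration: float = 28800.0
    arena_outer_radius: float = 40.0
    dome_radius: float = 17.5
    move_dist_params: BoutLawParams = field(
        default_factory=lambda: BoutLawParams(mu=1.49, beta=0.55, theta=8.0)
    )
    pause_dist_params: BoutLawParams = field(
        default_factory=lambda: BoutLawParams(mu=1.67, beta=0.23, theta=15.27)
    )
    turn_after_pause_curve: PiecewiseLogCurve = field(default_factory=default_turn_curve)
    within_pause_switch_rate: float = 0.6
    mode_schedule: tuple[tuple[float, float], ...] = ((0.0, 0.2), (28800.0, 0.6))
    mode_block_duration: float = 1200.0
    move_speed: float = 3.0
    move_max: float = 500.0  # truncation caps: finite records hold bounded bouts
    pause_max: float = 1000.0
    move_pause_corr: float = -0.6  # Gaussian-copula coupling of (move, pause) pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.arena_outer_radius <= 0 or self.dome_radius <= 0:
            raise ValueError("radii must be positive")
        if self.dome_radius >= self.arena_outer_radius:
            raise ValueError("dome must fit inside the outer wall")
        if not (0.0 <= self.within_pause_switch_rate <= 1.0):
            raise ValueError("within_pause_switch_rate must be a probability")
        for _, p in self.mode_schedule:
            if not (0.0 <= p <= 1.0):
                raise ValueError("mode schedule probabilities must be in [0, 1]")
        if self.move_speed * self.frame_dt <= 0.3:
            raise ValueError(
                "move_speed * frame_dt must exceed the 0.3 cm move threshold, "
                f"got {self.move_speed * self.frame_dt:.3f} cm per frame"
            )

    @property
    def mid_radius(self) -> float:
        return self.dome_radius + MID_RADIUS_FRACTION * (self.arena_outer_radius - self.dome_radius)

    def relocation_probability(self, t) -> np.ndarray:
        ts = np.asarray([k[0] for k in self.mode_schedule], dtype=float)
        ps = np.asarray([k[1] for k in self.mode_schedule], dtype=float)
        return np.interp(np.asarray(t, dtype=float), ts, ps)


@dataclass
class Trajectory:
    """Frame-level positions of one individual, arena centre at the origin."""

    individual_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times/x/y length mismatch")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=0, atol=1e-9)):
            raise ValueError("times must be strictly increasing and uniformly spaced")

    @property
    def frame_dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else GRID_DT

    @property
    def radius(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"individual_id": self.individual_id, "t_s": self.times, "x_cm": self.x, "y_cm": self.y}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        return cls(
            individual_id=str(df["individual_id"].iloc[0]),
            times=df["t_s"].to_numpy(dtype=float),
            x=df["x_cm"].to_numpy(dtype=float),
            y=df["y_cm"].to_numpy(dtype=float),
        )


@dataclass
class GroundTruthBout:
    state: str  # "move" | "pause"
    start_frame: int
    n_frames: int
    duration: float
    direction: int | None = None  # move travel direction: +1 ACW, -1 CW
    turned_after: bool | None = None  # pauses: did direction flip across it
    regime: str | None = None  # "relocation" | "local_search"


@dataclass
class GroundTruth:
    """Exact realised bout list and regime intervals for one individual."""

    bouts: list[GroundTruthBout]
    regime_intervals: list[tuple[float, float, str]]
    frame_dt: float

    def durations(self, state: str) -> np.ndarray:
        return np.asarray([b.duration for b in self.bouts if b.state == state])

    def to_json(self) -> str:
        payload = {
            "frame_dt": self.frame_dt,
            "bouts": [asdict(b) for b in self.bouts],
            "regime_intervals": [list(iv) for iv in self.regime_intervals],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        bouts = [GroundTruthBout(**b) for b in payload["bouts"]]
        ivs = [(iv[0], iv[1], iv[2]) for iv in payload["regime_intervals"]]
        return cls(bouts=bouts, regime_intervals=ivs, frame_dt=payload["frame_dt"])


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_bout_lengths(
    params: BoutLawParams,
    n: int,
    rng: np.random.Generator,
    frame_dt: float = GRID_DT,
    max_duration: float | None = None,
) -> np.ndarray:
    """Draw ``n`` bout durations (s) from the stretched-tail power law,
    snapped to the frame grid (each an exact multiple of ``frame_dt``).

    ``max_duration`` truncates the law (draws above it are resampled):
    trajectory simulation uses this to keep bout lengths within the
    physically bounded range a finite record can contain.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = sample_durations(params.model, params.as_dict(), n, rng, frame_dt=frame_dt)
    if max_duration is not None:
        while True:
            over = out > max_duration
            k = int(over.sum())
            if k == 0:
                break
            out[over] = sample_durations(params.model, params.as_dict(), k, rng, frame_dt=frame_dt)
    return out


def _draw_pair(
    config: GeneratorConfig, rng: np.random.Generator, regime: str, max_tries: int = 50
) -> tuple[float, float]:
    """Draw a coupled (move, pause) duration pair biased by the active regime.

    The pair is sampled through a Gaussian copula with correlation
    ``move_pause_corr`` (negative by default: long moves go with short
    pauses and vice versa); the regime then accepts pairs with move >= pause
    (relocation) or pause >= move (local search), with a retry cap so the
    marginals stay heavy-tailed.
    """
    from scipy.stats import norm

    rho = config.move_pause_corr
    dt = config.frame_dt
    for _ in range(max_tries):
        z1 = rng.normal()
        z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.normal()
        u1, u2 = norm.cdf(z1), norm.cdf(z2)
        m = float(stretch_pl_quantile(config.move_dist_params.as_dict(),
                                      config.move_dist_params.xmin, np.array([u1]),
                                      max_duration=config.move_max)[0])
        p = float(stretch_pl_quantile(config.pause_dist_params.as_dict(),
                                      config.pause_dist_params.xmin, np.array([u2]),
                                      max_duration=config.pause_max)[0])
        m = max(np.floor(m / dt + 1e-9) * dt, dt)
        p = max(np.floor(p / dt + 1e-9) * dt, dt)
        if regime == "relocation" and m >= p:
            return m, p
        if regime == "local_search" and p >= m:
            return m, p
    return m, p


def simulate_bout_sequence(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Realise the alternating move/pause bout plan for one individual.

    Regime blocks of ``mode_block_duration`` are assigned
    relocation/local-search labels Bernoulli from the interpolated schedule;
    bout pairs are drawn per block; travel direction flips across each pause
    with probability ``turn_after_pause_curve(pause length)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.frame_dt
    n_frames_total = int(round(config.duration / dt))

    # regime blocks
    block = config.mode_block_duration
    starts = np.arange(0.0, config.duration, block)
    regimes = []
    for s in starts:
        mid = min(s + 0.5 * block, config.duration)
        r = "relocation" if rng.uniform() < float(config.relocation_probability(mid)) else "local_search"
        regimes.append(r)
    regime_intervals = [
        (float(s), float(min(s + block, config.duration)), r) for s, r in zip(starts, regimes)
    ]

    def regime_at(t: float) -> str:
        i = min(int(t // block), len(regimes) - 1)
        return regimes[i]

    bouts: list[GroundTruthBout] = []
    frame = 0
    direction = int(rng.choice([-1, 1]))
    t = 0.0
    while frame < n_frames_total:
        reg = regime_at(t)
        m, p = _draw_pair(config, rng, reg)
        m_frames = int(round(m / dt))
        p_frames = int(round(p / dt))
        bouts.append(
            GroundTruthBout("move", frame, m_frames, m_frames * dt, direction=direction, regime=reg)
        )
        frame += m_frames
        t = frame * dt
        turned = bool(rng.uniform() < float(config.turn_after_pause_curve(p)))
        bouts.append(
            GroundTruthBout("pause", frame, p_frames, p_frames * dt, turned_after=turned, regime=reg)
        )
        frame += p_frames
        t = frame * dt
        if turned:
            direction = -direction
    return GroundTruth(bouts=bouts, regime_intervals=regime_intervals, frame_dt=dt)


def simulate_trajectory(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    individual_id: str = "ind0",
    return_truth: bool = False,
):
    """Render a bout plan into frame-level positions.

    Moves travel along the annulus mid-radius circle at ``move_speed``
    (constant angular speed), so every move frame-step has displacement
    ``move_speed * frame_dt`` > 0.3 cm.  Pause frames make tiny signed
    angular arc steps (~0.01 cm) whose sign switches at
    ``within_pause_switch_rate``, plus sub-millimetre radial jitter, so
    pause displacements stay far below the classification threshold while
    realising a controlled fidgeting rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = simulate_bout_sequence(config, rng)
    dt = config.frame_dt
    R = config.mid_radius
    move_dphi = config.move_speed * dt / R
    pause_arc = 0.01  # cm per pause frame-step
    pause_dphi = pause_arc / R

    n_transitions = sum(b.n_frames for b in truth.bouts)
    dphi = np.empty(n_transitions)
    dr = np.zeros(n_transitions)
    i = 0
    prev_sign = truth.bouts[0].direction or 1
    for b in truth.bouts:
        k = b.n_frames
        if b.state == "move":
            dphi[i : i + k] = b.direction * move_dphi
            prev_sign = b.direction
        else:
            # signed fidgeting process: start from the previous travel sign,
            # switch with the configured per-frame probability
            switches = rng.uniform(size=k) < config.within_pause_switch_rate
            signs = prev_sign * np.cumprod(np.where(switches, -1, 1))
            dphi[i : i + k] = signs * pause_dphi
            dr[i : i + k] = rng.uniform(-0.02, 0.02, size=k)
            prev_sign = int(signs[-1])
        i += k

    phi = np.concatenate([[rng.uniform(0, 2 * np.pi)], np.cumsum(dphi)])
    phi[1:] += phi[0]
    # radius: moves stay exactly on the mid-radius circle; pause frames carry
    # small clipped radial jitter so positions wander without leaving the bin
    rad = np.empty(n_transitions + 1)
    rad[0] = R
    i = 0
    for b in truth.bouts:
        k = b.n_frames
        if b.state == "move":
            rad[i + 1 : i + 1 + k] = R
        else:
            rad[i + 1 : i + 1 + k] = np.clip(rad[i] + np.cumsum(dr[i : i + k]), R - 0.1, R + 0.1)
        i += k
    times = np.arange(n_transitions + 1) * dt
    traj = Trajectory(individual_id, times, rad * np.cos(phi), rad * np.sin(phi))
    if return_truth:
        return traj, truth
    return traj


def generate_cohort(
    config: GeneratorConfig, n_individuals: int, return_truth: bool = False
):
    """Independent trajectories with per-individual seeds spawned from the
    master seed; bitwise reproducible."""
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    seeds = np.random.SeedSequence(config.seed).spawn(n_individuals)
    out, truths = [], []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        res = simulate_trajectory(config, rng, individual_id=f"ind{i}", return_truth=return_truth)
        if return_truth:
            out.append(res[0])
            truths.append(res[1])
        else:
            out.append(res)
    return (out, truths) if return_truth else out
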