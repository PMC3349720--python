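"""Frame-level trajectories -> labelled move/pause bouts.

A frame-pair is a *move* transition when the Euclidean displacement between
successive frames exceeds 0.3 cm (one 0.2 s frame), otherwise a *pause*
transition.  Rotational direction (clockwise vs anti-clockwise around the
arena centre) comes from the sign of the z-component of the cross product of
successive position vectors; a zero cross product carries the previous label
forward.  Frames within 3 cm of the outer wall or the central dome are
censored to remove edge effects; bouts touching a censored gap or a record
end are flagged so pooled duration statistics can drop them (their true
length is unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import Trajectory

__all__ = [
    "Bout",
    "BoutSequence",
    "classify_frames",
    "rotational_direction",
    "encode_bouts",
    "apply_edge_exclusion",
    "discretize_trajectory",
    "angular_speed_profile",
    "saturating_angular_speed",
    "BoutDiscretizer",
]

MOVE_THRESHOLD_CM = 0.3
EDGE_MARGIN_CM = 3.0


@dataclass
class Bout:
    """One maximal run of same-state frame transitions.

    A bout of n frames owns the n transitions starting at its start frame;
    ``directions`` holds their CW(-1)/ACW(+1) labels.  ``edge_censored``
    marks bouts abutting a censored gap or a record end, whose true duration
    is unknown.
    """

    state: str  # "move" | "pause"
    start_frame: int
    n_frames: int
    frame_dt: float
    directions: np.ndarray
    block: int = 0
    edge_censored: bool = False

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_dt


@dataclass
class BoutSequence:
    """Ordered bouts of one individual plus the censored frame gaps."""

    individual_id: str
    bouts: list[Bout]
    frame_dt: float
    censored_gaps: list[tuple[int, int]] = field(default_factory=list)

    def durations(self, state: str, include_censored: bool = False) -> np.ndarray:
        return np.asarray(
            [
                b.duration
                for b in self.bouts
                if b.state == state and (include_censored or not b.edge_censored)
            ]
        )

    def blocks(self) -> list[list[Bout]]:
        out: dict[int, list[Bout]] = {}
        for b in self.bouts:
            out.setdefault(b.block, []).append(b)
        return [out[k] for k in sorted(out)]


def classify_frames(traj: Trajectory, move_threshold: float = MOVE_THRESHOLD_CM) -> np.ndarray:
    """Per frame-transition state labels: True = move (displacement > threshold)."""
    if len(traj.times) < 2:
        raise ValueError("need at least two frames")
    if move_threshold <= 0:
        raise ValueError("threshold must be positive")
    disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return disp > move_threshold


def rotational_direction(traj: Trajectory) -> np.ndarray:
    """Per frame-transition rotation labels: +1 ACW, -1 CW.

    Sign of the z cross product of successive position vectors relative to
    the arena centre; zero cross products (no angular motion) carry the
    previous label forward, and leading zeros take the first nonzero label.
    """
    if len(traj.times) < 2:
        raise ValueError("need at least two frames")
    cross = traj.x[:-1] * traj.y[1:] - traj.y[:-1] * traj.x[1:]
    s = np.sign(cross).astype(int)
    if np.all(s == 0):
        return s  # no angular motion anywhere: all labels zero
    # forward-fill zeros, then back-fill the leading run
    idx = np.arange(len(s))
    nz = s != 0
    last = np.maximum.accumulate(np.where(nz, idx, -1))
    filled = np.where(last >= 0, s[np.clip(last, 0, None)], 0)
    first_nz = idx[nz][0]
    filled[:first_nz] = s[first_nz]
    return filled


def encode_bouts(
    labels: np.ndarray,
    dir_labels: np.ndarray,
    frame_dt: float,
    block: int = 0,
    frame_offset: int = 0,
) -> list[Bout]:
    """Collapse per-transition labels into maximal same-state bouts."""
    labels = np.asarray(labels)
    dir_labels = np.asarray(dir_labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.shape != dir_labels.shape:
        raise ValueError("state and direction label lengths differ")
    change = np.flatnonzero(np.diff(labels.astype(int)) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    bouts = []
    for s, e in zip(starts, ends):
        bouts.append(
            Bout(
                state="move" if labels[s] else "pause",
                start_frame=frame_offset + int(s),
                n_frames=int(e - s),
                frame_dt=frame_dt,
                directions=dir_labels[s:e].copy(),
                block=block,
            )
        )
    return bouts


def apply_edge_exclusion(
    traj: Trajectory,
    margin: float = EDGE_MARGIN_CM,
    outer_radius: float = 40.0,
    dome_radius: float = 17.5,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split the frame index range into kept blocks and censored gaps.

    Frames with radius above ``outer_radius - margin`` or below
    ``dome_radius + margin`` are censored.  Returns ``(blocks, gaps)`` as
    half-open frame index intervals.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if dome_radius + margin >= outer_radius - margin:
        raise ValueError("margin leaves no annulus")
    r = traj.radius
    bad = (r > outer_radius - margin) | (r < dome_radius + margin)
    blocks, gaps = [], []
    n = len(bad)
    i = 0
    while i < n:
        j = i
        while j < n and bad[j] == bad[i]:
            j += 1
        (gaps if bad[i] else blocks).append((i, j))
        i = j
    return blocks, gaps


def discretize_trajectory(
    traj: Trajectory,
    move_threshold: float = MOVE_THRESHOLD_CM,
    edge_margin: float = EDGE_MARGIN_CM,
    outer_radius: float = 40.0,
    dome_radius: float = 17.5,
) -> BoutSequence:
    """Full discretization: edge exclusion, state labels, direction labels,
    bout encoding per uncensored block, censoring flags at block edges."""
    blocks, gaps = apply_edge_exclusion(traj, edge_margin, outer_radius, dome_radius)
    labels_all = classify_frames(traj, move_threshold)
    dirs_all = rotational_direction(traj)
    bouts: list[Bout] = []
    for bi, (lo, hi) in enumerate(blocks):
        # transitions fully inside the block: frames lo..hi-1 -> transitions lo..hi-2
        t_lo, t_hi = lo, hi - 1
        if t_hi <= t_lo:
            continue
        bl = encode_bouts(labels_all[t_lo:t_hi], dirs_all[t_lo:t_hi], traj.frame_dt,
                          block=bi, frame_offset=t_lo)
        # the first and last bout of every block touch either a censored gap
        # or a record end, so their true durations are unknown
        bl[0].edge_censored = True
        bl[-1].edge_censored = True
        bouts.extend(bl)
    return BoutSequence(
        individual_id=traj.individual_id,
        bouts=bouts,
        frame_dt=traj.frame_dt,
        censored_gaps=gaps,
    )


def saturating_angular_speed(t: np.ndarray, a: float, c: float) -> np.ndarray:
    """Hyperbolic saturation omega(t) = c * t / (a + t) (degrees/s)."""
    return c * np.asarray(t, dtype=float) / (a + np.asarray(t, dtype=float))


def angular_speed_profile(
    seq: BoutSequence,
    traj: Trajectory,
    bins: Sequence[float],
) -> dict[str, np.ndarray | tuple[float, float]]:
    """Mean angular speed of moves per move-length bin plus a saturating fit.

    Per move, omega = |unwrapped polar angle change over the bout| / duration
    in degrees per second; bin means carry normal 95% CIs; the saturating
    form omega(t) = c t / (a + t) is fitted to the per-move points by
    nonlinear least squares.
    """
    phi = np.unwrap(np.arctan2(traj.y, traj.x))
    omegas, lengths = [], []
    for b in seq.bouts:
        if b.state != "move":
            continue
        i0, i1 = b.start_frame, b.start_frame + b.n_frames
        dphi = abs(phi[i1] - phi[i0])
        omegas.append(np.degrees(dphi) / b.duration)
        lengths.append(b.duration)
    omegas = np.asarray(omegas)
    lengths = np.asarray(lengths)
    edges = np.asarray(bins, dtype=float)
    which = np.digitize(lengths, edges) - 1
    n_bins = len(edges) - 1
    mean = np.full(n_bins, np.nan)
    ci = np.full(n_bins, np.nan)
    n_obs = np.zeros(n_bins, dtype=int)
    for i in range(n_bins):
        sel = omegas[which == i]
        n_obs[i] = sel.size
        if sel.size:
            mean[i] = sel.mean()
            ci[i] = 1.96 * sel.std(ddof=1) / np.sqrt(sel.size) if sel.size > 1 else 0.0
    if lengths.size >= 3:
        popt, _ = curve_fit(saturating_angular_speed, lengths, omegas, p0=(3.0, 18.0), maxfev=10000)
    else:
        popt = (np.nan, np.nan)  # too few moves to constrain the saturation
    return {
        "bin_edges": edges,
        "mean": mean,
        "ci95": ci,
        "n_obs": n_obs,
        "fit_a": float(popt[0]),
        "fit_c": float(popt[1]),
    }


class BoutDiscretizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: Trajectory -> BoutSequence.

    Parameters mirror the classification thresholds: ``move_threshold`` (cm
    per frame), ``edge_margin`` (cm) and the arena radii.
    """

    def __init__(self, move_threshold: float = MOVE_THRESHOLD_CM,
                 edge_margin: float = EDGE_MARGIN_CM,
                 outer_radius: float = 40.0, dome_radius: float = 17.5):
        self.move_threshold = move_threshold
        self.edge_margin = edge_margin
        self.outer_radius = outer_radius
        self.dome_radius = dome_radius

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        single = isinstance(X, Trajectory)
        trajs = [X] if single else list(X)
        out = [
            discretize_trajectory(
                t, self.move_threshold, self.edge_margin, self.outer_radius, self.dome_radius
            )
            for t in trajs
        ]
        return out[0] if single else out
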