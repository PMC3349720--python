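"""Behavioural-mode segmentation of signed move/pause series (Partial Sums).

Moves enter with positive sign and pauses with negative sign, so the
cumulative sum (against the reference value T = 0) drifts upward through
movement-dominated stretches (*relocation*: long moves, short resting
pauses) and downward through pause-dominated stretches (*local search*:
long exploratory pauses, short moves).  Candidate breakpoints sit at local
extrema of the cumulative sum; a minimum wall-clock mode duration epsilon
(default 5 min) prunes extrema that would create shorter segments, keeping
the more extreme of any conflicting pair.  Each resulting segment is
labelled by the sign of its net signed sum.

Averaging segment labels over a cohort at each time point gives the
population probability of each mode through the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .discretize import BoutSequence

__all__ = [
    "SignedBoutSeries",
    "ModeSegmentation",
    "signed_series",
    "partial_sums_segment",
    "mode_probability_curve",
    "epsilon_sensitivity",
    "PartialSumsSegmenter",
]


@dataclass
class SignedBoutSeries:
    """Signed bout durations (+moves, -pauses) with cumulative end times."""

    values: np.ndarray  # signed durations, bout order
    times: np.ndarray  # wall-clock time at each bout END (s)
    t0: float = 0.0  # wall-clock time at series start

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty series")
        if self.values.size != self.times.size:
            raise ValueError("values/times length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must strictly increase")

    @property
    def total_duration(self) -> float:
        return float(self.times[-1] - self.t0)


@dataclass
class ModeSegmentation:
    """Breakpoints (bout indices) and per-segment mode labels."""

    breakpoints: np.ndarray  # indices i: a segment ends after bout i
    labels: list[str]  # per segment: "relocation" | "local_search"
    segment_times: np.ndarray  # shape (n_segments, 2): [start_s, end_s]
    epsilon: float

    @property
    def n_segments(self) -> int:
        return len(self.labels)

    def label_at(self, t: float) -> str | None:
        """Mode label of the segment containing wall-clock time t (None if
        outside the segmented record)."""
        for (s, e), lab in zip(self.segment_times, self.labels):
            if s <= t < e or (t == e and e == self.segment_times[-1][1]):
                return lab
        return None


def signed_series(seq: BoutSequence, block: int | None = None) -> SignedBoutSeries:
    """Signed duration series of one uncensored block (default: first).

    Order is preserved; moves are positive, pauses negative; times are the
    cumulative wall-clock offsets of each bout end from the block start.
    """
    blocks = seq.blocks()
    if not blocks:
        raise ValueError("no bouts")
    chosen = blocks[0 if block is None else block]
    vals = np.asarray([b.duration if b.state == "move" else -b.duration for b in chosen])
    t0 = chosen[0].start_frame * seq.frame_dt
    times = t0 + np.cumsum(np.abs(vals))
    return SignedBoutSeries(values=vals, times=times, t0=t0)


def _candidate_extrema(c: np.ndarray, times: np.ndarray, t0: float, epsilon: float) -> list[int]:
    """Indices where the cumulative sum is a strict local extremum over a
    wall-clock window of at least epsilon/2 on each side."""
    n = c.size
    half = epsilon / 2.0
    out = []
    t = times
    for j in range(n - 1):
        lo = np.searchsorted(t, t[j] - half, side="left")
        hi = np.searchsorted(t, t[j] + half, side="right")
        window = np.concatenate([c[lo:j], c[j + 1 : hi]])
        if window.size == 0:
            continue
        # non-strict: alternating bout signs tie neighbouring partial sums,
        # and the epsilon pruning keeps one representative of a tied run
        if c[j] >= window.max() or c[j] <= window.min():
            # require support on both sides (no extrema hugging the ends)
            if t[j] - t0 >= half and t[-1] - t[j] >= half:
                out.append(j)
    return out


def partial_sums_segment(
    series: SignedBoutSeries, epsilon: float = 300.0, T: float = 0.0
) -> ModeSegmentation:
    """Partial-Sums (CUSUM) segmentation into relocation / local-search modes.

    C_j = sum_{i<=j} (value_i - T); breakpoints are pruned local extrema of
    C (minimum mode duration epsilon); each segment is labelled by the sign
    of its net signed sum, and zero-sum or same-label neighbours merge.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if series.total_duration < 2 * epsilon:
        raise ValueError("record shorter than two modes")
    c = np.cumsum(series.values - T)
    t = series.times
    cands = _candidate_extrema(c, t, series.t0, epsilon)

    accepted: list[int] = []
    for j in cands:
        if not accepted:
            accepted.append(j)
            continue
        prev = accepted[-1]
        if t[j] - t[prev] < epsilon:
            # conflict: keep the more extreme cumulative-sum deviation
            if abs(c[j]) > abs(c[prev]):
                accepted[-1] = j
        else:
            accepted.append(j)
    # keep breakpoints clear of the record ends as well
    accepted = [j for j in accepted if t[j] - series.t0 >= epsilon and t[-1] - t[j] >= epsilon]

    bounds = [-1] + accepted + [len(c) - 1]
    segments, labels, times = [], [], []
    for s, e in zip(bounds[:-1], bounds[1:]):
        start_t = series.t0 if s < 0 else t[s]
        net = c[e] - (0.0 if s < 0 else c[s])
        if net > 0:
            lab = "relocation"
        elif net < 0:
            lab = "local_search"
        else:
            lab = labels[-1] if labels else "local_search"
        if labels and labels[-1] == lab:
            # merge with the preceding same-label segment
            times[-1][1] = t[e]
            segments[-1] = e
            continue
        labels.append(lab)
        times.append([start_t, t[e]])
        segments.append(e)
    return ModeSegmentation(
        breakpoints=np.asarray(segments[:-1], dtype=int),
        labels=labels,
        segment_times=np.asarray(times, dtype=float),
        epsilon=epsilon,
    )


def mode_probability_curve(
    cohort_segs: list[ModeSegmentation], time_grid: np.ndarray
) -> dict[str, np.ndarray]:
    """Population P(relocation, t) and P(local_search, t) over a time grid.

    At each grid time the fraction of individuals whose containing segment
    carries each label; individuals not covering the time are excluded from
    the denominator, and grid points covered by no individual are NaN.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    p_rel = np.full(time_grid.size, np.nan)
    p_loc = np.full(time_grid.size, np.nan)
    n_cov = np.zeros(time_grid.size, dtype=int)
    for i, t in enumerate(time_grid):
        labs = [s.label_at(float(t)) for s in cohort_segs]
        labs = [l for l in labs if l is not None]
        if labs:
            n_cov[i] = len(labs)
            p_rel[i] = sum(l == "relocation" for l in labs) / len(labs)
            p_loc[i] = sum(l == "local_search" for l in labs) / len(labs)
    return {"t": time_grid, "p_relocation": p_rel, "p_local_search": p_loc, "n": n_cov}


def epsilon_sensitivity(
    series: SignedBoutSeries, epsilons: list[float]
) -> dict[float, ModeSegmentation]:
    """Segmentations across candidate minimum-mode durations."""
    return {float(e): partial_sums_segment(series, epsilon=float(e)) for e in epsilons}


class PartialSumsSegmenter(BaseEstimator):
    """sklearn-style estimator for Partial-Sums mode segmentation.

    ``fit(X)`` takes a SignedBoutSeries (or a BoutSequence, converted via
    :func:`signed_series`); fitted attributes hold the breakpoints and
    labels; ``predict(t)`` returns the mode label at wall-clock times t.
    """

    def __init__(self, epsilon: float = 300.0, T: float = 0.0):
        self.epsilon = epsilon
        self.T = T

    def fit(self, X, y=None):
        series = signed_series(X) if isinstance(X, BoutSequence) else X
        seg = partial_sums_segment(series, epsilon=self.epsilon, T=self.T)
        self.segmentation_ = seg
        self.breakpoints_ = seg.breakpoints
        self.labels_ = seg.labels
        return self

    def predict(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.asarray([self.segmentation_.label_at(float(v)) for v in t], dtype=object)
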