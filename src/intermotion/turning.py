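"""Reorientation statistics: turning across and within bouts.

A *turn* is a switch between clockwise and anti-clockwise rotation.  Two
views are quantified:

* **turn after a pause** — comparing the travel direction of the frame
  transitions immediately before and after a pause, as a function of the
  pause length (log-binned probability curve with 95% CIs);
* **turning within a bout** — the proportion of CW/ACW sign changes between
  consecutive transitions a bout owns ("fidgeting" during pauses).

The *influence* of a pause-length bin is its turn probability weighted by
the share of pauses it holds: abundant short pauses can dominate overall
reorientation even at low per-pause probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .discretize import Bout, BoutSequence

__all__ = [
    "TurnCurve",
    "turn_after_pause",
    "turns_within_bout",
    "turn_probability_curve",
    "turn_influence",
    "compare_turn_proportions",
    "default_log_bins",
    "TurnCurveEstimator",
]


@dataclass
class TurnCurve:
    """Log-binned turn-after-pause probability curve."""

    bin_edges: np.ndarray
    mean_probability: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_obs: np.ndarray


def default_log_bins(max_duration: float = 1100.0, frame_dt: float = 0.2) -> np.ndarray:
    """Base-2 log bin edges anchored at one frame (0.2, 0.4, 0.8, ... s)."""
    n = int(np.ceil(np.log2(max_duration / frame_dt))) + 1
    return frame_dt * 2.0 ** np.arange(n + 1)


def turn_after_pause(seq: BoutSequence) -> tuple[np.ndarray, np.ndarray]:
    """(pause durations, turned booleans) for every eligible interior pause.

    A pause is eligible when a move bout flanks it on both sides within the
    same uncensored block; the comparison is between the last transition
    direction of the preceding move and the first of the following move.
    Pauses at block boundaries are excluded (not an error).
    """
    durs, turned = [], []
    for block in seq.blocks():
        for i in range(1, len(block) - 1):
            b = block[i]
            if b.state != "pause":
                continue
            prev_b, next_b = block[i - 1], block[i + 1]
            if prev_b.state != "move" or next_b.state != "move":
                continue
            if b.edge_censored or prev_b.edge_censored or next_b.edge_censored:
                continue
            durs.append(b.duration)
            turned.append(prev_b.directions[-1] != next_b.directions[0])
    return np.asarray(durs), np.asarray(turned, dtype=bool)


def turns_within_bout(bout: Bout) -> dict[str, float | bool | None]:
    """Sign-change summary of the transitions a bout owns.

    ``proportion`` = (#CW/ACW switches) / (#consecutive transition pairs);
    undefined (None) for single-transition bouts.
    """
    d = bout.directions
    if len(d) < 2:
        return {"any_turn": False, "proportion": None}
    switches = np.sum(d[1:] != d[:-1])
    return {
        "any_turn": bool(switches > 0),
        "proportion": float(switches / (len(d) - 1)),
    }


def _binom_ci(p_hat: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95% CI with Wilson fallback for small bins."""
    if n >= 30:
        half = 1.96 * np.sqrt(p_hat * (1 - p_hat) / n)
        return max(0.0, p_hat - half), min(1.0, p_hat + half)
    lo, hi = stats.binomtest(int(round(p_hat * n)), n).proportion_ci(method="wilson")
    return float(lo), float(hi)


def turn_probability_curve(
    durations: np.ndarray, turned: np.ndarray, bins: np.ndarray
) -> TurnCurve:
    """Log-binned mean turn probability with 95% CIs; empty bins are NaN."""
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bin edges must increase")
    durations = np.asarray(durations, dtype=float)
    turned = np.asarray(turned, dtype=bool)
    which = np.digitize(durations, bins) - 1
    n_bins = len(bins) - 1
    mean = np.full(n_bins, np.nan)
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    n_obs = np.zeros(n_bins, dtype=int)
    for i in range(n_bins):
        sel = turned[which == i]
        n_obs[i] = sel.size
        if sel.size:
            p = sel.mean()
            mean[i] = p
            lo[i], hi[i] = _binom_ci(p, sel.size)
    return TurnCurve(bins, mean, lo, hi, n_obs)


def turn_influence(curve: TurnCurve, pause_counts: np.ndarray | None = None) -> np.ndarray:
    """Per-bin influence = mean turn probability x share of pauses in the bin.

    Sums to at most 1; bins with no data contribute 0.
    """
    counts = curve.n_obs if pause_counts is None else np.asarray(pause_counts)
    if len(counts) != len(curve.mean_probability):
        raise ValueError("bin count mismatch between curve and counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("no observations")
    p = np.nan_to_num(curve.mean_probability, nan=0.0)
    return p * counts / total


def compare_turn_proportions(group_a, group_b) -> dict[str, float]:
    """Pooled-variance two-sample Student t-test on within-bout turn
    proportions of two pause-length classes."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "df": float(a.size + b.size - 2), "p": float(p)}


class TurnCurveEstimator(BaseEstimator):
    """sklearn-style estimator of the turn-after-pause probability curve.

    ``fit(X, y)`` takes pause durations X (seconds) and turned booleans y;
    fitted attributes expose the binned curve and per-bin influence.
    """

    def __init__(self, bins: np.ndarray | None = None):
        self.bins = bins

    def fit(self, X, y):
        d = np.asarray(X, dtype=float).ravel()
        turned = np.asarray(y, dtype=bool).ravel()
        bins = self.bins if self.bins is not None else default_log_bins(max(d.max(), 1.0))
        self.curve_ = turn_probability_curve(d, turned, bins)
        self.influence_ = turn_influence(self.curve_)
        self.n_ = d.size
        return self

    def predict(self, X) -> np.ndarray:
        """Binned probability looked up for new pause durations."""
        d = np.asarray(X, dtype=float).ravel()
        which = np.clip(np.digitize(d, self.curve_.bin_edges) - 1, 0,
                        len(self.curve_.mean_probability) - 1)
        return self.curve_.mean_probability[which]
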