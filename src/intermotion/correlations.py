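"""Sequence structure of bout durations: PACF, cross-correlation, pairing.

Durations are log-transformed before correlating (they are heavy-tailed, and
product-moment correlation on raw power-law data is dominated by single
extreme bouts).  The partial autocorrelation at lag k is defined literally
as the last coefficient of the order-k autoregression fitted by least
squares; the +/-1.96/sqrt(n) band is the white-noise null.  Cross-correlation
pairs each move with the pause that immediately follows it, and a shuffle
null re-pairs the two series at random to give per-lag percentile bands.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .discretize import BoutSequence

__all__ = [
    "partial_autocorrelation",
    "cross_correlation",
    "shuffle_null",
    "adjacent_pairs",
    "move_pause_series",
]


def _prep(series, log: bool) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if log:
        if np.any(x <= 0):
            raise ValueError("log transform requires positive durations")
        x = np.log(x)
    if np.var(x) == 0:
        raise ValueError("constant series has undefined correlation")
    return x


def partial_autocorrelation(
    series, max_lag: int, log: bool = True
) -> dict[str, np.ndarray | float]:
    """PACF by successive least-squares autoregressions.

    The lag-k coefficient is the last coefficient of the order-k AR model
    (with intercept) fitted by OLS on the overlapping windows of the series.
    Returns lags 1..max_lag and the white-noise band 1.96/sqrt(n).
    """
    x = _prep(series, log)
    n = x.size
    if n <= max_lag + 10:
        raise ValueError("series too short for the requested lags")
    coefs = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        # rows: x_t regressed on x_{t-1}..x_{t-k} plus intercept
        y = x[k:]
        cols = [np.ones(n - k)] + [x[k - j : n - j] for j in range(1, k + 1)]
        A = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        coefs[k - 1] = beta[-1]
    return {
        "lags": np.arange(1, max_lag + 1),
        "pacf": coefs,
        "band": 1.96 / np.sqrt(n),
        "n": n,
    }


def cross_correlation(
    moves, pauses, max_lag: int, log: bool = True
) -> dict[str, np.ndarray | float]:
    """Pearson correlation of (move_i, pause_{i+lag}) for lags in [-L, L].

    move_i is paired with the pause immediately following it; positive lags
    correlate a move with later pauses.
    """
    m = _prep(moves, log)
    p = _prep(pauses, log)
    n = min(m.size, p.size)
    if n <= max_lag + 10:
        raise ValueError("series too short for the requested lags")
    m, p = m[:n], p[:n]
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = m[: n - lag], p[lag:]
        else:
            a, b = m[-lag:], p[: n + lag]
        if np.var(a) == 0 or np.var(b) == 0:
            raise ValueError("zero variance in a lagged slice")
        r[i] = np.corrcoef(a, b)[0, 1]
    return {"lags": lags, "corr": r, "band": 1.96 / np.sqrt(n), "n": n}


def shuffle_null(
    moves,
    pauses,
    n_shuffles: int = 200,
    max_lag: int = 10,
    rng: np.random.Generator | None = None,
    log: bool = True,
) -> dict[str, np.ndarray]:
    """Permutation null for the move-pause cross-correlation.

    The pause order is permuted ``n_shuffles`` times (>= 100) and the
    cross-correlation recomputed; returns the 2.5/97.5 percentile band per
    lag.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    if rng is None:
        rng = np.random.default_rng(0)
    p = np.asarray(pauses, dtype=float)
    stats = []
    for _ in range(n_shuffles):
        perm = rng.permutation(p)
        stats.append(cross_correlation(moves, perm, max_lag, log=log)["corr"])
    stats = np.asarray(stats)
    return {
        "lags": np.arange(-max_lag, max_lag + 1),
        "lo": np.percentile(stats, 2.5, axis=0),
        "hi": np.percentile(stats, 97.5, axis=0),
    }


def move_pause_series(seq: BoutSequence) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per uncensored block: (ordered move durations, following pause durations).

    move_i pairs with the pause immediately after it; pairs never straddle a
    censored gap.
    """
    out = []
    for block in seq.blocks():
        ms, ps = [], []
        for i in range(len(block) - 1):
            a, b = block[i], block[i + 1]
            if a.state == "move" and b.state == "pause":
                ms.append(a.duration)
                ps.append(b.duration)
        if ms:
            out.append((np.asarray(ms), np.asarray(ps)))
    return out


def adjacent_pairs(seq: BoutSequence) -> pd.DataFrame:
    """One row per interior pause: (pause, preceding move, following move).

    First-order correlations (on log durations) are attached as DataFrame
    attrs; zero-variance cases are flagged as NaN.
    """
    rows = []
    for block in seq.blocks():
        for i in range(1, len(block) - 1):
            b = block[i]
            if b.state != "pause":
                continue
            if block[i - 1].state == "move" and block[i + 1].state == "move":
                rows.append(
                    {
                        "pause_s": b.duration,
                        "prev_move_s": block[i - 1].duration,
                        "next_move_s": block[i + 1].duration,
                    }
                )
    df = pd.DataFrame(rows, columns=["pause_s", "prev_move_s", "next_move_s"])

    def _safe_corr(a, b):
        if len(df) < 2 or np.var(np.log(a)) == 0 or np.var(np.log(b)) == 0:
            return np.nan
        return float(np.corrcoef(np.log(a), np.log(b))[0, 1])

    if len(df):
        df.attrs["corr_prev"] = _safe_corr(df["pause_s"], df["prev_move_s"])
        df.attrs["corr_next"] = _safe_corr(df["pause_s"], df["next_move_s"])
    return df
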