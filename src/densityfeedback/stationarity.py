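"""Return-time statistics and the stationarity index of an abundance series.

A series' long-term mean abundance is taken as a proxy for carrying capacity.
Each time the series crosses that mean contributes one return time T_R,
composed of the number of complete yearly steps since the previous crossing
plus a linearly interpolated fraction of the crossing step,
SF = (N_p - Nbar) / (N_p - N_a).  The stationarity index is mean(T_R) /
var(T_R); an index much below 1 (variance dominating) marks a highly
nonstationary series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ReturnTimeStats", "return_times", "stationarity_index"]


@dataclass
class ReturnTimeStats:
    mean_TR: float
    var_TR: float
    M: int
    index: float  # mean/var; inf when var == 0; nan when M < 2


def return_times(N_t: np.ndarray) -> np.ndarray:
    """Return times of a series around its own mean, one per mean-crossing.

    The first segment counts complete steps from the start of the series.  An
    exact touch of the mean completes a crossing with a full fractional step
    (SF = 1).  A constant series has no defined crossings and raises.
    """
    N = np.asarray(N_t, dtype=float)
    if N.ndim != 1 or len(N) < 2:
        raise ValueError("need a 1-D series of length >= 2")
    s = N - N.mean()
    if np.all(s == 0):
        raise ValueError("constant series: return times undefined")
    prev = s[:-1]
    nxt = s[1:]
    crossing = (prev != 0) & ((prev * nxt < 0) | (nxt == 0))
    idx = np.flatnonzero(crossing)
    if idx.size == 0:
        return np.empty(0)
    # complete steps before each crossing step
    sc = np.empty(idx.size)
    sc[0] = idx[0]
    sc[1:] = np.diff(idx) - 1
    sf = prev[idx] / (prev[idx] - nxt[idx])  # == 1 exactly when nxt == 0
    return sc + sf


def stationarity_index(TRs: np.ndarray) -> ReturnTimeStats:
    """Mean, sample variance (M - 1 denominator) and their ratio."""
    TRs = np.asarray(TRs, dtype=float)
    M = len(TRs)
    if M == 0:
        return ReturnTimeStats(float("nan"), float("nan"), 0, float("nan"))
    mean = float(TRs.mean())
    if M < 2:
        return ReturnTimeStats(mean, float("nan"), M, float("nan"))
    var = float(TRs.var(ddof=1))
    index = float("inf") if var == 0 else mean / var
    return ReturnTimeStats(mean, var, M, index)


def series_stationarity(N_t: np.ndarray) -> ReturnTimeStats:
    """Convenience wrapper: return-time stats straight from a census."""
    return stationarity_index(return_times(N_t))
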