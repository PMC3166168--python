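"""Lagged association rates: temporal persistence of social ties.

The lagged association rate g(tau) estimates the probability that two
individuals associated at time t are still associated tau time units
later.  With A_t the same-group indicator matrix at period t and O_t
the identified-individual indicator, the estimator pools over ordered
dyads (i, j) and period pairs at lag tau:

    g(tau) = sum A_t(i,j) A_{t+tau}(i,j)  /  sum A_t(i,j) O_{t+tau}(i) O_{t+tau}(j)

i.e. of the dyads associated at t and re-identifiable at t + tau, the
fraction still associated.  Frozen groups give g = 1 at every lag;
memoryless association gives g equal to the null rate.

Two time scales are analysed separately: *minute* lags within a single
observation session (no lag spans the gaps between study days) and
*day* lags pairing the same within-session minute across days.

The *null association rate* is the expected g if individuals associated
at random while keeping their observed gregariousness: the mean over
individuals and periods of deg_t(i) / (N_t - 1).

Precision comes from delete-one-block jackknifing over sampling
periods (5-minute blocks within sessions, or whole days), and curves
can be smoothed with a moving average that pools numerator and
denominator contributions across adjacent lags (ratio of sums, never
mean of ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .obsdata import ObservationSet

__all__ = [
    "LARCurve",
    "lar_contributions",
    "lagged_association_rate",
    "lar_curve",
    "null_association_rate",
    "smooth_moving_average",
    "jackknife_se",
]


@dataclass
class LARCurve:
    """Estimated lagged association rate over a lag grid.

    ``num``/``den`` are the raw estimator contributions at each lag, so
    curves can be re-pooled (smoothing, model fitting) without going
    back to the observations.  ``g`` is ``nan`` where ``den == 0``.
    """

    lags: np.ndarray  # strictly increasing, minutes or days
    g: np.ndarray
    num: np.ndarray
    den: np.ndarray
    null_rate: float
    scale: str  # "minute" | "day"
    se: np.ndarray | None = None

    @property
    def n_pairs(self) -> np.ndarray:
        return self.den

    def to_frame(self) -> pd.DataFrame:
        data = {
            "lag": self.lags,
            "g": self.g,
            "num": self.num,
            "n_pairs": self.den,
            "null_rate": self.null_rate,
        }
        if self.se is not None:
            data["se"] = self.se
        return pd.DataFrame(data)


def _period_arrays(obs: ObservationSet, periods: np.ndarray | None = None):
    arr = obs.membership_arrays()
    same = arr["same_group"].astype(np.int64)
    obs_mask = arr["observed"]
    days = np.array([p.day for p in obs.periods])
    minutes = np.array([p.minute for p in obs.periods])
    if periods is not None:
        mask = np.zeros(len(obs.periods), dtype=bool)
        mask[periods] = True
    else:
        mask = np.ones(len(obs.periods), dtype=bool)
    return same, obs_mask, days, minutes, mask


def lar_contributions(
    obs: ObservationSet,
    scale: str = "minute",
    include_periods: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-lag (lags, numerator, denominator) contributions of the estimator.

    ``include_periods`` restricts the pooling to a subset of period
    indices (used by the jackknife); a period pair contributes only if
    both periods are included.
    """
    if scale not in ("minute", "day"):
        raise ValueError(f"unknown LAR scale {scale!r}")
    same, obs_mask, days, minutes, mask = _period_arrays(obs, include_periods)
    contrib: dict[float, list[float]] = {}
    P = same.shape[0]
    idx = np.arange(P)
    if scale == "minute":
        for day in np.unique(days):
            sel = idx[(days == day) & mask]
            order = sel[np.argsort(minutes[sel])]
            mins = minutes[order]
            for a_pos in range(len(order)):
                for b_pos in range(a_pos + 1, len(order)):
                    t1, t2 = order[a_pos], order[b_pos]
                    tau = float(mins[b_pos] - mins[a_pos])
                    _accumulate(contrib, tau, same[t1], same[t2], obs_mask[t2])
    else:
        for minute in np.unique(minutes):
            sel = idx[(minutes == minute) & mask]
            order = sel[np.argsort(days[sel])]
            ds = days[order]
            for a_pos in range(len(order)):
                for b_pos in range(a_pos + 1, len(order)):
                    t1, t2 = order[a_pos], order[b_pos]
                    tau = float(ds[b_pos] - ds[a_pos])
                    _accumulate(contrib, tau, same[t1], same[t2], obs_mask[t2])
    lags = np.array(sorted(contrib))
    num = np.array([contrib[t][0] for t in lags])
    den = np.array([contrib[t][1] for t in lags])
    return lags, num, den


def _accumulate(contrib, tau, same1, same2, obs2) -> None:
    # ordered dyads: symmetric matrices, so the double sum over (i, j)
    # is the full off-diagonal elementwise sum
    n = float((same1 * same2).sum())
    both2 = np.outer(obs2, obs2)
    d = float((same1 * both2).sum())
    if tau not in contrib:
        contrib[tau] = [0.0, 0.0]
    contrib[tau][0] += n
    contrib[tau][1] += d


def lagged_association_rate(
    obs: ObservationSet, tau: float, scale: str = "minute"
) -> tuple[float, int]:
    """g at one lag; returns ``(nan, 0)`` when no pair contributes."""
    lags, num, den = lar_contributions(obs, scale)
    at = np.flatnonzero(lags == tau)
    if at.size == 0 or den[at[0]] == 0:
        return float("nan"), 0
    k = at[0]
    return float(num[k] / den[k]), int(den[k])


def lar_curve(obs: ObservationSet, scale: str = "minute") -> LARCurve:
    """Full lagged-association-rate curve over all realised lags."""
    lags, num, den = lar_contributions(obs, scale)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    return LARCurve(lags, g, num, den, null_association_rate(obs), scale)


def null_association_rate(obs: ObservationSet) -> float:
    """Expected g under random association given observed gregariousness.

    Mean over observed (individual, period) pairs of
    deg_t(i) / (N_t - 1); periods with a single observed individual are
    excluded.
    """
    arr = obs.membership_arrays()
    deg = arr["same_group"].sum(axis=2).astype(float)
    observed = arr["observed"]
    n_t = observed.sum(axis=1)
    vals = []
    for t in range(obs.n_periods):
        if n_t[t] >= 2:
            vals.append(deg[t, observed[t]] / (n_t[t] - 1))
    if not vals:
        return float("nan")
    return float(np.concatenate(vals).mean())


def smooth_moving_average(curve: LARCurve, window: float) -> LARCurve:
    """Moving-average smoothing by pooled contributions.

    At each lag the window grows symmetrically over adjacent lags until
    the pooled denominator reaches ``window`` contributions, and the
    smoothed rate is the ratio of pooled sums.  ``window = 1`` is the
    identity on defined lags; a window larger than the total
    contributions yields the single pooled estimate everywhere.
    """
    if window < 1:
        raise ValueError("smoothing window must be >= 1 contribution")
    K = len(curve.lags)
    g = np.empty(K)
    num_s = np.empty(K)
    den_s = np.empty(K)
    for k in range(K):
        lo = hi = k
        n, d = curve.num[k], curve.den[k]
        while d < window and (lo > 0 or hi < K - 1):
            # expand toward the nearer lag first
            go_left = lo > 0 and (
                hi == K - 1
                or abs(curve.lags[lo - 1] - curve.lags[k]) <= abs(curve.lags[hi + 1] - curve.lags[k])
            )
            if go_left:
                lo -= 1
                n += curve.num[lo]
                d += curve.den[lo]
            else:
                hi += 1
                n += curve.num[hi]
                d += curve.den[hi]
        num_s[k], den_s[k] = n, d
        g[k] = n / d if d > 0 else np.nan
    return replace(curve, g=g, num=num_s, den=den_s, se=None)


def _jackknife_blocks(obs: ObservationSet, block: str) -> list[np.ndarray]:
    """Period indices per delete-one block (5-minute or 1-day blocks)."""
    if block not in ("five_minutes", "one_day"):
        raise ValueError(f"unknown jackknife block {block!r}")
    keys: dict[tuple, list[int]] = {}
    for p in obs.periods:
        key = (p.day,) if block == "one_day" else (p.day, p.minute // 5)
        keys.setdefault(key, []).append(p.index)
    return [np.array(v) for _, v in sorted(keys.items())]


def jackknife_se(
    obs: ObservationSet,
    scale: str = "minute",
    block: str = "five_minutes",
    lags: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Delete-one-block jackknife SEs of g(tau).

    SE^2(tau) = (k - 1)/k * sum_b (g_(-b) - mean_b g_(-b))^2 over the k
    blocks; lags with contributions from fewer than two retained
    replicates get ``nan``.
    Returns ``(lags, se)`` on the full curve's lag grid (or ``lags``).
    """
    blocks = _jackknife_blocks(obs, block)
    k = len(blocks)
    if k < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    if lags is None:
        lags, _, _ = lar_contributions(obs, scale)
    all_idx = np.arange(obs.n_periods)
    loo = np.full((k, len(lags)), np.nan)
    for b, drop in enumerate(blocks):
        keep = np.setdiff1d(all_idx, drop)
        lb, nb, db = lar_contributions(obs, scale, include_periods=keep)
        pos = {t: i for i, t in enumerate(lb)}
        for i, t in enumerate(lags):
            j = pos.get(t)
            if j is not None and db[j] > 0:
                loo[b, i] = nb[j] / db[j]
    se = np.full(len(lags), np.nan)
    for i in range(len(lags)):
        vals = loo[:, i]
        vals = vals[~np.isnan(vals)]
        m = len(vals)
        if m >= 2:
            se[i] = np.sqrt((m - 1) / m * ((vals - vals.mean()) ** 2).sum())
    return np.asarray(lags), se
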