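"""Weighted social network measures on an association matrix.

Five individual-level measures standard for association-index networks:

strength
    s_i = sum_j AI_ij, the total association weight of i (the weighted
    analogue of degree).
eigenvector centrality
    principal eigenvector of the AI matrix, unit Euclidean norm,
    non-negative; high for individuals strongly connected to strongly
    connected neighbours.
reach
    r_i = sum_j AI_ij s_j, two-step connectivity (the strength of i's
    neighbourhood, weighted by i's ties to it).
clustering coefficient
    weighted triple ratio C_i = sum_{j!=k} AI_ij AI_jk AI_ki /
    (max_AI * sum_{j!=k} AI_ij AI_ki), in [0, 1]: 0 when none of i's
    neighbours associate with each other, 1 when the neighbourhood is
    saturated at the network's maximum weight.
affinity
    f_i = r_i / s_i, the mean strength of i's neighbours weighted by
    i's association with them.

Population means of each measure get bootstrap standard errors by
resampling sampling periods with replacement (periods, not individuals,
are the exchangeable sampling unit of a scan study).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationMatrix, association_matrix
from .obsdata import ObservationSet

__all__ = [
    "NetworkMetrics",
    "strength",
    "eigenvector_centrality",
    "reach",
    "clustering_coefficient",
    "affinity",
    "network_metrics",
    "bootstrap_ses",
]

METRIC_NAMES = ("strength", "eigenvector", "reach", "clustering", "affinity")


@dataclass
class NetworkMetrics:
    per_individual: pd.DataFrame  # columns = METRIC_NAMES, index = ids
    means: pd.Series
    ses: pd.Series | None = None
    n_boot: int | None = None


def _clean(am: AssociationMatrix) -> np.ndarray:
    a = np.nan_to_num(am.ai, nan=0.0).astype(float)
    np.fill_diagonal(a, 0.0)
    return a


def strength(am: AssociationMatrix) -> np.ndarray:
    return _clean(am).sum(axis=1)


def eigenvector_centrality(am: AssociationMatrix) -> np.ndarray:
    """Principal eigenvector, unit norm, sign fixed non-negative.

    For a disconnected network this is the Perron vector of the
    dominant component (zeros elsewhere).  A zero matrix has no
    principal direction and raises ``ValueError``.
    """
    a = _clean(am)
    if not np.any(a > 0):
        raise ValueError("eigenvector centrality undefined for an empty network")
    w, v = np.linalg.eigh(a)
    vec = v[:, np.argmax(w)]
    # Perron vector of the dominant component: fix the sign, zero out noise
    if vec.sum() < 0:
        vec = -vec
    vec = np.where(np.abs(vec) < 1e-12, 0.0, vec)
    if vec.min() < -1e-8:
        # degenerate top eigenvalue (symmetric components); fall back to power iteration
        x = np.ones(a.shape[0])
        for _ in range(10000):
            x_new = a @ x
            norm = np.linalg.norm(x_new)
            if norm == 0:
                break
            x_new /= norm
            if np.allclose(x_new, x, atol=1e-14):
                break
            x = x_new
        vec = x
    vec = np.abs(vec)
    return vec / np.linalg.norm(vec)


def reach(am: AssociationMatrix) -> np.ndarray:
    a = _clean(am)
    return a @ a.sum(axis=1)


def clustering_coefficient(am: AssociationMatrix) -> np.ndarray:
    """Weighted clustering; ``nan`` where an individual has < 2 neighbours."""
    a = _clean(am)
    max_ai = a.max()
    num = np.diag(a @ a @ a)  # sum over j != k of AI_ij AI_jk AI_ki
    s = a.sum(axis=1)
    den = max_ai * (s**2 - (a**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    return c


def affinity(am: AssociationMatrix) -> np.ndarray:
    """r_i / s_i; ``nan`` for isolated individuals."""
    s = strength(am)
    r = reach(am)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(s > 0, r / np.where(s > 0, s, 1), np.nan)


def _metric_frame(am: AssociationMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strength": strength(am),
            "eigenvector": eigenvector_centrality(am),
            "reach": reach(am),
            "clustering": clustering_coefficient(am),
            "affinity": affinity(am),
        },
        index=am.ids,
    )


def network_metrics(
    am: AssociationMatrix,
    obs: ObservationSet | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> NetworkMetrics:
    """All five measures per individual, with optional bootstrap SEs.

    Passing ``obs`` with ``n_boot > 0`` activates the period bootstrap.
    The identity mean(strength) = (N - 1) * mean(AI) holds exactly and
    is asserted on every run.
    """
    per = _metric_frame(am)
    means = per.mean()
    mean_ai = float(np.nanmean(am.upper_triangle("ai")))
    assert np.isclose(means["strength"], (am.N - 1) * mean_ai), (
        "strength/mean-AI identity violated; inconsistent association matrix"
    )
    ses = None
    if n_boot and obs is not None:
        ses = bootstrap_ses(obs, n_boot=n_boot, seed=seed, index=am.index)
    return NetworkMetrics(per, means, ses, n_boot or None)


def bootstrap_ses(
    obs: ObservationSet,
    n_boot: int = 1000,
    seed: int | None = None,
    index: str = "simple_ratio",
) -> pd.Series:
    """Bootstrap SEs of the population mean of each network measure.

    Sampling periods are resampled with replacement (preserving
    within-period group structure), the association matrix rebuilt, and
    the mean of each measure recomputed; the SE is the SD across
    replicates.  ``n_boot = 1`` is degenerate and returns zeros.
    """
    if obs.n_periods < 2:
        raise ValueError("bootstrap over sampling periods needs at least 2 periods")
    rng = np.random.default_rng(seed)
    arr = obs.membership_arrays()
    same = arr["same_group"].astype(np.int64)  # (P, N, N)
    observed = arr["observed"].astype(np.int64)  # (P, N)
    P, N = observed.shape
    means = np.empty((n_boot, len(METRIC_NAMES)))
    for b in range(n_boot):
        pick = rng.integers(0, P, size=P)
        x = same[pick].sum(axis=0)
        o = observed[pick]
        both = o.T @ o
        n_obs = o.sum(axis=0)
        denom = n_obs[:, None] + n_obs[None, :] - both
        if index == "half_weight":
            y_ab = both - x
            only = denom - both
            d = x + y_ab + only / 2.0
        else:
            d = denom.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ai = np.where(d > 0, x / np.where(d > 0, d, 1), np.nan)
        np.fill_diagonal(ai, 0.0)
        am = AssociationMatrix(list(obs.ids), ai, denom, x, index)
        try:
            per = _metric_frame(am)
        except ValueError:  # empty resampled network
            means[b] = np.nan
            continue
        means[b] = per.mean().to_numpy()
    ses = np.nanstd(means, axis=0, ddof=0)
    return pd.Series(ses, index=list(METRIC_NAMES), name="bootstrap_se")
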