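"""Dyadic association indices and population-level association summaries.

An association index (AI) estimates the proportion of time two
individuals spend in the same group: 0 = never associated, 1 = always.
The simple ratio index (SRI) is

    SRI = x / (x + y_AB + y_A + y_B)

where, over sampling periods, ``x`` counts periods the dyad was seen in
the same group, ``y_AB`` both seen apart, ``y_A``/``y_B`` only one seen.
Under the complete detection of a lab arena every individual is seen in
every scan, so the denominator is simply the number of periods and the
SRI and half-weight indices coincide.

The module also provides gregariousness (mean experienced group size,
self excluded), the coefficient of variation of the AIs, and social
differentiation *S* — the CV of the *true* underlying association
probabilities after removing binomial sampling noise — with the
associated correlation-power estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .obsdata import ObservationSet

__all__ = [
    "AssociationMatrix",
    "AssociationSummary",
    "simple_ratio_index",
    "half_weight_index",
    "association_matrix",
    "gregariousness",
    "typical_group_size",
    "cv_of_ais",
    "social_differentiation",
    "interpret_differentiation",
    "summarize",
]


@dataclass
class AssociationMatrix:
    """Symmetric dyadic association indices with their count data.

    ``ai[i, j] = x[i, j] / denom[i, j]`` wherever ``denom > 0``; the
    diagonal is zero and dyads never observed have AI ``nan``.
    """

    ids: list[str]
    ai: np.ndarray  # (N, N) float, symmetric, zero diagonal
    denom: np.ndarray  # (N, N) int, per-dyad denominator d_ij
    x: np.ndarray  # (N, N) int, co-occurrence counts
    index: str = "simple_ratio"

    @property
    def N(self) -> int:
        return len(self.ids)

    def upper_triangle(self, what: str = "ai") -> np.ndarray:
        """Off-diagonal upper-triangle values as a flat vector."""
        arr = getattr(self, what)
        iu = np.triu_indices(self.N, k=1)
        return arr[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ai, index=self.ids, columns=self.ids)


@dataclass
class AssociationSummary:
    """Population-level association summary (one population)."""

    mean_ai: float
    cv_ai: float
    gregariousness: pd.Series
    mean_gregariousness: float
    social_differentiation: float
    power_r: float
    differentiation_label: str


def simple_ratio_index(x: int, y_ab: int, y_a: int, y_b: int) -> float:
    """Simple ratio association index x / (x + y_AB + y_A + y_B)."""
    denom = x + y_ab + y_a + y_b
    if denom <= 0:
        raise ValueError("undefined dyad: no sampling period with either individual observed")
    return x / denom


def half_weight_index(x: int, y_ab: int, y_a: int, y_b: int) -> float:
    """Half-weight index x / (x + y_AB + (y_A + y_B)/2).

    Upweights co-occurrences when detection is incomplete; identical to
    the simple ratio when y_A = y_B = 0 (complete detection).
    """
    denom = x + y_ab + (y_a + y_b) / 2.0
    if denom <= 0:
        raise ValueError("undefined dyad: no sampling period with either individual observed")
    return x / denom


def association_matrix(obs: ObservationSet, index: str = "simple_ratio") -> AssociationMatrix:
    """Compute the full dyadic association matrix for one population."""
    if index not in ("simple_ratio", "half_weight"):
        raise ValueError(f"unknown association index {index!r}")
    arr = obs.membership_arrays()
    observed = arr["observed"].astype(np.int64)  # (P, N)
    x = arr["same_group"].astype(np.int64).sum(axis=0)  # (N, N)
    both = observed.T @ observed  # periods both observed
    n_obs = observed.sum(axis=0)  # periods each observed
    either = n_obs[:, None] + n_obs[None, :] - both
    y_ab = both - x
    if index == "simple_ratio":
        denom = either
    else:
        only = either - both  # y_A + y_B
        denom = x + y_ab + only / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(denom > 0, x / np.where(denom > 0, denom, 1), np.nan)
    np.fill_diagonal(ai, 0.0)
    d_int = either.astype(np.int64)
    np.fill_diagonal(d_int, 0)
    xi = x.astype(np.int64)
    np.fill_diagonal(xi, 0)
    return AssociationMatrix(list(obs.ids), ai.astype(float), d_int, xi, index)


def gregariousness(obs: ObservationSet) -> pd.Series:
    """Per-individual gregariousness: mean experienced group size minus one.

    An individual always observed alone has gregariousness 0.  A
    never-observed individual gets ``nan`` with a warning.
    """
    arr = obs.membership_arrays()
    sizes = arr["group_size"].astype(float)  # 0 where unobserved
    seen = arr["observed"]
    counts = seen.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_size = np.where(counts > 0, sizes.sum(axis=0) / np.maximum(counts, 1), np.nan)
    if (counts == 0).any():
        missing = [obs.ids[k] for k in np.flatnonzero(counts == 0)]
        warnings.warn(f"never-observed individuals have undefined gregariousness: {missing}")
    return pd.Series(mean_size - 1.0, index=obs.ids, name="gregariousness")


def typical_group_size(obs: ObservationSet) -> pd.Series:
    """Mean experienced group size including self (gregariousness + 1)."""
    g = gregariousness(obs)
    return (g + 1.0).rename("typical_group_size")


def cv_of_ais(am: AssociationMatrix) -> float:
    """Coefficient of variation (SD/mean) of the off-diagonal AIs.

    Uses the population (divide-by-n) standard deviation: the dyads of
    one study are treated as the complete set, not a sample.
    """
    vals = am.upper_triangle("ai")
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("CV of AIs needs at least two defined dyads")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("CV undefined: mean association index is zero")
    return float(vals.std(ddof=0) / mean)


def social_differentiation(
    am: AssociationMatrix, method: str = "moment"
) -> tuple[float, float]:
    """Estimate social differentiation S and the power correlation r.

    S is the coefficient of variation of the true (noise-free) dyadic
    association probabilities.  The default method-of-moments estimator
    subtracts the expected binomial sampling variance from the observed
    variance of the AIs:

        S^2 = max(0, var(AI) - mean[AI (1 - AI) / d]) / mean(AI)^2

    ``r = S * mean(AI) / sqrt(S^2 mean(AI)^2 + mean[AI(1-AI)/d])`` is the
    implied correlation between true and estimated indices, a power
    measure for detecting the true social system.

    ``method="mle"`` instead fits a beta-binomial by maximum likelihood
    to the per-dyad (x, d) counts and reports the CV of the fitted beta.
    """
    iu = np.triu_indices(am.N, k=1)
    ai = am.ai[iu]
    d = am.denom[iu].astype(float)
    keep = (d > 0) & ~np.isnan(ai)
    ai, d = ai[keep], d[keep]
    if ai.size < 2:
        raise ValueError("social differentiation needs at least two defined dyads")
    mean_ai = ai.mean()
    if mean_ai == 0:
        return 0.0, 0.0
    noise = float(np.mean(ai * (1.0 - ai) / d))
    if method == "moment":
        var_obs = float(ai.var(ddof=0))
        s2 = max(0.0, var_obs - noise) / mean_ai**2
        s = float(np.sqrt(s2))
        if np.all(d <= 1):
            warnings.warn("single sampling period: social differentiation has no power")
            s, s2 = 0.0, 0.0
    elif method == "mle":
        s = _betabinomial_mle_cv(am.x[iu][keep], d)
        s2 = s**2
    else:
        raise ValueError(f"unknown social differentiation method {method!r}")
    denom = s2 * mean_ai**2 + noise
    r = float(s * mean_ai / np.sqrt(denom)) if denom > 0 else 0.0
    return s, min(r, 1.0)


def _betabinomial_mle_cv(x: np.ndarray, d: np.ndarray) -> float:
    """CV of the beta fitted by beta-binomial ML to per-dyad counts."""
    x = np.asarray(x, float)
    d = np.asarray(d, float)

    def nll(params: np.ndarray) -> float:
        la, lb = params
        a, b = np.exp(la), np.exp(lb)
        ll = (
            special.betaln(x + a, d - x + b)
            - special.betaln(a, b)
        )
        return -float(ll.sum())

    m = max(x.sum() / d.sum(), 1e-6)
    best = None
    for scale in (1.0, 10.0, 100.0):
        res = optimize.minimize(
            nll, x0=[np.log(m * scale), np.log((1 - m) * scale)], method="Nelder-Mead"
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    # CV of Beta(a, b): sqrt(b / (a (a + b + 1)))
    return float(np.sqrt(b / (a * (a + b + 1.0))))


# Interpretation bands for S used in the shoaling literature.
_S_BANDS = [(2.0, "extremely differentiated"), (0.5, "well differentiated"), (0.3, "some differentiation")]


def interpret_differentiation(s: float) -> str:
    """Qualitative label for a social differentiation estimate."""
    for cut, label in _S_BANDS:
        if s > cut:
            return label
    return "little variation (homogeneous)"


def summarize(obs: ObservationSet, index: str = "simple_ratio") -> AssociationSummary:
    """Population-level association summary (Table-style row of means)."""
    am = association_matrix(obs, index=index)
    vals = am.upper_triangle("ai")
    mean_ai = float(np.nanmean(vals))
    cv = cv_of_ais(am)
    greg = gregariousness(obs)
    s, r = social_differentiation(am)
    return AssociationSummary(
        mean_ai=mean_ai,
        cv_ai=cv,
        gregariousness=greg,
        mean_gregariousness=float(greg.mean()),
        social_differentiation=s,
        power_r=r,
        differentiation_label=interpret_differentiation(s),
    )
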