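"""Synthetic observation data with known ground truth.

No raw scan data for the original lab populations is publicly
deposited, so every analysis stage is exercised on generated data that
reproduces the study design: N = 12 individuals per population, one
scan per minute for 30 minutes, repeated on 4 study days spaced 3 days
apart.  Four generators cover the statistical structures the analyses
assume:

homogeneous
    every dyad associates independently with one common probability;
    the calibration null for the permutation tests.
beta_dyadic
    dyad-specific association probabilities drawn once from a Beta
    distribution with chosen mean and CV; the fixture for social
    differentiation recovery.
bonded_markov
    each dyad runs a two-state (together/apart) continuous-time Markov
    chain sampled once per minute, with a bonded fraction of dyads on a
    slow dissociation hazard and the rest on a fast one — the mixture
    produces lagged association rates decaying on two time scales.
arena
    a spatially explicit shoal simulator: social units drift in a
    circular arena, fish scatter around their unit with a cohesion
    parameter, units split and merge stochastically, and observed
    groups are extracted per scan by the four-body-length chain rule
    (single-linkage at the association radius, so a shoal of three fish
    can span eight body lengths).

The dyadic generators draw pairwise links and then take connected
components, so observed co-membership slightly exceeds the drawn link
probabilities (chaining); :func:`beta_dyadic_counts` provides the
marginal-exact dyad-level counts used for estimator recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .association import AssociationMatrix
from .larmodels import MODELS, LARModel, evaluate_model
from .obsdata import GroupRecord, Individual, ObservationSet, SamplingPeriod

__all__ = [
    "SimConfig",
    "BondedMarkovParams",
    "ArenaParams",
    "generate_homogeneous",
    "generate_homogeneous_with_pair",
    "generate_beta_dyadic",
    "beta_dyadic_counts",
    "generate_bonded_markov",
    "high_risk_params",
    "low_risk_params",
    "generate_arena",
    "chain_groups",
    "simulate_lar_counts",
    "study_design_lag_weights",
]


@dataclass
class SimConfig:
    """Study-design layout shared by all generators.

    Defaults reproduce the lab protocol: 12 fish, a 30-scan session
    (one per minute) on each of days 1, 4, 7 and 10.
    """

    N: int = 12
    periods_per_day: int = 30
    days: tuple[int, ...] = (1, 4, 7, 10)
    seed: int | None = None
    population: str = "sim"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("need at least 2 individuals")
        if not self.days:
            raise ValueError("need at least one study day")

    @property
    def n_periods(self) -> int:
        return self.periods_per_day * len(self.days)

    def ids(self) -> list[str]:
        return [f"i{k:02d}" for k in range(1, self.N + 1)]

    def periods(self) -> list[SamplingPeriod]:
        out = []
        idx = 0
        for day in self.days:
            for minute in range(self.periods_per_day):
                out.append(SamplingPeriod(idx, day, minute))
                idx += 1
        return out


def _components(adj: np.ndarray) -> np.ndarray:
    """Component label per node for a boolean adjacency matrix."""
    n = adj.shape[0]
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def _obs_from_adjacency(cfg: SimConfig, adj_per_period: np.ndarray) -> ObservationSet:
    """Build a complete-detection ObservationSet from per-period adjacency."""
    ids = cfg.ids()
    individuals = [Individual(i, cfg.population) for i in ids]
    periods = cfg.periods()
    records = []
    for p, adj in zip(periods, adj_per_period):
        labels = _components(adj)
        for g in np.unique(labels):
            members = frozenset(ids[k] for k in np.flatnonzero(labels == g))
            records.append(GroupRecord(p.index, f"g{g}", members))
    return ObservationSet(individuals, periods, records)


def _dyad_index(N: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(N, k=1)


def _adjacency_from_dyads(N: int, states: np.ndarray) -> np.ndarray:
    iu = _dyad_index(N)
    adj = np.zeros((N, N), dtype=bool)
    adj[iu] = states
    return adj | adj.T


# -- homogeneous -------------------------------------------------------------


def generate_homogeneous(cfg: SimConfig, p: float) -> ObservationSet:
    """Independent dyadic association with one common probability.

    ``p = 0`` gives all-singleton scans; ``p = 1`` one group of N every
    scan.  Groups are the connected components of the drawn links.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("association probability must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    n_dyads = cfg.N * (cfg.N - 1) // 2
    adj = np.empty((cfg.n_periods, cfg.N, cfg.N), dtype=bool)
    for t in range(cfg.n_periods):
        adj[t] = _adjacency_from_dyads(cfg.N, rng.random(n_dyads) < p)
    return _obs_from_adjacency(cfg, adj)


def generate_homogeneous_with_pair(
    cfg: SimConfig, p: float, pair: tuple[int, int] = (0, 1)
) -> tuple[ObservationSet, tuple[str, str]]:
    """Homogeneous noise plus one permanently linked dyad.

    The pair's direct link is forced on in every scan (they always share
    a group, possibly with others); every other dyad associates with
    probability ``p``.  Returns the observations and the pair's ids —
    the standard fixture for dyadic preference power.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("association probability must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    iu = _dyad_index(cfg.N)
    forced = (iu[0] == min(pair)) & (iu[1] == max(pair))
    adj = np.empty((cfg.n_periods, cfg.N, cfg.N), dtype=bool)
    for t in range(cfg.n_periods):
        states = rng.random(len(iu[0])) < p
        states |= forced
        adj[t] = _adjacency_from_dyads(cfg.N, states)
    ids = cfg.ids()
    return _obs_from_adjacency(cfg, adj), (ids[pair[0]], ids[pair[1]])


# -- beta-dyadic -------------------------------------------------------------


def _beta_params(mean_p: float, cv: float) -> tuple[float, float]:
    if not 0 < mean_p < 1:
        raise ValueError("mean_p must lie strictly in (0, 1)")
    if cv < 0:
        raise ValueError("CV must be non-negative")
    var = (cv * mean_p) ** 2
    if var >= mean_p * (1 - mean_p):
        raise ValueError(f"no Beta distribution has mean {mean_p} and CV {cv}")
    nu = mean_p * (1 - mean_p) / var - 1.0
    return mean_p * nu, (1 - mean_p) * nu


def generate_beta_dyadic(
    cfg: SimConfig, mean_p: float, s_true: float
) -> tuple[ObservationSet, np.ndarray]:
    """Dyad-specific probabilities drawn once from Beta(mean, CV).

    Returns the observation set and the true probability matrix.
    ``s_true = 0`` reduces to the homogeneous generator.
    """
    rng = np.random.default_rng(cfg.seed)
    iu = _dyad_index(cfg.N)
    if s_true == 0:
        probs = np.full(len(iu[0]), mean_p)
    else:
        a, b = _beta_params(mean_p, s_true)
        probs = rng.beta(a, b, size=len(iu[0]))
    adj = np.empty((cfg.n_periods, cfg.N, cfg.N), dtype=bool)
    for t in range(cfg.n_periods):
        adj[t] = _adjacency_from_dyads(cfg.N, rng.random(len(probs)) < probs)
    pmat = np.zeros((cfg.N, cfg.N))
    pmat[iu] = probs
    pmat = pmat + pmat.T
    return _obs_from_adjacency(cfg, adj), pmat


def beta_dyadic_counts(
    N: int, mean_p: float, s_true: float, d: int, seed: int | None = None
) -> tuple[AssociationMatrix, np.ndarray]:
    """Marginal-exact synthetic dyad counts: x_ij ~ Binomial(d, p_ij).

    Bypasses group formation entirely, so the CV of the true per-dyad
    co-membership probabilities is exactly the Beta CV — the clean
    fixture for social differentiation recovery.
    """
    rng = np.random.default_rng(seed)
    iu = _dyad_index(N)
    if s_true == 0:
        probs = np.full(len(iu[0]), mean_p)
    else:
        a, b = _beta_params(mean_p, s_true)
        probs = rng.beta(a, b, size=len(iu[0]))
    x_flat = rng.binomial(d, probs)
    x = np.zeros((N, N), dtype=np.int64)
    x[iu] = x_flat
    x = x + x.T
    denom = np.full((N, N), d, dtype=np.int64)
    np.fill_diagonal(denom, 0)
    ai = np.where(denom > 0, x / np.maximum(denom, 1), 0.0)
    np.fill_diagonal(ai, 0.0)
    pmat = np.zeros((N, N))
    pmat[iu] = probs
    pmat = pmat + pmat.T
    ids = [f"i{k:02d}" for k in range(1, N + 1)]
    return AssociationMatrix(ids, ai.astype(float), denom, x), pmat


# -- bonded Markov -----------------------------------------------------------


@dataclass
class BondedMarkovParams:
    """Two-class dyadic Markov mixture.

    A ``fraction_bonded`` of dyads hold stable bonds (slow dissociation
    hazard, higher equilibrium association); the rest are casual (fast
    hazard, lower equilibrium).  Hazards are per minute.  Day breaks
    re-equilibrate every chain (no overnight memory), which keeps the
    minute and day scales separable.
    """

    fraction_bonded: float = 0.15
    p_assoc_eq_fast: float = 0.05
    p_assoc_eq_slow: float = 0.45
    rate_fast: float = 1.0
    rate_slow: float = 0.01

    def __post_init__(self) -> None:
        for name in ("fraction_bonded", "p_assoc_eq_fast", "p_assoc_eq_slow"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rate_fast < 0 or self.rate_slow < 0:
            raise ValueError("dissociation hazards must be non-negative")


def high_risk_params() -> BondedMarkovParams:
    """Preset emulating a high-risk-origin population: minute-scale
    fission is rare and bonds persist (slow-decay component dominates)."""
    return BondedMarkovParams(0.18, 0.03, 0.50, 1.0, 0.01)


def low_risk_params() -> BondedMarkovParams:
    """Preset emulating a low-risk-origin population: more short-lived
    associations that break up over a few minutes."""
    return BondedMarkovParams(0.12, 0.08, 0.35, 0.2, 0.02)


def _relaxation(p_eq: float, hazard: float) -> float:
    # CTMC with dissociation hazard mu and equilibrium pi: relaxation
    # rate is mu / (1 - pi) (association rate lambda = mu pi / (1 - pi))
    if p_eq >= 1.0:
        return np.inf
    return hazard / (1.0 - p_eq)


def generate_bonded_markov(
    cfg: SimConfig, params: BondedMarkovParams | None = None
) -> tuple[ObservationSet, dict]:
    """Simulate the two-class dyadic Markov mixture.

    Returns the observations and an ``info`` dict with the class
    assignment, per-class equilibrium/relaxation parameters, and
    ``dyadic_persistence(tau)`` — the exact dyad-level conditional
    probability of still being linked tau minutes after a link,
    mixture-weighted by class prevalence at equilibrium.  Observed
    group co-membership slightly exceeds the dyadic link rate because
    groups are the connected components of the links.
    """
    params = params or BondedMarkovParams()
    rng = np.random.default_rng(cfg.seed)
    iu = _dyad_index(cfg.N)
    n_dyads = len(iu[0])
    bonded = rng.random(n_dyads) < params.fraction_bonded
    pi = np.where(bonded, params.p_assoc_eq_slow, params.p_assoc_eq_fast)
    rho = np.where(
        bonded,
        _relaxation(params.p_assoc_eq_slow, params.rate_slow),
        _relaxation(params.p_assoc_eq_fast, params.rate_fast),
    )
    decay = np.exp(-np.clip(rho, 0, 700))
    p_stay = pi + (1.0 - pi) * decay  # P(1 -> 1) over one minute
    p_gain = pi * (1.0 - decay)  # P(0 -> 1)
    adj = np.empty((cfg.n_periods, cfg.N, cfg.N), dtype=bool)
    t = 0
    for _day in cfg.days:
        states = rng.random(n_dyads) < pi  # re-equilibrated each day
        for _minute in range(cfg.periods_per_day):
            adj[t] = _adjacency_from_dyads(cfg.N, states)
            t += 1
            trans = np.where(states, p_stay, p_gain)
            states = rng.random(n_dyads) < trans

    classes = [
        ("bonded", int(bonded.sum()), params.p_assoc_eq_slow, _relaxation(params.p_assoc_eq_slow, params.rate_slow)),
        ("casual", int((~bonded).sum()), params.p_assoc_eq_fast, _relaxation(params.p_assoc_eq_fast, params.rate_fast)),
    ]
    weights = np.array([n * p for _, n, p, _ in classes], float)
    total = weights.sum()
    weights = weights / total if total > 0 else weights

    def dyadic_persistence(tau):
        tau = np.asarray(tau, float)
        out = np.zeros_like(tau, dtype=float)
        for w, (_, _, p_eq, rate) in zip(weights, classes):
            out = out + w * (p_eq + (1.0 - p_eq) * np.exp(-rate * tau))
        return out

    info = {
        "bonded_dyads": bonded,
        "classes": classes,
        "weights": weights,
        "dyadic_persistence": dyadic_persistence,
    }
    return _obs_from_adjacency(cfg, adj), info


# -- arena -------------------------------------------------------------------


@dataclass
class ArenaParams:
    """Spatial shoal simulator settings (lengths in cm, hazards per minute)."""

    arena_diameter: float = 120.0
    body_length_mm: float = 26.9
    step_sd: float = 8.0  # unit-centre random walk scale
    cohesion: float = 2.0  # >0: fish scatter ~ radius/(2*cohesion); 0: free swimming
    fission_hazard: float = 0.10
    fusion_hazard: float = 0.30

    @property
    def body_length_cm(self) -> float:
        return self.body_length_mm / 10.0

    @property
    def association_radius(self) -> float:
        """Chain-rule radius: four body lengths."""
        return 4.0 * self.body_length_cm


def chain_groups(positions: np.ndarray, radius: float) -> np.ndarray:
    """Group label per individual by single-linkage chaining.

    Two individuals share a group if a chain of pairwise distances
    <= radius connects them (the whole group may span far more than one
    radius end-to-end).
    """
    if len(positions) == 1:
        return np.zeros(1, dtype=int)
    d = squareform(pdist(positions))
    return _components(d <= radius)


def _clip_to_arena(pos: np.ndarray, radius: float) -> np.ndarray:
    r = np.linalg.norm(pos, axis=-1, keepdims=True)
    scale = np.where(r > radius, radius / np.maximum(r, 1e-12), 1.0)
    return pos * scale


def generate_arena(cfg: SimConfig, params: ArenaParams | None = None) -> ObservationSet:
    """Spatially explicit fission-fusion simulation in a circular arena."""
    params = params or ArenaParams()
    rng = np.random.default_rng(cfg.seed)
    R = params.arena_diameter / 2.0
    N = cfg.N
    adj = np.empty((cfg.n_periods, N, N), dtype=bool)
    unit_of = np.zeros(N, dtype=int)  # start as one shoal
    centres = {0: _sample_disc(rng, R)}
    p_fission = 1.0 - np.exp(-params.fission_hazard)
    p_fusion = 1.0 - np.exp(-params.fusion_hazard)
    next_unit = 1
    t = 0
    for _day in cfg.days:
        for _minute in range(cfg.periods_per_day):
            # unit centres drift
            for u in centres:
                centres[u] = _clip_to_arena(centres[u] + rng.normal(0, params.step_sd, 2), R)
            # fission: a multi-member unit splits into two
            for u in list(centres):
                members = np.flatnonzero(unit_of == u)
                if len(members) >= 2 and rng.random() < p_fission:
                    k = rng.integers(1, len(members))
                    leavers = rng.choice(members, size=k, replace=False)
                    unit_of[leavers] = next_unit
                    offset = _sample_direction(rng) * 2.0 * params.association_radius
                    centres[next_unit] = _clip_to_arena(centres[u] + offset, R)
                    next_unit += 1
            # fusion: nearby units merge
            units = sorted(centres)
            for a_i in range(len(units)):
                for b_i in range(a_i + 1, len(units)):
                    ua, ub = units[a_i], units[b_i]
                    if ua not in centres or ub not in centres:
                        continue
                    gap = np.linalg.norm(centres[ua] - centres[ub])
                    if gap < 2.0 * params.association_radius and rng.random() < p_fusion:
                        unit_of[unit_of == ub] = ua
                        centres.pop(ub)
            centres = {u: c for u, c in centres.items() if np.any(unit_of == u)}
            # fish positions
            if params.cohesion > 0:
                spread = params.association_radius / (2.0 * params.cohesion)
                pos = np.stack([centres[unit_of[i]] for i in range(N)])
                pos = _clip_to_arena(pos + rng.normal(0, spread, (N, 2)), R)
            else:
                pos = np.stack([_sample_disc(rng, R) for _ in range(N)])
            labels = chain_groups(pos, params.association_radius)
            adj[t] = labels[:, None] == labels[None, :]
            np.fill_diagonal(adj[t], False)
            t += 1
    return _obs_from_adjacency(cfg, adj)


def _sample_disc(rng: np.random.Generator, radius: float) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, 2)
        if np.linalg.norm(p) <= radius:
            return p


def _sample_direction(rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi)
    return np.array([np.cos(theta), np.sin(theta)])


# -- model-level LAR simulation ----------------------------------------------


def study_design_lag_weights(
    total: int = 120_000, periods_per_day: int = 30, n_days: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Minute-scale lag grid with study-design denominator weights.

    Within a session of P scans, lag tau arises from P - tau ordered
    scan pairs, so denominators fall linearly with lag; ``total``
    contributions are allocated proportionally across all sessions.
    """
    lags = np.arange(1, periods_per_day, dtype=float)
    w = (periods_per_day - lags) * n_days
    den = np.maximum(np.round(total * w / w.sum()), 1).astype(int)
    return lags, den


def simulate_lar_counts(
    model: LARModel | str,
    theta,
    lags: np.ndarray,
    den: np.ndarray,
    seed: int | None = None,
) -> np.ndarray:
    """Binomial estimator contributions from a known g(tau).

    Draws the per-lag numerators N(tau) ~ Binomial(D(tau), g(tau)) —
    the sampling model under which the quasi-likelihood fit is exact.
    """
    rng = np.random.default_rng(seed)
    if isinstance(model, str):
        model = MODELS[model]
    g = np.clip(evaluate_model(model, theta, np.asarray(lags, float)), 0.0, 1.0)
    return rng.binomial(np.asarray(den, int), g)
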