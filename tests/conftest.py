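"""Shared fixtures: random observation sets and brute-force oracles.

The oracles recompute quantities by direct enumeration over the group
records, independently of the array-based implementation paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fissionet.obsdata import GroupRecord, Individual, ObservationSet, SamplingPeriod


def make_random_obs(
    rng: np.random.Generator,
    n_ind: int | None = None,
    n_days: int | None = None,
    periods_per_day: int | None = None,
    complete: bool = True,
) -> ObservationSet:
    """A random valid ObservationSet (small, for enumeration oracles)."""
    n_ind = n_ind or int(rng.integers(3, 9))
    n_days = n_days or int(rng.integers(1, 4))
    periods_per_day = periods_per_day or int(rng.integers(2, 8))
    ids = [chr(ord("A") + k) for k in range(n_ind)]
    individuals = [Individual(i) for i in ids]
    periods = []
    records = []
    idx = 0
    for day in range(1, n_days + 1):
        for minute in range(periods_per_day):
            periods.append(SamplingPeriod(idx, day, minute))
            present = [i for i in ids if complete or rng.random() < 0.8]
            if not present:  # the CSV format cannot express an empty scan
                present = [ids[int(rng.integers(n_ind))]]
            rng.shuffle(present)
            g = 0
            while present:
                size = int(min(len(present), rng.integers(1, n_ind + 1)))
                members, present = present[:size], present[size:]
                records.append(GroupRecord(idx, f"g{g}", frozenset(members)))
                g += 1
            idx += 1
    return ObservationSet(individuals, periods, records)


# -- enumeration oracles -----------------------------------------------------


def oracle_dyad_counts(obs: ObservationSet, i: str, j: str) -> tuple[int, int, int, int]:
    x = y_ab = y_a = y_b = 0
    for p in obs.periods:
        recs = [r for r in obs.records if r.period == p.index]
        gi = next((r for r in recs if i in r.members), None)
        gj = next((r for r in recs if j in r.members), None)
        if gi is not None and gj is not None:
            if gi is gj:
                x += 1
            else:
                y_ab += 1
        elif gi is not None:
            y_a += 1
        elif gj is not None:
            y_b += 1
    return x, y_ab, y_a, y_b


def oracle_ai_matrix(obs: ObservationSet) -> np.ndarray:
    n = obs.N
    ai = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        x, y_ab, y_a, y_b = oracle_dyad_counts(obs, obs.ids[a], obs.ids[b])
        d = x + y_ab + y_a + y_b
        ai[a, b] = ai[b, a] = x / d if d else np.nan
    return ai


def oracle_metrics(ai: np.ndarray) -> dict[str, np.ndarray]:
    """Brute-force loops for strength, reach, clustering, affinity."""
    a = np.nan_to_num(ai, nan=0.0)
    n = a.shape[0]
    s = np.array([sum(a[i, j] for j in range(n) if j != i) for i in range(n)])
    r = np.array([sum(a[i, j] * s[j] for j in range(n) if j != i) for i in range(n)])
    max_ai = a.max()
    c = np.full(n, np.nan)
    for i in range(n):
        num = den = 0.0
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) == 3:
                    num += a[i, j] * a[j, k] * a[k, i]
                    den += a[i, j] * a[i, k]
        if den > 0:
            c[i] = num / (max_ai * den)
    f = np.where(s > 0, r / np.where(s > 0, s, 1), np.nan)
    return {"strength": s, "reach": r, "clustering": c, "affinity": f}


def oracle_lar(obs: ObservationSet, scale: str = "minute") -> dict[float, tuple[float, float]]:
    """Brute-force lagged association rate: per-lag (num, den)."""
    groups: dict[int, dict[str, frozenset]] = {}
    for rec in obs.records:
        groups.setdefault(rec.period, {})
        for m in rec.members:
            groups[rec.period][m] = rec.members
    out: dict[float, list[float]] = {}
    for p1 in obs.periods:
        for p2 in obs.periods:
            if scale == "minute":
                if p1.day != p2.day or p2.minute <= p1.minute:
                    continue
                tau = float(p2.minute - p1.minute)
            else:
                if p1.minute != p2.minute or p2.day <= p1.day:
                    continue
                tau = float(p2.day - p1.day)
            out.setdefault(tau, [0.0, 0.0])  # lag realised by this period pair
            g1 = groups.get(p1.index, {})
            g2 = groups.get(p2.index, {})
            for i in obs.ids:
                for j in obs.ids:
                    if i == j:
                        continue
                    assoc1 = i in g1 and j in g1.get(i, frozenset())
                    if not assoc1:
                        continue
                    if i in g2 and j in g2:  # both identifiable at t2
                        out[tau][1] += 1
                        if j in g2.get(i, frozenset()):
                            out[tau][0] += 1
    return {t: (v[0], v[1]) for t, v in out.items()}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
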