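"""Scan-sampled group observation data.

The core record of a fission-fusion field or lab study is the *scan
sample*: at each sampling period (here, once per minute during a
30-minute session, repeated on several study days) every observed group
of individuals is written down as a set of identity tags.  This module
holds the domain types for such data, a CSV reader/writer, conversion to
the group-by-individual (GBI) matrix used by the permutation null
models, and the per-dyad counts that feed association indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "SamplingPeriod",
    "GroupRecord",
    "ObservationSet",
    "GBIMatrix",
    "ObservationError",
    "read_observations",
    "write_observations",
    "to_gbi",
    "dyad_counts",
]

OBSERVATION_COLUMNS = ("day", "minute", "group_id", "individual_id")


class ObservationError(ValueError):
    """Invalid observation data (format or invariant violation)."""


@dataclass(frozen=True)
class Individual:
    """One recognisable individual (e.g. a VIE-tagged fish).

    ``body_length_mm`` is optional; it matters only for simulators that
    apply the four-body-length chain rule to spatial positions.
    """

    id: str
    population: str = ""
    body_length_mm: float | None = None

    def __post_init__(self) -> None:
        if self.body_length_mm is not None and self.body_length_mm <= 0:
            raise ObservationError(f"body_length_mm must be positive, got {self.body_length_mm}")


@dataclass(frozen=True, order=True)
class SamplingPeriod:
    """One scan sample, identified by (day, minute-within-session)."""

    index: int
    day: int
    minute: int


@dataclass(frozen=True)
class GroupRecord:
    """One observed group in one sampling period.

    Singleton groups are legitimate observations: a lone individual was
    seen and identified, which contributes to association-index
    denominators and counts as an experienced group of size 1.
    """

    period: int  # SamplingPeriod.index
    group_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ObservationError(f"group {self.group_id!r} in period {self.period} is empty")


class ObservationSet:
    """A full set of scan samples for one population.

    Parameters
    ----------
    individuals
        The study individuals.  Ids must be unique.
    periods
        Sampling periods; sorted by ``(day, minute)`` on construction and
        re-indexed ``0..P-1``.
    records
        Observed groups.  Within one period each individual may belong
        to at most one group.
    """

    def __init__(
        self,
        individuals: Sequence[Individual],
        periods: Sequence[SamplingPeriod],
        records: Sequence[GroupRecord],
    ) -> None:
        ids = [ind.id for ind in individuals]
        if len(set(ids)) != len(ids):
            raise ObservationError("individual ids are not unique")
        keys = [(p.day, p.minute) for p in periods]
        if len(set(keys)) != len(keys):
            raise ObservationError("duplicate (day, minute) sampling periods")
        order = np.argsort(np.array(keys, dtype=[("day", int), ("minute", int)]) if keys else [])
        old_to_new = {periods[int(o)].index: rank for rank, o in enumerate(order)}
        self.periods: list[SamplingPeriod] = [
            SamplingPeriod(rank, periods[int(o)].day, periods[int(o)].minute)
            for rank, o in enumerate(order)
        ]
        self.individuals: list[Individual] = list(individuals)
        self.ids: list[str] = ids
        self._id_index = {i: k for k, i in enumerate(ids)}
        self.records: list[GroupRecord] = sorted(
            (GroupRecord(old_to_new[r.period], r.group_id, r.members) for r in records),
            key=lambda r: (r.period, r.group_id),
        )
        self._validate()
        self._cache: dict[str, np.ndarray] | None = None

    # -- basic properties -------------------------------------------------

    @property
    def N(self) -> int:
        """Population size."""
        return len(self.individuals)

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    def id_index(self, individual_id: str) -> int:
        try:
            return self._id_index[individual_id]
        except KeyError:
            raise ObservationError(f"unknown individual id {individual_id!r}") from None

    def _validate(self) -> None:
        if self.N < 2:
            raise ObservationError("an ObservationSet needs at least 2 individuals")
        valid_periods = {p.index for p in self.periods}
        seen: set[tuple[int, str]] = set()
        for rec in self.records:
            if rec.period not in valid_periods:
                raise ObservationError(f"group {rec.group_id!r} references unknown period {rec.period}")
            for m in rec.members:
                if m not in self._id_index:
                    raise ObservationError(
                        f"group {rec.group_id!r} (period {rec.period}) contains unknown individual {m!r}"
                    )
                key = (rec.period, m)
                if key in seen:
                    raise ObservationError(
                        f"individual {m!r} appears in more than one group in period {rec.period}"
                    )
                seen.add(key)

    # -- array views -------------------------------------------------------

    def membership_arrays(self) -> dict[str, np.ndarray]:
        """Dense per-period views used by the analysis modules.

        Returns a dict with:

        ``observed``   (P, N) bool — individual identified in period t
        ``group_of``   (P, N) int32 — within-period group label, -1 if unseen
        ``same_group`` (P, N, N) bool — co-membership, zero diagonal
        ``group_size`` (P, N) int32 — size of own group, 0 if unseen
        """
        if self._cache is not None:
            return self._cache
        P, N = self.n_periods, self.N
        observed = np.zeros((P, N), dtype=bool)
        group_of = np.full((P, N), -1, dtype=np.int32)
        group_size = np.zeros((P, N), dtype=np.int32)
        counters = np.zeros(P, dtype=np.int32)
        for rec in self.records:
            g = counters[rec.period]
            counters[rec.period] += 1
            idx = [self._id_index[m] for m in rec.members]
            observed[rec.period, idx] = True
            group_of[rec.period, idx] = g
            group_size[rec.period, idx] = len(rec.members)
        same = np.zeros((P, N, N), dtype=bool)
        for t in range(P):
            gt = group_of[t]
            eq = (gt[:, None] == gt[None, :]) & (gt[:, None] >= 0)
            np.fill_diagonal(eq, False)
            same[t] = eq
        self._cache = {
            "observed": observed,
            "group_of": group_of,
            "same_group": same,
            "group_size": group_size,
        }
        return self._cache

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ObservationSet(N={self.N}, periods={self.n_periods}, "
            f"groups={len(self.records)})"
        )


@dataclass
class GBIMatrix:
    """Group-by-individual matrix: rows are observed groups, columns individuals.

    ``row_period`` and ``row_day`` tag each group row with its sampling
    period index and study day; the swap null models permute rows within
    a day.
    """

    matrix: np.ndarray  # (G, N) uint8
    ids: list[str]
    row_period: np.ndarray  # (G,) int32
    row_day: np.ndarray  # (G,) int32
    row_labels: list[str]

    @property
    def n_groups(self) -> int:
        return self.matrix.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_labels, columns=self.ids)


def to_gbi(obs: ObservationSet) -> GBIMatrix:
    """Convert an ObservationSet into its GBI matrix.

    One row per observed group (in period order); cell = 1 iff the
    individual is a member.  An empty record list yields a 0-row matrix.
    """
    G, N = len(obs.records), obs.N
    mat = np.zeros((G, N), dtype=np.uint8)
    row_period = np.zeros(G, dtype=np.int32)
    row_day = np.zeros(G, dtype=np.int32)
    labels = []
    period_by_index = {p.index: p for p in obs.periods}
    for r, rec in enumerate(obs.records):
        for m in rec.members:
            mat[r, obs.id_index(m)] = 1
        p = period_by_index[rec.period]
        row_period[r] = rec.period
        row_day[r] = p.day
        labels.append(f"d{p.day}_m{p.minute}_{rec.group_id}")
    return GBIMatrix(mat, list(obs.ids), row_period, row_day, labels)


def dyad_counts(obs: ObservationSet, i: str, j: str) -> tuple[int, int, int, int]:
    """Per-dyad sampling-period counts ``(x, y_AB, y_A, y_B)``.

    ``x``    periods with i and j in the same group,
    ``y_AB`` periods with both observed but in different groups,
    ``y_A``  periods with only i observed, ``y_B`` only j.
    Periods where neither is observed contribute to none of the four.
    """
    if i == j:
        raise ObservationError("dyad_counts requires two distinct individuals")
    a, b = obs.id_index(i), obs.id_index(j)
    arr = obs.membership_arrays()
    oi, oj = arr["observed"][:, a], arr["observed"][:, b]
    together = arr["same_group"][:, a, b]
    x = int(together.sum())
    y_ab = int((oi & oj & ~together).sum())
    y_a = int((oi & ~oj).sum())
    y_b = int((oj & ~oi).sum())
    return x, y_ab, y_a, y_b


# -- file I/O ----------------------------------------------------------------


def read_observations(
    path: str | Path,
    population: str = "",
) -> ObservationSet:
    """Read an observation CSV (``day,minute,group_id,individual_id``).

    Lines starting with ``#`` are treated as comments (provenance
    headers written by :func:`write_observations`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"observation file not found: {path}")
    df = pd.read_csv(path, comment="#", dtype={"group_id": str, "individual_id": str})
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationError(f"observation file {path} lacks columns: {', '.join(missing)}")
    return observations_from_frame(df, population=population)


def observations_from_frame(df: pd.DataFrame, population: str = "") -> ObservationSet:
    """Build an ObservationSet from a long-format frame (one row per member)."""
    ids = sorted(df["individual_id"].astype(str).unique())
    individuals = [Individual(i, population) for i in ids]
    period_keys = sorted({(int(d), int(m)) for d, m in zip(df["day"], df["minute"])})
    period_index = {k: n for n, k in enumerate(period_keys)}
    periods = [SamplingPeriod(n, d, m) for (d, m), n in period_index.items()]
    records = []
    grouped = df.groupby(["day", "minute", "group_id"], sort=True)
    for (day, minute, gid), sub in grouped:
        members = list(sub["individual_id"].astype(str))
        if len(set(members)) != len(members):
            dup = sub["individual_id"][sub["individual_id"].duplicated()].iloc[0]
            raise ObservationError(
                f"individual {dup!r} listed twice in group {gid!r} (day {day}, minute {minute})"
            )
        records.append(
            GroupRecord(period_index[(int(day), int(minute))], str(gid), frozenset(members))
        )
    return ObservationSet(individuals, periods, records)


def write_observations(obs: ObservationSet, path: str | Path, header: str | None = None) -> None:
    """Write observation CSV, rows sorted by (day, minute, group_id)."""
    period_by_index = {p.index: p for p in obs.periods}
    rows = []
    for rec in obs.records:
        p = period_by_index[rec.period]
        for m in sorted(rec.members):
            rows.append((p.day, p.minute, rec.group_id, m))
    rows.sort()
    df = pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
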