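"""Domain types for collective group-departure data.

The unit of analysis is an individually marked group member.  A *departure
event* is one group movement: an initiator leaves, and every other member
either joins within a fixed window (a *follower*, with a latency in seconds
from initiation) or does not.  Affiliative relationships are measured from
instantaneous *group scans* recording which individuals were visible and
which dyads were grooming or huddling.  Dyadic statistics (rates, DSI, IDI)
live in a symmetric :class:`DyadMatrix` with per-dyad support counts.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

#: Followers must depart within this many seconds of the initiator.
JOINING_WINDOW_S: float = 600.0


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


class AgeSexClass(str, enum.Enum):
    """Age-sex class of an individual (juveniles are animals < 2.5 years)."""

    ADULT_FEMALE = "adult_female"
    ADULT_MALE = "adult_male"
    JUVENILE = "juvenile"

    @classmethod
    def parse(cls, text: str) -> "AgeSexClass":
        try:
            return cls(text.strip())
        except ValueError:
            raise ValidationError(f"unknown age-sex class: {text!r}") from None


class DistanceCategory(enum.Enum):
    """Ordinal inter-individual distance category.

    Five half-open bins with edges 0, 1, 3, 5, 10 m; the last bin is
    unbounded.  Each level carries a numeric midpoint in metres for
    ordinal-as-numeric analyses (15 m is used for the open-ended bin).
    """

    D0_1 = ("0-1", 0.0, 1.0, 0.5)
    D1_3 = ("1-3", 1.0, 3.0, 2.0)
    D3_5 = ("3-5", 3.0, 5.0, 4.0)
    D5_10 = ("5-10", 5.0, 10.0, 7.5)
    D_GT10 = (">10", 10.0, math.inf, 15.0)

    def __init__(self, label: str, lo: float, hi: float, midpoint: float):
        self.label = label
        self.lo_m = lo
        self.hi_m = hi
        self.midpoint_m = midpoint

    @property
    def order(self) -> int:
        return list(type(self)).index(self)

    def __lt__(self, other: "DistanceCategory") -> bool:
        return self.order < other.order

    @classmethod
    def from_label(cls, label: str) -> "DistanceCategory":
        for cat in cls:
            if cat.label == label.strip():
                return cat
        raise ValidationError(f"unknown distance category: {label!r}")

    @classmethod
    def from_distance(cls, metres: float) -> "DistanceCategory":
        if metres < 0 or not math.isfinite(metres):
            raise ValidationError(f"invalid distance: {metres}")
        for cat in cls:
            if cat.lo_m <= metres < cat.hi_m:
                return cat
        return cls.D_GT10


@dataclass(frozen=True)
class Individual:
    id: str
    group_id: str
    age_sex_class: AgeSexClass


@dataclass(frozen=True)
class GroupComposition:
    """A group roster: member individuals and their age-sex class counts."""

    group_id: str
    members: tuple[Individual, ...]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate individual ids in group {self.group_id}")
        if len(ids) < 2:
            raise ValidationError(f"group {self.group_id} needs at least 2 members")
        for m in self.members:
            if m.group_id != self.group_id:
                raise ValidationError(
                    f"member {m.id} has group {m.group_id!r}, expected {self.group_id!r}"
                )

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.members)

    def class_counts(self) -> dict[AgeSexClass, int]:
        counts = {c: 0 for c in AgeSexClass}
        for m in self.members:
            counts[m.age_sex_class] += 1
        return counts

    def class_of(self, individual_id: str) -> AgeSexClass:
        for m in self.members:
            if m.id == individual_id:
                return m.age_sex_class
        raise KeyError(individual_id)


def competition_ranks(latencies: Mapping[str, float]) -> dict[str, int]:
    """Competition ("1224") ranks of departure latencies.

    Ties share the minimum rank and subsequent ranks are skipped, so two
    individuals departing at the same second are both, e.g., rank 2 and the
    next departer is rank 4.
    """
    ordered = sorted(latencies.items(), key=lambda kv: kv[1])
    ranks: dict[str, int] = {}
    for pos, (ind, lat) in enumerate(ordered):
        if pos > 0 and lat == ordered[pos - 1][1]:
            ranks[ind] = ranks[ordered[pos - 1][0]]
        else:
            ranks[ind] = pos + 1
    return ranks


@dataclass
class DepartureRecord:
    """One individual's outcome in one departure event.

    ``latency_s`` is seconds from initiation (0 for the initiator, ``None``
    for non-joiners).  ``rank`` is the competition rank of the departure
    (1 = initiator).  Distance categories may be missing when not recorded.
    """

    event_id: str
    individual_id: str
    joined: bool
    is_initiator: bool = False
    latency_s: float | None = None
    rank: int | None = None
    dist_to_initiator: DistanceCategory | None = None
    dist_to_predecessor: DistanceCategory | None = None

    def validate(self, window_s: float = JOINING_WINDOW_S) -> None:
        if self.is_initiator:
            if not self.joined:
                raise ValidationError(f"{self.event_id}/{self.individual_id}: initiator must be joined")
            if self.latency_s != 0:
                raise ValidationError(
                    f"{self.event_id}/{self.individual_id}: initiator latency must be 0"
                )
            if self.rank != 1:
                raise ValidationError(f"{self.event_id}/{self.individual_id}: initiator rank must be 1")
        if self.joined:
            if self.latency_s is None:
                raise ValidationError(
                    f"{self.event_id}/{self.individual_id}: joined record missing latency"
                )
            if self.latency_s < 0:
                raise ValidationError(f"{self.event_id}/{self.individual_id}: negative latency")
            if self.latency_s > window_s:
                raise ValidationError(
                    f"{self.event_id}/{self.individual_id}: latency {self.latency_s} s exceeds "
                    f"the {window_s:.0f} s joining window but record is flagged joined "
                    "(ambiguous record)"
                )
        else:
            if self.latency_s is not None:
                raise ValidationError(
                    f"{self.event_id}/{self.individual_id}: non-joiner must not carry a latency"
                )


@dataclass
class DepartureEvent:
    """One group movement: records for every group member.

    Exactly one record is the initiator; ``n_followers`` counts the other
    joiners.  Joiner ranks are recomputed from latencies with competition
    ranking on construction.
    """

    event_id: str
    group_id: str
    records: list[DepartureRecord]

    def __post_init__(self) -> None:
        ids = [r.individual_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"event {self.event_id}: duplicate individual rows")
        initiators = [r for r in self.records if r.is_initiator]
        if len(initiators) != 1:
            raise ValidationError(
                f"event {self.event_id}: expected exactly 1 initiator, found {len(initiators)}"
            )
        # recompute joiner ranks from latencies (competition ranking)
        lat = {
            r.individual_id: float(r.latency_s)
            for r in self.records
            if r.joined and r.latency_s is not None
        }
        ranks = competition_ranks(lat)
        for r in self.records:
            r.rank = ranks.get(r.individual_id)
        for r in self.records:
            r.validate()
        if initiators[0].rank != 1:
            raise ValidationError(
                f"event {self.event_id}: a joiner departs before the initiator"
            )

    @property
    def initiator_id(self) -> str:
        return next(r.individual_id for r in self.records if r.is_initiator)

    @property
    def joiners(self) -> list[DepartureRecord]:
        """Joined records in departure order (rank, then latency, then id)."""
        return sorted(
            (r for r in self.records if r.joined),
            key=lambda r: (r.rank, r.latency_s, r.individual_id),
        )

    @property
    def followers(self) -> list[DepartureRecord]:
        return [r for r in self.joiners if not r.is_initiator]

    @property
    def n_followers(self) -> int:
        return sum(r.joined for r in self.records) - 1

    @property
    def group_size(self) -> int:
        return len(self.records)

    @property
    def is_full_group(self) -> bool:
        return self.n_followers == self.group_size - 1


@dataclass(frozen=True)
class Scan:
    """One instantaneous group scan: visible individuals and interacting dyads."""

    scan_id: str
    group_id: str
    visible_ids: frozenset[str]
    grooming_dyads: frozenset[frozenset[str]] = frozenset()
    huddling_dyads: frozenset[frozenset[str]] = frozenset()

    def __post_init__(self) -> None:
        for name, dyads in (("grooming", self.grooming_dyads), ("huddling", self.huddling_dyads)):
            for dyad in dyads:
                if len(dyad) != 2:
                    raise ValidationError(f"scan {self.scan_id}: {name} dyad must have 2 ids")
                if not dyad <= self.visible_ids:
                    raise ValidationError(
                        f"scan {self.scan_id}: {name} dyad {sorted(dyad)} not within visible ids"
                    )


@dataclass
class ScanDataset:
    scans: list[Scan]

    def __iter__(self) -> Iterator[Scan]:
        return iter(self.scans)

    def __len__(self) -> int:
        return len(self.scans)

    def group_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.scans:
            seen.setdefault(s.group_id, None)
        return list(seen)

    def for_group(self, group_id: str) -> "ScanDataset":
        return ScanDataset([s for s in self.scans if s.group_id == group_id])

    def individual_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.scans:
            for i in sorted(s.visible_ids):
                seen.setdefault(i, None)
        return list(seen)


def dyad_key(x: str, y: str) -> tuple[str, str]:
    """Canonical unordered dyad key."""
    if x == y:
        raise ValidationError(f"self-dyad not allowed: {x!r}")
    return (x, y) if x < y else (y, x)


class DyadMatrix:
    """Symmetric within-group dyadic values with per-dyad support counts.

    Support is the number of observations the value rests on (co-visible
    scans for interaction rates, co-departure movements for the IDI).  A
    dyad with zero support is *missing*, never imputed as 0.
    """

    def __init__(self, group_id: str, label: str = ""):
        self.group_id = group_id
        self.label = label
        self._values: dict[tuple[str, str], float] = {}
        self._support: dict[tuple[str, str], int] = {}

    def set(self, x: str, y: str, value: float | None, support: int = 0) -> None:
        key = dyad_key(x, y)
        if support < 0:
            raise ValidationError("support must be non-negative")
        self._support[key] = int(support)
        if value is None:
            self._values.pop(key, None)
        else:
            if support == 0:
                raise ValidationError(
                    f"dyad {key}: value with zero support (missing values are never imputed)"
                )
            self._values[key] = float(value)

    def value(self, x: str, y: str) -> float | None:
        return self._values.get(dyad_key(x, y))

    def support(self, x: str, y: str) -> int:
        return self._support.get(dyad_key(x, y), 0)

    def dyads(self) -> list[tuple[str, str]]:
        return sorted(self._support)

    def defined_dyads(self) -> list[tuple[str, str]]:
        return sorted(self._values)

    def defined_values(self) -> list[float]:
        return [self._values[k] for k in sorted(self._values)]

    def ids(self) -> list[str]:
        out: set[str] = set()
        for x, y in self._support:
            out.update((x, y))
        return sorted(out)

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        for key in sorted(self._values):
            yield key, self._values[key]

    def __len__(self) -> int:
        return len(self._support)

    def __contains__(self, pair: Iterable[str]) -> bool:
        x, y = pair
        return dyad_key(x, y) in self._values
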