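"""Departure-order metrics: IDI, position categories, cohesion, occupancy.

The inter-departure interval (IDI) of a dyad is its mean absolute
departure-time difference across movements, each movement normalized by
that movement's mean absolute pairwise departure-time difference:

    IDI_xy = (1/n) * sum_i |t_xi - t_yi| / m_i

where m_i is the mean of |t_a - t_b| over all joiner dyads of movement i
and the sum runs over the n movements in which both x and y joined.  A
dyad that departs in close succession has a small IDI; the average of the
normalized differences over all joiner dyads of one movement is exactly 1.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    DepartureEvent,
    DistanceCategory,
    DyadMatrix,
    GroupComposition,
    ValidationError,
    dyad_key,
)

logger = logging.getLogger(__name__)


def compute_idi(events: list[DepartureEvent]) -> dict[str, DyadMatrix]:
    """IDI matrices per group from a list of departure events.

    Movements with fewer than two joiners carry no pairwise information and
    are skipped with a warning; so are movements whose joiners all departed
    at the same recorded second (zero mean difference).  Support counts the
    movements contributing to each dyad.
    """
    sums: dict[str, dict[tuple[str, str], float]] = {}
    counts: dict[str, dict[tuple[str, str], int]] = {}
    members: dict[str, set[str]] = {}
    for event in events:
        gid = event.group_id
        members.setdefault(gid, set()).update(r.individual_id for r in event.records)
        joiners = [(r.individual_id, float(r.latency_s)) for r in event.joiners]
        if len(joiners) < 2:
            logger.warning("event %s: fewer than 2 joiners; skipped for IDI", event.event_id)
            continue
        diffs = [abs(a[1] - b[1]) for a, b in combinations(joiners, 2)]
        m_i = float(np.mean(diffs))
        if m_i == 0:
            logger.warning(
                "event %s: all joiners departed simultaneously; skipped for IDI",
                event.event_id,
            )
            continue
        g_sums = sums.setdefault(gid, {})
        g_counts = counts.setdefault(gid, {})
        for (x, tx), (y, ty) in combinations(joiners, 2):
            key = dyad_key(x, y)
            g_sums[key] = g_sums.get(key, 0.0) + abs(tx - ty) / m_i
            g_counts[key] = g_counts.get(key, 0) + 1

    out: dict[str, DyadMatrix] = {}
    for gid in sorted(members):
        matrix = DyadMatrix(gid, label="idi")
        ids = sorted(members[gid])
        g_sums = sums.get(gid, {})
        g_counts = counts.get(gid, {})
        for x, y in combinations(ids, 2):
            key = dyad_key(x, y)
            n = g_counts.get(key, 0)
            if n == 0:
                matrix.set(x, y, None, support=0)
            else:
                matrix.set(x, y, g_sums[key] / n, support=n)
        out[gid] = matrix
    return out


class PositionCategory(str, enum.Enum):
    """Departure-order position: van (first two movers), rear (last two),
    centre (remaining joiners), or not joined."""

    VAN = "van"
    CENTRE = "centre"
    REAR = "rear"
    NOT_JOINED = "not_joined"


def assign_positions(event: DepartureEvent) -> dict[str, PositionCategory]:
    """Map each group member of one event to its position category.

    Joiners are ordered by competition rank (latency ties broken by id so
    the partition is deterministic).  The first two are the van and the
    last two of the remainder the rear; when four or fewer individuals
    join, van takes precedence and the centre may be empty.
    """
    order = [r.individual_id for r in event.joiners]
    positions = {
        r.individual_id: PositionCategory.NOT_JOINED for r in event.records if not r.joined
    }
    van, rest = order[:2], order[2:]
    rear = rest[-2:] if rest else []
    centre = rest[: len(rest) - len(rear)]
    for ind in van:
        positions[ind] = PositionCategory.VAN
    for ind in centre:
        positions[ind] = PositionCategory.CENTRE
    for ind in rear:
        positions[ind] = PositionCategory.REAR
    return positions


@dataclass
class PositionScores:
    """Per-individual fraction of events spent in each position category."""

    individual_id: str
    proportions: dict[PositionCategory, float]
    n_events_observed: int


def position_scores(
    events: list[DepartureEvent], group: GroupComposition
) -> dict[str, PositionScores]:
    """Position-category proportions per individual over a group's events."""
    counts: dict[str, Counter] = {i: Counter() for i in group.member_ids}
    n_events: dict[str, int] = {i: 0 for i in group.member_ids}
    for event in events:
        if event.group_id != group.group_id:
            continue
        for ind, pos in assign_positions(event).items():
            if ind in counts:
                counts[ind][pos] += 1
                n_events[ind] += 1
    out = {}
    for ind in group.member_ids:
        if n_events[ind] == 0:
            raise ValidationError(f"individual {ind} observed in no events")
        out[ind] = PositionScores(
            individual_id=ind,
            proportions={p: counts[ind][p] / n_events[ind] for p in PositionCategory},
            n_events_observed=n_events[ind],
        )
    return out


@dataclass
class CohesionSummary:
    """Group-cohesion statistics over successful movements."""

    median_join_latency_s: float
    iqr_join_latency_s: tuple[float, float]
    last_follower_latency_s: list[float]  # full-group events only
    follower_count_histogram: dict[int, int]
    full_group_fraction: float
    n_events: int


def follower_histogram(events: list[DepartureEvent]) -> tuple[dict[int, int], float]:
    """Histogram of follower counts and the fraction of full-group events."""
    if not events:
        raise ValidationError("no events")
    hist: Counter = Counter()
    full = 0
    for event in events:
        if event.n_followers < 1:
            raise ValidationError(f"event {event.event_id}: not a successful movement")
        hist[event.n_followers] += 1
        if event.is_full_group:
            full += 1
    return dict(sorted(hist.items())), full / len(events)


def chi_square_homogeneity(
    histogram: dict[int, int], group_size: int
) -> tuple[float, int, float]:
    """Pearson chi-square of the follower-count distribution against uniform.

    Expected counts are uniform over all possible follower counts
    1..group_size-1 (df = group_size - 2), including categories never
    observed.  A large statistic rejects homogeneity, the signature of an
    all-or-nothing joining process.
    """
    if group_size < 3:
        raise ValidationError("chi-square homogeneity needs group_size >= 3")
    categories = range(1, group_size)
    bad = [k for k in histogram if k not in categories]
    if bad:
        raise ValidationError(f"follower counts {bad} outside 1..{group_size - 1}")
    observed = np.array([histogram.get(k, 0) for k in categories], dtype=float)
    total = observed.sum()
    if total < 1:
        raise ValidationError("empty histogram")
    expected = np.full(len(observed), total / len(observed))
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = group_size - 2
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def cohesion_summary(events: list[DepartureEvent]) -> CohesionSummary:
    """Median/IQR follower latency, follower-count histogram, and the
    per-event last-follower latency restricted to full-group movements."""
    if not events:
        raise ValidationError("no events")
    latencies = [float(r.latency_s) for ev in events for r in ev.followers]
    if not latencies:
        raise ValidationError("no followers in any event")
    hist, full_fraction = follower_histogram(events)
    last = [
        max(float(r.latency_s) for r in ev.followers) for ev in events if ev.is_full_group
    ]
    q1, med, q3 = np.percentile(latencies, [25, 50, 75])
    return CohesionSummary(
        median_join_latency_s=float(med),
        iqr_join_latency_s=(float(q1), float(q3)),
        last_follower_latency_s=last,
        follower_count_histogram=hist,
        full_group_fraction=full_fraction,
        n_events=len(events),
    )


def distance_occupancy(
    events: list[DepartureEvent], group: GroupComposition
) -> pd.DataFrame:
    """Per-individual proportion of observations in each distance-to-initiator
    category.

    Initiators are excluded from their own events; individuals without any
    recorded distance observation are absent from the result (missing, not
    zero).  Rows sum to 1.
    """
    counts: dict[str, Counter] = {}
    for event in events:
        if event.group_id != group.group_id:
            continue
        for r in event.records:
            if r.is_initiator or r.dist_to_initiator is None:
                continue
            counts.setdefault(r.individual_id, Counter())[r.dist_to_initiator] += 1
    if not counts:
        raise ValidationError("no distance-to-initiator observations")
    rows = {}
    for ind in sorted(counts):
        total = sum(counts[ind].values())
        rows[ind] = {cat.label: counts[ind][cat] / total for cat in DistanceCategory}
    return pd.DataFrame.from_dict(rows, orient="index")[
        [c.label for c in DistanceCategory]
    ]
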