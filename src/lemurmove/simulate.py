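"""Agent-based generator of group departures under configurable mimetism.

The generator produces the three ingredients the analysis pipeline consumes
— group rosters, scan datasets and departure events — from a known latent
affiliation network, so that every downstream statistic can be checked by
parameter recovery.

Mechanism.  Each group carries a latent symmetric affiliation weight
``w_xy >= 0`` (right-skewed gamma, scaled to group mean 1).  Scans read the
weights out through per-scan Bernoulli grooming/huddling draws.  For each
movement, spatial positions are drawn afresh, an initiator is sampled with
a female bias, and the remaining members join in continuous time with a
log-linear hazard (Gillespie competing-risks sampling):

    lambda_j(t) = lambda0 * exp( beta_anonymous   * n_departed(t)
                               + beta_affiliative * sum_{k departed} w_jk
                               - beta_spatial     * s_j )

where ``s_j`` in [0, 1] is the scaled rank of j's distance to the most
recent departer (0 = nearest).  Individuals still present after the joining
window are recorded as not joined.  With all betas zero, joiner identities
are exchangeable and inter-departure waits are Exp(n_remaining * lambda0).
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import io as lio
from .datatypes import (
    AgeSexClass,
    DepartureEvent,
    DepartureRecord,
    DistanceCategory,
    DyadMatrix,
    GroupComposition,
    Individual,
    Scan,
    ScanDataset,
    ValidationError,
    dyad_key,
)

#: Study-design defaults: four groups (females, males, juveniles),
#: per-group movement counts and per-group scan counts.
DEFAULT_GROUPS: tuple[tuple[int, int, int], ...] = ((3, 3, 2), (2, 2, 2), (2, 2, 2), (4, 3, 4))
DEFAULT_EVENTS_PER_GROUP: tuple[int, ...] = (49, 37, 35, 46)
DEFAULT_SCANS_PER_GROUP: tuple[int, ...] = (199, 200, 181, 279)


@dataclass
class SimulationConfig:
    """Parameters of the departure simulator.

    Rates are per second; the joining window is seconds.  ``groups`` lists
    (n_females, n_males, n_juveniles) per group.  ``n_events_per_group`` and
    ``n_scans_per_group`` may be a single integer applied to every group or
    one integer per group.
    """

    seed: int = 0
    groups: Sequence[tuple[int, int, int]] = DEFAULT_GROUPS
    n_events_per_group: int | Sequence[int] = DEFAULT_EVENTS_PER_GROUP
    n_scans_per_group: int | Sequence[int] = DEFAULT_SCANS_PER_GROUP
    window_s: float = 600.0
    base_rate: float = 0.0012
    beta_affiliative: float = 0.55
    beta_spatial: float = 1.5
    beta_anonymous: float = 0.1
    female_initiator_weight: float = 4.0
    juvenile_centrality: float = 1.5
    male_peripherality: float = 0.5
    affiliation_shape: float = 0.5
    scan_visibility_p: float = 0.85
    interaction_scale: float = 0.08
    affiliation_distance_coupling: float = 0.5
    layout_radius_m: float = 7.5

    def __post_init__(self) -> None:
        if self.base_rate < 0 or not np.isfinite(self.base_rate):
            raise ValidationError("base_rate must be finite and >= 0")
        for name in ("beta_affiliative", "beta_spatial", "beta_anonymous"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.female_initiator_weight < 1:
            raise ValidationError("female_initiator_weight must be >= 1")
        if self.juvenile_centrality < 0 or self.male_peripherality < 0:
            raise ValidationError("class spatial factors must be >= 0")
        if not (0 < self.scan_visibility_p <= 1):
            raise ValidationError("scan_visibility_p must be in (0, 1]")
        if not (0 <= self.affiliation_distance_coupling <= 1):
            raise ValidationError("affiliation_distance_coupling must be in [0, 1]")
        if self.affiliation_shape <= 0:
            raise ValidationError("affiliation_shape must be > 0")
        if self.window_s <= 0 or self.layout_radius_m <= 0:
            raise ValidationError("window_s and layout_radius_m must be > 0")
        if self.interaction_scale < 0:
            raise ValidationError("interaction_scale must be >= 0")

    def _per_group(self, value: int | Sequence[int]) -> list[int]:
        n = len(self.groups)
        if isinstance(value, (int, np.integer)):
            return [int(value)] * n
        value = list(value)
        if len(value) != n:
            raise ValidationError("per-group counts must match number of groups")
        return [int(v) for v in value]

    def events_per_group(self) -> list[int]:
        return self._per_group(self.n_events_per_group)

    def scans_per_group(self) -> list[int]:
        return self._per_group(self.n_scans_per_group)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = [list(g) for g in self.groups]
        for key in ("n_events_per_group", "n_scans_per_group"):
            if not isinstance(d[key], int):
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown simulation config fields: {sorted(unknown)}")
        d = dict(data)
        if "groups" in d:
            d["groups"] = tuple(tuple(int(v) for v in g) for g in d["groups"])
        return cls(**d)


def make_groups(config: SimulationConfig) -> list[GroupComposition]:
    """Build rosters with ids like ``A-F1`` (group letter, class letter, index)."""
    letters = string.ascii_uppercase
    groups = []
    for gi, (nf, nm, nj) in enumerate(config.groups):
        gid = letters[gi % 26] * (1 + gi // 26)
        members = []
        for cls, letter, count in (
            (AgeSexClass.ADULT_FEMALE, "F", nf),
            (AgeSexClass.ADULT_MALE, "M", nm),
            (AgeSexClass.JUVENILE, "J", nj),
        ):
            for k in range(count):
                members.append(Individual(id=f"{gid}-{letter}{k + 1}", group_id=gid, age_sex_class=cls))
        if len(members) < 3:
            raise ValidationError(f"group {gid}: simulator needs groups of size >= 3")
        groups.append(GroupComposition(group_id=gid, members=tuple(members)))
    return groups


def simulate_affiliation(
    group: GroupComposition, config: SimulationConfig, rng: np.random.Generator
) -> DyadMatrix:
    """Latent dyadic affiliation weights: i.i.d. gamma, scaled to mean 1.

    ``affiliation_shape`` < 1 gives the strongly right-skewed weight
    distributions real grooming networks show; shape -> infinity collapses
    to equal weights.  The generator is class-blind: weights do not depend
    on age-sex classes.
    """
    ids = sorted(group.member_ids)
    pairs = [(x, y) for i, x in enumerate(ids) for y in ids[i + 1 :]]
    shape = config.affiliation_shape
    raw = rng.gamma(shape, 1.0 / shape, size=len(pairs))
    mean = raw.mean()
    if mean <= 0:
        raw = np.ones(len(pairs))
        mean = 1.0
    weights = raw / mean  # exact sample mean 1
    matrix = DyadMatrix(group.group_id, label="latent_affiliation")
    for (x, y), w in zip(pairs, weights):
        matrix.set(x, y, float(w), support=1)
    return matrix


def simulate_scans(
    group: GroupComposition,
    affiliation: DyadMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_scans: int | None = None,
) -> ScanDataset:
    """Generate scans: independent visibility, then per-dyad interaction draws.

    When both members of a dyad are visible, the dyad grooms with
    probability ``clip(interaction_scale * w, 0, 1)`` and huddles with the
    same probability from an independent draw; both behaviours read out the
    same latent weight.
    """
    if n_scans is None:
        n_scans = config.scans_per_group()[0]
    ids = sorted(group.member_ids)
    n = len(ids)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    probs = np.array(
        [min(1.0, config.interaction_scale * affiliation.value(ids[i], ids[j])) for i, j in pairs]
    )
    visible = rng.random((n_scans, n)) < config.scan_visibility_p
    covis = np.stack([visible[:, i] & visible[:, j] for i, j in pairs], axis=1)
    groom = covis & (rng.random((n_scans, len(pairs))) < probs)
    huddle = covis & (rng.random((n_scans, len(pairs))) < probs)

    scans = []
    width = max(4, len(str(n_scans)))
    for s in range(n_scans):
        vis = frozenset(ids[i] for i in range(n) if visible[s, i])
        g_dyads = frozenset(
            frozenset((ids[i], ids[j])) for k, (i, j) in enumerate(pairs) if groom[s, k]
        )
        h_dyads = frozenset(
            frozenset((ids[i], ids[j])) for k, (i, j) in enumerate(pairs) if huddle[s, k]
        )
        scans.append(
            Scan(
                scan_id=f"{group.group_id}-S{s + 1:0{width}d}",
                group_id=group.group_id,
                visible_ids=vis,
                grooming_dyads=g_dyads,
                huddling_dyads=h_dyads,
            )
        )
    return ScanDataset(scans)


@dataclass
class PositionSample:
    """Planar positions for one movement plus the coupled dyadic distances.

    ``coords`` are metres relative to the group centroid.  ``distances`` is
    the dyadic distance map actually used for recording and for the spatial
    hazard; under affiliation-distance coupling its rank order interpolates
    between the geometric ranks (coupling 0) and the exact reverse ranks of
    affiliation (coupling 1), while the distance *values* always come from
    the geometric configuration.
    """

    coords: dict[str, tuple[float, float]]
    distances: dict[tuple[str, str], float]

    def distance(self, x: str, y: str) -> float:
        return self.distances[dyad_key(x, y)]

    def category(self, x: str, y: str) -> DistanceCategory:
        return DistanceCategory.from_distance(self.distance(x, y))

    def centroid_distance(self, x: str) -> float:
        xs = np.array([c[0] for c in self.coords.values()])
        ys = np.array([c[1] for c in self.coords.values()])
        cx, cy = xs.mean(), ys.mean()
        px, py = self.coords[x]
        return float(np.hypot(px - cx, py - cy))


def simulate_positions(
    group: GroupComposition,
    affiliation: DyadMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PositionSample:
    """Draw spatial positions for one movement.

    Members scatter uniformly in a disc of ``layout_radius_m``; juveniles
    are pulled toward the centroid by 1/(1 + juvenile_centrality) and adult
    males pushed outward by (1 + male_peripherality).  Dyadic distances are
    then rank-blended with the reverse ranks of affiliation according to
    ``affiliation_distance_coupling`` (rho): rho = 0 leaves the geometric
    distances untouched; rho = 1 makes the most affiliated dyad exactly the
    closest one.
    """
    ids = sorted(group.member_ids)
    n = len(ids)
    r = config.layout_radius_m * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    pts = np.column_stack((r * np.cos(theta), r * np.sin(theta)))
    centroid = pts.mean(axis=0)
    scale = np.ones(n)
    for i, ind in enumerate(ids):
        cls = group.class_of(ind)
        if cls is AgeSexClass.JUVENILE:
            scale[i] = 1.0 / (1.0 + config.juvenile_centrality)
        elif cls is AgeSexClass.ADULT_MALE:
            scale[i] = 1.0 + config.male_peripherality
    pts = centroid + (pts - centroid) * scale[:, None]

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    d0 = np.array([float(np.hypot(*(pts[i] - pts[j]))) for i, j in pairs])
    w = np.array([affiliation.value(ids[i], ids[j]) for i, j in pairs])
    rho = config.affiliation_distance_coupling
    if rho > 0:
        r_geo = rankdata(d0, method="ordinal")
        r_aff = rankdata(-w, method="ordinal")  # strongest bond -> rank 1
        blended = (1 - rho) * r_geo + rho * r_aff
        final = rankdata(blended, method="ordinal")
        d = np.sort(d0)[final - 1]
    else:
        d = d0
    distances = {dyad_key(ids[i], ids[j]): float(v) for (i, j), v in zip(pairs, d)}
    coords = {ind: (float(p[0]), float(p[1])) for ind, p in zip(ids, pts)}
    return PositionSample(coords=coords, distances=distances)


def _sample_initiator(
    group: GroupComposition, config: SimulationConfig, rng: np.random.Generator
) -> str:
    ids = sorted(group.member_ids)
    weights = np.array(
        [
            config.female_initiator_weight
            if group.class_of(i) is AgeSexClass.ADULT_FEMALE
            else 1.0
            for i in ids
        ]
    )
    return ids[rng.choice(len(ids), p=weights / weights.sum())]


def simulate_departure_event(
    group: GroupComposition,
    affiliation: DyadMatrix,
    positions: PositionSample,
    config: SimulationConfig,
    rng: np.random.Generator,
    event_id: str = "E1",
    initiator_id: str | None = None,
) -> DepartureEvent:
    """Simulate one movement with continuous (unrounded) latencies."""
    if config.base_rate == 0:
        raise ValidationError("base_rate must be > 0 to simulate departures")
    ids = sorted(group.member_ids)
    initiator = initiator_id or _sample_initiator(group, config, rng)
    if initiator not in ids:
        raise ValidationError(f"initiator {initiator!r} not in group {group.group_id}")

    departed: list[tuple[str, float]] = [(initiator, 0.0)]
    remaining = [i for i in ids if i != initiator]
    t = 0.0
    while remaining:
        last = departed[-1][0]
        n_rem = len(remaining)
        if n_rem > 1:
            dists = np.array([positions.distance(j, last) for j in remaining])
            s = (rankdata(dists, method="ordinal") - 1) / (n_rem - 1)
        else:
            s = np.zeros(1)
        aff = np.array(
            [sum(affiliation.value(j, k) for k, _ in departed) for j in remaining]
        )
        log_rate = (
            np.log(config.base_rate)
            + config.beta_anonymous * len(departed)
            + config.beta_affiliative * aff
            - config.beta_spatial * s
        )
        rates = np.exp(log_rate)
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        if t > config.window_s:
            break
        idx = rng.choice(n_rem, p=rates / total)
        departed.append((remaining.pop(idx), t))

    joined_times = dict(departed)
    records = []
    for ind in ids:
        if ind == initiator:
            records.append(
                DepartureRecord(
                    event_id=event_id,
                    individual_id=ind,
                    joined=True,
                    is_initiator=True,
                    latency_s=0.0,
                    dist_to_initiator=None,
                    dist_to_predecessor=None,
                )
            )
        elif ind in joined_times:
            order = [d[0] for d in departed]
            predecessor = order[order.index(ind) - 1]
            records.append(
                DepartureRecord(
                    event_id=event_id,
                    individual_id=ind,
                    joined=True,
                    latency_s=joined_times[ind],
                    dist_to_initiator=positions.category(ind, initiator),
                    dist_to_predecessor=positions.category(ind, predecessor),
                )
            )
        else:
            # distance to the initiator at initiation is observable for
            # non-joiners too and is recorded for occupancy analyses
            records.append(
                DepartureRecord(
                    event_id=event_id,
                    individual_id=ind,
                    joined=False,
                    dist_to_initiator=positions.category(ind, initiator),
                )
            )
    return DepartureEvent(event_id=event_id, group_id=group.group_id, records=records)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    groups: list[GroupComposition]
    events: list[DepartureEvent]
    scans: ScanDataset
    affiliation: dict[str, DyadMatrix]

    def truth(self) -> dict:
        return {
            "seed": self.config.seed,
            "config": self.config.to_dict(),
            "beta_affiliative": self.config.beta_affiliative,
            "beta_spatial": self.config.beta_spatial,
            "beta_anonymous": self.config.beta_anonymous,
            "latent_weights": {
                gid: {f"{x}|{y}": v for (x, y), v in mat.items()}
                for gid, mat in self.affiliation.items()
            },
        }


def _round_event_latencies(event: DepartureEvent) -> DepartureEvent:
    """Round latencies to whole seconds (field resolution) and re-rank.

    Follower latencies are floored at 1 s: at second resolution a follower
    is by definition recorded after the initiator.
    """
    records = []
    for r in event.records:
        if r.latency_s is None:
            lat = None
        elif r.is_initiator:
            lat = 0.0
        else:
            lat = float(max(1, round(r.latency_s)))
        records.append(
            DepartureRecord(
                event_id=r.event_id,
                individual_id=r.individual_id,
                joined=r.joined,
                is_initiator=r.is_initiator,
                latency_s=lat,
                dist_to_initiator=r.dist_to_initiator,
                dist_to_predecessor=r.dist_to_predecessor,
            )
        )
    return DepartureEvent(event_id=event.event_id, group_id=event.group_id, records=records)


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Simulate rosters, scans and departure events for every group.

    Reproducible: identical config (including seed) gives identical output.
    Each group consumes an independent child stream of the seed so group
    counts can change without reshuffling other groups' draws.  Written
    latencies are whole seconds.  Events that recruit no follower within
    the window (failed initiations) are re-drawn, so every emitted event is
    a successful movement.
    """
    groups = make_groups(config)
    n_events = config.events_per_group()
    n_scans = config.scans_per_group()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(groups))

    all_events: list[DepartureEvent] = []
    all_scans: list[Scan] = []
    affiliation: dict[str, DyadMatrix] = {}
    for gi, group in enumerate(groups):
        rng = np.random.default_rng(children[gi])
        aff = simulate_affiliation(group, config, rng)
        affiliation[group.group_id] = aff
        scans = simulate_scans(group, aff, config, rng, n_scans=n_scans[gi])
        all_scans.extend(scans.scans)
        width = max(3, len(str(n_events[gi])))
        for ei in range(n_events[gi]):
            event_id = f"{group.group_id}-E{ei + 1:0{width}d}"
            for _attempt in range(1000):
                positions = simulate_positions(group, aff, config, rng)
                event = simulate_departure_event(
                    group, aff, positions, config, rng, event_id=event_id
                )
                if event.n_followers >= 1:
                    break
            else:  # pragma: no cover - requires pathological config
                raise ValidationError(
                    f"group {group.group_id}: could not draw a successful event; "
                    "base_rate or window too small"
                )
            all_events.append(_round_event_latencies(event))

    dataset = SimulatedDataset(
        config=config,
        groups=groups,
        events=all_events,
        scans=ScanDataset(all_scans),
        affiliation=affiliation,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lio.write_groups(groups, out / "groups.csv")
        lio.write_events(all_events, out / "events.csv")
        lio.write_scans(dataset.scans, out / "scans.csv")
        with (out / "truth.json").open("w", encoding="utf-8") as fh:
            json.dump(dataset.truth(), fh, indent=2, sort_keys=True)
    return dataset
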