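"""CSV readers and writers for departure events, group scans and rosters.

All files are comma-separated UTF-8 with a header row; missing values are
empty fields.  Latencies are stored as integer seconds; distance categories
use the labels ``0-1, 1-3, 3-5, 5-10, >10`` (metres).  Booleans are
``true``/``false``.  Non-joiners appear as explicit rows (``joined=false``)
so "did not join" is observable rather than inferred from absence.

events.csv  columns: event_id, group_id, individual_id, is_initiator,
            joined, latency_s, dist_to_initiator, dist_to_predecessor
scans.csv   columns: scan_id, group_id, visible_ids (semicolon-joined),
            behaviour (grooming|huddling|none), id_x, id_y
groups.csv  columns: group_id, individual_id, age_sex_class
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

from .datatypes import (
    AgeSexClass,
    DepartureEvent,
    DepartureRecord,
    DistanceCategory,
    GroupComposition,
    Individual,
    Scan,
    ScanDataset,
    ValidationError,
)

EVENT_COLUMNS = [
    "event_id",
    "group_id",
    "individual_id",
    "is_initiator",
    "joined",
    "latency_s",
    "dist_to_initiator",
    "dist_to_predecessor",
]
SCAN_COLUMNS = ["scan_id", "group_id", "visible_ids", "behaviour", "id_x", "id_y"]
GROUP_COLUMNS = ["group_id", "individual_id", "age_sex_class"]


def _parse_bool(text: str, where: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValidationError(f"{where}: cannot parse boolean {text!r}")


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _read_rows(path: str | Path, required: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, header required")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        return [dict(row) for row in reader]


def read_events(path: str | Path) -> list[DepartureEvent]:
    """Read and validate a departure-event table (one row per member per event)."""
    rows = _read_rows(path, EVENT_COLUMNS)
    by_event: dict[str, list[dict[str, str]]] = {}
    for row in rows:
        by_event.setdefault(row["event_id"], []).append(row)

    events: list[DepartureEvent] = []
    for event_id, event_rows in by_event.items():
        group_ids = {r["group_id"] for r in event_rows}
        if len(group_ids) != 1:
            raise ValidationError(f"event {event_id}: rows span groups {sorted(group_ids)}")
        seen: set[str] = set()
        records = []
        for r in event_rows:
            ind = r["individual_id"]
            if ind in seen:
                raise ValidationError(f"event {event_id}: duplicate row for individual {ind}")
            seen.add(ind)
            joined = _parse_bool(r["joined"], f"event {event_id}/{ind}")
            lat_text = r["latency_s"].strip()
            latency = None
            if lat_text:
                latency = float(lat_text)
            if joined and latency is None:
                raise ValidationError(f"event {event_id}/{ind}: joined row with missing latency")
            records.append(
                DepartureRecord(
                    event_id=event_id,
                    individual_id=ind,
                    joined=joined,
                    is_initiator=_parse_bool(r["is_initiator"], f"event {event_id}/{ind}"),
                    latency_s=latency,
                    dist_to_initiator=(
                        DistanceCategory.from_label(r["dist_to_initiator"])
                        if r["dist_to_initiator"].strip()
                        else None
                    ),
                    dist_to_predecessor=(
                        DistanceCategory.from_label(r["dist_to_predecessor"])
                        if r["dist_to_predecessor"].strip()
                        else None
                    ),
                )
            )
        events.append(DepartureEvent(event_id=event_id, group_id=group_ids.pop(), records=records))
    return events


def write_events(events: list[DepartureEvent], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for ev in events:
            for r in ev.records:
                if r.latency_s is None:
                    lat = ""
                elif float(r.latency_s).is_integer():
                    lat = str(int(r.latency_s))
                else:
                    lat = repr(float(r.latency_s))
                writer.writerow(
                    [
                        ev.event_id,
                        ev.group_id,
                        r.individual_id,
                        _fmt_bool(r.is_initiator),
                        _fmt_bool(r.joined),
                        lat,
                        r.dist_to_initiator.label if r.dist_to_initiator else "",
                        r.dist_to_predecessor.label if r.dist_to_predecessor else "",
                    ]
                )


def read_scans(path: str | Path) -> ScanDataset:
    """Read a group-scan table (long-form interaction rows + visibility lists)."""
    rows = _read_rows(path, SCAN_COLUMNS)
    order: list[str] = []
    meta: dict[str, tuple[str, frozenset[str]]] = {}
    interactions: dict[str, dict[str, set[frozenset[str]]]] = {}
    for row in rows:
        sid = row["scan_id"]
        visible = frozenset(v for v in row["visible_ids"].split(";") if v)
        if sid not in meta:
            order.append(sid)
            meta[sid] = (row["group_id"], visible)
            interactions[sid] = {"grooming": set(), "huddling": set()}
        else:
            if meta[sid] != (row["group_id"], visible):
                raise ValidationError(f"scan {sid}: inconsistent group or visibility across rows")
        behaviour = row["behaviour"].strip().lower() or "none"
        if behaviour == "none":
            continue
        if behaviour not in ("grooming", "huddling"):
            raise ValidationError(f"scan {sid}: unknown behaviour {behaviour!r}")
        x, y = row["id_x"].strip(), row["id_y"].strip()
        if not x or not y:
            raise ValidationError(f"scan {sid}: {behaviour} row missing dyad ids")
        dyad = frozenset((x, y))
        if len(dyad) != 2:
            raise ValidationError(f"scan {sid}: self-interaction {x!r}")
        if not dyad <= visible:
            raise ValidationError(
                f"scan {sid}: {behaviour} dyad ({x},{y}) not within visible ids"
            )
        if dyad in interactions[sid][behaviour]:
            raise ValidationError(f"scan {sid}: duplicate {behaviour} row for dyad ({x},{y})")
        interactions[sid][behaviour].add(dyad)

    scans = [
        Scan(
            scan_id=sid,
            group_id=meta[sid][0],
            visible_ids=meta[sid][1],
            grooming_dyads=frozenset(interactions[sid]["grooming"]),
            huddling_dyads=frozenset(interactions[sid]["huddling"]),
        )
        for sid in order
    ]
    return ScanDataset(scans)


def write_scans(dataset: ScanDataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCAN_COLUMNS)
        for scan in dataset:
            visible = ";".join(sorted(scan.visible_ids))
            rows = []
            for behaviour, dyads in (
                ("grooming", scan.grooming_dyads),
                ("huddling", scan.huddling_dyads),
            ):
                for dyad in sorted(dyads, key=sorted):
                    x, y = sorted(dyad)
                    rows.append([scan.scan_id, scan.group_id, visible, behaviour, x, y])
            if not rows:
                rows.append([scan.scan_id, scan.group_id, visible, "none", "", ""])
            writer.writerows(rows)


def read_groups(path: str | Path) -> list[GroupComposition]:
    rows = _read_rows(path, GROUP_COLUMNS)
    by_group: dict[str, list[Individual]] = {}
    for row in rows:
        gid = row["group_id"]
        by_group.setdefault(gid, []).append(
            Individual(
                id=row["individual_id"],
                group_id=gid,
                age_sex_class=AgeSexClass.parse(row["age_sex_class"]),
            )
        )
    return [GroupComposition(group_id=g, members=tuple(m)) for g, m in by_group.items()]


def write_groups(groups: list[GroupComposition], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(GROUP_COLUMNS)
        for group in groups:
            for m in group.members:
                writer.writerow([group.group_id, m.id, m.age_sex_class.value])


def count_dyads(groups: list[GroupComposition]) -> int:
    """Number of unordered within-group dyads, summed over groups."""
    return sum(math.comb(g.size, 2) for g in groups)
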