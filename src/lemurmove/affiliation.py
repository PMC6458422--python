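"""Dyadic affiliation metrics: interaction rates, DSI, and assortativity.

The dyadic composite sociability index (DSI) of dyad (x, y) averages the
dyad's grooming and huddling rates, each normalized by the group mean of
that rate:

    DSI_xy = ( g_xy / mean_g  +  h_xy / mean_h ) / 2

so the mean DSI over a group's dyads is 1 by construction; values above 1
mark dyads affiliated more strongly than the group average.  Rates are
proportions of scans in which the dyad interacted, corrected for the number
of scans in which both members were visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AgeSexClass,
    DyadMatrix,
    ScanDataset,
    ValidationError,
    dyad_key,
)

logger = logging.getLogger(__name__)

BEHAVIOURS = ("grooming", "huddling")


def dyadic_rate(
    scans: ScanDataset,
    behaviour: str,
    individual_ids: list[str] | None = None,
) -> DyadMatrix:
    """Per-dyad interaction rate from a single group's scans.

    value(x, y) = (#scans with the dyad interacting) / (#scans with both
    visible); support is the co-visibility count; dyads never co-visible are
    missing.  ``individual_ids`` fixes the roster (defaults to everyone seen
    in the scans).
    """
    if behaviour not in BEHAVIOURS:
        raise ValidationError(f"behaviour must be one of {BEHAVIOURS}, got {behaviour!r}")
    group_ids = scans.group_ids()
    if len(group_ids) != 1:
        raise ValidationError(
            f"dyadic_rate expects scans from one group, got {group_ids}; "
            "use for_group() to split"
        )
    ids = sorted(individual_ids) if individual_ids is not None else sorted(scans.individual_ids())
    matrix = DyadMatrix(group_ids[0], label=f"{behaviour}_rate")
    pairs = [(x, y) for i, x in enumerate(ids) for y in ids[i + 1 :]]
    together = {p: 0 for p in pairs}
    interacting = {p: 0 for p in pairs}
    for scan in scans:
        dyads = scan.grooming_dyads if behaviour == "grooming" else scan.huddling_dyads
        vis = scan.visible_ids
        for p in pairs:
            if p[0] in vis and p[1] in vis:
                together[p] += 1
                if frozenset(p) in dyads:
                    interacting[p] += 1
    for p in pairs:
        if together[p] == 0:
            matrix.set(*p, None, support=0)
        else:
            matrix.set(*p, interacting[p] / together[p], support=together[p])
    return matrix


def dyadic_rates_by_group(
    scans: ScanDataset,
    behaviour: str,
    groups=None,
) -> dict[str, DyadMatrix]:
    """``dyadic_rate`` per group of a multi-group scan dataset."""
    rosters = {g.group_id: list(g.member_ids) for g in groups} if groups else {}
    return {
        gid: dyadic_rate(scans.for_group(gid), behaviour, rosters.get(gid))
        for gid in scans.group_ids()
    }


def compute_dsi(grooming: DyadMatrix, huddling: DyadMatrix) -> DyadMatrix:
    """Dyadic composite sociability index from grooming and huddling rates.

    Group means are taken over dyads with defined rates.  If one
    behaviour's group mean is 0 (never observed), that component is dropped
    and the DSI is the remaining normalized rate, preserving the mean-1
    property; if both means are 0 no index exists.
    """
    if grooming.group_id != huddling.group_id:
        raise ValidationError("grooming and huddling matrices must be from the same group")
    common = sorted(set(grooming.defined_dyads()) & set(huddling.defined_dyads()))
    if not common:
        raise ValidationError("no dyads with both rates defined")
    g_mean = float(np.mean([grooming.value(*d) for d in common]))
    h_mean = float(np.mean([huddling.value(*d) for d in common]))
    components = []
    if g_mean > 0:
        components.append((grooming, g_mean))
    else:
        logger.warning("group %s: grooming never observed; DSI uses huddling only", grooming.group_id)
    if h_mean > 0:
        components.append((huddling, h_mean))
    else:
        logger.warning("group %s: huddling never observed; DSI uses grooming only", huddling.group_id)
    if not components:
        raise ValidationError(
            f"group {grooming.group_id}: no affiliative interactions observed"
        )
    dsi = DyadMatrix(grooming.group_id, label="dsi")
    for x, y in common:
        value = sum(mat.value(x, y) / mean for mat, mean in components) / len(components)
        support = min(grooming.support(x, y), huddling.support(x, y))
        dsi.set(x, y, value, support=support)
    # carry over dyads missing either rate as explicitly missing
    for x, y in set(grooming.dyads()) | set(huddling.dyads()):
        if (x, y) not in set(common):
            dsi.set(x, y, None, support=0)
    return dsi


def compute_dsi_by_group(
    grooming: dict[str, DyadMatrix], huddling: dict[str, DyadMatrix]
) -> dict[str, DyadMatrix]:
    return {gid: compute_dsi(grooming[gid], huddling[gid]) for gid in sorted(grooming)}


@dataclass
class DsiSummary:
    """Distribution diagnostics of a group's DSI values.

    A right-skewed distribution (median well below the mean of 1, few dyads
    above the mean) indicates strongly differentiated affiliative bonds.
    Skewness is the adjusted Fisher-Pearson coefficient.
    """

    group_id: str
    mean: float
    median: float
    fraction_above_mean: float
    n_dyads: int
    skewness: float


def dsi_summary(dsi: DyadMatrix) -> DsiSummary:
    values = np.asarray(dsi.defined_values(), dtype=float)
    if values.size < 2:
        raise ValidationError("dsi_summary needs at least 2 defined dyads")
    mean = float(values.mean())
    return DsiSummary(
        group_id=dsi.group_id,
        mean=mean,
        median=float(np.median(values)),
        fraction_above_mean=float(np.mean(values > mean)),
        n_dyads=int(values.size),
        skewness=float(stats.skew(values, bias=False)),
    )


@dataclass
class AssortativityResult:
    group_id: str
    attribute: str
    r_weighted: float
    mixing_matrix: pd.DataFrame  # class x class, entries sum to 1


def weighted_assortativity(
    weights: DyadMatrix, classes: dict[str, AgeSexClass | str]
) -> AssortativityResult:
    """Newman's weighted assortativity coefficient for a categorical attribute.

    The mixing matrix e_ij holds the fraction of total edge weight joining
    classes i and j; each unordered dyad's weight enters once, split 50/50
    across the two symmetric cells (a within-class dyad contributes wholly
    to its diagonal cell).  r = (sum_i e_ii - sum_i a_i^2)/(1 - sum_i a_i^2)
    with a_i the marginal weight fraction of class i; r = 1 iff all weight
    is within-class, and r is undefined for a single class (0/0).
    """
    labels = sorted({str(getattr(c, "value", c)) for c in classes.values()})
    if len(labels) < 2:
        raise ValidationError("weighted assortativity is undefined with a single class")
    idx = {lab: i for i, lab in enumerate(labels)}
    e = np.zeros((len(labels), len(labels)))
    total = 0.0
    for (x, y), w in weights.items():
        if w < 0:
            raise ValidationError(f"negative edge weight for dyad ({x},{y})")
        cx = idx[str(getattr(classes[x], "value", classes[x]))]
        cy = idx[str(getattr(classes[y], "value", classes[y]))]
        e[cx, cy] += w / 2.0
        e[cy, cx] += w / 2.0
        total += w
    if total <= 0:
        raise ValidationError("total edge weight must be positive")
    e /= total
    a = e.sum(axis=1)
    denom = 1.0 - float(a @ a)
    if denom == 0:
        raise ValidationError("assortativity undefined: all weight within one class (0/0 form)")
    r = (float(np.trace(e)) - float(a @ a)) / denom
    return AssortativityResult(
        group_id=weights.group_id,
        attribute="age_sex_class",
        r_weighted=r,
        mixing_matrix=pd.DataFrame(e, index=labels, columns=labels),
    )
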