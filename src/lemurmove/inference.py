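"""Statistical models for departure analyses with permutation inference.

Dyadic observations (DSI, IDI, proximity) are not independent: every
individual sits in many dyads.  Instead of fitting multiple-membership
random effects, each dyadic model pairs an ordinary linear fit (for
coefficient estimates and confidence intervals) with a node-label
permutation test: individual identities are shuffled *within groups*, the
dyadic covariate is remapped through the shuffled labels, and the focal
slope is recomputed, giving a null distribution that preserves the dyadic
design.  Latency models use linear mixed models (random intercept per
event) when the solver converges, with a documented ordinary-least-squares
fallback.  Families of p-values are corrected with the Holm step-down
procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .datatypes import (
    AgeSexClass,
    DepartureEvent,
    DistanceCategory,
    DyadMatrix,
    GroupComposition,
    ValidationError,
    dyad_key,
)
from .departures import PositionCategory, PositionScores

logger = logging.getLogger(__name__)

DIST_LEVELS = [c.label for c in DistanceCategory]
CLASS_LEVELS = [
    AgeSexClass.JUVENILE.value,
    AgeSexClass.ADULT_FEMALE.value,
    AgeSexClass.ADULT_MALE.value,
]

_CLASS_SHORT = {
    AgeSexClass.ADULT_FEMALE: "female",
    AgeSexClass.ADULT_MALE: "male",
    AgeSexClass.JUVENILE: "juvenile",
}


@dataclass
class ModelResult:
    """Coefficients, uncertainty and (optionally) permutation p-values."""

    model_name: str
    method: str  # "mixed" or "ols"
    transform: str  # "none" | "sqrt" | "log"
    coefficients: dict[str, float]
    se: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    permutation_p: dict[str, float] = field(default_factory=dict)
    n_obs: int = 0
    n_permutations: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "method": self.method,
            "transform": self.transform,
            "coefficients": self.coefficients,
            "se": self.se,
            "conf_int": {k: list(v) for k, v in self.conf_int.items()},
            "p_values": self.p_values,
            "permutation_p": self.permutation_p,
            "n_obs": self.n_obs,
            "n_permutations": self.n_permutations,
            "extras": self.extras,
        }


@dataclass
class HolmAdjustment:
    family: list[tuple[str, float]]
    adjusted: dict[str, float]


def holm_adjust(family: list[tuple[str, float]]) -> HolmAdjustment:
    """Holm step-down familywise adjustment.

    Sort raw p ascending; adjusted p_(j) = max_{k <= j} min(1, (m-k+1) p_(k)),
    so adjusted values are monotone in the raw ordering and never below raw.
    """
    for name, p in family:
        if not (0 <= p <= 1) and not np.isnan(p):
            raise ValidationError(f"p-value for {name!r} outside [0, 1]: {p}")
    m = len(family)
    order = sorted(range(m), key=lambda i: (np.isnan(family[i][1]), family[i][1]))
    adjusted: dict[str, float] = {}
    running = 0.0
    for j, i in enumerate(order):
        name, p = family[i]
        if np.isnan(p):
            adjusted[name] = float("nan")
            continue
        running = max(running, min(1.0, (m - j) * p))
        adjusted[name] = running
    return HolmAdjustment(family=list(family), adjusted=adjusted)


# ---------------------------------------------------------------------------
# node-label permutation engine for dyadic covariates


class _DyadPermuter:
    """Permutes a dyadic covariate by shuffling node labels within groups.

    Rows reference dyads (x, y) of per-group value matrices; a permutation
    replaces each row's value with value(sigma(x), sigma(y)) for a
    group-local relabeling sigma.
    """

    def __init__(self, matrices: dict[str, DyadMatrix], rows: pd.DataFrame):
        # rows: columns group, id_x, id_y
        self._groups = []
        self._row_groups = []
        for gid in sorted(matrices):
            mat = matrices[gid]
            ids = mat.ids()
            index = {i: k for k, i in enumerate(ids)}
            m = len(ids)
            W = np.full((m, m), np.nan)
            for (x, y), v in mat.items():
                W[index[x], index[y]] = v
                W[index[y], index[x]] = v
            mask = rows["group"].to_numpy() == gid
            if not mask.any():
                continue
            try:
                a = np.array([index[i] for i in rows.loc[mask, "id_x"]])
                b = np.array([index[i] for i in rows.loc[mask, "id_y"]])
            except KeyError as exc:  # pragma: no cover - inconsistent inputs
                raise ValidationError(f"id {exc} missing from dyad matrix for group {gid}")
            self._groups.append((W, a, b, np.flatnonzero(mask)))
        self.n_rows = len(rows)

    def observed(self) -> np.ndarray:
        out = np.empty(self.n_rows)
        for W, a, b, rows_idx in self._groups:
            out[rows_idx] = W[a, b]
        return out

    def permuted(self, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(self.n_rows)
        for W, a, b, rows_idx in self._groups:
            perm = rng.permutation(W.shape[0])
            out[rows_idx] = W[perm[a], perm[b]]
        return out


def _partial_slope(z: np.ndarray, y_resid: np.ndarray, Q: np.ndarray) -> float:
    zr = z - Q @ (Q.T @ z)
    denom = zr @ zr
    if denom == 0:
        return 0.0
    return float((zr @ y_resid) / denom)


def _permutation_pvalue(
    y: np.ndarray,
    nuisance: np.ndarray,
    permuter: _DyadPermuter,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Two-sided permutation p for the slope of the permuted covariate."""
    Q, _ = np.linalg.qr(nuisance)
    y_resid = y - Q @ (Q.T @ y)
    z_obs = permuter.observed()
    if np.isnan(z_obs).any():
        raise ValidationError("dyadic covariate undefined for some rows")
    slope_obs = _partial_slope(z_obs, y_resid, Q)
    hits = 0
    for _ in range(n_permutations):
        z_p = permuter.permuted(rng)
        if np.isnan(z_p).any():
            raise ValidationError(
                "node permutation hit an undefined dyad; the dyadic matrix must "
                "cover all within-group dyads"
            )
        if abs(_partial_slope(z_p, y_resid, Q)) >= abs(slope_obs) - 1e-12:
            hits += 1
    return slope_obs, (1 + hits) / (n_permutations + 1)


def _ols_result(
    model_name: str,
    formula: str,
    data: pd.DataFrame,
    transform: str = "none",
) -> tuple[ModelResult, sm.regression.linear_model.RegressionResultsWrapper]:
    fit = smf.ols(formula, data=data).fit()
    ci = fit.conf_int()
    result = ModelResult(
        model_name=model_name,
        method="ols",
        transform=transform,
        coefficients={k: float(v) for k, v in fit.params.items()},
        se={k: float(v) for k, v in fit.bse.items()},
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in fit.params.index},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        n_obs=int(fit.nobs),
    )
    return result, fit


# ---------------------------------------------------------------------------
# model fits


def fit_idi_on_dsi(
    idi: dict[str, DyadMatrix],
    dsi: dict[str, DyadMatrix],
    groups: list[GroupComposition] | None = None,
    support_threshold: int = 5,
    n_permutations: int = 2000,
    seed: int | np.random.Generator = 0,
) -> ModelResult:
    """Travel association as a function of affiliation: IDI ~ DSI + group.

    Uses dyads whose IDI rests on at least ``support_threshold`` joint
    movements and whose DSI is defined.  The DSI slope carries a two-sided
    node-permutation p (labels shuffled within groups); a negative slope
    means strongly bonded dyads depart in closer succession (affiliative
    mimetism).
    """
    rows = []
    for gid in sorted(idi):
        if gid not in dsi:
            continue
        for (x, y), v in idi[gid].items():
            if idi[gid].support(x, y) < support_threshold:
                continue
            d = dsi[gid].value(x, y)
            if d is None:
                continue
            rows.append({"group": gid, "id_x": x, "id_y": y, "idi": v, "dsi": d})
    data = pd.DataFrame(rows)
    if len(data) < 10:
        raise ValidationError(f"only {len(data)} usable dyads; need at least 10")
    data = data.sort_values(["group", "id_x", "id_y"], ignore_index=True)

    formula = "idi ~ dsi + C(group)" if data["group"].nunique() > 1 else "idi ~ dsi"
    result, _ = _ols_result("idi_on_dsi", formula, data)
    result.model_name = "idi_on_dsi"

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nuisance = pd.get_dummies(data["group"], drop_first=True, dtype=float)
    nuisance.insert(0, "const", 1.0)
    permuter = _DyadPermuter({g: dsi[g] for g in data["group"].unique()}, data)
    slope, p_perm = _permutation_pvalue(
        data["idi"].to_numpy(), nuisance.to_numpy(), permuter, n_permutations, rng
    )
    result.permutation_p = {"dsi": p_perm}
    result.n_permutations = n_permutations
    result.extras["partial_slope"] = slope
    return result


def _latency_table(
    events: list[DepartureEvent],
    reference: str,
    groups: list[GroupComposition],
) -> pd.DataFrame:
    """Follower-level table for the latency-on-distance models.

    Applies the completeness filter: an event enters only if the relevant
    distance was recorded for every follower.  The response is the
    following latency (time since predecessor for the predecessor model,
    time since initiation for the initiator model), divided by the event
    mean of that quantity.
    """
    if reference not in ("predecessor", "initiator"):
        raise ValidationError("reference must be 'predecessor' or 'initiator'")
    class_of = {m.id: m.age_sex_class for g in groups for m in g.members}
    rows = []
    n_dropped = 0
    for event in events:
        followers = event.followers
        if not followers:
            continue
        dists = [
            r.dist_to_predecessor if reference == "predecessor" else r.dist_to_initiator
            for r in followers
        ]
        if any(d is None for d in dists):
            n_dropped += 1
            continue
        order = event.joiners
        times = {r.individual_id: float(r.latency_s) for r in order}
        ids_in_order = [r.individual_id for r in order]
        lat = []
        for r in followers:
            if reference == "predecessor":
                prev = ids_in_order[ids_in_order.index(r.individual_id) - 1]
                lat.append(times[r.individual_id] - times[prev])
            else:
                lat.append(times[r.individual_id])
        mean_lat = float(np.mean(lat))
        if mean_lat <= 0:
            n_dropped += 1
            continue
        for r, d, value in zip(followers, dists, lat):
            rows.append(
                {
                    "event": event.event_id,
                    "group": event.group_id,
                    "individual": r.individual_id,
                    "cls": class_of[r.individual_id].value,
                    "dist": d.label,
                    "norm_latency": value / mean_lat,
                }
            )
    if n_dropped:
        logger.info(
            "latency model (%s): %d events dropped by the completeness filter",
            reference,
            n_dropped,
        )
    return pd.DataFrame(rows)


def fit_latency_on_distance(
    events: list[DepartureEvent],
    reference: str,
    groups: list[GroupComposition],
    use_mixed: bool = True,
) -> ModelResult:
    """Following latency as a function of distance category and class.

    Predecessor model: sqrt-transformed normalized inter-departure gap.
    Initiator model: log-transformed normalized latency from initiation.
    Fixed effects: distance category (reference 0-1 m) and follower
    age-sex class (reference juvenile); random intercept per event when
    the mixed solver converges, OLS otherwise (``method`` records which
    ran).  Holm-adjusted p-values over the model's fixed terms are in
    ``extras['p_holm']``; the non-reference distance coefficients in
    category order are in ``extras['distance_coefficients']``.
    """
    data = _latency_table(events, reference, groups)
    if len(data) < 10:
        raise ValidationError(f"only {len(data)} follower observations after filtering")
    if reference == "predecessor":
        transform = "sqrt"
        data["y"] = np.sqrt(data["norm_latency"])
    else:
        transform = "log"
        positive = data["norm_latency"] > 0
        if (~positive).any():
            logger.info(
                "latency model (initiator): dropping %d zero-latency rows before log",
                int((~positive).sum()),
            )
            data = data[positive].reset_index(drop=True)
        data["y"] = np.log(data["norm_latency"])

    dist_levels = [l for l in DIST_LEVELS if l in set(data["dist"])]
    cls_levels = [l for l in CLASS_LEVELS if l in set(data["cls"])]
    formula = f"y ~ C(dist, levels={dist_levels!r}) + C(cls, levels={cls_levels!r})"

    method = "ols"
    fit = None
    if use_mixed and data["event"].nunique() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mixed = smf.mixedlm(formula, data=data, groups=data["event"]).fit(reml=True)
            if np.isfinite(mixed.params.drop("Group Var", errors="ignore")).all():
                fit = mixed
                method = "mixed"
        except Exception:  # singular fits fall back to OLS
            fit = None
    if fit is None:
        fit = smf.ols(formula, data=data).fit()

    params = fit.params.drop("Group Var", errors="ignore")
    pvals = fit.pvalues.drop("Group Var", errors="ignore")
    bse = fit.bse.drop("Group Var", errors="ignore")
    ci_frame = fit.conf_int()
    ci = {
        k: (float(ci_frame.loc[k, 0]), float(ci_frame.loc[k, 1]))
        for k in params.index
        if k in ci_frame.index
    }
    result = ModelResult(
        model_name=f"latency_on_distance_{reference}",
        method=method,
        transform=transform,
        coefficients={k: float(v) for k, v in params.items()},
        se={k: float(v) for k, v in bse.items()},
        conf_int=ci,
        p_values={k: float(v) for k, v in pvals.items()},
        n_obs=len(data),
    )
    family = [(k, p) for k, p in result.p_values.items() if k != "Intercept"]
    result.extras["p_holm"] = holm_adjust(family).adjusted
    dist_terms = []
    for level in dist_levels[1:]:
        term = f"C(dist, levels={dist_levels!r})[T.{level}]"
        if term in result.coefficients:
            dist_terms.append((level, result.coefficients[term], result.extras["p_holm"][term]))
    result.extras["distance_coefficients"] = dist_terms
    result.extras["n_events"] = int(data["event"].nunique())
    return result


def fit_last_latency_on_group_size(
    events: list[DepartureEvent],
    groups: list[GroupComposition] | None = None,
    use_mixed: bool = True,
) -> ModelResult:
    """Time to complete recruitment as a function of group size.

    Restricted to movements in which the entire group followed.  Slope of
    group size on the last follower's latency, with a likelihood-ratio
    test against the intercept-only model; random intercept per initiator
    when mixed fitting is requested and converges.
    """
    rows = [
        {
            "event": ev.event_id,
            "group": ev.group_id,
            "size": ev.group_size,
            "initiator": ev.initiator_id,
            "last_latency": max(float(r.latency_s) for r in ev.followers),
        }
        for ev in events
        if ev.is_full_group
    ]
    data = pd.DataFrame(rows)
    if data.empty or data["size"].nunique() < 2:
        raise ValidationError("need full-group events from at least two group sizes")

    method = "ols"
    fit = null_fit = None
    if use_mixed and data["initiator"].nunique() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm("last_latency ~ size", data, groups=data["initiator"]).fit(
                    reml=False
                )
                null_fit = smf.mixedlm("last_latency ~ 1", data, groups=data["initiator"]).fit(
                    reml=False
                )
            method = "mixed"
        except Exception:
            fit = null_fit = None
    if fit is None:
        fit = smf.ols("last_latency ~ size", data).fit()
        null_fit = smf.ols("last_latency ~ 1", data).fit()
        method = "ols"

    lr = 2 * (fit.llf - null_fit.llf)
    lr_p = float(stats.chi2.sf(max(lr, 0.0), 1))
    params = fit.params.drop("Group Var", errors="ignore")
    ci_frame = fit.conf_int()
    result = ModelResult(
        model_name="last_latency_on_group_size",
        method=method,
        transform="none",
        coefficients={k: float(v) for k, v in params.items()},
        se={k: float(v) for k, v in fit.bse.reindex(params.index).items()},
        conf_int={
            k: (float(ci_frame.loc[k, 0]), float(ci_frame.loc[k, 1]))
            for k in params.index
            if k in ci_frame.index
        },
        p_values={k: float(v) for k, v in fit.pvalues.reindex(params.index).items()},
        n_obs=len(data),
    )
    result.extras["lr_statistic"] = float(max(lr, 0.0))
    result.extras["lr_p"] = lr_p
    return result


def fit_position_by_class(
    scores: dict[str, dict[str, PositionScores]],
    groups: list[GroupComposition],
) -> tuple[ModelResult, list[dict]]:
    """Position scores on age-sex class, with within-category contrasts.

    Fits a no-intercept linear model of the per-individual position score
    on group and a combined class-by-category factor, then tests all
    pairwise class differences within each position category, Holm-adjusted
    over the whole contrast set.
    """
    class_of = {m.id: m.age_sex_class for g in groups for m in g.members}
    rows = []
    for gid, per_ind in scores.items():
        for ind, sc in per_ind.items():
            for cat in PositionCategory:
                rows.append(
                    {
                        "group": gid,
                        "individual": ind,
                        "cls": class_of[ind].value,
                        "category": cat.value,
                        "combo": f"{class_of[ind].value}:{cat.value}",
                        "score": sc.proportions[cat],
                    }
                )
    data = pd.DataFrame(rows)
    if data["cls"].nunique() < 2:
        raise ValidationError("need at least 2 age-sex classes to contrast")

    formula = "score ~ 0 + C(combo)"
    if data["group"].nunique() > 1:
        formula += " + C(group)"
    result, fit = _ols_result("position_by_class", formula, data)

    present = set(data["combo"])
    contrasts = []
    family = []
    for cat in PositionCategory:
        classes = [c for c in CLASS_LEVELS if f"{c}:{cat.value}" in present]
        for i, ca in enumerate(classes):
            for cb in classes[i + 1 :]:
                term_a = f"C(combo)[{ca}:{cat.value}]"
                term_b = f"C(combo)[{cb}:{cat.value}]"
                test = fit.t_test(f"{term_a} - {term_b} = 0")
                est = float(np.squeeze(test.effect))
                p = float(np.squeeze(test.pvalue))
                key = f"{cat.value}:{ca}-{cb}"
                contrasts.append(
                    {
                        "category": cat.value,
                        "class_a": ca,
                        "class_b": cb,
                        "estimate": est,
                        "p_raw": p,
                    }
                )
                family.append((key, p))
    adjusted = holm_adjust(family).adjusted
    for c in contrasts:
        c["p_holm"] = adjusted[f"{c['category']}:{c['class_a']}-{c['class_b']}"]
    result.extras["contrasts"] = contrasts
    return result, contrasts


def fit_proximity_on_dsi(
    events: list[DepartureEvent],
    dsi: dict[str, DyadMatrix],
    groups: list[GroupComposition],
    n_permutations: int = 2000,
    seed: int | np.random.Generator = 0,
) -> ModelResult:
    """Proximity at departure as a function of the dyad's DSI.

    Observations pair each follower with the initiator (distance to
    initiator) and with its predecessor (distance to predecessor); the
    response is the log midpoint (m) of the recorded distance category.
    Covariates: DSI, the dyad's age-sex class combination, group, and the
    reference type.  The DSI slope carries a node-permutation p; a negative
    slope means strongly bonded dyads sit closer at departure.
    """
    class_of = {m.id: m.age_sex_class for g in groups for m in g.members}
    rows = []
    for event in events:
        gid = event.group_id
        if gid not in dsi:
            continue
        order = [r.individual_id for r in event.joiners]
        initiator = event.initiator_id
        for r in event.followers:
            pairs = []
            if r.dist_to_initiator is not None:
                pairs.append(("initiator", initiator, r.dist_to_initiator))
            if r.dist_to_predecessor is not None:
                prev = order[order.index(r.individual_id) - 1]
                if prev != r.individual_id:
                    pairs.append(("predecessor", prev, r.dist_to_predecessor))
            for ref_type, other, cat in pairs:
                if other == r.individual_id:
                    continue
                value = dsi[gid].value(r.individual_id, other)
                if value is None:
                    continue
                combo = "-".join(
                    sorted(
                        (
                            _CLASS_SHORT[class_of[r.individual_id]],
                            _CLASS_SHORT[class_of[other]],
                        )
                    )
                )
                rows.append(
                    {
                        "event": event.event_id,
                        "group": gid,
                        "id_x": r.individual_id,
                        "id_y": other,
                        "ref_type": ref_type,
                        "combo": combo,
                        "dsi": value,
                        "log_distance": float(np.log(cat.midpoint_m)),
                    }
                )
    data = pd.DataFrame(rows)
    if data.empty:
        raise ValidationError("no distance observations with a defined DSI")
    if data["log_distance"].nunique() < 2:
        raise ValidationError("zero-variance response: all observations in one distance category")
    data = data.sort_values(["group", "event", "id_x", "ref_type"], ignore_index=True)

    formula = "log_distance ~ dsi + C(combo)"
    if data["group"].nunique() > 1:
        formula += " + C(group)"
    if data["ref_type"].nunique() > 1:
        formula += " + C(ref_type)"
    result, _ = _ols_result("proximity_on_dsi", formula, data)

    nuisance = pd.get_dummies(
        data[["combo", "group", "ref_type"]], drop_first=True, dtype=float
    )
    nuisance.insert(0, "const", 1.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    permuter = _DyadPermuter({g: dsi[g] for g in data["group"].unique()}, data)
    slope, p_perm = _permutation_pvalue(
        data["log_distance"].to_numpy(), nuisance.to_numpy(), permuter, n_permutations, rng
    )
    result.permutation_p = {"dsi": p_perm}
    result.n_permutations = n_permutations
    result.extras["partial_slope"] = slope
    return result
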