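# Methods

This note documents the statistical definitions, the simulator's model and
calibration, numerical conventions, and known limitations.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

A *departure event* is one group movement: exactly one initiator
(latency 0, rank 1), followers with latencies in whole seconds up to the
600 s joining window, and explicit non-joiner rows.  Ranks are recomputed
from latencies with **competition ranking** (ties share the minimum rank,
later ranks skip), so position assignment is deterministic; remaining
latency ties are broken by individual id.  A record flagged joined with a
latency beyond the window is a hard error, never silently reclassified.

Distance categories are ordinal with bin edges 0, 1, 3, 5, 10 m (half-open,
last bin unbounded).  For ordinal-as-numeric analyses each category carries
a midpoint: 0.5, 2, 4, 7.5 m, and 15 m for the open-ended bin — a value in
the lower half of plausible far distances for a cohesive group; results
using it are interpreted on the log scale, where the exact choice matters
little.

Dyadic statistics live in symmetric matrices with per-dyad *support* (the
number of observations behind the value).  Zero support means *missing*;
missing values are never imputed as 0.

## Dyadic sociability (DSI)

Grooming and huddling rates are proportions of scans in which the dyad
interacted, corrected for the number of scans in which both members were
visible.  The DSI averages the two rates after normalizing each by its
group mean, taken over dyads with defined rates; the group mean DSI is
therefore exactly 1 whenever all dyads are defined.  If one behaviour was
never observed in a group its component is dropped (with a warning) rather
than dividing by zero, which preserves the mean-1 normalization on the
remaining component; if neither was observed the index does not exist and
an error is raised.  Distribution diagnostics report mean, median, the
fraction of dyads strictly above the mean, and adjusted Fisher–Pearson
skewness; the mean-median comparison is the primary skew diagnostic.

## Travel association (IDI)

For each movement with at least two joiners, the movement's mean absolute
pairwise departure-time difference m_i normalizes every dyad's difference;
a dyad's IDI is the average of its normalized differences over the
movements in which both members joined, with that count recorded as
support.  Two identities follow and are tested: the average of the
normalized differences over all joiner dyads of one movement is exactly 1,
and the IDI is invariant to uniform time dilation of a movement.
Movements whose joiners all departed at the same recorded second carry no
pairwise information and are skipped with a warning.  The per-movement
mean is taken over **all joiner dyads**; a variant over consecutive
departure gaps would change only the scale of m_i, and the all-dyads
reading is what makes the unit-mean identity hold.

## Departure positions

Van = first two movers, rear = last two, centre = the remainder,
plus *not joined*.  When four or fewer individuals join, van takes
precedence over rear and the centre may be empty (with exactly three
joiners: two van, one rear).  Position scores are per-individual
proportions over the events in which the individual was observed.

## Cohesion statistics

Median and IQR of follower latencies; the follower-count histogram with a
Pearson χ² test against a uniform distribution over all possible counts
1..N−1 (df = N−2, unobserved categories included as zeros — a convention
that must be fixed somewhere, and including all structurally possible
categories keeps the null well defined); and per-event last-follower
latencies restricted to movements the entire group joined.

## Weighted assortativity

Newman's weighted categorical coefficient on the affiliation network: the
class-mixing matrix splits each unordered dyad's weight 50/50 across the
two symmetric cells (a within-class dyad contributes wholly to its
diagonal cell), r = (Σe_ii − Σa_i²)/(1 − Σa_i²).  One property worth
flagging: on a *complete* weighted network without self-dyads the
within-class dyad share is below the product of the class marginals, so r
is negative in expectation even for class-blind weights (equal weights on
a 3/3/2 group of 8 give r = −1/7 exactly).  Tests therefore compare the
class-blind simulator against this structural null, not against 0 — and
observed "tendencies toward disassortativity" in small complete networks
should be read with the same caveat.

## Inference

Dyadic responses (IDI, proximity) violate ordinary-sample independence
because each individual sits in many dyads.  Rather than multiple-
membership random effects (which need a Bayesian sampler and add nothing
at sign level), each dyadic model pairs an OLS fit — for estimates and
confidence intervals — with a **node-label permutation test**: individual
identities are shuffled within groups, the dyadic covariate is remapped,
and the focal partial slope recomputed (QR residualization against the
nuisance design makes each permutation O(n)).  Two-sided p =
(1 + #{|slope*| ≥ |slope|}) / (B + 1); default B = 2000 (p floor 1/2001),
reduced to 500 inside Monte-Carlo meta-tests.  Permutations are
seed-deterministic and respect group structure.

Latency-on-distance models use the follower's latency (from the
predecessor, or cumulatively from the initiator) divided by the event mean
of that quantity — square-root transformed for the predecessor model, log
for the initiator model (zero recorded latencies, impossible after the
event-mean normalization except through 1 s rounding, are dropped from the
log model with a count logged).  Events missing the relevant distance for
any follower are excluded (completeness filter; row counts in/out are
logged).  Fixed effects: distance category (reference 0–1 m) and follower
age-sex class (reference juvenile).  A random intercept per event is
fitted with a linear mixed model when the solver converges; otherwise the
documented fallback is OLS, and `ModelResult.method` records which path
ran.  The richer crossed random-effect structures (predecessor, follower
and initiator identities) are not fitted; the event intercept is the
dominant grouping once latencies are event-normalized.  p-values within a
model are Holm-adjusted as one family (per-model families are the
default policy).

The position-score model is a no-intercept linear model on group and a
combined class × category factor, with all pairwise class contrasts within
each category Holm-adjusted over the full contrast set.  The group-size
model regresses last-follower latency (full-group events) on group size
with a random intercept per initiator (OLS fallback) and a likelihood-
ratio test against the intercept-only model.  Holm adjustment itself is
the standard step-down: sorted ascending, adjusted_(j) = max_{k≤j}
min(1, (m−k+1) p_(k)).

## The simulator

Each group receives i.i.d. latent affiliation weights from a gamma
distribution (shape `affiliation_shape`, default 0.5) rescaled to sample
mean 1 — strongly right-skewed, like real grooming networks; weights are
class-blind.  Scans draw per-individual visibility
(`scan_visibility_p` = 0.85) and, for co-visible dyads, independent
grooming and huddling Bernoullis with probability
clip(`interaction_scale`·w, 0, 1); both behaviours read out the same
latent weight, mirroring their use as two read-outs of one affiliation
construct.

Positions are redrawn for every movement (distances are measured per
departure, not persistent): uniform scatter in a disc of
`layout_radius_m` = 7.5 m (pairwise distances then populate all five
categories), juveniles pulled toward the centroid by
1/(1 + `juvenile_centrality`), adult males pushed outward by
(1 + `male_peripherality`).  Affiliation-distance coupling ρ rank-blends
the geometric distances with the reverse ranks of affiliation: ρ = 0
leaves geometry untouched, ρ = 1 makes the most-affiliated dyad exactly
the closest.  (Exact reverse-rank coupling is not realizable *through*
planar coordinates for arbitrary weights, so the blended distances are
the recorded ones while coordinates serve the centroid-distance
mechanics.)

Departures: the initiator is sampled with `female_initiator_weight`
(default 4, making adult females a clear majority of initiators), then
remaining individuals join in continuous time with hazard

    lambda_j(t) = lambda0 * exp( beta_anonymous * D(t)
                               + beta_affiliative * sum_{k departed} w_jk
                               - beta_spatial * s_j ),

where D(t) counts departed individuals and s_j ∈ [0,1] is the scaled rank
of j's distance to the most recent departer.  The rank form gives
beta_spatial a comparable scale across group sizes.  Waiting times and
identities are drawn Gillespie-style; individuals remaining at 600 s are
non-joiners; latencies are rounded to whole seconds (followers floored at
1 s) and ranks recomputed.  With all betas zero the process is exchangeable
and inter-departure waits are exponential — both tested against closed
forms.

### Default calibration

The default configuration reproduces the study design exactly (groups of
8/6/6/11 with 3f/3m/2j, 2/2/2, 2/2/2, 4f/3m/4j; 49/37/35/46 movements;
199/200/181/279 scans) and was calibrated once, against descriptive
targets only, to `base_rate` = 0.0012 s⁻¹, `beta_affiliative` = 0.55,
`beta_spatial` = 1.5, `beta_anonymous` = 0.1: this yields median follower
latency ≈ 2 min with a right-skewed IQR and ≈ 90% full-group movements.
A homogeneous per-event hazard cannot jointly push the median latency
lower *and* the full-group share down to ~65%; matching both would need
between-event heterogeneity (e.g. per-movement excitability), which is out
of scope.

One emergent behaviour to note: with the snowball terms on, the affiliative
sum grows with the number already departed, so *larger groups complete
recruitment faster* and the group-size → completion-time slope can turn
negative.  The classical positive slope (max of more exponential clocks)
appears when per-capita rates are fixed and feedback is off — which is the
configuration under which the recovery test for that model runs.

### Recovery scenarios

`pipeline.default_scenarios()` isolates one mechanism each on a single
group of 8 with `base_rate` = 0.01 s⁻¹ (feedback-free hazards need a
faster clock to complete recruitment inside the window): null (all betas
0), affiliative (β_A = 1), spatial (β_S = 4, 200 movements), anonymous
(β_N = 0.6), and the full paper-shaped default.  Spatial-mimetism recovery
is measured on the **latency-to-initiator** model: under the rank-based
competing-risk hazard the waiting time between departures is independent
of *which* individual departs next (the argmin and the minimum of
exponentials are independent), so the predecessor-gap response is nearly
signal-free, while cumulative latency from initiation tracks spatial
order strongly.

## Problem sizes used in validation

Monte-Carlo checks run at: 100 replicates for affiliative sign recovery,
50 for spatial monotonicity, 500 replicates × 500 permutations for the
null type-I error of the permutation test (3-SE band around 0.05), 1000
events for the exponential closed form, 150 replicates for the latency
model's Wald calibration, and ≥ 100 random instances per oracle-
equivalence check (tolerance 1e−12).

## What passing tests do and do not show

The simulator emulates the statistical *structure* of field data:
skewed dyadic affiliation, partial visibility, per-movement spatial
reshuffling, hazard-based joining with a hard window.  It does not emulate
temporal autocorrelation between movements, habitat or predator context,
vocal pre-departure coordination, kinship or dominance structure, or
observer error in distance categories.  Parameter recovery therefore shows
the *pipeline* is faithful (estimators point the right way with calibrated
error rates under the stated mechanisms); it cannot show those mechanisms
are the ones operating in any particular field system.

## Other limitations

- Bayesian multiple-membership GLMMs are deliberately replaced by the
  permutation contract; posterior summaries are out of scope.
- Failed initiations (no follower recruited) are re-drawn rather than
  emitted, so recruitment-failure rates are not a simulator output.
- The χ² homogeneity test uses the all-categories convention for df; with
  data-defined categories the statistic is the same but df shrink —
  both can be computed from the returned histogram if needed.
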