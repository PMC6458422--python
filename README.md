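# lemurmove

Analysis of **collective group departures** in individually marked animal
groups — built around the movement ecology of wild red-fronted lemurs
(*Eulemur rufifrons*), where an initiator leaves and the rest of the group
decides, individual by individual, whether and when to follow.

The package answers three kinds of question:

1. **Who sits where in the departure order?**  Departure ranks are grouped
   into *van* (first two movers), *centre*, *rear* (last two movers) and
   *not joined*, and per-individual position scores are contrasted across
   age-sex classes (adult females, adult males, juveniles).
2. **Does affiliation or spatial proximity drive joining (mimetism)?**
   Dyadic affiliation is measured from group scans as the **composite
   sociability index**

   DSI<sub>xy</sub> = ( g<sub>xy</sub>/ḡ + h<sub>xy</sub>/h̄ ) / 2,

   where g and h are a dyad's grooming and huddling rates corrected for
   co-visibility and ḡ, h̄ are their group means — so mean DSI = 1 by
   construction.  Travel association is the **inter-departure interval**

   IDI<sub>xy</sub> = (1/n) Σ<sub>i</sub> |t<sub>xi</sub> − t<sub>yi</sub>| / m<sub>i</sub>,

   the dyad's mean absolute departure-time difference across the n
   movements both joined, each normalized by that movement's mean pairwise
   difference m<sub>i</sub>.  Affiliative mimetism appears as a negative
   DSI → IDI slope; spatial mimetism as longer following latencies at
   greater distance categories (0–1, 1–3, 3–5, 5–10, >10 m).  Because
   dyadic data are non-independent, slopes are tested with **node-label
   permutations** within groups.
3. **How cohesive are departures?**  Median joining latency, the
   follower-count distribution against a uniform ("subgrouping") null via
   χ², and the time to complete recruitment as a function of group size.

Everything is validated by **parameter recovery**: an agent-based simulator
generates departures from known mechanisms — anonymous, affiliative and
spatial mimetism enter a Gillespie competing-risk hazard
λ<sub>j</sub>(t) = λ₀ exp(β_N·D(t) + β_A·Σ<sub>k departed</sub> w<sub>jk</sub> − β_S·s<sub>j</sub>) —
and the pipeline must recover the built-in signs and orderings.

## Worked example

Run the whole pipeline on a simulated study (4 groups of 8/6/6/11 = 31
individuals, 167 movements, 181–279 scans per group):

```sh
lemurmove run --out out/ --seed 7
```

`out/results.md` then contains, among others (output abridged):

```
- groups: 4, individuals: 31, within-group dyads: 113
- movements: 167, scans: 859

| group | mean DSI | median | frac > mean | skewness | n dyads |
| A     | 1.000    | 0.677  | 0.36        | 2.51     | 28      |
...

### idi_on_dsi (ols, n=113)
- `dsi`: -0.2119 CI [-0.273, -0.151]
- permutation p (dsi, 2000 node permutations): 0.0005
```

Reading this: each group's mean DSI is exactly 1 (the index's built-in
normalization) while the median sits well below it — affiliative bonds are
strongly right-skewed.  The IDI ~ DSI slope of −0.21 with a node-permutation
p ≈ 0.0005 says strongly bonded dyads depart in closer succession:
affiliative mimetism, which is indeed switched on in the default simulator
configuration.  The `latency_on_distance_*` models in the same report show
following latency rising monotonically across distance categories —
spatial mimetism, also switched on.

Other entry points: `lemurmove simulate` (data only),
`lemurmove affiliation` / `lemurmove departures` (metrics from CSVs),
`lemurmove infer` (models from CSVs), and `lemurmove recover`, which
tabulates sign-recovery and type-I-error rates over many seeds for the
null / affiliative / spatial / anonymous scenarios.

## Layout

- `src/lemurmove/datatypes.py` — domain types (events, scans, dyad matrices)
- `src/lemurmove/io.py` — CSV dialects and validation
- `src/lemurmove/simulate.py` — the mimetism simulator
- `src/lemurmove/affiliation.py` — rates, DSI, assortativity
- `src/lemurmove/departures.py` — IDI, positions, cohesion, occupancy
- `src/lemurmove/inference.py` — model fits and permutation tests
- `src/lemurmove/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
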