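"""Model fits, node-permutation inference, and Holm correction."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

import lemurmove as lm
from lemurmove.inference import _latency_table
from lemurmove.simulate import SimulationConfig, simulate_dataset

from conftest import make_event


class TestHolm:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([("a", 0.01), ("b", 0.04)], {"a": 0.02, "b": 0.04}),
            ([("a", 0.03)], {"a": 0.03}),
            ([("a", 1.0), ("b", 1.0), ("c", 1.0)], {"a": 1.0, "b": 1.0, "c": 1.0}),
        ],
    )
    def test_hand_cases(self, raw, expected):
        adjusted = lm.holm_adjust(raw).adjusted
        for key, value in expected.items():
            assert adjusted[key] == pytest.approx(value)

    def test_matches_statsmodels_on_random_vectors(self, rng):
        """Independent oracle: statsmodels' Holm implementation."""
        for _ in range(200):
            m = int(rng.integers(1, 12))
            ps = rng.random(m)
            ours = lm.holm_adjust([(f"t{i}", p) for i, p in enumerate(ps)]).adjusted
            _, oracle, _, _ = multipletests(ps, method="holm")
            for i in range(m):
                assert ours[f"t{i}"] == pytest.approx(oracle[i], abs=1e-12)

    def test_monotone_and_never_below_raw(self, rng):
        ps = rng.random(8)
        adjusted = lm.holm_adjust([(f"t{i}", p) for i, p in enumerate(ps)]).adjusted
        for i, p in enumerate(ps):
            assert adjusted[f"t{i}"] >= p
        order = np.argsort(ps)
        adj_sorted = [adjusted[f"t{i}"] for i in order]
        assert all(a <= b for a, b in zip(adj_sorted, adj_sorted[1:]))


def _toy_dyadic_fit(n_ids=6, slope=-0.5, intercept=2.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"i{k}" for k in range(n_ids)]
    dsi = lm.DyadMatrix("g", label="dsi")
    idi = lm.DyadMatrix("g", label="idi")
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            d = float(rng.random() * 3)
            dsi.set(x, y, d, support=10)
            idi.set(x, y, intercept + slope * d + noise * rng.normal(), support=10)
    return {"g": idi}, {"g": dsi}


class TestIdiOnDsi:
    def test_exact_linear_relation_recovered(self):
        idi, dsi = _toy_dyadic_fit()
        result = lm.fit_idi_on_dsi(idi, dsi, n_permutations=199, seed=5)
        assert result.coefficients["dsi"] == pytest.approx(-0.5, abs=1e-9)
        assert result.permutation_p["dsi"] < 0.02  # at or near the 1/200 floor

    def test_too_few_dyads_rejected(self):
        idi, dsi = _toy_dyadic_fit(n_ids=4)  # 6 dyads < 10
        with pytest.raises(lm.ValidationError, match="usable dyads"):
            lm.fit_idi_on_dsi(idi, dsi)

    def test_permutation_p_deterministic_in_seed(self):
        idi, dsi = _toy_dyadic_fit(noise=0.5, seed=3)
        a = lm.fit_idi_on_dsi(idi, dsi, n_permutations=200, seed=7)
        b = lm.fit_idi_on_dsi(idi, dsi, n_permutations=200, seed=7)
        assert a.permutation_p == b.permutation_p

    def test_support_threshold_filters_dyads(self):
        idi, dsi = _toy_dyadic_fit(n_ids=7, noise=0.2)
        idi["g"].set("i0", "i1", idi["g"].value("i0", "i1"), support=2)
        full = lm.fit_idi_on_dsi(idi, dsi, support_threshold=5, n_permutations=49)
        assert full.n_obs == 20  # 21 dyads minus the low-support one


class TestLatencyOnDistance:
    def test_normalized_latencies_mean_one_per_event(self, paper_shaped_dataset):
        table = _latency_table(
            paper_shaped_dataset.events, "initiator", paper_shaped_dataset.groups
        )
        means = table.groupby("event")["norm_latency"].mean()
        np.testing.assert_allclose(means, 1.0, atol=1e-12)

    def test_distance_slows_following_under_spatial_mimetism(self):
        """beta_spatial > 0: distance coefficients rise with category and the
        far category is significantly positive."""
        from lemurmove.pipeline import default_scenarios

        config = SimulationConfig.from_dict(
            {**default_scenarios()["spatial"].to_dict(), "seed": 2}
        )
        ds = simulate_dataset(config)
        result = lm.fit_latency_on_distance(ds.events, "initiator", ds.groups)
        coefs = [c for _, c, _ in result.extras["distance_coefficients"]]
        ps = {lvl: p for lvl, _, p in result.extras["distance_coefficients"]}
        assert len(coefs) == 4
        assert all(a <= b for a, b in zip(coefs, coefs[1:]))
        assert coefs[-1] > 0 and ps[">10"] < 0.05

    def test_null_rejection_rate_near_nominal(self):
        """beta_spatial = 0: the far-category Wald test rejects at ~alpha."""
        base = dict(
            groups=((3, 3, 2),),
            n_events_per_group=60,
            n_scans_per_group=5,
            base_rate=0.01,
            beta_affiliative=0.0,
            beta_spatial=0.0,
            beta_anonymous=0.0,
            female_initiator_weight=1.0,
            juvenile_centrality=0.0,
            male_peripherality=0.0,
            affiliation_distance_coupling=0.0,
        )
        reps, rejections = 150, 0
        for s in range(1, reps + 1):
            ds = simulate_dataset(SimulationConfig(seed=s, **base))
            result = lm.fit_latency_on_distance(ds.events, "initiator", ds.groups)
            p = dict(
                (lvl, p) for lvl, _, p in result.extras["distance_coefficients"]
            ).get(">10")
            # raw Wald p for the far category (Holm is for families)
            term = [
                k for k in result.p_values if k.endswith("[T.>10]") and "dist" in k
            ]
            rejections += bool(term) and result.p_values[term[0]] < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) <= 3 * se


class TestLastLatencyOnGroupSize:
    def test_two_point_no_noise_slope(self):
        events = []
        for k in range(4):
            lat = {f"a{j}": j * 10 for j in range(6)}
            events.append(make_event(f"s{k}", "g6", lat, "a0"))
        for k in range(4):
            lat = {f"b{j}": j * 20 for j in range(11)}
            events.append(make_event(f"l{k}", "g11", lat, "b0"))
        result = lm.fit_last_latency_on_group_size(events, use_mixed=False)
        assert result.coefficients["size"] == pytest.approx((200 - 50) / (11 - 6))

    def test_same_size_everywhere_rejected(self):
        events = [
            make_event(f"e{k}", "g", {f"i{j}": j * 10 for j in range(6)}, "i0")
            for k in range(5)
        ]
        with pytest.raises(lm.ValidationError):
            lm.fit_last_latency_on_group_size(events)

    def test_positive_slope_recovered_with_fixed_per_capita_rate(self):
        hits = 0
        reps = 25
        for s in range(1, reps + 1):
            config = SimulationConfig(
                groups=((2, 2, 2), (4, 4, 3)),
                n_events_per_group=40,
                n_scans_per_group=5,
                base_rate=0.02,
                beta_affiliative=0.0,
                beta_spatial=0.0,
                beta_anonymous=0.0,
                female_initiator_weight=1.0,
                seed=s,
            )
            ds = simulate_dataset(config)
            result = lm.fit_last_latency_on_group_size(ds.events)
            hits += result.coefficients["size"] > 0
        assert hits >= 22


class TestPositionByClass:
    def test_contrasts_equal_raw_differences_without_noise(self):
        """One individual per class, one group: contrast = score difference."""
        plan = {
            "f1": {"van": 0.8, "centre": 0.1, "rear": 0.1, "not_joined": 0.0},
            "m1": {"van": 0.1, "centre": 0.2, "rear": 0.7, "not_joined": 0.0},
            "j1": {"van": 0.1, "centre": 0.7, "rear": 0.2, "not_joined": 0.0},
        }
        cls = {
            "f1": lm.AgeSexClass.ADULT_FEMALE,
            "m1": lm.AgeSexClass.ADULT_MALE,
            "j1": lm.AgeSexClass.JUVENILE,
        }
        group = lm.GroupComposition(
            "g", tuple(lm.Individual(i, "g", cls[i]) for i in plan)
        )
        scores = {
            "g": {
                i: lm.PositionScores(
                    individual_id=i,
                    proportions={lm.PositionCategory(k): v for k, v in plan[i].items()},
                    n_events_observed=10,
                )
                for i in plan
            }
        }
        _, contrasts = lm.fit_position_by_class(scores, [group])
        van_fm = next(
            c
            for c in contrasts
            if c["category"] == "van"
            and {c["class_a"], c["class_b"]} == {"adult_female", "adult_male"}
        )
        assert abs(van_fm["estimate"]) == pytest.approx(0.7, abs=1e-9)

    def test_female_van_bias_recovered_at_study_scale(self):
        """Strong female leadership shows up as a significant female van
        excess over both males and juveniles at the study's sample size."""
        ds = simulate_dataset(SimulationConfig(seed=2, female_initiator_weight=8.0))
        scores = {
            g.group_id: lm.position_scores(
                [e for e in ds.events if e.group_id == g.group_id], g
            )
            for g in ds.groups
        }
        _, contrasts = lm.fit_position_by_class(scores, ds.groups)
        van = {
            frozenset((c["class_a"], c["class_b"])): c
            for c in contrasts
            if c["category"] == "van"
        }
        fm = van[frozenset(("adult_female", "adult_male"))]
        fj = van[frozenset(("adult_female", "juvenile"))]
        for c in (fm, fj):
            female_first = c["class_a"] == "adult_female"
            estimate = c["estimate"] if female_first else -c["estimate"]
            assert estimate > 0
            assert c["p_holm"] < 0.05


class TestProximityOnDsi:
    def _coupled_dataset(self, seed=1):
        config = SimulationConfig(
            groups=((3, 3, 2),),
            n_events_per_group=100,
            n_scans_per_group=300,
            scan_visibility_p=1.0,
            base_rate=0.01,
            beta_affiliative=0.0,
            beta_spatial=0.0,
            beta_anonymous=0.0,
            female_initiator_weight=1.0,
            juvenile_centrality=0.0,
            male_peripherality=0.0,
            affiliation_distance_coupling=1.0,
            seed=seed,
        )
        return simulate_dataset(config)

    def test_coupled_simulation_gives_negative_dsi_slope(self):
        ds = self._coupled_dataset()
        grooming = lm.dyadic_rates_by_group(ds.scans, "grooming", ds.groups)
        huddling = lm.dyadic_rates_by_group(ds.scans, "huddling", ds.groups)
        dsi = lm.compute_dsi_by_group(grooming, huddling)
        result = lm.fit_proximity_on_dsi(
            ds.events, dsi, ds.groups, n_permutations=199, seed=2
        )
        assert result.coefficients["dsi"] < 0
        assert result.permutation_p["dsi"] <= 2 / 200
        assert result.n_obs >= 300

    def test_zero_variance_response_rejected(self):
        d = lm.DistanceCategory.D1_3
        events = [
            make_event(
                "e1",
                "g",
                {"i0": 0, "i1": 10, "i2": 30},
                "i0",
                dist_to_initiator={"i1": d, "i2": d},
                dist_to_predecessor={"i1": d, "i2": d},
            )
        ]
        group = lm.GroupComposition(
            "g", tuple(lm.Individual(i, "g", lm.AgeSexClass.ADULT_MALE) for i in ("i0", "i1", "i2"))
        )
        dsi = lm.DyadMatrix("g")
        for a, b in (("i0", "i1"), ("i0", "i2"), ("i1", "i2")):
            dsi.set(a, b, 1.0, support=5)
        with pytest.raises(lm.ValidationError, match="zero-variance"):
            lm.fit_proximity_on_dsi(events, {"g": dsi}, [group])

    def test_uncoupled_null_rejects_at_nominal_rate(self):
        base = dict(
            groups=((3, 3, 2),),
            n_events_per_group=40,
            n_scans_per_group=150,
            scan_visibility_p=1.0,
            base_rate=0.01,
            beta_affiliative=0.0,
            beta_spatial=0.0,
            beta_anonymous=0.0,
            female_initiator_weight=1.0,
            juvenile_centrality=0.0,
            male_peripherality=0.0,
            affiliation_distance_coupling=0.0,
        )
        reps, rejections = 100, 0
        for s in range(1, reps + 1):
            ds = simulate_dataset(SimulationConfig(seed=s, **base))
            grooming = lm.dyadic_rates_by_group(ds.scans, "grooming", ds.groups)
            huddling = lm.dyadic_rates_by_group(ds.scans, "huddling", ds.groups)
            dsi = lm.compute_dsi_by_group(grooming, huddling)
            result = lm.fit_proximity_on_dsi(
                ds.events, dsi, ds.groups, n_permutations=99, seed=s
            )
            rejections += result.permutation_p["dsi"] < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) <= 3 * se + 1e-9

    def test_fit_invariant_to_event_order(self):
        ds = self._coupled_dataset(seed=4)
        grooming = lm.dyadic_rates_by_group(ds.scans, "grooming", ds.groups)
        huddling = lm.dyadic_rates_by_group(ds.scans, "huddling", ds.groups)
        dsi = lm.compute_dsi_by_group(grooming, huddling)
        forward = lm.fit_proximity_on_dsi(ds.events, dsi, ds.groups, n_permutations=9, seed=1)
        backward = lm.fit_proximity_on_dsi(
            list(reversed(ds.events)), dsi, ds.groups, n_permutations=9, seed=1
        )
        for term, value in forward.coefficients.items():
            assert backward.coefficients[term] == pytest.approx(value, abs=1e-9)
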