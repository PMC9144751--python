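"""Synthetic-data generator: growth law, renderer, metabolite tables."""
import numpy as np
import pytest

from phenoprime import (
    GrowthScenario,
    TreatmentEffect,
    make_grid_layout,
    render_plate,
    simulate_growth,
    simulate_metabolites,
)
from phenoprime.simulate import (
    ScenarioError,
    default_metabolite_panel,
    frame_to_series,
    logistic_area,
    series_to_frame,
)
from phenoprime.traits import gli


class TestSimulateGrowth:
    def test_zero_noise_is_exactly_logistic(self, noiseless_scenario):
        series = simulate_growth(noiseless_scenario)
        sc = noiseless_scenario
        for s in series:
            if s.treatment != "control" or s.condition != "optimal":
                continue
            expected = logistic_area(s.times, sc.A0, sc.K, sc.r)
            np.testing.assert_array_equal(s.areas, expected)

    def test_group_counts(self, small_scenario):
        series = simulate_growth(small_scenario)
        sc = small_scenario
        assert len(series) == sc.n_plants_per_group * len(sc.treatments) * len(sc.conditions)
        assert all(len(s) == len(sc.timepoints) for s in series)

    def test_stress_reduces_final_size_by_70_and_78_percent(self):
        """Default capacity multipliers 0.30/0.22 give the assay's 70%/78%
        final-size reductions under osmotic/salt stress."""
        sc = GrowthScenario(n_plants_per_group=3, noise_cv=0.0, gli_sd=0.0,
                            timepoints=np.array([0.0, 20.0]), seed=0)
        series = simulate_growth(sc)
        final = {}
        for s in series:
            if s.treatment == "control":
                final.setdefault(s.condition, s.areas[-1])
        assert 1 - final["osmotic"] / final["optimal"] == pytest.approx(0.70, abs=1e-6)
        assert 1 - final["salt"] / final["optimal"] == pytest.approx(0.78, abs=1e-6)

    def test_seed_determinism(self, small_scenario):
        a = simulate_growth(small_scenario)
        b = simulate_growth(small_scenario)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.areas, y.areas)
        c = simulate_growth(GrowthScenario(n_plants_per_group=6, seed=43))
        assert not np.array_equal(a[0].areas, c[0].areas)

    def test_noise_cv_is_scale_free(self):
        sc = GrowthScenario(n_plants_per_group=400, noise_cv=0.15,
                            timepoints=np.array([0.0, 5.0]), seed=1,
                            conditions=("optimal",),
                            treatments=(("control", 0.0),))
        series = simulate_growth(sc)
        finals = np.array([s.areas[-1] for s in series])
        cv = finals.std() / finals.mean()
        assert cv == pytest.approx(0.15, abs=0.02)

    def test_exponential_regime_log_affine(self):
        sc = GrowthScenario(n_plants_per_group=1, A0=1.0, K=1e12, r=0.9,
                            noise_cv=0.0, seed=0, conditions=("optimal",),
                            treatments=(("control", 0.0),))
        s = simulate_growth(sc)[0]
        slope, intercept = np.polyfit(s.times, np.log(s.areas), 1)
        assert slope == pytest.approx(0.9, rel=1e-9)

    def test_treatment_effects_multiply_K(self):
        eff = {(("DAP", 1.0), "optimal"): TreatmentEffect(K=1.3)}
        sc = GrowthScenario(n_plants_per_group=1, noise_cv=0.0, gli_sd=0.0,
                            timepoints=np.array([0.0, 30.0]),
                            conditions=("optimal",),
                            treatments=(("control", 0.0), ("DAP", 1.0)),
                            treatment_effects=eff, seed=0)
        series = {s.treatment: s for s in simulate_growth(sc)}
        ratio = series["DAP"].areas[-1] / series["control"].areas[-1]
        assert ratio == pytest.approx(1.3, rel=1e-6)

    @pytest.mark.parametrize(
        "kw,msg",
        [
            (dict(A0=0.0), "A0"),
            (dict(r=-1.0), "r must"),
            (dict(K=10.0, A0=40.0), "K must"),
            (dict(noise_cv=-0.1), "noise_cv"),
            (dict(timepoints=np.array([0.0, 0.0, 1.0])), "strictly increasing"),
            (dict(stress_K_multiplier={"optimal": 1.0, "osmotic": 1.5, "salt": 0.2}),
             "stress_K_multiplier"),
        ],
    )
    def test_invalid_scenarios_name_the_invariant(self, kw, msg):
        with pytest.raises(ScenarioError, match=msg):
            GrowthScenario(**kw)

    def test_frame_round_trip(self, small_scenario):
        series = simulate_growth(small_scenario)
        frame = series_to_frame(series)
        back = frame_to_series(frame)
        assert len(back) == len(series)
        lookup = {s.plant_id: s for s in back}
        for s in series:
            np.testing.assert_allclose(lookup[s.plant_id].areas, s.areas)


class TestRenderPlate:
    def test_empty_well_has_no_truth_label(self, rendered_scene):
        scene, entries = rendered_scene
        assert not np.any(scene.truth_mask == 6)  # well 5 requested area 0

    def test_truth_mask_counts_match_requested_areas(self, rendered_scene):
        scene, entries = rendered_scene
        for well, area, _ in entries:
            count = int((scene.truth_mask == well + 1).sum())
            assert abs(count - area) <= max(1, 0.01 * area)

    def test_blob_mean_gli_matches_request(self, rendered_scene):
        scene, entries = rendered_scene
        img = scene.image.astype(float)
        for well, area, greenness in entries:
            if area == 0:
                continue
            sel = scene.truth_mask == well + 1
            vals = gli(img[sel, 0], img[sel, 1], img[sel, 2])
            assert np.nanmean(vals) == pytest.approx(greenness, abs=0.02)

    def test_truth_labels_inside_well_disc(self, rendered_scene):
        scene, _ = rendered_scene
        layout = scene.layout
        rad = layout.well_diameter_px / 2.0
        for k, (cx, cy) in enumerate(layout.well_centers):
            ys, xs = np.nonzero(scene.truth_mask == k + 1)
            if ys.size:
                assert np.hypot(xs - cx, ys - cy).max() <= rad + 1e-9

    def test_background_is_not_green(self, rendered_scene):
        scene, _ = rendered_scene
        img = scene.image.astype(float)
        bg = scene.truth_mask == 0
        vals = gli(img[bg, 0], img[bg, 1], img[bg, 2])
        assert np.nanmean(vals) < 0.05

    def test_seed_determinism(self):
        layout = make_grid_layout(1, 2)
        entries = [(0, 400, 0.4), (1, 200, 0.3)]
        a = render_plate(entries, layout, seed=5)
        b = render_plate(entries, layout, seed=5)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.truth_mask, b.truth_mask)

    def test_area_exceeding_well_disc_raises(self):
        layout = make_grid_layout(1, 1)
        disc_area = np.pi * (layout.well_diameter_px / 2) ** 2
        with pytest.raises(ScenarioError, match="exceeds"):
            render_plate([(0, int(disc_area * 1.2), 0.4)], layout, seed=0)

    def test_duplicate_well_raises(self):
        layout = make_grid_layout(1, 2)
        with pytest.raises(ScenarioError, match="twice"):
            render_plate([(0, 100, 0.4), (0, 100, 0.4)], layout, seed=0)

    def test_overlapping_layout_rejected(self):
        with pytest.raises(ScenarioError, match="overlap"):
            make_grid_layout(1, 2, well_diameter_px=64, pitch_px=30, margin_px=40)


class TestSimulateMetabolites:
    def test_zero_noise_zero_effect_equals_baseline(self):
        groups = [("control", 0.0, "optimal"), ("DAP", 1.0, "optimal")]
        t = simulate_metabolites(groups, n_per_group=3, noise_sd=0.0, seed=0)
        _, _, baselines = default_metabolite_panel()
        np.testing.assert_allclose(t.values.to_numpy(), np.tile(baselines, (6, 1)))

    def test_ln2_effect_doubles_group(self):
        groups = [("control", 0.0, "optimal"), ("DAP", 1.0, "optimal")]
        names, classes, baselines = default_metabolite_panel()
        effects = np.zeros((2, len(names)))
        effects[1, 0] = np.log(2.0)
        t = simulate_metabolites(groups, n_per_group=3, metabolites=names,
                                 classes=classes, effects=effects,
                                 baselines=baselines, noise_sd=0.0, seed=0)
        treated = t.values[t.meta["treatment"] == "DAP"].iloc[:, 0]
        np.testing.assert_allclose(treated, 2.0 * baselines[0])

    def test_row_count_is_groups_times_replicates(self):
        groups = [(t, c, "optimal") for t, c in
                  [("control", 0.0), ("DAP", 0.1), ("DAP", 1.0), ("Orn", 0.1),
                   ("Orn", 1.0), ("Put", 0.1), ("Put", 1.0)]]
        t = simulate_metabolites(groups, n_per_group=4, seed=0)
        assert t.n_samples == 28

    def test_all_values_positive_and_deterministic(self):
        groups = [("control", 0.0, "salt"), ("Put", 1.0, "salt")]
        a = simulate_metabolites(groups, n_per_group=4, noise_sd=0.5, seed=9)
        b = simulate_metabolites(groups, n_per_group=4, noise_sd=0.5, seed=9)
        assert (a.values.to_numpy() > 0).all()
        np.testing.assert_array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_nonfinite_effects_rejected(self):
        groups = [("control", 0.0, "optimal"), ("DAP", 1.0, "optimal")]
        names, classes, baselines = default_metabolite_panel()
        effects = np.zeros((2, len(names)))
        effects[0, 0] = np.inf
        with pytest.raises(ScenarioError, match="finite"):
            simulate_metabolites(groups, metabolites=names, classes=classes,
                                 effects=effects, baselines=baselines, seed=0)
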