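import numpy as np
import pytest

from targetperim.bundles import BundleCoords
from targetperim.circle import (
    LocationCategory,
    ScotomaCluster,
    circle_locations,
    detect_scotomata,
    neighbours,
    run_circle_perimetry,
)
from targetperim.highdensity import (
    INNER_RADIUS,
    STAGE_STEP,
    NoClustersError,
    StageState,
    fit_scotoma,
    identify_edge_points,
    initial_region,
    next_stage_locations,
    run_high_density,
)
from targetperim.observer import (
    ArcuateDefectSpec,
    Observer,
    make_glaucoma_field,
    make_healthy_field,
)
from targetperim.units import FieldLocation

from conftest import BS_CENTRE


def _glaucoma_observer(normative, bundle_model, defect, seed):
    base = make_healthy_field(normative=normative)
    return Observer(
        true_field=make_glaucoma_field(base, [defect], bundle_model), rng_seed=seed
    )


def _delineate(normative, reference, bundle_model, defect, seed, **kw):
    obs = _glaucoma_observer(normative, bundle_model, defect, seed)
    grid = circle_locations(BS_CENTRE)
    res = run_circle_perimetry(obs, grid, reference, 5.0)
    clusters = detect_scotomata(res.categories)
    if not clusters:
        return None
    return run_high_density(obs, reference, 5.0, clusters, grid, bundle_model, **kw)


class TestInitialRegion:
    def test_members_plus_neighbours(self):
        grid = circle_locations(BS_CENTRE)
        cluster = ScotomaCluster(frozenset({(1, 5), (1, 6)}), "missed_twice_pair")
        region = initial_region([cluster], grid)
        expected_idx = {(1, 5), (1, 6)} | neighbours((1, 5)) | neighbours((1, 6))
        assert region == {grid.location(i) for i in expected_idx}
        for loc in region:
            assert 6.0 - 1e-9 <= loc.distance_to(BS_CENTRE) <= 10.0 + 1e-9

    def test_disjoint_clusters_union(self):
        grid = circle_locations(BS_CENTRE)
        c1 = ScotomaCluster(frozenset({(0, 2)}), "t")
        c2 = ScotomaCluster(frozenset({(2, 15)}), "t")
        both = initial_region([c1, c2], grid)
        assert both == initial_region([c1], grid) | initial_region([c2], grid)

    def test_empty_cluster_list_rejected(self):
        with pytest.raises(NoClustersError):
            initial_region([], circle_locations(BS_CENTRE))


class TestEdgePoints:
    def test_min_max_theta_at_single_distance(self):
        pts = [BundleCoords(8.0, t) for t in (10.0, 20.0, 30.0)]
        low, high = identify_edge_points(pts)
        assert low == [BundleCoords(8.0, 10.0)]
        assert high == [BundleCoords(8.0, 30.0)]

    def test_one_point_per_bin_per_edge(self):
        pts = [
            BundleCoords(d, t) for d in (7.0, 9.0, 11.0) for t in (100.0, 104.0)
        ]
        low, high = identify_edge_points(pts, bin_width=2.0)
        assert len(low) == 3 and len(high) == 3
        assert all(p.theta == 100.0 for p in low)
        assert all(p.theta == 104.0 for p in high)

    def test_single_point_degenerates_to_both_edges(self):
        low, high = identify_edge_points([BundleCoords(8.0, 115.0)])
        assert low == high == [BundleCoords(8.0, 115.0)]

    def test_collinear_points_give_identical_edges(self):
        pts = [BundleCoords(d, 110.0 + d) for d in (6.0, 8.0, 10.0)]
        low, high = identify_edge_points(pts)
        assert low == high


class TestNextStageLocations:
    def test_growth_capped_at_stage_radius(self, bundle_model):
        fit = fit_scotoma([BundleCoords(d, 115.0 + 0.3 * d) for d in (6.0, 8.0, 10.0)])
        state = StageState(stage_number=2, tested=[], fits=[fit])
        locs = next_stage_locations(state, bundle_model)
        assert locs
        for loc in locs:
            d = loc.distance_to(BS_CENTRE)
            assert INNER_RADIUS - 1e-9 <= d <= 14.0 + 1e-9

    def test_already_tested_locations_excluded(self, bundle_model):
        fit = fit_scotoma([BundleCoords(d, 115.0 + 0.3 * d) for d in (6.0, 8.0, 10.0)])
        state = StageState(stage_number=2, tested=[], fits=[fit])
        first = next_stage_locations(state, bundle_model)
        state2 = StageState(stage_number=2, tested=sorted(first), fits=[fit])
        assert next_stage_locations(state2, bundle_model) == set()

    def test_zero_width_scotoma_still_yields_a_band(self, bundle_model):
        # single-file points: both edges coincide; the 4 deg orthogonal
        # expansions open an 8 deg wide corridor around the middle path
        fit = fit_scotoma([BundleCoords(d, 115.0) for d in (6.0, 8.0, 10.0)])
        state = StageState(stage_number=2, tested=[], fits=[fit])
        locs = next_stage_locations(state, bundle_model)
        assert len(locs) > 3

    def test_fovea_limit_clips_candidates(self, bundle_model):
        fit = fit_scotoma([BundleCoords(d, 115.0 + 0.3 * d) for d in (6.0, 8.0, 10.0)])
        state = StageState(stage_number=5, tested=[], fits=[fit])
        for loc in next_stage_locations(state, bundle_model, fovea_limit=30.0):
            assert loc.eccentricity <= 30.0 + 1e-9


class TestRunHighDensity:
    DEFECT = ArcuateDefectSpec(120.0, 15.0, (6.0, 20.0), depth=15.0)

    def test_requires_clusters(self, reference, bundle_model):
        obs = Observer(true_field=make_healthy_field(), rng_seed=0)
        with pytest.raises(NoClustersError):
            run_high_density(
                obs, reference, 5.0, [], circle_locations(BS_CENTRE), bundle_model
            )

    def test_confined_defect_terminates_without_growth(
        self, normative, reference, bundle_model
    ):
        defect = ArcuateDefectSpec(120.0, 12.0, (6.0, 9.5), depth=15.0)
        hd = _delineate(normative, reference, bundle_model, defect, seed=1)
        assert hd is not None
        assert all(
            s.termination_reason == "no-new-locations" for s in hd.scotomata
        )

    def test_radius_schedule_invariant(self, normative, reference, bundle_model):
        hd = _delineate(normative, reference, bundle_model, self.DEFECT, seed=2)
        for p in hd.presentations:
            stage = int(p.record.tag.split("-")[0].removeprefix("stage"))
            d = p.record.loc.distance_to(BS_CENTRE)
            assert d <= INNER_RADIUS + STAGE_STEP * stage + 1e-9
            assert p.record.loc.eccentricity <= 30.0 + 1e-9

    def test_no_duplicate_first_presentations(
        self, normative, reference, bundle_model
    ):
        hd = _delineate(normative, reference, bundle_model, self.DEFECT, seed=3)
        firsts = [p.record.loc for p in hd.presentations if not p.is_retest]
        assert len(firsts) == len(set(firsts))

    def test_deterministic_given_seed(self, normative, reference, bundle_model):
        def run():
            hd = _delineate(normative, reference, bundle_model, self.DEFECT, seed=4)
            return [
                (p.record.loc, p.record.stimulus_db, p.record.seen)
                for p in hd.presentations
            ]

        assert run() == run()

    def test_middle_fit_between_edges(self, normative, reference, bundle_model):
        hd = _delineate(normative, reference, bundle_model, self.DEFECT, seed=5)
        sc = max(hd.scotomata, key=lambda s: len(s.non_seen_locations))
        assert sc.fit is not None
        for d in np.linspace(*sc.fit.d_range, 10):
            lo = sc.fit.edge_low.theta_at(d)
            hi = sc.fit.edge_high.theta_at(d)
            mid = sc.fit.middle.theta_at(d)
            assert lo - 1e-6 <= mid <= hi + 1e-6

    def test_delineation_overlaps_truth(self, normative, reference, bundle_model):
        hd = _delineate(normative, reference, bundle_model, self.DEFECT, seed=6)
        sc = max(hd.scotomata, key=lambda s: len(s.non_seen_locations))
        tested = set(hd.categories)
        truth = {
            loc for loc in tested if self.DEFECT.covers(bundle_model.to_bundle(loc))
        }
        pred = set(sc.non_seen_locations)
        jaccard = len(pred & truth) / len(pred | truth)
        assert jaccard >= 0.5
        assert sc.termination_reason in ("no-new-locations", "reached-boundary")

    def test_long_defect_reaches_boundary(self, normative, reference, bundle_model):
        defect = ArcuateDefectSpec(100.0, 18.0, (6.0, 28.0), depth=18.0)
        hd = _delineate(normative, reference, bundle_model, defect, seed=7)
        reasons = {s.termination_reason for s in hd.scotomata}
        assert "reached-boundary" in reasons or "no-new-locations" in reasons

    def test_false_trigger_in_healthy_eye_stays_small(
        self, normative, reference, bundle_model
    ):
        """A cluster triggered by false positives at a 5 dB offset should
        collapse: few non-seen locations, early termination."""
        grid = circle_locations(BS_CENTRE)
        outcomes = []
        for seed in range(60):
            # an unreliable responder, so enough runs actually trigger
            obs = Observer(
                true_field=make_healthy_field(normative=normative, shadows=()),
                fp_rate=0.10, fn_rate=0.10, rng_seed=seed,
            )
            res = run_circle_perimetry(obs, grid, reference, 5.0)
            clusters = detect_scotomata(res.categories)
            if not clusters:
                continue
            hd = run_high_density(obs, reference, 5.0, clusters, grid, bundle_model)
            total = sum(len(s.non_seen_locations) for s in hd.scotomata)
            stages = max(s.stages_completed for s in hd.scotomata)
            outcomes.append(total < 10 and stages <= 3)
        assert len(outcomes) >= 5
        assert np.mean(outcomes) >= 0.9
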