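import math

import networkx as nx
import numpy as np
import pytest

from targetperim.circle import (
    ANGLE_STEP,
    LOCATIONS_PER_RING,
    RING_RADII,
    LocationCategory,
    circle_locations,
    detect_scotomata,
    false_positive_rate,
    neighbours,
    run_circle_perimetry,
)
from targetperim.observer import (
    ArcuateDefectSpec,
    Observer,
    make_glaucoma_field,
    make_healthy_field,
)
from targetperim.units import FieldLocation

from conftest import BS_CENTRE, noiseless_observer

S = LocationCategory.SEEN_FIRST
M1 = LocationCategory.MISSED_THEN_SEEN
M2 = LocationCategory.MISSED_TWICE


def all_seen():
    return {idx: S for idx in circle_locations(BS_CENTRE).indices}


class TestGrid:
    def test_75_locations_on_three_rings(self):
        grid = circle_locations(BS_CENTRE)
        locs = grid.locations
        assert len(locs) == 75
        for (ring, _), loc in locs.items():
            assert loc.distance_to(BS_CENTRE) == pytest.approx(
                RING_RADII[ring], abs=1e-9
            )

    def test_adjacent_angular_spacing(self):
        grid = circle_locations(BS_CENTRE)
        a = grid.location((1, 4))
        b = grid.location((1, 5))
        va = (a.x - BS_CENTRE.x, a.y - BS_CENTRE.y)
        vb = (b.x - BS_CENTRE.x, b.y - BS_CENTRE.y)
        ang = math.degrees(
            math.acos(
                (va[0] * vb[0] + va[1] * vb[1])
                / (math.hypot(*va) * math.hypot(*vb))
            )
        )
        assert ang == pytest.approx(ANGLE_STEP)
        assert ANGLE_STEP == pytest.approx(360.0 / LOCATIONS_PER_RING)

    def test_angle_origin_is_temporal(self):
        # angle index 0 points toward the fovea (temporal) in right-eye format
        loc = circle_locations(BS_CENTRE).location((0, 0))
        assert loc.x < BS_CENTRE.x and loc.y == pytest.approx(BS_CENTRE.y)
        left = circle_locations(FieldLocation(-15.0, -1.5), eye="left").location((0, 0))
        assert left.x > -15.0


class TestNeighbours:
    def test_middle_ring_has_four(self):
        assert len(neighbours((1, 5))) == 4

    def test_outer_rings_have_three(self):
        assert len(neighbours((0, 5))) == 3
        assert len(neighbours((2, 5))) == 3

    def test_angle_wraps(self):
        assert (1, 24) in neighbours((1, 0))
        assert (1, 0) in neighbours((1, 24))

    def test_invalid_index(self):
        with pytest.raises(ValueError):
            neighbours((3, 0))


class TestRun:
    def test_all_seen_single_pass(self, reference):
        class Bright:
            def __call__(self, loc):
                return 60.0

        res = run_circle_perimetry(
            noiseless_observer(Bright()), circle_locations(BS_CENTRE), reference, 5.0
        )
        assert all(c is S for c in res.categories.values())
        assert res.n_presentations == 75

    def test_none_seen_double_pass(self, reference):
        class Dark:
            def __call__(self, loc):
                return -60.0

        res = run_circle_perimetry(
            noiseless_observer(Dark()), circle_locations(BS_CENTRE), reference, 5.0
        )
        assert all(c is M2 for c in res.categories.values())
        assert res.n_presentations == 150

    def test_presentation_count_identity(self, normative, reference):
        fld = make_healthy_field(normative=normative)
        obs = Observer(true_field=fld, rng_seed=5)
        res = run_circle_perimetry(obs, circle_locations(BS_CENTRE), reference, 2.0)
        first_misses = sum(
            1 for p in res.presentations if not p.is_retest and not p.record.seen
        )
        assert res.n_presentations == 75 + first_misses

    def test_retest_gap_respected(self, normative, reference):
        fld = make_healthy_field(normative=normative)
        obs = Observer(true_field=fld, rng_seed=5)
        res = run_circle_perimetry(
            obs, circle_locations(BS_CENTRE), reference, 2.0, min_gap=5
        )
        first_pos = {}
        for i, p in enumerate(res.presentations):
            if p.is_retest:
                assert i - first_pos[p.idx] > 5
            elif not p.record.seen:
                first_pos[p.idx] = i

    def test_retests_use_identical_stimulus(self, normative, reference):
        fld = make_healthy_field(normative=normative)
        obs = Observer(true_field=fld, rng_seed=9)
        res = run_circle_perimetry(obs, circle_locations(BS_CENTRE), reference, 2.0)
        stim = {}
        for p in res.presentations:
            if p.idx in stim:
                assert p.record.stimulus_db == stim[p.idx]
            stim[p.idx] = p.record.stimulus_db

    def test_healthy_miss_fraction_low_at_offset_five(self, normative, reference):
        fld = make_healthy_field(normative=normative)
        rates = []
        for s in range(50):
            obs = Observer(true_field=fld, rng_seed=s)
            res = run_circle_perimetry(obs, circle_locations(BS_CENTRE), reference, 5.0)
            rates.append(false_positive_rate(res.categories))
        assert np.mean(rates) < 10.0


class TestDetect:
    def test_two_adjacent_missed_twice(self):
        cats = all_seen()
        cats[(1, 5)] = M2
        cats[(1, 6)] = M2
        (cluster,) = detect_scotomata(cats)
        assert cluster.member_indices == {(1, 5), (1, 6)}
        assert "missed_twice_pair" in cluster.trigger

    def test_single_missed_twice_is_not_a_scotoma(self):
        cats = all_seen()
        cats[(1, 5)] = M2
        assert detect_scotomata(cats) == []

    def test_three_consecutive_missed_once(self):
        cats = all_seen()
        for a in (4, 5, 6):
            cats[(2, a)] = M1
        (cluster,) = detect_scotomata(cats)
        assert "missed_first_triplet" in cluster.trigger

    def test_two_missed_twice_in_same_component_but_not_adjacent(self):
        # M2 - M1 - M2 chain: no mutually neighbouring M2 pair, but the
        # component has three members, so the triplet rule still fires
        cats = all_seen()
        cats[(1, 5)] = M2
        cats[(1, 6)] = M1
        cats[(1, 7)] = M2
        (cluster,) = detect_scotomata(cats)
        assert "missed_first_triplet" in cluster.trigger
        # with only two members the mutual-pair requirement matters:
        cats2 = all_seen()
        cats2[(1, 5)] = M2
        cats2[(0, 5)] = M2  # neighbours across rings
        assert len(detect_scotomata(cats2)) == 1
        cats3 = all_seen()
        cats3[(1, 5)] = M2
        cats3[(1, 7)] = M2  # not neighbours, separate components of size 1
        assert detect_scotomata(cats3) == []

    def test_component_mode_switch(self):
        cats = all_seen()
        cats[(1, 5)] = M2
        cats[(1, 6)] = M1
        cats[(1, 7)] = M2
        found = detect_scotomata(cats, mutual_pair=False)
        assert len(found) == 1
        assert "missed_twice_pair" in found[0].trigger

    def test_monotone_under_category_upgrade(self):
        """Upgrading any location toward more-missed never removes coverage
        of an existing scotoma."""
        rng = np.random.default_rng(2)
        indices = circle_locations(BS_CENTRE).indices
        order = [S, M1, M2]
        for _ in range(50):
            cats = {
                idx: order[rng.choice(3, p=[0.85, 0.08, 0.07])] for idx in indices
            }
            before = detect_scotomata(cats)
            covered_before = set().union(*(c.member_indices for c in before)) if before else set()
            idx = indices[int(rng.integers(75))]
            if cats[idx] is not M2:
                cats[idx] = order[order.index(cats[idx]) + 1]
            after = detect_scotomata(cats)
            covered_after = set().union(*(c.member_indices for c in after)) if after else set()
            assert covered_before <= covered_after

    def test_matches_independent_graph_oracle(self):
        """1,000 random category maps against an independent implementation
        built on networkx connected components."""
        indices = circle_locations(BS_CENTRE).indices
        order = [S, M1, M2]
        rng = np.random.default_rng(7)

        def oracle(cats):
            g = nx.Graph()
            damaged = [i for i in indices if cats[i] is not S]
            g.add_nodes_from(damaged)
            for r, a in damaged:
                for nb in ((r, (a + 1) % 25), (r + 1, a)):
                    if nb in cats and cats[nb] is not S:
                        g.add_edge((r, a), nb)
            out = []
            for comp in nx.connected_components(g):
                twice = [i for i in comp if cats[i] is M2]
                pair = any(
                    b in neighbours(a) for k, a in enumerate(twice) for b in twice[k + 1:]
                )
                if pair or len(comp) >= 3:
                    out.append(frozenset(comp))
            return sorted(out, key=lambda c: sorted(c)[0])

        for _ in range(1000):
            p = rng.uniform(0.02, 0.3)
            cats = {
                idx: order[rng.choice(3, p=[1 - p, p / 2, p / 2])] for idx in indices
            }
            got = [c.member_indices for c in detect_scotomata(cats)]
            assert got == oracle(cats)


class TestFalsePositiveRate:
    def test_identities(self):
        cats = all_seen()
        assert false_positive_rate(cats) == 0.0
        for a in range(15):
            cats[(0, a)] = M1 if a % 2 else M2
        assert false_positive_rate(cats) == pytest.approx(20.0)
        seen_first = sum(1 for c in cats.values() if c is S)
        assert false_positive_rate(cats) == pytest.approx(100 - 100 * seen_first / 75)

    def test_requires_full_grid(self):
        with pytest.raises(ValueError):
            false_positive_rate({(0, 0): S})


def test_arcuate_defect_detected_reliably(normative, reference, bundle_model):
    """A defect deeper than offset + 3 * slope_sd crossing the rings is
    flagged as a scotoma in at least 95% of seeded runs."""
    defect = ArcuateDefectSpec(120.0, 15.0, (6.0, 20.0), depth=5.0 + 3 * 1.5 + 0.5)
    base = make_healthy_field(normative=normative)
    fld = make_glaucoma_field(base, [defect], bundle_model)
    grid = circle_locations(BS_CENTRE)
    hits = sum(
        bool(
            detect_scotomata(
                run_circle_perimetry(
                    Observer(true_field=fld, rng_seed=s), grid, reference, 5.0
                ).categories
            )
        )
        for s in range(60)
    )
    assert hits / 60 >= 0.95
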