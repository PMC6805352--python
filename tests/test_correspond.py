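"""Corresponding-cell matching, differences, consensus, asynchrony."""

import math

import numpy as np
import pytest

from conftest import RandomTreeGen, build_tree, cell
from epilineage.correspond import (CorrespondenceMap, FeatureWeights,
                                   RigidTransform, build_consensus,
                                   count_differences, difference_report,
                                   division_features, match_lineages,
                                   max_timing_asynchrony, pairing_similarity,
                                   register_frames)
from epilineage.lineage_core import LineageError

ROOTS = [("1a", "1a"), ("1b", "1b"), ("1c", "1c"), ("1d", "1d")]


def pairwise_maps(trees, **kw):
    return [match_lineages(trees[i], trees[j], ROOTS, **kw)
            for i, j in [(0, 1), (0, 2), (1, 2)]]


# ---------------------------------------------------------------------------
# Features and similarity
# ---------------------------------------------------------------------------

class TestFeatures:
    def test_censored_daughter_carries_lower_bound(self):
        tree = build_tree([
            cell("m", 0.0, 2.0, fate="divided"),
            cell("d1", 2.0, 10.0, parent="m", fate="censored"),
            cell("d2", 2.0, 6.0, parent="m", fate="divided"),
            cell("g1", 6.0, 10.0, parent="d2", fate="censored"),
            cell("g2", 6.0, 10.0, parent="d2", fate="censored"),
        ], window=(0.0, 10.0))
        f = division_features(tree, "m", horizon=10.0)
        assert f.cycle_censored == (True, False)
        assert f.cycle_lengths[0] == pytest.approx(8.0)  # t_end - birth
        assert f.descendant_counts == (0, 2)

    def test_horizon_limits_descendant_counts(self):
        tree = build_tree([
            cell("m", 0.0, 2.0, fate="divided"),
            cell("d1", 2.0, 20.0, parent="m"),
            cell("d2", 2.0, 8.0, parent="m", fate="divided"),
            cell("g1", 8.0, 20.0, parent="d2"),
            cell("g2", 8.0, 20.0, parent="d2"),
        ], window=(0.0, 20.0))
        f = division_features(tree, "m", horizon=5.0)
        assert f.descendant_counts == (0, 0)

    def test_non_divided_node_raises(self):
        tree = build_tree([cell("x", 0.0, 5.0)])
        with pytest.raises(LineageError):
            division_features(tree, "x", horizon=10.0)


def _hand_score(fa, fb, assign, w):
    """The similarity formula written out independently for the oracle."""
    s = 0.0
    for i, j in assign:
        cos = float(np.dot(fa.daughter_offsets[i], fb.daughter_offsets[j]))
        s += w.w_pos * (1 + cos) / 2
        c1, c2 = fa.cycle_lengths[i], fb.cycle_lengths[j]
        z1, z2 = fa.cycle_censored[i], fb.cycle_censored[j]
        if z1 and z2:
            s += w.w_cycle
        elif z1 or z2:
            bound, obs = (c1, c2) if z1 else (c2, c1)
            s += w.w_cycle * math.exp(-max(0.0, bound - obs) / w.tau_cycle)
        else:
            s += w.w_cycle * math.exp(-abs(c1 - c2) / w.tau_cycle)
        n1, n2 = fa.descendant_counts[i], fb.descendant_counts[j]
        s += w.w_desc * (1 - abs(n1 - n2) / max(n1, n2, 1))
    return s / (2 * (w.w_pos + w.w_cycle + w.w_desc))


class TestPairingSimilarity:
    def _features(self, offs, cycles, counts, censored=(False, False)):
        from epilineage.correspond import DivisionFeatures
        return DivisionFeatures(
            daughter_offsets=tuple(np.asarray(o, float) for o in offs),
            cycle_lengths=tuple(cycles), cycle_censored=tuple(censored),
            descendant_counts=tuple(counts))

    def test_identical_features_score_one_straight(self):
        f = self._features([(1, 0, 0), (0, 1, 0)], (3.0, 4.0), (2, 3))
        score, pairing = pairing_similarity(f, f)
        assert score == pytest.approx(1.0)
        assert pairing == "straight"

    def test_swapped_daughters_score_one_swapped(self):
        f = self._features([(1, 0, 0), (0, 1, 0)], (3.0, 4.0), (2, 3))
        g = self._features([(0, 1, 0), (1, 0, 0)], (4.0, 3.0), (3, 2))
        score, pairing = pairing_similarity(f, g)
        assert score == pytest.approx(1.0)
        assert pairing == "swapped"

    def test_hand_built_example_matches_formula(self):
        # orthogonal offsets, cycle gap = tau on one side, counts 2 vs 4
        w = FeatureWeights()
        fa = self._features([(1, 0, 0), (0, 0, 1)], (3.0, 5.0), (2, 1))
        fb = self._features([(0, 1, 0), (0, 0, 1)], (3.0 + w.tau_cycle, 5.0),
                            (4, 1))
        expected = max(_hand_score(fa, fb, ((0, 0), (1, 1)), w),
                       _hand_score(fa, fb, ((0, 1), (1, 0)), w))
        score, _ = pairing_similarity(fa, fb, w)
        assert score == pytest.approx(expected, abs=1e-9)
        assert 0.0 <= score <= 1.0

    def test_censored_pair_is_not_penalized(self):
        fa = self._features([(1, 0, 0), (0, 1, 0)], (5.0, 5.0), (0, 0),
                            censored=(True, True))
        fb = self._features([(1, 0, 0), (0, 1, 0)], (9.0, 2.0), (0, 0),
                            censored=(True, True))
        score, _ = pairing_similarity(fa, fb)
        assert score == pytest.approx(1.0)


class TestRegistration:
    def test_identity_for_identical_trees(self, canonical_embryo):
        t = register_frames(canonical_embryo.tree, canonical_embryo.tree)
        assert t.angle_deg == pytest.approx(0.0)

    def test_metadata_rotation_recovered(self, canonical_embryo):
        import copy
        b = copy.copy(canonical_embryo.tree)
        b.frame = dict(b.frame, dorsal_azimuth_deg=60.0)
        t = register_frames(canonical_embryo.tree, b)
        assert t.angle_deg == pytest.approx(30.0)

    def test_landmark_fit_matches_metadata(self, canonical_embryo):
        tree = canonical_embryo.tree
        rot = RigidTransform(30.0)
        rotated_nodes = {}
        import dataclasses
        for uid, n in tree.nodes.items():
            pts = [(t, *rot.apply(np.array([x, y, z])))
                   for t, x, y, z in n.positions]
            rotated_nodes[uid] = dataclasses.replace(n, positions=pts)
        from epilineage.lineage_core import LineageTree
        b = LineageTree("rot", rotated_nodes,
                        recording_window=tree.recording_window,
                        frame={"mirror_plane": "x=0"})
        t = register_frames(tree, b, method="landmarks")
        assert t.angle_deg == pytest.approx(-30.0, abs=1.0)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

class TestMatching:
    def test_self_match_is_identity_with_unit_scores(self, canonical_embryo):
        tree = canonical_embryo.tree
        m = match_lineages(tree, tree, ROOTS, t_compare=30.0, guard=2.0)
        assert all(ua == v[0] for ua, v in m.pairs.items())
        assert all(v[1] == pytest.approx(1.0) for v in m.pairs.values())
        assert not m.unmatched_a and not m.unmatched_b

    def test_skipped_division_flags_exactly_that_subtree(self):
        def make(skip):
            cells = [
                cell("1a", 0.0, 5.0, fate="divided", name="1a",
                     xyz=(0.2, 0.1, 0.97)),
                cell("L", 5.0, 10.0, parent="1a", fate="divided",
                     xyz=(0.3, 0.1, 0.95)),
                cell("R", 5.0, 40.0, parent="1a", fate="terminal",
                     xyz=(0.1, 0.1, 0.98)),
                cell("L1", 10.0, 40.0, parent="L", xyz=(0.35, 0.1, 0.93)),
                cell("L2", 10.0, 40.0, parent="L", xyz=(0.25, 0.1, 0.96)),
            ]
            if skip:
                cells = cells[:1] + [
                    cell("L", 5.0, 40.0, parent="1a", fate="terminal",
                         xyz=(0.3, 0.1, 0.95)),
                    cells[2]]
            return build_tree(cells, window=(0.0, 40.0))

        a, b = make(skip=False), make(skip=True)
        m = match_lineages(a, b, [("1a", "1a")], t_compare=30.0, guard=3.0)
        assert m.real_differences("a") == {"L1", "L2"}
        assert not m.real_differences("b")

    def test_zero_variability_cohort_fully_matches(self, zero_cohort):
        trees = [e.tree for e in zero_cohort]
        for m in pairwise_maps(trees):
            assert not m.real_differences("a") and not m.real_differences("b")
            assert all(ua == v[0] for ua, v in m.pairs.items())

    def test_missing_root_raises(self, zero_cohort):
        trees = [e.tree for e in zero_cohort]
        with pytest.raises(LineageError):
            match_lineages(trees[0], trees[1], [("nope", "1a")])


class TestGreedyVersusBruteForce:
    def brute_total(self, ta, ua, tb, ub, horizon, w):
        """Exhaustive best recursive assignment (independent oracle)."""
        na, nb = ta.nodes[ua], tb.nodes[ub]
        if na.end_fate != "divided" or nb.end_fate != "divided":
            return 0.0
        fa = division_features(ta, ua, max(horizon, na.end_time))
        fb = division_features(tb, ub, max(horizon, nb.end_time))
        best = -1.0
        ka, kb = ta.children(ua), tb.children(ub)
        for assign in (((0, 0), (1, 1)), ((0, 1), (1, 0))):
            s = _hand_score(fa, fb, assign, w)
            sub = sum(self.brute_total(ta, ka[i], tb, kb[j], horizon, w)
                      for i, j in assign)
            best = max(best, s + sub)
        return best

    def greedy_total(self, ta, tb, cmap, horizon, w):
        total = 0.0
        for ua, (ub, _s, pairing) in cmap.pairs.items():
            if ta.nodes[ua].end_fate == "divided" and \
                    tb.nodes[ub].end_fate == "divided":
                fa = division_features(ta, ua,
                                       max(horizon, ta.nodes[ua].end_time))
                fb = division_features(tb, ub,
                                       max(horizon, tb.nodes[ub].end_time))
                assign = (((0, 0), (1, 1)) if pairing == "straight"
                          else ((0, 1), (1, 0)))
                total += _hand_score(fa, fb, assign, w)
        return total

    def test_greedy_equals_brute_force_on_identical_trees(self):
        rng = np.random.default_rng(7)
        gen = RandomTreeGen(rng)
        w = FeatureWeights()
        for _ in range(60):
            tree = gen.grow(max_leaves=8, t_end=20.0)
            m = match_lineages(tree, tree, [("c0", "c0")],
                               t_compare=18.0, guard=2.0)
            g = self.greedy_total(tree, tree, m, 20.0, w)
            b = self.brute_total(tree, "c0", tree, "c0", 20.0, w)
            assert g == pytest.approx(b, abs=1e-9)

    def test_greedy_within_5pct_of_brute_force_under_jitter(self):
        rng = np.random.default_rng(11)
        gen = RandomTreeGen(rng)
        w = FeatureWeights()
        for _ in range(40):
            a = gen.grow(max_leaves=8, t_end=20.0)
            b = gen.grow(base=gen.plan, t_end=20.0, jitter=0.4, noise=0.02)
            m = match_lineages(a, b, [("c0", "c0")],
                               t_compare=18.0, guard=2.0)
            g = self.greedy_total(a, b, m, 20.0, w)
            best = self.brute_total(a, "c0", b, "c0", 20.0, w)
            if best > 0:
                assert g >= 0.95 * best


# ---------------------------------------------------------------------------
# Differences, consensus, asynchrony
# ---------------------------------------------------------------------------

class TestDifferences:
    def test_zero_variability_cohort_has_zero_differences(self, zero_cohort):
        trees = [e.tree for e in zero_cohort]
        maps = pairwise_maps(trees)
        for t in (8.0, 16.0, 24.0, 30.0):
            entry = count_differences(trees, maps, t)
            assert sum(entry.counts.values()) == 0

    def test_single_extra_division_counts_two_cells_after_it(self):
        def make(extra):
            cells = [
                cell("1a", 0.0, 5.0, fate="divided", name="1a",
                     xyz=(0.2, 0.1, 0.97)),
                cell("A", 5.0, 30.0 if not extra else 20.0, parent="1a",
                     fate="terminal" if not extra else "divided",
                     xyz=(0.3, 0.1, 0.95)),
                cell("B", 5.0, 30.0, parent="1a", xyz=(0.1, 0.1, 0.98)),
            ]
            if extra:
                cells += [cell("A1", 20.0, 30.0, parent="A",
                               xyz=(0.33, 0.1, 0.94)),
                          cell("A2", 20.0, 30.0, parent="A",
                               xyz=(0.27, 0.1, 0.95))]
            return build_tree(cells, window=(0.0, 30.0))

        t1, t2, t3 = make(True), make(False), make(False)
        t1.embryo_id, t2.embryo_id, t3.embryo_id = "e1", "e2", "e3"
        maps = [match_lineages(a, b, [("1a", "1a")], t_compare=25.0,
                               guard=3.0)
                for a, b in [(t1, t2), (t1, t3), (t2, t3)]]
        before = count_differences([t1, t2, t3], maps, 15.0)
        after = count_differences([t1, t2, t3], maps, 24.0)
        assert sum(before.counts.values()) == 0
        assert after.counts["e1"] == 2
        assert sum(after.counts.values()) == 2

    def test_counts_symmetric_under_cohort_relabeling(self, default_cohort):
        trees = [e.tree for e in default_cohort]
        maps = pairwise_maps(trees)
        entry = count_differences(trees, maps, 28.0)
        rev = list(reversed(trees))
        maps_r = [match_lineages(rev[i], rev[j], ROOTS)
                  for i, j in [(0, 1), (0, 2), (1, 2)]]
        entry_r = count_differences(rev, maps_r, 28.0)
        assert entry.counts == entry_r.counts

    def test_time_outside_recordings_raises(self, zero_cohort):
        trees = [e.tree for e in zero_cohort]
        maps = pairwise_maps(trees)
        with pytest.raises(LineageError):
            count_differences(trees, maps, 99.0)

    def test_truncation_never_adds_real_differences(self, program):
        from epilineage.spiralsim import VariabilityModel, simulate_embryo
        full = simulate_embryo(program, VariabilityModel.zero(), 1,
                               t_end=33.0).tree
        short = simulate_embryo(program, VariabilityModel.zero(), 1,
                                t_end=28.0).tree
        m_full = match_lineages(full, full, ROOTS, t_compare=30, guard=3)
        m_short = match_lineages(full, short, ROOTS, t_compare=30, guard=3)
        assert len(m_short.real_differences("a")) <= \
            len(m_full.real_differences("a"))
        # cells unmatched against the truncated embryo are censored only
        assert m_short.real_differences("a") == set()


class TestConsensus:
    def test_consensus_of_identical_trees_is_the_tree(self, zero_cohort):
        trees = [e.tree for e in zero_cohort]
        maps = pairwise_maps(trees)
        ct = build_consensus(trees, maps)
        assert len(ct.nodes) == len(trees[0].nodes)
        assert all(n.support == 3 for n in ct.nodes.values())
        assert all(n.t_min == n.t_max for n in ct.nodes.values()
                   if n.t_min is not None)
        assert not any(n.low_support for n in ct.nodes.values())

    def test_division_missing_in_one_embryo_gets_support_two(self):
        def make(eid, with_division):
            cells = [cell("1a", 0.0, 5.0, fate="divided", name="1a",
                          xyz=(0.2, 0.1, 0.97)),
                     cell("A", 5.0, 12.0 if with_division else 30.0,
                          parent="1a",
                          fate="divided" if with_division else "terminal",
                          xyz=(0.3, 0.1, 0.95)),
                     cell("B", 5.0, 30.0, parent="1a", xyz=(0.1, 0.1, 0.98))]
            if with_division:
                cells += [cell("A1", 12.0, 30.0, parent="A",
                               xyz=(0.32, 0.1, 0.94)),
                          cell("A2", 12.0, 30.0, parent="A",
                               xyz=(0.28, 0.1, 0.95))]
            t = build_tree(cells, window=(0.0, 30.0))
            t.embryo_id = eid
            return t

        trees = [make("e1", True), make("e2", True), make("e3", False)]
        maps = [match_lineages(a, b, [("1a", "1a")], t_compare=25, guard=3)
                for a, b in [(trees[0], trees[1]), (trees[0], trees[2]),
                             (trees[1], trees[2])]]
        ct = build_consensus(trees, maps)
        a_node = next(n for n in ct.nodes.values()
                      if n.members.get("e1") == "A")
        assert a_node.division_support == 2
        kids = [ct.nodes[c] for c in a_node.children]
        assert kids and all(k.low_support for k in kids)
        assert all(k.support == 2 for k in kids)

    def test_rids_deterministic_and_prefixed(self, zero_cohort):
        trees = [e.tree for e in zero_cohort]
        maps = pairwise_maps(trees)
        c1 = build_consensus(trees, maps)
        c2 = build_consensus(trees, maps)
        assert list(c1.nodes) == list(c2.nodes)
        assert all(r.startswith("r") for r in c1.nodes)

    def test_time_ranges_bounded_by_observed_asynchrony(self, default_cohort):
        trees = [e.tree for e in default_cohort]
        maps = pairwise_maps(trees)
        ct = build_consensus(trees, maps, strict=False)
        widths = [(n.t_min, n.t_max - n.t_min) for n in ct.nodes.values()
                  if n.t_max is not None and n.division_support == 3]
        for lo_t, width in widths:
            window = (max(2.0, lo_t - 2.0), lo_t + 4.0)
            observed = max_timing_asynchrony(trees, maps, window)
            if observed is not None:
                # a single class range cannot exceed ~max of its hour band;
                # sanity bound: range <= 6 * mean asynchrony + 1
                assert width <= 6.0 * observed + 1.0


class TestAsynchrony:
    def test_zero_jitter_gives_zero(self, zero_cohort):
        trees = [e.tree for e in zero_cohort]
        maps = pairwise_maps(trees)
        assert max_timing_asynchrony(trees, maps, (10.0, 33.0)) == 0.0

    def test_two_embryo_definition(self):
        def make(eid, tdiv):
            cells = [cell("1a", 0.0, tdiv, fate="divided", name="1a",
                          xyz=(0.2, 0.1, 0.97)),
                     cell("A", tdiv, 20.0, parent="1a", xyz=(0.3, 0.1, 0.95)),
                     cell("B", tdiv, 20.0, parent="1a", xyz=(0.1, 0.1, 0.98))]
            t = build_tree(cells, window=(0.0, 20.0))
            t.embryo_id = eid
            return t
        a, b = make("e1", 10.0), make("e2", 11.0)
        m = match_lineages(a, b, [("1a", "1a")], t_compare=15, guard=3)
        assert max_timing_asynchrony([a, b], [m], (8.0, 14.0)) == \
            pytest.approx(1.0)

    def test_empty_window_returns_none(self, zero_cohort):
        trees = [e.tree for e in zero_cohort]
        maps = pairwise_maps(trees)
        assert max_timing_asynchrony(trees, maps, (2.0, 2.5)) is None


def test_map_serialization_round_trip(zero_cohort):
    trees = [e.tree for e in zero_cohort]
    m = match_lineages(trees[0], trees[1], ROOTS)
    again = CorrespondenceMap.from_dict(m.to_dict())
    assert again.pairs == m.pairs
    assert again.unmatched_a == m.unmatched_a


def test_difference_report_series(default_cohort):
    trees = [e.tree for e in default_cohort]
    maps = pairwise_maps(trees)
    rep = difference_report(trees, maps, [12.0, 16.0, 24.0, 30.0])
    pct = dict(rep.percentages())
    # before deviation onset only the variable rosette cell can differ
    for entry in rep.entries[:2]:
        for hits in entry.differing.values():
            assert all(u.startswith("1b-111") for u in hits)
    assert pct[30.0] > pct[12.0]
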