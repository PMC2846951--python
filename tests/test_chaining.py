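import numpy as np
import pytest

from flexalign.afp_extraction import Afp, afp_weight, extract_afps, filter_contained
from flexalign.alignment_io_eval import agreement, coverage
from flexalign.chaining import (
    Alignment,
    RigidRegion,
    align,
    chainable,
    compatible,
    connection_cost,
    extension_score,
    greedy_chain,
    precedes,
    precedes_sequential,
    rmsd_penalty,
    select_region,
    trim_overlap,
)
from flexalign.config import ScoringParams
from flexalign.geometry import RmsdAccumulator, rmsd_from_accumulator
from flexalign.synthetic_fixtures import FixtureSpec, FragmentMotion, make_pair
from oracles import max_weight_consistent_subset
from conftest import random_walk_coords, trace_from_coords

PARAMS = ScoringParams()


def afp(i, j, l, rmsd=0.1):
    return Afp(i=i, j=j, l=l, rmsd=rmsd, acc=RmsdAccumulator(n=l))


def identity_afp(coords, i, j, l):
    """AFP over an identity trace pair (B == A), carrying a real accumulator."""
    acc = RmsdAccumulator.from_points(coords[i:i + l], coords[j:j + l])
    p = Afp(i=i, j=j, l=l, rmsd=rmsd_from_accumulator(acc), acc=acc)
    p.weight = afp_weight(p, PARAMS)
    return p


# Quadrant layout mirroring the narrative figure: R = {P1, P2, P3} on one
# ascending diagonal band; P4, P5 sequential continuations; P7 a sequential
# prefix; P6, P8 non-sequential (below R in B).
P1 = afp(10, 20, 5)
P2 = afp(16, 26, 5)
P3 = afp(22, 32, 5)
P4 = afp(28, 38, 5)
P5 = afp(34, 44, 5)
P6 = afp(28, 5, 5)
P7 = afp(0, 5, 5)
P8 = afp(34, 12, 5)


class TestPrecedes:
    def test_upper_left(self):
        assert precedes(afp(0, 0, 5), afp(10, 10, 5))

    def test_a_overlap_rejected(self):
        assert not precedes(afp(0, 0, 5), afp(3, 10, 5))

    def test_lower_left(self):
        assert precedes(afp(0, 10, 5), afp(10, 0, 5))

    def test_quadrant_layout(self):
        assert precedes(P1, P7) or precedes(P7, P1)  # chainable to P1
        assert precedes(P1, P8) or precedes(P8, P1)
        assert precedes_sequential(P7, P1)  # P7 sequentially before P1
        assert precedes_sequential(P1, P2)
        assert not precedes_sequential(P1, P8)  # P8 only non-sequentially

    def test_sequential_b_overlap_rejected(self):
        assert not precedes_sequential(afp(0, 0, 5), afp(10, 2, 5))

    def test_sequential_implies_general(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            a = afp(int(rng.integers(0, 50)), int(rng.integers(0, 50)),
                    int(rng.integers(3, 15)))
            b = afp(int(rng.integers(0, 50)), int(rng.integers(0, 50)),
                    int(rng.integers(3, 15)))
            if precedes_sequential(a, b):
                assert precedes(a, b)


def _alignment_of(*afps_by_region):
    regions = [RigidRegion(members=list(ms), acc=RmsdAccumulator(n=1))
               for ms in afps_by_region]
    return Alignment(regions=regions, total_score=0.0)


class TestChainable:
    def test_empty_alignment(self):
        assert chainable(Alignment(), P4)

    def test_self_not_chainable(self):
        r = _alignment_of([P1])
        assert not chainable(r, P1)

    def test_quadrant_layout_truth_values(self):
        r = _alignment_of([P1], [P2, P3])
        for p in (P7, P4, P5):
            assert chainable(r, p, "sequential")
        for p in (P6, P8):
            assert chainable(r, p, "flexible")
            assert not chainable(r, p, "sequential")


class TestRmsdPenalty:
    def test_free_below_epsilon(self):
        assert rmsd_penalty(2.0, PARAMS) == (0.0, False)
        assert rmsd_penalty(0.5, PARAMS) == (0.0, False)

    def test_proportional_ramp(self):
        pen, hinge = rmsd_penalty(2.5, PARAMS)
        assert pen == pytest.approx(-5.0)
        assert not hinge

    def test_hinge_above_threshold(self):
        pen, hinge = rmsd_penalty(3.1, PARAMS)
        assert pen == pytest.approx(-10.0)
        assert hinge


class TestConnectionCost:
    def test_consistent_extension_is_free(self):
        coords = random_walk_coords(40, seed=1)
        q = identity_afp(coords, 0, 0, 10)
        region = RigidRegion(members=[q], acc=q.acc.copy())
        p = identity_afp(coords, 10, 10, 10)  # contiguous, same transform
        res = connection_cost(region, p, PARAMS, hinges_used=0)
        assert res.allowed and not res.starts_new_region
        assert res.cost == pytest.approx(0.0)
        assert res.merged_acc.n == 20

    def _hinge_candidate(self):
        coords = random_walk_coords(40, seed=2)
        q = identity_afp(coords, 0, 0, 10)
        region = RigidRegion(members=[q], acc=q.acc.copy())
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = coords[20:30] @ rot.T + np.array([30.0, 0.0, 0.0])
        acc = RmsdAccumulator.from_points(coords[20:30], moved)
        p = Afp(i=20, j=20, l=10, rmsd=0.0, acc=acc)
        p.weight = afp_weight(p, PARAMS)
        merged = rmsd_from_accumulator(
            RmsdAccumulator.from_points(
                np.vstack([coords[0:10], coords[20:30]]),
                np.vstack([coords[0:10], moved])))
        assert merged > PARAMS.d_c  # construction sanity
        return region, p

    def test_hinge_introduced(self):
        region, p = self._hinge_candidate()
        res = connection_cost(region, p, PARAMS, hinges_used=0)
        assert res.allowed and res.starts_new_region
        assert res.cost == pytest.approx(PARAMS.m_r)  # same diagonal: g = 0
        assert res.merged_acc is None

    def test_hinge_budget_exhausted(self):
        region, p = self._hinge_candidate()
        res = connection_cost(region, p, PARAMS, hinges_used=PARAMS.h_max)
        assert not res.allowed

    def test_gap_penalty(self):
        coords = random_walk_coords(60, seed=3)
        q = identity_afp(coords, 0, 0, 10)
        region = RigidRegion(members=[q], acc=q.acc.copy())
        # 4 residues skipped on A, 0 on B -> g = 4
        p_off = identity_afp(coords, 14, 10, 10)
        # the pairing (14..23 <-> 10..19) is not rigid-consistent with the
        # identity region in general; only check the gap term when no hinge
        res = connection_cost(region, p_off, PARAMS, hinges_used=0)
        if res.allowed and not res.starts_new_region:
            merged = rmsd_from_accumulator(
                RmsdAccumulator.from_points(
                    np.vstack([coords[0:10], coords[14:24]]),
                    np.vstack([coords[0:10], coords[10:20]])))
            pen, _ = rmsd_penalty(merged, PARAMS)
            assert res.cost == pytest.approx(pen + PARAMS.m_g * 4)


class TestExtensionScoreAndRegionSelection:
    def test_empty_alignment_scores_weight(self):
        p = afp(0, 0, 10, rmsd=0.0)
        p.acc = RmsdAccumulator.from_points(np.zeros((10, 3)), np.zeros((10, 3)))
        score, conn, ridx = extension_score(Alignment(), p, PARAMS)
        assert score == pytest.approx(afp_weight(p, PARAMS)) == pytest.approx(15.0)
        assert conn is None and ridx == -1

    def test_select_region_nearest_on_a(self):
        r = _alignment_of([P1], [P2, P3])
        # P4 continues to the right: scored against the region of P3
        assert select_region(r, P4) == 1
        # P7 lies before everything: scored against the region of P1
        assert select_region(r, P7) == 0

    def test_score_is_weight_plus_cost(self):
        coords = random_walk_coords(40, seed=4)
        q = identity_afp(coords, 0, 0, 10)
        aln = Alignment(regions=[RigidRegion(members=[q], acc=q.acc.copy())],
                        total_score=q.weight)
        p = identity_afp(coords, 10, 10, 12)
        score, conn, ridx = extension_score(aln, p, PARAMS)
        expected = connection_cost(aln.regions[0], p, PARAMS, 0)
        assert score == pytest.approx(afp_weight(p, PARAMS) + expected.cost)


class TestTrimOverlap:
    def setup_method(self):
        self.coords = random_walk_coords(60, seed=5)

    def _alignment_with(self, *windows):
        regions = []
        for (i, l) in windows:
            q = identity_afp(self.coords, i, i, l)
            regions.append(RigidRegion(members=[q], acc=q.acc.copy()))
        return Alignment(regions=regions, total_score=0.0)

    def test_disjoint_unchanged(self):
        aln = self._alignment_with((0, 10))
        p = identity_afp(self.coords, 20, 20, 12)
        assert trim_overlap(p, aln, PARAMS, self.coords, self.coords) is p

    def test_leading_overlap_trimmed(self):
        aln = self._alignment_with((0, 10))
        p = identity_afp(self.coords, 7, 7, 12)  # offsets 0..2 collide
        sub = trim_overlap(p, aln, PARAMS, self.coords, self.coords)
        assert sub is not None
        assert (sub.i, sub.j, sub.l) == (10, 10, 9)
        # rmsd recomputed for the sub-fragment
        expected = rmsd_from_accumulator(
            RmsdAccumulator.from_points(self.coords[10:19], self.coords[10:19]))
        assert sub.rmsd == pytest.approx(expected, abs=1e-9)

    def test_fully_inside_none(self):
        aln = self._alignment_with((0, 30))
        p = identity_afp(self.coords, 5, 5, 12)
        assert trim_overlap(p, aln, PARAMS, self.coords, self.coords) is None

    def test_too_short_after_trim_none(self):
        aln = self._alignment_with((0, 10))
        p = identity_afp(self.coords, 4, 4, 12)  # only 6 free offsets remain
        assert trim_overlap(p, aln, PARAMS, self.coords, self.coords) is None


class TestGreedyChain:
    def test_single_afp(self):
        coords = random_walk_coords(20, seed=6)
        p = identity_afp(coords, 0, 0, 20)
        aln = greedy_chain([p], PARAMS, p)
        assert aln.hinges == 0
        assert aln.total_score == pytest.approx(afp_weight(p, PARAMS))
        assert aln.n_mat == 20

    def test_self_alignment_rigid_covers_all(self):
        trace = trace_from_coords(random_walk_coords(40, seed=7))
        aln = align(trace, trace, PARAMS, mode="rigid")
        assert coverage(aln, 40, 40) == pytest.approx(100.0)
        assert aln.hinges == 0
        assert aln.pooled_rmsd() == pytest.approx(0.0, abs=1e-5)

    def _interval_instance(self, rng, coords, k, disjoint):
        afps = []
        if disjoint:
            pos = 0
            while len(afps) < k and pos + 8 <= len(coords):
                l = int(rng.integers(8, 13))
                if pos + l > len(coords):
                    break
                afps.append(identity_afp(coords, pos, pos, l))
                pos += l + int(rng.integers(0, 3))
        else:
            for _ in range(k):
                l = int(rng.integers(8, 15))
                i = int(rng.integers(0, len(coords) - l))
                afps.append(identity_afp(coords, i, i, l))
        return afps

    def test_greedy_bounded_by_exhaustive_optimum(self):
        rng = np.random.default_rng(8)
        coords = random_walk_coords(60, seed=8)
        for trial in range(15):
            afps = self._interval_instance(rng, coords, 9, disjoint=False)
            start = max(afps, key=lambda p: p.weight)
            aln = greedy_chain(afps, PARAMS, start, allow_trim=False)
            triples = [(p.i, p.j, p.l) for p in afps]
            weights = [p.weight for p in afps]
            opt = max_weight_consistent_subset(triples, weights)
            assert aln.total_score <= opt + 1e-9

    def test_greedy_optimal_on_disjoint_instances(self):
        rng = np.random.default_rng(9)
        coords = random_walk_coords(80, seed=9)
        for trial in range(10):
            afps = self._interval_instance(rng, coords, 6, disjoint=True)
            start = max(afps, key=lambda p: p.weight)
            aln = greedy_chain(afps, PARAMS, start, allow_trim=False)
            opt = sum(p.weight for p in afps)  # all mutually compatible
            assert aln.total_score == pytest.approx(opt, abs=1e-9)

    def test_score_audit_replay(self, suite):
        aln = suite.flexible("ONE-HINGE")
        # stored total equals the sum of logged step scores
        total = sum(step.weight + step.cost for step in aln.extension_log)
        assert aln.total_score == pytest.approx(total, abs=1e-9)
        # replaying the acceptance order reproduces every logged cost
        start = aln.extension_log[0].afp
        partial = Alignment(
            regions=[RigidRegion(members=[start], acc=start.acc.copy())],
            total_score=aln.extension_log[0].weight)
        for step in aln.extension_log[1:]:
            score, conn, ridx = extension_score(partial, step.afp, suite.params)
            assert score == pytest.approx(step.weight + step.cost, abs=1e-9)
            if conn.starts_new_region:
                partial.regions.append(
                    RigidRegion(members=[step.afp], acc=step.afp.acc.copy()))
            else:
                partial.regions[ridx].members.append(step.afp)
                partial.regions[ridx].acc = conn.merged_acc
        assert len(partial.regions) == len(aln.regions)


class TestAlign:
    def test_unrelated_traces_empty(self):
        ta = trace_from_coords(random_walk_coords(20, seed=10))
        tb = trace_from_coords(random_walk_coords(20, seed=11))
        tight = ScoringParams(epsilon=0.1, d_c=0.1)
        aln = align(ta, tb, tight)
        assert aln.is_empty and aln.n_mat == 0

    def test_exact_copy(self):
        trace = trace_from_coords(random_walk_coords(50, seed=12))
        aln = align(trace, trace, PARAMS)
        assert coverage(aln, 50, 50) == pytest.approx(100.0)
        assert aln.hinges == 0

    def test_small_one_hinge_pair(self):
        spec = FixtureSpec(
            name="mini-hinge", n=60,
            fragments=[FragmentMotion(0, 30),
                       FragmentMotion(30, 60, axis=(0, 1, 0), angle_deg=60.0,
                                      translation=(8.0, -5.0, 4.0))],
            noise_sigma=0.1, rng_seed=21)
        ta, tb, truth, true_hinges = make_pair(spec)
        flex = align(ta, tb, PARAMS, mode="flexible")
        assert flex.hinges == true_hinges == 1
        assert coverage(flex, 60, 60) >= 95.0
        assert all(r.region_rmsd <= 0.5 for r in flex.regions)
        rigid = align(ta, tb, PARAMS, mode="rigid")
        assert (coverage(rigid, 60, 60) < coverage(flex, 60, 60)
                or rigid.pooled_rmsd() > 2.0)

    def test_unknown_mode(self):
        trace = trace_from_coords(random_walk_coords(20, seed=13))
        with pytest.raises(ValueError, match="unknown mode"):
            align(trace, trace, PARAMS, mode="bogus")

    def test_pairs_partial_injection(self, suite):
        for name in suite.names():
            aln = suite.flexible(name)
            pairs = aln.pairs
            assert len(pairs) == aln.n_mat
            assert len({a for a, _ in pairs}) == len(pairs)
            assert len({b for _, b in pairs}) == len(pairs)

    def test_hinge_cap_and_region_threshold(self, suite):
        for name in suite.names():
            aln = suite.flexible(name)
            assert aln.hinges <= suite.params.h_max
            for region in aln.regions:
                assert region.region_rmsd <= suite.params.d_c + 1e-9

    def test_flexible_never_below_rigid(self, suite):
        for name in suite.names():
            ta, tb, _, _ = suite.pair(name)
            flex = suite.flexible(name)
            rigid = align(ta, tb, suite.params, mode="rigid",
                          afps=suite.afps(name))
            assert flex.total_score >= rigid.total_score - 1e-9

    def test_circular_permutation_recovery(self, suite):
        ta, tb, truth, _ = suite.pair("CIRC-PERM")
        flex = suite.flexible("CIRC-PERM")
        assert agreement(flex, truth) >= 90.0
        seq = align(ta, tb, suite.params, mode="sequential",
                    afps=suite.afps("CIRC-PERM"))
        assert agreement(seq, truth) <= 60.0
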