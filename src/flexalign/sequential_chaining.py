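"""Sequential flexible chaining by an endpoint sweep with score-based pruning.

Fragment start/end events are processed in increasing A-coordinate.  When a
fragment starts, it is chained to the best live solution ending strictly in
its upper-left quadrant; when a fragment ends, its solution goes live and
dominated solutions with comparatively low scores are pruned.  Unlike classic
substring chaining — which deletes *every* dominated solution with a lower
score — pruning here keeps dominated solutions whose score is at least
``prune_factor`` times the finishing solution's score, because the RMSD term
breaks the optimal-substructure property: a lower-scoring prefix can still
lead to the better full alignment.

Two connection-cost flavors are provided: ``whole_region`` evaluates the
joint RMSD of the candidate against the entire terminal rigid region (the
default — it guarantees every reported region's RMSD stays below the hinge
threshold), while ``last_segment`` checks only the terminal fragment, which
is cheaper but lets a slowly drifting chain accumulate arbitrarily large
region RMSD before a hinge is ever declared.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .afp_extraction import Afp, afp_weight, extract_afps, filter_contained
from .chaining import Alignment, RigidRegion, _gap_units, rmsd_penalty
from .config import ScoringParams
from .geometry import merge, rmsd_from_accumulator
from .structure_io import CaTrace

__all__ = ["SweepSolution", "sequential_chain", "compare_region_modes"]


@dataclass
class SweepSolution:
    """A live partial alignment ending at a particular AFP."""

    terminal: Afp
    score: float
    back: Optional["SweepSolution"]
    region_acc: object  # RmsdAccumulator of the terminal rigid region
    hinges: int
    new_region: bool  # terminal AFP opened a new rigid region

    @property
    def end_a(self) -> int:
        return self.terminal.end_a

    @property
    def end_b(self) -> int:
        return self.terminal.end_b


def _join(sol: SweepSolution, p: Afp, params: ScoringParams,
          region_cost_mode: str, gap_cost: float) -> Optional[Tuple[float, bool, object]]:
    """Cost and bookkeeping of chaining ``p`` after ``sol``.

    Returns (cost, starts_new_region, new_region_acc) or None if disallowed.
    The joint accumulator always merges the whole region — the mode only
    changes which RMSD the *decision* is based on, which is exactly the
    asymmetry under test between the two flavors.
    """
    merged = merge(sol.region_acc, p.acc)
    if region_cost_mode == "whole_region":
        r_c = rmsd_from_accumulator(merged)
    elif region_cost_mode == "last_segment":
        r_c = rmsd_from_accumulator(merge(sol.terminal.acc, p.acc))
    else:
        raise ValueError(f"unknown region_cost_mode: {region_cost_mode!r}")
    penalty, new_region = rmsd_penalty(r_c, params)
    if new_region and sol.hinges >= params.h_max:
        return None
    cost = penalty + gap_cost
    new_acc = p.acc.copy() if new_region else merged
    return cost, new_region, new_acc


def _solution_to_alignment(sol: SweepSolution, mode_label: str) -> Alignment:
    chain: List[SweepSolution] = []
    cur: Optional[SweepSolution] = sol
    while cur is not None:
        chain.append(cur)
        cur = cur.back
    chain.reverse()
    regions: List[RigidRegion] = []
    for step in chain:
        if step.new_region or not regions:
            regions.append(RigidRegion(members=[step.terminal],
                                       acc=step.terminal.acc.copy()))
        else:
            region = regions[-1]
            region.members.append(step.terminal)
            region.acc = merge(region.acc, step.terminal.acc)
    return Alignment(regions=regions, total_score=sol.score, mode=mode_label)


def sequential_chain(afps: Sequence[Afp], params: ScoringParams | None = None,
                     region_cost_mode: str = "whole_region") -> Alignment:
    """Best sequential flexible alignment over the given AFP set.

    Sweeps start/end events in increasing A-coordinate (ends before starts at
    equal coordinate, ties within a class by B-coordinate).  At a start
    event the AFP is chained to the live solution giving the highest score;
    at an end event the finished solution goes live and dominated live
    solutions scoring below ``prune_factor`` times its score are dropped.
    ``prune_factor`` 1 keeps only the best dominated solution's competitors;
    0 disables pruning entirely.
    """
    params = params or ScoringParams()
    if not afps:
        return Alignment(regions=[], total_score=0.0,
                         mode=f"sequential/{region_cost_mode}")
    for p in afps:
        p.weight = afp_weight(p, params)
    # (coord, kind, b_coord, afp_index): ends (kind 0) before starts (kind 1)
    events = []
    for idx, p in enumerate(afps):
        events.append((p.begin_a, 1, p.begin_b, idx))
        events.append((p.end_a, 0, p.end_b, idx))
    events.sort()
    solutions: List[Optional[SweepSolution]] = [None] * len(afps)
    # live solutions kept sorted by descending score: connection costs are
    # always <= 0, so S(Q) + W(P) bounds any chain through Q and the scan can
    # stop as soon as that bound cannot beat the best join found so far.
    live: List[SweepSolution] = []
    for coord, kind, _bcoord, idx in events:
        p = afps[idx]
        if kind == 1:  # start: chain p to the best live predecessor
            best: Optional[SweepSolution] = None
            best_key = None
            for sol in live:
                if best_key is not None and sol.score + p.weight < best_key[0]:
                    break
                if not (sol.end_a < p.begin_a and sol.end_b < p.begin_b):
                    continue
                # gap penalty alone often disqualifies distant-diagonal
                # predecessors; check it before the O(1)-but-costly SVD merge
                gap_cost = params.m_g * _gap_units(p, sol.terminal)
                if best_key is not None and sol.score + p.weight + gap_cost <= best_key[0]:
                    continue
                joined = _join(sol, p, params, region_cost_mode, gap_cost)
                if joined is None:
                    continue
                cost, new_region, new_acc = joined
                score = sol.score + p.weight + cost
                key = (score, -sol.end_a, -sol.end_b)
                if best_key is None or key > best_key:
                    best_key = key
                    best = SweepSolution(terminal=p, score=score, back=sol,
                                         region_acc=new_acc, hinges=sol.hinges + int(new_region),
                                         new_region=new_region)
            standalone = SweepSolution(terminal=p, score=p.weight, back=None,
                                       region_acc=p.acc.copy(), hinges=0,
                                       new_region=True)
            if best is None or standalone.score > best.score:
                best = standalone
            solutions[idx] = best
        else:  # end: publish the solution, prune dominated low scorers
            sol = solutions[idx]
            if sol is None:  # degenerate single-residue ordering safety
                continue
            if params.prune_factor > 0:
                threshold = params.prune_factor * sol.score
                live = [x for x in live
                        if not (x.end_a < sol.end_a and x.end_b < sol.end_b
                                and x.score < threshold)]
            live.insert(bisect.bisect_left([-x.score for x in live], -sol.score), sol)
    best_sol = max((s for s in solutions if s is not None),
                   key=lambda s: (s.score, -s.terminal.i, -s.terminal.j))
    return _solution_to_alignment(best_sol, f"sequential/{region_cost_mode}")


def compare_region_modes(trace_a: CaTrace, trace_b: CaTrace,
                         params: ScoringParams | None = None):
    """Run both connection-cost flavors on one shared AFP set.

    Returns ``(whole_region_alignment, last_segment_alignment, delta)`` where
    delta reports the differences in aligned length, pooled RMSD, and hinge
    count (whole_region minus last_segment).
    """
    params = params or ScoringParams()
    afps = filter_contained(extract_afps(trace_a, trace_b, params))
    aln_f = sequential_chain(afps, params, region_cost_mode="whole_region")
    aln_l = sequential_chain(afps, params, region_cost_mode="last_segment")
    delta = {
        "n_mat": aln_f.n_mat - aln_l.n_mat,
        "pooled_rmsd": (aln_f.pooled_rmsd() - aln_l.pooled_rmsd()
                        if not (aln_f.is_empty or aln_l.is_empty) else float("nan")),
        "hinges": aln_f.hinges - aln_l.hinges,
    }
    return aln_f, aln_l, delta
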