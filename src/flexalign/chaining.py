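"""Greedy flexible chaining of aligned fragment pairs.

The chaining problem — pick a mutually non-overlapping subset of AFPs
maximizing a score that rewards aligned length and penalizes RMSD growth,
gaps, and hinges — is a maximum-weight clique problem, so it is solved
greedily: grow an alignment from a seed AFP, always adding the AFP whose
extension score is largest, stopping when the best extension is negative.
The search restarts from the K highest-weight mutually non-overlapping seeds
and keeps the best result.

A hinge is introduced when joining a fragment to the current rigid region
would push that region's joint superposition RMSD above the threshold
``d_c``; each rigid region therefore keeps a single transform whose RMSD
never exceeds ``d_c``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from .afp_extraction import Afp, afp_weight, extract_afps, filter_contained
from .config import ScoringParams
from .geometry import (
    RmsdAccumulator,
    Superposition,
    accumulate,
    merge,
    rmsd_from_accumulator,
    superposition_from_accumulator,
)
from .structure_io import CaTrace

__all__ = [
    "ScoringParams",
    "RigidRegion",
    "Alignment",
    "ExtensionStep",
    "precedes",
    "precedes_sequential",
    "compatible",
    "chainable",
    "connection_cost",
    "rmsd_penalty",
    "ConnectionResult",
    "select_region",
    "extension_score",
    "greedy_chain",
    "trim_overlap",
    "align",
    "write_alignment",
    "read_alignment_pairs",
]


# ---------------------------------------------------------------------------
# precedence relations


def precedes(p_a: Afp, p_b: Afp) -> bool:
    """General (non-sequential) precedence: ``p_a`` strictly left of ``p_b``
    along A, and strictly above or strictly below it along B."""
    return p_a.end_a < p_b.begin_a and (
        p_a.end_b < p_b.begin_b or p_a.begin_b > p_b.end_b
    )


def precedes_sequential(p_a: Afp, p_b: Afp) -> bool:
    """Sequential precedence: ``p_a`` strictly in the upper-left quadrant."""
    return p_a.end_a < p_b.begin_a and p_a.end_b < p_b.begin_b


def compatible(p_a: Afp, p_b: Afp, mode: str = "flexible") -> bool:
    """Two AFPs can coexist in one alignment (one precedes the other)."""
    if mode == "sequential":
        return precedes_sequential(p_a, p_b) or precedes_sequential(p_b, p_a)
    return precedes(p_a, p_b) or precedes(p_b, p_a)


# ---------------------------------------------------------------------------
# alignment containers


@dataclass
class RigidRegion:
    """Mutually consistent AFPs sharing one superposition."""

    members: List[Afp]
    acc: RmsdAccumulator

    @property
    def region_rmsd(self) -> float:
        return rmsd_from_accumulator(self.acc)

    @property
    def superposition(self) -> Superposition:
        return superposition_from_accumulator(self.acc)

    def pairs(self) -> List[Tuple[int, int]]:
        out: List[Tuple[int, int]] = []
        for m in self.members:
            out.extend(m.pairs())
        return out

    @property
    def n_pairs(self) -> int:
        return sum(m.l for m in self.members)


@dataclass
class ExtensionStep:
    """One acceptance in the greedy chain, for score auditing."""

    afp: Afp
    weight: float
    cost: float
    region_index: int
    new_region: bool

    @property
    def score(self) -> float:
        return self.weight + self.cost


@dataclass
class Alignment:
    """Ordered rigid regions separated by hinges."""

    regions: List[RigidRegion] = field(default_factory=list)
    total_score: float = 0.0
    mode: str = "flexible"
    extension_log: List[ExtensionStep] = field(default_factory=list)

    @property
    def hinges(self) -> int:
        return max(0, len(self.regions) - 1)

    @property
    def members(self) -> List[Afp]:
        return [m for r in self.regions for m in r.members]

    @property
    def pairs(self) -> Set[Tuple[int, int]]:
        return {p for r in self.regions for p in r.pairs()}

    @property
    def n_mat(self) -> int:
        return sum(r.n_pairs for r in self.regions)

    @property
    def is_empty(self) -> bool:
        return not self.regions

    def pooled_rmsd(self) -> float:
        """RMSD pooled over regions (each pair measured under its own
        region's superposition): sqrt(sum N_r * rmsd_r^2 / sum N_r)."""
        if self.is_empty:
            return float("nan")
        num = sum(r.n_pairs * r.region_rmsd ** 2 for r in self.regions)
        den = sum(r.n_pairs for r in self.regions)
        return float(np.sqrt(num / den))


def chainable(alignment: Alignment, p: Afp, mode: str = "flexible") -> bool:
    """True iff ``p`` overlaps no AFP already in the alignment."""
    return all(compatible(q, p, mode) for q in alignment.members)


# ---------------------------------------------------------------------------
# connection cost and extension score


@dataclass(frozen=True)
class ConnectionResult:
    """Outcome of evaluating a join of an AFP to a rigid region."""

    cost: float
    starts_new_region: bool
    merged_acc: Optional[RmsdAccumulator]
    allowed: bool = True


_REJECTED = ConnectionResult(cost=0.0, starts_new_region=False,
                             merged_acc=None, allowed=False)


def _interval_gap_a(p: Afp, q: Afp) -> int:
    """Non-negative gap between the A-intervals of two AFPs (0 if touching)."""
    return max(0, p.begin_a - q.end_a - 1, q.begin_a - p.end_a - 1)


def _gap_units(p: Afp, q: Afp) -> int:
    """Diagonal-offset gap |dA - dB| between sequentially related AFPs.

    Across a non-sequential (quadrant) jump a diagonal offset is meaningless
    — penalizing it would bias against permuted alignments — so g is 0 there.
    """
    if precedes_sequential(q, p):
        da = p.begin_a - q.end_a - 1
        db = p.begin_b - q.end_b - 1
        return abs(da - db)
    if precedes_sequential(p, q):
        da = q.begin_a - p.end_a - 1
        db = q.begin_b - p.end_b - 1
        return abs(da - db)
    return 0


def _nearest_member(members: Sequence[Afp], p: Afp) -> Afp:
    """Member nearest to ``p`` along A (deterministic tie-breaking)."""
    return min(members, key=lambda q: (_interval_gap_a(p, q), q.begin_a, q.begin_b))


def rmsd_penalty(r_c: float, params: ScoringParams) -> Tuple[float, bool]:
    """Piecewise join penalty: ``(penalty, is_hinge)``.

    Free up to ``epsilon``; a linear ramp from 0 to the full hinge penalty
    ``m_r`` between ``epsilon`` and ``d_c`` (proportional to how far the
    joint RMSD is from ``epsilon``); a hinge at maximum penalty above ``d_c``.
    """
    if r_c <= params.epsilon:
        return 0.0, False
    if r_c <= params.d_c:
        ramp = (r_c - params.epsilon) / (params.d_c - params.epsilon)
        return params.m_r * ramp, False
    return params.m_r, True


def connection_cost(region: RigidRegion, p: Afp, params: ScoringParams,
                    hinges_used: int) -> ConnectionResult:
    """Penalty (<= 0) for joining ``p`` to ``region``.

    The joint RMSD ``r_c`` of the region's accumulator merged with the AFP's
    is evaluated in O(1).  Below ``epsilon`` the join is free; between
    ``epsilon`` and ``d_c`` the penalty ramps linearly up to the full hinge
    penalty ``m_r``; above ``d_c`` a hinge is introduced at maximum penalty
    (rejected outright once ``h_max`` hinges have been spent).  A gap penalty
    ``m_g * |dA - dB|`` against the nearest member of the region is added for
    sequential placements.
    """
    merged = merge(region.acc, p.acc)
    r_c = rmsd_from_accumulator(merged)
    penalty, new_region = rmsd_penalty(r_c, params)
    if new_region:
        if hinges_used >= params.h_max:
            return _REJECTED
        merged = None
    g = _gap_units(p, _nearest_member(region.members, p))
    cost = penalty + params.m_g * g
    return ConnectionResult(cost=cost, starts_new_region=new_region,
                            merged_acc=merged, allowed=True)


def select_region(alignment: Alignment, p: Afp) -> int:
    """Index of the rigid region the join of ``p`` is scored against.

    The region containing the accepted AFP nearest to ``p`` along A.  When
    ``p`` lies to the right of everything accepted, that is the region of the
    rightmost AFP (the "last rigid region"); non-sequential insertions score
    against their nearest neighbor's region.
    """
    best = None
    for ridx, region in enumerate(alignment.regions):
        q = _nearest_member(region.members, p)
        key = (_interval_gap_a(p, q), q.begin_a, q.begin_b)
        if best is None or key < best[0]:
            best = (key, ridx)
    assert best is not None
    return best[1]


def extension_score(alignment: Alignment, p: Afp,
                    params: ScoringParams) -> Tuple[Optional[float],
                                                    Optional[ConnectionResult], int]:
    """Score ``S = W(p) + C`` of chaining ``p`` to the alignment.

    Returns ``(score, connection, region_index)``; score is None when the
    extension is disallowed (hinge budget exhausted).  For an empty alignment
    the score is just the AFP weight.
    """
    w = afp_weight(p, params)
    if alignment.is_empty:
        return w, None, -1
    ridx = select_region(alignment, p)
    conn = connection_cost(alignment.regions[ridx], p, params, alignment.hinges)
    if not conn.allowed:
        return None, None, ridx
    return w + conn.cost, conn, ridx


# ---------------------------------------------------------------------------
# overlap trimming


def trim_overlap(p: Afp, alignment: Alignment, params: ScoringParams,
                 coords_a: np.ndarray, coords_b: np.ndarray,
                 mode: str = "flexible") -> Optional[Afp]:
    """Largest sub-fragment of ``p`` (same diagonal) that is chainable.

    Offsets whose A or B residue falls inside an accepted AFP's interval are
    blocked; the longest unblocked run is re-extended under the RMSD cutoff
    (recomputed from coordinates) and returned if it still meets ``l_min``.
    Returns None when no such sub-fragment exists.
    """
    members = alignment.members
    if not members:
        return p
    blocked = np.zeros(p.l, dtype=bool)
    for q in members:
        lo = max(0, q.begin_a - p.i)
        hi = min(p.l - 1, q.end_a - p.i)
        if lo <= hi:
            blocked[lo:hi + 1] = True
        lo = max(0, q.begin_b - p.j)
        hi = min(p.l - 1, q.end_b - p.j)
        if lo <= hi:
            blocked[lo:hi + 1] = True
    if not blocked.any():
        # no interval collision: either p is already chainable, or the
        # conflict is an ordering inconsistency no trim can repair
        return p if chainable(alignment, p, mode) else None
    # longest run of unblocked offsets
    best_s, best_l, s = 0, 0, None
    for k in range(p.l + 1):
        if k < p.l and not blocked[k]:
            if s is None:
                s = k
        else:
            if s is not None and k - s > best_l:
                best_s, best_l = s, k - s
            s = None
    if best_l < params.l_min:
        return None
    # re-extend under the rmsd cutoff within the window (greedy, like extraction)
    i0, j0 = p.i + best_s, p.j + best_s
    acc = RmsdAccumulator()
    l = 0
    last_ok: Optional[RmsdAccumulator] = None
    while l < best_l:
        acc = accumulate(acc, coords_a[i0 + l], coords_b[j0 + l])
        if rmsd_from_accumulator(acc) > params.epsilon:
            break
        l += 1
        last_ok = acc
    if l < params.l_min or last_ok is None:
        return None
    sub = Afp(i=i0, j=j0, l=l, rmsd=rmsd_from_accumulator(last_ok), acc=last_ok)
    sub.weight = afp_weight(sub, params)
    if not chainable(alignment, sub, mode):
        return None
    return sub


# ---------------------------------------------------------------------------
# greedy chaining


def _candidate_key(score: float, cand: Afp) -> Tuple[float, float, float, int, int]:
    """Sort key for argmax with deterministic tie-breaking:
    higher score, then higher weight, then lower rmsd, then smaller (i, j)."""
    return (score, cand.weight, -cand.rmsd, -cand.i, -cand.j)


def greedy_chain(afps: Sequence[Afp], params: ScoringParams, start: Afp,
                 mode: str = "flexible",
                 coords_a: Optional[np.ndarray] = None,
                 coords_b: Optional[np.ndarray] = None,
                 allow_trim: bool = True) -> Alignment:
    """Grow an alignment greedily from ``start``.

    Every remaining AFP (or, when it overlaps the alignment only at its ends
    and coordinates are available, its trimmed sub-fragment) is scored with
    :func:`extension_score`; the best is accepted while its score is
    non-negative.  ``mode`` selects the precedence relation ("flexible" or
    "sequential"); rigid alignment is flexible chaining with ``h_max`` 0.
    """
    if start.acc is None:
        raise ValueError("start AFP must carry its accumulator")
    start_w = afp_weight(start, params)
    start.weight = start_w
    alignment = Alignment(
        regions=[RigidRegion(members=[start], acc=start.acc.copy())],
        total_score=start_w,
        mode=mode,
        extension_log=[ExtensionStep(afp=start, weight=start_w, cost=0.0,
                                     region_index=0, new_region=True)],
    )
    # descending weight: connection costs are <= 0, so an AFP's weight bounds
    # its extension score and the candidate scan can stop early.
    remaining = sorted((p for p in afps if p is not start),
                       key=lambda p: (-afp_weight(p, params), p.rmsd, p.i, p.j))
    for p in remaining:
        p.weight = afp_weight(p, params)
    can_trim = allow_trim and coords_a is not None and coords_b is not None
    while remaining:
        best = None  # (key, index_in_remaining, cand, conn, ridx)
        for idx, p in enumerate(remaining):
            if best is not None and p.weight < best[0][0]:
                break
            cand = p
            if not chainable(alignment, cand, mode):
                if not can_trim:
                    continue
                cand = trim_overlap(p, alignment, params, coords_a, coords_b, mode)
                if cand is None:
                    continue
            score, conn, ridx = extension_score(alignment, cand, params)
            if score is None:
                continue
            key = _candidate_key(score, cand)
            if best is None or key > best[0]:
                best = (key, idx, cand, conn, ridx)
        if best is None:
            break
        key, idx, cand, conn, ridx = best
        score = key[0]
        if score < 0:
            break
        assert conn is not None
        if conn.starts_new_region:
            alignment.regions.append(RigidRegion(members=[cand], acc=cand.acc.copy()))
            ridx = len(alignment.regions) - 1
        else:
            region = alignment.regions[ridx]
            region.members.append(cand)
            region.acc = conn.merged_acc
        alignment.total_score += score
        alignment.extension_log.append(
            ExtensionStep(afp=cand, weight=cand.weight, cost=conn.cost,
                          region_index=ridx, new_region=conn.starts_new_region)
        )
        remaining.pop(idx)
    return alignment


def _select_starts(afps: Sequence[Afp], k: int, mode: str) -> List[Afp]:
    """The K highest-weight mutually non-overlapping AFPs (greedy selection)."""
    order = sorted(afps, key=lambda p: (-p.weight, p.rmsd, p.i, p.j))
    starts: List[Afp] = []
    for p in order:
        if all(compatible(p, q, mode) for q in starts):
            starts.append(p)
            if len(starts) == k:
                break
    return starts


def align(trace_a: CaTrace, trace_b: CaTrace,
          params: ScoringParams | None = None,
          mode: str = "flexible",
          afps: Optional[Sequence[Afp]] = None) -> Alignment:
    """End-to-end alignment of two Cα traces.

    Extracts AFPs, restarts the greedy chain from the K highest-weight
    non-overlapping seeds, and returns the best-scoring alignment.  An input
    pair with no AFPs yields an empty alignment ("no significant
    similarity"), not an exception.  ``mode`` is "flexible", "rigid"
    (flexible with the hinge budget forced to 0) or "sequential" (greedy
    chaining under the sequential precedence relation).
    """
    params = params or ScoringParams()
    chain_mode = mode
    if mode == "rigid":
        params = params.rigid()
        chain_mode = "flexible"
    elif mode not in ("flexible", "sequential"):
        raise ValueError(f"unknown mode: {mode!r}")
    if afps is None:
        afps = extract_afps(trace_a, trace_b, params)
    afps = filter_contained(list(afps))
    if not afps:
        return Alignment(regions=[], total_score=0.0, mode=mode)
    starts = _select_starts(afps, params.k_restarts, chain_mode)
    best: Optional[Alignment] = None
    best_key = None
    ca = np.asarray(trace_a.coords, dtype=float)
    cb = np.asarray(trace_b.coords, dtype=float)
    for start in starts:
        aln = greedy_chain(afps, params, start, mode=chain_mode,
                           coords_a=ca, coords_b=cb)
        key = (aln.total_score, aln.n_mat, -aln.pooled_rmsd(),
               (-start.i, -start.j))
        if best is None or key > best_key:
            best, best_key = aln, key
    assert best is not None
    best.mode = mode
    return best


# ---------------------------------------------------------------------------
# alignment serialization (TSV body + JSON header line)


def write_alignment(alignment: Alignment, trace_a: CaTrace, trace_b: CaTrace,
                    params: ScoringParams, out) -> None:
    """Write the alignment as TSV with a JSON header line.

    The first line is ``#JSON {...}`` carrying per-region transforms
    (row-major rotation, translation, rmsd), the hinge count, total score,
    mode, and the parameter set; subsequent rows list the equivalenced pairs.
    """
    header = {
        "mode": alignment.mode,
        "total_score": alignment.total_score,
        "hinges": alignment.hinges,
        "n_mat": alignment.n_mat,
        "regions": [
            {
                "rotation": [float(x) for x in r.superposition.rotation.ravel()],
                "translation": [float(x) for x in r.superposition.translation],
                "rmsd": r.region_rmsd,
                "n_pairs": r.n_pairs,
            }
            for r in alignment.regions
        ],
        "params": {
            "l_min": params.l_min, "epsilon": params.epsilon, "d_c": params.d_c,
            "alpha": params.alpha, "m_r": params.m_r, "m_g": params.m_g,
            "h_max": params.h_max, "k_restarts": params.k_restarts,
            "prune_factor": params.prune_factor,
        },
    }
    lines = ["#JSON " + json.dumps(header),
             "region_id\tA_internal_index\tA_author_resnum\tB_internal_index\tB_author_resnum"]
    for ridx, region in enumerate(alignment.regions, start=1):
        for (ia, jb) in sorted(region.pairs()):
            ra = trace_a.residue_labels[ia][0]
            rb = trace_b.residue_labels[jb][0]
            lines.append(f"{ridx}\t{ia}\t{ra}\t{jb}\t{rb}")
    Path(out).write_text("\n".join(lines) + "\n")


def read_alignment_pairs(path):
    """Load an alignment TSV; returns (header dict, list of (region_id, ia, jb))."""
    header = None
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#JSON "):
            header = json.loads(line[len("#JSON "):])
            continue
        if not line or line.startswith("region_id") or line.startswith("#"):
            continue
        parts = line.split("\t")
        rows.append((int(parts[0]), int(parts[1]), int(parts[3])))
    if header is None:
        raise ValueError(f"missing #JSON header in {path}")
    return header, rows
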