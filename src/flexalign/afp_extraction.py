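"""Aligned fragment pair (AFP) enumeration.

An AFP ``(i, j, l)`` equivalences ``l`` consecutive residues starting at
internal index ``i`` of structure A and ``j`` of structure B, subject to
``l >= l_min`` and superposition RMSD ``<= epsilon``.

Enumeration walks every start pair ``(i, j)`` and extends the fragment one
residue at a time, updating the RMSD sufficient statistics in O(1) per step
(prefix sums along the diagonal), so the whole extraction is cubic rather
than quartic.  Only the maximal fragment per start pair is emitted: extension
stops at the first length whose RMSD exceeds epsilon.  Sub-fragments carry no
extra chaining power; the chaining stage re-derives them by trimming when it
needs to resolve overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .config import ScoringParams
from .geometry import RmsdAccumulator, rmsd_from_accumulator
from .structure_io import CaTrace

__all__ = ["Afp", "extract_afps", "afp_weight", "filter_contained", "dump_afps_tsv"]


@dataclass
class Afp:
    """A maximal aligned fragment pair with cached statistics."""

    i: int
    j: int
    l: int
    rmsd: float
    weight: float = 0.0
    acc: Optional[RmsdAccumulator] = field(default=None, repr=False)

    @property
    def begin_a(self) -> int:
        return self.i

    @property
    def end_a(self) -> int:
        return self.i + self.l - 1

    @property
    def begin_b(self) -> int:
        return self.j

    @property
    def end_b(self) -> int:
        return self.j + self.l - 1

    def pairs(self):
        """The l equivalenced (A index, B index) residue pairs."""
        return [(self.i + k, self.j + k) for k in range(self.l)]


def afp_weight(afp: Afp, params: ScoringParams) -> float:
    """Fragment score: length plus an alpha-weighted RMSD bonus.

    ``W = l * (1 + alpha * (epsilon - rmsd) / epsilon)``.  Always positive,
    increasing in length and decreasing in RMSD; the bonus vanishes at the
    RMSD cutoff.  (The exact coefficients are a reconstruction consistent
    with the qualitative description of the score.)
    """
    return afp.l * (1.0 + params.alpha * (params.epsilon - afp.rmsd) / params.epsilon)


class _DiagonalStats:
    """O(1) windowed RMSD statistics along one diagonal of the (A, B) grid.

    For the diagonal starting at ``(i0, j0)`` the k-th pair is
    ``(A[i0+k], B[j0+k])``; prefix sums over k give any window's accumulator
    by subtraction.
    """

    def __init__(self, coords_a: np.ndarray, coords_b: np.ndarray, i0: int, j0: int):
        self.i0, self.j0 = i0, j0
        length = min(coords_a.shape[0] - i0, coords_b.shape[0] - j0)
        self.length = length
        a = coords_a[i0:i0 + length]
        b = coords_b[j0:j0 + length]
        self.csum_a = np.vstack([np.zeros(3), np.cumsum(a, axis=0)])
        self.csum_b = np.vstack([np.zeros(3), np.cumsum(b, axis=0)])
        self.csq_a = np.concatenate([[0.0], np.cumsum(np.einsum("ij,ij->i", a, a))])
        self.csq_b = np.concatenate([[0.0], np.cumsum(np.einsum("ij,ij->i", b, b))])
        outer = np.einsum("ki,kj->kij", a, b)
        self.ccross = np.concatenate([np.zeros((1, 3, 3)), np.cumsum(outer, axis=0)])

    def accumulator(self, s: int, l: int) -> RmsdAccumulator:
        """Accumulator for the window of ``l`` pairs starting at offset ``s``."""
        e = s + l
        return RmsdAccumulator(
            n=l,
            sum_a=self.csum_a[e] - self.csum_a[s],
            sum_b=self.csum_b[e] - self.csum_b[s],
            sum_sq_a=float(self.csq_a[e] - self.csq_a[s]),
            sum_sq_b=float(self.csq_b[e] - self.csq_b[s]),
            cross=self.ccross[e] - self.ccross[s],
        )

    def window_rmsd(self, s: int, l: int) -> float:
        return rmsd_from_accumulator(self.accumulator(s, l))


def extract_afps(trace_a: CaTrace, trace_b: CaTrace,
                 params: ScoringParams | None = None,
                 step_counter: list | None = None) -> List[Afp]:
    """Enumerate all maximal AFPs between two traces.

    For every start pair the fragment is extended greedily: the first length
    whose RMSD exceeds ``params.epsilon`` terminates the extension, and the
    AFP is emitted if the surviving length is at least ``params.l_min``.

    ``step_counter``, if given a one-element list, is incremented once per
    O(1) extension step — used by complexity tests, never by callers.
    """
    params = params or ScoringParams()
    ca = np.asarray(trace_a.coords, dtype=float)
    cb = np.asarray(trace_b.coords, dtype=float)
    n, m = ca.shape[0], cb.shape[0]
    afps: List[Afp] = []
    starts = [(i, 0) for i in range(n)] + [(0, j) for j in range(1, m)]
    for i0, j0 in starts:
        diag = _DiagonalStats(ca, cb, i0, j0)
        if diag.length < params.l_min:
            continue
        for s in range(diag.length - params.l_min + 1):
            max_l = diag.length - s
            l = 0
            while l < max_l:
                if step_counter is not None:
                    step_counter[0] += 1
                if diag.window_rmsd(s, l + 1) > params.epsilon:
                    break
                l += 1
            if l >= params.l_min:
                acc = diag.accumulator(s, l)
                afp = Afp(i=i0 + s, j=j0 + s, l=l,
                          rmsd=rmsd_from_accumulator(acc), acc=acc)
                afp.weight = afp_weight(afp, params)
                afps.append(afp)
    return afps


def filter_contained(afps: List[Afp]) -> List[Afp]:
    """Drop AFPs fully contained in a longer AFP on the same diagonal.

    Per-start maximal extraction emits heavily nested fragments along each
    diagonal (start k+1 is usually a suffix of start k's fragment).  Nested
    fragments add no chaining power — the chaining stage re-derives any
    needed sub-fragment by trimming — so they are removed before chaining to
    keep the candidate set small.
    """
    by_diag: dict = {}
    for p in afps:
        by_diag.setdefault(p.i - p.j, []).append(p)
    kept: List[Afp] = []
    for group in by_diag.values():
        group.sort(key=lambda p: (p.i, -p.l))
        max_end = -1
        for p in group:
            if p.end_a > max_end:
                kept.append(p)
                max_end = p.end_a
    kept.sort(key=lambda p: (p.i, p.j))
    return kept


def dump_afps_tsv(afps: List[Afp], out) -> None:
    """Write the AFP set as a TSV (0-based indices) for debugging/regression."""
    lines = ["i\tj\tl\trmsd\tweight"]
    for p in afps:
        lines.append(f"{p.i}\t{p.j}\t{p.l}\t{p.rmsd:.6f}\t{p.weight:.6f}")
    Path(out).write_text("\n".join(lines) + "\n")
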