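"""Reference-alignment parsing and evaluation metrics.

Agreement measures how much of a curated reference alignment a test
alignment reproduces identically: ``A = 100 * |test ∩ ref| / L_R`` where
``L_R`` is the reference length.  Coverage is the aligned pair count as a
percentage of the smaller structure's length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Set, Tuple

from .chaining import Alignment
from .geometry import superpose
from .structure_io import CaTrace

__all__ = [
    "ReferenceAlignment",
    "EvaluationReport",
    "agreement",
    "coverage",
    "load_reference",
    "write_reference",
    "evaluate",
]


@dataclass
class ReferenceAlignment:
    """A curated set of equivalenced (A internal index, B internal index) pairs."""

    pairs: Set[Tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("reference alignment must contain at least one pair")
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("not an injection: a residue is referenced twice")

    @property
    def length(self) -> int:
        return len(self.pairs)


@dataclass
class EvaluationReport:
    agreement: float
    identical_pairs: int
    coverage: float
    n_mat: int
    region_rmsds: List[float] = field(default_factory=list)
    hinges: int = 0

    def to_dict(self) -> dict:
        return {
            "agreement": self.agreement,
            "identical_pairs": self.identical_pairs,
            "coverage": self.coverage,
            "n_mat": self.n_mat,
            "region_rmsds": self.region_rmsds,
            "hinges": self.hinges,
        }


def agreement(test: Alignment, ref: ReferenceAlignment) -> float:
    """Percentage of the reference's pairs reproduced identically."""
    if ref.length == 0:
        raise ValueError("empty reference alignment")
    identical = len(test.pairs & ref.pairs)
    return 100.0 * identical / ref.length


def coverage(test: Alignment, len_a: int, len_b: int) -> float:
    """Aligned pairs relative to the smaller structure, in percent."""
    if len_a < 1 or len_b < 1:
        raise ValueError("structure lengths must be >= 1")
    return 100.0 * test.n_mat / min(len_a, len_b)


def _author_to_internal(trace: CaTrace) -> dict:
    mapping = {}
    for idx, (resnum, icode, _resname) in enumerate(trace.residue_labels):
        mapping[(resnum, icode)] = idx
    return mapping


def _parse_residue_token(token: str) -> Tuple[int, str]:
    """Author residue token: an integer optionally followed by an insertion
    code letter, e.g. '52' or '52A'."""
    token = token.strip()
    if token and token[-1].isalpha():
        return int(token[:-1]), token[-1]
    return int(token), ""


def load_reference(path, trace_a: CaTrace, trace_b: CaTrace) -> ReferenceAlignment:
    """Load a two-column reference alignment in author residue numbering.

    Each non-comment line pairs one residue of A with one of B; '#' starts a
    comment.  Residue numbers are converted to internal indices via the
    traces; unknown residues and duplicates are rejected with the offending
    line number.
    """
    map_a = _author_to_internal(trace_a)
    map_b = _author_to_internal(trace_b)
    pairs: Set[Tuple[int, int]] = set()
    seen_a: Set[int] = set()
    seen_b: Set[int] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise ValueError(f"line {lineno}: expected two columns, got {len(tokens)}")
        key_a = _parse_residue_token(tokens[0])
        key_b = _parse_residue_token(tokens[1])
        if key_a not in map_a:
            raise ValueError(f"line {lineno}: residue {tokens[0]} not in trace A")
        if key_b not in map_b:
            raise ValueError(f"line {lineno}: residue {tokens[1]} not in trace B")
        ia, jb = map_a[key_a], map_b[key_b]
        if ia in seen_a or jb in seen_b:
            raise ValueError(f"line {lineno}: not an injection (duplicate residue)")
        seen_a.add(ia)
        seen_b.add(jb)
        pairs.add((ia, jb))
    return ReferenceAlignment(pairs=pairs)


def write_reference(pairs, trace_a: CaTrace, trace_b: CaTrace, out) -> None:
    """Write pairs (internal indices) in the two-column author-number format."""
    lines = ["# A_resnum B_resnum"]
    for ia, jb in sorted(pairs):
        ra, ica, _ = trace_a.residue_labels[ia]
        rb, icb, _ = trace_b.residue_labels[jb]
        lines.append(f"{ra}{ica} {rb}{icb}")
    Path(out).write_text("\n".join(lines) + "\n")


def recompute_region_rmsds(alignment: Alignment, trace_a: CaTrace,
                           trace_b: CaTrace) -> List[float]:
    """Per-region RMSD recomputed from coordinates by explicit superposition
    (independent of the accumulators kept during chaining)."""
    out = []
    for region in alignment.regions:
        prs = region.pairs()
        a_pts = trace_a.coords[[ia for ia, _ in prs]]
        b_pts = trace_b.coords[[jb for _, jb in prs]]
        out.append(superpose(a_pts, b_pts).rmsd)
    return out


def evaluate(test: Alignment, trace_a: CaTrace, trace_b: CaTrace,
             ref: ReferenceAlignment | None = None) -> EvaluationReport:
    """Full evaluation report for an alignment (agreement only if a
    reference is supplied)."""
    agr = agreement(test, ref) if ref is not None else float("nan")
    identical = len(test.pairs & ref.pairs) if ref is not None else 0
    return EvaluationReport(
        agreement=agr,
        identical_pairs=identical,
        coverage=coverage(test, len(trace_a), len(trace_b)),
        n_mat=test.n_mat,
        region_rmsds=recompute_region_rmsds(test, trace_a, trace_b),
        hinges=test.hinges,
    )
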