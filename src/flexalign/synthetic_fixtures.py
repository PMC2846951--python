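"""Deterministic synthetic structure pairs with known ground truth.

Each fixture builds a template Cα backbone, cuts it into fragments, applies
an independent rigid motion per fragment (hinges), optionally reorders the
fragments (circular permutation), and adds isotropic Gaussian coordinate
noise.  The true residue correspondence and the true hinge count are
returned alongside the pair, so alignment recovery can be scored exactly
with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .alignment_io_eval import ReferenceAlignment
from .structure_io import CaTrace

__all__ = ["FragmentMotion", "FixtureSpec", "make_pair", "fixture_suite"]

CA_SPACING = 3.8  # canonical consecutive-Cα distance, Å


@dataclass(frozen=True)
class FragmentMotion:
    """Rigid motion of one backbone fragment [start, end).

    Rotation is ``angle_deg`` about ``axis`` through the fragment's centroid,
    followed by ``translation``.  (A centroid pivot displaces residues near
    the fragment boundaries, keeping hinges geometrically sharp; a pivot on
    the junction residue would let fragments spanning the junction superpose
    within the AFP cutoff.)
    """

    start: int
    end: int
    axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    angle_deg: float = 0.0
    translation: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def motion_key(self):
        return (tuple(np.round(self.axis, 9)), round(self.angle_deg, 9),
                tuple(np.round(self.translation, 9)))

    def is_identity(self) -> bool:
        return self.angle_deg == 0.0 and not any(self.translation)


@dataclass
class FixtureSpec:
    name: str
    n: int
    fragments: List[FragmentMotion]
    permutation: Optional[Tuple[int, ...]] = None  # fragment output order in B
    noise_sigma: float = 0.0
    rng_seed: int = 0
    backbone: str = "walk"  # "walk" (smoothed random walk) or "helix"

    def __post_init__(self) -> None:
        covered = []
        for f in self.fragments:
            if not (0 <= f.start < f.end <= self.n):
                raise ValueError(f"fragment [{f.start}, {f.end}) out of range")
            covered.append((f.start, f.end))
        covered.sort()
        pos = 0
        for s, e in covered:
            if s != pos:
                raise ValueError("fragments must tile [0, n) without overlap or gap")
            pos = e
        if pos != self.n:
            raise ValueError("fragments must tile [0, n) without overlap or gap")
        if self.permutation is not None:
            if sorted(self.permutation) != list(range(len(self.fragments))):
                raise ValueError("permutation must reorder all fragments")


def _walk_backbone(n: int, rng: np.random.Generator) -> np.ndarray:
    """Smoothed random walk with exact 3.8 Å steps — irregular local geometry
    so that only genuinely corresponding windows superpose well."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    coords = np.zeros((n, 3))
    for k in range(1, n):
        direction = direction + 0.45 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[k] = coords[k - 1] + CA_SPACING * direction
    return coords


def _helix_backbone(n: int, rng: np.random.Generator) -> np.ndarray:
    """Helix-like parametric curve with modulated radius and pitch, marched
    at 3.8 Å arc steps.  Modulation breaks the translational self-similarity
    of a perfect helix."""
    ph = rng.uniform(0, 2 * np.pi, size=3)

    def point(t: float) -> np.ndarray:
        r = 9.0 + 2.5 * np.sin(0.37 * t + ph[0]) + 1.5 * np.sin(0.11 * t + ph[1])
        z = 1.6 * t + 0.9 * np.sin(0.23 * t + ph[2])
        return np.array([r * np.cos(t), r * np.sin(t), z])

    coords = [point(0.0)]
    t = 0.0
    for _ in range(1, n):
        lo, hi = t, t + 1.0
        while np.linalg.norm(point(hi) - coords[-1]) < CA_SPACING:
            hi += 0.5
        for _ in range(60):  # bisection to the 3.8 Å step
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(point(mid) - coords[-1]) < CA_SPACING:
                lo = mid
            else:
                hi = mid
        t = 0.5 * (lo + hi)
        coords.append(point(t))
    return np.asarray(coords)


def _labels(n: int) -> List[Tuple[int, str, str]]:
    return [(k + 1, "", "GLY") for k in range(n)]


def make_pair(spec: FixtureSpec):
    """Build ``(trace_a, trace_b, truth, true_hinges)`` from a spec.

    ``trace_b`` is the template with each fragment rigidly moved, fragments
    emitted in permutation order, and per-atom Gaussian noise added after the
    motions.  ``truth`` pairs every template residue with its copy.
    ``true_hinges`` is the number of distinct fragment motions minus one.
    """
    rng = np.random.default_rng(spec.rng_seed)
    backbone = {"walk": _walk_backbone, "helix": _helix_backbone}[spec.backbone](spec.n, rng)
    spacing = np.linalg.norm(np.diff(backbone, axis=0), axis=1)
    assert np.all(np.abs(spacing - CA_SPACING) <= 0.4), "backbone spacing out of range"

    moved_fragments = []
    for frag in spec.fragments:
        pts = backbone[frag.start:frag.end]
        if frag.is_identity():
            moved = pts.copy()
        else:
            axis = np.asarray(frag.axis, dtype=float)
            axis /= np.linalg.norm(axis)
            rot = Rotation.from_rotvec(np.deg2rad(frag.angle_deg) * axis)
            pivot = pts.mean(axis=0)
            moved = rot.apply(pts - pivot) + pivot + np.asarray(frag.translation)
        moved_fragments.append(moved)

    order = spec.permutation or tuple(range(len(spec.fragments)))
    coords_b = np.vstack([moved_fragments[f] for f in order])
    # truth: template residue a -> its position in the permuted B ordering
    pairs = set()
    pos = 0
    for f in order:
        frag = spec.fragments[f]
        for a_idx in range(frag.start, frag.end):
            pairs.add((a_idx, pos))
            pos += 1
    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng(spec.rng_seed + 10_000)
        coords_b = coords_b + noise_rng.normal(0.0, spec.noise_sigma, coords_b.shape)

    trace_a = CaTrace(structure_id=f"{spec.name}_A", chain_id="A",
                      residue_labels=_labels(spec.n), coords=backbone)
    trace_b = CaTrace(structure_id=f"{spec.name}_B", chain_id="B",
                      residue_labels=_labels(spec.n), coords=coords_b)
    true_hinges = len({f.motion_key() for f in spec.fragments}) - 1
    return trace_a, trace_b, ReferenceAlignment(pairs=pairs), true_hinges


def fixture_suite() -> List[FixtureSpec]:
    """The canonical seeded fixture suite used by the acceptance tests."""
    suite = [
        FixtureSpec(
            name="RIGID-COPY", n=100,
            fragments=[FragmentMotion(0, 100, axis=(0.3, 0.8, 0.5),
                                      angle_deg=35.0, translation=(6.0, -3.0, 2.0))],
            noise_sigma=0.1, rng_seed=11,
        ),
        FixtureSpec(
            name="ONE-HINGE", n=120,
            fragments=[
                FragmentMotion(0, 60),
                FragmentMotion(60, 120, axis=(0.0, 1.0, 0.0), angle_deg=60.0),
            ],
            noise_sigma=0.1, rng_seed=12,
        ),
        FixtureSpec(
            name="TWO-HINGE", n=150,
            fragments=[
                FragmentMotion(0, 50),
                FragmentMotion(50, 100, axis=(1.0, 0.0, 0.0), angle_deg=55.0),
                FragmentMotion(100, 150, axis=(0.0, 0.2, 1.0), angle_deg=-75.0,
                               translation=(2.0, 2.0, -4.0)),
            ],
            noise_sigma=0.1, rng_seed=13,
        ),
        FixtureSpec(
            name="CIRC-PERM", n=100,
            fragments=[FragmentMotion(0, 50), FragmentMotion(50, 100)],
            permutation=(1, 0),
            noise_sigma=0.1, rng_seed=14,
        ),
        FixtureSpec(
            name="DRIFT", n=160,
            fragments=[
                FragmentMotion(20 * k, 20 * (k + 1), axis=(0.2, 0.9, 0.4),
                               angle_deg=4.2 * k)
                for k in range(8)
            ],
            noise_sigma=0.05, rng_seed=15,
        ),
    ]
    return suite


def get_fixture(name: str) -> FixtureSpec:
    for spec in fixture_suite():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown fixture: {name!r}")
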