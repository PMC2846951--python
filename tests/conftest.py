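from __future__ import annotations

import numpy as np
import pytest

from flexalign.afp_extraction import extract_afps, filter_contained
from flexalign.chaining import align
from flexalign.config import ScoringParams
from flexalign.structure_io import CaTrace
from flexalign.synthetic_fixtures import fixture_suite, get_fixture, make_pair


def random_walk_coords(n: int, seed: int) -> np.ndarray:
    """Small independent random-walk backbone for throwaway test traces."""
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    coords = np.zeros((n, 3))
    for k in range(1, n):
        direction = direction + 0.5 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[k] = coords[k - 1] + 3.8 * direction
    return coords


def trace_from_coords(coords, name="t", chain="A") -> CaTrace:
    coords = np.asarray(coords, dtype=float)
    labels = [(k + 1, "", "GLY") for k in range(coords.shape[0])]
    return CaTrace(structure_id=name, chain_id=chain,
                   residue_labels=labels, coords=coords)


class SuiteCache:
    """Lazily computed, session-shared fixture data (extraction is the
    expensive step, so it runs at most once per fixture pair)."""

    def __init__(self):
        self._pairs = {}
        self._afps = {}
        self._flexible = {}
        self._self_aligned = {}
        self.params = ScoringParams()

    def names(self):
        return [s.name for s in fixture_suite()]

    def pair(self, name):
        if name not in self._pairs:
            self._pairs[name] = make_pair(get_fixture(name))
        return self._pairs[name]

    def afps(self, name):
        if name not in self._afps:
            ta, tb, _, _ = self.pair(name)
            self._afps[name] = filter_contained(extract_afps(ta, tb, self.params))
        return self._afps[name]

    def flexible(self, name):
        if name not in self._flexible:
            ta, tb, _, _ = self.pair(name)
            self._flexible[name] = align(ta, tb, self.params, mode="flexible",
                                         afps=self.afps(name))
        return self._flexible[name]

    def self_rigid(self, name):
        if name not in self._self_aligned:
            ta, _, _, _ = self.pair(name)
            self._self_aligned[name] = align(ta, ta, self.params, mode="rigid")
        return self._self_aligned[name]


@pytest.fixture(scope="session")
def suite():
    return SuiteCache()


@pytest.fixture(scope="session")
def default_params():
    return ScoringParams()
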