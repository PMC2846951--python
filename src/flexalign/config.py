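"""Scoring parameters shared by extraction and chaining."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ScoringParams"]


@dataclass
class ScoringParams:
    """Tunable parameters of the alignment engine.

    Defaults are the empirically tuned operating point: minimum fragment
    length 8, fragment RMSD cutoff 2 Å, hinge threshold 3 Å, alpha 0.5,
    hinge penalty -10, gap penalty -1, at most 3 hinges.

    ``seed`` is reserved for future stochastic restart strategies; the
    algorithm as implemented is fully deterministic.
    """

    l_min: int = 8
    epsilon: float = 2.0
    d_c: float = 3.0
    alpha: float = 0.5
    m_r: float = -10.0
    m_g: float = -1.0
    h_max: int = 3
    k_restarts: int = 10
    prune_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.d_c < self.epsilon:
            raise ValueError("d_c must be >= epsilon")
        if self.h_max < 0:
            raise ValueError("h_max must be >= 0")
        if self.l_min < 3:
            raise ValueError("l_min must be >= 3")
        if self.m_r > 0 or self.m_g > 0:
            raise ValueError("penalties must be <= 0")
        if not (0.0 <= self.prune_factor <= 1.0):
            raise ValueError("prune_factor must be in [0, 1]")
        if self.k_restarts < 1:
            raise ValueError("k_restarts must be >= 1")

    def rigid(self) -> "ScoringParams":
        """Copy of the parameters with hinges disabled."""
        return ScoringParams(
            l_min=self.l_min, epsilon=self.epsilon, d_c=self.d_c,
            alpha=self.alpha, m_r=self.m_r, m_g=self.m_g, h_max=0,
            k_restarts=self.k_restarts, prune_factor=self.prune_factor,
            seed=self.seed,
        )
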