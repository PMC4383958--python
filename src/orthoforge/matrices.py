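"""PAM-style amino-acid substitution model and log-odds scoring matrices.

The model is a 20-state reversible Markov process of the Felsenstein-81 type:
every substitution lands on residue ``j`` with probability proportional to the
equilibrium frequency ``pi_j`` (Dayhoff composition).  The transition matrix
therefore has the closed form

    P_ij(d) = exp(-beta*d) * delta_ij + pi_j * (1 - exp(-beta*d))

with ``beta`` calibrated so that one PAM unit corresponds to an expected 1% of
sites accepting a substitution, i.e. ``sum_i pi_i P_ii(1) = 0.99``.  The closed
form gives exact expected identities, exact log-likelihoods for distance
estimation, and an exact simulation recipe — the same model drives scoring,
maximum-likelihood distances and the sequence simulator.

Scores follow the Dayhoff convention ``s_ij = 10 * log10(P_ij(d) / pi_j)``
(rounded to integers for alignment); reversibility makes them symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}

# Dayhoff (1978) amino-acid composition, renormalised to sum to one.
_DAYHOFF = {
    "A": 0.087, "R": 0.041, "N": 0.040, "D": 0.047, "C": 0.033,
    "Q": 0.038, "E": 0.050, "G": 0.089, "H": 0.034, "I": 0.037,
    "L": 0.085, "K": 0.081, "M": 0.015, "F": 0.040, "P": 0.051,
    "S": 0.070, "T": 0.058, "W": 0.010, "Y": 0.030, "V": 0.065,
}


def equilibrium_frequencies() -> np.ndarray:
    """Equilibrium residue frequencies in ``AA20`` order (sums to 1)."""
    pi = np.array([_DAYHOFF[a] for a in AA20], dtype=float)
    return pi / pi.sum()


@lru_cache(maxsize=1)
def _model_constants() -> tuple[tuple[float, ...], float]:
    pi = equilibrium_frequencies()
    s = float(np.sum(pi**2))
    # identity(d) = exp(-beta d) + S (1 - exp(-beta d));  identity(1) = 0.99
    beta = -math.log((0.99 - s) / (1.0 - s))
    return tuple(pi), beta


class PamModel:
    """The substitution process: transition matrices, identities, likelihoods."""

    def __init__(self) -> None:
        pi_t, beta = _model_constants()
        self.pi = np.asarray(pi_t)
        self.beta = beta
        self._homogeneity = float(np.sum(self.pi**2))

    def decay(self, d: float) -> float:
        return math.exp(-self.beta * d)

    def transition(self, d: float) -> np.ndarray:
        """20x20 matrix of P(residue j at time d | residue i at time 0)."""
        e = self.decay(d)
        return e * np.eye(20) + (1.0 - e) * self.pi[None, :]

    def expected_identity(self, d: float) -> float:
        """Probability that a site shows the same residue after distance d."""
        e = self.decay(d)
        return e + (1.0 - e) * self._homogeneity

    def log_odds(self, d: float) -> np.ndarray:
        """Real-valued 10*log10(P_ij/pi_j) matrix (symmetric)."""
        p = self.transition(d)
        return 10.0 * np.log10(p / self.pi[None, :])

    def pair_log_likelihood(self, match_counts: np.ndarray, n_mismatch: int,
                            d: float) -> float:
        """Natural-log likelihood of an ungapped column profile at distance d.

        ``match_counts[i]`` is the number of aligned columns where both
        sequences carry residue ``i``; ``n_mismatch`` the number of columns
        with differing residues.  Constant terms in the residue priors are
        dropped (they do not affect the location or curvature of the maximum).
        """
        d = max(d, 1e-9)
        e = self.decay(d)
        diag = e + self.pi * (1.0 - e)          # P_ii(d)
        off = 1.0 - e                            # P_ij(d)/pi_j for i != j
        ll = float(np.dot(match_counts, np.log(diag / self.pi)))
        if n_mismatch:
            ll += n_mismatch * math.log(off)
        return ll


@dataclass(frozen=True)
class ScoringMatrixFamily:
    """A grid of integer log-odds matrices over ascending PAM distances.

    ``matrices[k]`` scores alignments at evolutionary distance ``grid[k]``;
    ``reference_index`` selects the matrix used for the initial
    Smith–Waterman search (scores at other grid points are obtained by
    re-scoring the fixed alignment).  Gap penalties are in matrix units and a
    gap of length ``l`` costs ``-(gap_open + (l-1)*gap_extend)``.
    """

    grid: tuple[float, ...]
    gap_open: int = 12
    gap_extend: int = 2
    reference_distance: float = 120.0
    model: PamModel = field(default_factory=PamModel, compare=False)
    matrices: tuple[np.ndarray, ...] = field(init=False, compare=False)
    reference_index: int = field(init=False)

    def __post_init__(self) -> None:
        mats = tuple(
            np.rint(self.model.log_odds(d)).astype(np.int32) for d in self.grid
        )
        object.__setattr__(self, "matrices", mats)
        ref = int(np.argmin([abs(d - self.reference_distance) for d in self.grid]))
        object.__setattr__(self, "reference_index", ref)

    @property
    def reference_matrix(self) -> np.ndarray:
        return self.matrices[self.reference_index]


DEFAULT_GRID = tuple(float(d) for d in range(10, 301, 10))


def build_matrix_family(grid_spec=DEFAULT_GRID, gap_open: int = 12,
                        gap_extend: int = 2,
                        reference_distance: float = 120.0) -> ScoringMatrixFamily:
    """Build the scoring family for an ascending, positive PAM grid.

    Deterministic: the same ``grid_spec`` always yields bitwise-identical
    matrices.
    """
    grid = tuple(float(g) for g in grid_spec)
    if not grid:
        raise ValueError("grid_spec must be non-empty")
    if any(g <= 0 for g in grid):
        raise ValueError("grid distances must be positive")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid distances must be strictly increasing")
    return ScoringMatrixFamily(grid=grid, gap_open=gap_open,
                               gap_extend=gap_extend,
                               reference_distance=reference_distance)
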