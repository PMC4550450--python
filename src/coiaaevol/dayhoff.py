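"""Dayhoff-1978 (PAM) empirical amino-acid substitution model.

The model is specified by a symmetric exchangeability matrix ``S`` and
equilibrium frequencies ``pi``.  The instantaneous rate matrix is
``Q_ij = S_ij * pi_j`` (i != j), with the diagonal set so rows sum to
zero, and the whole matrix scaled so the expected substitution rate at
equilibrium, ``-sum_i pi_i Q_ii``, equals 1.  Branch lengths / distances
are then in expected substitutions per site.

The numerical values below are the canonical Dayhoff-1978 tables as
distributed with phylogenetic software (the classic ``dayhoff.dat``
exchangeabilities, lower triangle, and the matching frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

#: Canonical amino-acid ordering used throughout the package.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Lower triangle (row-major: row i lists columns 0..i-1) of the Dayhoff-78
# exchangeabilities, in the AMINO_ACIDS order.
_DAYHOFF_LOWER = (
    (27,),
    (98, 32),
    (120, 0, 905),
    (36, 23, 0, 0),
    (89, 246, 103, 134, 0),
    (198, 1, 148, 1153, 0, 716),
    (240, 9, 139, 125, 11, 28, 81),
    (23, 240, 535, 86, 28, 606, 43, 10),
    (65, 64, 77, 24, 44, 18, 61, 0, 7),
    (41, 15, 34, 0, 0, 73, 11, 7, 44, 257),
    (26, 464, 318, 71, 0, 153, 83, 27, 26, 46, 18),
    (72, 90, 1, 0, 0, 114, 30, 17, 0, 336, 527, 243),
    (18, 14, 14, 0, 0, 0, 0, 15, 48, 196, 157, 0, 92),
    (250, 103, 42, 13, 19, 153, 51, 34, 94, 12, 32, 33, 17, 11),
    (409, 154, 495, 95, 161, 56, 79, 234, 35, 24, 17, 96, 62, 46, 245),
    (371, 26, 229, 66, 16, 53, 34, 30, 22, 192, 33, 136, 104, 13, 78, 550),
    (0, 201, 23, 0, 0, 0, 0, 0, 27, 0, 46, 0, 0, 76, 0, 75, 0),
    (24, 8, 95, 0, 96, 0, 22, 0, 127, 37, 28, 13, 0, 698, 0, 34, 42, 61),
    (208, 24, 15, 18, 49, 35, 37, 54, 44, 889, 175, 10, 258, 12, 48, 30,
     157, 0, 28),
)

# Dayhoff-78 equilibrium frequencies (same ordering); normalized at load.
_DAYHOFF_FREQS = (
    0.087127, 0.040904, 0.040432, 0.046872, 0.033474,
    0.038255, 0.049530, 0.088612, 0.033618, 0.036886,
    0.085357, 0.080482, 0.014753, 0.039772, 0.050680,
    0.069577, 0.058542, 0.010494, 0.029916, 0.064718,
)


@dataclass
class SubstitutionModel:
    """A time-reversible amino-acid CTMC with unit expected rate.

    Attributes
    ----------
    exchangeabilities : (20, 20) symmetric nonnegative matrix.
    equilibrium_freqs : (20,) probability vector ``pi``.
    rate_matrix : (20, 20) matrix ``Q`` with zero row sums, scaled so the
        equilibrium substitution rate is 1.
    """

    exchangeabilities: np.ndarray
    equilibrium_freqs: np.ndarray
    rate_matrix: np.ndarray
    name: str = "dayhoff"
    _eigen: tuple | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_exchangeabilities(cls, S: np.ndarray, pi: np.ndarray,
                               name: str = "custom") -> "SubstitutionModel":
        S = np.asarray(S, dtype=float)
        pi = np.asarray(pi, dtype=float)
        pi = pi / pi.sum()
        Q = S * pi[np.newaxis, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.sum(pi * np.diag(Q))
        Q = Q / rate
        return cls(S, pi, Q, name=name)

    def _eigendecomposition(self):
        if self._eigen is None:
            d = np.sqrt(self.equilibrium_freqs)
            # similarity transform to a symmetric matrix: same spectrum
            B = (d[:, None] * self.rate_matrix) / d[None, :]
            B = 0.5 * (B + B.T)  # enforce exact symmetry
            w, V = np.linalg.eigh(B)
            left = V / d[:, None]
            right = (V * d[:, None]).T
            self._eigen = (w, left, right)
        return self._eigen

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are conditional distributions."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        w, left, right = self._eigendecomposition()
        P = (left * np.exp(w * t)) @ right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def log_odds_matrix(self, t: float = 2.5) -> np.ndarray:
        """Half-bit log-odds scores, ``2 * log2(P_ij(t) / pi_j)``.

        At ``t = 2.5`` (250 PAM) this is the PAM250-style scoring matrix
        implied by the model; it is symmetric by reversibility.
        """
        P = self.transition_matrix(t)
        with np.errstate(divide="ignore"):
            s = 2.0 * np.log2(P / self.equilibrium_freqs[None, :])
        s = 0.5 * (s + s.T)
        return s


@lru_cache(maxsize=1)
def load_dayhoff_model() -> SubstitutionModel:
    """Build the normalized Dayhoff-1978 model."""
    S = np.zeros((20, 20))
    for i, row in enumerate(_DAYHOFF_LOWER, start=1):
        for j, v in enumerate(row):
            S[i, j] = S[j, i] = float(v)
    return SubstitutionModel.from_exchangeabilities(
        S, np.array(_DAYHOFF_FREQS), name="dayhoff")


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """Module-level convenience wrapper for ``model.transition_matrix``."""
    return model.transition_matrix(t)
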