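"""Pairwise protein distances: uncorrected p and ML Dayhoff distance.

Gapped or ambiguous (X) sites are excluded pair by pair ("pairwise
deletion"), so each pair is compared over its own set of sites.  The
Dayhoff distance is the maximum-likelihood branch length t of a
two-sequence tree under the Dayhoff-78 CTMC:

    d = argmax_t  sum_sites log( pi[a_i] * P[a_i, b_i](t) )

which by time reversibility is symmetric in the two sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .alignment import AlignedProtein
from .dayhoff import AA_INDEX, SubstitutionModel, load_dayhoff_model

D_MAX = 10.0
_T_MIN = 1e-6

_ENCODE = np.full(128, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _ENCODE[ord(_aa)] = _i


def encode(seq: str | AlignedProtein) -> np.ndarray:
    """Residues as 0..19; gaps, X and anything nonstandard as -1."""
    if isinstance(seq, AlignedProtein):
        seq = seq.columns
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[arr]


def p_distance(a, b) -> tuple[float, int]:
    """Proportion of differing residues over pairwise-complete sites.

    Returns ``(p, n_sites)``; ``p`` is NaN when no site is comparable.
    """
    ea, eb = encode(a), encode(b)
    if ea.shape != eb.shape:
        raise ValueError("sequences have different column counts")
    mask = (ea >= 0) & (eb >= 0)
    n = int(mask.sum())
    if n == 0:
        return float("nan"), 0
    p = float(np.count_nonzero(ea[mask] != eb[mask])) / n
    return p, n


def _neg_log_likelihood(counts: np.ndarray, model: SubstitutionModel):
    idx = np.nonzero(counts)
    c = counts[idx].astype(float)

    def nll(t: float) -> float:
        P = model.transition_matrix(t)
        return -float(np.sum(c * np.log(np.maximum(P[idx], 1e-300))))

    return nll


def dayhoff_distance(a, b, model: SubstitutionModel | None = None,
                     d_max: float = D_MAX) -> float:
    """ML distance in expected substitutions/site under the Dayhoff model.

    Identical pairs return exactly 0.  The optimum is bracketed by a
    50-point log-spaced grid on [1e-6, d_max] and refined by Brent's
    method; a likelihood still rising at the upper grid end (saturation)
    returns ``d_max``.
    """
    if model is None:
        model = load_dayhoff_model()
    ea, eb = encode(a), encode(b)
    if ea.shape != eb.shape:
        raise ValueError("sequences have different column counts")
    return dayhoff_distance_encoded(ea, eb, model, d_max=d_max)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances plus per-pair compared-site counts."""

    ids: list[str]
    values: np.ndarray       # (n, n) float; NaN marks missing pairs
    sites_compared: np.ndarray  # (n, n) int
    metric: str              # 'p' or 'dayhoff'

    def __post_init__(self):
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    def get(self, id1: str, id2: str) -> float:
        return float(self.values[self._index[id1], self._index[id2]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_square_tsv(self, path: Path | str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id",
                                   float_format="%.6f")

    def write_long_tsv(self, path: Path | str) -> None:
        rows = []
        for i, a in enumerate(self.ids):
            for j in range(i + 1, len(self.ids)):
                rows.append((a, self.ids[j], self.metric,
                             self.values[i, j], int(self.sites_compared[i, j])))
        pd.DataFrame(rows, columns=["id1", "id2", "metric", "value", "n_sites"]
                     ).to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def read_square_tsv(cls, path: Path | str, metric: str = "dayhoff"
                        ) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        values = df.to_numpy(dtype=float)
        n = len(df)
        return cls(list(df.index), values, np.zeros((n, n), dtype=int), metric)


def distance_matrix(rows: list[AlignedProtein] | dict[str, str], metric: str,
                    model: SubstitutionModel | None = None) -> DistanceMatrix:
    """All pairwise distances under the chosen metric ('p' or 'dayhoff')."""
    if metric not in ("p", "dayhoff"):
        raise ValueError(f"unknown metric {metric!r}")
    if isinstance(rows, dict):
        items = [(rid, rows[rid]) for rid in rows]
    else:
        items = [(r.record_id, r) for r in rows]
    if len(items) < 2:
        raise ValueError("need at least 2 rows")
    if model is None and metric == "dayhoff":
        model = load_dayhoff_model()
    ids = [rid for rid, _ in items]
    enc = [encode(seq) for _, seq in items]
    n = len(items)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "p":
                d, m = p_distance_encoded(enc[i], enc[j])
            else:
                d = dayhoff_distance_encoded(enc[i], enc[j], model)
                m = int(((enc[i] >= 0) & (enc[j] >= 0)).sum())
            values[i, j] = values[j, i] = d
            sites[i, j] = sites[j, i] = m
    return DistanceMatrix(ids, values, sites, metric)


# encoded-input variants (skip re-encoding in hot loops)

def p_distance_encoded(ea: np.ndarray, eb: np.ndarray) -> tuple[float, int]:
    mask = (ea >= 0) & (eb >= 0)
    n = int(mask.sum())
    if n == 0:
        return float("nan"), 0
    return float(np.count_nonzero(ea[mask] != eb[mask])) / n, n


def dayhoff_distance_encoded(ea: np.ndarray, eb: np.ndarray,
                             model: SubstitutionModel,
                             d_max: float = D_MAX) -> float:
    mask = (ea >= 0) & (eb >= 0)
    n = int(mask.sum())
    if n == 0:
        return float("nan")
    if not np.any(ea[mask] != eb[mask]):
        return 0.0
    counts = np.bincount(ea[mask].astype(np.int64) * 20 + eb[mask],
                         minlength=400).reshape(20, 20)
    # symmetrizing leaves the ML point unchanged (reversibility) and makes
    # d(a, b) == d(b, a) bit-for-bit
    counts = counts + counts.T
    nll = _neg_log_likelihood(counts, model)
    grid = np.geomspace(_T_MIN, d_max, 50)
    vals = np.array([nll(t) for t in grid])
    i = int(np.argmin(vals))
    if i == len(grid) - 1:
        return d_max
    if i == 0:
        res = minimize_scalar(nll, bounds=(grid[0], grid[1]), method="bounded",
                              options={"xatol": 1e-9})
        return min(float(res.x), d_max)
    res = minimize_scalar(nll, bracket=(grid[i - 1], grid[i], grid[i + 1]),
                          method="brent", options={"xtol": 1e-7})
    return float(np.clip(res.x, 0.0, d_max))
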