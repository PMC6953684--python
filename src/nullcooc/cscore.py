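"""Checkerboard units and the C-score segregation statistic.

For a species pair occupying r_i and r_j leaflets and sharing S of them,
the number of checkerboard units is

    CU = (r_i - S) * (r_j - S)

the count of leaflet pairs showing the mutually exclusive (1,0)/(0,1)
pattern. The C-score of a matrix is the mean CU over all unordered species
pairs; larger values mean the community is more segregated than expected
for the given occupancy counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import PresenceAbsenceMatrix

__all__ = ["PairCU", "checkerboard_units", "c_score", "pair_cu_table"]


@dataclass(frozen=True)
class PairCU:
    """Checkerboard-unit record for one unordered species pair."""

    species_i: str
    species_j: str
    r_i: int
    r_j: int
    shared: int  # S, leaflets occupied by both species
    cu: int

    def __post_init__(self) -> None:
        assert 0 <= self.shared <= min(self.r_i, self.r_j)
        assert 0 <= self.cu <= self.r_i * self.r_j


def checkerboard_units(
    row_i,
    row_j,
    species_i: str = "i",
    species_j: str = "j",
) -> PairCU:
    """CU = (r_i - S)(r_j - S) for one pair of binary occurrence vectors."""
    a = np.asarray(row_i, dtype=np.int64)
    b = np.asarray(row_j, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"occurrence vectors must be 1-D and equal length, got {a.shape} vs {b.shape}")
    r_i = int(a.sum())
    r_j = int(b.sum())
    s = int((a & b).sum())
    return PairCU(species_i, species_j, r_i, r_j, s, (r_i - s) * (r_j - s))


def _as_array(m) -> np.ndarray:
    if isinstance(m, PresenceAbsenceMatrix):
        return np.asarray(m.values, dtype=np.int64)
    return np.asarray(m, dtype=np.int64)


def c_score(m) -> float:
    """Mean checkerboard units over all R(R-1)/2 species pairs.

    Accepts a :class:`PresenceAbsenceMatrix` or a plain binary array.
    Invariant under any permutation of rows or columns.
    """
    a = _as_array(m)
    r_n = a.shape[0]
    if r_n < 2:
        raise ValueError("C-score needs at least 2 species rows")
    r = a.sum(axis=1)
    shared = a @ a.T
    cu = (r[:, None] - shared) * (r[None, :] - shared)
    iu = np.triu_indices(r_n, k=1)
    return float(cu[iu].mean())


def pair_cu_table(m: PresenceAbsenceMatrix) -> pd.DataFrame:
    """All pairwise CU records of a matrix as a tidy table."""
    a = np.asarray(m.values, dtype=np.int64)
    r = a.sum(axis=1)
    shared = a @ a.T
    rows = []
    for i in range(m.n_species):
        for j in range(i + 1, m.n_species):
            s = int(shared[i, j])
            rows.append(
                {
                    "species_i": m.species_ids[i],
                    "species_j": m.species_ids[j],
                    "r_i": int(r[i]),
                    "r_j": int(r[j]),
                    "shared": s,
                    "cu": int((r[i] - s) * (r[j] - s)),
                }
            )
    return pd.DataFrame(rows)
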