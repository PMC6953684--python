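"""Fixed-fixed null model: margin-preserving randomization of 0/1 matrices.

The null hypothesis keeps both row totals (species occurrence frequencies)
and column totals (species per leaflet) of the observed matrix and treats
all binary matrices with those margins as equally likely. Null matrices are
sampled with a swap chain — repeatedly flipping random 2x2 checkerboard
submatrices — and, for small margin sets, the full fixed-margin family can
be enumerated exactly to serve as an oracle for the sampler.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from . import _kernels
from .cscore import c_score
from .matrix import PresenceAbsenceMatrix

__all__ = [
    "NullEnsemble",
    "swap_step",
    "generate_null_ensemble",
    "enumerate_fixed_margin_matrices",
    "exact_null_distribution",
    "site_seed",
]

#: attempted swaps discarded before sampling starts
DEFAULT_BURN_IN = 30_000


def default_thin(n_rows: int, n_cols: int) -> int:
    """Attempted swaps between consecutive samples: max(1000, 10*R*C)."""
    return max(1_000, 10 * n_rows * n_cols)


def site_seed(master_seed: int, site_id: str) -> int:
    """Derive a stable per-site 32-bit seed from one master seed.

    The site label is hashed with CRC-32 so multi-site runs are reproducible
    regardless of the order in which sites are analyzed.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(site_id.encode("utf-8"))])
    return int(ss.generate_state(1, np.uint32)[0])


@dataclass
class NullEnsemble:
    """A statistic evaluated on n margin-preserving null matrices."""

    statistic_name: str
    values: np.ndarray
    n: int
    algorithm: str
    burn_in: int
    thin: int
    thin_unit: str  # "attempts" (uniform sampling) or "swaps" (EcoSim-style)
    seed: int
    row_totals: np.ndarray
    col_totals: np.ndarray
    degenerate: bool = False
    n_accepted_burn_in: int = 0
    n_accepted_total: int = 0
    matrices: list[np.ndarray] | None = field(default=None, repr=False)


def swap_step(
    m: PresenceAbsenceMatrix | np.ndarray,
    rng: np.random.Generator,
    indices: tuple[int, int, int, int] | None = None,
):
    """One attempted checkerboard swap; returns ``(array, accepted)``.

    Two rows and two columns are drawn uniformly with replacement (or
    supplied via ``indices`` as ``(r1, r2, c1, c2)``); if they are distinct
    and the induced 2x2 submatrix is [[1,0],[0,1]] or [[0,1],[1,0]] it is
    flipped to the other form. A repeated row or column is a lazy move
    (rejected), which keeps the chain aperiodic. Margins are preserved
    either way, and applying the same accepted swap again restores the
    input (the move is an involution).
    """
    arr = m.values if isinstance(m, PresenceAbsenceMatrix) else np.asarray(m)
    out = np.array(arr, dtype=np.int8)
    n_rows, n_cols = out.shape
    if indices is None:
        r1, r2 = rng.integers(0, n_rows, size=2)
        c1, c2 = rng.integers(0, n_cols, size=2)
    else:
        r1, r2, c1, c2 = indices
    if r1 == r2 or c1 == c2:
        return out, False
    sub = out[np.ix_([r1, r2], [c1, c2])]
    accepted = sub[0, 0] == sub[1, 1] and sub[0, 1] == sub[1, 0] and sub[0, 0] != sub[0, 1]
    if accepted:
        out[np.ix_([r1, r2], [c1, c2])] = 1 - sub
    return out, bool(accepted)


def generate_null_ensemble(
    m: PresenceAbsenceMatrix,
    statistic: Callable[[np.ndarray], float] = c_score,
    n: int = 5_000,
    burn_in: int = DEFAULT_BURN_IN,
    thin: int | None = None,
    seed: int = 0,
    thin_unit: str = "attempts",
    keep_matrices: bool = False,
    check_margins: bool = True,
) -> NullEnsemble:
    """Sample ``n`` fixed-fixed null matrices and evaluate ``statistic`` on each.

    The chain starts at the observed matrix, discards ``burn_in`` attempted
    swaps, then records the statistic every ``thin`` attempts (default
    ``max(1000, 10*R*C)``). With ``thin_unit="swaps"`` thinning counts
    accepted swaps instead, reproducing EcoSim-style sequential-swap
    spacing (known to weight matrices unevenly on some margin sets).

    A matrix on which no swap is ever accepted during burn-in admits no
    rearrangement detectable by the chain; the ensemble is then flagged
    ``degenerate`` and downstream inference reports p = 1, NES = 0.
    """
    if m.n_species < 2 or m.n_leaflets < 2:
        raise ValueError("null model needs at least a 2x2 matrix")
    if thin_unit not in ("attempts", "swaps"):
        raise ValueError(f"unknown thin_unit {thin_unit!r}")
    thin = default_thin(m.n_species, m.n_leaflets) if thin is None else int(thin)
    mat = np.array(m.values, dtype=np.int8)  # writable working copy
    rng = np.random.default_rng(seed)
    # independent 32-bit seeds for the compiled kernel, one per chain segment
    kernel_seeds = rng.integers(0, 2**32 - 1, size=n + 1, dtype=np.uint64)

    burn_accepted = int(_kernels.advance_attempts(mat, int(burn_in), int(kernel_seeds[0])))
    degenerate = burn_accepted == 0
    if degenerate:
        warnings.warn(
            f"site {m.site_id!r}: no swap accepted in {burn_in} burn-in attempts; "
            "matrix is rigid under fixed-fixed randomization",
            stacklevel=2,
        )

    values = np.empty(n, dtype=float)
    matrices: list[np.ndarray] | None = [] if keep_matrices else None
    accepted_total = burn_accepted
    max_attempts_per_sample = 1_000 * thin  # swaps-mode safety valve
    for k in range(n):
        if thin_unit == "attempts":
            accepted_total += int(_kernels.advance_attempts(mat, thin, int(kernel_seeds[k + 1])))
        else:
            acc, _ = _kernels.advance_swaps(mat, thin, max_attempts_per_sample, int(kernel_seeds[k + 1]))
            accepted_total += int(acc)
        values[k] = statistic(mat)
        if matrices is not None:
            matrices.append(mat.copy())
    if check_margins:
        if not (
            np.array_equal(mat.sum(axis=1), m.row_totals)
            and np.array_equal(mat.sum(axis=0), m.col_totals)
        ):  # pragma: no cover - guarded by construction
            raise AssertionError("swap chain violated fixed margins")
    return NullEnsemble(
        statistic_name=getattr(statistic, "__name__", "statistic"),
        values=values,
        n=n,
        algorithm="sequential_swap",
        burn_in=int(burn_in),
        thin=thin,
        thin_unit=thin_unit,
        seed=int(seed),
        row_totals=m.row_totals,
        col_totals=m.col_totals,
        degenerate=degenerate,
        n_accepted_burn_in=burn_accepted,
        n_accepted_total=accepted_total,
        matrices=matrices,
    )


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle


def _gale_ryser_feasible(row_caps: Sequence[int], col_degrees: Sequence[int]) -> bool:
    """Existence of a 0/1 matrix with the given row/column sums (Gale-Ryser)."""
    r = sorted((x for x in row_caps if x > 0), reverse=True)
    c = [x for x in col_degrees if x > 0]
    if sum(r) != sum(c):
        return False
    if any(x > len(c) for x in r) or any(x > len(r) for x in c):
        return False
    for k in range(1, len(r) + 1):
        lhs = sum(r[:k])
        rhs = sum(min(cj, k) for cj in c)
        if lhs > rhs:
            return False
    return True


def enumerate_fixed_margin_matrices(
    row_totals: Sequence[int],
    col_totals: Sequence[int],
    max_states: int = 1_000_000,
) -> list[np.ndarray]:
    """Every distinct binary matrix with the given margins.

    Column-wise backtracking: each column picks which rows receive its 1s,
    pruning branches whose remaining margins fail the Gale-Ryser condition.
    Infeasible margins yield an empty list. ``max_states`` bounds the number
    of partial states visited; beyond it the sampler should be used instead.
    """
    r = np.asarray(row_totals, dtype=np.int64)
    c = np.asarray(col_totals, dtype=np.int64)
    if (r < 0).any() or (c < 0).any():
        raise ValueError("margins must be non-negative")
    if r.sum() != c.sum():
        return []
    n_rows = len(r)
    out: list[np.ndarray] = []
    work = np.zeros((n_rows, len(c)), dtype=np.int8)
    states = 0

    def backtrack(col: int, caps: np.ndarray) -> None:
        nonlocal states
        states += 1
        if states > max_states:
            raise RuntimeError(
                f"enumeration exceeded {max_states} partial states; "
                "use the swap sampler for margins this rich"
            )
        if col == len(c):
            if (caps == 0).all():
                out.append(work.copy())
            return
        need = int(c[col])
        candidates = [i for i in range(n_rows) if caps[i] > 0]
        if len(candidates) < need:
            return
        for rows in itertools.combinations(candidates, need):
            caps2 = caps.copy()
            for i in rows:
                caps2[i] -= 1
            if not _gale_ryser_feasible(caps2, c[col + 1 :]):
                continue
            for i in rows:
                work[i, col] = 1
            backtrack(col + 1, caps2)
            for i in rows:
                work[i, col] = 0

    if _gale_ryser_feasible(r, c):
        backtrack(0, r.copy())
    return out


def exact_null_distribution(
    m: PresenceAbsenceMatrix | tuple[Sequence[int], Sequence[int]],
    statistic: Callable[[np.ndarray], float] = c_score,
    max_states: int = 1_000_000,
) -> dict[float, float]:
    """Distribution of ``statistic`` under uniform weight on the fixed-margin set.

    Accepts a matrix (margins are taken from it) or a ``(row_totals,
    col_totals)`` pair. Values are rounded to 9 decimals to pool numerically
    identical statistic values.
    """
    if isinstance(m, PresenceAbsenceMatrix):
        row_totals, col_totals = m.row_totals, m.col_totals
    else:
        row_totals, col_totals = m
    mats = enumerate_fixed_margin_matrices(row_totals, col_totals, max_states=max_states)
    if not mats:
        raise ValueError("margins are infeasible: no binary matrix exists")
    dist: dict[float, float] = {}
    w = 1.0 / len(mats)
    for mat in mats:
        v = round(float(statistic(mat)), 9)
        dist[v] = dist.get(v, 0.0) + w
    return dist
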