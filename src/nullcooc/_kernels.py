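"""Compiled inner loops for the fixed-fixed swap chain.

The chain proposes a uniformly random (row, row, column, column) tuple and
flips the induced 2x2 submatrix when it is one of the two checkerboard
configurations; any other configuration — including tuples with a repeated
row or column, which act as lazy moves and keep the chain aperiodic — is a
rejected attempt. Row and column totals are invariant by construction.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def advance_attempts(mat, n_attempts, seed):
    """Run ``n_attempts`` swap attempts in place; return the number accepted.

    ``mat`` must be a writable 2-D int8 array with >= 2 rows and columns.
    """
    np.random.seed(seed)
    n_rows, n_cols = mat.shape
    accepted = 0
    for _ in range(n_attempts):
        r1 = np.random.randint(n_rows)
        r2 = np.random.randint(n_rows)
        c1 = np.random.randint(n_cols)
        c2 = np.random.randint(n_cols)
        if r1 == r2 or c1 == c2:
            # lazy move: keeps the chain aperiodic (a 2x2 checkerboard
            # matrix would otherwise oscillate with period 2)
            continue
        a = mat[r1, c1]
        b = mat[r1, c2]
        c = mat[r2, c1]
        d = mat[r2, c2]
        if a == d and b == c and a != b:
            mat[r1, c1] = b
            mat[r1, c2] = a
            mat[r2, c1] = d
            mat[r2, c2] = c
            accepted += 1
    return accepted


@njit(cache=True)
def advance_swaps(mat, n_swaps, max_attempts, seed):
    """Run attempts until ``n_swaps`` are accepted (or ``max_attempts`` spent).

    Returns (accepted, attempts). Used by the acceptance-counted
    ("sequential swap" in the EcoSim sense) thinning mode.
    """
    np.random.seed(seed)
    n_rows, n_cols = mat.shape
    accepted = 0
    attempts = 0
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        r1 = np.random.randint(n_rows)
        r2 = np.random.randint(n_rows)
        c1 = np.random.randint(n_cols)
        c2 = np.random.randint(n_cols)
        if r1 == r2 or c1 == c2:
            # lazy move: keeps the chain aperiodic (a 2x2 checkerboard
            # matrix would otherwise oscillate with period 2)
            continue
        a = mat[r1, c1]
        b = mat[r1, c2]
        c = mat[r2, c1]
        d = mat[r2, c2]
        if a == d and b == c and a != b:
            mat[r1, c1] = b
            mat[r1, c2] = a
            mat[r2, c1] = d
            mat[r2, c2] = c
            accepted += 1
    return accepted, attempts
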