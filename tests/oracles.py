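"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the library's algorithms: plain enumeration and
numpy rank computations only.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_futile_cycles(entries, max_coeff=3):
    """All support-minimal non-negative integer vectors v != 0 with S v = 0
    and entries <= max_coeff, by exhaustive enumeration."""
    n_rx = len(entries[0])
    solutions = []
    for v in itertools.product(range(max_coeff + 1), repeat=n_rx):
        if not any(v):
            continue
        if all(
            sum(row[j] * v[j] for j in range(n_rx)) == 0 for row in entries
        ):
            solutions.append(v)
    supports = [frozenset(i for i, x in enumerate(v) if x) for v in solutions]
    minimal = []
    for i, v in enumerate(solutions):
        if not any(supports[k] < supports[i] for k in range(len(solutions))):
            minimal.append(v)
    # deduplicate by support (scalar multiples share a support)
    by_support = {}
    for v in minimal:
        s = frozenset(i for i, x in enumerate(v) if x)
        if s not in by_support or sum(v) < sum(by_support[s]):
            by_support[s] = v
    return sorted(by_support.values())


def brute_minimal_mcls(entries, bound):
    """All componentwise-minimal non-zero y in N0^X with y^T S = 0 and
    y <= bound componentwise."""
    n_sp = len(entries)
    n_rx = len(entries[0]) if entries else 0
    members = []
    for y in itertools.product(*(range(b + 1) for b in bound)):
        if not any(y):
            continue
        if all(
            sum(entries[i][j] * y[i] for i in range(n_sp)) == 0
            for j in range(n_rx)
        ):
            members.append(y)
    minimal = []
    for y in members:
        if not any(
            z != y and all(a <= b for a, b in zip(z, y)) for z in members
        ):
            minimal.append(y)
    return sorted(minimal)


def kernel_dim_left(entries):
    """dim ker S^T via numpy rank (float, but reliable for tiny integers)."""
    M = np.array(entries, dtype=float)
    return M.shape[0] - np.linalg.matrix_rank(M)


def kernel_dim_right(entries):
    M = np.array(entries, dtype=float)
    return M.shape[1] - np.linalg.matrix_rank(M)


def has_nonneg_kernel_vector(entries, support_subset=None, max_coeff=3):
    """Exhaustively check for v > 0, S v = 0 with supp(v) within a subset."""
    n_rx = len(entries[0])
    allowed = set(range(n_rx)) if support_subset is None else set(support_subset)
    for v in itertools.product(range(max_coeff + 1), repeat=n_rx):
        if not any(v):
            continue
        if any(v[j] and j not in allowed for j in range(n_rx)):
            continue
        if all(sum(row[j] * v[j] for j in range(n_rx)) == 0 for row in entries):
            return True
    return False
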