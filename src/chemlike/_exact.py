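"""Exact rational linear algebra used throughout the package.

Everything that ends up in a certificate is computed here with `Fraction`
or sympy rationals: integer kernel bases, extreme rays of s-cones
{v >= 0 : A v = 0} via a double-description tableau, a small two-phase
rational simplex for feasibility problems, and exact linear solves.
Floating point never enters any certificate.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd
from typing import Sequence

import sympy

__all__ = [
    "integer_kernel_basis",
    "integer_left_kernel_basis",
    "solve_exact",
    "extreme_rays",
    "rational_feasible",
    "reduce_to_coprime",
]


def reduce_to_coprime(vec: Sequence) -> list[int]:
    """Scale a rational vector to coprime integers, keeping signs."""
    fracs = [Fraction(v) for v in vec]
    if all(f == 0 for f in fracs):
        return [0] * len(fracs)
    denom_lcm = 1
    for f in fracs:
        denom_lcm = denom_lcm * f.denominator // gcd(denom_lcm, f.denominator)
    ints = [int(f * denom_lcm) for f in fracs]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    return [x // g for x in ints]


def integer_kernel_basis(A: Sequence[Sequence[int]]) -> list[list[int]]:
    """Exact integer basis of ker(A), each vector content-reduced, in the
    deterministic order produced by sympy's RREF-based nullspace."""
    M = sympy.Matrix([[sympy.Rational(x) for x in row] for row in A])
    basis = M.nullspace()
    return [reduce_to_coprime([Fraction(x) for x in vec]) for vec in basis]


def integer_left_kernel_basis(A: Sequence[Sequence[int]]) -> list[list[int]]:
    """Exact integer basis of the left kernel {m : m^T A = 0}."""
    transposed = [list(col) for col in zip(*A)] if A else []
    return integer_kernel_basis(transposed)


def solve_exact(A: Sequence[Sequence[int]], b: Sequence) -> list[Fraction] | None:
    """One exact rational solution of A x = b, or None if inconsistent."""
    M = sympy.Matrix([[sympy.Rational(x) for x in row] for row in A])
    rhs = sympy.Matrix([sympy.Rational(x) for x in b])
    try:
        sol, params = M.gauss_jordan_solve(rhs)
    except ValueError:
        return None
    sol = sol.subs({p: 0 for p in params})
    return [Fraction(sympy.Rational(x)) for x in sol]


# ---------------------------------------------------------------------------
# extreme rays of {v >= 0 : A v = 0}
# ---------------------------------------------------------------------------

class RayEnumerationTruncated(RuntimeError):
    """Raised when the intermediate ray count exceeds the configured cap."""


def extreme_rays(
    A: Sequence[Sequence[int]], max_rays: int | None = 100_000
) -> list[list[int]]:
    """All extreme rays of the pointed cone {v >= 0 : A v = 0}.

    Double-description tableau: start from the unit rays of the orthant and
    impose the equality constraints one at a time, combining adjacent
    positive/negative rays and discarding support-dominated candidates.
    Rays are returned as coprime integer vectors, sorted lexicographically
    by support and then entries (deterministic).
    """
    if not A:
        return []
    n = len(A[0])
    # rows: (generator v, constraint values A v), both exact
    rays: list[tuple[list[Fraction], list[Fraction]]] = []
    for j in range(n):
        v = [Fraction(0)] * n
        v[j] = Fraction(1)
        rays.append((v, [Fraction(row[j]) for row in A]))

    for k in range(len(A)):
        zero, pos, neg = [], [], []
        for v, w in rays:
            if w[k] == 0:
                zero.append((v, w))
            elif w[k] > 0:
                pos.append((v, w))
            else:
                neg.append((v, w))
        new = list(zero)
        supports = [frozenset(i for i, x in enumerate(v) if x) for v, _ in new]
        for vp, wp in pos:
            for vn, wn in neg:
                a, b = wp[k], -wn[k]
                v = [b * x + a * y for x, y in zip(vp, vn)]
                w = [b * x + a * y for x, y in zip(wp, wn)]
                supp = frozenset(i for i, x in enumerate(v) if x)
                # minimality filter: drop if support strictly contains another
                if any(s < supp or s == supp for s in supports):
                    continue
                # remove rows dominated by the new one
                keep = [i for i, s in enumerate(supports) if not supp < s]
                if len(keep) != len(new):
                    new = [new[i] for i in keep]
                    supports = [supports[i] for i in keep]
                new.append((v, w))
                supports.append(supp)
                if max_rays is not None and len(new) > max_rays:
                    raise RayEnumerationTruncated(
                        f"ray count exceeded cap {max_rays}"
                    )
        rays = new

    out = {tuple(reduce_to_coprime(v)) for v, _ in rays if any(x != 0 for x in v)}
    return sorted(
        (list(t) for t in out),
        key=lambda v: (sorted(i for i, x in enumerate(v) if x), v),
    )


# ---------------------------------------------------------------------------
# exact two-phase simplex (feasibility / optimization at small scale)
# ---------------------------------------------------------------------------

def _simplex_standard(
    A: list[list[Fraction]], b: list[Fraction], c: list[Fraction]
) -> tuple[str, list[Fraction] | None]:
    """min c^T x s.t. A x = b, x >= 0. Returns (status, x).

    Two-phase tableau simplex with Bland's rule; exact Fractions only.
    Status is one of 'optimal', 'infeasible', 'unbounded'.
    """
    m, n = len(A), (len(A[0]) if A else len(c))
    A = [row[:] for row in A]
    b = b[:]
    for i in range(m):
        if b[i] < 0:
            A[i] = [-x for x in A[i]]
            b[i] = -b[i]

    # phase 1: artificials
    total = n + m
    tab = [A[i] + [Fraction(1) if j == i else Fraction(0) for j in range(m)] + [b[i]]
           for i in range(m)]
    basis = list(range(n, total))
    cost = [Fraction(0)] * n + [Fraction(1)] * m

    def run(cost_vec: list[Fraction], ncols: int) -> str:
        while True:
            # reduced costs
            y = [cost_vec[basis[i]] for i in range(m)]
            entering = -1
            for j in range(ncols):
                if j in basis:
                    continue
                red = cost_vec[j] - sum(y[i] * tab[i][j] for i in range(m))
                if red < 0:
                    entering = j
                    break  # Bland: smallest index
            if entering < 0:
                return "optimal"
            # ratio test (Bland tie-break on basis index)
            leaving, best = -1, None
            for i in range(m):
                if tab[i][entering] > 0:
                    ratio = tab[i][-1] / tab[i][entering]
                    if best is None or ratio < best or (
                        ratio == best and basis[i] < basis[leaving]
                    ):
                        best, leaving = ratio, i
            if leaving < 0:
                return "unbounded"
            piv = tab[leaving][entering]
            tab[leaving] = [x / piv for x in tab[leaving]]
            for i in range(m):
                if i != leaving and tab[i][entering] != 0:
                    f = tab[i][entering]
                    tab[i] = [x - f * y2 for x, y2 in zip(tab[i], tab[leaving])]
            basis[leaving] = entering

    run(cost, total)
    obj = sum(cost[basis[i]] * tab[i][-1] for i in range(m))
    if obj > 0:
        return "infeasible", None
    # drive artificials out of the basis where possible
    for i in range(m):
        if basis[i] >= n:
            for j in range(n):
                if tab[i][j] != 0:
                    piv = tab[i][j]
                    tab[i] = [x / piv for x in tab[i]]
                    for k in range(m):
                        if k != i and tab[k][j] != 0:
                            f = tab[k][j]
                            tab[k] = [x - f * y2 for x, y2 in zip(tab[k], tab[i])]
                    basis[i] = j
                    break

    # phase 2 on original columns only
    full_cost = list(c) + [Fraction(0)] * m
    status = run(full_cost, n)
    if status == "unbounded":
        return "unbounded", None
    x = [Fraction(0)] * n
    for i in range(m):
        if basis[i] < n:
            x[basis[i]] = tab[i][-1]
    return "optimal", x


def rational_feasible(
    n_free: int,
    A_eq: list[list] | None = None,
    b_eq: list | None = None,
    A_ub: list[list] | None = None,
    b_ub: list | None = None,
    objective: list | None = None,
) -> list[Fraction] | None:
    """Exact feasible (or optimal) point for a small LP over free variables.

    Variables are unrestricted in sign; constraints are A_eq y = b_eq and
    A_ub y <= b_ub. If ``objective`` is given, minimizes objective @ y.
    Returns None when infeasible; raises on unbounded optimization.
    """
    A_eq = A_eq or []
    b_eq = b_eq or []
    A_ub = A_ub or []
    b_ub = b_ub or []
    m_eq, m_ub = len(A_eq), len(A_ub)
    # y = u - w with u, w >= 0; slacks s >= 0 for inequalities
    n_std = 2 * n_free + m_ub
    rows: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    for i in range(m_eq):
        row = [Fraction(0)] * n_std
        for j in range(n_free):
            row[j] = Fraction(A_eq[i][j])
            row[n_free + j] = -Fraction(A_eq[i][j])
        rows.append(row)
        rhs.append(Fraction(b_eq[i]))
    for i in range(m_ub):
        row = [Fraction(0)] * n_std
        for j in range(n_free):
            row[j] = Fraction(A_ub[i][j])
            row[n_free + j] = -Fraction(A_ub[i][j])
        row[2 * n_free + i] = Fraction(1)
        rows.append(row)
        rhs.append(Fraction(b_ub[i]))
    c = [Fraction(0)] * n_std
    if objective is not None:
        for j in range(n_free):
            c[j] = Fraction(objective[j])
            c[n_free + j] = -Fraction(objective[j])
    status, x = _simplex_standard(rows, rhs, c)
    if status == "infeasible":
        return None
    if status == "unbounded":
        raise ArithmeticError("LP unbounded")
    assert x is not None
    return [x[j] - x[n_free + j] for j in range(n_free)]
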