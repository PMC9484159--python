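"""Conservativity, moiety conservation laws, and obligatory isomers.

Conservativity is decided via the Stiemke alternative: either a strictly
positive integer conservation law exists, or a flow creating (or, negated,
annihilating) mass exists for the reversible completion.  Minimal moiety
conservation laws are the minimal elements of the monoid
{y in N0^X : y^T S = 0}; they are computed exactly from the extreme rays of
the associated s-cone followed by a bounded lattice enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from typing import Sequence

import sympy

from ._exact import (
    extreme_rays,
    integer_kernel_basis,
    reduce_to_coprime,
    solve_exact,
)
from .network import StoichiometricMatrix

__all__ = [
    "ConservationLaw",
    "MCL",
    "MCLList",
    "MMRepresentation",
    "IsomerPartition",
    "MassCertificate",
    "NotConservativeError",
    "integer_left_kernel_basis",
    "is_conservative",
    "minimal_mcls",
    "mm_representation",
    "obligatory_isomer_classes",
    "net_isomerization_flow",
    "oligomer_ratio",
    "validate_conservation_vectors",
]


@dataclass
class ConservationLaw:
    """Rational vector m over species with m^T S = 0."""

    m: list

    @property
    def positive(self) -> bool:
        return all(x > 0 for x in self.m)


@dataclass(frozen=True)
class MCL:
    """Moiety conservation law: non-zero y in N0^X with y^T S = 0."""

    y: tuple[int, ...]
    minimal: bool = True

    def __iter__(self):
        return iter(self.y)


class MCLList(list):
    """List of MCLs with a flag recording whether enumeration was complete."""

    truncated: bool = False


@dataclass
class MMRepresentation:
    """Matrix of all minimal MCLs (moieties x species)."""

    matrix: list[list[int]]
    species: list[str]
    moiety_names: list[str]

    @property
    def n_moieties(self) -> int:
        return len(self.matrix)


@dataclass
class IsomerPartition:
    """Partition of species into obligatory-isomer classes."""

    classes: list[list[str]]
    inert: list[str] = field(default_factory=list)

    def class_of(self, species: str) -> list[str]:
        for cls in self.classes:
            if species in cls:
                return cls
        raise KeyError(species)

    def are_isomers(self, x: str, y: str) -> bool:
        return y in self.class_of(x)


@dataclass
class MassCertificate:
    """Certificate from the conservativity decision.

    kind 'conservation_law': vector is an integer m >> 0 with m^T S = 0.
    kind 'cornucopia': vector is a signed integer v with S v > 0 (valid as a
    flow in the reversible completion); negating v yields an abyss.
    """

    kind: str
    vector: list[int]
    image: list[int] | None = None  # S v for cornucopia certificates

    @property
    def conservative(self) -> bool:
        return self.kind == "conservation_law"


class NotConservativeError(ValueError):
    def __init__(self, certificate: MassCertificate):
        self.certificate = certificate
        super().__init__(
            "network is not conservative (cornucopia/abyss certificate attached)"
        )


# ---------------------------------------------------------------------------

def integer_left_kernel_basis(S: StoichiometricMatrix) -> list[list[int]]:
    """Exact content-reduced integer basis of ker S^T, deterministic order."""
    return integer_kernel_basis([list(col) for col in zip(*S.entries)])


def _left_cone_rays(S: StoichiometricMatrix) -> list[list[int]]:
    """Extreme rays of the s-cone K(S) = {y >= 0 : y^T S = 0}."""
    St = [list(col) for col in zip(*S.entries)]
    return extreme_rays(St)


def is_conservative(S: StoichiometricMatrix) -> MassCertificate:
    """Stiemke alternative with exact certificates, exactly one branch.

    Either an integer m >> 0 with m^T S = 0 (the sum of the extreme rays of
    the non-negative left kernel, reduced), or an integer v with S v > 0.
    """
    n_sp = S.shape[0]
    rays = _left_cone_rays(S)
    if rays:
        m = [sum(r[i] for r in rays) for i in range(n_sp)]
        if all(x > 0 for x in m):
            m = reduce_to_coprime(m)
            assert all(x == 0 for x in S.multiply_left(m))
            return MassCertificate(kind="conservation_law", vector=m)

    # no positive law: find w > 0 in im S, then v with S v = w
    C = integer_kernel_basis([list(col) for col in zip(*S.entries)])
    if C:
        image_rays = extreme_rays(C)
        assert image_rays, "Stiemke alternative violated (internal error)"
        w = image_rays[0]
    else:
        w = [1 if i == 0 else 0 for i in range(n_sp)]
    v = solve_exact(S.entries, w)
    assert v is not None
    scale = 1
    for x in v:
        scale = scale * Fraction(x).denominator // gcd(scale, Fraction(x).denominator)
    v_int = [int(x * scale) for x in v]
    image = S.multiply(v_int)
    assert all(x >= 0 for x in image) and any(x > 0 for x in image)
    return MassCertificate(kind="cornucopia", vector=v_int, image=image)


# ---------------------------------------------------------------------------
# minimal MCLs (Hilbert-basis style enumeration)
# ---------------------------------------------------------------------------

def minimal_mcls(S: StoichiometricMatrix, cap: int = 5_000_000) -> MCLList:
    """The complete set of minimal elements of {y in N0^X : y^T S = 0}.

    Every minimal element lies below the componentwise sum of the coprime
    integer extreme rays of K(S) (the zonotope bound), so a bounded lattice
    enumeration with exact pruning is complete.  If the search box exceeds
    ``cap`` lattice points, a partial (flagged) result of rays and pairwise
    ray sums is returned.
    """
    n_sp, n_rx = S.shape
    rays = _left_cone_rays(S)
    result = MCLList()
    if not rays:
        return result
    bound = [sum(r[i] for r in rays) for i in range(n_sp)]

    box = 1
    for b in bound:
        box *= b + 1
        if box > cap:
            break
    if box > cap:
        # flagged fallback: rays plus componentwise-minimal pairwise sums
        candidates = {tuple(r) for r in rays}
        for i in range(len(rays)):
            for j in range(i, len(rays)):
                candidates.add(tuple(a + b for a, b in zip(rays[i], rays[j])))
        minimal = _minimal_elements(sorted(candidates))
        result.extend(MCL(y=t) for t in minimal)
        result.truncated = True
        return result

    # DFS over the box with interval pruning on each reaction constraint
    cols = S.entries  # cols[i][j] = S_{ij}
    suffix_min = [[0] * n_rx for _ in range(n_sp + 1)]
    suffix_max = [[0] * n_rx for _ in range(n_sp + 1)]
    for i in range(n_sp - 1, -1, -1):
        for j in range(n_rx):
            contrib = cols[i][j] * bound[i]
            suffix_min[i][j] = suffix_min[i + 1][j] + min(0, contrib)
            suffix_max[i][j] = suffix_max[i + 1][j] + max(0, contrib)

    found: list[tuple[int, ...]] = []
    y = [0] * n_sp
    partial = [0] * n_rx

    def dfs(i: int):
        if i == n_sp:
            if any(y) and all(p == 0 for p in partial):
                found.append(tuple(y))
            return
        for val in range(bound[i] + 1):
            y[i] = val
            ok = True
            for j in range(n_rx):
                p = partial[j] + cols[i][j] * val
                if p + suffix_max[i + 1][j] < 0 or p + suffix_min[i + 1][j] > 0:
                    ok = False
                    break
            if ok:
                for j in range(n_rx):
                    partial[j] += cols[i][j] * val
                dfs(i + 1)
                for j in range(n_rx):
                    partial[j] -= cols[i][j] * val
        y[i] = 0

    dfs(0)
    minimal = _minimal_elements(sorted(found))
    result.extend(MCL(y=t) for t in minimal)
    return result


def _minimal_elements(vectors: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    """Componentwise-minimal members of a set of non-negative vectors."""
    out = []
    for v in vectors:
        dominated = False
        for w in vectors:
            if w != v and all(a <= b for a, b in zip(w, v)):
                dominated = True
                break
        if not dominated:
            out.append(v)
    return sorted(out)


def mm_representation(S: StoichiometricMatrix) -> MMRepresentation:
    """Matrix of all minimal MCLs; its row space equals ker S^T exactly."""
    cert = is_conservative(S)
    if not cert.conservative:
        raise NotConservativeError(cert)
    mcls = minimal_mcls(S)
    if mcls.truncated:
        raise RuntimeError("minimal MCL enumeration truncated; cannot build mm-representation")
    matrix = [list(m.y) for m in mcls]
    # Lemma: rows of the mm-representation span ker S^T
    kernel_dim = len(integer_left_kernel_basis(S))
    rank = sympy.Matrix(matrix).rank() if matrix else 0
    assert rank == kernel_dim, "mm-representation rows do not span the left kernel"
    names = [f"M{i+1}" for i in range(len(matrix))]
    return MMRepresentation(matrix=matrix, species=list(S.row_labels), moiety_names=names)


# ---------------------------------------------------------------------------
# obligatory isomers and oligomers
# ---------------------------------------------------------------------------

def obligatory_isomer_classes(S: StoichiometricMatrix) -> IsomerPartition:
    """Equal-column classes of a left-kernel basis matrix.

    Two species are obligatory isomers iff every left-kernel vector assigns
    them equal coordinates; inert species (all-zero rows of S) are flagged.
    """
    basis = integer_left_kernel_basis(S)
    cols: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    for i, sp in enumerate(S.row_labels):
        key = tuple(m[i] for m in basis)
        if key not in cols:
            cols[key] = []
            order.append(key)
        cols[key].append(sp)
    inert = [
        sp
        for i, sp in enumerate(S.row_labels)
        if all(S.entries[i][j] == 0 for j in range(S.shape[1]))
    ]
    return IsomerPartition(classes=[cols[k] for k in order], inert=inert)


def net_isomerization_flow(
    S: StoichiometricMatrix, x: str, y: str
) -> list[int] | None:
    """Integer v with S v = k (e_y - e_x) for minimal k, or None.

    Solves S v = e_y - e_x exactly and scales by the least common
    denominator.  Returns the zero vector for x == y (trivial).
    """
    if x == y:
        return [0] * S.shape[1]
    ix, iy = S.row_labels.index(x), S.row_labels.index(y)
    w = [0] * S.shape[0]
    w[ix] = -1
    w[iy] = 1
    v = solve_exact(S.entries, w)
    if v is None:
        return None
    lcd = 1
    for q in v:
        lcd = lcd * Fraction(q).denominator // gcd(lcd, Fraction(q).denominator)
    v_int = [int(q * lcd) for q in v]
    image = S.multiply(v_int)
    assert image[ix] == -lcd and image[iy] == lcd
    assert all(c == 0 for i, c in enumerate(image) if i not in (ix, iy))
    return v_int


def oligomer_ratio(
    S: StoichiometricMatrix, x: str, y: str
) -> tuple[int, int] | None:
    """Coprime (p, q) with q m_x = p m_y for all left-kernel m, or None.

    When such a ratio exists, a net reaction p x -> q y exists in the
    reversible completion (obligatory oligomers).
    """
    if x == y:
        raise ValueError("x and y must be distinct")
    ix, iy = S.row_labels.index(x), S.row_labels.index(y)
    basis = integer_left_kernel_basis(S)
    ratio: Fraction | None = None
    for m in basis:
        mx, my = m[ix], m[iy]
        if mx == 0 and my == 0:
            continue
        if mx == 0 or my == 0:
            return None
        r = Fraction(my, mx)
        if r < 0:
            return None
        if ratio is None:
            ratio = r
        elif ratio != r:
            return None
    if ratio is None:
        return (1, 1)  # both coordinates free in every law
    return (ratio.numerator, ratio.denominator)


def validate_conservation_vectors(
    S: StoichiometricMatrix, vectors: Sequence[Sequence]
) -> tuple[list[bool], int]:
    """Exact y^T S = 0 check per vector, plus the rank of the passing set."""
    passing = []
    flags = []
    for vec in vectors:
        if len(vec) != S.shape[0]:
            raise ValueError("vector length does not match species count")
        ok = all(x == 0 for x in S.multiply_left([Fraction(v) for v in vec]))
        flags.append(ok)
        if ok:
            passing.append([sympy.Rational(v) for v in vec])
    rank = sympy.Matrix(passing).rank() if passing else 0
    return flags, rank
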