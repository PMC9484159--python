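"""Sum-formula and Lewis (colored multigraph) realizations.

A sum-formula instance assigns atom counts to species such that every
reaction balances atoms; a realization additionally spans the left kernel,
so exactly the obligatory isomers share sum formulas.  Lewis realizations
render each species as a connected vertex-colored multigraph with fixed
valency per color; the injective construction distinguishes obligatory
isomers by rewiring loop pairs into parallel edges along the base cycle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import sympy

from .conservation import (
    MassCertificate,
    NotConservativeError,
    integer_left_kernel_basis,
    is_conservative,
    minimal_mcls,
    mm_representation,
    obligatory_isomer_classes,
)
from .network import ReactionNetwork, StoichiometricMatrix

__all__ = [
    "SumFormulaMatrix",
    "ColoredMultigraph",
    "LewisRealization",
    "validate_sf_instance",
    "validate_sf_realization",
    "default_sf_realization",
    "sum_formula_string",
    "inequivalent_sf_realizations",
    "cycle_structural_formula",
    "lewis_realization",
    "injective_lewis_realization",
    "are_isomorphic",
    "validate_lewis_realization",
]

_PRIMES = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61,
           67, 71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113]


@dataclass
class SumFormulaMatrix:
    """Non-negative integer matrix (atoms x species) with atom names."""

    matrix: list[list[int]]
    atoms: list[str]
    species: list[str]

    def column(self, x: str) -> list[int]:
        j = self.species.index(x)
        return [row[j] for row in self.matrix]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.atoms), len(self.species))


class ColoredMultigraph:
    """Vertex-colored multigraph with loops and a fixed valency per color.

    The degree of a vertex counts non-loop incidences once and loops twice.
    Backed by a networkx MultiGraph; loops are self-edges.
    """

    def __init__(self, colors: Sequence[str], val: dict[str, int]):
        self.graph = nx.MultiGraph()
        self.val = dict(val)
        for i, c in enumerate(colors):
            self.graph.add_node(i, color=c)

    def add_edge(self, u: int, v: int, count: int = 1) -> None:
        for _ in range(count):
            self.graph.add_edge(u, v)

    def color(self, u: int) -> str:
        return self.graph.nodes[u]["color"]

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Total edge count; loops counted once."""
        return self.graph.number_of_edges()

    def degree(self, u: int) -> int:
        # networkx counts a loop twice in MultiGraph.degree already
        return self.graph.degree(u)

    def color_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for u in self.graph.nodes:
            c = self.color(u)
            counts[c] = counts.get(c, 0) + 1
        return counts

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def degrees_match_valency(self) -> bool:
        return all(
            self.degree(u) == self.val[self.color(u)] for u in self.graph.nodes
        )

    def copy(self) -> "ColoredMultigraph":
        out = ColoredMultigraph([], self.val)
        out.graph = self.graph.copy()
        return out

    def edge_list(self) -> list[tuple[int, int]]:
        return sorted((min(u, v), max(u, v)) for u, v, _ in self.graph.edges(keys=True))


def are_isomorphic(g1: ColoredMultigraph, g2: ColoredMultigraph) -> bool:
    """Colored-multigraph isomorphism (multiplicities and loops respected)."""
    if g1.val != g2.val:
        raise ValueError("graphs must share the same valency function")
    if g1.color_counts() != g2.color_counts():
        return False
    return nx.is_isomorphic(
        g1.graph, g2.graph, node_match=lambda a, b: a["color"] == b["color"]
    )


@dataclass
class LewisRealization:
    """Assignment of colored multigraphs to species + derived atom matrix."""

    graphs: dict[str, ColoredMultigraph]
    sf: SumFormulaMatrix
    val: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sum formulas
# ---------------------------------------------------------------------------

def validate_sf_instance(
    S: StoichiometricMatrix, A: SumFormulaMatrix | Sequence[Sequence[int]]
) -> tuple[bool, list[str]]:
    """Check non-zero columns and A S = 0 exactly; diagnostics name failures."""
    matrix = A.matrix if isinstance(A, SumFormulaMatrix) else [list(r) for r in A]
    n_sp, n_rx = S.shape
    if any(len(row) != n_sp for row in matrix):
        raise ValueError("atom matrix width does not match species count")
    diagnostics: list[str] = []
    for j in range(n_sp):
        if any(row[j] < 0 for row in matrix):
            diagnostics.append(f"negative entry in column for species {S.row_labels[j]!r}")
        if all(row[j] == 0 for row in matrix):
            diagnostics.append(f"zero column for species {S.row_labels[j]!r}")
    for row in matrix:
        prod = S.multiply_left(row)
        for j, x in enumerate(prod):
            if x != 0:
                diagnostics.append(
                    f"atom row {matrix.index(row)} unbalanced in reaction "
                    f"{S.col_labels[j]!r}"
                )
                break
    return (not diagnostics), diagnostics


def validate_sf_realization(
    S: StoichiometricMatrix, A: SumFormulaMatrix | Sequence[Sequence[int]]
) -> bool:
    """True iff A is an sf-instance whose rows span ker S^T exactly."""
    ok, _ = validate_sf_instance(S, A)
    if not ok:
        return False
    matrix = A.matrix if isinstance(A, SumFormulaMatrix) else [list(r) for r in A]
    kernel_dim = len(integer_left_kernel_basis(S))
    return sympy.Matrix(matrix).rank() == kernel_dim


def default_sf_realization(S: StoichiometricMatrix) -> SumFormulaMatrix:
    """The mm-representation read as a sum-formula realization."""
    cert = is_conservative(S)
    if not cert.conservative:
        raise NotConservativeError(cert)
    mm = mm_representation(S)
    atoms = _atom_names(len(mm.matrix))
    return SumFormulaMatrix(matrix=mm.matrix, atoms=atoms, species=mm.species)


def _atom_names(n: int) -> list[str]:
    base = ["X", "Y", "Z", "W", "Q", "R", "T", "U"]
    if n <= len(base):
        return base[:n]
    return base + [f"A{i}" for i in range(n - len(base))]


def sum_formula_string(A: SumFormulaMatrix, x: str) -> str:
    """Deterministic Hill-like formatting, count suffix omitted when 1."""
    col = A.column(x)
    if all(c == 0 for c in col):
        raise ValueError(f"zero sum formula for species {x!r}")
    parts = []
    for atom, c in zip(A.atoms, col):
        if c == 1:
            parts.append(atom)
        elif c > 1:
            parts.append(f"{atom}{c}")
    return "".join(parts)


def inequivalent_sf_realizations(
    S: StoichiometricMatrix, count: int, seed: int = 0
) -> list[SumFormulaMatrix]:
    """Pairwise-inequivalent realizations A_t with rows t_i * y^i.

    Rows are independent minimal MCLs scaled by distinct primes per matrix,
    so no two outputs satisfy p A = q A'.  Requires dim ker S^T > 1.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    kernel_dim = len(integer_left_kernel_basis(S))
    if kernel_dim <= 1:
        raise ValueError(
            "all realizations equivalent: dim ker S^T <= 1"
        )
    mcls = minimal_mcls(S)
    # pick kernel_dim linearly independent minimal MCLs
    chosen: list[list[int]] = []
    for m in mcls:
        cand = chosen + [list(m.y)]
        if sympy.Matrix(cand).rank() == len(cand):
            chosen = cand
        if len(chosen) == kernel_dim:
            break
    assert len(chosen) == kernel_dim
    species = list(S.row_labels)
    atoms = _atom_names(kernel_dim)
    out: list[SumFormulaMatrix] = []
    prime_pool = itertools.combinations(_PRIMES, kernel_dim)
    for t in prime_pool:
        matrix = [[t[i] * v for v in chosen[i]] for i in range(kernel_dim)]
        A = SumFormulaMatrix(matrix=matrix, atoms=atoms, species=species)
        if all(not _equivalent(A, B) for B in out):
            out.append(A)
        if len(out) == count:
            break
    if len(out) < count:
        raise RuntimeError("prime pool exhausted before reaching requested count")
    for A in out:
        assert validate_sf_realization(S, A)
    return out


def _equivalent(A: SumFormulaMatrix, B: SumFormulaMatrix) -> bool:
    """True iff p A = q B for some positive integers p, q."""
    flat_a = [x for row in A.matrix for x in row]
    flat_b = [x for row in B.matrix for x in row]
    if len(flat_a) != len(flat_b):
        return False
    ratio = None
    for a, b in zip(flat_a, flat_b):
        if a == 0 and b == 0:
            continue
        if a == 0 or b == 0:
            return False
        r = sympy.Rational(a, b)
        if ratio is None:
            ratio = r
        elif ratio != r:
            return False
    return True


# ---------------------------------------------------------------------------
# structural formulas
# ---------------------------------------------------------------------------

def cycle_structural_formula(
    formula: dict[str, int], k: int = 1
) -> ColoredMultigraph:
    """Connected multigraph with uniform valency 2k for a sum formula.

    A single moiety yields one vertex with k loops; otherwise all vertices
    are arranged in a cycle (parallel edges for length 2) with k-1 extra
    loops per vertex.
    """
    colors: list[str] = []
    for atom in formula:
        colors.extend([atom] * formula[atom])
    if not colors:
        raise ValueError("empty sum formula")
    val = {a: 2 * k for a in formula}
    g = ColoredMultigraph(colors, val)
    n = len(colors)
    if n == 1:
        g.add_edge(0, 0, count=k)
        return g
    if n == 2:
        g.add_edge(0, 1, count=2)
    else:
        for i in range(n):
            g.add_edge(i, (i + 1) % n)
    for i in range(n):
        g.add_edge(i, i, count=k - 1)
    assert g.degrees_match_valency() and g.is_connected()
    return g


def lewis_realization(S: StoichiometricMatrix) -> LewisRealization:
    """Default sf-realization rendered as valency-2 cycle graphs per species."""
    A = default_sf_realization(S)
    val = {a: 2 for a in A.atoms}
    graphs: dict[str, ColoredMultigraph] = {}
    for x in A.species:
        formula = {a: c for a, c in zip(A.atoms, A.column(x)) if c}
        g = cycle_structural_formula(formula, k=1)
        g.val = dict(val)  # shared valency map across the realization
        graphs[x] = g
    L = LewisRealization(graphs=graphs, sf=A, val=val)
    report = validate_lewis_realization(S, L)
    assert report["valid"], report
    return L


def _loop_pair_variants(base: ColoredMultigraph, n: int) -> Iterable[ColoredMultigraph]:
    """Variants of a valency-4 loop-cycle graph, in canonical order.

    Each variant replaces the loops at the vertices of a matching of cycle
    positions by parallel edges between the matched vertices; crossing-free
    matchings are generated by increasing size and leftmost pair.
    """
    yield base
    positions = list(range(n))
    for size in range(1, n // 2 + 1):
        for pairs in _crossing_free_matchings(positions, size):
            g = base.copy()
            ok = True
            for (u, v) in pairs:
                # remove one loop at each endpoint, add two parallel edges
                if g.graph.number_of_edges(u, u) < 1 or g.graph.number_of_edges(v, v) < 1:
                    ok = False
                    break
                g.graph.remove_edge(u, u)
                g.graph.remove_edge(v, v)
                g.add_edge(u, v, count=2)
            if ok:
                yield g


def _crossing_free_matchings(
    positions: list[int], size: int
) -> Iterable[list[tuple[int, int]]]:
    """All crossing-free matchings of given size on linearly ordered points.

    Not every point needs to be matched; arcs may nest but not cross.
    """

    def rec_subsets(avail: tuple[int, ...], need: int):
        if need == 0:
            yield []
            return
        if len(avail) < 2 * need:
            return
        # variant where the first point stays unmatched
        yield from rec_subsets(avail[1:], need)
        first = avail[0]
        for idx in range(1, len(avail)):
            partner = avail[idx]
            inside = avail[1:idx]
            outside = avail[idx + 1:]
            for k in range(0, need):
                for inner in rec_subsets(inside, k):
                    for outer in rec_subsets(outside, need - 1 - k):
                        yield [(first, partner)] + inner + outer

    yield from rec_subsets(tuple(positions), size)


def injective_lewis_realization(S: StoichiometricMatrix) -> LewisRealization:
    """Valency-4 realization with pairwise non-isomorphic graphs.

    The default sf-realization is scaled by a single integer so the smallest
    member of each obligatory-isomer class admits at least class-size many
    pairwise non-isomorphic loop-pair rewirings of its base cycle; variants
    are assigned in canonical order and verified non-isomorphic.
    """
    cert = is_conservative(S)
    if not cert.conservative:
        raise NotConservativeError(cert)
    partition = obligatory_isomer_classes(S)
    base_A = default_sf_realization(S)
    val = {a: 4 for a in base_A.atoms}

    for scale in range(1, 64):
        A = SumFormulaMatrix(
            matrix=[[scale * x for x in row] for row in base_A.matrix],
            atoms=base_A.atoms,
            species=base_A.species,
        )
        graphs: dict[str, ColoredMultigraph] = {}
        feasible = True
        for cls in partition.classes:
            col = A.column(cls[0])
            formula = {a: c for a, c in zip(A.atoms, col) if c}
            base = cycle_structural_formula(formula, k=2)
            base.val = dict(val)  # shared valency map across the realization
            n = base.n_vertices
            assigned: list[ColoredMultigraph] = []
            for variant in _loop_pair_variants(base, n):
                if not (variant.is_connected() and variant.degrees_match_valency()):
                    continue
                if any(are_isomorphic(variant, g) for g in assigned):
                    continue
                assigned.append(variant)
                if len(assigned) == len(cls):
                    break
            if len(assigned) < len(cls):
                feasible = False
                break
            for x, g in zip(cls, assigned):
                graphs[x] = g
        if feasible:
            L = LewisRealization(graphs=graphs, sf=A, val=val)
            report = validate_lewis_realization(S, L)
            assert report["valid"], report
            species = list(A.species)
            for i in range(len(species)):
                for j in range(i + 1, len(species)):
                    assert not are_isomorphic(graphs[species[i]], graphs[species[j]])
            return L
    raise RuntimeError("no scale found for injective realization (unexpected)")


def validate_lewis_realization(
    S: StoichiometricMatrix | ReactionNetwork, L: LewisRealization
) -> dict:
    """Per-graph structural checks plus per-reaction balance checks.

    Checks: degrees equal valency, connectedness, color counts matching the
    atom matrix; per reaction, per-color vertex counts balance (A S column
    zero) and total edge counts (loops counted once) balance.
    """
    if isinstance(S, ReactionNetwork):
        S = S.stoichiometric_matrix()
    problems: list[str] = []
    for x in S.row_labels:
        if x not in L.graphs:
            problems.append(f"species {x!r} has no graph")
            continue
        g = L.graphs[x]
        for u in g.graph.nodes:
            if g.degree(u) != L.val[g.color(u)]:
                problems.append(
                    f"graph for {x!r}: vertex {u} degree {g.degree(u)} != "
                    f"val({g.color(u)}) = {L.val[g.color(u)]}"
                )
        if not g.is_connected():
            problems.append(f"graph for {x!r} is not connected")
        counts = g.color_counts()
        expected = {a: c for a, c in zip(L.sf.atoms, L.sf.column(x)) if c}
        if counts != expected:
            problems.append(f"graph for {x!r}: color counts {counts} != {expected}")
    ok, diag = validate_sf_instance(S, L.sf)
    if not ok:
        problems.extend(diag)
    n_edges = {x: L.graphs[x].n_edges for x in S.row_labels if x in L.graphs}
    edge_balance = []
    for j, rid in enumerate(S.col_labels):
        col = S.column(j)
        delta = sum(c * n_edges.get(x, 0) for x, c in zip(S.row_labels, col))
        edge_balance.append(delta)
        if delta != 0:
            problems.append(f"reaction {rid!r}: edge count unbalanced by {delta}")
    return {"valid": not problems, "problems": problems, "edge_balance": edge_balance}
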