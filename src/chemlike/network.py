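"""Reaction networks as directed integer-weighted hypergraphs.

A reaction network is a pair of a species list and a reaction list. Each
reaction converts a multiset of educts into a multiset of products; the
stoichiometric matrix records only the net change per species, so explicit
catalysis cancels. All matrix entries are integers and all derived
computations are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "StoichiometricMatrix",
    "Flow",
    "FormalSum",
    "ComplexDecomposition",
    "NullReactionWarning",
    "build_stoichiometric_matrix",
    "classify_reaction",
    "proper_part",
    "is_closed",
    "reverse_reaction",
    "composite_reaction",
    "net_reaction",
    "complex_decomposition",
    "subnetwork",
]

REVERSAL_SUFFIX = "_rev"


class NullReactionWarning(UserWarning):
    """A reaction whose net stoichiometric column is all zero."""


class FormalSum(dict):
    """Formal sum of species with non-negative integer coefficients.

    Used for reaction sides (complexes) and for composite / net reaction
    sides.  The empty sum prints as the empty-set symbol.
    """

    def __init__(self, coeffs: Mapping[str, int] | None = None):
        super().__init__()
        if coeffs:
            for sp, c in coeffs.items():
                c = int(c)
                if c < 0:
                    raise ValueError(f"negative coefficient for {sp!r}")
                if c > 0:
                    self[sp] = c

    def __str__(self) -> str:
        if not self:
            return "∅"
        parts = []
        for sp in self:
            c = self[sp]
            parts.append(sp if c == 1 else f"{c} {sp}")
        return " + ".join(parts)

    def __hash__(self):  # type: ignore[override]
        return hash(frozenset(self.items()))


@dataclass(frozen=True)
class Reaction:
    """One reaction with explicit educt/product coefficients.

    Educt and product coefficients are kept separately so that explicit
    catalysts (species with equal coefficients on both sides) are preserved
    even though they cancel in the stoichiometric matrix.
    """

    id: str
    educts: Mapping[str, int]
    products: Mapping[str, int]
    reversible: bool = False
    # provenance only; excluded from equality
    reverse_of: str | None = field(default=None, compare=False)

    def __post_init__(self):
        for side in (self.educts, self.products):
            for sp, c in side.items():
                if int(c) != c or c < 0:
                    raise ValueError(
                        f"reaction {self.id!r}: coefficient of {sp!r} must be a "
                        f"non-negative integer, got {c!r}"
                    )
        object.__setattr__(self, "educts", {s: int(c) for s, c in self.educts.items() if c})
        object.__setattr__(self, "products", {s: int(c) for s, c in self.products.items() if c})
        if not self.educts and not self.products:
            raise ValueError(f"reaction {self.id!r} has empty support")

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.educts) | frozenset(self.products)

    def net_coefficient(self, species: str) -> int:
        return self.products.get(species, 0) - self.educts.get(species, 0)

    def __str__(self) -> str:
        arrow = "<=>" if self.reversible else "->"
        return f"{FormalSum(self.educts)} {arrow} {FormalSum(self.products)}"


class ReactionNetwork:
    """A finite reaction network: ordered species and ordered reactions."""

    def __init__(self, species: Sequence[str], reactions: Sequence[Reaction]):
        species = list(species)
        reactions = list(reactions)
        if not species:
            raise ValueError("species list must be non-empty")
        if not reactions:
            raise ValueError("reaction list must be non-empty")
        if len(set(species)) != len(species):
            raise ValueError("species ids must be unique")
        ids = [r.id for r in reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("reaction ids must be unique")
        known = set(species)
        for r in reactions:
            missing = r.support - known
            if missing:
                raise ValueError(
                    f"reaction {r.id!r} references unknown species {sorted(missing)}"
                )
        self.species: list[str] = species
        self.reactions: list[Reaction] = reactions
        self._species_index = {s: i for i, s in enumerate(species)}
        self._reaction_index = {r.id: i for i, r in enumerate(reactions)}

    # -- basic accessors ---------------------------------------------------
    def species_index(self, species: str) -> int:
        return self._species_index[species]

    def reaction_index(self, rid: str) -> int:
        return self._reaction_index[rid]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._reaction_index[rid]]

    @property
    def reversible_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.reversible]

    @property
    def irreversible_ids(self) -> list[str]:
        return [r.id for r in self.reactions if not r.reversible]

    def reverse_pairs(self) -> list[tuple[str, str]]:
        """Structurally reverse pairs (equal complexes, swapped), each pair once."""
        pairs = []
        seen = set()
        sides = {
            r.id: (frozenset(r.educts.items()), frozenset(r.products.items()))
            for r in self.reactions
        }
        for r in self.reactions:
            if r.id in seen:
                continue
            e, p = sides[r.id]
            for q in self.reactions:
                if q.id == r.id or q.id in seen:
                    continue
                if sides[q.id] == (p, e):
                    pairs.append((r.id, q.id))
                    seen.update((r.id, q.id))
                    break
        return pairs

    def stoichiometric_matrix(self) -> "StoichiometricMatrix":
        return build_stoichiometric_matrix(self)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReactionNetwork)
            and self.species == other.species
            and self.reactions == other.reactions
        )

    def __repr__(self) -> str:
        return f"<ReactionNetwork |X|={len(self.species)} |R|={len(self.reactions)}>"


class StoichiometricMatrix:
    """Integer matrix (species x reactions) of net stoichiometric changes."""

    def __init__(
        self,
        entries: Sequence[Sequence[int]],
        row_labels: Sequence[str],
        col_labels: Sequence[str],
    ):
        rows = [list(map(int, row)) for row in entries]
        if len(rows) != len(row_labels):
            raise ValueError("row count does not match row labels")
        for row in rows:
            if len(row) != len(col_labels):
                raise ValueError("ragged or mislabelled matrix")
        self.entries: list[list[int]] = rows
        self.row_labels = list(row_labels)
        self.col_labels = list(col_labels)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_labels), len(self.col_labels))

    def column(self, j: int) -> list[int]:
        return [row[j] for row in self.entries]

    def columns(self) -> list[list[int]]:
        return [self.column(j) for j in range(len(self.col_labels))]

    def multiply(self, v: Sequence) -> list:
        """Exact S @ v for a rational/integer vector over reactions."""
        if len(v) != len(self.col_labels):
            raise ValueError("vector length does not match reaction count")
        return [sum(row[j] * v[j] for j in range(len(v))) for row in self.entries]

    def multiply_left(self, m: Sequence) -> list:
        """Exact m^T @ S for a rational/integer vector over species."""
        if len(m) != len(self.row_labels):
            raise ValueError("vector length does not match species count")
        return [
            sum(self.entries[i][j] * m[i] for i in range(len(m)))
            for j in range(len(self.col_labels))
        ]

    def transpose_multiply(self, G: Sequence) -> list:
        """Exact S^T @ G (alias of :meth:`multiply_left` as a column vector)."""
        return self.multiply_left(G)

    def submatrix(self, col_ids: Iterable[str]) -> "StoichiometricMatrix":
        idx = [self.col_labels.index(c) for c in col_ids]
        return StoichiometricMatrix(
            [[row[j] for j in idx] for row in self.entries],
            self.row_labels,
            [self.col_labels[j] for j in idx],
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StoichiometricMatrix)
            and self.entries == other.entries
            and self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
        )

    def __repr__(self) -> str:
        return f"<StoichiometricMatrix {self.shape[0]}x{self.shape[1]}>"


@dataclass
class Flow:
    """A vector over reactions; flows proper require all entries >= 0."""

    values: list
    integer: bool = True

    def __post_init__(self):
        self.values = [Fraction(v) if not isinstance(v, int) else v for v in self.values]
        self.integer = all(Fraction(v).denominator == 1 for v in self.values)

    @property
    def nonnegative(self) -> bool:
        return all(v >= 0 for v in self.values)

    @property
    def nontrivial(self) -> bool:
        return any(v != 0 for v in self.values)

    @property
    def support(self) -> frozenset[int]:
        return frozenset(i for i, v in enumerate(self.values) if v != 0)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def __getitem__(self, i):
        return self.values[i]


@dataclass
class ComplexDecomposition:
    """Factorization S = Y Z through the complex-reaction graph."""

    complexes: list[FormalSum]
    complex_matrix: list[list[int]]  # Y: species x complexes
    incidence: list[list[int]]  # Z: complexes x reactions, entries in {-1,0,1}
    species: list[str] = field(default_factory=list)
    reaction_ids: list[str] = field(default_factory=list)

    def verify(self, S: StoichiometricMatrix) -> bool:
        n_sp, n_rx = S.shape
        for i in range(n_sp):
            for j in range(n_rx):
                yz = sum(
                    self.complex_matrix[i][k] * self.incidence[k][j]
                    for k in range(len(self.complexes))
                )
                if yz != S.entries[i][j]:
                    return False
        return True


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(net: ReactionNetwork) -> StoichiometricMatrix:
    """Net stoichiometric matrix in network species/reaction order."""
    entries = [
        [r.net_coefficient(sp) for r in net.reactions] for sp in net.species
    ]
    return StoichiometricMatrix(entries, list(net.species), [r.id for r in net.reactions])


def classify_reaction(r: Reaction, species: Sequence[str] | None = None) -> str:
    """Classify a reaction as ``proper``, ``import``, or ``export``.

    Classification uses net coefficients, so a catalyzed import such as
    C -> C + A is recognized as an import.  An all-zero net column is both an
    import and an export; it is reported as ``null`` with a warning.
    """
    support = sorted(r.support) if species is None else list(species)
    net = [r.net_coefficient(sp) for sp in support]
    has_pos = any(c > 0 for c in net)
    has_neg = any(c < 0 for c in net)
    if has_pos and has_neg:
        return "proper"
    if not has_pos and not has_neg:
        warnings.warn(
            f"reaction {r.id!r} is a null reaction (all-zero net column)",
            NullReactionWarning,
            stacklevel=2,
        )
        return "null"
    return "import" if has_pos else "export"


def is_closed(net: ReactionNetwork) -> bool:
    """True iff every reaction is proper (Definition of a closed network)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NullReactionWarning)
        return all(classify_reaction(r) == "proper" for r in net.reactions)


def proper_part(net: ReactionNetwork) -> ReactionNetwork:
    """The inclusion-maximal closed subnetwork: same species, proper reactions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NullReactionWarning)
        proper = [r for r in net.reactions if classify_reaction(r) == "proper"]
    if not proper:
        raise ValueError("no proper reactions: proper part would be empty")
    return ReactionNetwork(net.species, proper)


def reverse_reaction(r: Reaction) -> Reaction:
    """Exchange educts and products; the reverse column is the negated column."""
    if r.id.endswith(REVERSAL_SUFFIX):
        rid = r.id[: -len(REVERSAL_SUFFIX)]
    else:
        rid = r.id + REVERSAL_SUFFIX
    return Reaction(
        id=rid,
        educts=dict(r.products),
        products=dict(r.educts),
        reversible=r.reversible,
        reverse_of=r.id,
    )


def composite_reaction(net: ReactionNetwork, v: Flow | Sequence) -> tuple[FormalSum, FormalSum]:
    """Composite reaction for a non-negative integer flow: literal column sums.

    No cancellation is performed; intermediates (formal catalysts) appear on
    both sides.  Use :func:`net_reaction` for the cancelled version.
    """
    vals = list(v.values) if isinstance(v, Flow) else list(v)
    if len(vals) != len(net.reactions):
        raise ValueError("flow length does not match reaction count")
    if any(x < 0 for x in vals):
        raise ValueError("not a flow: negative entry")
    left: dict[str, int] = {}
    right: dict[str, int] = {}
    for r, vr in zip(net.reactions, vals):
        if vr == 0:
            continue
        for sp, c in r.educts.items():
            left[sp] = left.get(sp, 0) + c * vr
        for sp, c in r.products.items():
            right[sp] = right.get(sp, 0) + c * vr
    return FormalSum(left), FormalSum(right)


def net_reaction(
    net: ReactionNetwork,
    v: Flow | Sequence,
    allow_reverse: bool = False,
) -> tuple[FormalSum, FormalSum]:
    """Net reaction of an integer hyperflow: positive/negative parts of S v.

    Signed entries are permitted when every reaction carrying a negative
    entry is reversible (interpreted in the reversible completion), or when
    ``allow_reverse`` is set.
    """
    vals = list(v.values) if isinstance(v, Flow) else list(v)
    if len(vals) != len(net.reactions):
        raise ValueError("flow length does not match reaction count")
    if not allow_reverse:
        for r, vr in zip(net.reactions, vals):
            if vr < 0 and not r.reversible:
                raise ValueError(
                    f"negative entry on irreversible reaction {r.id!r}; "
                    "pass allow_reverse=True for reversible-completion semantics"
                )
    S = build_stoichiometric_matrix(net)
    sv = S.multiply(vals)
    left = {sp: -c for sp, c in zip(net.species, sv) if c < 0}
    right = {sp: c for sp, c in zip(net.species, sv) if c > 0}
    return FormalSum(left), FormalSum(right)


def complex_decomposition(net: ReactionNetwork) -> ComplexDecomposition:
    """Collect distinct complexes and factor S = Y Z exactly."""
    complexes: list[FormalSum] = []
    index: dict[FormalSum, int] = {}

    def intern(side: Mapping[str, int]) -> int:
        fs = FormalSum(side)
        if fs not in index:
            index[fs] = len(complexes)
            complexes.append(fs)
        return index[fs]

    edges = [(intern(r.educts), intern(r.products)) for r in net.reactions]
    Y = [[fs.get(sp, 0) for fs in complexes] for sp in net.species]
    Z = [[0] * len(net.reactions) for _ in complexes]
    for j, (e, p) in enumerate(edges):
        if e != p:
            Z[e][j] = -1
            Z[p][j] = 1
    dec = ComplexDecomposition(
        complexes=complexes,
        complex_matrix=Y,
        incidence=Z,
        species=list(net.species),
        reaction_ids=[r.id for r in net.reactions],
    )
    S = build_stoichiometric_matrix(net)
    assert dec.verify(S), "internal error: Y Z != S"
    return dec


def subnetwork(
    net: ReactionNetwork,
    species_subset: Iterable[str],
    reaction_subset: Iterable[str],
) -> ReactionNetwork:
    """Validated subnetwork: supp(r) within X' must imply r in R'."""
    keep_sp = [s for s in net.species if s in set(species_subset)]
    keep_rx = set(reaction_subset)
    unknown = keep_rx - {r.id for r in net.reactions}
    if unknown:
        raise ValueError(f"unknown reaction ids {sorted(unknown)}")
    sp_set = set(keep_sp)
    for r in net.reactions:
        if r.support <= sp_set and r.id not in keep_rx:
            raise ValueError(
                f"closure violation: reaction {r.id!r} is supported on the "
                "species subset but was not included"
            )
    reactions = [r for r in net.reactions if r.id in keep_rx]
    for r in reactions:
        if not r.support <= sp_set:
            raise ValueError(
                f"reaction {r.id!r} references species outside the subset"
            )
    return ReactionNetwork(keep_sp, reactions)
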