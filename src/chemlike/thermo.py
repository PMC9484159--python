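"""Reaction energies, Hess's law, futile cycles, and soundness decisions.

The central decision procedures implement theorems of the alternative:
either a witness energy vector exists (g in the row space of S with the
required sign pattern) or there is a futile-cycle certificate.  Witness
search may use the exact rational simplex; every certificate is re-verified
in exact arithmetic before it is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from ._exact import (
    extreme_rays,
    integer_kernel_basis,
    rational_feasible,
    reduce_to_coprime,
    solve_exact,
)
from .network import (
    Flow,
    Reaction,
    ReactionNetwork,
    StoichiometricMatrix,
    build_stoichiometric_matrix,
    reverse_reaction,
)

__all__ = [
    "ReactionEnergies",
    "MolecularEnergies",
    "SoundnessReport",
    "hess_reaction_energies",
    "recover_molecular_energies",
    "is_thermodynamic",
    "reverse_pair_energy_check",
    "enumerate_futile_cycles",
    "FutileCycle",
    "find_perpetuum_mobile",
    "is_thermodynamically_sound",
    "is_strictly_sound",
    "reversible_completion",
    "nonneg_equivalent_flow",
]

ReactionEnergies = list  # rational vector over reactions
MolecularEnergies = list  # rational vector over species


@dataclass
class FutileCycle:
    """A support-minimal integer flow v > 0 with S v = 0.

    ``signed`` marks certificates whose entries on reversible reactions are
    negative; these are futile cycles of the reversible completion (used when
    reversibility is a flag rather than an explicit reverse column).
    """

    values: list[int]
    trivial: bool = False  # support is exactly an expanded reversible pair
    signed: bool = False

    @property
    def support(self) -> frozenset[int]:
        return frozenset(i for i, x in enumerate(self.values) if x)

    def as_flow(self) -> Flow:
        return Flow(list(self.values))


@dataclass
class SoundnessReport:
    """Outcome of a (lax or strict) thermodynamic soundness decision.

    Exactly one of ``witness_g`` / ``certificate`` is present.  In the sound
    branch, ``witness_G`` holds molecular energies with
    ``witness_g = S^T witness_G``; in the unsound branch, ``certificate`` is
    a futile cycle whose support lies in (lax) or intersects (strict) the
    irreversible reaction set.
    """

    sound: bool
    mode: str  # "lax" or "strict"
    witness_g: list | None = None
    witness_G: list | None = None
    certificate: FutileCycle | None = None
    gamma_used: Fraction | None = None
    trivial_kernel: bool = False

    def __post_init__(self):
        assert (self.witness_g is None) != (self.certificate is None)


def _as_matrix(S: StoichiometricMatrix) -> list[list[int]]:
    return S.entries


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def hess_reaction_energies(S: StoichiometricMatrix, G: Sequence) -> ReactionEnergies:
    """g = S^T G in exact rational arithmetic (Hess's law)."""
    if len(G) != S.shape[0]:
        raise ValueError("molecular energy vector length does not match species")
    return [Fraction(x) for x in S.transpose_multiply([Fraction(g) for g in G])]


def recover_molecular_energies(
    S: StoichiometricMatrix, g: Sequence
) -> MolecularEnergies | None:
    """Any exact G with S^T G = g, or None iff g is not in im S^T.

    G is not uniquely determined in general; one particular solution is
    returned.
    """
    if len(g) != S.shape[1]:
        raise ValueError("reaction energy vector length does not match reactions")
    St = [list(col) for col in zip(*S.entries)]
    return solve_exact(St, [Fraction(x) for x in g])


def is_thermodynamic(S: StoichiometricMatrix, g: Sequence) -> bool:
    """True iff g is orthogonal to ker S (checked against an exact basis)."""
    if len(g) != S.shape[1]:
        raise ValueError("dimension mismatch")
    gf = [Fraction(x) for x in g]
    for v in integer_kernel_basis(S.entries):
        if sum(a * b for a, b in zip(gf, v)) != 0:
            return False
    return True


def reverse_pair_energy_check(
    net: ReactionNetwork, g: Sequence
) -> list[tuple[str, str, Fraction]]:
    """Pairs of structurally reverse reactions with g_r + g_rbar != 0.

    An empty list is necessary (not sufficient) for the network with these
    energies to be thermodynamic.
    """
    gf = [Fraction(x) for x in g]
    violations = []
    for rid, qid in net.reverse_pairs():
        total = gf[net.reaction_index(rid)] + gf[net.reaction_index(qid)]
        if total != 0:
            violations.append((rid, qid, total))
    return violations


# ---------------------------------------------------------------------------
# futile cycles and perpetuum mobile
# ---------------------------------------------------------------------------

def enumerate_futile_cycles(
    S: StoichiometricMatrix,
    net: ReactionNetwork | None = None,
    max_rays: int | None = 100_000,
) -> list[FutileCycle]:
    """All support-minimal integer futile cycles (extreme rays of
    {v >= 0 : S v = 0}), coprime-scaled and deterministically ordered.

    When the generating network is supplied, cycles whose support is exactly
    an expanded reversible pair are flagged trivial.
    """
    rays = extreme_rays(_as_matrix(S), max_rays=max_rays)
    pair_supports: set[frozenset[int]] = set()
    if net is not None:
        for rid, qid in net.reverse_pairs():
            pair_supports.add(
                frozenset((net.reaction_index(rid), net.reaction_index(qid)))
            )
    out = []
    for v in rays:
        supp = frozenset(i for i, x in enumerate(v) if x)
        out.append(FutileCycle(values=v, trivial=supp in pair_supports))
    for fc in out:
        assert all(x == 0 for x in S.multiply(fc.values)), "certificate failed"
    return out


def find_perpetuum_mobile(
    S: StoichiometricMatrix, g: Sequence
) -> Flow | None:
    """A flow v > 0 with S v = 0 and <g, v> != 0, or None.

    A linear functional is non-zero on the futile cone iff it is non-zero on
    some extreme ray, so the search reduces to the enumerated cycles.
    """
    gf = [Fraction(x) for x in g]
    for fc in enumerate_futile_cycles(S):
        energy = sum(a * b for a, b in zip(gf, fc.values))
        if energy != 0:
            return fc.as_flow()
    return None


# ---------------------------------------------------------------------------
# soundness decisions (theorems of the alternative)
# ---------------------------------------------------------------------------

def _witness_from_G(S: StoichiometricMatrix, G: list[Fraction]) -> list[Fraction]:
    return [Fraction(x) for x in S.transpose_multiply(G)]


def is_thermodynamically_sound(
    S: StoichiometricMatrix, irr: Sequence[str] | Sequence[int] | None = None
) -> SoundnessReport:
    """Lax soundness: admissible energies exist iff there is no futile cycle
    supported entirely on irreversible reactions.

    ``irr`` may be reaction ids (matching column labels) or column indices;
    by default all reactions are irreversible.
    """
    n_sp, n_rx = S.shape
    irr_idx = _resolve_irr(S, irr)
    trivial_kernel = not integer_kernel_basis(S.entries)

    # unsound branch: nonzero ray of {v >= 0, S v = 0, supp(v) in irr}
    if irr_idx:
        sub = [[row[j] for j in irr_idx] for row in S.entries]
        rays = extreme_rays(sub)
        if rays:
            v = [0] * n_rx
            for pos, j in enumerate(irr_idx):
                v[j] = rays[0][pos]
            assert all(x == 0 for x in S.multiply(v))
            return SoundnessReport(
                sound=False, mode="lax",
                certificate=FutileCycle(values=v),
                trivial_kernel=trivial_kernel,
            )

    # sound branch: find G with (S^T G)_r <= -1 for r in irr
    if not irr_idx:
        G = [Fraction(0)] * n_sp
    else:
        St = [list(col) for col in zip(*S.entries)]
        A_ub = [St[j] for j in irr_idx]
        b_ub = [Fraction(-1)] * len(irr_idx)
        G = rational_feasible(n_sp, A_ub=A_ub, b_ub=b_ub)
        assert G is not None, "Minty alternative violated (internal error)"
    g = _witness_from_G(S, G)
    for j in irr_idx:
        assert g[j] < 0
    return SoundnessReport(
        sound=True, mode="lax", witness_g=g, witness_G=G,
        trivial_kernel=trivial_kernel,
    )


def is_strictly_sound(
    S: StoichiometricMatrix,
    rev: Sequence[str] | Sequence[int] | None = None,
    irr: Sequence[str] | Sequence[int] | None = None,
    gamma: int | Fraction = 1000,
    net: ReactionNetwork | None = None,
) -> SoundnessReport:
    """Strict soundness: holds iff no futile cycle's support intersects the
    irreversible set.  The witness (for the requested gamma > 1) satisfies
    |g_r| <= 1 on reversible and g_r <= -gamma on irreversible reactions.
    """
    if Fraction(gamma) <= 1:
        raise ValueError("gamma must exceed 1")
    n_sp, n_rx = S.shape
    irr_idx = _resolve_irr(S, irr)
    if rev is None:
        rev_idx = [j for j in range(n_rx) if j not in set(irr_idx)]
    else:
        rev_idx = _resolve_irr(S, rev)
    if set(rev_idx) | set(irr_idx) != set(range(n_rx)):
        raise ValueError("rev and irr must cover all reactions")
    kernel = integer_kernel_basis(S.entries)
    trivial_kernel = not kernel

    # non-negative futile cycles touching the irreversible set
    for fc in enumerate_futile_cycles(S, net=net):
        if fc.support & set(irr_idx):
            return SoundnessReport(
                sound=False, mode="strict", certificate=fc,
                gamma_used=Fraction(gamma), trivial_kernel=trivial_kernel,
            )
    # cycles of the reversible completion: v in ker S, v >= 0 on irr,
    # v_{r*} > 0 for some irreversible r*; entries on reversible reactions
    # may be negative (rerouted through the implicit reverse column).
    irr_set = set(irr_idx)
    for r_star in irr_idx:
        if all(v[r_star] == 0 for v in kernel):
            continue  # r* never carries flux in any kernel vector
        A_eq = [list(row) for row in S.entries]
        A_eq.append([1 if j == r_star else 0 for j in range(n_rx)])
        b_eq = [Fraction(0)] * n_sp + [Fraction(1)]
        A_ub = [[-1 if j == r else 0 for j in range(n_rx)]
                for r in irr_idx if r != r_star]
        b_ub = [Fraction(0)] * len(A_ub)
        v = rational_feasible(n_rx, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub)
        if v is not None:
            v_int = reduce_to_coprime(v)
            if v_int[r_star] < 0:
                v_int = [-x for x in v_int]
            assert all(x == 0 for x in S.multiply(v_int))
            assert all(v_int[r] >= 0 for r in irr_idx) and v_int[r_star] > 0
            return SoundnessReport(
                sound=False, mode="strict",
                certificate=FutileCycle(
                    values=v_int,
                    signed=any(v_int[j] < 0 for j in range(n_rx)),
                ),
                gamma_used=Fraction(gamma), trivial_kernel=trivial_kernel,
            )

    St = [list(col) for col in zip(*S.entries)]
    A_ub: list[list] = []
    b_ub: list = []
    for j in irr_idx:
        A_ub.append(St[j])
        b_ub.append(-Fraction(gamma))
    for j in rev_idx:
        A_ub.append(St[j])
        b_ub.append(Fraction(1))
        A_ub.append([-x for x in St[j]])
        b_ub.append(Fraction(1))
    G = rational_feasible(n_sp, A_ub=A_ub, b_ub=b_ub)
    assert G is not None, "Minty alternative violated (internal error)"
    g = _witness_from_G(S, G)
    for j in irr_idx:
        assert g[j] <= -Fraction(gamma)
    for j in rev_idx:
        assert abs(g[j]) <= 1
    return SoundnessReport(
        sound=True, mode="strict", witness_g=g, witness_G=G,
        gamma_used=Fraction(gamma), trivial_kernel=trivial_kernel,
    )


def _resolve_irr(S: StoichiometricMatrix, irr) -> list[int]:
    if irr is None:
        return list(range(S.shape[1]))
    idx = []
    for r in irr:
        if isinstance(r, str):
            idx.append(S.col_labels.index(r))
        else:
            idx.append(int(r))
    return sorted(set(idx))


# ---------------------------------------------------------------------------
# reversible completion and flow rerouting
# ---------------------------------------------------------------------------

def reversible_completion(
    net: ReactionNetwork, g: Sequence | None = None
) -> tuple[ReactionNetwork, ReactionEnergies | None]:
    """Add the reverse of every irreversible reaction (with negated energy).

    When energies are supplied the input must be thermodynamic; the
    completed network is then thermodynamic as well.
    """
    S = build_stoichiometric_matrix(net)
    if g is not None:
        if not is_thermodynamic(S, g):
            raise ValueError("input network with these energies is not thermodynamic")
        g = [Fraction(x) for x in g]

    existing = {
        (frozenset(r.educts.items()), frozenset(r.products.items()))
        for r in net.reactions
    }
    reactions: list[Reaction] = []
    energies: list[Fraction] = []
    for j, r in enumerate(net.reactions):
        reactions.append(
            Reaction(r.id, dict(r.educts), dict(r.products), reversible=True,
                     reverse_of=r.reverse_of)
        )
        if g is not None:
            energies.append(g[j])
    for j, r in enumerate(net.reactions):
        key = (frozenset(r.products.items()), frozenset(r.educts.items()))
        if key in existing:
            continue
        existing.add(key)
        rbar = reverse_reaction(r)
        reactions.append(
            Reaction(rbar.id, dict(rbar.educts), dict(rbar.products),
                     reversible=True, reverse_of=r.id)
        )
        if g is not None:
            energies.append(-g[j])
    completed = ReactionNetwork(net.species, reactions)
    return completed, (energies if g is not None else None)


def nonneg_equivalent_flow(
    net: ReactionNetwork, v: Sequence, g: Sequence | None = None
) -> Flow:
    """Reroute negative entries through reverse columns: returns vtilde >= 0
    with S vtilde = S v (and equal energy when g is antisymmetric on pairs).

    The network must contain the reverse of every reaction carrying a
    negative entry.
    """
    vals = list(v.values) if isinstance(v, Flow) else [Fraction(x) for x in v]
    if len(vals) != len(net.reactions):
        raise ValueError("vector length does not match reaction count")
    sides = {
        r.id: (frozenset(r.educts.items()), frozenset(r.products.items()))
        for r in net.reactions
    }
    reverse_of: dict[int, int] = {}
    for i, r in enumerate(net.reactions):
        e, p = sides[r.id]
        for k, q in enumerate(net.reactions):
            if k != i and sides[q.id] == (p, e):
                reverse_of[i] = k
                break
    out = list(vals)
    for i, x in enumerate(vals):
        if x < 0:
            if i not in reverse_of:
                raise ValueError(
                    f"negative entry on reaction {net.reactions[i].id!r} "
                    "without a reverse in the network"
                )
            out[i] = Fraction(0) if isinstance(x, Fraction) else 0
            out[reverse_of[i]] = out[reverse_of[i]] - x
    flow = Flow(out)
    S = build_stoichiometric_matrix(net)
    assert S.multiply(flow.values) == S.multiply(vals)
    if g is not None:
        gf = [Fraction(x) for x in g]
        e_old = sum(a * b for a, b in zip(gf, vals))
        e_new = sum(a * b for a, b in zip(gf, flow.values))
        assert e_old == e_new, "energy not preserved (g not antisymmetric on pairs?)"
    return flow
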