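"""Random chemistry-like networks: conservative and sound by construction.

The generator first samples a strictly positive integer mass vector, then
samples proper mass-balanced columns (so a positive conservation law exists
by construction), then derives reaction energies from random molecular
energies via Hess's law (so the energies are thermodynamic by construction).
Irreversibility is only assigned where the chosen soundness mode permits.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction

from ._exact import integer_kernel_basis
from .network import Reaction, ReactionNetwork, StoichiometricMatrix

__all__ = ["GeneratorConfig", "add_catalysts", "random_conservative_sound_network",
           "random_subnetwork"]


@dataclass
class GeneratorConfig:
    n_species: int = 6
    n_reactions: int = 8
    max_coeff: int = 3
    mass_min: int = 1
    mass_max: int = 6
    sparsity: float = 0.5
    irreversible_fraction: float = 0.5
    strict: bool = False
    seed: int = 0
    max_retries: int = 2000

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")
        if self.max_coeff < 1:
            raise ValueError("max_coeff must be >= 1")
        if not 1 <= self.mass_min <= self.mass_max:
            raise ValueError("mass range must satisfy 1 <= mass_min <= mass_max")


def add_catalysts(
    S: StoichiometricMatrix, C: list[list[int]]
) -> tuple[list[list[int]], list[list[int]]]:
    """Catalyst augmentation: s- = C + [-S]_+, s+ = C + [S]_+.

    The reconstructed net matrix s+ - s- equals S for any non-negative C.
    """
    n_sp, n_rx = S.shape
    if len(C) != n_sp or any(len(row) != n_rx for row in C):
        raise ValueError("catalyst matrix shape does not match S")
    for row in C:
        for x in row:
            if x < 0:
                raise ValueError("catalyst entries must be non-negative")
    s_minus = [
        [C[i][j] + max(0, -S.entries[i][j]) for j in range(n_rx)]
        for i in range(n_sp)
    ]
    s_plus = [
        [C[i][j] + max(0, S.entries[i][j]) for j in range(n_rx)]
        for i in range(n_sp)
    ]
    return s_minus, s_plus


def _sample_balanced_column(
    rng: random.Random, masses: list[int], cfg: GeneratorConfig
) -> list[int] | None:
    """One proper integer column z with m . z = 0 and entries <= max_coeff.

    Educt multiset first, then a bounded-knapsack search for a product
    multiset of exactly matching mass over the remaining species.
    """
    n = len(masses)
    target_nonzero = max(2, round(n * (1.0 - cfg.sparsity)))
    n_educt = rng.randint(1, max(1, target_nonzero // 2))
    educt_species = rng.sample(range(n), min(n_educt, n - 1))
    z = [0] * n
    total = 0
    for i in educt_species:
        c = rng.randint(1, cfg.max_coeff)
        z[i] = -c
        total += c * masses[i]
    remaining = [i for i in range(n) if z[i] == 0]
    rng.shuffle(remaining)
    # bounded knapsack: pick product coefficients summing to `total` in mass
    picks = _knapsack(remaining, masses, total, cfg.max_coeff, rng)
    if picks is None:
        return None
    for i, c in picks:
        z[i] = c
    return z


def _knapsack(
    items: list[int], masses: list[int], target: int, max_coeff: int,
    rng: random.Random,
) -> list[tuple[int, int]] | None:
    """Find coefficients c_i in [1, max_coeff] over a subset of items with
    sum c_i * m_i == target; randomized DFS."""

    def rec(idx: int, left: int) -> list[tuple[int, int]] | None:
        if left == 0:
            return []
        if idx >= len(items):
            return None
        # upper bound prune
        ub = sum(max_coeff * masses[i] for i in items[idx:])
        if ub < left:
            return None
        i = items[idx]
        choices = [0] + list(range(1, max_coeff + 1))
        rng.shuffle(choices)
        for c in choices:
            if c * masses[i] <= left:
                rest = rec(idx + 1, left - c * masses[i])
                if rest is not None:
                    return ([(i, c)] if c else []) + rest
        return None

    return rec(0, target)


def random_conservative_sound_network(
    cfg: GeneratorConfig,
) -> tuple[ReactionNetwork, list, list]:
    """Generate (network, molecular energies G, reaction energies g).

    Conservative by construction (witness: the sampled mass vector) and
    thermodynamic by construction (g = S^T G).  Reactions are marked
    irreversible only when exergonic; in strict mode additionally only when
    provably absent from every futile cycle.
    """
    rng = random.Random(cfg.seed)
    species = [f"S{i+1}" for i in range(cfg.n_species)]
    masses = [rng.randint(cfg.mass_min, cfg.mass_max) for _ in range(cfg.n_species)]

    columns: list[list[int]] = []
    seen = set()
    attempts = 0
    while len(columns) < cfg.n_reactions:
        attempts += 1
        if attempts > cfg.max_retries:
            raise RuntimeError(
                "could not sample enough mass-balanced columns; "
                "loosen max_coeff / sparsity or shrink the network"
            )
        z = _sample_balanced_column(rng, masses, cfg)
        if z is None:
            continue
        if not (any(x > 0 for x in z) and any(x < 0 for x in z)):
            continue
        key = tuple(z)
        if key in seen:
            continue
        seen.add(key)
        columns.append(z)

    entries = [[columns[j][i] for j in range(cfg.n_reactions)]
               for i in range(cfg.n_species)]
    S = StoichiometricMatrix(entries, species,
                             [f"r{j+1}" for j in range(cfg.n_reactions)])
    assert all(x == 0 for x in S.multiply_left(masses))

    # energies via Hess's law
    G = [Fraction(rng.randint(-20, 20)) for _ in range(cfg.n_species)]
    g = [Fraction(x) for x in S.transpose_multiply(G)]

    # irreversibility marking
    eligible = [j for j in range(cfg.n_reactions) if g[j] < 0]
    if cfg.strict and eligible:
        # a reaction may be irreversible only if no kernel vector (hence no
        # futile cycle of the reversible completion) carries flux through it
        kernel = integer_kernel_basis(entries)
        eligible = [j for j in eligible if all(v[j] == 0 for v in kernel)]
    n_irr = round(cfg.irreversible_fraction * cfg.n_reactions)
    irr = set(rng.sample(eligible, min(n_irr, len(eligible))))

    reactions = []
    for j in range(cfg.n_reactions):
        educts = {species[i]: -columns[j][i] for i in range(cfg.n_species)
                  if columns[j][i] < 0}
        products = {species[i]: columns[j][i] for i in range(cfg.n_species)
                    if columns[j][i] > 0}
        reactions.append(
            Reaction(f"r{j+1}", educts, products, reversible=j not in irr)
        )
    net = ReactionNetwork(species, reactions)
    return net, G, g


def random_subnetwork(net: ReactionNetwork, k: int, seed: int = 0) -> ReactionNetwork:
    """Uniform k-reaction subnetwork with induced species, closure enforced.

    Reactions forced by the closure condition (their support lies inside the
    induced species set) are added to the sample.
    """
    if not 1 <= k <= len(net.reactions):
        raise ValueError("k out of range")
    rng = random.Random(seed)
    chosen = set(rng.sample([r.id for r in net.reactions], k))
    while True:
        sp = set()
        for r in net.reactions:
            if r.id in chosen:
                sp |= r.support
        forced = {
            r.id for r in net.reactions
            if r.support <= sp and r.id not in chosen
        }
        if not forced:
            break
        chosen |= forced
    species = [s for s in net.species if s in sp]
    from .network import subnetwork as _sub
    return _sub(net, species, chosen)
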