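"""Built-in example networks used throughout the tests and the CLI.

Each fixture is a small network with documented expected outcomes: futile
cycle counts, soundness verdicts, kernel dimensions, and where applicable
molecular or reaction energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .network import Reaction, ReactionNetwork

__all__ = ["Fixture", "builtin_fixture", "fixture_names"]


@dataclass
class Fixture:
    name: str
    network: ReactionNetwork
    molecular_energies: list[Fraction] | None = None
    reaction_energies: list[Fraction] | None = None
    notes: str = ""
    expected: dict = field(default_factory=dict)


def _rn(species, triples) -> ReactionNetwork:
    reactions = [
        Reaction(rid, educts, products, reversible=rev)
        for rid, educts, products, rev in triples
    ]
    return ReactionNetwork(species, reactions)


def _build_registry() -> dict[str, Fixture]:
    reg: dict[str, Fixture] = {}

    # A -> B, B -> A, B -> C, A -> C with g = (1, -1, -3, -1)
    reg["example10"] = Fixture(
        name="example10",
        network=_rn(
            ["A", "B", "C"],
            [
                ("r1", {"A": 1}, {"B": 1}, True),
                ("r1_rev", {"B": 1}, {"A": 1}, True),
                ("r2", {"B": 1}, {"C": 1}, False),
                ("r3", {"A": 1}, {"C": 1}, False),
            ],
        ),
        reaction_energies=[Fraction(1), Fraction(-1), Fraction(-3), Fraction(-1)],
        notes="one futile cycle, no perpetuum mobile; not thermodynamic with "
              "the given energies, fixable by g3 = -2",
        expected={"futile_cycles": 1},
    )

    # A <-> B, B -> C, C -> A with g = (1, -1, -g, -g), default g = 1
    g = Fraction(1)
    reg["example15"] = Fixture(
        name="example15",
        network=_rn(
            ["A", "B", "C"],
            [
                ("r1", {"A": 1}, {"B": 1}, True),
                ("r1_rev", {"B": 1}, {"A": 1}, True),
                ("r2", {"B": 1}, {"C": 1}, False),
                ("r3", {"C": 1}, {"A": 1}, False),
            ],
        ),
        reaction_energies=[Fraction(1), Fraction(-1), -g, -g],
        notes="two futile cycles; sound but not strictly sound",
        expected={"futile_cycles": 2},
    )

    # four irreversible pair reactions forming a futile cycle
    reg["eq9"] = Fixture(
        name="eq9",
        network=_rn(
            ["A", "B", "C", "D", "E", "F"],
            [
                ("r1", {"A": 1, "B": 1}, {"C": 1, "D": 1}, False),
                ("r2", {"A": 1, "C": 1}, {"E": 1, "B": 1}, False),
                ("r3", {"B": 1, "D": 1}, {"F": 1, "A": 1}, False),
                ("r4", {"E": 1, "F": 1}, {"A": 1, "B": 1}, False),
            ],
        ),
        notes="all-irreversible futile cycle (1,1,1,1); not sound",
        expected={"sound": False, "certificate": [1, 1, 1, 1]},
    )

    # A + B -> C + X, C -> A + B with G = (-5, -5, -10, -2)
    reg["eq16"] = Fixture(
        name="eq16",
        network=_rn(
            ["A", "B", "C", "X"],
            [
                ("r1", {"A": 1, "B": 1}, {"C": 1, "X": 1}, False),
                ("r2", {"C": 1}, {"A": 1, "B": 1}, False),
            ],
        ),
        molecular_energies=[Fraction(-5), Fraction(-5), Fraction(-10), Fraction(-2)],
        notes="creates mass: net reaction 0 -> X; not conservative",
        expected={"conservative": False, "hess_g": [Fraction(-2), Fraction(0)]},
    )

    reg["eq18"] = Fixture(
        name="eq18",
        network=_rn(
            ["MgCO3", "MgO", "CO2"],
            [("r1", {"MgCO3": 1}, {"MgO": 1, "CO2": 1}, False)],
        ),
        notes="two linearly independent conservation laws",
        expected={"kernel_dim": 2},
    )

    reg["eq19"] = Fixture(
        name="eq19",
        network=_rn(
            ["C7H8", "H2", "C6H6", "CH4"],
            [("r1", {"C7H8": 1, "H2": 1}, {"C6H6": 1, "CH4": 1}, False)],
        ),
        notes="three conservation laws but only two atom types",
        expected={
            "kernel_dim": 3,
            "atom_vectors": [[7, 0, 6, 1], [8, 2, 6, 4]],
        },
    )

    reg["eq20"] = Fixture(
        name="eq20",
        network=_rn(
            ["MgO", "H2SO4", "MgSO4", "H2O"],
            [("r1", {"MgO": 1, "H2SO4": 1}, {"MgSO4": 1, "H2O": 1}, False)],
        ),
        notes="four atom conservation laws, rank 3",
        expected={
            "atom_vectors": [
                [1, 0, 1, 0],
                [1, 4, 4, 1],
                [0, 2, 0, 2],
                [0, 1, 1, 0],
            ]
        },
    )

    reg["eq23"] = Fixture(
        name="eq23",
        network=_rn(
            ["A", "B", "C"],
            [("r1", {"A": 1, "B": 1}, {"C": 2}, False)],
        ),
        notes="three minimal MCLs: (2,0,1), (0,2,1), (1,1,1)",
        expected={"minimal_mcls": [(0, 2, 1), (1, 1, 1), (2, 0, 1)]},
    )

    eq26_reactions = [
        ("r1", {"U": 1, "V": 1}, {"X": 1}, False),
        ("r2", {"U": 1, "W": 1}, {"Y": 1}, False),
        ("r3", {"X": 1, "W": 1}, {"Z": 1}, False),
        ("r4", {"Y": 1, "V": 1}, {"Z": 1}, False),
    ]
    reg["eq26"] = Fixture(
        name="eq26",
        network=_rn(["U", "V", "W", "X", "Y", "Z"], eq26_reactions),
        notes="basic system: kernel dimension 3, all isomer classes singletons",
        expected={"kernel_dim": 3},
    )

    reg["eq27"] = Fixture(
        name="eq27",
        network=_rn(
            ["U", "V", "W", "X", "Y", "Z"],
            eq26_reactions
            + [
                ("r5", {"U": 1}, {"V": 1}, False),
                ("r6", {"V": 1}, {"W": 1}, False),
                ("r7", {"U": 1}, {"W": 1}, False),
            ],
        ),
        notes="extended system: kernel dimension 1, unique MCL (1,1,1,2,2,3), "
              "isomer classes {U,V,W}, {X,Y}, {Z}",
        expected={
            "kernel_dim": 1,
            "mcl": (1, 1, 1, 2, 2, 3),
            "isomer_classes": [["U", "V", "W"], ["X", "Y"], ["Z"]],
        },
    )

    reg["fig2_substrate_cycle"] = Fixture(
        name="fig2_substrate_cycle",
        network=_rn(
            ["S", "E", "ES", "P", "F", "FP"],
            [
                ("r1", {"S": 1, "E": 1}, {"ES": 1}, True),
                ("r2", {"ES": 1}, {"S": 1, "E": 1}, True),
                ("r3", {"ES": 1}, {"E": 1, "P": 1}, False),
                ("r4", {"P": 1, "F": 1}, {"FP": 1}, True),
                ("r5", {"FP": 1}, {"P": 1, "F": 1}, True),
                ("r6", {"FP": 1}, {"F": 1, "S": 1}, False),
            ],
        ),
        notes="substrate cycle: sound (irr={r3,r6}) but not strictly sound; "
              "non-trivial futile cycle (1,0,1,1,0,1)",
        expected={
            "sound": True,
            "strictly_sound": False,
            "nontrivial_cycle": [1, 0, 1, 1, 0, 1],
        },
    )

    return reg


_REGISTRY = _build_registry()


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def builtin_fixture(name: str) -> Fixture:
    """Look up a fixture by name; fresh copies are not needed (treat as
    read-only)."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    return _REGISTRY[name]
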