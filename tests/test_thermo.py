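from fractions import Fraction

import pytest

from chemlike.fixtures import builtin_fixture
from chemlike.network import Flow, Reaction, ReactionNetwork
from chemlike.thermo import (
    enumerate_futile_cycles,
    find_perpetuum_mobile,
    hess_reaction_energies,
    is_strictly_sound,
    is_thermodynamic,
    is_thermodynamically_sound,
    nonneg_equivalent_flow,
    recover_molecular_energies,
    reverse_pair_energy_check,
    reversible_completion,
)

from .oracles import brute_futile_cycles


def S_of(name):
    return builtin_fixture(name).network.stoichiometric_matrix()


class TestHess:
    def test_eq16_energies(self):
        fx = builtin_fixture("eq16")
        g = hess_reaction_energies(S_of("eq16"), fx.molecular_energies)
        assert g == [Fraction(-2), Fraction(0)]

    def test_zero_G(self):
        g = hess_reaction_energies(S_of("eq16"), [0, 0, 0, 0])
        assert g == [0, 0]

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            hess_reaction_energies(S_of("eq16"), [0, 0])


class TestRecover:
    def test_round_trip_residual_zero(self):
        S = S_of("eq16")
        g = hess_reaction_energies(S, [-5, -5, -10, -2])
        G = recover_molecular_energies(S, g)
        assert G is not None
        assert hess_reaction_energies(S, G) == g

    def test_example10_bad_energies_unrecoverable(self):
        S = S_of("example10")
        assert recover_molecular_energies(S, [1, -1, -3, -1]) is None

    def test_zero_g(self):
        S = S_of("eq16")
        G = recover_molecular_energies(S, [0, 0])
        assert G is not None
        assert hess_reaction_energies(S, G) == [0, 0]


class TestIsThermodynamic:
    def test_example10_not_thermodynamic(self):
        assert not is_thermodynamic(S_of("example10"), [1, -1, -3, -1])

    def test_example10_fixed_by_g3(self):
        assert is_thermodynamic(S_of("example10"), [1, -1, -3, -2])

    def test_trivial_kernel_always_thermodynamic(self):
        # eq23: single reaction, trivial right kernel
        assert is_thermodynamic(S_of("eq23"), [17])

    def test_matches_recoverability(self):
        S = S_of("example15")
        for g in ([1, -1, -1, -1], [1, -1, 0, -1], [2, -2, 1, -1]):
            assert is_thermodynamic(S, g) == (
                recover_molecular_energies(S, g) is not None
            )


class TestReversePairCheck:
    def test_antisymmetric_ok(self):
        net = builtin_fixture("example10").network
        assert reverse_pair_energy_check(net, [1, -1, -3, -2]) == []

    def test_violation_listed(self):
        net = builtin_fixture("example10").network
        violations = reverse_pair_energy_check(net, [1, -2, -3, -2])
        assert len(violations) == 1
        assert violations[0][:2] == ("r1", "r1_rev")

    def test_thermodynamic_implies_no_violation(self):
        net = builtin_fixture("example15").network
        S = net.stoichiometric_matrix()
        g = hess_reaction_energies(S, [3, 1, -4])
        assert is_thermodynamic(S, g)
        assert reverse_pair_energy_check(net, g) == []


class TestFutileCycles:
    def test_example10_one_cycle(self):
        cycles = enumerate_futile_cycles(S_of("example10"))
        assert [c.values for c in cycles] == [[1, 1, 0, 0]]

    def test_example15_two_cycles(self):
        cycles = enumerate_futile_cycles(S_of("example15"))
        assert sorted(c.values for c in cycles) == [[1, 0, 1, 1], [1, 1, 0, 0]]

    def test_fig2_contains_nontrivial(self):
        net = builtin_fixture("fig2_substrate_cycle").network
        cycles = enumerate_futile_cycles(net.stoichiometric_matrix(), net=net)
        values = [c.values for c in cycles]
        assert [1, 0, 1, 1, 0, 1] in values
        nontrivial = [c for c in cycles if not c.trivial]
        assert [c.values for c in nontrivial] == [[1, 0, 1, 1, 0, 1]]

    def test_coprime_and_exact(self):
        from math import gcd

        for name in ("example10", "example15", "eq9", "fig2_substrate_cycle"):
            S = S_of(name)
            for c in enumerate_futile_cycles(S):
                assert all(x == 0 for x in S.multiply(c.values))
                g = 0
                for x in c.values:
                    g = gcd(g, x)
                assert g == 1

    @pytest.mark.parametrize(
        "name", ["example10", "example15", "eq9", "fig2_substrate_cycle", "eq16"]
    )
    def test_agrees_with_bruteforce(self, name):
        S = S_of(name)
        oracle = brute_futile_cycles(S.entries, max_coeff=3)
        got = sorted(tuple(c.values) for c in enumerate_futile_cycles(S))
        assert got == [tuple(v) for v in oracle]


class TestPerpetuumMobile:
    def test_eq9_all_exergonic(self):
        v = find_perpetuum_mobile(S_of("eq9"), [-1, -1, -1, -1])
        assert v is not None
        assert list(v.values) == [1, 1, 1, 1]

    def test_example10_none(self):
        assert find_perpetuum_mobile(S_of("example10"), [1, -1, -3, -1]) is None

    def test_thermodynamic_has_none(self):
        S = S_of("fig2_substrate_cycle")
        g = hess_reaction_energies(S, [1, 2, 3, 4, 5, 6])
        assert find_perpetuum_mobile(S, g) is None


class TestLaxSoundness:
    def test_eq9_unsound_with_certificate(self):
        rep = is_thermodynamically_sound(S_of("eq9"))
        assert not rep.sound
        assert rep.certificate.values == [1, 1, 1, 1]

    def test_fully_reversible_sound(self):
        net, _ = reversible_completion(builtin_fixture("eq9").network)
        S = net.stoichiometric_matrix()
        rep = is_thermodynamically_sound(S, irr=[])
        assert rep.sound

    def test_fig2_sound(self):
        rep = is_thermodynamically_sound(S_of("fig2_substrate_cycle"), ["r3", "r6"])
        assert rep.sound
        # witness satisfies the definition
        assert rep.witness_g[2] < 0 and rep.witness_g[5] < 0

    def test_witness_is_hess_image(self):
        S = S_of("fig2_substrate_cycle")
        rep = is_thermodynamically_sound(S, ["r3", "r6"])
        assert hess_reaction_energies(S, rep.witness_G) == rep.witness_g

    def test_witness_antisymmetric_on_pairs(self):
        net = builtin_fixture("fig2_substrate_cycle").network
        rep = is_thermodynamically_sound(net.stoichiometric_matrix(), ["r3", "r6"])
        assert reverse_pair_energy_check(net, rep.witness_g) == []


class TestStrictSoundness:
    def test_fig2_not_strict(self):
        net = builtin_fixture("fig2_substrate_cycle").network
        rep = is_strictly_sound(
            net.stoichiometric_matrix(),
            rev=["r1", "r2", "r4", "r5"], irr=["r3", "r6"], net=net,
        )
        assert not rep.sound
        assert rep.certificate.values == [1, 0, 1, 1, 0, 1]

    def test_example15_not_strict(self):
        rep = is_strictly_sound(
            S_of("example15"), rev=["r1", "r1_rev"], irr=["r2", "r3"]
        )
        assert not rep.sound
        assert rep.certificate.values == [1, 0, 1, 1]

    def test_reversible_pair_only(self):
        net = ReactionNetwork(
            ["A", "B"],
            [
                Reaction("f", {"A": 1}, {"B": 1}, reversible=True),
                Reaction("b", {"B": 1}, {"A": 1}, reversible=True),
            ],
        )
        for gamma in (2, 10, 1000):
            rep = is_strictly_sound(
                net.stoichiometric_matrix(), rev=["f", "b"], irr=[], gamma=gamma
            )
            assert rep.sound

    def test_strict_witness_bounds(self):
        S = S_of("eq23")
        rep = is_strictly_sound(S, rev=[], irr=["r1"], gamma=1000)
        assert rep.sound
        assert rep.witness_g[0] <= -1000

    def test_flag_reversible_parallel_reactions(self):
        # A -> B irreversible parallel to A <-> B (flag only, no explicit
        # reverse column): a reversible-completion cycle exists
        net = ReactionNetwork(
            ["A", "B"],
            [
                Reaction("f", {"A": 1}, {"B": 1}, reversible=True),
                Reaction("g", {"A": 1}, {"B": 1}, reversible=False),
            ],
        )
        S = net.stoichiometric_matrix()
        rep = is_strictly_sound(S, rev=["f"], irr=["g"])
        assert not rep.sound
        assert rep.certificate.signed
        lax = is_thermodynamically_sound(S, ["g"])
        assert lax.sound

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError):
            is_strictly_sound(S_of("eq23"), rev=[], irr=["r1"], gamma=1)


class TestReversibleCompletion:
    def test_single_reaction(self):
        net = ReactionNetwork(["A", "B"], [Reaction("r", {"A": 1}, {"B": 1})])
        completed, g = reversible_completion(net, [-1])
        assert [r.id for r in completed.reactions] == ["r", "r_rev"]
        assert g == [Fraction(-1), Fraction(1)]
        assert is_thermodynamic(completed.stoichiometric_matrix(), g)

    def test_reversible_input_unchanged_structure(self):
        net = builtin_fixture("fig2_substrate_cycle").network
        completed, _ = reversible_completion(net)
        # r1/r2 and r4/r5 pairs exist; only r3, r6 gain reverses
        assert len(completed.reactions) == 8

    def test_eq26_completion_thermodynamic(self, eq26_S):
        net = builtin_fixture("eq26").network
        g = hess_reaction_energies(eq26_S, [1, 2, 3, 4, 5, 6])
        completed, g2 = reversible_completion(net, g)
        assert is_thermodynamic(completed.stoichiometric_matrix(), g2)

    def test_not_thermodynamic_rejected(self):
        net = builtin_fixture("example10").network
        with pytest.raises(ValueError, match="not thermodynamic"):
            reversible_completion(net, [1, -1, -3, -1])


class TestNonnegEquivalentFlow:
    def test_pair_rerouting(self):
        net = ReactionNetwork(
            ["A", "B"],
            [
                Reaction("f", {"A": 1}, {"B": 1}, reversible=True),
                Reaction("b", {"B": 1}, {"A": 1}, reversible=True),
            ],
        )
        flow = nonneg_equivalent_flow(net, [1, -1])
        assert list(flow.values) == [2, 0]
        S = net.stoichiometric_matrix()
        assert S.multiply(flow.values) == [-2, 2]

    def test_nonnegative_unchanged(self):
        net, _ = reversible_completion(builtin_fixture("eq9").network)
        v = [1, 0, 2, 0, 0, 0, 0, 0]
        assert list(nonneg_equivalent_flow(net, v).values) == v

    def test_energy_preserved(self):
        net = builtin_fixture("example15").network
        S = net.stoichiometric_matrix()
        g = hess_reaction_energies(S, [5, 3, 2])
        flow = nonneg_equivalent_flow(net, [2, -1, 0, 0], g=g)
        assert flow.nonnegative

    def test_missing_reverse_rejected(self):
        net = builtin_fixture("eq9").network
        with pytest.raises(ValueError, match="without a reverse"):
            nonneg_equivalent_flow(net, [-1, 0, 0, 0])


class TestHeredity:
    def test_deleting_reactions_preserves_soundness(self):
        net = builtin_fixture("fig2_substrate_cycle").network
        S = net.stoichiometric_matrix()
        irr = ["r3", "r6"]
        assert is_thermodynamically_sound(S, irr).sound
        for drop in [r.id for r in net.reactions]:
            keep = [r.id for r in net.reactions if r.id != drop]
            sub = S.submatrix(keep)
            rep = is_thermodynamically_sound(sub, [r for r in irr if r != drop])
            assert rep.sound, f"dropping {drop} broke soundness"
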