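import itertools

import pytest

from chemlike.conservation import NotConservativeError
from chemlike.fixtures import builtin_fixture
from chemlike.network import StoichiometricMatrix
from chemlike.realization import (
    SumFormulaMatrix,
    are_isomorphic,
    cycle_structural_formula,
    default_sf_realization,
    inequivalent_sf_realizations,
    injective_lewis_realization,
    lewis_realization,
    sum_formula_string,
    validate_lewis_realization,
    validate_sf_instance,
    validate_sf_realization,
)


def S_of(name):
    return builtin_fixture(name).network.stoichiometric_matrix()


EQ24 = [[2, 0, 1], [0, 2, 1], [1, 1, 1]]


class TestSfInstance:
    def test_eq24_valid(self):
        ok, diag = validate_sf_instance(S_of("eq23"), EQ24)
        assert ok, diag

    def test_single_positive_row(self):
        ok, _ = validate_sf_instance(S_of("eq23"), [[1, 1, 1]])
        assert ok

    def test_zero_column_invalid(self):
        ok, diag = validate_sf_instance(S_of("eq23"), [[1, 1, 0]])
        assert not ok
        assert any("zero column" in d for d in diag)

    def test_unbalanced_row_named(self):
        ok, diag = validate_sf_instance(S_of("eq23"), [[1, 1, 2]])
        assert not ok
        assert any("r1" in d for d in diag)


class TestSfRealization:
    def test_eq24_is_realization(self):
        assert validate_sf_realization(S_of("eq23"), EQ24)

    def test_reduced_representation_not_realization(self):
        # assuming U=V=W=D on the basic system: instance but not realization
        S = S_of("eq26")
        A_reduced = [[1, 1, 1, 2, 2, 3]]
        ok, _ = validate_sf_instance(S, A_reduced)
        assert ok
        assert not validate_sf_realization(S, A_reduced)

    def test_mm_representation_always_realization(self):
        for name in ("eq18", "eq19", "eq23", "eq26", "eq27"):
            S = S_of(name)
            A = default_sf_realization(S)
            assert validate_sf_realization(S, A), name


class TestDefaultRealization:
    def test_eq23_matches_eq24(self):
        A = default_sf_realization(S_of("eq23"))
        assert sorted(A.matrix) == sorted(EQ24)

    def test_eq27_monomer_formulas(self):
        A = default_sf_realization(S_of("eq27"))
        formulas = [sum_formula_string(A, x) for x in A.species]
        assert formulas == ["X", "X", "X", "X2", "X2", "X3"]

    def test_eq16_not_conservative(self):
        with pytest.raises(NotConservativeError):
            default_sf_realization(S_of("eq16"))


class TestSumFormulaString:
    def test_suffix_omitted_for_one(self):
        A = SumFormulaMatrix([[2], [0], [1]], ["X", "Y", "Z"], ["c"])
        assert sum_formula_string(A, "c") == "X2Z"

    def test_all_ones(self):
        A = SumFormulaMatrix([[1], [1], [1]], ["X", "Y", "Z"], ["c"])
        assert sum_formula_string(A, "c") == "XYZ"

    def test_zero_column_error(self):
        A = SumFormulaMatrix([[0]], ["X"], ["c"])
        with pytest.raises(ValueError):
            sum_formula_string(A, "c")


class TestInequivalent:
    def test_eq23_three_pairwise_inequivalent(self):
        reals = inequivalent_sf_realizations(S_of("eq23"), 3)
        assert len(reals) == 3
        for A, B in itertools.combinations(reals, 2):
            flat_a = [x for row in A.matrix for x in row]
            flat_b = [x for row in B.matrix for x in row]
            # no p, q with p A = q B
            ratios = {
                (a, b) for a, b in zip(flat_a, flat_b) if a or b
            }
            assert len({a * 1000000 // b for a, b in ratios if b}) > 1 or any(
                (a == 0) != (b == 0) for a, b in ratios
            )

    def test_unique_mcl_rejected(self):
        with pytest.raises(ValueError, match="equivalent"):
            inequivalent_sf_realizations(S_of("eq27"), 2)

    def test_count_one(self):
        reals = inequivalent_sf_realizations(S_of("eq23"), 1)
        assert len(reals) == 1


class TestCycleStructuralFormula:
    def test_single_moiety_loop(self):
        g = cycle_structural_formula({"a": 1})
        assert g.n_vertices == 1
        assert g.degree(0) == 2
        assert g.is_connected()

    def test_x2z_triangle(self):
        g = cycle_structural_formula({"X": 2, "Z": 1})
        assert g.n_vertices == 3
        assert g.edge_list() == [(0, 1), (0, 2), (1, 2)]
        assert sorted(g.color(u) for u in range(3)) == ["X", "X", "Z"]

    def test_val4_adds_loops(self):
        g = cycle_structural_formula({"X": 2, "Z": 1}, k=2)
        assert all(g.degree(u) == 4 for u in range(3))
        assert g.is_connected()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cycle_structural_formula({})

    def test_connected_all_degrees_exhaustive(self):
        # all formulas with up to 8 atoms over a two-letter alphabet
        for na in range(0, 9):
            for nb in range(0, 9 - na):
                if na + nb == 0:
                    continue
                formula = {}
                if na:
                    formula["a"] = na
                if nb:
                    formula["b"] = nb
                for k in (1, 2):
                    g = cycle_structural_formula(formula, k=k)
                    assert g.is_connected()
                    assert all(
                        g.degree(u) == 2 * k for u in g.graph.nodes
                    )


class TestIsomorphism:
    def test_same_cycles(self):
        g1 = cycle_structural_formula({"X": 2, "Z": 1})
        g2 = cycle_structural_formula({"X": 2, "Z": 1})
        assert are_isomorphic(g1, g2)

    def test_loop_rewiring_distinguished(self):
        base = cycle_structural_formula({"a": 4}, k=2)
        variant = base.copy()
        variant.graph.remove_edge(0, 0)
        variant.graph.remove_edge(1, 1)
        variant.add_edge(0, 1, count=2)
        assert not are_isomorphic(base, variant)

    def test_relabelled_graph_isomorphic(self):
        g1 = cycle_structural_formula({"a": 3, "b": 1}, k=2)
        g2 = cycle_structural_formula({"b": 1, "a": 3}, k=2)
        assert are_isomorphic(g1, g2)

    def test_valency_mismatch_rejected(self):
        g1 = cycle_structural_formula({"a": 2})
        g2 = cycle_structural_formula({"a": 2}, k=2)
        with pytest.raises(ValueError):
            are_isomorphic(g1, g2)


class TestLewisRealization:
    def test_eq23_passes_validation(self):
        S = S_of("eq23")
        L = lewis_realization(S)
        report = validate_lewis_realization(S, L)
        assert report["valid"], report["problems"]

    def test_eq16_rejected(self):
        with pytest.raises(NotConservativeError):
            lewis_realization(S_of("eq16"))

    def test_single_isomerization_two_loops(self):
        S = StoichiometricMatrix([[-1], [1]], ["A", "B"], ["r1"])
        L = lewis_realization(S)
        for x in ("A", "B"):
            assert L.graphs[x].n_vertices == 1

    def test_edge_conservation_per_reaction(self):
        for name in ("eq18", "eq23", "eq26", "eq27"):
            S = S_of(name)
            report = validate_lewis_realization(S, lewis_realization(S))
            assert report["edge_balance"] == [0] * S.shape[1], name

    def test_degree_mismatch_detected(self):
        S = S_of("eq23")
        L = lewis_realization(S)
        L.graphs["A"].add_edge(0, 0)  # corrupt one graph
        report = validate_lewis_realization(S, L)
        assert not report["valid"]
        assert any("degree" in p for p in report["problems"])


class TestInjectiveLewis:
    def test_eq27_six_pairwise_nonisomorphic(self):
        S = S_of("eq27")
        L = injective_lewis_realization(S)
        species = list(L.graphs)
        assert len(species) == 6
        for x, y in itertools.combinations(species, 2):
            assert not are_isomorphic(L.graphs[x], L.graphs[y]), (x, y)

    def test_eq27_isomers_share_color_counts(self):
        L = injective_lewis_realization(S_of("eq27"))
        assert L.graphs["U"].color_counts() == L.graphs["V"].color_counts()
        assert L.graphs["U"].color_counts() == L.graphs["W"].color_counts()
        assert L.graphs["X"].color_counts() == L.graphs["Y"].color_counts()

    def test_degrees_all_four(self):
        L = injective_lewis_realization(S_of("eq27"))
        for g in L.graphs.values():
            assert all(g.degree(u) == 4 for u in g.graph.nodes)
            assert g.is_connected()

    def test_no_isomers_base_cycles_suffice(self):
        S = S_of("eq26")
        L = injective_lewis_realization(S)
        report = validate_lewis_realization(S, L)
        assert report["valid"]

    def test_edge_conservation(self):
        for name in ("eq23", "eq26", "eq27"):
            S = S_of(name)
            report = validate_lewis_realization(S, injective_lewis_realization(S))
            assert report["edge_balance"] == [0] * S.shape[1], name


class TestIsomerColumnsInRealizations:
    def test_realization_columns_equal_iff_isomers(self):
        from chemlike.conservation import obligatory_isomer_classes

        for name in ("eq26", "eq27"):
            S = S_of(name)
            A = default_sf_realization(S)
            part = obligatory_isomer_classes(S)
            for x in S.row_labels:
                for y in S.row_labels:
                    if x >= y:
                        continue
                    same = A.column(x) == A.column(y)
                    assert same == part.are_isomers(x, y), (name, x, y)
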