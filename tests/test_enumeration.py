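import itertools

import pytest

import parsimech as pm
from oracles import brute_force_enumerate, row_admissible


class TestCandidateRows:
    def test_two_species_has_eight_rows(self, default_config):
        # frozen from exhaustive filtering of all 5**2 vectors: each row pairs
        # one of {-1,-2} in one slot with one of {+1,+2} in the other
        rows = pm.candidate_rows(2, default_config)
        assert len(rows) == 8
        assert set(rows) == {
            (-2, 1), (-2, 2), (-1, 1), (-1, 2), (1, -2), (1, -1), (2, -2), (2, -1),
        }

    def test_single_species_cannot_hold_reactant_and_product(self, default_config):
        assert pm.candidate_rows(1, default_config) == []

    def test_three_species_count_matches_bruteforce(self, default_config):
        rows = pm.candidate_rows(3, default_config)
        oracle = [
            v
            for v in itertools.product(range(-2, 3), repeat=3)
            if row_admissible(v)
        ]
        assert len(rows) == 36
        assert rows == sorted(oracle)

    def test_lexicographic_order(self, default_config):
        rows = pm.candidate_rows(4, default_config)
        assert rows == sorted(rows)

    def test_invalid_species_count_raises(self, default_config):
        with pytest.raises(ValueError):
            pm.candidate_rows(0, default_config)

    def test_raised_molecularity_limits_admit_more_rows(self):
        loose = pm.EnumerationConfig(
            max_reactant_molecules=3, max_product_molecules=3, entry_min=-3, entry_max=3
        )
        assert len(pm.candidate_rows(2, loose)) > 8


class TestSearchSpaceSize:
    @pytest.mark.parametrize(
        "steps,species,expected",
        [(2, 3, 15_625), (4, 5, 95_367_431_640_625), (1, 1, 5), (3, 4, 244_140_625)],
    )
    def test_exact_power(self, default_config, steps, species, expected):
        assert pm.search_space_size(steps, species, default_config) == expected

    def test_no_float_overflow_for_large_instances(self, default_config):
        assert pm.search_space_size(6, 7, default_config) == 5**42

    def test_invalid_arguments_raise(self, default_config):
        with pytest.raises(ValueError):
            pm.search_space_size(0, 3, default_config)


class TestIsFeasible:
    def test_two_step_disproportionation_is_feasible(self):
        stoich = pm.StoichiometrySpec(("A", "B", "C"), (-4, 1, 1))
        ok, tag = pm.is_feasible(
            pm.MechanismMatrix([[-2, 1, 0], [-2, 0, 1]]),
            stoich,
            pm.EnumerationConfig(n_steps=2),
        )
        assert ok and tag is None

    def test_row_without_product_reports_rule(self):
        stoich = pm.StoichiometrySpec(("A", "B", "C"), (-4, 1, 1))
        ok, tag = pm.is_feasible(
            pm.MechanismMatrix([[-2, 1, 1], [-2, 0, 0]]),
            stoich,
            pm.EnumerationConfig(n_steps=2),
        )
        assert not ok and tag == "row-needs-product"

    def test_intermediate_consumed_before_production_reports_rule(self):
        stoich = pm.StoichiometrySpec(("A", "B", "C"), (-2, 1, 1), n_intermediates=1)
        ok, tag = pm.is_feasible(
            pm.MechanismMatrix([[-1, 1, 0, -1], [-1, 0, 1, 1]]),
            stoich,
            pm.EnumerationConfig(n_steps=2),
        )
        assert not ok and tag == "intermediate-availability"

    def test_overall_product_consumption_reports_rule(self):
        stoich = pm.StoichiometrySpec(("A", "B"), (-1, 1), n_intermediates=1)
        ok, tag = pm.is_feasible(
            pm.MechanismMatrix([[-2, 2, 0], [1, -1, 0]]),
            stoich,
            pm.EnumerationConfig(n_steps=2),
        )
        assert not ok and tag == "product-consumed"

    def test_dimension_mismatch_raises(self):
        stoich = pm.StoichiometrySpec(("A", "B"), (-1, 1))
        with pytest.raises(ValueError):
            pm.is_feasible(
                pm.MechanismMatrix([[-1, 1, 0]]), stoich, pm.EnumerationConfig(n_steps=1)
            )


class TestEnumerateFeasible:
    def test_two_step_instance_yields_both_orderings(self):
        stoich = pm.StoichiometrySpec(("A", "B", "C"), (-4, 1, 1))
        result = pm.enumerate_feasible(stoich, pm.EnumerationConfig(n_steps=2))
        assert result.complete
        assert {m.entries for m in result} == {
            ((-2, 1, 0), (-2, 0, 1)),
            ((-2, 0, 1), (-2, 1, 0)),
        }

    @pytest.mark.parametrize(
        "names,coeffs,n_inter,n_steps,expected",
        [
            (("A", "B", "C"), (-4, 1, 1), 0, 2, 2),
            (("A", "B", "C"), (-4, 1, 1), 1, 3, 31),
            (("A", "B", "C"), (-1, 3, 1), 2, 3, 10),
        ],
    )
    def test_case_study_ladder_counts(self, names, coeffs, n_inter, n_steps, expected):
        stoich = pm.StoichiometrySpec(names, coeffs, n_inter)
        result = pm.enumerate_feasible(stoich, pm.EnumerationConfig(n_steps=n_steps))
        assert len(result) == expected

    def test_every_emitted_matrix_is_feasible(self):
        config = pm.EnumerationConfig(n_steps=3)
        for names, coeffs, n_inter in [
            (("A", "B", "C"), (-4, 1, 1), 1),
            (("A", "B", "C"), (-1, 3, 1), 2),
            (("A", "B", "C", "D"), (-1, -1, 1, 1), 2),
        ]:
            stoich = pm.StoichiometrySpec(names, coeffs, n_inter)
            result = pm.enumerate_feasible(stoich, config)
            assert len(result) > 0
            for m in result:
                ok, tag = pm.is_feasible(m, stoich, config)
                assert ok, tag

    @pytest.mark.parametrize("workers", [1, 2, 4])
    def test_worker_invariance(self, workers):
        stoich = pm.StoichiometrySpec(("A", "B", "C"), (-4, 1, 1), 1)
        result = pm.enumerate_feasible(
            stoich, pm.EnumerationConfig(n_steps=3, n_workers=workers)
        )
        assert [m.entries for m in result] == sorted(m.entries for m in result)
        assert len(result) == 31

    def test_matches_bruteforce_on_small_instances(self):
        # every instance here has at most 5**8 unconstrained matrices
        instances = [
            ((-4, 1, 1), 3, 2),
            ((-1, -1, 1, 1), 4, 1),
            ((-1, -1, 1, 1), 4, 2),
            ((-1, 1), 2, 2),
            ((-2, 1, 0), None, 2),  # (-2, 1) plus one intermediate
        ]
        for coeffs, n_obs, n_steps in instances:
            if n_obs is None:
                names = ("A", "B")
                stoich = pm.StoichiometrySpec(names, (-2, 1), n_intermediates=1)
                targets, n_observed = (-2, 1, 0), 2
            else:
                names = tuple("ABCD"[: n_obs])
                stoich = pm.StoichiometrySpec(names, coeffs)
                targets, n_observed = coeffs, n_obs
            got = {
                m.entries
                for m in pm.enumerate_feasible(
                    stoich, pm.EnumerationConfig(n_steps=n_steps)
                )
            }
            expected = brute_force_enumerate(targets, n_observed, n_steps)
            assert got == expected

    def test_infeasible_settings_return_empty_set(self):
        # one bimolecular step cannot consume four molecules of A
        stoich = pm.StoichiometrySpec(("A", "B", "C"), (-4, 1, 1))
        result = pm.enumerate_feasible(stoich, pm.EnumerationConfig(n_steps=1))
        assert len(result) == 0 and result.complete

    def test_time_budget_expiry_returns_partial_set_with_flag(self):
        stoich = pm.StoichiometrySpec(("A", "B", "C"), (-1, 3, 1), 3)
        result = pm.enumerate_feasible(
            stoich, pm.EnumerationConfig(n_steps=5, time_budget=0.05)
        )
        assert not result.complete

    def test_serialization_roundtrip(self):
        m = pm.MechanismMatrix([[-2, 1, 0], [-2, 0, 1]])
        assert pm.MechanismMatrix.from_dict(m.to_dict()) == m
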