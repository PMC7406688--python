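"""Mass-action terms, k-cone enumeration, and differential activity."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kcone.cone import (
    annotate_with_expression,
    differential_activity,
    enumerate_rays_bruteforce,
    kcone_basis,
    kcone_residual,
    mass_action_terms,
    transform_cone,
)
from kcone.network import parse_reaction_file, stoichiometric_matrix
from kcone.stats import ConcentrationTable
from kcone.synth import generate_experiment, toy_network

from conftest import random_concentrations, random_network

CHAIN = "R1: X_ext -> A\nR2: A -> B\nR3: B -> Y_ext\n"


def conc_table(condition, mapping, n=1):
    df = pd.DataFrame({f"rep{i+1}": pd.Series(mapping, dtype=float) for i in range(n)})
    return ConcentrationTable(condition, df)


class TestMassActionTerms:
    def test_product_of_substrates(self):
        net = parse_reaction_file("R1: A + B -> C")
        m = mass_action_terms(net, {"A": 2, "B": 3, "C": 1})
        assert m.M == (Fraction(6),)

    def test_stoichiometric_exponent(self):
        net = parse_reaction_file("R1: 2 A -> C")
        m = mass_action_terms(net, {"A": 3, "C": 1})
        assert m.M == (Fraction(9),)

    def test_boundary_only_substrates_give_unit_term(self):
        net = parse_reaction_file("R1: X_ext -> A")
        m = mass_action_terms(net, {"A": 5})
        assert m.M == (Fraction(1),)

    def test_literal_convention_uses_signed_exponents(self):
        net = parse_reaction_file("R1: A -> C")
        m = mass_action_terms(net, {"A": 2, "C": 4}, convention="literal")
        assert m.M == (Fraction(4, 2),)  # x_C^{+1} * x_A^{-1}

    def test_non_positive_concentration_rejected(self):
        net = parse_reaction_file("R1: A -> B")
        with pytest.raises(ValueError, match="positive"):
            mass_action_terms(net, {"A": 0.0, "B": 1.0})

    def test_strict_policy_rejects_missing_metabolite(self):
        net = parse_reaction_file("R1: A -> B")
        with pytest.raises(ValueError, match="no concentration"):
            mass_action_terms(net, {"A": 1.0})
        m = mass_action_terms(net, {"A": 1.0}, unmeasured="one")
        assert m.M == (Fraction(1),)


class TestKConeBasis:
    def test_chain_single_ray(self):
        net = parse_reaction_file(CHAIN)
        S = stoichiometric_matrix(net)
        M = mass_action_terms(net, {"A": 2, "B": 4})
        basis = kcone_basis(S, M)
        assert basis.rays == ((Fraction(1), Fraction(1, 2), Fraction(1, 4)),)

    def test_unit_concentrations_reduce_to_flux_cone(self):
        net = parse_reaction_file(CHAIN)
        S = stoichiometric_matrix(net)
        M1 = mass_action_terms(net, {"A": 1, "B": 1})
        basis = kcone_basis(S, M1)
        assert basis.rays == ((Fraction(1), Fraction(1), Fraction(1)),)

    def test_rays_satisfy_residual_exactly(self):
        net = parse_reaction_file("R1: X_ext -> A\nR2: A -> B\nR3: A -> C\nR4: B -> Y_ext\nR5: C -> Z_ext")
        S = stoichiometric_matrix(net)
        M = mass_action_terms(net, {"A": Fraction(3, 7), "B": Fraction(5, 2), "C": 11})
        basis = kcone_basis(S, M)
        assert basis.n_rays == 2  # branchpoint: two elementary routes
        for ray in basis.rays:
            assert kcone_residual(S, M, ray) == 0

    def test_trivial_cone_yields_empty_basis(self):
        # A is produced but never consumed: no nonzero nonnegative solution
        net = parse_reaction_file("R1: X_ext -> A\nR2: B -> A")
        S = stoichiometric_matrix(net)
        M = mass_action_terms(net, {"A": 1, "B": 1})
        basis = kcone_basis(S, M)
        assert basis.n_rays == 0
        assert basis.to_float().shape == (2, 0)

    def test_dimension_mismatch_rejected(self):
        net = parse_reaction_file(CHAIN)
        other = parse_reaction_file("R9: A -> B")
        S = stoichiometric_matrix(net)
        M = mass_action_terms(other, {"A": 1, "B": 1})
        with pytest.raises(ValueError, match="columns"):
            kcone_basis(S, M)


class TestResidual:
    def test_zero_vector_has_zero_residual(self, chain_network, chain_S):
        M = mass_action_terms(chain_network, {"A": 2, "B": 4})
        assert kcone_residual(chain_S, M, [Fraction(0)] * 3) == 0

    def test_chain_ray_residual_zero(self, chain_network, chain_S):
        M = mass_action_terms(chain_network, {"A": 2, "B": 4})
        assert kcone_residual(chain_S, M, [Fraction(1), Fraction(1, 2), Fraction(1, 4)]) == 0

    def test_perturbed_ray_has_positive_residual(self, chain_network, chain_S):
        M = mass_action_terms(chain_network, {"A": 2, "B": 4})
        assert kcone_residual(chain_S, M, [Fraction(1), Fraction(1, 2) + Fraction(1, 100), Fraction(1, 4)]) > 0

    def test_dimension_mismatch_rejected(self, chain_network, chain_S):
        M = mass_action_terms(chain_network, {"A": 2, "B": 4})
        with pytest.raises(ValueError, match="length"):
            kcone_residual(chain_S, M, [Fraction(1)])


class TestTransformCone:
    def _chain_setup(self):
        net = parse_reaction_file(CHAIN)
        S = stoichiometric_matrix(net)
        Ma = mass_action_terms(net, {"A": 2, "B": 4})
        Mb = mass_action_terms(net, {"A": 1, "B": 1})
        return net, S, Ma, Mb

    def test_identity_when_terms_equal(self):
        _, S, Ma, _ = self._chain_setup()
        basis = kcone_basis(S, Ma)
        assert transform_cone(basis, Ma, Ma).rays == basis.rays

    def test_chain_example_maps_to_unit_ray(self):
        _, S, Ma, Mb = self._chain_setup()
        basis = kcone_basis(S, Ma)
        moved = transform_cone(basis, Ma, Mb)
        assert moved.rays == ((Fraction(1), Fraction(1), Fraction(1)),)
        for ray in moved.rays:
            assert kcone_residual(S, Mb, ray) == 0

    def test_involution_up_to_normalization(self):
        _, S, Ma, Mb = self._chain_setup()
        basis = kcone_basis(S, Ma)
        back = transform_cone(transform_cone(basis, Ma, Mb), Mb, Ma)
        assert back.rays == basis.rays

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_correspondence_with_from_scratch_cone(self, seed):
        """Condition-B cone from scratch equals the transformed A cone."""
        rng = np.random.default_rng(seed)
        net = random_network(rng, max_mets=5, max_steps=6)
        S = stoichiometric_matrix(net)
        Ma = mass_action_terms(net, random_concentrations(rng, net))
        Mb = mass_action_terms(net, random_concentrations(rng, net))
        scratch = kcone_basis(S, Mb)
        moved = transform_cone(kcone_basis(S, Ma), Ma, Mb)
        assert scratch.rays == moved.rays


class TestBruteForceOracle:
    def test_flux_invariant_vector_is_in_cone_for_any_positive_M(self):
        # v in null(S) => k = v / M has exactly zero residual
        net = parse_reaction_file(CHAIN)
        S = stoichiometric_matrix(net)
        v = [Fraction(3), Fraction(3), Fraction(3)]  # null space of the chain
        for conc in ({"A": Fraction(2), "B": Fraction(4)}, {"A": Fraction(7, 3), "B": Fraction(1, 5)}):
            M = mass_action_terms(net, conc)
            k = [vi / mi for vi, mi in zip(v, M.M)]
            assert kcone_residual(S, M, k) == 0

    def test_oracle_size_guard(self, chain_network, chain_S):
        M = mass_action_terms(chain_network, {"A": 1, "B": 1})
        with pytest.raises(ValueError, match="small"):
            enumerate_rays_bruteforce(chain_S, M, max_steps=2)


class TestDifferentialActivity:
    def test_identical_tables_all_unchanged(self, chain_network):
        t = conc_table("a", {"A": 0.5, "B": 0.25}, n=3)
        recs = differential_activity(chain_network, t, t)
        assert all(r.mean_log2_fc == 0 for r in recs)
        assert all(r.direction == "unchanged" for r in recs)

    def test_halved_downstream_metabolite_doubles_efflux_activity(self, chain_network):
        ta = conc_table("a", {"A": 0.5, "B": 0.25}, n=2)
        tb = conc_table("b", {"A": 0.5, "B": 0.125}, n=2)
        recs = {r.step_id: r for r in differential_activity(chain_network, ta, tb)}
        assert recs["R3"].mean_log2_fc == pytest.approx(1.0)
        assert recs["R2"].mean_log2_fc == pytest.approx(0.0)
        assert recs["R1"].constant_term and recs["R1"].mean_log2_fc == 0.0

    def test_single_pair_reports_undefined_p_with_fallback_direction(self, chain_network):
        ta = conc_table("a", {"A": 0.5, "B": 0.25}, n=1)
        tb = conc_table("b", {"A": 0.5, "B": 0.05}, n=1)
        recs = {r.step_id: r for r in differential_activity(chain_network, ta, tb)}
        assert math.isnan(recs["R3"].p_value)
        assert recs["R3"].direction == "up"  # |log2 fc| > fallback threshold
        assert recs["R2"].direction == "unchanged"

    def test_common_scaling_of_both_conditions_cancels(self, chain_network):
        rng = np.random.default_rng(3)
        a = {"A": 0.5, "B": 0.25}
        b = {"A": 0.4, "B": 0.1}
        ta, tb = conc_table("a", a, n=2), conc_table("b", b, n=2)
        sa = conc_table("a", {k: 9.0 * v for k, v in a.items()}, n=2)
        sb = conc_table("b", {k: 9.0 * v for k, v in b.items()}, n=2)
        r1 = differential_activity(chain_network, ta, tb)
        r2 = differential_activity(chain_network, sa, sb)
        for x, y in zip(r1, r2):
            assert x.mean_log2_fc == pytest.approx(y.mean_log2_fc, abs=1e-9)

    def test_index_pairing_requires_equal_counts(self, chain_network):
        ta = conc_table("a", {"A": 0.5, "B": 0.25}, n=2)
        tb = conc_table("b", {"A": 0.5, "B": 0.25}, n=3)
        with pytest.raises(ValueError, match="equal replicate"):
            differential_activity(chain_network, ta, tb, pairing="index")

    def test_unmeasured_metabolite_flagged_and_neutral(self):
        net = parse_reaction_file(CHAIN)
        ta = conc_table("a", {"A": 0.5}, n=2)  # B unmeasured
        tb = conc_table("b", {"A": 0.25}, n=2)
        recs = {r.step_id: r for r in differential_activity(net, ta, tb)}
        assert recs["R3"].uses_unmeasured
        assert recs["R3"].mean_log2_fc == 0.0  # B defaults to 1 in both conditions
        assert recs["R2"].mean_log2_fc == pytest.approx(1.0)


class TestExpressionOverlay:
    def _records(self, chain_network, direction="up"):
        ta = conc_table("a", {"A": 0.5, "B": 0.25}, n=3)
        scale = 0.125 if direction == "up" else 0.5
        tb = conc_table("b", {"A": 0.5, "B": scale * 0.5}, n=3)
        return differential_activity(chain_network, ta, tb)

    def test_concordant_up_up(self):
        net = parse_reaction_file(
            "R1: X_ext -> A\nR2: A -> B\nR3: B -> Y_ext genes=GLS\n")
        recs = self._records(net)
        de = pd.DataFrame({"gene": ["GLS"], "log2_fc": [2.0], "q_value": [0.001]})
        out = {r.step_id: r for r in annotate_with_expression(recs, de)}
        assert out["R3"].direction == "up"
        assert out["R3"].concordant == "concordant"

    def test_no_gene_annotation_leaves_empty(self, chain_network):
        de = pd.DataFrame({"gene": ["GPX1"], "log2_fc": [1.0], "q_value": [0.01]})
        out = annotate_with_expression(self._records(chain_network), de)
        assert all(r.concordant == "" for r in out)

    def test_conflicting_genes_flagged_ambiguous(self):
        net = parse_reaction_file(
            "R1: X_ext -> A\nR2: A -> B\nR3: B -> Y_ext genes=GPX1,GPX2\n")
        recs = self._records(net)
        de = pd.DataFrame({"gene": ["GPX1", "GPX2"], "log2_fc": [2.0, -2.0],
                           "q_value": [0.001, 0.001]})
        out = {r.step_id: r for r in annotate_with_expression(recs, de)}
        assert out["R3"].concordant == "ambiguous"
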