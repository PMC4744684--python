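import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcmca import (
    Participant,
    Reaction,
    ReactionSaturations,
    elasticity_matrix,
    product_elasticity,
    rate_law_denominator,
    substrate_elasticity,
)
from mcmca.errors import KineticsError


def simple_reaction():
    return Reaction("r", substrates=(Participant("A"),), products=(Participant("B"),))


def gogat_like():
    """akG + Gln + NADPH -> 2 Glu + NADP (glutamate synthase)."""
    return Reaction(
        "GOGAT",
        substrates=(Participant("akG"), Participant("Gln"), Participant("NADPH")),
        products=(Participant("Glu", 2), Participant("NADP")),
    )


def gogat_saturations(alpha=1.0, pi=1.0):
    return ReactionSaturations(
        alpha={"akG": alpha, "Gln": alpha, "NADPH": alpha},
        pi={"Glu": pi, "NADP": pi},
    )


class TestDenominator:
    def test_one_to_one_reaction(self):
        sat = ReactionSaturations(alpha={"A": 1.0}, pi={"B": 1.0})
        assert rate_law_denominator(simple_reaction(), sat) == pytest.approx(3.0)

    def test_gogat_at_half_saturation(self):
        # (1+1)^3 + (1+1)^2 (1+1) - 1 = 8 + 8 - 1
        assert rate_law_denominator(gogat_like(), gogat_saturations()) == pytest.approx(15.0)

    def test_limit_of_vanishing_saturation(self):
        sat = ReactionSaturations(alpha={"A": 1e-12}, pi={"B": 1e-12})
        assert rate_law_denominator(simple_reaction(), sat) == pytest.approx(1.0)

    def test_species_on_both_sides_rejected(self):
        rxn = Reaction("bad", substrates=(Participant("A"),), products=(Participant("A"),))
        sat = ReactionSaturations(alpha={"A": 1.0}, pi={"A": 1.0})
        with pytest.raises(KineticsError, match="both sides"):
            rate_law_denominator(rxn, sat)


class TestSubstrateElasticity:
    def test_hand_evaluated_value(self):
        # n=1, alpha=pi=1, rho=0.5: 1/(1-0.5) - 1/3 = 5/3
        sat = ReactionSaturations(alpha={"A": 1.0}, pi={"B": 1.0})
        val = substrate_elasticity(simple_reaction(), "A", sat, rho=0.5)
        assert val == pytest.approx(2.0 - 1.0 / 3.0, rel=1e-12)

    def test_irreversible_first_order_limit(self):
        sat = ReactionSaturations(alpha={"A": 1e-12}, pi={"B": 1e-12})
        val = substrate_elasticity(simple_reaction(), "A", sat, rho=0.0)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_saturated_enzyme_limit(self):
        sat = ReactionSaturations(alpha={"A": 1e6}, pi={"B": 1e-12})
        val = substrate_elasticity(simple_reaction(), "A", sat, rho=0.0)
        assert abs(val) < 1e-5

    def test_divergence_near_equilibrium(self):
        sat = ReactionSaturations(alpha={"A": 1.0}, pi={"B": 1.0})
        assert substrate_elasticity(simple_reaction(), "A", sat, rho=1 - 1e-9) > 1e8

    def test_rho_at_or_above_one_rejected(self):
        sat = ReactionSaturations(alpha={"A": 1.0}, pi={"B": 1.0})
        with pytest.raises(KineticsError):
            substrate_elasticity(simple_reaction(), "A", sat, rho=1.0)


class TestProductElasticity:
    def test_hand_evaluated_value_derivative(self):
        # exact derivative: -rho/(1-rho) - pi/((1+pi) cross / D) = -1 - 1/3
        sat = ReactionSaturations(alpha={"A": 1.0}, pi={"B": 1.0})
        val = product_elasticity(simple_reaction(), "B", sat, rho=0.5)
        assert val == pytest.approx(-1.0 - 1.0 / 3.0, rel=1e-12)

    def test_hand_evaluated_value_printed_variant(self):
        sat = ReactionSaturations(alpha={"A": 1.0}, pi={"B": 1.0})
        val = product_elasticity(simple_reaction(), "B", sat, rho=0.5, mode="printed")
        assert val == pytest.approx(-1.0 + 1.0 / 3.0, rel=1e-12)

    def test_gogat_glu_hand_value(self):
        # n_Glu = 2, all saturations 1, rho = 0.5, D = 15:
        # derivative: -2*1 - 2*(1*2*2)/15 = -38/15
        val = product_elasticity(gogat_like(), "Glu", gogat_saturations(), rho=0.5)
        assert val == pytest.approx(-38.0 / 15.0, rel=1e-12)

    def test_far_from_equilibrium_low_product_limit(self):
        sat = ReactionSaturations(alpha={"A": 1.0}, pi={"B": 1e-12})
        val = product_elasticity(simple_reaction(), "B", sat, rho=0.0)
        assert abs(val) < 1e-9

    @settings(derandomize=True, max_examples=200)
    @given(
        sat=st.floats(0.01, 100),
        rho=st.floats(0.0, 0.99, exclude_max=False),
    )
    def test_product_always_inhibits(self, sat, rho):
        """In the derivative convention a product can never activate its producer."""
        s = ReactionSaturations(alpha={"A": sat}, pi={"B": sat})
        assert product_elasticity(simple_reaction(), "B", s, rho=rho) < 0


class TestGogatCrossCheck:
    def test_generic_matches_dedicated_transcription(self):
        """The generic product elasticity must agree with a reaction-specific
        hard-coded expression for glutamate synthase with respect to Glu,
        written out term by term, over 1000 random draws."""
        rxn = gogat_like()
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            a_akg, a_gln, a_nadph, p_glu, p_nadp = np.exp(rng.uniform(np.log(0.1), np.log(10), 5))
            rho = rng.uniform(0.0, 0.99)
            sat = ReactionSaturations(
                alpha={"akG": a_akg, "Gln": a_gln, "NADPH": a_nadph},
                pi={"Glu": p_glu, "NADP": p_nadp},
            )
            D = (1 + a_akg) * (1 + a_gln) * (1 + a_nadph) + (1 + p_glu) ** 2 * (1 + p_nadp) - 1
            dedicated = -2 * rho / (1 - rho) - 2 * p_glu * (1 + p_glu) * (1 + p_nadp) / D
            generic = product_elasticity(rxn, "Glu", sat, rho)
            assert generic == pytest.approx(dedicated, rel=1e-12)


class TestElasticityMatrix:
    def _sats(self, spec, value=1.0):
        return {
            r.id: ReactionSaturations(
                alpha={p.species: value for p in r.substrates},
                pi={p.species: value for p in r.products},
            )
            for r in spec.reactions
            if r.kind == "enzymatic"
        }

    def test_boundary_rows(self, proline, lp_thermo):
        eps = elasticity_matrix(proline, self._sats(proline), lp_thermo)
        j = proline.reaction_index("PROCO")
        row = eps[j]
        assert np.count_nonzero(row) == 1
        assert row[proline.metabolite_index("Pro")] == 1.0  # first-order consumption
        for rid in ("AKGPR", "GLUPR"):
            assert np.all(eps[proline.reaction_index(rid)] == 0.0)  # constant sources

    def test_gogat_row_sparsity(self, proline, lp_thermo):
        eps = elasticity_matrix(proline, self._sats(proline), lp_thermo)
        row = eps[proline.reaction_index("GOGAT")]
        nonzero = {proline.metabolites[i] for i in np.flatnonzero(row)}
        assert nonzero == {"akG", "Gln", "Glu"}

    def test_vanishing_saturation_limit(self, proline, lp_thermo):
        """At vanishing saturation, substrate entries approach their
        stoichiometric exponents scaled by the thermodynamic factor."""
        eps = elasticity_matrix(proline, self._sats(proline, 1e-12), lp_thermo)
        for rxn in proline.reactions:
            if rxn.kind == "boundary":
                continue
            rho = lp_thermo[rxn.id].rho
            for p in rxn.substrates:
                if proline.is_internal(p.species):
                    got = eps[proline.reaction_index(rxn.id), proline.metabolite_index(p.species)]
                    assert got == pytest.approx(p.n / (1 - rho), rel=1e-6)
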