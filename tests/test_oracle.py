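import numpy as np
import pytest

from mcmca import (
    ReactionSaturations,
    ReactionThermo,
    SamplingConfig,
    control_matrices,
    sample_saturations,
    sample_steady_state_flux,
)
from mcmca.kinetics import elasticity_matrix
from mcmca.errors import OracleError
from mcmca.oracle import finite_difference_control, instantiate


def chain_setup(two_step_chain):
    sats = {
        "R1": ReactionSaturations(alpha={"X": 1.5}, pi={"S": 0.8}),
        "R2": ReactionSaturations(alpha={"S": 1.2}, pi={"Y": 2.0}),
    }
    thermo = {
        "R1": ReactionThermo("R1", None, None, rho=0.3),
        "R2": ReactionThermo("R2", None, None, rho=0.2),
    }
    J = np.ones(2)
    return sats, thermo, J


def proline_draw(proline, proline_structure, lp_thermo, seed):
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cfg = SamplingConfig(seed=seed)
    sats = sample_saturations(proline, cfg, rng)
    fv = sample_steady_state_flux(
        proline, proline_structure.right_nullspace.astype(float), (0.1, 10.0), rng
    )
    return sats, fv


class TestInstantiate:
    def test_chain_nominal_state_is_steady(self, two_step_chain):
        sats, thermo, J = chain_setup(two_step_chain)
        inst = instantiate(two_step_chain, sats, thermo, J)
        np.testing.assert_allclose(inst.velocities(inst.S0), J, rtol=1e-12)
        assert np.abs(inst.rhs(inst.S0)).max() < 1e-10

    def test_proline_nominal_residuals(self, proline, proline_structure, lp_thermo):
        sats, fv = proline_draw(proline, proline_structure, lp_thermo, seed=8)
        inst = instantiate(proline, sats, lp_thermo, fv.J)
        resid = np.abs(inst.velocities(inst.S0) - fv.J).max()
        assert resid < 1e-8 * np.abs(fv.J).max()
        assert np.abs(inst.rhs(inst.S0)).max() < 1e-8 * np.abs(fv.J).max()

    def test_near_equilibrium_draw_flagged(self, two_step_chain):
        sats, thermo, J = chain_setup(two_step_chain)
        thermo["R1"] = ReactionThermo("R1", None, None, rho=0.999)
        inst = instantiate(two_step_chain, sats, thermo, J)
        assert inst.near_equilibrium == ["R1"]

    def test_invalid_rho_rejected(self, two_step_chain):
        sats, thermo, J = chain_setup(two_step_chain)
        thermo["R1"] = ReactionThermo("R1", None, None, rho=1.5)
        with pytest.raises(OracleError):
            instantiate(two_step_chain, sats, thermo, J)


class TestFiniteDifferenceControl:
    def test_chain_matches_matrix_inversion(self, two_step_chain):
        sats, thermo, J = chain_setup(two_step_chain)
        inst = instantiate(two_step_chain, sats, thermo, J)
        eps = elasticity_matrix(two_step_chain, sats, thermo)
        cm = control_matrices(two_step_chain, eps, J)
        fd = finite_difference_control(inst, delta=0.01, target="S")
        np.testing.assert_allclose(fd, cm.CS[0], rtol=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_proline_agreement_with_matrix_method(
        self, proline, proline_structure, lp_thermo, seed
    ):
        """Matrix-inversion and ODE finite-difference coefficients agree within
        1% relative on all entries of appreciable size."""
        sats, fv = proline_draw(proline, proline_structure, lp_thermo, seed)
        eps = elasticity_matrix(proline, sats, lp_thermo)
        cm = control_matrices(proline, eps, fv, structure=proline_structure)
        cs = cm.CS[proline.metabolite_index("Pro")]
        inst = instantiate(proline, sats, lp_thermo, fv.J)
        fd = finite_difference_control(inst, delta=0.01)
        mask = np.abs(cs) > 0.01
        assert not np.isnan(fd[mask]).any()
        np.testing.assert_allclose(fd[mask], cs[mask], rtol=0.01)

    def test_supply_perturbation_sign_agreement(self, proline, proline_structure, lp_thermo):
        sats, fv = proline_draw(proline, proline_structure, lp_thermo, seed=13)
        eps = elasticity_matrix(proline, sats, lp_thermo)
        cm = control_matrices(proline, eps, fv, structure=proline_structure)
        cs = cm.CS[proline.metabolite_index("Pro")]
        inst = instantiate(proline, sats, lp_thermo, fv.J)
        fd = finite_difference_control(inst, delta=0.01)
        for rid in ("AKGPR", "GLUPR"):
            j = proline.reaction_index(rid)
            assert np.sign(fd[j]) == np.sign(cs[j])

    def test_error_shrinks_with_delta(self, proline, proline_structure, lp_thermo):
        """The forward-difference estimate converges to the matrix coefficients
        as the perturbation shrinks."""
        sats, fv = proline_draw(proline, proline_structure, lp_thermo, seed=21)
        eps = elasticity_matrix(proline, sats, lp_thermo)
        cm = control_matrices(proline, eps, fv, structure=proline_structure)
        cs = cm.CS[proline.metabolite_index("Pro")]
        inst = instantiate(proline, sats, lp_thermo, fv.J)
        mask = np.abs(cs) > 0.01
        errs = []
        for delta in (0.05, 0.01, 0.002):
            fd = finite_difference_control(inst, delta=delta, scheme="forward")
            errs.append(np.max(np.abs(fd[mask] - cs[mask]) / np.abs(cs[mask])))
        assert errs[0] > errs[1] > errs[2]

    def test_steady_state_unique_from_distinct_starts(
        self, proline, proline_structure, lp_thermo
    ):
        sats, fv = proline_draw(proline, proline_structure, lp_thermo, seed=34)
        inst = instantiate(proline, sats, lp_thermo, fv.J)
        scale = np.ones(len(proline.reactions))
        scale[proline.reaction_index("P5CS")] = 1.01
        s_a = inst.steady_state(scale=scale, S_init=inst.S0)
        s_b = inst.steady_state(scale=scale, S_init=0.5 * inst.S0)
        np.testing.assert_allclose(s_a, s_b, rtol=1e-6)

    def test_invalid_delta_rejected(self, proline, proline_structure, lp_thermo):
        sats, fv = proline_draw(proline, proline_structure, lp_thermo, seed=3)
        inst = instantiate(proline, sats, lp_thermo, fv.J)
        with pytest.raises(OracleError):
            finite_difference_control(inst, delta=0.5)
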