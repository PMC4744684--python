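"""Independent validation path: explicit kinetics, ODE steady states, finite differences.

The matrix method never writes down a full kinetic model — it works directly
with saturation, disequilibrium and flux ratios.  This module closes the
loop: it *instantiates* a complete generalized-reversible-kinetics model
consistent with one Monte Carlo draw (Michaelis constants from the sampled
saturations, the effective equilibrium constant from rho, maximal rates from
the flux vector), verifies that the nominal state is a steady state, and
estimates control coefficients the definitional way — scale one enzyme's
maximal rate by a small factor, relax the ODE system to its new steady
state, and form the log-ratio response of the target metabolite.  Agreement
with the inversion-based coefficients validates both routes.

Nominal internal concentrations are set to 1 in model units: scaled control
coefficients do not depend on absolute concentrations, which is the same
cancellation the matrix method exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import OracleError
from .kinetics import BoundaryKinetics, SaturationSet
from .pathway import PathwaySpec
from .thermo import ReactionThermo

__all__ = ["KineticInstance", "instantiate", "finite_difference_control"]


@dataclass
class _EnzymaticRate:
    """v = W (prod alpha^n - prod pi^n / keq_sat) / D with alpha = S/Km."""

    substrates: list[tuple[int | None, str, int, float]]  # (state index or None, species, n, Km)
    products: list[tuple[int | None, str, int, float]]
    W: float
    keq_sat: float | None  # equilibrium constant in saturation units; None = irreversible

    def __call__(self, S: np.ndarray, ext: dict[str, float]) -> float:
        fwd = 1.0
        dsub = 1.0
        for idx, sp, n, Km in self.substrates:
            a = (S[idx] if idx is not None else ext[sp]) / Km
            fwd *= a**n
            dsub *= (1.0 + a) ** n
        rev = 1.0
        dprod = 1.0
        for idx, sp, n, Km in self.products:
            p = (S[idx] if idx is not None else ext[sp]) / Km
            rev *= p**n
            dprod *= (1.0 + p) ** n
        num = fwd if self.keq_sat is None else fwd - rev / self.keq_sat
        return self.W * num / (dsub + dprod - 1.0)


@dataclass
class _BoundaryRate:
    """Power-law boundary rate v = W * S^order (order 0 for constant supplies)."""

    index: int | None
    order: float
    W: float

    def __call__(self, S: np.ndarray, ext: dict[str, float]) -> float:
        if self.index is None or self.order == 0.0:
            return self.W
        return self.W * S[self.index] ** self.order


@dataclass
class KineticInstance:
    """A fully parameterized kinetic model consistent with one parameter draw."""

    spec: PathwaySpec
    rates: list[_EnzymaticRate | _BoundaryRate]
    J: np.ndarray
    S0: np.ndarray
    external_conc: dict[str, float]
    near_equilibrium: list[str]

    def velocities(self, S: np.ndarray, scale: np.ndarray | None = None) -> np.ndarray:
        v = np.array([rate(S, self.external_conc) for rate in self.rates])
        return v if scale is None else v * scale

    def rhs(self, S: np.ndarray, scale: np.ndarray | None = None) -> np.ndarray:
        return self.spec.N.astype(float) @ self.velocities(S, scale)

    def steady_state(
        self,
        scale: np.ndarray | None = None,
        S_init: np.ndarray | None = None,
        t_final: float = 1e5,
        residual_tol: float = 1e-8,
    ) -> np.ndarray:
        """Relax to steady state by stiff integration, then polish in log space.

        Raises :class:`OracleError` if the residual check fails (non-convergent
        or runaway dynamics).
        """
        S_init = self.S0 if S_init is None else S_init
        sol = solve_ivp(
            lambda _, S: self.rhs(np.maximum(S, 1e-12), scale),
            (0.0, t_final),
            S_init,
            method="BDF",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise OracleError(f"steady-state integration failed: {sol.message}")
        S_end = np.maximum(sol.y[:, -1], 1e-12)
        # Polish: root of N v(exp(x)) in log concentrations keeps S positive.
        res = root(lambda x: self.rhs(np.exp(x), scale), np.log(S_end), method="hybr")
        S_ss = np.exp(res.x) if res.success else S_end
        Jscale = max(np.max(np.abs(self.velocities(S_ss, scale))), 1e-300)
        if np.max(np.abs(self.rhs(S_ss, scale))) > residual_tol * Jscale:
            raise OracleError("steady-state residual check failed")
        return S_ss


def instantiate(
    spec: PathwaySpec,
    sats: SaturationSet,
    thermo: dict[str, ReactionThermo],
    J: np.ndarray,
    boundary: BoundaryKinetics = BoundaryKinetics(),
    near_equilibrium_rho: float = 0.99,
) -> KineticInstance:
    """Build a kinetic model whose nominal state realizes one parameter draw.

    At internal and external concentrations of 1 (model units) every
    reaction's saturations equal the draw's alpha/pi, its disequilibrium
    ratio equals the (adjusted) rho, and its net rate equals the drawn flux.
    Draws with rho at or beyond ``near_equilibrium_rho`` are accepted but
    flagged in ``near_equilibrium``.
    """
    J = np.asarray(J, dtype=float)
    rates: list[_EnzymaticRate | _BoundaryRate] = []
    flagged: list[str] = []
    ext = {sp: 1.0 for sp in spec.externals}
    for j, rxn in enumerate(spec.reactions):
        if rxn.kind == "boundary":
            if rxn.substrates:  # consumption of one internal metabolite
                p = rxn.substrates[0]
                idx = spec.metabolite_index(p.species) if spec.is_internal(p.species) else None
                order = boundary.consumption_elasticity
            else:  # supply
                p = rxn.products[0]
                idx = spec.metabolite_index(p.species) if spec.is_internal(p.species) else None
                order = -boundary.supply_elasticity
            rates.append(_BoundaryRate(index=idx, order=order, W=J[j]))
            continue
        sat = sats[rxn.id]
        rho = thermo[rxn.id].rho
        if not 0.0 <= rho < 1.0:
            raise OracleError(f"reaction {rxn.id!r} has rho = {rho}, cannot instantiate")
        if rho >= near_equilibrium_rho:
            flagged.append(rxn.id)
        subs = []
        fwd0 = 1.0
        D0 = 1.0
        for p in rxn.substrates:
            a0 = sat.alpha[p.species]
            idx = spec.metabolite_index(p.species) if spec.is_internal(p.species) else None
            subs.append((idx, p.species, p.n, 1.0 / a0))
            fwd0 *= a0**p.n
            D0 *= (1.0 + a0) ** p.n
        prods = []
        rev0 = 1.0
        Dp0 = 1.0
        for p in rxn.products:
            p0 = sat.pi[p.species]
            idx = spec.metabolite_index(p.species) if spec.is_internal(p.species) else None
            prods.append((idx, p.species, p.n, 1.0 / p0))
            rev0 *= p0**p.n
            Dp0 *= (1.0 + p0) ** p.n
        D0 = D0 + Dp0 - 1.0
        keq_sat = None if rho == 0.0 else rev0 / (rho * fwd0)
        if J[j] <= 0:
            raise OracleError(f"non-positive flux for reaction {rxn.id!r}")
        W = J[j] * D0 / (fwd0 * (1.0 - rho))
        rates.append(_EnzymaticRate(substrates=subs, products=prods, W=W, keq_sat=keq_sat))
    inst = KineticInstance(
        spec=spec,
        rates=rates,
        J=J,
        S0=np.ones(len(spec.metabolites)),
        external_conc=ext,
        near_equilibrium=flagged,
    )
    v0 = inst.velocities(inst.S0)
    if np.max(np.abs(v0 - J)) > 1e-8 * max(np.max(np.abs(J)), 1e-300):
        raise OracleError("nominal rates do not reproduce the drawn fluxes")
    return inst


def finite_difference_control(
    instance: KineticInstance,
    delta: float = 0.01,
    target: str = "Pro",
    scheme: str = "central",
) -> np.ndarray:
    """Control coefficients of ``target`` by enzyme perturbation, one per reaction.

    Each reaction's maximal rate is scaled by (1 + delta) (and by 1/(1 + delta)
    for the central scheme), the ODE system is relaxed to its new steady
    state, and the coefficient is the log-ratio response
    ln(S_p/S_0) / ln(E_p/E_0).  Non-convergent perturbations yield NaN.
    """
    if not 0.0 < delta <= 0.05:
        raise OracleError(f"delta must lie in (0, 0.05], got {delta}")
    if scheme not in ("central", "forward"):
        raise OracleError(f"unknown scheme {scheme!r}")
    m_idx = instance.spec.metabolite_index(target)
    S_base = instance.steady_state()
    base = np.log(S_base[m_idx])
    n_r = len(instance.spec.reactions)
    out = np.empty(n_r)
    for j in range(n_r):
        try:
            up = np.ones(n_r)
            up[j] = 1.0 + delta
            S_up = instance.steady_state(scale=up, S_init=S_base)
            if scheme == "central":
                dn = np.ones(n_r)
                dn[j] = 1.0 / (1.0 + delta)
                S_dn = instance.steady_state(scale=dn, S_init=S_base)
                out[j] = (np.log(S_up[m_idx]) - np.log(S_dn[m_idx])) / (2 * np.log(1.0 + delta))
            else:
                out[j] = (np.log(S_up[m_idx]) - base) / np.log(1.0 + delta)
        except OracleError:
            out[j] = np.nan
    return out
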