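"""Scaled elasticities of the generalized reversible (common modular) rate law.

For a reaction with substrate saturation ratios alpha_i (concentration over
Michaelis constant), product saturation ratios pi_j and disequilibrium ratio
rho, the rate law without allosteric terms is

    v = W * (prod_i alpha_i^n_i) * (1 - rho) / D,
    D = prod_i (1 + alpha_i)^n_i + prod_j (1 + pi_j)^n_j - 1

and its exact scaled elasticities (``mode="derivative"``, the default) are

    eps_S,i =  n_i / (1 - rho)       - n_i alpha_i (1+alpha_i)^(n_i-1)
               prod_{j != i, substrates} (1+alpha_j)^n_j / D
    eps_P,i = -n_i rho / (1 - rho)   - n_i pi_i (1+pi_i)^(n_i-1)
               prod_{j != i, products} (1+pi_j)^n_j / D

The first (thermodynamic) term diverges as rho -> 1; the second
(saturation) term is the logarithmic derivative of D and always damps the
rate, so substrates excite (eps_S > 0 away from strong saturation) and
products inhibit (eps_P < 0).  A published transcription of these formulas
circulates with the product saturation term added instead of subtracted and
without the n_i factor in the saturation terms; that variant is kept as
``mode="printed"`` for sensitivity comparisons but is not a derivative of
the rate law above (it would let a product activate its own producer).

External species (fixed cofactor pools) contribute saturation factors to D
and to the cross-products but get no elasticity of their own.  Boundary
steps bypass the rate law: supplies are constant sources (zero elasticity)
and the consumption step defaults to first order in its substrate; both
orders are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import KineticsError
from .pathway import PathwaySpec, Reaction
from .thermo import ReactionThermo

__all__ = [
    "ReactionSaturations",
    "BoundaryKinetics",
    "rate_law_denominator",
    "substrate_elasticity",
    "product_elasticity",
    "elasticity_matrix",
]

#: Recognized elasticity conventions.
ELASTICITY_MODES = ("derivative", "printed")


@dataclass
class ReactionSaturations:
    """Saturation ratios for one reaction: alpha per substrate, pi per product."""

    alpha: dict[str, float] = field(default_factory=dict)
    pi: dict[str, float] = field(default_factory=dict)

    def validate_against(self, reaction: Reaction) -> None:
        subs = {p.species for p in reaction.substrates}
        prods = {p.species for p in reaction.products}
        if set(self.alpha) != subs or set(self.pi) != prods:
            raise KineticsError(
                f"saturations for reaction {reaction.id!r} must cover exactly its "
                f"participants: need alpha for {sorted(subs)}, pi for {sorted(prods)}; "
                f"got alpha for {sorted(self.alpha)}, pi for {sorted(self.pi)}"
            )
        for name, vals in (("alpha", self.alpha), ("pi", self.pi)):
            for sp, v in vals.items():
                if not v > 0:
                    raise KineticsError(
                        f"{name}[{sp!r}] of reaction {reaction.id!r} must be > 0, got {v}"
                    )


#: Saturations for every enzymatic reaction of a pathway, keyed by reaction id.
SaturationSet = dict[str, ReactionSaturations]


@dataclass(frozen=True)
class BoundaryKinetics:
    """Kinetic orders assigned to boundary steps.

    Supplies default to constant sources (zero order, zero elasticity); the
    consumption step defaults to first order in its single internal substrate.
    """

    supply_elasticity: float = 0.0
    consumption_elasticity: float = 1.0


def _check_mode(mode: str) -> None:
    if mode not in ELASTICITY_MODES:
        raise KineticsError(f"unknown elasticity mode {mode!r}; choose from {ELASTICITY_MODES}")


def _check_sides(reaction: Reaction) -> None:
    both = {p.species for p in reaction.substrates} & {p.species for p in reaction.products}
    if both:
        raise KineticsError(
            f"reaction {reaction.id!r} has species on both sides ({sorted(both)}); "
            "the rate-law elasticities do not support this configuration"
        )


def rate_law_denominator(reaction: Reaction, sat: ReactionSaturations) -> float:
    """Denominator D of the generalized reversible rate law, without allosteric terms."""
    _check_sides(reaction)
    sat.validate_against(reaction)
    a = 1.0
    for p in reaction.substrates:
        a *= (1.0 + sat.alpha[p.species]) ** p.n
    b = 1.0
    for p in reaction.products:
        b *= (1.0 + sat.pi[p.species]) ** p.n
    return a + b - 1.0


def _check_rho(rho: float) -> None:
    if not (0.0 <= rho < 1.0):
        raise KineticsError(
            f"disequilibrium ratio must satisfy 0 <= rho < 1, got {rho}; "
            "near-equilibrium draws must be capped upstream"
        )


def substrate_elasticity(
    reaction: Reaction,
    species: str,
    sat: ReactionSaturations,
    rho: float,
    mode: str = "derivative",
) -> float:
    """Scaled elasticity of the reaction rate with respect to substrate ``species``."""
    _check_rho(rho)
    _check_mode(mode)
    D = rate_law_denominator(reaction, sat)
    n = next(p.n for p in reaction.substrates if p.species == species)
    a_i = sat.alpha[species]
    cross = 1.0
    for p in reaction.substrates:
        if p.species != species:
            cross *= (1.0 + sat.alpha[p.species]) ** p.n
    sat_term = a_i * (1.0 + a_i) ** (n - 1) * cross / D
    if mode == "derivative":
        sat_term *= n
    return n / (1.0 - rho) - sat_term


def product_elasticity(
    reaction: Reaction,
    species: str,
    sat: ReactionSaturations,
    rho: float,
    mode: str = "derivative",
) -> float:
    """Scaled elasticity of the reaction rate with respect to product ``species``."""
    _check_rho(rho)
    _check_mode(mode)
    D = rate_law_denominator(reaction, sat)
    n = next(p.n for p in reaction.products if p.species == species)
    p_i = sat.pi[species]
    cross = 1.0
    for p in reaction.products:
        if p.species != species:
            cross *= (1.0 + sat.pi[p.species]) ** p.n
    sat_term = p_i * (1.0 + p_i) ** (n - 1) * cross / D
    if mode == "derivative":
        return -n * rho / (1.0 - rho) - n * sat_term
    return -n * rho / (1.0 - rho) + sat_term


def elasticity_matrix(
    spec: PathwaySpec,
    sats: SaturationSet,
    thermo: dict[str, ReactionThermo],
    mode: str = "derivative",
    boundary: BoundaryKinetics = BoundaryKinetics(),
) -> np.ndarray:
    """Assemble the (reactions x internal metabolites) scaled elasticity matrix.

    Entry (r, m) is the substrate or product elasticity of reaction r with
    respect to internal metabolite m, zero if m does not participate.
    External species only shape the denominators.
    """
    eps = np.zeros((len(spec.reactions), len(spec.metabolites)))
    for j, rxn in enumerate(spec.reactions):
        if rxn.kind == "boundary":
            for p in rxn.substrates:
                if spec.is_internal(p.species):
                    eps[j, spec.metabolite_index(p.species)] = boundary.consumption_elasticity
            for p in rxn.products:
                if spec.is_internal(p.species):
                    eps[j, spec.metabolite_index(p.species)] = -boundary.supply_elasticity
            continue
        sat = sats[rxn.id]
        rho = thermo[rxn.id].rho
        for p in rxn.substrates:
            if spec.is_internal(p.species):
                eps[j, spec.metabolite_index(p.species)] = substrate_elasticity(
                    rxn, p.species, sat, rho, mode
                )
        for p in rxn.products:
            if spec.is_internal(p.species):
                eps[j, spec.metabolite_index(p.species)] = product_elasticity(
                    rxn, p.species, sat, rho, mode
                )
    return eps
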