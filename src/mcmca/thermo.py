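"""Reaction thermodynamics: free energies, equilibrium constants, disequilibrium ratios.

The disequilibrium ratio rho = Gamma'/K'eq = exp(dG'/RT) measures how far a
reaction operates from equilibrium in its oriented (net-forward) direction:
rho -> 0 means strongly driven, rho -> 1 means near equilibrium, and rho >= 1
means the parameterized concentrations would push the reaction backwards
against its stored orientation.  Reactions in the last situation (in the
bundled tables: arginase and proline dehydrogenase) get their rho adjusted
below one — by default mirrored to the same distance under equilibrium —
with the adjustment recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .errors import ThermoError
from .pathway import PathwaySpec

__all__ = [
    "DEFAULT_RT",
    "ReactionThermo",
    "reaction_free_energy",
    "disequilibrium_ratio",
    "adjust_rho",
    "load_thermo_table",
]

#: Gas constant, kJ mol^-1 K^-1.
R_GAS = 8.314462618e-3

#: R*T at 298.15 K in kJ mol^-1 — the package default reference temperature.
DEFAULT_RT = 2.479


@dataclass(frozen=True)
class ReactionThermo:
    """Thermodynamic state of one oriented reaction.

    ``dG0_prime`` is the biochemical standard reaction free energy and
    ``dG_prime`` the condition-adjusted one (both kJ/mol); ``rho`` is the
    disequilibrium ratio after any adjustment, with ``adjusted`` recording
    whether the cap was applied.  Boundary steps are marked ``irreversible``
    and carry ``rho = 0`` by convention.
    """

    reaction_id: str
    dG0_prime: float | None
    dG_prime: float | None
    rho: float
    adjusted: bool = False
    irreversible: bool = False
    RT: float = DEFAULT_RT

    @property
    def keq_prime(self) -> float | None:
        """Equilibrium constant K'eq = exp(-dG0'/RT)."""
        if self.dG0_prime is None:
            return None
        return math.exp(-self.dG0_prime / self.RT)

    @property
    def gamma_prime(self) -> float | None:
        """Mass-action ratio Gamma' implied by dG' and dG0' (rho * K'eq)."""
        if self.dG_prime is None or self.dG0_prime is None:
            return None
        return math.exp((self.dG_prime - self.dG0_prime) / self.RT)


def reaction_free_energy(dG0_prime: float, gamma_prime: float, RT: float = DEFAULT_RT) -> float:
    """Condition-adjusted reaction free energy dG' = dG0' + RT ln Gamma'."""
    if gamma_prime <= 0:
        raise ThermoError(f"mass-action ratio must be positive, got {gamma_prime}")
    if RT <= 0:
        raise ThermoError(f"RT must be positive, got {RT}")
    return dG0_prime + RT * math.log(gamma_prime)


def disequilibrium_ratio(dG_prime: float, RT: float = DEFAULT_RT) -> float:
    """Disequilibrium ratio rho = Gamma'/K'eq = exp(dG'/RT), unclamped."""
    if RT <= 0:
        raise ThermoError(f"RT must be positive, got {RT}")
    return math.exp(dG_prime / RT)


def adjust_rho(
    thermo: ReactionThermo, rho_cap: float = 0.99, rule: str = "mirror"
) -> ReactionThermo:
    """Adjust a thermodynamically blocked reaction (rho >= 1) below equilibrium.

    A rho at or above one means the parameterized concentrations would push
    the reaction against its known net-flux direction — in the bundled
    tables this happens for arginase (an essentially irreversible hydrolysis)
    and proline dehydrogenase (coupled to the respiratory chain), whose
    effective in-vivo driving forces the single-pool concentration estimates
    misrepresent.  Two rules are available:

    - ``"mirror"`` (default): rho -> min(1/rho, rho_cap), i.e. the reaction
      is taken as far below equilibrium in its flux direction as the
      concentration estimate had placed it above.
    - ``"cap"``: rho -> rho_cap, a near-equilibrium clamp.

    Unblocked reactions (rho < 1) pass through unchanged.
    """
    if not (0 < rho_cap < 1):
        raise ThermoError(f"rho_cap must lie in (0, 1), got {rho_cap}")
    if rule not in ("mirror", "cap"):
        raise ThermoError(f"unknown adjustment rule {rule!r}")
    if thermo.rho >= 1:
        new = min(1.0 / thermo.rho, rho_cap) if rule == "mirror" else rho_cap
        return replace(thermo, rho=new, adjusted=True)
    return thermo


def load_thermo_table(
    path: str | Path,
    spec: PathwaySpec,
    condition: str | None = None,
    RT: float = DEFAULT_RT,
    rho_cap: float = 0.99,
    adjust_rule: str = "mirror",
) -> dict[str, ReactionThermo]:
    """Load per-reaction thermodynamics from TSV and compute adjusted rho values.

    The table needs columns ``reaction_id``, ``dG0_prime_kJ_mol`` and either
    ``dG_prime_kJ_mol`` (single-condition file) or ``dG_prime_<condition>_kJ_mol``
    (multi-condition file, selected via ``condition``).  Every enzymatic
    reaction of ``spec`` must have a row; boundary reactions may be absent and
    are returned as irreversible entries with rho = 0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if "reaction_id" not in df.columns:
        raise ThermoError(f"{path}: missing 'reaction_id' column")
    if condition is not None:
        col = f"dG_prime_{condition.lower()}_kJ_mol"
    else:
        col = "dG_prime_kJ_mol"
    if col not in df.columns:
        raise ThermoError(f"{path}: missing column {col!r}")

    rows = {str(r["reaction_id"]): r for _, r in df.iterrows()}
    out: dict[str, ReactionThermo] = {}
    missing = []
    for rxn in spec.reactions:
        if rxn.kind == "boundary":
            out[rxn.id] = ReactionThermo(
                reaction_id=rxn.id,
                dG0_prime=None,
                dG_prime=None,
                rho=0.0,
                irreversible=True,
                RT=RT,
            )
            continue
        if rxn.id not in rows:
            missing.append(rxn.id)
            continue
        row = rows[rxn.id]
        dG0 = float(row["dG0_prime_kJ_mol"])
        dG = float(row[col])
        th = ReactionThermo(
            reaction_id=rxn.id,
            dG0_prime=dG0,
            dG_prime=dG,
            rho=disequilibrium_ratio(dG, RT),
            RT=RT,
        )
        out[rxn.id] = adjust_rho(th, rho_cap, rule=adjust_rule)
    if missing:
        raise ThermoError(f"{path}: missing thermodynamics for reactions {missing}")
    return out
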