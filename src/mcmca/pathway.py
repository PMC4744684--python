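"""Pathway data model: network topology, stoichiometry and structural analysis.

A pathway is a set of internal metabolites (the model variables), external
species held at fixed pools (cofactors, sources and sinks), and oriented
reactions.  Every reaction is stored in the orientation of its expected net
flux, so that at a sampled steady state all fluxes are positive and all
disequilibrium ratios lie below one.  The signed stoichiometric matrix ``N``
(metabolites x reactions) collects the internal stoichiometric numbers;
external species never get a row in ``N`` and never carry control
coefficients, but they do contribute saturation terms to rate-law
denominators downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import lcm
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import sympy

from .errors import PathwayValidationError

__all__ = [
    "Participant",
    "Reaction",
    "PathwaySpec",
    "StructuralReport",
    "load_pathway",
    "write_pathway",
    "builtin_proline_pathway",
    "structural_analysis",
]


@dataclass(frozen=True)
class Participant:
    """One species taking part in a reaction with stoichiometric exponent ``n`` (>= 1)."""

    species: str
    n: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.n, int) and self.n >= 1):
            raise PathwayValidationError(
                f"stoichiometric exponent of {self.species!r} must be a positive "
                f"integer, got {self.n!r}"
            )


@dataclass(frozen=True)
class Reaction:
    """An oriented reaction step.

    ``kind`` distinguishes enzymatic steps, which carry thermodynamics and
    sampled saturation kinetics, from boundary steps (supply or consumption of
    a single internal metabolite) representing exchange with the rest of
    metabolism.  ``orientation_note`` records any sign flip applied relative
    to the source table the reaction was transcribed from.
    """

    id: str
    substrates: tuple[Participant, ...]
    products: tuple[Participant, ...]
    kind: Literal["enzymatic", "boundary"] = "enzymatic"
    orientation_note: str = ""

    def __post_init__(self) -> None:
        if not self.substrates and not self.products:
            raise PathwayValidationError(f"reaction {self.id!r} has no participants")

    def participants(self) -> tuple[Participant, ...]:
        return self.substrates + self.products

    def exponent(self, species: str) -> int:
        """Stoichiometric exponent of ``species`` in this reaction (substrate or product)."""
        for p in self.participants():
            if p.species == species:
                return p.n
        raise KeyError(f"{species!r} does not participate in reaction {self.id!r}")


@dataclass
class PathwaySpec:
    """A validated pathway: ordered internal metabolites, externals, reactions and N."""

    metabolites: list[str]
    externals: list[str]
    reactions: list[Reaction]
    N: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self._validate_ids()
        self.N = self._assemble_matrix()
        self._validate_reactions()

    # -- construction helpers -------------------------------------------------

    def _validate_ids(self) -> None:
        if len(set(self.metabolites)) != len(self.metabolites):
            raise PathwayValidationError("duplicate metabolite identifiers")
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise PathwayValidationError("duplicate reaction identifiers")
        overlap = set(self.metabolites) & set(self.externals)
        if overlap:
            raise PathwayValidationError(
                f"species declared both internal and external: {sorted(overlap)}"
            )

    def _assemble_matrix(self) -> np.ndarray:
        declared = set(self.metabolites) | set(self.externals)
        N = np.zeros((len(self.metabolites), len(self.reactions)), dtype=int)
        idx = {m: i for i, m in enumerate(self.metabolites)}
        for j, rxn in enumerate(self.reactions):
            seen: set[str] = set()
            for part, sign in [(rxn.substrates, -1), (rxn.products, +1)]:
                for p in part:
                    if p.species not in declared:
                        raise PathwayValidationError(
                            f"reaction {rxn.id!r} references undeclared species "
                            f"{p.species!r}"
                        )
                    if p.species in seen:
                        raise PathwayValidationError(
                            f"species {p.species!r} appears twice in reaction {rxn.id!r}"
                        )
                    seen.add(p.species)
                    if p.species in idx:
                        N[idx[p.species], j] = sign * p.n
        return N

    def _validate_reactions(self) -> None:
        for j, rxn in enumerate(self.reactions):
            if rxn.kind == "boundary":
                internal = np.count_nonzero(self.N[:, j])
                if internal != 1:
                    raise PathwayValidationError(
                        f"boundary reaction {rxn.id!r} must touch exactly one "
                        f"internal metabolite, touches {internal}"
                    )

    # -- lookups --------------------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in pathway")

    def metabolite_index(self, species: str) -> int:
        return self.metabolites.index(species)

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def is_internal(self, species: str) -> bool:
        return species in self.metabolites


# -- JSON round-trip ---------------------------------------------------------


def _participant_list(raw: object, rxn_id: str, side: str) -> tuple[Participant, ...]:
    if not isinstance(raw, list):
        raise PathwayValidationError(f"reaction {rxn_id!r}: {side} must be a list")
    out = []
    for entry in raw:
        if not isinstance(entry, dict) or "species" not in entry:
            raise PathwayValidationError(
                f"reaction {rxn_id!r}: each {side} entry needs a 'species' field"
            )
        out.append(Participant(str(entry["species"]), int(entry.get("n", 1))))
    return tuple(out)


def load_pathway(path: str | Path) -> PathwaySpec:
    """Load a pathway from the documented JSON schema and validate it.

    Schema::

        {"metabolites": [...], "externals": [...],
         "reactions": [{"id": ..., "substrates": [{"species":..., "n":...}],
                        "products": [...], "kind": "enzymatic"|"boundary",
                        "orientation_note": "..."}]}
    """
    path = Path(path)
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise PathwayValidationError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("metabolites", "externals", "reactions"):
        if key not in raw:
            raise PathwayValidationError(f"{path}: missing top-level field {key!r}")
    reactions = []
    for r in raw["reactions"]:
        if "id" not in r:
            raise PathwayValidationError(f"{path}: reaction without 'id'")
        kind = r.get("kind", "enzymatic")
        if kind not in ("enzymatic", "boundary"):
            raise PathwayValidationError(
                f"{path}: reaction {r['id']!r} has unknown kind {kind!r}"
            )
        reactions.append(
            Reaction(
                id=str(r["id"]),
                substrates=_participant_list(r.get("substrates", []), r["id"], "substrates"),
                products=_participant_list(r.get("products", []), r["id"], "products"),
                kind=kind,
                orientation_note=str(r.get("orientation_note", "")),
            )
        )
    return PathwaySpec(
        metabolites=[str(m) for m in raw["metabolites"]],
        externals=[str(e) for e in raw["externals"]],
        reactions=reactions,
    )


def write_pathway(spec: PathwaySpec, path: str | Path) -> None:
    """Serialize a pathway back to the JSON schema read by :func:`load_pathway`."""
    doc = {
        "metabolites": spec.metabolites,
        "externals": spec.externals,
        "reactions": [
            {
                "id": r.id,
                "substrates": [{"species": p.species, "n": p.n} for p in r.substrates],
                "products": [{"species": p.species, "n": p.n} for p in r.products],
                "kind": r.kind,
                "orientation_note": r.orientation_note,
            }
            for r in spec.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def export_stoichiometry_tsv(spec: PathwaySpec, path: str | Path) -> None:
    """Write N as TSV with metabolite rows and reaction columns."""
    with open(path, "w") as fh:
        fh.write("metabolite\t" + "\t".join(spec.reaction_ids) + "\n")
        for i, m in enumerate(spec.metabolites):
            fh.write(m + "\t" + "\t".join(str(int(x)) for x in spec.N[i]) + "\n")


# -- bundled proline pathway --------------------------------------------------


def builtin_proline_pathway() -> PathwaySpec:
    """The six-metabolite, twelve-reaction proline metabolism network.

    Internal metabolites are ornithine (Orn), alpha-ketoglutarate (akG),
    glutamate (Glu), glutamine (Gln), pyrroline-5-carboxylate (P5c) and
    proline (Pro).  Nine enzymatic steps (ARG, OAT, GDH, GOGAT, GS, P5CS,
    P5CR, PRODH, P5CDH) are joined by three boundary steps: Pro consumption
    (PROCO) and constant akG and Glu supplies (AKGPR, GLUPR).  All reactions
    are oriented along their expected net flux: in particular GDH is stored
    in the glutamate-producing direction (akG -> Glu) and P5CR in the
    proline-producing direction (P5c -> Pro), with the flips recorded in
    ``orientation_note``.
    """
    S = Participant
    reactions = [
        Reaction(
            "ARG",
            substrates=(S("Arg"),),
            products=(S("Orn"), S("urea")),
        ),
        Reaction(
            "OAT",
            substrates=(S("Orn"), S("akG")),
            products=(S("Glu"), S("P5c")),
        ),
        Reaction(
            "GDH",
            substrates=(S("akG"), S("NH4"), S("NADH")),
            products=(S("Glu"), S("NAD")),
            orientation_note=(
                "stored akG -> Glu (glutamate-producing direction); the source "
                "stoichiometry table prints the opposite sign"
            ),
        ),
        Reaction(
            "GOGAT",
            substrates=(S("akG"), S("Gln"), S("NADPH")),
            products=(S("Glu", 2), S("NADP")),
        ),
        Reaction(
            "GS",
            substrates=(S("Glu"), S("NH4"), S("ATP")),
            products=(S("Gln"), S("ADP"), S("Pi")),
        ),
        Reaction(
            "P5CS",
            substrates=(S("Glu"), S("ATP"), S("NADPH")),
            products=(S("P5c"), S("ADP"), S("Pi"), S("NADP")),
        ),
        Reaction(
            "P5CR",
            substrates=(S("P5c"), S("NADPH")),
            products=(S("Pro"), S("NADP")),
            orientation_note=(
                "stored P5c -> Pro (proline-producing direction); the source "
                "stoichiometry table prints the opposite sign"
            ),
        ),
        Reaction(
            "PRODH",
            substrates=(S("Pro"),),
            products=(S("P5c"),),
        ),
        Reaction(
            "PROCO",
            substrates=(S("Pro"),),
            products=(),
            kind="boundary",
        ),
        Reaction(
            "AKGPR",
            substrates=(),
            products=(S("akG"),),
            kind="boundary",
        ),
        Reaction(
            "GLUPR",
            substrates=(),
            products=(S("Glu"),),
            kind="boundary",
        ),
        Reaction(
            "P5CDH",
            substrates=(S("P5c"), S("NAD")),
            products=(S("Glu"), S("NADH")),
        ),
    ]
    return PathwaySpec(
        metabolites=["Orn", "akG", "Glu", "Gln", "P5c", "Pro"],
        externals=[
            "Arg",
            "urea",
            "NH4",
            "NAD",
            "NADH",
            "NADP",
            "NADPH",
            "ATP",
            "ADP",
            "Pi",
        ],
        reactions=reactions,
    )


# -- structural analysis -------------------------------------------------------


@dataclass
class StructuralReport:
    """Exact structural properties of a stoichiometric matrix.

    ``right_nullspace`` columns span the steady-state flux modes (N B = 0),
    ``left_nullspace`` columns span conserved moieties (b^T N = 0).  When
    conserved moieties exist, ``reduced_N`` holds an independent row subset
    ``N_R`` and ``link_matrix`` the matrix L with N = L N_R (Reder reduction);
    otherwise ``reduced_N`` is N itself and L the identity.  All matrices are
    integer and exact.
    """

    rank: int
    right_nullspace: np.ndarray
    left_nullspace: np.ndarray
    independent_rows: list[int]
    reduced_N: np.ndarray
    link_matrix: np.ndarray

    @property
    def n_conserved_moieties(self) -> int:
        return self.left_nullspace.shape[1]


def _integer_columns(vectors: Sequence[sympy.Matrix], nrows: int) -> np.ndarray:
    """Stack rational sympy column vectors into an integer numpy matrix."""
    if not vectors:
        return np.zeros((nrows, 0), dtype=int)
    cols = []
    for v in vectors:
        fracs = [Fraction(sympy.Rational(x)) for x in v]
        mult = lcm(*(f.denominator for f in fracs)) if fracs else 1
        cols.append([int(f * mult) for f in fracs])
    return np.array(cols, dtype=int).T


def structural_analysis(spec: PathwaySpec) -> StructuralReport:
    """Exact rank, flux-mode basis and conserved-moiety analysis of ``spec.N``."""
    M = sympy.Matrix(spec.N.tolist())
    rank = M.rank()
    right = _integer_columns(M.nullspace(), M.cols)
    left = _integer_columns(M.T.nullspace(), M.rows)

    # Independent rows via the pivot columns of N^T.
    _, pivots = M.T.rref()
    independent = list(pivots)
    N_R = spec.N[independent, :]
    if left.shape[1] == 0:
        L = np.eye(len(spec.metabolites), dtype=int)
        N_R = spec.N
        independent = list(range(len(spec.metabolites)))
    else:
        # Solve N = L N_R row by row, exactly.
        NR_sym = sympy.Matrix(N_R.tolist())
        L_sym = sympy.Matrix(spec.N.tolist()) * NR_sym.pinv()
        L = np.array([[float(x) for x in row] for row in L_sym.tolist()])
    return StructuralReport(
        rank=rank,
        right_nullspace=right,
        left_nullspace=left,
        independent_rows=independent,
        reduced_N=N_R,
        link_matrix=L,
    )
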