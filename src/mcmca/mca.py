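"""Structural metabolic control analysis by elasticity-matrix inversion.

With stoichiometry N (internal metabolites x reactions), steady-state flux
vector J (N J = 0) and scaled elasticity matrix eps (reactions x
metabolites), the scaled concentration control coefficients are

    C^S = -(N diag(J) eps)^-1 N diag(J)          (metabolites x reactions)
    C^J = eps C^S + I                             (reactions x reactions)

assuming enzyme activity proportional to enzyme concentration, so that a
relative enzyme change scales the rate one-for-one.  Absolute metabolite
concentrations cancel from the scaled formula — only saturation ratios,
disequilibrium ratios and flux ratios enter, which is what makes the Monte
Carlo parameterization possible.  If the network has conserved moieties the
Reder-reduced system (independent rows N_R, link matrix L) is inverted
instead.

The summation theorems (concentration rows sum to 0, flux rows to 1) and the
connectivity identities (C^S eps = -I, C^J eps = 0 for moiety-free networks)
hold exactly for any valid (J, eps) pair and serve as per-draw self-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SamplingError, SingularDrawError
from .pathway import PathwaySpec, StructuralReport

__all__ = [
    "FluxVector",
    "ControlMatrix",
    "sample_steady_state_flux",
    "control_matrices",
    "theorem_report",
]


@dataclass
class FluxVector:
    """A steady-state flux vector (all entries positive in oriented convention)."""

    J: np.ndarray
    rejections: int = 0

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)


@dataclass
class ControlMatrix:
    """Scaled control coefficients of one parameter draw.

    ``CS[m, r]`` is d ln S_m / d ln E_r, ``CJ[r', r]`` is d ln J_r' / d ln E_r.
    """

    CS: np.ndarray
    CJ: np.ndarray
    metabolites: list[str]
    reactions: list[str]
    condition: str = ""
    run_index: int = -1
    meta: dict = field(default_factory=dict)

    def concentration_control(self, metabolite: str, reaction: str) -> float:
        return float(
            self.CS[self.metabolites.index(metabolite), self.reactions.index(reaction)]
        )


def sample_steady_state_flux(
    spec: PathwaySpec,
    null_basis: np.ndarray,
    interval: tuple[float, float],
    rng: np.random.Generator,
    max_attempts: int = 100_000,
    batch: int = 256,
) -> FluxVector:
    """Sample a positive steady-state flux vector J = B c.

    Free coefficients c are drawn log-uniformly from ``interval`` and the
    combination is rejected until every oriented flux is strictly positive.
    ``rejections`` records how many candidate vectors were discarded.
    """
    lo, hi = interval
    if not (0 < lo <= hi):
        raise SamplingError(f"flux interval must satisfy 0 < lo <= hi, got {interval}")
    B = np.asarray(null_basis, dtype=float)
    d = B.shape[1]
    tried = 0
    while tried < max_attempts:
        m = min(batch, max_attempts - tried)
        c = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(m, d)))
        J = c @ B.T  # (m, reactions)
        ok = np.all(J > 0, axis=1)
        idx = np.flatnonzero(ok)
        if idx.size:
            return FluxVector(J=J[idx[0]], rejections=tried + int(idx[0]))
        tried += m
    raise SamplingError(
        f"no feasible positive flux vector in {max_attempts} attempts over "
        f"interval {interval}; the null-space basis may not admit positive "
        "combinations in this range"
    )


def control_matrices(
    spec: PathwaySpec,
    eps: np.ndarray,
    flux: FluxVector | np.ndarray,
    structure: StructuralReport | None = None,
    cond_threshold: float = 1e12,
    condition: str = "",
    run_index: int = -1,
) -> ControlMatrix:
    """Invert the flux-weighted elasticity system into control matrices.

    Raises :class:`SingularDrawError` when the system matrix is singular or
    its condition number exceeds ``cond_threshold``; callers discard and
    resample such draws rather than regularizing them.
    """
    J = flux.J if isinstance(flux, FluxVector) else np.asarray(flux, dtype=float)
    N = spec.N.astype(float)
    r, m = eps.shape
    if (r, m) != (N.shape[1], N.shape[0]):
        raise ValueError(f"elasticity matrix shape {eps.shape} does not match N {N.shape}")
    NdJ = N * J[np.newaxis, :]  # N diag(J), metabolites x reactions
    if structure is not None and structure.n_conserved_moieties > 0:
        rows = structure.independent_rows
        L = structure.link_matrix.astype(float)
        NdJ_R = NdJ[rows, :]
        A = NdJ_R @ eps @ L
        with np.errstate(all="ignore"):
            cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > cond_threshold:
            raise SingularDrawError(f"system matrix condition number {cond:.3g}")
        CS = -L @ np.linalg.solve(A, NdJ_R)
    else:
        A = NdJ @ eps
        with np.errstate(all="ignore"):
            cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > cond_threshold:
            raise SingularDrawError(f"system matrix condition number {cond:.3g}")
        CS = -np.linalg.solve(A, NdJ)
    CJ = eps @ CS + np.eye(r)
    return ControlMatrix(
        CS=CS,
        CJ=CJ,
        metabolites=list(spec.metabolites),
        reactions=list(spec.reaction_ids),
        condition=condition,
        run_index=run_index,
        meta={"condition_number": float(cond)},
    )


def theorem_report(
    cm: ControlMatrix,
    eps: np.ndarray,
    flux: FluxVector | np.ndarray,
    N: np.ndarray,
) -> dict[str, float]:
    """Maximum absolute deviations from the classical control theorems.

    Returns the concentration-summation deviation (rows of C^S should sum to
    0), flux-summation deviation (rows of C^J should sum to 1), steady-state
    residual of J, and the connectivity deviations C^S eps + I and C^J eps
    (both should vanish for moiety-free networks).
    """
    J = flux.J if isinstance(flux, FluxVector) else np.asarray(flux, dtype=float)
    m = cm.CS.shape[0]
    r = cm.CJ.shape[0]
    dev = {
        "concentration_summation": float(np.max(np.abs(cm.CS.sum(axis=1)))),
        "flux_summation": float(np.max(np.abs(cm.CJ.sum(axis=1) - 1.0))),
        "steady_state_residual": float(
            np.max(np.abs(N.astype(float) @ J)) / max(np.max(np.abs(J)), 1e-300)
        ),
        "connectivity_CS": float(np.max(np.abs(cm.CS @ eps + np.eye(m)))),
        "connectivity_CJ": float(np.max(np.abs(cm.CJ @ eps))),
    }
    return dev
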