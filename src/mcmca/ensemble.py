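"""Monte Carlo ensemble of control matrices and its distribution summaries.

One run = one parameter draw: saturation ratios for every reaction
participant (log-uniform), a positive steady-state flux vector (log-uniform
free coefficients on the null-space basis), elasticity matrix assembly, and
inversion into control matrices.  Near-singular draws are discarded and
resampled, with the discard count reported.  The ensemble is summarized per
reaction by linear-interpolation percentiles (default P10/median/P90) of the
proline concentration control coefficient, and by the Pearson correlation
matrix of per-run proline control coefficients across reaction pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SamplingError, SingularDrawError
from .kinetics import (
    BoundaryKinetics,
    ReactionSaturations,
    SaturationSet,
    elasticity_matrix,
)
from .mca import control_matrices, sample_steady_state_flux, theorem_report
from .pathway import PathwaySpec, StructuralReport, structural_analysis
from .thermo import ReactionThermo

__all__ = [
    "SamplingConfig",
    "EnsembleResult",
    "sample_saturations",
    "run_ensemble",
    "summarize",
    "correlate",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Monte Carlo sampling configuration.

    Saturation ratios alpha/pi and free-flux coefficients are drawn
    log-uniformly from their intervals; the defaults span one decade either
    side of half-saturation (0.1 to 10 times the Michaelis constant) and the
    same decade span for flux ratios.  ``rho_cap`` is the near-equilibrium
    clamp applied upstream to thermodynamically blocked reactions and is
    echoed here for provenance.
    """

    n_runs: int = 1000
    seed: int = 0
    alpha_interval: tuple[float, float] = (0.1, 10.0)
    pi_interval: tuple[float, float] = (0.1, 10.0)
    flux_interval: tuple[float, float] = (0.1, 10.0)
    rho_cap: float = 0.99
    percentiles: tuple[float, ...] = (10.0, 50.0, 90.0)
    cond_threshold: float = 1e12
    max_discard_fraction: float = 0.05
    elasticity_mode: str = "derivative"
    tie_cofactors: bool = False
    boundary: BoundaryKinetics = BoundaryKinetics()

    def __post_init__(self) -> None:
        for name in ("alpha_interval", "pi_interval", "flux_interval"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got {(lo, hi)}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def _log_uniform(rng: np.random.Generator, interval: tuple[float, float]) -> float:
    lo, hi = interval
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_saturations(
    spec: PathwaySpec, config: SamplingConfig, rng: np.random.Generator
) -> SaturationSet:
    """Draw one saturation set: log-uniform alpha/pi per reaction participant.

    By default each (reaction, species) pair is sampled independently; with
    ``tie_cofactors`` a species shared by several reactions receives one draw
    reused everywhere (same Michaelis constant for every enzyme).
    """
    tied: dict[str, float] = {}

    def draw(species: str, interval: tuple[float, float]) -> float:
        if config.tie_cofactors:
            if species not in tied:
                tied[species] = _log_uniform(rng, interval)
            return tied[species]
        return _log_uniform(rng, interval)

    sats: SaturationSet = {}
    for rxn in spec.reactions:
        if rxn.kind == "boundary":
            continue
        sats[rxn.id] = ReactionSaturations(
            alpha={p.species: draw(p.species, config.alpha_interval) for p in rxn.substrates},
            pi={p.species: draw(p.species, config.pi_interval) for p in rxn.products},
        )
    return sats


@dataclass
class EnsembleResult:
    """Stacked control matrices over Monte Carlo runs plus provenance."""

    spec: PathwaySpec
    config: SamplingConfig
    condition: str
    CS: np.ndarray  # (n_runs, metabolites, reactions)
    discarded: int
    flux_rejections: int
    theorem_deviation: float

    @property
    def metabolites(self) -> list[str]:
        return list(self.spec.metabolites)

    @property
    def reactions(self) -> list[str]:
        return list(self.spec.reaction_ids)

    def metabolite_control(self, metabolite: str = "Pro") -> np.ndarray:
        """Per-run control coefficients of one metabolite: (n_runs, reactions)."""
        return self.CS[:, self.spec.metabolite_index(metabolite), :]

    def summarize(self, metabolite: str = "Pro") -> pd.DataFrame:
        return summarize(self, metabolite)

    def correlate(self, metabolite: str = "Pro") -> pd.DataFrame:
        return correlate(self, metabolite)


def run_ensemble(
    spec: PathwaySpec,
    thermo: dict[str, ReactionThermo],
    config: SamplingConfig,
    condition: str = "",
) -> EnsembleResult:
    """Run the full Monte Carlo ensemble, resampling discarded singular draws.

    Deterministic for a fixed config: a single root seed spawns one child
    stream per attempted run.
    """
    structure = structural_analysis(spec)
    basis = structure.right_nullspace.astype(float)
    n_runs = config.n_runs
    CS = np.empty((n_runs, len(spec.metabolites), len(spec.reactions)))
    discarded = 0
    flux_rejections = 0
    worst_dev = 0.0
    root = np.random.SeedSequence(config.seed)
    accepted = 0
    attempt = 0
    max_attempts = max(int(np.ceil(n_runs / (1 - config.max_discard_fraction))) + 16, n_runs + 16)
    while accepted < n_runs:
        if attempt >= max_attempts:
            raise SamplingError(
                f"discard rate too high: {discarded} of {attempt} draws were "
                f"singular (allowed fraction {config.max_discard_fraction}); "
                "widen the condition-number threshold or revisit the intervals"
            )
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(attempt,)))
        attempt += 1
        sats = sample_saturations(spec, config, rng)
        flux = sample_steady_state_flux(spec, basis, config.flux_interval, rng)
        flux_rejections += flux.rejections
        eps = elasticity_matrix(
            spec, sats, thermo, mode=config.elasticity_mode, boundary=config.boundary
        )
        try:
            cm = control_matrices(
                spec,
                eps,
                flux,
                structure=structure,
                cond_threshold=config.cond_threshold,
                condition=condition,
                run_index=accepted,
            )
        except SingularDrawError:
            discarded += 1
            continue
        dev = theorem_report(cm, eps, flux, spec.N)
        worst_dev = max(
            worst_dev, dev["concentration_summation"], dev["flux_summation"]
        )
        CS[accepted] = cm.CS
        accepted += 1
    _ = root  # root seed retained in config provenance
    return EnsembleResult(
        spec=spec,
        config=config,
        condition=condition,
        CS=CS,
        discarded=discarded,
        flux_rejections=flux_rejections,
        theorem_deviation=worst_dev,
    )


def summarize(result: EnsembleResult, metabolite: str = "Pro") -> pd.DataFrame:
    """Percentile summary (linear-interpolation quantiles) per reaction.

    Columns: reaction plus one column per configured percentile (p10, median,
    p90 by default) of the chosen metabolite's control coefficient.
    """
    ctrl = result.metabolite_control(metabolite)
    qs = np.percentile(ctrl, result.config.percentiles, axis=0, method="linear")
    cols: dict[str, np.ndarray] = {}
    for p, row in zip(result.config.percentiles, qs):
        name = "median" if p == 50 else f"p{p:g}"
        cols[name] = row
    return pd.DataFrame({"reaction": result.reactions, **cols})


def correlate(result: EnsembleResult, metabolite: str = "Pro") -> pd.DataFrame:
    """Pearson correlations across runs between per-reaction control coefficients.

    Zero-variance distributions yield NaN entries (undefined, not zero).
    """
    ctrl = result.metabolite_control(metabolite)
    if ctrl.shape[0] < 3:
        raise ValueError("correlation requires at least 3 runs")
    sd = ctrl.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ctrl, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=result.reactions, columns=result.reactions)
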