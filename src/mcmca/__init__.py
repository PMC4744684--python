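"""Monte Carlo metabolic control analysis from stoichiometry, thermodynamics and generic kinetics."""

from importlib import resources

from .casestudy import CaseStudyResult, run_proline_case_study
from .ensemble import (
    EnsembleResult,
    SamplingConfig,
    correlate,
    run_ensemble,
    sample_saturations,
    summarize,
)
from .kinetics import (
    BoundaryKinetics,
    ReactionSaturations,
    elasticity_matrix,
    product_elasticity,
    rate_law_denominator,
    substrate_elasticity,
)
from .mca import (
    ControlMatrix,
    FluxVector,
    control_matrices,
    sample_steady_state_flux,
    theorem_report,
)
from .pathway import (
    PathwaySpec,
    Participant,
    Reaction,
    StructuralReport,
    builtin_proline_pathway,
    load_pathway,
    structural_analysis,
    write_pathway,
)
from .thermo import (
    DEFAULT_RT,
    ReactionThermo,
    adjust_rho,
    disequilibrium_ratio,
    load_thermo_table,
    reaction_free_energy,
)

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a bundled data file (thermo tables, pathway JSON, reference summaries)."""
    return resources.files("mcmca") / "data" / name


def builtin_thermo(
    condition: str,
    RT: float = DEFAULT_RT,
    rho_cap: float = 0.99,
    adjust_rule: str = "mirror",
):
    """Load the bundled thermodynamics table for condition ``"lp"`` or ``"ml"``."""
    cond = condition.lower()
    if cond not in ("lp", "ml"):
        raise ValueError(f"no bundled thermodynamics for condition {condition!r}")
    spec = builtin_proline_pathway()
    return load_thermo_table(
        data_path(f"thermo_{cond}.tsv"), spec, RT=RT, rho_cap=rho_cap, adjust_rule=adjust_rule
    )
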