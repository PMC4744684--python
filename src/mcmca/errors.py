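"""Exception hierarchy for mcmca."""


class McmcaError(Exception):
    """Base class for all mcmca errors."""


class PathwayValidationError(McmcaError):
    """A pathway definition violates the schema or its structural invariants."""


class ThermoError(McmcaError):
    """Invalid thermodynamic input (non-positive mass-action ratio, bad cap, missing rows)."""


class KineticsError(McmcaError):
    """Invalid kinetic configuration (rho >= 1, species on both sides of one reaction)."""


class SingularDrawError(McmcaError):
    """The flux-weighted elasticity system of one Monte Carlo draw is (near-)singular."""


class SamplingError(McmcaError):
    """Feasible steady-state fluxes could not be sampled within the attempt budget."""


class OracleError(McmcaError):
    """Kinetic-instance construction or steady-state solution failed."""
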