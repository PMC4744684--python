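# Methods

## Model

The package performs structural metabolic control analysis on a reaction
network given as (i) a stoichiometric matrix **N** over internal
metabolites, (ii) per-reaction thermodynamics, and (iii) a generic
reversible rate law standing in for unknown enzyme kinetics. All reactions
are stored *oriented*: positive flux in the expected net direction, so that
a valid parameterization has every disequilibrium ratio ρ < 1 and every
steady-state flux positive. For the bundled proline network two reactions
are flipped relative to the stoichiometry table they were transcribed from
(GDH to the glutamate-producing direction, P5CR to the proline-producing
direction, both recorded in `orientation_note`), because their
thermodynamics and biochemistry fix those as the net directions.

Scaled control coefficients are obtained by inversion,
C^S = −(N diag(J) ε)⁻¹ N diag(J), with C^J = ε C^S + I. The derivation
assumes (a) enzyme activity proportional to enzyme concentration, so a
relative enzyme change scales its rate one-for-one, and (b) an asymptotically
stable steady state. Absolute metabolite concentrations cancel from the
scaled formula; this is the load-bearing observation that lets the method
run on saturation, disequilibrium and flux *ratios* alone. If a network has
conserved moieties the reduced system (independent rows of N and the link
matrix, computed exactly over the rationals) is inverted instead; the
bundled proline network has none (rank 6, six flux modes, no left-null
vectors).

## Elasticities

Rates follow the common modular (generalized reversible) rate law without
allosteric terms, v = W·Πα^n·(1−ρ)/D with
D = Π(1+α_i)^{n_i} + Π(1+π_j)^{n_j} − 1. The elasticities used are the
exact logarithmic derivatives of this law (see `kinetics.py`): a
thermodynamic term n_i/(1−ρ) (substrates) or −n_i·ρ/(1−ρ) (products) minus
the logarithmic derivative of D. Two properties are worth stating
explicitly:

- both terms of a product elasticity are negative — in this rate-law family
  a product can never activate the reaction producing it;
- elasticities diverge as ρ → 1, so near-equilibrium reactions behave as
  concentration clamps with vanishing control.

A variant of these formulas circulates in print with the product saturation
term *added* and without the n_i factor in the saturation terms; it is
retained as `mode="printed"` for sensitivity comparisons, but it is not the
derivative of the rate law above and with it product pools can
(unphysically) activate their producers. The default everywhere is the
exact derivative, which is also what makes the finite-difference oracle
(below) directly comparable to the matrix path.

External species — cofactor pools, the arginine source, the urea sink —
contribute saturation factors to D and to the cross-products but have no
row in N, no elasticity column and no control coefficients. The cofactor
assignments of the bundled network (e.g. NADPH/NADP⁺ for GOGAT, P5CS and
P5CR; NH₄⁺, ATP/ADP/Pi for GS; NAD⁺/NADH for GDH and P5CDH) follow standard
plant biochemistry; ProDH is given no sampled cofactor because its electron
acceptor is the membrane quinone pool. Boundary steps bypass the rate law:
the two supplies are constant sources (zero elasticity, matching their role
as exchange with the rest of metabolism) and Pro consumption is first-order
in Pro; both orders are configurable (`BoundaryKinetics`).

## Thermodynamics

ρ = exp(ΔG′_r/RT) per reaction, with ΔG′_r = ΔG⁰′_r + RT·ln Γ′ when a
mass-action ratio is supplied instead. RT defaults to 2.479 kJ/mol (298.15
K) and is configurable because growth temperature varies between
experiments. In the bundled tables exactly two reactions (ARG and ProDH)
have ΔG′_r > 0, i.e. the single-pool concentration estimates would push
them against their known net direction — arginase catalyzes an essentially
irreversible hydrolysis, and ProDH is coupled to the respiratory chain, so
the discrepancy is attributed to the concentration estimates (no
compartmentation; the mitochondrial NAD⁺:NADH and Pro:P5C ratios are not
those of the whole-tissue pools). Their ρ is therefore *adjusted*. The
default rule is `mirror`: ρ → min(1/ρ, rho_cap), placing the reaction as
far below equilibrium as the estimate had placed it above; the alternative
`cap` rule (ρ → rho_cap, default 0.99) pins the reaction just under
equilibrium. The mirror default was chosen because a near-equilibrium clamp
gives ARG and ProDH elasticities of order 1/(1−ρ) ≈ 100, which collapses
their control and freezes the Pro pool they touch — inconsistent with both
enzymes' physiology. The adjustment is flagged per reaction and echoed in
run manifests.

## Monte Carlo sampling

Per run, every (reaction, participant) saturation ratio is drawn
log-uniformly from [0.1, 10] — between one-tenth and ten times the
Michaelis constant, the range usually quoted as physiological — and
independently per reaction (a flag ties draws per species instead). Flux
vectors are sampled as J = B·c with B an exact integer basis of the right
null space of N and coefficients c log-uniform on [0.1, 10], rejecting
candidates until all oriented fluxes are positive (for the proline network
roughly one candidate in thirty is feasible; the rejection count is
reported). Each accepted draw yields one control matrix; draws whose system
matrix exceeds a condition number of 1e12 are discarded and resampled, with
the discard count reported (at default settings none are discarded in
practice, and runs abort if more than 5% are).

Reproducibility: one root seed; attempt k of an ensemble uses the child
stream `SeedSequence(seed, spawn_key=(k,))`, so results are bit-identical
for a fixed configuration, including across discards. Percentiles use
linear interpolation (`numpy.percentile` default); with 1000 runs the P10
and P90 of heavy-tailed distributions are convention-sensitive at the
percent level, so the convention is fixed and documented. Pearson
correlations across runs are reported for all reaction pairs;
zero-variance distributions give undefined (NaN) entries rather than 0.

Ensemble size 1000 follows the bundled case study and converges: two
independent 1000-run ensembles agree in every reaction's median to within
10% relative or a tenth of the P10–P90 spread (tested).

## Finite-difference oracle

`oracle.instantiate` inverts a draw into a concrete kinetic model: Michaelis
constants K_m = S/α at nominal concentrations of 1 (model units), the
saturation-space equilibrium constant from ρ, maximal rates solved from the
drawn fluxes. The nominal state is then a steady state by construction
(residuals < 1e−8 relative, asserted). Control coefficients are re-derived
definitionally: scale one reaction's maximal rate by 1±δ, relax to the new
steady state (stiff BDF integration to t = 1e5 followed by a root polish in
log-concentration space, with a residual check), and form the central
log-ratio ln(S₊/S₋)/ln((1+δ)²·…). At δ = 0.01 the matrix and
finite-difference coefficients agree to better than 1% relative on all
entries with |C| > 0.01 across random draws, and the forward-difference
error shrinks monotonically with δ. Setting nominal concentrations to 1 is
immaterial for the comparison — the same cancellation that removes absolute
concentrations from the matrix method removes them here.

## Numerical choices and degenerate inputs

- Theorem tolerances: summation/connectivity deviations above 1e−9 would
  indicate an implementation or input error; typical values are < 1e−12.
- Singular draws are discarded, never regularized, to keep the sampled
  distribution interpretable.
- ρ ≥ 1 reaching the elasticity layer is a hard error; adjustment happens
  in the thermodynamics layer only.
- Degenerate sampling intervals (lo = hi) are allowed and yield
  deterministic draws; `n_runs = 1` collapses all percentiles onto the
  single run.
- Stoichiometric exponents must be positive integers; a species appearing
  on both sides of one reaction is rejected (the rate-law elasticities are
  not defined for that configuration).

## What the case study does and does not show

The bundled thermodynamic tables are measured/estimated values for two
grassland species under ambient conditions; the sampling intervals and the
ρ-adjustment rule are this package's own defaults, stated above. The
ensembles reproduce the qualitative published control pattern — dominant
negative control by Pro consumption, strong positive control by the
α-ketoglutarate supply, positive ornithine-branch and P5CS/P5CR control,
negative GS/GDH control, small ProDH/P5CDH/GOGAT control, and most of the
published correlation structure. Published distributions are wider and the
enzymatic medians larger by a factor of roughly 2–4, consistent with wider
(unpublished) sampling intervals; one published correlation (ARG–OAT,
+0.64) is not reproduced under the defaults (we obtain ≈ +0.1), which is
sensitive to the unknown adjusted ρ of ARG. Beyond parameter uncertainty,
the model ignores compartmentation (single pools), allosteric regulation,
and any coupling to pathways outside the boundary steps, so conclusions are
about the modeled network, not the whole cell.
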