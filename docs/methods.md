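# Methods

## Model

A community model is a set of organism-level stoichiometric models
joined through a pool of shared extracellular ("community")
metabolites.  Organism *k* has stoichiometry S^k, reactions J^k with
specific-flux bounds LB^k_j ≤ v^k_j ≤ UB^k_j (mmol gdw⁻¹ h⁻¹; the
biomass reaction in h⁻¹), and an exchange map ex(i) naming, for each
community metabolite *i* it can exchange, the reaction that moves it
between the organism's extracellular compartment and the community
space.  Sign convention (declared, used consistently): exchange flux
< 0 is uptake into the organism, > 0 is export — the common SBML
convention.

Under the community steady-state assumption all members share one
time-averaged growth rate μ, since otherwise the fastest grower
displaces the rest and the composition cannot be stationary.  Each
organism receives a biomass variable X^k ≥ 0 and the model is written
in aggregate fluxes V^k_j = X^k v^k_j (mmol h⁻¹):

    Σ_j S^k_ij V^k_j = 0                      (per-organism steady state)
    LB^k_j X^k ≤ V^k_j ≤ UB^k_j X^k           (capacity scales with biomass)
    V^k_biomass = μ X^k                       (common growth rate)
    u_i − e_i + Σ_k V^k_ex(i) = 0             (community balance)
    0 ≤ u_i ≤ uptake_ub_i,  e_i ≥ 0
    Σ_k X^k = X0                              (non-trivial community)

Community uptake bounds are expressed per X0 of total biomass; by
default X0 = 1 gdw so X^k is the relative abundance.  The formulation
is linear at fixed μ and reduces exactly to single-organism FBA when
|K| = 1.

Key structural consequences, both covered by tests: X^k = 0 forces
V^k_j = 0 for every finitely-bounded reaction (no metabolic service
from an extinct member), and maintenance demands (ATPM lower bounds)
scale with biomass rather than with species count.

### Capacity rows and infinite bounds

Each finite bound becomes a one-sided row (V − UB·X ≤ 0, V − LB·X ≥ 0)
so both directions of a reversible reaction scale with X^k.  Rows for
infinite bounds are omitted rather than big-M encoded, avoiding
numerical artifacts; the zero-abundance→zero-flux coupling therefore
only applies to reactions with finite bounds, which is the norm in
published genome-scale models (±1000 defaults).  The toy fixtures use
the same ±1000 convention for exactly this reason.

### Organism-specific uptake caps

When a maximum specific uptake rate r_max for organism k on metabolite
i is supplied (e.g. fiber uptake rates, or the randomized ensembles),
it is imposed as the scaled row V^k_ex(i) + r_max X^k ≥ 0 (uptake being
negative flux).  In the joint-FBA baseline the same cap is the plain
bound v^k_ex(i) ≥ −r_max.

## Growth-rate search

The solver works with the scalar function

    X_T(μ) = max { Σ_k X^k : all constraints above, Σ X^k = X0 dropped }

X_T is non-increasing in μ, and X_T(μ) ≥ X0 iff the full problem is
feasible at μ: every constraint is homogeneous in (V, X), so a
larger-total solution scales down onto Σ X^k = X0 while only relaxing
the fixed community uptake bounds.  Hence μ_max = sup{μ : X_T(μ) ≥ X0}.

The search has two phases, both guided by the empirical shape of X_T.
When a single resource bound limits growth, X_T is exactly hyperbolic —
X_T = c/(μ + d), e.g. U·Y/μ for a yield-Y organism on bound U, or
U/(μ + a) with maintenance a — so a two-point hyperbola fit lands on
μ_max in one step:

1. **Bracketing.** From mu_guess (default 0.1 h⁻¹, inside the
   0.02–0.25 h⁻¹ range reported for gut microbes), step upward or
   downward using the hyperbola fit through the last two evaluations
   (first step: the one-point fit c/μ).  A proposal within mu_tol of
   the current point becomes a +mu_tol probe; if the probe is feasible
   the fit underestimated and the step falls back to geometric growth
   (factor bracket_growth_factor, default 2).
2. **Refinement.** Maintain [lo, hi] with X_T(lo) ≥ X0 > X_T(hi);
   interpolate with the hyperbola fit, clamped strictly inside the
   bracket, falling back to bisection when the fit is degenerate.  A
   candidate glued to lo becomes a lo+mu_tol probe whose infeasibility
   certifies convergence in one LP.

Termination: hi − lo ≤ mu_tol (default 10⁻⁶ h⁻¹, with a 10⁻⁹ relative
slack absorbing floating-point rounding of lo + mu_tol).  On all
fixture families the whole search takes 3–5 LPs independent of the
number of organisms; max_iter (default 50) guards pathological cases.
Feasibility comparisons use the slack feas_tol (default 10⁻⁹) on the
LP-reported X_T.  Because the final lower bracket end is usually the
fit root itself — an LP vertex — the returned μ_max is typically far
more accurate than mu_tol on models with a single binding resource.

Abundances at μ_max come from one final LP with Σ X^k = X0 restored and
a fixed secondary objective (minimize total community uptake Σ u_i) so
the report is reproducible under degeneracy; whether the composition is
*unique* is a question for FVA, never assumed.  Status is
`zero_growth` when X_T(mu_tol) < X0 but the μ = 0 problem is feasible
(the μ = 0 check solves with Σ X = X0 in place, since max Σ X can be
legitimately unbounded when nothing demands flux), and `infeasible`
when even μ = 0 fails (maintenance unpayable under the given uptake
bounds).  An unbounded X_T aborts with a message naming the community
metabolites that lack uptake bounds.

`iterations` counts LPs solved during bracketing + refinement,
excluding the final abundance solve.

## Variability and dependency analyses

At any μ0 ≤ μ_max the constraint set is a polytope;
`steadycom_fva` minimizes and maximizes arbitrary weighted sums of
aggregate fluxes and abundances over it (unbounded directions reported
as ±inf).  `abundance_fva` tabulates per-organism abundance ranges at
fractions of μ_max.  `pairwise_fva` pins one organism's abundance at
grid values (default 30 log-spaced points in [10⁻³·X0, X0]) and records
the allowed range of a second; grid points where the community is
infeasible are marked absent.  The scan is classified
**competitive** when the dependent organism's ceiling is non-increasing
along the grid and **conditionally mutualistic** when a region of
positive slope exists; slope detection uses a finite-difference
tolerance of 10⁻⁶·max(1, X0) to ignore LP degeneracy noise on flat
segments.  FVA LPs are independent; results do not depend on
evaluation order.

## Diet bounds and uptake-rate ensembles

`diet_to_uptake_bounds` converts a daily diet to community uptake
bounds: for each food row, mass (g day⁻¹) × molar composition
(mmol g⁻¹) × (1 − host absorption for its macronutrient category),
divided by 24 h and by the community biomass the fluxes are spread over
(default 10 gdw for a human gut community), scaled to X0.  Default
absorption fractions: carbohydrate 0.97 (alternatives 0.95/0.99),
amino acids 0.90, fatty acids 0.90, fiber 0.00.  The day→hour
conversion uses a flat 24 h; meal-timing structure is not modeled.

`sample_uptake_bounds` draws ensembles of per-organism maximum specific
uptake rates for carbon sources.  For each organism the *total* carbon
uptake capacity is drawn from the named law — exponential with the
requested mean, or uniform on [0, 2·mean] — and partitioned across the
organism's carbon sources proportionally to i.i.d. Exp(1) draws; each
source's rate is its carbon allotment divided by its carbon count, so
the C-weighted sum equals the drawn total exactly.  Drawing the total
(rather than per-source rates that are then rescaled) matches the
convention of stating ensemble means as "total carbon uptake per
organism".  Carbon counts are supplied as an explicit table rather than
parsed from formula annotations, which are unreliable across models.
Sampling uses numpy's PCG64 generator; identical seeds give identical
ensembles across platforms.

`run_ensemble` applies each bound set, solves (community steady state
or joint FBA), and summarizes per-organism abundance distributions
(mean, std, 2.5/25/50/75/97.5% quantiles), with optional aggregation by
an organism→taxon map.  For joint FBA the "abundance" analog is each
organism's share of total biomass flux.  Failed or zero-growth sets are
counted and excluded; failures are logged, never fatal.

## Synthetic fixtures

The generators in `steadycom.fixtures` produce communities with
closed-form optima (units abstract, yield-1 conventions; they target LP
correctness, not physiology):

* **single-organism toy** (uptake u, yield Y): μ_max = u·Y/X0.
* **maintenance (ATPM) toy** (n members, demand a, uptake U):
  μ_max = U − a independent of n; joint FBA total = U − n·a.
* **auxotroph ring** (n members): each consumes 1 unit of its
  predecessor's amino acid per unit growth and exports `export_yield`
  units of its own.  μ_max = U·Y/X0; every member is obligate.
  export_yield = 1 forces the unique equal-abundance composition;
  the default 1.5 leaves slack that produces nontrivial FVA bands and
  the conditionally-mutualistic pairwise pattern.
* **converter toy**: a high-yield grower that needs a derived substrate
  producible only by a low-yield converter through a dedicated,
  growth-independent conversion reaction (finite specific rate cap).
  Joint FBA lets the converter work without growing; the steady-state
  community must allocate it real biomass — the qualitative contrast
  between the two methods on communities with degrader species.

`brute_force_mu_max` is the independent oracle: a multi-resolution
feasibility grid scan (each stage a fixed-step sweep over the surviving
interval, refined 10× per stage down to the requested step), one LP per
grid point, no interpolation.  Fixture optima asserted in tests were
confirmed against this oracle and, for the single-organism case,
against cobra's FBA on independently hand-built models.

## What the fixtures do and do not show

The fixtures exercise every constraint type the formulation contains —
scaled capacity, growth coupling, community balance, maintenance,
obligate cross-feeding, growth-independent conversion — at sizes where
the optima are analytic, so passing tests show the LP assembly, search,
and analyses are correct.  They do not probe genome-scale numerics
(thousands of reactions, wide coefficient ranges, thermodynamically
infeasible cycles), model curation questions, or the biological realism
of any particular uptake parameterization; conclusions about real
communities additionally depend on the quality of the input models and
bounds.  Problem sizes throughout (rings up to 16 members, ensembles of
200 draws, 30-point pairwise grids) were chosen so the full suite and
the acceptance script each run in well under a minute of LP time while
still covering the scaling claims.

## Numerical choices

* LP backend: scipy's HiGHS interface behind a single `solve_lp`
  contract; swapping solvers means reimplementing that function.
* zero_tol = 10⁻⁸ gdw for declaring an organism absent when deriving
  specific fluxes (LP solver tolerance scale).
* mu_tol 10⁻⁶ h⁻¹, feas_tol 10⁻⁹, mu_guess 0.1 h⁻¹, max_iter 50,
  bracket growth factor 2 (see above for rationale).
* Degenerate abundance reports are pinned by the min-Σu secondary
  objective; ties inside that optimum are resolved by the solver's
  vertex choice and are deterministic for a fixed backend.
* Toy SBML export writes infinite bounds as FBC infinities so models
  round-trip exactly; metabolite ids ending in an extracellular tag
  (`_e`, `[e]`, `_e0`) map to community metabolites by stripping that
  one tag, and an explicit alias table covers models whose ids do not
  line up.
* Biomass identification in SBML: the FBC objective if unique,
  otherwise a case-insensitive id match on "biomass" (logged); an
  ambiguous objective is an error.

## Known limitations

* Organism-specific dilution rates (members washing out at different
  rates) are not modeled; all members share one μ.
* No thermodynamic loop removal: models containing energy-generating
  cycles must be curated upstream.
* The abundance report at μ_max is one vertex of a possibly degenerate
  optimum; always pair it with `abundance_fva` before interpreting
  uniqueness.
* Bilevel community/individual objectives, dynamic simulation, and
  random flux sampling of the community polytope are out of scope.
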