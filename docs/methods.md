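# Methods

## Model representation and LP formulation

A model is a set of metabolites (rows of the stoichiometric matrix S) and
bounded reactions (columns), with a designated biomass objective. Fluxes
are in mmol g-DW⁻¹ h⁻¹; the biomass pseudo-reaction produces 1 g dry
weight per unit flux, so its flux is µ in h⁻¹ and all yields follow the
single conversion `Y (g-DW mol⁻¹) = 1000·µ/q_s`, centralized in one
constant (`constants.MMOL_PER_MOL`). Exchange pseudo-reactions touch one
metabolite (or carry the conventional `EX_` prefix); a negative exchange
flux is uptake, a positive one secretion. Protocol layers always speak in
positive uptake magnitudes and translate through the model's sign helpers,
so user-facing numbers stay positive regardless of how a file writes its
exchanges.

The LP has one variable per reaction and one equality row per metabolite
(S·v = 0); no matrix inversion anywhere. The backend is HiGHS via
`scipy.optimize.linprog` with primal/dual feasibility tolerances of 1e-9 —
tight enough that reported objective values are stable far below the one-
decimal precision at which yields are quoted. Statuses map to
optimal/infeasible/unbounded; an infeasible flux-variability query raises
rather than returning (0, 0), so "no feasible flux" can never be confused
with "forced to zero".

Degeneracy policy: FBA flux vectors are generically non-unique, so no
protocol reads a single flux off a solve to decide whether a reaction is
active. Activity is a range statement: `flux_range` minimizes and
maximizes the target over the (near-)optimal face, with the optimum pinned
through a bound with relative slack 1e-9 to avoid an exactly-degenerate
equality at the solver's own tolerance. A flux is "nonzero" above 1e-6
mmol g-DW⁻¹ h⁻¹ — above solver noise, far below any biologically
meaningful flux.

## I/O

SBML is read and written through python-libsbml. Reading accepts Level 3
with the `fbc` package (bounds as parameters, objective via the active fbc
objective, gene products mapped back to labels) and Level 2 with bounds as
kinetic-law parameters named `LOWER_BOUND`/`UPPER_BOUND` and
`GENE_ASSOCIATION:`/`FORMULA:` notes — the dialect SEED-era exports use.
Missing bounds default to [-1000, 1000] for reversible and [0, 1000] for
irreversible reactions (the community convention for "effectively
unbounded"). Without an fbc objective, a reaction whose id or name
contains "biomass" is taken as the objective.

The two-file tab format is this package's documented schema (the deposited
listings are named in the literature but their columns are not): reactions
as `id, name, equation, lower_bound, upper_bound, gene_association,
subsystem` with an optional `# objective: <id>` comment, metabolites as
`id, name, formula, charge, compartment`. The equation grammar is
`2 A + B --> C` (an empty side encodes an exchange; `<=>` marks
reversibility informatively — the bound columns are authoritative). Bounds
and coefficients are serialized with full float precision (`repr`), which
is what makes the write→parse round trip exact field-by-field. Column-name
variants (`lb`, `lower`, `gpr`, ...) are accepted; unrecognized columns
are recorded in the model annotations instead of being silently dropped.

Mass-balance checking is element-wise on parsed formulas: a non-exchange
reaction is balanced iff every element's coefficient-weighted net count is
zero; any reaction touching a formula-less metabolite is "unverifiable",
never "imbalanced"; exchanges are excluded by construction.

## Protocols

* **Maximal theoretical yield.** Substrate uptake fixed to 1 mmol g-DW⁻¹
  h⁻¹, non-growth ATP hydrolysis fixed to 0, biomass maximized. A model
  that cannot grow returns an explicit zero-yield result with a
  diagnostic, because "no growth on this substrate" is a finding, not an
  error.
* **Batch yield.** Biomass fixed to the measured µ, maintenance fixed
  (default 5.5 mmol ATP g-DW⁻¹ h⁻¹, the low end of the chemostat-derived
  7.5 ± 2 interval, kept as a separate named constant), substrate uptake
  minimized. Minimizing an uptake means driving the signed exchange flux
  toward zero from the import side; reversible-flux minimization is signed
  unless an absolute-value split is requested, which no protocol here
  needs (all minimized fluxes are irreversible supplies or imports).
* **Denitrifying yield.** The medium's O₂ exchange is removed from the
  uptake set, nitrate is opened, N₂ (like all secretions) is free to
  leave; otherwise identical to the batch protocol.
* **ATP yield.** Growth fixed to 0, uptake fixed to 1, flux through the
  ATP hydrolysis reaction maximized. The maintenance reaction is located
  by annotation, by an `ATPM`-like id or "maintenance" name, or by the
  stoichiometric pattern ATP + H₂O → ADP + Pi (+ H) with no other
  participants.
* **Mixture-ratio scan.** For each ratio r, one irreversible pseudo-
  reaction supplies r mol of the numerator substrate per mol of the
  denominator substrate; direct uptake exchanges of both components are
  closed so the mixture is the only way in. At fixed µ and maintenance the
  supply flux is minimized, then the target's flux range is measured with
  the supply pinned at its optimum; fluxes are reported per mol of
  denominator substrate consumed. Infeasible ratios are flagged and the
  scan continues (a scanned interval may legitimately contain infeasible
  extremes). The activation threshold is the smallest grid ratio whose
  minimal target flux exceeds the nonzero tolerance, refined by bisection
  between the bracketing grid points to a resolution of 0.01.
* **Maintenance estimation.** Per condition,
  `m_ATP = Σᵢ yieldᵢ·m_s,ᵢ`; mean and sample standard deviation (ddof=1)
  over conditions. Two mannitol ATP-yield coefficients circulate in the
  source material for this organism (29.1 in the combination equation,
  29.7 in the running text); both are exported as named constants and the
  choice is always explicit at the call site.
* **Leak check.** Every exchange not in the inorganic keep-open set has
  its uptake closed (secretion untouched); the model passes iff maximal
  biomass is ≤ 1e-6 with maintenance pinned to zero — the most permissive
  setting, so even marginal mass creation is exposed.

Media are explicit objects: a map from exchange id to maximal uptake, with
everything else closed for uptake and secretion never touched. The
`inorganic` factory opens O₂, water, protons, phosphate, ammonium,
sulfate and trace elements by metabolite id stem or name, keeps CO₂ and N₂
secretion-only, and leaves nitrate closed unless the anoxic variant is
requested. It is a heuristic convenience — any real study should pass an
explicit medium.

## Pirt fitting

Ordinary least squares of q_s on µ (scipy's linregress): intercept = m_s,
slope = 1000/Y^max, standard errors from the residual variance (defined
for n ≥ 3). No weighting, because the chemostat literature this serves
reports no per-point error model; equal-variance residuals are assumed. A
non-positive slope leaves the yield undefined and raises a diagnostic
error rather than reporting a negative Y^max. `uptake_ratio` evaluates
q_A(µ)/q_B(µ) from two fits; it tends to the slope ratio as µ grows and to
the maintenance ratio as µ → 0.

## Synthetic networks: what they emulate, and what they do not

The generators produce small mass-consistent networks (formulas attached
where elemental bookkeeping is meaningful) with analytically known
behavior:

* *linear* — a chain whose maximal yield at unit uptake is exact by
  construction; anchors the unit convention.
* *dual_pathway* — two stoichiometrically equivalent branches; closing
  either must leave every yield unchanged while each branch's flux range
  spans (0, total). This is the degenerate-alternatives situation (e.g.
  the two propionyl-CoA assimilation routes).
* *respiratory* — oxidation routes with different ATP-per-substrate
  stoichiometries around an explicit ATP/ADP/Pi cycle and an ATPM sink;
  O₂-dependent by construction, so the anoxic protocol is infeasible on
  it. On this family the Pirt loop closes exactly:
  q_s = m_ATP/ATP-yield + 1000·µ/Y^max.
* *dual_substrate* — an energy-only C1 substrate (oxidation yields k_C1
  ATP and one fixable CO₂), a carbon substrate (direct assimilation or
  burning for ATP), and a fixation reaction consuming CO₂ plus ATP. A
  forced activation threshold exists only when fixation is an energy sink
  of last resort (its ATP cost exceeds the ATP yield of burning the
  carbon substrate); the defaults place the threshold at
  (b_A·µ + m)/(k_C1·b_P·µ) = 2.5 at µ = 0.3 h⁻¹ and maintenance
  7.5 mmol g-DW⁻¹ h⁻¹ — the operating point of the mixed-substrate
  experiments this emulates. The generator returns the exact threshold
  from an internal oracle that solves the balance equations directly on a
  dense ratio grid with bisection, sharing no code with the protocol
  layer: a test oracle must not inherit the bug it guards against.
* *leaky* — a deliberately defective model containing an internal
  water→AMP reaction, so it grows with every organic uptake closed. The
  defect is internal rather than an open AMP exchange because the leak
  check closes all non-inorganic exchanges by construction; an internal
  mass-creating reaction reproduces the observable (carbonless growth)
  that distinguishes a broken automatic reconstruction from a curated one.
* *chemostat_dataset* — q_s = m_s + 1000·µ/Y^max + N(0, σ), from an
  explicitly seeded generator; no global random state anywhere.

What passing on these networks shows: the LP core, the sign conventions,
the degeneracy handling, the threshold logic and the statistics are
correct. What it does not show: anything about the biological fidelity of
a real genome-scale reconstruction — compartments, cofactor specificity,
many-thousand-column numerics are exercised only when the deposited model
is supplied.

## Numerical and design choices

* Solver tolerance 1e-9; nonzero-flux threshold 1e-6; steady-state
  residual verified to ≤ 1e-6 for every optimal state in the tests.
* Supply pinning in the scan uses relative slack 1e-9 rather than an
  exact equality at the optimum, trading an immeasurably conservative
  forced-flux for robustness at the solver tolerance.
* Threshold bisection treats an infeasible probe as "not active", which
  is the conservative direction (it can only push the detected threshold
  up, never invent one).
* The statistical recovery test checks interval coverage with a one-sided
  binomial test of the hypothesis "coverage ≥ 90%" at 200 replicates: an
  empirical proportion from finitely many replicates fluctuates around
  the true rate, so a point comparison against the nominal level would
  reject correct intervals with substantial probability.
* Problem sizes in the default test run and the acceptance script are the
  toy networks (4–11 reactions), 200-replicate regression studies and a
  101-point ratio scan — sizes at which every expected value is either
  closed-form or exhaustively enumerable.

## Known limitations

* No kinetic/dynamic FBA, no thermodynamic or loopless constraints, no
  quadratic objectives, no full-network FVA batch mode.
* The fraction of C1 substrate assimilated is reported only as forced
  fixation flux per substrate consumed; no atom mapping or isotope
  labeling is modeled.
* The inorganic-medium factory is a name heuristic; on models with opaque
  metabolite ids an explicit medium must be supplied.
* The tab parser assumes one record per line and tab-free names.
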