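# Methods

## Scope

`planoflux` models the growth of a filamentous actinomycete (the GE2270A
producer *Planobispora rosea*) through a phosphate-starvation transition,
and implements the statistics used alongside such a fermentation study:
TPM normalization, ANOVA with FDR control, temporal trend clustering, and
rank-based group enrichment (iGA).  Everything runs from synthetic inputs
generated inside the package; a user's own genome-scale model (SBML L3+fbc
or the package's JSON dialect) and count matrices drop into the same
interfaces.

## Constraint-based core

A model is metabolites, reactions with signed stoichiometry and bounds,
boolean gene rules, and one objective reaction.  FBA maximizes the
objective flux subject to S·v = 0 and the bounds (HiGHS via
`scipy.optimize.linprog`; feasibility tolerance 1e-9).  Because alternate
optima would make the exchange fluxes that drive the dynamic simulation
ill-defined, every solve runs a second, parsimonious stage: the objective
value is fixed and the total absolute flux is minimized.  Reported
solutions are checked against |S·v| ≤ 1e-6 per metabolite; violations
raise rather than propagate.  Sign convention: negative exchange flux is
uptake; exchange ids start with `EX_` and touch exactly one extracellular
metabolite.

Orthology-based pruning removes a reaction iff its gene rule evaluates
false when genes outside the retained set are treated as absent; rules are
infix and/or expressions with parentheses, case-insensitive.  Reactions
without a rule survive, orphaned metabolites are dropped.  The operation is
idempotent and monotone in the retained set.

## The starvation extension

Under phosphate limitation, Gram-positive bacteria can swap the
phosphate-rich wall teichoic acid (TA) for phosphate-free teichuronic acid
(TUA), scavenging the phosphodiester phosphate.  The extension adds, to
any model carrying UDP-N-acetylglucosamine and UDP-d-glucuronate:

* a reversible UDP-N-acetylglucosamine 4-epimerase (galE-type, gene
  EV45_RS04840) producing UDP-N-acetylgalactosamine;
* a teichuronate synthase consuming `polymer_units` (default 25) each of
  UDP-N-acetylgalactosamine and UDP-d-glucuronate per polymer — equal
  proportions of the two sugars — and releasing the UDP moieties;
* an alternative biomass reaction: the original with its TA term replaced
  by an equimolar TUA term, created closed (regime control opens it);
* the wall replacement reaction: 1 TA polymer + the UDP-sugar precursors
  of one TUA polymer → 1 TUA polymer + `polymer_units ×
  phosphate_per_ta_unit` inorganic phosphate + the dephosphorylated TA
  backbone.  The backbone leaves through a dedicated sink, and TUA built
  into the pre-existing wall (rather than into new biomass) leaves through
  a demand reaction; both carry zero phosphorus, so the replacement is
  exactly P-balanced.  The two outlets are this package's design choice:
  the replacement acts on the existing wall, so its TUA output cannot be
  forced through the new-biomass TUA demand without artificially coupling
  wall turnover to the growth rate.
* a "lumped product" helper adds one irreversible global reaction plus an
  exchange for a secondary metabolite whose pathway is unresolved (used
  for the GE2270A stand-in).

`phosphate_per_ta_unit` defaults to 1 — one phosphodiester phosphate per
glycerol/ribitol repeat unit of wall teichoic acid — and is configurable.
All extension operations are idempotent, preserve model validity, and
assert phosphorus balance whenever the involved metabolites carry
phosphorus counts.

## Kinetic priors

Seven parameters govern the dynamics: Vmax and Km for glucose uptake,
phosphate uptake, and teichoic-acid conversion (mmol/gDW/h and
mmol/liter), plus a constant maximum O2 uptake.  Each has a log-normal
prior stated as a mode with a central 95% interval, taken from
measurements on related organisms:

| parameter | mode | 95% interval | units |
|---|---|---|---|
| O2 Vmax | 12 | [6.7, 15] | mmol/gDW/h |
| glucose Vmax | 10 | [9.6, 15] | mmol/gDW/h |
| glucose Km | 3 | [1.5, 6] | mmol/L |
| phosphate Vmax | 0.13 | [0.108, 0.156] | mmol/gDW/h |
| phosphate Km | 0.065 | [0.054, 0.078] | mmol/L |
| TA Vmax | 10 | [1, 100] | mmol/gDW/h |
| TA Km | 0.015 | [0.0015, 0.15] | mmol/L |

The interval is authoritative: μ = (ln lo + ln hi)/2 and
σ = (ln hi − ln lo)/(2·z), z = Φ⁻¹(0.975), so the fitted median equals
the geometric mean of the bounds and the interval carries exactly 95%
mass.  For five parameters the stated mode equals that geometric mean
(to its printed precision); for the O2 and glucose Vmax the printed mode
and interval are mutually inconsistent under any single log-normal, so
the interval wins and the mode is kept as metadata.  For the wide TA
priors the printed "mode" coincides with the fitted median, not the
log-normal mode exp(μ − σ²) — a terminology wrinkle we record rather than
resolve.  Sampling drives one seeded NumPy generator; parameters are drawn
in alphabetical name order so seeds are portable across prior subsets.

## Two-regime dynamic FBA

Static-optimization dFBA on a fixed grid (forward Euler, default
dt = 0.05 h over 30 h).  Defaults mirror a minimal glucose medium with
low phosphate: glucose 222.2 mM, phosphate 4.6 mM, biomass 0.5 gDW/L.

**Normal growth** — glucose and phosphate uptake bounds follow
Michaelis–Menten kinetics in the extracellular concentrations,
v = Vmax·c/(Km + c); O2 uptake is capped at its Vmax; all other nutrient
exchanges are opened to −1000 (effectively unlimited); wall TA is made as
part of biomass; the replacement reaction is closed.

**Starvation** — entered permanently at the first grid point where
extracellular phosphate falls below the threshold (default 0.1 mM, the
concentration at which the Pho regulon activates in a related
streptomycete).  Phosphate uptake and TA synthesis close, the alternative
biomass becomes the objective, and the replacement reaction opens with a
Michaelis–Menten bound evaluated at the teichoic-acid pool.

The TA pool is tracked in mmol polymer per liter of culture: initialized
as biomass₀ × (biomass TA coefficient), it grows with biomass during
normal growth (the synthesis flux at steady state is exactly the biomass
demand) and is drawn down by the replacement after the switch.  Whether
oxygen should be depleted dynamically is not specified by the physiology
we target; it is held as a constant bound.  Only extracellular phosphate
is compared against the threshold — wall-bound phosphate does not count.

Euler updates: X' = X(1 + μ·dt); c' = c + v_ex·X·dt per tracked
metabolite; pool' = pool + (v_synth − v_repl)·X·dt.  If any pool would
cross zero, the entire step's fluxes are rescaled so the limiting pool is
exhausted exactly (a limiting-substrate sub-step).  Rescaling the whole
step rather than the clipped pool alone keeps elemental bookkeeping exact:
growth cannot consume phosphate whose release was clipped away.  With
that rule, total phosphorus (extracellular + biomass-bound + wall pool)
is conserved to floating-point accuracy on the toy model; the test suite
asserts it within O(dt) to stay agnostic about future model variants.
An infeasible FBA step contributes zero growth and carries the state
forward; when glucose is exhausted before the switch, growth stops and
the state freezes (no maintenance or death term is modelled).

On the built-in toy model the pre-switch growth rate is constant whenever
the Michaelis–Menten factors saturate, so the switch time has a closed
form t* = (1/μ)·ln(1 + (pi₀ − threshold)/(q_P·X₀)) with q_P the total
phosphate drain per gDW grown; the simulator reproduces it within 2·dt.

## Ensemble summaries

`run_ensemble` draws n parameter sets (default study size 1,000),
simulates each on the shared grid, and summarizes:

* **medoid** — the member minimizing the summed Euclidean distance to all
  others over the concatenated state series (biomass, glucose, phosphate,
  TA pool), each variable z-scored with its global ensemble mean/sd so no
  scale dominates; ties break to the lowest index.  The metric is this
  package's choice — the summarized study does not define one.
* **bands** — pointwise central 95% intervals: per variable and grid
  point, the 2.5th/97.5th empirical percentiles with linear interpolation
  between order statistics ("type 7").  Pointwise bands were chosen over
  whole-trajectory selection; users comparing against envelope-style
  figures should note the difference.
* **switch times** — one per member (absent if a member never switches).

Members are independent with pre-assigned draws, so any execution order
reproduces the identical result for a given seed.

## Omics statistics

* **TPM**: per sample, rate = count/length, TPM = 1e6·rate/Σrate; columns
  sum to 1e6; all-zero samples stay zero.  A detection helper flags
  features whose per-time-point mean exceeds 5 TPM at any time point.
* **ANOVA + BH**: one-way fixed-effects ANOVA across time points on
  log2(count/size-factor + 1) with median-of-ratios size factors — a
  documented substitution for a regularized-log transform, keeping the
  test structure identical while remaining dependency-light.  Features
  constant across all samples get p = 1 so the BH denominator is stable.
  BH step-up adjustment; significant iff adjusted p < α (default 0.05).
  Metabolite-style selection adds a max |log2 fold change| > 1 gate over
  per-time-point means, with zero means replaced by the smallest positive
  value in the profile matrix before taking ratios.
* **Trend clustering**: per-feature z-scored time-point means, k-means
  (k = 8, 50 k-means++ restarts under the user seed).  Clusters are
  relabeled A, B, … deterministically: by time of centroid peak, then by
  size, then by the centroid profile itself, so identical partitions get
  identical letters regardless of k-means' internal label order.
* **iGA**: for a group of K features inside a ranked list of N, the
  PC-value is the minimum over member-occupied ranks t of
  P(X ≥ x_t), X ~ Hypergeometric(N, K, t), with x_t the members at rank
  ≤ t.  The tail is accumulated from log-gamma terms (logsumexp), so
  values at the 1e-92 scale retain full relative precision; a result
  within 1e-12 of certainty in log space is reported as exactly 1.  The
  minimum over member-occupied ranks equals the minimum over all cutoffs,
  since the tail only grows between member ranks; the test suite checks
  equality against an exact-rational brute force over all cutoffs.

## Synthetic data

* **Toy model** (~25 reactions after extension): exchanges for glucose,
  phosphate, O2, ammonium and the product; lumped catabolism (1 glucose +
  1 O2 + 0.2 ammonium → 1 precursor); UDP-sugar supply; TA synthesis
  (25 phosphate + 25 precursor per polymer); UDP recycling; a biomass
  consuming precursor, phosphate (0.8 mmol/gDW) and TA (0.008 mmol
  polymer/gDW ≈ 0.2 mmol wall P/gDW, a realistic cellular P partition);
  and the full starvation extension.  The biomass precursor coefficient
  is net of the wall's precursor cost, so glucose-limited growth is
  exactly glucose_yield × v_glc (default yield 0.05 gDW/mmol), and every
  non-boundary, non-biomass reaction is phosphorus-balanced by
  construction.  With the central priors the phosphate-limited growth
  rate is 0.13 h⁻¹ and the switch falls at ~18 h — the same qualitative
  trajectory shape as the organism-scale study (exponential growth, switch,
  brief wall-scavenging, near-arrest), at toy magnitudes.
* **Counts**: eight temporal archetypes over the 15/24/39/48/63 h ×
  3-replicate design, chosen mutually well separated after z-scoring so
  shapes remain distinguishable at realistic noise; per-feature log-normal
  baselines (~2 orders of magnitude); negative-binomial noise with
  variance m + φm² (default φ = 0.1, typical RNA-seq overdispersion);
  optional flat null features.  What passing tests show: the pipeline
  recovers planted structure under NB noise of this magnitude.  What they
  do not show: robustness to library-size artifacts, batch effects,
  zero-inflation, or correlated genes — real data properties the
  generator does not emulate.
* **Ranked lists**: a group with a chosen number of members placed
  uniformly in the top decile, the rest uniformly below.

## Numerical choices and limitations

* LP feasibility 1e-9; steady-state check 1e-6; ties in FBA broken
  parsimoniously; quantiles type 7; k-means restarts 50.
* The regime switch is irreversible and grid-quantized (first crossing),
  so switch times carry O(dt) discretization error; dt is configurable.
* Problem sizes in the shipped tests and the reproduction script are
  scaled to desk hardware: ensembles of 3–100 members at dt 0.1–0.5 h
  instead of 1,000 at 0.05 h.  The ensemble machinery is size-agnostic;
  the full study size is a flag away.
* Trajectory magnitudes of the organism-scale study depend on its full
  genome-scale model (distributed separately); the toy model reproduces
  mechanisms and closed forms, not those magnitudes.
* No maintenance energy, death phase, oxygen transfer, or pH; kinetics
  constrain only uptake/conversion bounds, not intracellular reactions.
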