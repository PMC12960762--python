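# Methods

## Model structure and assumptions

The model is a discrete-time cohort Markov state-transition model over ten
states: the Cartesian product of dementia severity {mild, moderate, severe}
and care setting {no formal care, home care, institutional care}, plus one
absorbing death state. The canonical ordering is severity-major,
care-minor, death last; state names serialize as `mild|no_formal_care` …
`severe|institutional_care`, `death`.

Three conditional components define one cycle, composed in a fixed order:
death is resolved first (probability `p_death(severity, care)`), survivors
then progress in severity (stepwise `p_progress`; mild→severe in one cycle
is structurally zero), and finally care transitions occur with
probabilities conditioned on **start-of-cycle** severity. Conditioning care
on start-of-cycle rather than post-progression severity is a deliberate,
non-configurable choice: it keeps the cycle matrix an exact product of the
three supplied components and removes any ambiguity about which severity a
care probability refers to. Severity never regresses; care never regresses
unless `allow_care_reversal` is set (forward skips such as no formal care →
institutional are allowed slots that may be zero). Row closure is by the
residual stay probability, so modifying one outgoing probability never
rescales the others.

All probabilities in a configuration are **per cycle**; no rate rescaling
is applied to inputs. The default cycle length is one month (1/12 year) so
that pilot-scale persistence windows of a few weeks to months are
representable on the cycle grid. Mortality is constant per (severity,
care) pair — no age or calendar-time dependence.

## Cohort accounting

Occupancy is recorded at cycle boundaries; row 0 is the initial
distribution (default: the whole cohort in mild dementia with no formal
care, the community-dwelling population that early-stage technologies
target). "Lifetime" horizon is realized as a fixed maximum (default 40
years of cycles) with a convergence stop once living mass falls below
1e-8.

Time in state credits end-of-boundary occupancy; the optional half-cycle
(trapezoid) correction, on by default for reported results and off for
closed-form checks, credits the average of adjacent boundaries. Under
these conventions the undiscounted expected number of cycles spent in
transient state *j* equals `N − I` (no correction) or `N − I/2`
(trapezoid) where `N = (I − Q)⁻¹` is the absorbing-chain fundamental
matrix; the test suite verifies both identities.

Discounting is annual-rate, compounded per cycle: cycle *t* (1-indexed)
is multiplied by `(1 + r)^(−t·cycle_length)`; the first cycle is
discounted. Costs and effects use separate rates, defaulting to 4% and
1.5% respectively (the Dutch guideline convention), both overridable.

## Valuation

QALYs accumulate as occupancy × utility × cycle length. The caregiver
stream is a per-cycle utility increment or decrement attached to the
*patient's* state — one caregiver per patient, ending at the patient's
death (no bereavement effects) — and is always reported separately from
patient QALYs. Costs take a societal perspective: formal care cost per
year of occupancy, plus informal caregiving hours/week × 52.18 weeks/year
× a single opportunity-cost wage, plus the intervention's own cost.
Currency is an abstract label (default EUR) with no inflation indexing.
The intervention cost stream accrues over start-of-cycle occupancy of
eligible states, only within the persistence window; being a payment
stream rather than occupancy, it is discounted but not trapezoid-corrected.

Comparison is pairwise against usual care: ΔQ, ΔC, ICER = ΔC/ΔQ when
|ΔQ| > 1e-12 and otherwise a label (`dominant`, `dominated`,
`undefined (dQ=0)`), and NMB(λ) = λ·ΔQ − ΔC over the willingness-to-pay
grid. No multi-strategy efficiency frontier is computed.

## Intervention effects

Relative risks on care transitions are applied on the rate scale,
`p′ = 1 − (1 − p)^rr`, i.e., the reported RR is treated as a hazard ratio
under cycle-constant rates. This keeps any rr > 0 inside [0, 1) (a
`nextafter` guard absorbs the one-ulp float rounding possible at extreme
rr) and makes several effects on the same transition compose
multiplicatively on the rr scale — an independence assumption. Value
effects are absolute per-year deltas; resulting utilities are clamped to
[−1, 1] and hours/costs floored at 0, each with a warning.

Effects apply only where the technology is in use: transition effects to
rows whose source state is eligible, value effects to eligible states.
Persistence is a required strategy field with no default — how long pilot
effects last is exactly the assumption an early model must make explicit.
Optional linear waning appends a tail of `w` cycles over which deltas
scale by `(w − k)/(w + 1)` (k cycles into the tail) and RRs interpolate
toward 1 on the log scale. At any cycle beyond the window the effective
parameters are the baseline objects themselves, so reversion is exact,
not approximate; null effects (delta 0, rr 1) are dropped at construction
so nominally-null strategies take the identical code path as usual care
and reproduce it bitwise.

## Surrogate translation

Directly applicable pilot outcomes (utility, caregiving hours/week, formal
resource use in currency/year, admission risk as a **log** relative risk so
that zero is uniformly the null) become effects verbatim. Everything else
passes through a surrogate link — a per-unit coefficient with a citation
label, shipped as *data* in the configuration, never hard-coded. The one
default exemplar is the functional-ability link: 0.008 utility per
ADCS-ADL point. Transition links are log-linear (`rr = exp(effect ×
log-RR/point)`), value links linear. Link coefficients are
severity-invariant by default.

Double-counting is guarded at assembly: a directly measured
quality-of-life effect excludes every surrogate-to-utility link, and no
single outcome may feed both the utility and the transition pathway.
Functional or behavioral outcomes feeding only care transitions are always
admissible — these technologies are modeled as changing *care use*, never
disease progression, which also avoids indirect mortality benefits that a
progression pathway would smuggle in.

## Uncertainty analysis

Parameter priors follow health-economic convention: beta for probabilities
(moment-matched from mean and SE; an SE too large for the beta support is
an error, not a silent clamp), gamma for non-negative quantities,
lognormal for positive ratios, Dirichlet for whole care-transition rows
(counts with the stay destination first). Parameter addressing uses dotted
paths into the configuration document; every draw re-validates the
document, and a draw violating an invariant aborts the PSA with its index.

PSA re-runs control and intervention on the **same** drawn baseline
(common random baseline), so increments are differenced within a draw.
The CEAC reports P(NMB > 0) per willingness-to-pay value, ties counting
as not cost-effective. Tornado analysis varies one parameter at a time at
fixed WTP and sorts bars by |NMB(high) − NMB(low)|. Scenarios are named
override bundles (e.g., best/worst case over surrogate-link coefficients
and persistence) applied before validation.

Because the model response is nonlinear in its parameters, the PSA mean of
(ΔQ, ΔC) carries an O(σ²) bias relative to the base case even with priors
centered there, while the Monte-Carlo band shrinks as σ/√n. The
mean-recovery check in the test suite therefore runs in the small-variance
regime (prior SEs scaled to a quarter of the exemplar values, n = 2000),
where the linearization holds and the mean lies within three standard
errors of the base-case increments; at the exemplar's 20–30% SEs the bias
itself is the dominant term, which is expected behavior, not a defect.

## Synthetic fixtures

The generator emulates the qualitative structure of the dementia care
pathway — utility strictly declining with severity and care intensity,
total annual cost strictly rising toward institutional care, death risk
and care escalation non-decreasing in severity — with seeded multiplicative
jitter. One jitter factor is drawn per base quantity (shared across the
graded dimension), never per cell, so the orderings survive any jitter
width. All magnitudes (utilities ≈ 0.85/0.65/0.45, institutional cost
≈ €65k/year, monthly transition probabilities of order 10⁻³–10⁻²) are
ILLUSTRATIVE defaults chosen for qualitative plausibility; they are not
estimates of any registry or trial, and no calibration machinery exists.
Pilot effects are emitted for the implemented outcome list with follow-up
lengths of 2–12 weeks and small-pilot standard errors.

Consequently, passing tests demonstrate the *mechanics* — conservation,
reversion, direction of effects, dominance logic, seed determinism — not
the realism of any number. Real analyses must supply their own parameter
table and surrogate evidence.

## Numerical choices and problem sizes

Row-stochasticity is enforced to 1e-12 at validation and verified to
1e-12 in tests; trace mass conservation to 1e-10. Closed-form engine
checks run single-state collapses to residual living mass < 1e-10.
Default test and example runs use a 40-year monthly horizon (480 cycles);
uncertainty tests shrink the horizon to 10 years and use 100–2000 draws,
sizes at which every analysis reproduces exactly under a fixed seed.
Effective parameters are cached per effect fraction (at most
persistence + waning distinct values), making strategy runs as cheap as
baseline runs.

## Known limitations

* Cohort averages only: no individual-level heterogeneity, no
  micro-simulation, no tunnel states; subgroup analysis means re-running
  with subgroup inputs.
* Mortality does not depend on age or time since onset.
* One caregiver per patient, tied to the patient's state; no caregiver
  labor-market, supervision-time, or productivity-loss costing; no
  bereavement effects.
* Surrogate links are assumed causal and severity-invariant; nothing in
  the package validates surrogacy.
* No value-of-information (EVPI/EVPPI), no efficiency frontier across
  three or more strategies, no equity weighting.
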