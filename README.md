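# demcea

A cohort Markov state-transition model for **early cost-effectiveness
analysis of dementia care technologies** — assistive agents, social robots,
monitoring systems and similar non-pharmacological innovations whose main
promise is not to slow the disease but to keep people living with dementia
in lower-intensity care settings for longer and to relieve their caregivers.

It is written for health economists and technology developers who need
lifetime estimates of quality-adjusted life years (QALYs) and societal costs
**before** long-term trial evidence exists, using only the short-term pilot
evidence that early development can realistically produce.

## The model

The cohort moves over 10 states: the 3 × 3 grid of dementia severity
(mild, moderate, severe) by care setting (no formal care, home care,
institutional care), plus absorbing death. Within each cycle the one-step
transition matrix factors into three conditional components,

```
P[(s,c) → (s′,c′)] = (1 − p_death(s,c)) · P_sev(s → s′) · P_care(c → c′ | s)
P[(s,c) → death]   = p_death(s,c)
```

with stepwise, irreversible severity progression and (by default)
irreversible care escalation; care transitions condition on start-of-cycle
severity, and death conditions on both severity and care. Each living state
carries per-year values — patient utility, a caregiver utility increment,
formal care cost, and informal caregiving hours valued at an
opportunity-cost wage — which the cohort trace turns into discounted QALYs
and societal costs (half-cycle corrected, separate discount rates for costs
and effects).

A technology strategy modifies this baseline while it is in use:

* **state-value deltas** (e.g., +0.012 utility/year in eligible states), and
* **relative risks on care transitions**, applied on the rate scale as
  `p′ = 1 − (1 − p)^rr`, so any rr > 0 yields a valid probability.

Effects last for an explicit persistence window (optionally with linear
waning) and then revert *exactly* to baseline: once use stops, benefits are
not sustained. Short-term pilot outcomes enter either directly (utility,
caregiving hours, resource use, admission risk) or through literature-derived
surrogate links — e.g., one ADCS-ADL point ↔ 0.008 utility, or caregiver
burden ↔ log-relative-risk of institutionalization — with a guard that
refuses double-counting (a directly measured quality-of-life effect excludes
any surrogate-to-utility link, and no outcome may feed both the utility and
the transition pathway).

Strategies are compared pairwise against usual care: ΔQALY, ΔCost,
ICER = ΔC/ΔQ (with dominance labels), and net monetary benefit
NMB(λ) = λ·ΔQ − ΔC over a willingness-to-pay grid. Uncertainty machinery
includes probabilistic sensitivity analysis (beta/gamma/lognormal/Dirichlet
priors, common random baseline for both arms, CEAC), one-way tornado
analysis, and named best/worst-case scenario bundles.

## Worked example

No empirical parameter set ships with the package; the `fixtures` module
generates structurally valid, clearly illustrative inputs (utility declining
with severity, costs rising steeply toward institutional care, a community
technology whose pilot evidence enters through the caregiving-hours,
ADCS-ADL→utility and burden→institutionalization pathways):

```python
from demcea import FixtureSpec, fixture_config, run_cea

cfg = fixture_config(FixtureSpec(seed=3))
result, control, treated = run_cea(cfg, "community_technology")

for o in (result.control, result.intervention):
    print(f"{o.name:22s} QALYs {o.qaly_total:8.3f}  "
          f"costs {o.cost_total:12,.0f} EUR")
print(f"incremental QALYs {result.delta_qaly:+.4f}")
print(f"incremental costs {result.delta_cost:+,.0f} EUR")
print(f"ICER              {result.icer}")
```

prints

```
usual_care             QALYs    6.200  costs      256,097 EUR
community_technology   QALYs    6.224  costs      255,249 EUR
incremental QALYs +0.0238
incremental costs -848 EUR
ICER              dominant
```

Read: over a 40-year horizon the illustrative technology adds 0.024
discounted QALYs per person (patient + caregiver) and *saves* €848 of
societal cost — the informal-care savings and delayed institutionalization
outweigh its €1,200/year price during the 24-cycle persistence window — so
it dominates usual care. These numbers describe the synthetic exemplar
only, not any real technology.

The same analyses are available from a shell:

```bash
demcea fixtures --seed 3 --out config.json
demcea run config.json --out outputs/
demcea psa config.json --n 500 --out outputs/
demcea tornado config.json --out outputs/
demcea scenarios config.json --out outputs/
```

All outputs are CSV plus a run log with the seed and a config hash; repeated
runs are byte-identical.

## Documentation

`docs/methods.md` describes the model assumptions, parameter conventions,
numerical choices, what the synthetic fixtures do and do not emulate, and
known limitations.
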