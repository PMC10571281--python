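# Methods

## Model and assumptions

`mscua` implements a closed-cohort, discrete-time Markov model of
relapsing-remitting multiple sclerosis with a one-month cycle.  Seven states:
four living EDSS bands (0.0–2.5, 3.0–5.5, 6.0–7.5, 8.0–9.5), relapse states
attached to the first two bands, and death.  Structural assumptions:

1. Disease is strictly progressive — no transition ever lowers the EDSS band
   (relapse recovery back to the parent band is not an improvement).
2. Relapse occurs only from EDSS 0.0–5.5, with one shared entry probability
   for both bands; beyond EDSS 6.0 relapse is treated as clinically absorbed
   into progression.
3. Treated patients stop drug (and its administration/adverse-event costs) on
   reaching EDSS 6.0; thereafter they follow BSC transition rows.
4. The biosimilar shares the originator's efficacy exactly; only drug cost
   differs.  Consequently treated strategies have identical traces, LYs and
   QALYs — a structural identity, not a numerical coincidence.
5. First-order Markov: no tunnel states, no relapse memory, no
   secondary-progressive conversion point, no treatment switching.
6. Mortality is MS-specific only (per-band monthly probabilities); background
   all-cause mortality is not modelled, which overstates late-horizon
   survival in all arms equally.

## Input parameters

All inputs live in one YAML table
(`src/mscua/data/thailand_rrms_2022.yaml`): per row a distribution family
(Beta for probabilities/utilities, Gamma for costs), mean, SD and source tag.
Costs are 2022 THB; 37.97 THB/USD is used for display only.  Since only the
first two moments are published, Beta and Gamma shapes are fitted by method
of moments; several rows have SD equal to the mean (relapse 0.0755 ± 0.0755,
the mortality rows), which is implausibly wide but reproduced as printed —
it drives both the tornado ranking and the Jensen bias discussed below.

95% intervals for one-way sensitivity analysis are fitted-distribution
quantiles, not mean ± 1.96·SD: the SD = mean rows would otherwise produce
negative lower bounds.  A `ci_method: normal` setting provides
support-truncated normal intervals for comparison.  Drug acquisition costs
use a ±20% band instead of a fitted CI.

## Conventions the source tables leave open

Four modelling choices are not pinned down by the published inputs.  Package
defaults (all switchable in `settings`):

| convention | default | alternative |
|---|---|---|
| treated relapse parameter (0.4220) | relative risk on the BSC relapse probability | literal monthly probability |
| relapse duration | one cycle (return with all remaining mass) | symmetric return at the relapse-entry probability |
| EDSS progression during a relapse cycle | allowed, at the band's progression probability | forbidden |
| death from EDSS 6.0–7.5 | 0 (no tabulated value) | any probability, e.g. the EDSS 3.0–5.5 value |

Rationale.  A literal treated relapse probability of 0.4220/month would be
six times the untreated probability for a drug that prevents relapse, and the
parameter's source trial reports a relapse-rate ratio; the relative-risk
reading is the only coherent one.  A one-cycle relapse is the standard
convention for monthly-cycle MS models and matches per-event relapse costing;
the symmetric reading (mean relapse ≈ 13 months) roughly doubles BSC lifetime
cost and is kept only as a scenario.  Allowing progression during the relapse
cycle avoids the artefact that relapsing patients are shielded from
progression; it also calibrates the BSC arm closer to the published totals.
With no tabulated EDSS 6.0–7.5 mortality the default is zero; raising it
shortens BSC survival (that band is BSC-heavy) and flips the sign of the
treated-vs-BSC life-year difference while weakening the biosimilar's cost
dominance — the headline conclusions are robust to it, the LY increment is
not.

**Horizon.** The default is 600 cycles (50 years), read as "lifetime" for an
adult cohort diagnosed around age 30.  A 30-year horizon is inconsistent
with the published discounted life-year levels (they exceed the 30-year
discounted annuity maximum), which is why the longer default was adopted;
`horizon_cycles` is a setting, and totals at 360 cycles are roughly 25–30%
lower for the BSC arm.

## Accrual and discounting

Start-of-cycle occupancy is costed over cycles `0..H-1` with discount factor
`(1+r)^(-t/12)`, both rates 3%/year by default.  No half-cycle correction by
default (a trapezoidal `half_cycle` option exists).  Life-years are
discounted (flag to disable).  Relapse-cycle medical cost replaces routine
OPD cost for that cycle; with the one-cycle relapse convention this equals
per-event costing.  Adverse events enter as expected values — annual
probability × unit cost / 12 per on-treatment cycle — with no disutility
(none is published).  The relapse-cost rows for EDSS ≥ 6 load and validate
but never accrue (assumption 2); they are retained so the table mirrors its
source and are exercised as "inert parameter → zero tornado spread" in tests.

ICERs are computed from unrounded intermediates.  Dominance labelling:
cheaper-and-more-effective = Dominant, costlier-and-less-effective =
Dominated; equal-effect comparisons yield NaN rather than a sign-unstable
ratio.

## Probabilistic sensitivity analysis and CEAC

1,000 draws by default; every non-fixed parameter sampled independently (no
published correlation structure).  Two coherence rules per draw, both
deterministic in the seed: relapse-state utilities are clipped to their band
utility, and draws producing an infeasible transition row (outgoing mass
> 1, vanishingly rare under the fitted distributions) are redrawn.  The CEAC
is the per-WTP fraction of draws in which a strategy has the strictly
highest net monetary benefit, ties split equally; the grid default is
0–500,000 THB step 10,000.

Because the model is convex in the heavy-tailed SD = mean inputs, PSA means
sit a few percent away from the deterministic base case (Jensen bias, worst
on the BSC arm); the convergence test asserts a 10% band for this reason,
not as a loose tolerance for bugs.

The tornado reports incremental net monetary benefit of the biosimilar vs
BSC at 160,000 THB/QALY (the ICER is undefined around dominance, and the
published diagram's exact outcome metric is not stated).  Under this metric
the BSC progression probability and the relapse probability are the two
dominant drivers; which of the two ranks first depends on the outcome metric
chosen.

## Budget impact

Government perspective, undiscounted, five fiscal years.  Covered cohorts
(90% of 572 prevalent patients, plus 90% of 51 incident patients entering at
the start of every year) are aged along the biosimilar and BSC traces; the
incremental budget differences the *direct medical* streams only — drug,
administration, OPD, relapse care, adverse events; direct non-medical costs
never enter, asserted in tests.  Prevalent patients start in EDSS 0.0–2.5
like incident ones (no published severity mix; a start-state hook exists via
the engine's `initial` vector).  This all-EDSS-0 start maximizes the relapse
offsets and is therefore the *most* offset-inclusive reading: the resulting
year-1 increment (≈ 14M THB) sits well below the published ≈ 26M, which is
arithmetically consistent only with a gross acquisition costing; that
variant is available as `costing="drug_related_only"` (≈ 24M in year 1).
The published year-over-year decline likewise cannot be produced by a
constant-incidence pool under either costing — attrition off treatment is
slower than the incident inflow — so the acceptance check on the budget
pattern is expected to fail and is left failing rather than retuned.

## Microsimulation oracle and synthetic data

`simulate_patients` walks individual patients through the same transition
matrix (categorical sampling against row cumulative sums).  Patient `i`
consumes uniforms `[i·H, (i+1)·H)` of one seeded PCG64 stream, so runs are
reproducible and enlarging `n` never perturbs earlier patients.  It backs
three validation loops: occupancy equivalence with the cohort trace within
`4·sqrt(p(1-p)/n)` per cell, per-arrow maximum-likelihood recovery of every
tabulated transition probability within 3 SE, and undiscounted mean accrual
agreement at zero discount.  As a synthetic data generator it emulates state
sequences, relapse/progression/death events and per-patient accruals under
the model's own assumptions; it does *not* emulate patient heterogeneity
(age, sex, baseline EDSS mix), measurement error, dropout, or any violation
of the Markov property — passing these tests validates internal consistency
of the implementation, not the model's fit to real Thai patients, for whom
no individual-level data are available.

## Numerical choices

- Trace rows are renormalized after propagation to absorb float drift over
  600 cycles; matrices must be row-stochastic to 1e-12, traces to 1e-10.
- Degenerate inputs fail loudly: infeasible Beta moments, overfull transition
  rows (error names the row), non-simplex initial vectors, horizon/trace
  mismatches, zero-exposure transition estimates (NaN + flagged, never 0).
- CEAC argmax ties split equally (measure-zero under continuous sampling but
  exercised in tests with constructed draws).
- Problem sizes used by the default suite and acceptance run: 600-cycle
  deterministic traces; 1,000 PSA draws; microsim equivalence at
  n = 100,000 patients × 240 cycles, recovery/accrual checks at 20–30k.

## Known limitations

- No background mortality and immortal EDSS 6.0–7.5 under the default
  conventions: absolute life expectancy is overstated; incremental results
  are affected mainly through the LY difference (sign-unstable near zero).
- Independence of all sampled parameters likely overstates tail uncertainty
  in the CEAC.
- The budget module inherits the cohort model's newly-diagnosed trace for
  prevalent patients; a realistic prevalent severity mix would lower both
  arms' costs and shrink offsets.
- USD figures are a fixed-rate display conversion, not a currency model.
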