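# mscua — cost-utility and budget impact of rituximab for RRMS in Thailand

`mscua` is a decision-analytic modelling package for health-technology
assessment of off-label rituximab (original and biosimilar) versus best
supportive care (BSC) in newly diagnosed relapsing-remitting multiple
sclerosis (RRMS), built around the Thai reimbursement context (costs in THB,
price year 2022, the 160,000 THB/QALY national willingness-to-pay threshold).
It is aimed at HTA analysts who need a scriptable, testable alternative to
spreadsheet Markov models.

## The model

A monthly-cycle Markov cohort model over seven EDSS-banded health states:

```
EDSS 0.0-2.5  ⇄  Relapse 0.0-2.5
     ↓ p_edss3
EDSS 3.0-5.5  ⇄  Relapse 3.0-5.5
     ↓ p_edss6
EDSS 6.0-7.5 → EDSS 8.0-9.5 → Death
```

Disease is strictly progressive (no arrow to a lower band) and death is
absorbing; each living band also has an MS-specific monthly death
probability.  The cohort trace `x_{t+1} = x_t P` is accrued into discounted
totals per patient:

- cost: `Σ_t (1+r_c)^(-t/12) · x_t · c`, where `c` holds OPD + direct
  non-medical costs per band, relapse-cycle medical cost in the relapse
  states, and drug + administration + expected adverse-event cost while on
  treatment;
- QALYs: `Σ_t (1+r_o)^(-t/12) · x_t · u / 12` with annual utility weights `u`;
- life-years analogously with `u = 1`.

Rituximab multiplies the relapse-entry probability by a relative risk
(0.4220) and substitutes slower progression probabilities in EDSS 0.0–5.5;
treatment (and its cost) stops on reaching EDSS 6.0.  The biosimilar is
identical except for drug cost, so for any willingness-to-pay it can only
dominate or be dominated by the originator.  Incremental results are
summarized as ICERs (`ΔC/ΔE`) with standard dominance labelling, net
monetary benefit `λ·ΔQALY − ΔC`, cost-effectiveness acceptability curves
from probabilistic sensitivity analysis (method-of-moments Beta/Gamma
sampling of every uncertain input), a tornado diagram from one-way 95% CI
sweeps, and a five-fiscal-year government budget projection.

An individual-level microsimulation of the same transition matrices serves
as a brute-force validation oracle (cohort–microsim equivalence, transition
parameter recovery) and as the synthetic patient-level data generator for
testing; see `docs/methods.md` for conventions, assumptions and limits.

## Worked example

```python
from mscua import CostUtilityAnalysis, PopulationInputs, Strategy

analysis = CostUtilityAnalysis()          # bundled Thai base case
results = analysis.run()
print(results.summary_text())
```

```
Cost-utility results (per patient, discounted)

BSC                    cost    2,830,620 THB (   74,549 USD)  LY  22.23  QALY  8.31
Rituximab              cost    3,817,570 THB (  100,542 USD)  LY  21.76  QALY 10.07
Rituximab biosimilar   cost    2,762,101 THB (   72,744 USD)  LY  21.76  QALY 10.07

Rituximab vs BSC: dCost +986,950 THB, dQALY +1.76, dLY -0.47, ICER 559,817 THB/QALY
Rituximab biosimilar vs BSC: dCost -68,519 THB, dQALY +1.76, dLY -0.47, ICER Dominant
```

Reading: over a lifetime horizon a treated patient gains about 1.8
discounted QALYs.  At originator prices that costs ≈ 987k THB extra — an
ICER of ≈ 560k THB/QALY, far above the 160k threshold — while the
biosimilar delivers the same health gain *and* saves ≈ 69k THB, i.e. it
dominates best supportive care.  Uncertainty and affordability:

```python
psa = analysis.run_psa(1000, seed=1)
print(analysis.ceac(psa).probability_at(Strategy.BIOSIMILAR, 160_000))
# 0.634  — P(biosimilar optimal at 160,000 THB/QALY)

print(analysis.budget(PopulationInputs()).incremental_by_year() / 1e6)
# [14.02 13.28 13.43 13.74 14.18]  — incremental M THB per fiscal year
```

The same analyses are available from the shell:

```sh
mscua all --out-dir out/           # base case + tornado + PSA/CEAC + budget
mscua base-case --discount-cost 0 --discount-outcome 0
```

Every run writes a `manifest.json` (config hash, seed, outputs) and is
bit-reproducible under a fixed seed.

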