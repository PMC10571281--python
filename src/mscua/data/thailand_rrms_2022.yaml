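# Base-case inputs for the Thai RRMS cost-utility model.
#
# Every uncertain quantity carries a distribution family (beta for
# probabilities and utilities, gamma for costs) with its mean and standard
# deviation; Beta/Gamma shapes are fitted by method of moments at load time.
# Probabilities are per monthly cycle unless marked per-year (adverse events).
# Costs are THB, price year 2022. `source` is a citation tag, free text.

transitions:
  p_edss3:        {family: beta, mean: 0.0075, sd: 0.0046, source: "BSC progression EDSS 0.0-2.5 -> 3.0-5.5"}
  p_edss6:        {family: beta, mean: 0.0079, sd: 0.0021, source: "BSC progression EDSS 3.0-5.5 -> 6.0-7.5"}
  p_edss8:        {family: beta, mean: 0.0018, sd: 0.0018, source: "progression EDSS 6.0-7.5 -> 8.0-9.5"}
  p_edss10:       {family: beta, mean: 0.0017, sd: 0.0017, source: "EDSS 8.0-9.5 -> death"}
  p_relapse:      {family: beta, mean: 0.0755, sd: 0.0755, source: "relapse entry, EDSS 0.0-5.5"}
  p_death_edss0:  {family: beta, mean: 0.0009, sd: 0.0009, source: "MS death from EDSS 0.0-2.5"}
  p_death_edss3:  {family: beta, mean: 0.0011, sd: 0.0011, source: "MS death from EDSS 3.0-5.5"}

treatment_effect:
  relapse_effect:   {family: beta, mean: 0.4220, sd: 0.1727, source: "relapse relative risk, rituximab vs no DMT (phase II RCT)"}
  p_prog_rtx_0to3:  {family: beta, mean: 0.0041, sd: 0.0008, source: "rituximab progression EDSS 0.0-2.5 -> 3.0-5.5 (phase III RCT)"}
  p_prog_rtx_3to6:  {family: beta, mean: 0.0041, sd: 0.0008, source: "rituximab progression EDSS 3.0-5.5 -> 6.0-7.5 (phase III RCT)"}

adverse_events:   # probabilities are per year on treatment
  p_infusion_reaction:  {family: beta, mean: 0.1880, sd: 0.0376, source: "meta-analysis of rituximab in MS"}
  p_minor_infection:    {family: beta, mean: 0.1690, sd: 0.0338, source: "meta-analysis of rituximab in MS"}
  p_agranulocytosis:    {family: beta, mean: 0.0111, sd: 0.0022, source: "meta-analysis of rituximab in MS"}
  p_pneumonia:          {family: beta, mean: 0.0065, sd: 0.0013, source: "meta-analysis of rituximab in MS"}
  c_infusion_reaction:  {family: gamma, mean: 1465.12, sd: 293.0, source: "standard cost list for HTA"}
  c_minor_infection:    {family: gamma, mean: 4999.92, sd: 1000.0, source: "standard cost list for HTA"}
  c_agranulocytosis:    {family: gamma, mean: 23952.00, sd: 4790.0, source: "standard cost list for HTA"}
  c_pneumonia:          {family: gamma, mean: 9118.03, sd: 1824.0, source: "standard cost list for HTA"}

costs:            # THB per month unless noted; relapse costs are per relapse cycle
  opd_cost_edss0:     {family: gamma, mean: 1317.70, sd: 131.84, source: "OPD direct medical, EDSS 0.0-2.5"}
  opd_cost_edss3:     {family: gamma, mean: 2408.77, sd: 349.20, source: "OPD direct medical, EDSS 3.0-5.5"}
  opd_cost_edss6:     {family: gamma, mean: 2202.10, sd: 256.56, source: "OPD direct medical, EDSS 6.0-7.5"}
  opd_cost_edss8:     {family: gamma, mean: 2013.25, sd: 260.12, source: "OPD direct medical, EDSS 8.0-9.5"}
  relapse_cost_edss0: {family: gamma, mean: 40585.63, sd: 4407.76, source: "direct medical, EDSS 0.0-2.5 with relapse"}
  relapse_cost_edss3: {family: gamma, mean: 71144.23, sd: 7710.91, source: "direct medical, EDSS 3.0-5.5 with relapse"}
  relapse_cost_edss6: {family: gamma, mean: 80814.94, sd: 9688.53, source: "direct medical, EDSS 6.0-7.5 with relapse (unused: relapse ends at EDSS 6)"}
  relapse_cost_edss8: {family: gamma, mean: 55626.19, sd: 7917.58, source: "direct medical, EDSS 8.0-9.5 with relapse (unused: relapse ends at EDSS 6)"}
  nonmed_cost_edss0:  {family: gamma, mean: 2686.70, sd: 734.03, source: "direct non-medical, EDSS 0.0-2.5"}
  nonmed_cost_edss3:  {family: gamma, mean: 2975.33, sd: 1172.32, source: "direct non-medical, EDSS 3.0-5.5"}
  nonmed_cost_edss6:  {family: gamma, mean: 10846.59, sd: 1949.11, source: "direct non-medical, EDSS 6.0-7.5"}
  nonmed_cost_edss8:  {family: gamma, mean: 15061.94, sd: 2782.91, source: "direct non-medical, EDSS 8.0-9.5"}
  c_rituximab_month:  {family: gamma, mean: 8236.0, sd: 1647.0, source: "original rituximab, monthly average over 5-y regimen (24,182 THB/500 mg vial)"}
  c_biosimilar_month: {family: gamma, mean: 2967.0, sd: 590.0, source: "rituximab biosimilar, monthly average over 5-y regimen (8,667 THB/500 mg vial)"}
  c_admin_month:      {family: gamma, mean: 506.34, sd: 101.0, source: "administration, monthly average"}

utilities:        # utility weight per year in state
  u_edss0: {family: beta, mean: 0.600, sd: 0.02, source: "Thai cross-sectional utility study"}
  u_rel0:  {family: beta, mean: 0.524, sd: 0.10, source: "EDSS 0.0-2.5 with relapse (UK disutility)"}
  u_edss3: {family: beta, mean: 0.490, sd: 0.04, source: "Thai cross-sectional utility study"}
  u_rel3:  {family: beta, mean: 0.414, sd: 0.08, source: "EDSS 3.0-5.5 with relapse (UK disutility)"}
  u_edss6: {family: beta, mean: 0.170, sd: 0.06, source: "Thai cross-sectional utility study"}
  u_edss8: {family: beta, mean: 0.026, sd: 0.01, source: "Thai cross-sectional utility study"}

settings:
  cycle_length_months: 1
  horizon_cycles: 600          # lifetime horizon (50 y) for a newly diagnosed adult cohort
  discount_cost_annual: 0.03
  discount_outcome_annual: 0.03
  wtp: 160000.0                # THB per QALY (Thai NLEM threshold)
  thb_per_usd: 37.97
  psa_draws: 1000
  seed: 20220101
  # modelling conventions (see docs/methods.md)
  relapse_return: one_cycle    # or: symmetric
  relapse_effect_form: relative_risk   # or: probability
  relapse_progression: true    # EDSS progression possible during a relapse cycle
  p_death_edss6: 0.0           # no tabulated MS mortality for EDSS 6.0-7.5
  half_cycle: false
  discount_ly: true
  ci_method: quantile          # or: normal (truncated to support)
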