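"""Five-fiscal-year budget impact of adopting the rituximab biosimilar.

Government perspective: only direct medical components (drug, administration,
OPD, relapse care, adverse events) enter; direct non-medical costs never do.
No discounting is applied.  The per-patient annual cost streams come from the
same Markov traces as the cost-utility analysis, so survival and treatment
stopping (at EDSS 6.0) are inherited from the cohort model.

Cohort accounting: covered prevalent patients (coverage x prevalent) start
treatment at the beginning of fiscal year 1; a covered incident cohort
(coverage x incidence) enters at the start of every year, including year 1.
Patients outside coverage cost the same under both scenarios and cancel out
of the incremental budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ALIVE_STATES, ON_TREATMENT_STATES, Strategy, build_matrix, run_cohort
from .outcomes import state_cost_components
from .params import ParameterSet, ValidationError

__all__ = ["PopulationInputs", "BudgetProjection", "project_population", "compute_budget"]

#: budget-relevant cost components (direct medical only)
DIRECT_MEDICAL = ("drug", "administration", "opd", "relapse", "adverse_events")

_COSTINGS = ("incremental_direct_medical", "drug_related_only")


@dataclass(frozen=True)
class PopulationInputs:
    """Thai MS population served by the programme."""

    prevalent_patients: float = 572.0
    incident_per_year: float = 51.0
    coverage: float = 0.90
    years: int = 5

    def __post_init__(self) -> None:
        if self.prevalent_patients < 0 or self.incident_per_year < 0:
            raise ValidationError("patient counts must be nonnegative")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValidationError("coverage must be in [0, 1]")
        if self.years < 1:
            raise ValidationError("years must be >= 1")


def _annual_stream(params: ParameterSet, strategy: Strategy, years: int,
                   components=DIRECT_MEDICAL) -> np.ndarray:
    """Undiscounted per-patient direct-medical cost by year since entry."""
    cycles = years * 12
    if cycles > params.settings.horizon_cycles:
        raise ValidationError("budget years exceed the model horizon")
    m = build_matrix(params, strategy)
    trace = run_cohort(m, horizon_cycles=cycles)
    comp = state_cost_components(params, strategy)
    sc = comp[list(components)].to_numpy().sum(axis=1)  # (6,)
    occ = trace.occupancy[:cycles, [s.value for s in ALIVE_STATES]]
    monthly = occ @ sc
    return np.add.reduceat(monthly, np.arange(0, cycles, 12))


def _on_treatment_fraction(params: ParameterSet, strategy: Strategy, years: int) -> np.ndarray:
    """On-treatment occupancy at the start of each year since entry."""
    cycles = years * 12
    m = build_matrix(params, strategy)
    trace = run_cohort(m, horizon_cycles=cycles)
    idx = [s.value for s in ON_TREATMENT_STATES]
    return trace.occupancy[0:cycles:12, idx].sum(axis=1)


def _cohort_sizes(pop: PopulationInputs, year: int) -> list[tuple[float, int]]:
    """(covered size, cohort age in years) for every cohort active in ``year``."""
    out = [(pop.coverage * pop.prevalent_patients, year)]
    for entry_year in range(year + 1):
        out.append((pop.coverage * pop.incident_per_year, year - entry_year))
    return out


def project_population(pop: PopulationInputs, params: ParameterSet,
                       strategy: Strategy = Strategy.BIOSIMILAR) -> pd.DataFrame:
    """Treated head-counts per fiscal year (start-of-year, post-attrition)."""
    frac = _on_treatment_fraction(params, strategy, pop.years)
    rows = []
    for y in range(pop.years):
        treated = sum(size * frac[age] for size, age in _cohort_sizes(pop, y))
        rows.append({"fiscal_year": y + 1, "treated_count": treated})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BudgetProjection:
    """Per-fiscal-year costs with/without adoption and the incremental budget."""

    table: pd.DataFrame  # fiscal_year, treated_count, cost_with, cost_without, incremental
    strategy: Strategy
    costing: str

    def incremental_by_year(self) -> np.ndarray:
        return self.table["incremental_thb"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_budget(
    pop: PopulationInputs,
    params: ParameterSet,
    strategy: Strategy = Strategy.BIOSIMILAR,
    costing: str = "incremental_direct_medical",
) -> BudgetProjection:
    """Incremental government budget of replacing BSC with ``strategy``.

    ``costing='incremental_direct_medical'`` (default) differences the full
    direct-medical streams of the treated and BSC traces, so relapse-care
    savings offset drug spending.  ``costing='drug_related_only'`` counts only
    drug, administration and adverse-event spending of the treated arm — the
    gross acquisition budget with no offsets.
    """
    if costing not in _COSTINGS:
        raise ValidationError(f"costing must be one of {_COSTINGS}")
    if costing == "drug_related_only":
        with_stream = _annual_stream(
            params, strategy, pop.years,
            components=("drug", "administration", "adverse_events"),
        )
        without_stream = np.zeros_like(with_stream)
    else:
        with_stream = _annual_stream(params, strategy, pop.years)
        without_stream = _annual_stream(params, Strategy.BSC, pop.years)

    counts = project_population(pop, params, strategy)["treated_count"].to_numpy()
    usd = params.settings.thb_per_usd
    rows = []
    for y in range(pop.years):
        cw = sum(size * with_stream[age] for size, age in _cohort_sizes(pop, y))
        co = sum(size * without_stream[age] for size, age in _cohort_sizes(pop, y))
        rows.append(
            {
                "fiscal_year": y + 1,
                "treated_count": counts[y],
                "cost_with_thb": cw,
                "cost_without_thb": co,
                "incremental_thb": cw - co,
                "incremental_usd": (cw - co) / usd,
            }
        )
    return BudgetProjection(pd.DataFrame(rows), strategy, costing)
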