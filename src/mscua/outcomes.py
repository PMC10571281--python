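"""Discounted cost, life-year and QALY accrual along a cohort trace, and ICERs.

Costs enter per monthly cycle.  In a relapse cycle the band's relapse direct
medical cost replaces routine OPD care; direct non-medical costs accrue in
every living state; drug, administration and expected adverse-event costs
accrue only while on treatment (EDSS < 6.0 under a treated strategy).
Utilities are annual weights, so each cycle contributes ``u/12`` QALYs.

Discounting uses the standard per-cycle factor ``(1 + r)^(-t/12)`` with the
annual rate ``r``; by default the state at the start of each cycle is costed
(no half-cycle correction), with a trapezoidal half-cycle option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    ALIVE_STATES,
    ON_TREATMENT_STATES,
    CohortTrace,
    HealthState,
    Strategy,
)
from .params import ParameterSet, ValidationError

__all__ = [
    "discount_factor",
    "accrue",
    "StrategyResult",
    "IcerEntry",
    "IcerTable",
    "compute_icer",
]

COST_COMPONENTS = ("drug", "administration", "opd", "relapse", "nonmedical", "adverse_events")

_BAND_OF = {s: s.band for s in ALIVE_STATES}
_UTILITY_BY_STATE = ("u_edss0", "u_rel0", "u_edss3", "u_rel3", "u_edss6", "u_edss8")


def discount_factor(cycle: int | np.ndarray, annual_rate: float, cycles_per_year: float = 12.0):
    """Present-value factor ``(1 + r)^(-cycle / cycles_per_year)``."""
    if annual_rate < 0:
        raise ValidationError(f"discount rate must be nonnegative, got {annual_rate}")
    return (1.0 + annual_rate) ** (-np.asarray(cycle, dtype=float) / cycles_per_year)


@dataclass(frozen=True)
class StrategyResult:
    """Discounted totals per patient for one strategy."""

    strategy: Strategy
    total_cost: float
    total_ly: float
    total_qaly: float
    cost_breakdown: dict[str, float] = field(default_factory=dict)

    def cost_usd(self, thb_per_usd: float = 37.97) -> float:
        return self.total_cost / thb_per_usd


def state_cost_components(params: ParameterSet, strategy: Strategy) -> pd.DataFrame:
    """Per-cycle cost of occupying each living state, split by component."""
    v = params.values
    drug_month = {
        Strategy.BSC: 0.0,
        Strategy.RITUXIMAB: v["c_rituximab_month"],
        Strategy.BIOSIMILAR: v["c_biosimilar_month"],
    }[strategy]
    ae_cycle = params.expected_ae_cost_per_cycle()
    opd = [v[f"opd_cost_edss{b}"] for b in (0, 3, 6, 8)]
    relc = [v[f"relapse_cost_edss{b}"] for b in (0, 3, 6, 8)]
    nonmed = [v[f"nonmed_cost_edss{b}"] for b in (0, 3, 6, 8)]

    rows = {}
    for s in ALIVE_STATES:
        b = _BAND_OF[s]
        on_drug = strategy.treated and s in ON_TREATMENT_STATES
        rows[s.display_name] = {
            "drug": drug_month if on_drug else 0.0,
            "administration": v["c_admin_month"] if on_drug else 0.0,
            "opd": 0.0 if s.is_relapse else opd[b],
            "relapse": relc[b] if s.is_relapse else 0.0,
            "nonmedical": nonmed[b],
            "adverse_events": ae_cycle if on_drug else 0.0,
        }
    return pd.DataFrame(rows).T[list(COST_COMPONENTS)]


def _cycle_weights(n_cycles: int, half_cycle: bool) -> tuple[np.ndarray, np.ndarray]:
    """(cycle indices, occupancy weights) for accrual over a trace."""
    if half_cycle:
        t = np.arange(n_cycles + 1)
        w = np.ones(n_cycles + 1)
        w[0] = w[-1] = 0.5
    else:
        t = np.arange(n_cycles)
        w = np.ones(n_cycles)
    return t, w


def accrue(trace: CohortTrace, params: ParameterSet, strategy: Strategy) -> StrategyResult:
    """Total discounted cost, LYs and QALYs along ``trace`` for ``strategy``."""
    if trace.strategy is not strategy:
        raise ValidationError(
            f"trace was run for {trace.strategy.value!r}, not {strategy.value!r}"
        )
    s = params.settings
    n = trace.horizon_cycles
    t, w = _cycle_weights(n, s.half_cycle)
    occ = trace.occupancy[t][:, [st.value for st in ALIVE_STATES]]  # (T, 6)
    df_cost = discount_factor(t, s.discount_cost_annual)
    df_out = discount_factor(t, s.discount_outcome_annual)

    comp = state_cost_components(params, strategy)  # (6 states, components)
    weighted_occ_cost = occ * (w * df_cost)[:, None]
    breakdown = {
        c: float(weighted_occ_cost.sum(axis=0) @ comp[c].to_numpy())
        for c in COST_COMPONENTS
    }
    total_cost = float(sum(breakdown.values()))

    u = np.array([params.values[name] for name in _UTILITY_BY_STATE])
    total_qaly = float(((occ @ u) * w * df_out).sum()) / 12.0
    df_ly = df_out if s.discount_ly else np.ones_like(df_out)
    total_ly = float((occ.sum(axis=1) * w * df_ly).sum()) / 12.0
    return StrategyResult(strategy, total_cost, total_ly, total_qaly, breakdown)


@dataclass(frozen=True)
class IcerEntry:
    """Incremental results of one strategy against the reference."""

    strategy: Strategy
    incremental_cost: float
    incremental_ly: float
    incremental_qaly: float
    icer_per_qaly: float | str
    icer_per_ly: float | str


def _ratio(d_cost: float, d_effect: float) -> float | str:
    if d_cost < 0 and d_effect > 0:
        return "Dominant"
    if d_cost > 0 and d_effect < 0:
        return "Dominated"
    if d_effect == 0:
        # equal effect: no meaningful ratio (flagged as undefined)
        return float("nan") if d_cost != 0 else 0.0
    return d_cost / d_effect


@dataclass(frozen=True)
class IcerTable:
    reference: Strategy
    entries: tuple[IcerEntry, ...]

    def __getitem__(self, strategy: Strategy) -> IcerEntry:
        for e in self.entries:
            if e.strategy is strategy:
                return e
        raise KeyError(strategy)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": e.strategy.value,
                    "incremental_cost_thb": e.incremental_cost,
                    "incremental_ly": e.incremental_ly,
                    "incremental_qaly": e.incremental_qaly,
                    "icer_per_qaly": e.icer_per_qaly,
                    "icer_per_ly": e.icer_per_ly,
                }
                for e in self.entries
            ]
        ).set_index("strategy")


def compute_icer(results: list[StrategyResult], reference: Strategy = Strategy.BSC) -> IcerTable:
    """Incremental cost-effectiveness of every strategy against ``reference``.

    ICERs are reported from unrounded intermediates.  A strategy that is
    cheaper and more effective is labelled ``Dominant``; costlier and less
    effective, ``Dominated``; equal effect with unequal cost yields NaN.
    """
    by_strategy = {r.strategy: r for r in results}
    if reference not in by_strategy:
        raise ValidationError(f"reference strategy {reference.value!r} not in results")
    ref = by_strategy[reference]
    entries = []
    for r in results:
        if r.strategy is reference:
            continue
        d_cost = r.total_cost - ref.total_cost
        d_ly = r.total_ly - ref.total_ly
        d_qaly = r.total_qaly - ref.total_qaly
        entries.append(
            IcerEntry(
                strategy=r.strategy,
                incremental_cost=d_cost,
                incremental_ly=d_ly,
                incremental_qaly=d_qaly,
                icer_per_qaly=_ratio(d_cost, d_qaly),
                icer_per_ly=_ratio(d_cost, d_ly),
            )
        )
    return IcerTable(reference, tuple(entries))
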