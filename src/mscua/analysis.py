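"""High-level interface: build the analysis from inputs, run it, inspect results.

`CostUtilityAnalysis` bundles a :class:`~mscua.params.ParameterSet` with the
cohort engine and accrual; :meth:`run` evaluates all strategies and returns a
:class:`CUAResults` carrying per-strategy totals, the ICER table and traces,
with a ``summary()`` in the familiar cost-effectiveness-table layout.
Sensitivity, CEAC and budget-impact analyses hang off the analysis object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import budget as _budget
from . import sensitivity as _sens
from .engine import CohortTrace, Strategy, build_matrix, run_cohort
from .outcomes import IcerTable, StrategyResult, accrue, compute_icer
from .params import ParameterSet, default_parameters, load_parameters

__all__ = ["CostUtilityAnalysis", "CUAResults"]


class CostUtilityAnalysis:
    """Cost-utility comparison of rituximab strategies against BSC.

    Parameters
    ----------
    params :
        A validated parameter set; the bundled Thai RRMS base case if omitted.
    **settings :
        Overrides applied to ``params.settings`` (e.g. ``horizon_cycles=360``,
        ``discount_cost_annual=0.0``).
    """

    def __init__(self, params: ParameterSet | None = None, **settings) -> None:
        params = params if params is not None else default_parameters()
        if settings:
            params = params.with_settings(**settings)
        self.params = params
        self.strategies = _sens.ALL_STRATEGIES

    @classmethod
    def from_yaml(cls, path: str | Path, **settings) -> "CostUtilityAnalysis":
        return cls(load_parameters(path), **settings)

    def trace(self, strategy: Strategy) -> CohortTrace:
        matrix = build_matrix(self.params, strategy)
        return run_cohort(matrix, horizon_cycles=self.params.settings.horizon_cycles)

    def run(self, reference: Strategy = Strategy.BSC) -> "CUAResults":
        results, traces = [], {}
        for s in self.strategies:
            tr = self.trace(s)
            traces[s] = tr
            results.append(accrue(tr, self.params, s))
        icer = compute_icer(results, reference)
        return CUAResults(self.params, tuple(results), icer, traces)

    # -- uncertainty / budget -------------------------------------------

    def run_psa(self, n_draws: int | None = None, seed: int | None = None) -> _sens.PsaResult:
        return _sens.run_psa(self.params, n_draws, seed, self.strategies)

    def ceac(self, psa: _sens.PsaResult | None = None,
             wtp_grid: np.ndarray | None = None) -> _sens.CeacCurve:
        if psa is None:
            psa = self.run_psa()
        return _sens.ceac(psa, wtp_grid)

    def owsa(self, **kwargs) -> list[_sens.TornadoEntry]:
        return _sens.owsa(self.params, **kwargs)

    def budget(self, pop: _budget.PopulationInputs | None = None,
               **kwargs) -> _budget.BudgetProjection:
        pop = pop if pop is not None else _budget.PopulationInputs()
        return _budget.compute_budget(pop, self.params, **kwargs)


@dataclass(frozen=True)
class CUAResults:
    """Evaluated strategies: totals, incrementals, dominance labels, traces."""

    params: ParameterSet
    strategy_results: tuple[StrategyResult, ...]
    icer_table: IcerTable
    traces: dict[Strategy, CohortTrace]

    def result(self, strategy: Strategy) -> StrategyResult:
        for r in self.strategy_results:
            if r.strategy is strategy:
                return r
        raise KeyError(strategy)

    def summary(self) -> pd.DataFrame:
        """Cost-effectiveness table: totals, incrementals, ICERs per strategy."""
        usd = self.params.settings.thb_per_usd
        rows = []
        for r in self.strategy_results:
            row = {
                "strategy": r.strategy.value,
                "total_cost_thb": r.total_cost,
                "total_cost_usd": r.total_cost / usd,
                "ly": r.total_ly,
                "qaly": r.total_qaly,
                "incremental_cost_thb": "",
                "incremental_ly": "",
                "incremental_qaly": "",
                "icer_per_ly": "",
                "icer_per_qaly": "",
            }
            if r.strategy is not self.icer_table.reference:
                e = self.icer_table[r.strategy]
                row.update(
                    incremental_cost_thb=e.incremental_cost,
                    incremental_ly=e.incremental_ly,
                    incremental_qaly=e.incremental_qaly,
                    icer_per_ly=e.icer_per_ly,
                    icer_per_qaly=e.icer_per_qaly,
                )
            rows.append(row)
        return pd.DataFrame(rows).set_index("strategy")

    def summary_text(self) -> str:
        usd = self.params.settings.thb_per_usd
        lines = ["Cost-utility results (per patient, discounted)", ""]
        for r in self.strategy_results:
            lines.append(
                f"{r.strategy.value:22s} cost {r.total_cost:>12,.0f} THB "
                f"({r.total_cost / usd:>9,.0f} USD)  LY {r.total_ly:6.2f}  "
                f"QALY {r.total_qaly:5.2f}"
            )
        lines.append("")
        for e in self.icer_table.entries:
            icer = e.icer_per_qaly
            icer_s = icer if isinstance(icer, str) else f"{icer:,.0f} THB/QALY"
            lines.append(
                f"{e.strategy.value} vs {self.icer_table.reference.value}: "
                f"dCost {e.incremental_cost:+,.0f} THB, dQALY {e.incremental_qaly:+.2f}, "
                f"dLY {e.incremental_ly:+.2f}, ICER {icer_s}"
            )
        return "\n".join(lines)

    def to_json(self) -> dict:
        usd = self.params.settings.thb_per_usd
        out = {"strategies": {}, "incremental": {}}
        for r in self.strategy_results:
            out["strategies"][r.strategy.value] = {
                "total_cost_thb": r.total_cost,
                "total_cost_usd": r.total_cost / usd,
                "ly": r.total_ly,
                "qaly": r.total_qaly,
                "cost_breakdown_thb": r.cost_breakdown,
            }
        for e in self.icer_table.entries:
            out["incremental"][e.strategy.value] = {
                "vs": self.icer_table.reference.value,
                "cost_thb": e.incremental_cost,
                "ly": e.incremental_ly,
                "qaly": e.incremental_qaly,
                "icer_per_qaly": e.icer_per_qaly,
                "icer_per_ly": e.icer_per_ly,
            }
        return out
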