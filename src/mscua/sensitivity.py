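"""Uncertainty analysis: one-way (tornado), probabilistic (PSA), NMB, CEAC.

PSA samples every non-fixed parameter independently from its method-of-moments
Beta/Gamma fit.  Two coherence rules are enforced on each draw: relapse-state
utilities may not exceed their band utility (clipped), and any draw whose
transition rows would be infeasible (outgoing mass > 1) is redrawn — both
events are deterministic functions of the seed, so draws are reproducible.

The cost-effectiveness acceptability curve ranks strategies per draw by net
monetary benefit ``NMB = WTP * QALY - cost``; exact ties split equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ALIVE_STATES, HealthState, Strategy, build_matrix, run_cohort
from .outcomes import accrue, discount_factor, state_cost_components
from .params import PARAM_NAMES, ParameterSet, ValidationError, ci95

__all__ = [
    "nmb",
    "sample_psa",
    "run_psa",
    "PsaResult",
    "ceac",
    "CeacCurve",
    "owsa",
    "TornadoEntry",
    "DEFAULT_WTP_GRID",
]

ALL_STRATEGIES = (Strategy.BSC, Strategy.RITUXIMAB, Strategy.BIOSIMILAR)

#: default WTP grid for CEAC export: 0 to 500,000 THB/QALY in 10,000 steps
DEFAULT_WTP_GRID = np.arange(0, 500_001, 10_000)

_UTILITY_CLIP = (("u_rel0", "u_edss0"), ("u_rel3", "u_edss3"))
_DRUG_COST_PARAMS = ("c_rituximab_month", "c_biosimilar_month")


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * qaly - cost`` (THB)."""
    if wtp < 0:
        raise ValidationError(f"wtp must be nonnegative, got {wtp}")
    return wtp * qaly - cost


def _draw_values(base: ParameterSet, rng: np.random.Generator) -> dict[str, float]:
    values = {}
    for name in PARAM_NAMES:
        values[name] = float(base.specs[name].sample(rng))
    for rel, band in _UTILITY_CLIP:
        values[rel] = min(values[rel], values[band])
    return values


def _feasible(draw: ParameterSet) -> bool:
    try:
        for strategy in (Strategy.BSC, Strategy.RITUXIMAB):
            build_matrix(draw, strategy)
    except ValidationError:
        return False
    return True


def sample_psa(
    base: ParameterSet, n_draws: int | None = None, seed: int | None = None
) -> list[ParameterSet]:
    """``n_draws`` independent sampled parameter sets (reproducible from seed)."""
    n = n_draws if n_draws is not None else base.settings.psa_draws
    if n < 1:
        raise ValidationError("n_draws must be >= 1")
    rng = np.random.default_rng(seed if seed is not None else base.settings.seed)
    draws = []
    for _ in range(n):
        for _attempt in range(100):
            draw = base.with_values(_draw_values(base, rng))
            if _feasible(draw):
                break
        else:  # pragma: no cover - would need pathological inputs
            raise ValidationError("could not draw a feasible parameter set")
        draws.append(draw)
    return draws


@dataclass(frozen=True)
class PsaResult:
    """Per-draw discounted (cost, QALY) pairs for each strategy."""

    strategies: tuple[Strategy, ...]
    costs: np.ndarray  # (n_draws, n_strategies) THB
    qalys: np.ndarray  # (n_draws, n_strategies)
    seed: int

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def mean_costs(self) -> dict[Strategy, float]:
        return dict(zip(self.strategies, self.costs.mean(axis=0)))

    def mean_qalys(self) -> dict[Strategy, float]:
        return dict(zip(self.strategies, self.qalys.mean(axis=0)))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for j, s in enumerate(self.strategies):
            for i in range(self.n_draws):
                rows.append(
                    {"draw": i, "strategy": s.value,
                     "cost_thb": self.costs[i, j], "qaly": self.qalys[i, j]}
                )
        return pd.DataFrame(rows)


def _batch_evaluate(draws: list[ParameterSet], strategies) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized cohort propagation + accrual over all PSA draws.

    Rituximab and its biosimilar share the treated transition matrix, so only
    two traces per draw are propagated; their cost vectors differ by drug cost.
    """
    n = len(draws)
    settings = draws[0].settings
    H = settings.horizon_cycles
    alive = [s.value for s in ALIVE_STATES]

    need_bsc = Strategy.BSC in strategies
    need_treated = any(s.treated for s in strategies)
    mats = {}
    if need_bsc:
        mats["bsc"] = np.stack([build_matrix(d, Strategy.BSC).values for d in draws])
    if need_treated:
        mats["treated"] = np.stack(
            [build_matrix(d, Strategy.RITUXIMAB).values for d in draws]
        )

    # per-draw state cost vectors and utilities
    cost_vecs = {
        s: np.stack(
            [state_cost_components(d, s).to_numpy().sum(axis=1) for d in draws]
        )
        for s in strategies
    }
    utils = np.stack(
        [[d.values[u] for u in ("u_edss0", "u_rel0", "u_edss3", "u_rel3", "u_edss6", "u_edss8")]
         for d in draws]
    )

    t = np.arange(H)
    df_cost = discount_factor(t, settings.discount_cost_annual)
    df_out = discount_factor(t, settings.discount_outcome_annual)

    costs = {s: np.zeros(n) for s in strategies}
    qalys = {s: np.zeros(n) for s in strategies}
    for arm, mat in mats.items():
        x = np.zeros((n, 7))
        x[:, HealthState.EDSS0_2] = 1.0
        arm_strategies = [
            s for s in strategies if (s is Strategy.BSC) == (arm == "bsc")
        ]
        for k in range(H):
            xa = x[:, alive]
            for s in arm_strategies:
                costs[s] += df_cost[k] * np.einsum("ij,ij->i", xa, cost_vecs[s])
                qalys[s] += df_out[k] * np.einsum("ij,ij->i", xa, utils) / 12.0
            x = np.einsum("ni,nij->nj", x, mat)
    cost_arr = np.column_stack([costs[s] for s in strategies])
    qaly_arr = np.column_stack([qalys[s] for s in strategies])
    return cost_arr, qaly_arr


def run_psa(
    base: ParameterSet,
    n_draws: int | None = None,
    seed: int | None = None,
    strategies: tuple[Strategy, ...] = ALL_STRATEGIES,
) -> PsaResult:
    """Sample parameters and evaluate every strategy on each draw."""
    used_seed = seed if seed is not None else base.settings.seed
    draws = sample_psa(base, n_draws, used_seed)
    if base.settings.half_cycle:
        # half-cycle accrual takes the slower per-draw path
        costs = np.empty((len(draws), len(strategies)))
        qalys = np.empty_like(costs)
        for i, d in enumerate(draws):
            traces = {}
            for j, s in enumerate(strategies):
                key = "t" if s.treated else "b"
                if key not in traces:
                    m = build_matrix(d, s)
                    traces[key] = run_cohort(m, horizon_cycles=d.settings.horizon_cycles)
                tr = traces[key]
                if tr.strategy is not s:
                    tr = type(tr)(tr.occupancy, s)
                res = accrue(tr, d, s)
                costs[i, j], qalys[i, j] = res.total_cost, res.total_qaly
    else:
        costs, qalys = _batch_evaluate(draws, strategies)
    return PsaResult(tuple(strategies), costs, qalys, used_seed)


@dataclass(frozen=True)
class CeacCurve:
    """P(strategy is cost-effective) over a WTP grid (NMB argmax per draw)."""

    wtp: np.ndarray
    strategies: tuple[Strategy, ...]
    probabilities: np.ndarray  # (len(wtp), n_strategies), rows sum to 1

    def probability_at(self, strategy: Strategy, wtp: float) -> float:
        i = int(np.argmin(np.abs(self.wtp - wtp)))
        return float(self.probabilities[i, self.strategies.index(strategy)])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, columns=[s.value for s in self.strategies])
        df.insert(0, "wtp_thb_per_qaly", self.wtp)
        return df


def ceac(psa: PsaResult, wtp_grid: np.ndarray | None = None) -> CeacCurve:
    """Acceptability curve from PSA draws: ties split equally across winners."""
    if psa.n_draws < 1:
        raise ValidationError("need at least one PSA draw")
    grid = np.asarray(DEFAULT_WTP_GRID if wtp_grid is None else wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("wtp grid must be non-empty")
    probs = np.empty((grid.size, len(psa.strategies)))
    for i, w in enumerate(grid):
        benefit = w * psa.qalys - psa.costs
        best = benefit.max(axis=1, keepdims=True)
        winners = benefit == best
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CeacCurve(grid, psa.strategies, probs)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    outcome_low: float
    outcome_high: float

    @property
    def spread(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _pair_outcome(
    params: ParameterSet, pair: tuple[Strategy, Strategy], outcome: str, wtp: float
) -> float:
    results = {}
    for s in pair:
        m = build_matrix(params, s)
        tr = run_cohort(m, horizon_cycles=params.settings.horizon_cycles)
        results[s] = accrue(tr, params, s)
    a, ref = (results[pair[0]], results[pair[1]])
    d_cost = a.total_cost - ref.total_cost
    d_qaly = a.total_qaly - ref.total_qaly
    if outcome == "inmb":
        return wtp * d_qaly - d_cost
    if outcome == "icer":
        if d_qaly == 0:
            return float("nan")
        return d_cost / d_qaly
    raise ValueError(f"unknown outcome {outcome!r}")


def owsa(
    base: ParameterSet,
    target_params: list[str] | None = None,
    outcome: str = "inmb",
    pair: tuple[Strategy, Strategy] = (Strategy.BIOSIMILAR, Strategy.BSC),
    wtp: float | None = None,
    drug_cost_fraction: float = 0.2,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis (tornado), sorted by descending spread.

    Each parameter is set to the bounds of its 95% CI (fitted-distribution
    quantiles by default; drug acquisition costs use a +/-``drug_cost_fraction``
    band instead), the full model is re-run at each bound with all other
    parameters at base case, and the outcome — incremental net monetary
    benefit at ``wtp`` by default, since the ICER is sign-unstable around
    dominance — is recorded.
    """
    names = list(target_params) if target_params is not None else list(PARAM_NAMES)
    for n in names:
        if n not in base.specs:
            raise ValidationError(f"unknown parameter {n!r}")
    w = wtp if wtp is not None else base.settings.wtp
    entries = []
    for name in names:
        if name in _DRUG_COST_PARAMS:
            lo = base.values[name] * (1 - drug_cost_fraction)
            hi = base.values[name] * (1 + drug_cost_fraction)
        else:
            lo, hi = ci95(base.spec(name), method=base.settings.ci_method)
        # keep the relapse <= band utility ordering while varying one at a time
        for rel, band in _UTILITY_CLIP:
            if name == rel:
                hi = min(hi, base.values[band])
            elif name == band:
                lo = max(lo, base.values[rel])
        out_lo = _pair_outcome(base.with_values({name: lo}), pair, outcome, w)
        out_hi = _pair_outcome(base.with_values({name: hi}), pair, outcome, w)
        entries.append(TornadoEntry(name, lo, hi, out_lo, out_hi))
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


def tornado_to_dataframe(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "outcome_low": e.outcome_low,
                "outcome_high": e.outcome_high,
                "spread": e.spread,
            }
            for e in entries
        ]
    )
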