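"""Individual-level microsimulation: synthetic trajectories and validation.

This is the package's brute-force oracle.  Patients are walked one by one
through the same transition matrix the cohort engine uses; state frequencies
must converge on the cohort trace (law of large numbers), per-arrow maximum
likelihood estimates must recover the generating transition probabilities, and
mean undiscounted accruals must match cohort accrual at zero discount.  None
of these checks share code with the cohort engine beyond the matrix itself.

Randomness protocol: patient ``i`` consumes uniforms ``[i*horizon, (i+1)*horizon)``
of a single seeded PCG64 stream, so trajectories are reproducible and earlier
patients are unchanged when ``n`` grows (for a fixed horizon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ALIVE_STATES, HealthState, Strategy, TransitionMatrix, N_STATES
from .outcomes import state_cost_components
from .params import ParameterSet, ValidationError

__all__ = [
    "PatientTrajectories",
    "simulate_patients",
    "estimate_transitions",
    "TransitionEstimates",
    "compare_cohort_microsim",
]

_CHUNK = 20_000  # patients per simulation block (memory/speed balance)


@dataclass(frozen=True)
class PatientTrajectories:
    """State sequences for ``n`` simulated patients (rows), cycles 0..horizon."""

    states: np.ndarray  # (n, horizon + 1) small ints
    strategy: Strategy
    seed: int

    @property
    def n_patients(self) -> int:
        return self.states.shape[0]

    @property
    def horizon_cycles(self) -> int:
        return self.states.shape[1] - 1

    def state_frequencies(self) -> np.ndarray:
        """(horizon + 1, 7) empirical occupancy proportions per cycle."""
        freq = np.empty((self.states.shape[1], N_STATES))
        for s in range(N_STATES):
            freq[:, s] = (self.states == s).mean(axis=0)
        return freq

    def death_cycle(self) -> np.ndarray:
        """First cycle in death per patient (horizon + 1 if still alive)."""
        dead = self.states == HealthState.DEAD
        first = np.argmax(dead, axis=1)
        first[~dead.any(axis=1)] = self.states.shape[1]
        return first

    def event_log(self) -> pd.DataFrame:
        """Long-format log of relapse entries, progressions and deaths."""
        prev = self.states[:, :-1]
        nxt = self.states[:, 1:]
        events = {
            "relapse": (HealthState.REL0_2, HealthState.REL3_5),
            "progression": (HealthState.EDSS3_5, HealthState.EDSS6_7, HealthState.EDSS8_9),
            "death": (HealthState.DEAD,),
        }
        rows = []
        for label, targets in events.items():
            mask = (prev != nxt) & np.isin(nxt, [t.value for t in targets])
            pid, cyc = np.nonzero(mask)
            for p, c in zip(pid, cyc):
                rows.append(
                    {"patient_id": int(p), "cycle": int(c + 1), "event": label,
                     "state": HealthState(int(nxt[p, c])).display_name}
                )
        return pd.DataFrame(rows, columns=["patient_id", "cycle", "event", "state"])

    def to_dataframe(self) -> pd.DataFrame:
        n, h1 = self.states.shape
        return pd.DataFrame(
            {
                "patient_id": np.repeat(np.arange(n), h1),
                "cycle": np.tile(np.arange(h1), n),
                "state": self.states.ravel(),
            }
        )

    def accrue_undiscounted(self, params: ParameterSet, per_patient: bool = False):
        """Undiscounted (cost, QALY) totals, averaged unless ``per_patient``.

        Start-of-cycle states over cycles ``0 .. horizon-1`` are costed, the
        same accrual convention as the cohort engine at zero discount.
        """
        comp = state_cost_components(params, self.strategy)
        cost_by_state = np.zeros(N_STATES)
        cost_by_state[: len(ALIVE_STATES)] = comp.to_numpy().sum(axis=1)
        u_by_state = np.zeros(N_STATES)
        u_by_state[: len(ALIVE_STATES)] = [
            params.values[k]
            for k in ("u_edss0", "u_rel0", "u_edss3", "u_rel3", "u_edss6", "u_edss8")
        ]
        occupied = self.states[:, :-1]
        costs = cost_by_state[occupied].sum(axis=1)
        qalys = u_by_state[occupied].sum(axis=1) / 12.0
        if per_patient:
            return costs, qalys
        return float(costs.mean()), float(qalys.mean())


def simulate_patients(
    matrix: TransitionMatrix,
    n: int,
    horizon_cycles: int,
    seed: int,
    initial_state: HealthState = HealthState.EDSS0_2,
) -> PatientTrajectories:
    """Simulate ``n`` independent patient trajectories from ``matrix``."""
    if n < 1:
        raise ValidationError("need at least one patient")
    if horizon_cycles < 1:
        raise ValidationError("horizon_cycles must be >= 1")
    cum = np.cumsum(matrix.values, axis=1)
    cum[:, -1] = 1.0  # guard against float round-off at the top bin
    rng = np.random.default_rng(seed)
    states = np.empty((n, horizon_cycles + 1), dtype=np.int8)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        k = stop - start
        u = rng.random((k, horizon_cycles))
        cur = np.full(k, int(initial_state), dtype=np.int8)
        states[start:stop, 0] = cur
        for t in range(horizon_cycles):
            nxt = (u[:, t, None] >= cum[cur]).sum(axis=1)
            cur = nxt.astype(np.int8)
            states[start:stop, t + 1] = cur
    return PatientTrajectories(states, matrix.strategy, seed)


@dataclass(frozen=True)
class TransitionEstimates:
    """Per-arrow MLE ``transitions / cycles at risk`` with exposure counts."""

    probabilities: np.ndarray  # (7, 7); NaN rows where exposure is zero
    exposure: np.ndarray  # (7,) cycles at risk per source state
    counts: np.ndarray  # (7, 7) observed transitions

    @property
    def undefined_states(self) -> tuple[HealthState, ...]:
        return tuple(HealthState(int(i)) for i in np.nonzero(self.exposure == 0)[0])

    def named(self) -> dict[str, float]:
        """Estimates for the named BSC arrows of the model diagram."""
        H = HealthState
        p = self.probabilities
        return {
            "p_edss3": p[H.EDSS0_2, H.EDSS3_5],
            "p_edss6": p[H.EDSS3_5, H.EDSS6_7],
            "p_edss8": p[H.EDSS6_7, H.EDSS8_9],
            "p_edss10": p[H.EDSS8_9, H.DEAD],
            "p_relapse": p[H.EDSS0_2, H.REL0_2],
            "p_death_edss0": p[H.EDSS0_2, H.DEAD],
            "p_death_edss3": p[H.EDSS3_5, H.DEAD],
        }


def estimate_transitions(trajectories: PatientTrajectories) -> TransitionEstimates:
    """Maximum-likelihood per-cycle transition frequencies from trajectories."""
    prev = trajectories.states[:, :-1].ravel()
    nxt = trajectories.states[:, 1:].ravel()
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (prev, nxt), 1)
    exposure = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / exposure[:, None]
    return TransitionEstimates(probs, exposure, counts)


def compare_cohort_microsim(trace, trajectories: PatientTrajectories) -> np.ndarray:
    """Per-cycle max |empirical state frequency - cohort occupancy|."""
    if trace.horizon_cycles != trajectories.horizon_cycles:
        raise ValidationError(
            f"horizon mismatch: trace {trace.horizon_cycles} vs "
            f"microsim {trajectories.horizon_cycles}"
        )
    freq = trajectories.state_frequencies()
    return np.abs(freq - trace.occupancy).max(axis=1)
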