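"""Seven-state monthly Markov cohort engine.

Health states follow the EDSS banding used in Thai HTA modelling of MS:
four living severity bands (EDSS 0.0-2.5, 3.0-5.5, 6.0-7.5, 8.0-9.5), two
transient relapse states attached to the first two bands, and death.  Disease
is strictly progressive: no arrow ever points to a lower band, and death is
absorbing.

Strategy differences are confined to the transition rows of the first two
bands (rituximab reduces relapse entry and slows progression) — treatment
stops at EDSS 6.0, so rows from EDSS 6.0-7.5 onward are identical across
strategies.  The biosimilar shares the rituximab rows entirely; it differs
only in drug cost, which lives in :mod:`mscua.outcomes`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ParameterSet, ValidationError

__all__ = [
    "HealthState",
    "Strategy",
    "TransitionMatrix",
    "CohortTrace",
    "build_matrix",
    "run_cohort",
]


class HealthState(IntEnum):
    EDSS0_2 = 0
    REL0_2 = 1
    EDSS3_5 = 2
    REL3_5 = 3
    EDSS6_7 = 4
    EDSS8_9 = 5
    DEAD = 6

    @property
    def display_name(self) -> str:
        return _DISPLAY[self]

    @property
    def band(self) -> int | None:
        """EDSS band index 0..3, or None for death."""
        return {0: 0, 1: 0, 2: 1, 3: 1, 4: 2, 5: 3}.get(self.value)

    @property
    def is_relapse(self) -> bool:
        return self in (HealthState.REL0_2, HealthState.REL3_5)


_DISPLAY = {
    HealthState.EDSS0_2: "EDSS 0.0-2.5",
    HealthState.REL0_2: "Relapse EDSS 0.0-2.5",
    HealthState.EDSS3_5: "EDSS 3.0-5.5",
    HealthState.REL3_5: "Relapse EDSS 3.0-5.5",
    HealthState.EDSS6_7: "EDSS 6.0-7.5",
    HealthState.EDSS8_9: "EDSS 8.0-9.5",
    HealthState.DEAD: "Death",
}

N_STATES = len(HealthState)

#: states in which a treated patient is receiving drug (stops at EDSS 6.0)
ON_TREATMENT_STATES = (
    HealthState.EDSS0_2, HealthState.REL0_2, HealthState.EDSS3_5, HealthState.REL3_5,
)

#: alive states
ALIVE_STATES = tuple(s for s in HealthState if s is not HealthState.DEAD)


class Strategy(str, Enum):
    BSC = "BSC"
    RITUXIMAB = "Rituximab"
    BIOSIMILAR = "Rituximab biosimilar"

    @property
    def treated(self) -> bool:
        return self is not Strategy.BSC


# state pairs that would mean EDSS improvement; must stay zero in any matrix.
# (Relapse recovery back to the parent band is not an improvement.)
_FORBIDDEN = [
    (HealthState.EDSS3_5, HealthState.EDSS0_2),
    (HealthState.EDSS3_5, HealthState.REL0_2),
    (HealthState.REL3_5, HealthState.EDSS0_2),
    (HealthState.REL3_5, HealthState.REL0_2),
    (HealthState.EDSS6_7, HealthState.EDSS0_2),
    (HealthState.EDSS6_7, HealthState.REL0_2),
    (HealthState.EDSS6_7, HealthState.EDSS3_5),
    (HealthState.EDSS6_7, HealthState.REL3_5),
    (HealthState.EDSS8_9, HealthState.EDSS0_2),
    (HealthState.EDSS8_9, HealthState.REL0_2),
    (HealthState.EDSS8_9, HealthState.EDSS3_5),
    (HealthState.EDSS8_9, HealthState.REL3_5),
    (HealthState.EDSS8_9, HealthState.EDSS6_7),
    (HealthState.DEAD, HealthState.EDSS0_2),
    (HealthState.DEAD, HealthState.REL0_2),
    (HealthState.DEAD, HealthState.EDSS3_5),
    (HealthState.DEAD, HealthState.REL3_5),
    (HealthState.DEAD, HealthState.EDSS6_7),
    (HealthState.DEAD, HealthState.EDSS8_9),
    # relapse entry only from the band's own non-relapse state
    (HealthState.EDSS0_2, HealthState.REL3_5),
    (HealthState.EDSS6_7, HealthState.REL0_2),
    (HealthState.EDSS6_7, HealthState.REL3_5),
    (HealthState.EDSS8_9, HealthState.REL0_2),
    (HealthState.EDSS8_9, HealthState.REL3_5),
]


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 7x7 monthly transition matrix for one strategy."""

    values: np.ndarray
    strategy: Strategy

    def __post_init__(self) -> None:
        m = np.asarray(self.values, dtype=float)
        if m.shape != (N_STATES, N_STATES):
            raise ValidationError(f"matrix must be {N_STATES}x{N_STATES}, got {m.shape}")
        if np.any(m < -1e-15) or np.any(m > 1 + 1e-12):
            raise ValidationError("matrix entries must be probabilities in [0, 1]")
        rows = m.sum(axis=1)
        bad = np.where(np.abs(rows - 1.0) > 1e-12)[0]
        if bad.size:
            raise ValidationError(
                f"rows not stochastic: {[HealthState(i).display_name for i in bad]}"
            )
        for frm, to in _FORBIDDEN:
            if m[frm, to] != 0.0:
                raise ValidationError(
                    f"forbidden transition {HealthState(frm).display_name} -> "
                    f"{HealthState(to).display_name} has probability {m[frm, to]}"
                )
        if m[HealthState.DEAD, HealthState.DEAD] != 1.0:
            raise ValidationError("death must be absorbing")
        object.__setattr__(self, "values", m)

    def __getitem__(self, key) -> float:
        return float(self.values[key])

    def to_dataframe(self) -> pd.DataFrame:
        names = [s.display_name for s in HealthState]
        return pd.DataFrame(self.values, index=names, columns=names)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


def _row(m: np.ndarray, frm: HealthState, entries: dict[HealthState, float]) -> None:
    """Fill one row; the diagonal takes the remaining mass."""
    out = sum(entries.values())
    if out > 1.0 + 1e-12:
        raise ValidationError(
            f"outgoing probabilities from {frm.display_name} sum to {out:.6f} > 1"
        )
    for to, p in entries.items():
        if not 0.0 <= p <= 1.0:
            raise ValidationError(
                f"transition {frm.display_name} -> {to.display_name} = {p} outside [0, 1]"
            )
        m[frm, to] = p
    m[frm, frm] = 1.0 - min(out, 1.0)


def build_matrix(params: ParameterSet, strategy: Strategy) -> TransitionMatrix:
    """Strategy-specific monthly transition matrix from the parameter set.

    Treated strategies (rituximab / biosimilar, identical by assumption) use
    the treated progression probabilities and a reduced relapse-entry
    probability in the EDSS 0.0-5.5 rows; from EDSS 6.0-7.5 onward treatment
    has stopped and the rows equal the BSC rows.  Conventions taken from
    ``params.settings``:

    * ``relapse_effect_form`` — ``relative_risk`` multiplies the BSC relapse
      probability by ``relapse_effect``; ``probability`` uses
      ``relapse_effect`` directly as the treated relapse probability.
    * ``relapse_return`` — ``one_cycle``: a relapse lasts one cycle (return
      with all probability not spent on death/progression); ``symmetric``:
      return probability equals the relapse-entry probability.
    * ``relapse_progression`` — whether EDSS progression can occur during a
      relapse cycle.
    * ``p_death_edss6`` — MS mortality from EDSS 6.0-7.5 (no tabulated value).
    """
    s = params.settings
    v = params.values
    if strategy.treated:
        if s.relapse_effect_form == "relative_risk":
            p_rel = v["p_relapse"] * v["relapse_effect"]
        else:
            p_rel = v["relapse_effect"]
        p03, p36 = v["p_prog_rtx_0to3"], v["p_prog_rtx_3to6"]
    else:
        p_rel = v["p_relapse"]
        p03, p36 = v["p_edss3"], v["p_edss6"]
    p_rel = min(p_rel, 1.0)

    m = np.zeros((N_STATES, N_STATES))
    H = HealthState
    _row(m, H.EDSS0_2, {H.REL0_2: p_rel, H.EDSS3_5: p03, H.DEAD: v["p_death_edss0"]})
    _row(m, H.EDSS3_5, {H.REL3_5: p_rel, H.EDSS6_7: p36, H.DEAD: v["p_death_edss3"]})

    for rel, parent, prog_to, p_prog, p_death in (
        (H.REL0_2, H.EDSS0_2, H.EDSS3_5, p03, v["p_death_edss0"]),
        (H.REL3_5, H.EDSS3_5, H.EDSS6_7, p36, v["p_death_edss3"]),
    ):
        entries = {H.DEAD: p_death}
        if s.relapse_progression:
            entries[prog_to] = p_prog
        if s.relapse_return == "one_cycle":
            entries[parent] = 1.0 - sum(entries.values())
        else:  # symmetric: leave relapse at the relapse-entry probability
            entries[parent] = min(p_rel, 1.0 - sum(entries.values()))
        _row(m, rel, entries)

    _row(m, H.EDSS6_7, {H.EDSS8_9: v["p_edss8"], H.DEAD: s.p_death_edss6})
    _row(m, H.EDSS8_9, {H.DEAD: v["p_edss10"]})
    m[H.DEAD, H.DEAD] = 1.0
    return TransitionMatrix(m, strategy)


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy proportions per cycle; row 0 is the initial cohort."""

    occupancy: np.ndarray  # (horizon + 1, 7)
    strategy: Strategy

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValidationError("trace must have one column per health state")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-10):
            raise ValidationError("trace rows must each sum to 1")
        dead = occ[:, HealthState.DEAD]
        if np.any(np.diff(dead) < -1e-12):
            raise ValidationError("death occupancy must be non-decreasing")
        object.__setattr__(self, "occupancy", occ)

    @property
    def horizon_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.display_name for s in HealthState])
        df.index.name = "cycle"
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


def run_cohort(
    matrix: TransitionMatrix,
    initial: np.ndarray | None = None,
    horizon_cycles: int = 600,
) -> CohortTrace:
    """Propagate a closed cohort: row ``t+1`` = row ``t`` @ matrix.

    ``initial`` defaults to the whole cohort in EDSS 0.0-2.5 (newly diagnosed
    RRMS).
    """
    if horizon_cycles < 1:
        raise ValidationError("horizon_cycles must be >= 1")
    if initial is None:
        x = np.zeros(N_STATES)
        x[HealthState.EDSS0_2] = 1.0
    else:
        x = np.asarray(initial, dtype=float)
        if x.shape != (N_STATES,) or np.any(x < 0) or abs(x.sum() - 1.0) > 1e-10:
            raise ValidationError("initial occupancy must be a length-7 simplex vector")
    occ = np.empty((horizon_cycles + 1, N_STATES))
    occ[0] = x
    mv = matrix.values
    for t in range(horizon_cycles):
        x = x @ mv
        occ[t + 1] = x
    # guard against drift over long horizons
    occ /= occ.sum(axis=1, keepdims=True)
    return CohortTrace(occ, matrix.strategy)
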