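"""Model inputs: parameter table, distribution fitting, and settings.

All uncertain inputs are described by a distribution family (``beta`` for
probabilities and utilities, ``gamma`` for costs) together with a mean and
standard deviation.  Shapes are obtained by method of moments, the standard
parameterization in health-technology-assessment practice when only the first
two moments are published:

* Beta:  ``k = mean (1 - mean) / sd^2 - 1``, ``alpha = mean k``,
  ``beta = (1 - mean) k``; feasible iff ``sd^2 < mean (1 - mean)``.
* Gamma: ``shape = (mean / sd)^2``, ``scale = sd^2 / mean``.

A :class:`ParameterSet` couples the full table of :class:`ParamSpec` entries
with a vector of *current values* (the means in the base case, or one Monte
Carlo draw during probabilistic sensitivity analysis) plus the
:class:`ModelSettings` block that fixes cycle length, horizon, discounting and
the modelling conventions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "ParamSpec",
    "ModelSettings",
    "ParameterSet",
    "ValidationError",
    "beta_moments",
    "gamma_moments",
    "ci95",
    "load_parameters",
    "default_parameters",
]

_FAMILIES = ("beta", "gamma", "fixed")

#: Parameter names grouped by the sections of the input file.
SECTIONS: dict[str, tuple[str, ...]] = {
    "transitions": (
        "p_edss3", "p_edss6", "p_edss8", "p_edss10",
        "p_relapse", "p_death_edss0", "p_death_edss3",
    ),
    "treatment_effect": ("relapse_effect", "p_prog_rtx_0to3", "p_prog_rtx_3to6"),
    "adverse_events": (
        "p_infusion_reaction", "p_minor_infection", "p_agranulocytosis",
        "p_pneumonia", "c_infusion_reaction", "c_minor_infection",
        "c_agranulocytosis", "c_pneumonia",
    ),
    "costs": (
        "opd_cost_edss0", "opd_cost_edss3", "opd_cost_edss6", "opd_cost_edss8",
        "relapse_cost_edss0", "relapse_cost_edss3", "relapse_cost_edss6",
        "relapse_cost_edss8",
        "nonmed_cost_edss0", "nonmed_cost_edss3", "nonmed_cost_edss6",
        "nonmed_cost_edss8",
        "c_rituximab_month", "c_biosimilar_month", "c_admin_month",
    ),
    "utilities": ("u_edss0", "u_rel0", "u_edss3", "u_rel3", "u_edss6", "u_edss8"),
}

#: All parameter names in file order.
PARAM_NAMES: tuple[str, ...] = tuple(n for sec in SECTIONS.values() for n in sec)


class ValidationError(ValueError):
    """An input violates a parameter or settings invariant."""


def beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Beta shape parameters ``(alpha, beta)``.

    Requires ``0 < mean < 1`` and ``0 < sd^2 < mean (1 - mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"beta mean must be in (0, 1), got {mean}")
    var = sd * sd
    if not 0.0 < var < mean * (1.0 - mean):
        raise ValidationError(
            f"infeasible beta moments: need 0 < sd^2 < mean(1-mean), "
            f"got mean={mean}, sd={sd}"
        )
    k = mean * (1.0 - mean) / var - 1.0
    return mean * k, (1.0 - mean) * k


def gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Gamma ``(shape, scale)`` with ``shape*scale = mean``."""
    if mean <= 0 or sd <= 0:
        raise ValidationError(
            f"gamma moments require mean > 0 and sd > 0, got mean={mean}, sd={sd}"
        )
    return (mean / sd) ** 2, sd * sd / mean


@dataclass(frozen=True)
class ParamSpec:
    """One row of the input table: a named quantity and its distribution."""

    name: str
    family: str
    mean: float
    sd: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(
                f"{self.name}: unknown family {self.family!r} (expected one of {_FAMILIES})"
            )
        if self.sd < 0:
            raise ValidationError(f"{self.name}: sd must be nonnegative, got {self.sd}")
        if self.family == "fixed":
            return
        if self.sd == 0:
            raise ValidationError(
                f"{self.name}: sd = 0 is only permitted with family='fixed'"
            )
        # moment fits raise ValidationError on infeasible mean/sd pairs
        if self.family == "beta":
            beta_moments(self.mean, self.sd)
        else:
            gamma_moments(self.mean, self.sd)

    def distribution(self):
        """Frozen scipy distribution fitted by method of moments (None if fixed)."""
        if self.family == "beta":
            a, b = beta_moments(self.mean, self.sd)
            return stats.beta(a, b)
        if self.family == "gamma":
            shape, scale = gamma_moments(self.mean, self.sd)
            return stats.gamma(shape, scale=scale)
        return None

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the fitted distribution (the mean itself if fixed)."""
        if self.family == "beta":
            a, b = beta_moments(self.mean, self.sd)
            return rng.beta(a, b, size=size)
        if self.family == "gamma":
            shape, scale = gamma_moments(self.mean, self.sd)
            return rng.gamma(shape, scale, size=size)
        return np.full(size, self.mean) if size is not None else self.mean


def ci95(spec: ParamSpec, method: str = "quantile") -> tuple[float, float]:
    """95% interval of the fitted distribution.

    ``method='quantile'`` returns the 2.5th and 97.5th percentiles;
    ``method='normal'`` returns ``mean +/- 1.96 sd`` truncated to the
    distribution's support (useful for comparison with normal-approximation
    reporting, but it collapses for the Table rows whose sd equals the mean).
    Fixed parameters return ``(mean, mean)``.
    """
    if spec.family == "fixed":
        return spec.mean, spec.mean
    if method == "normal":
        lo = spec.mean - 1.96 * spec.sd
        hi = spec.mean + 1.96 * spec.sd
        lo = max(lo, 0.0)
        if spec.family == "beta":
            hi = min(hi, 1.0)
        return lo, hi
    if method != "quantile":
        raise ValueError(f"unknown ci method {method!r}")
    dist = spec.distribution()
    return float(dist.ppf(0.025)), float(dist.ppf(0.975))


_CONVENTION_CHOICES = {
    "relapse_return": ("one_cycle", "symmetric"),
    "relapse_effect_form": ("relative_risk", "probability"),
    "ci_method": ("quantile", "normal"),
}


@dataclass
class ModelSettings:
    """Cycle structure, discounting, thresholds and modelling conventions."""

    cycle_length_months: float = 1.0
    horizon_cycles: int = 600
    discount_cost_annual: float = 0.03
    discount_outcome_annual: float = 0.03
    wtp: float = 160_000.0
    thb_per_usd: float = 37.97
    psa_draws: int = 1000
    seed: int = 20220101
    relapse_return: str = "one_cycle"
    relapse_effect_form: str = "relative_risk"
    relapse_progression: bool = True
    p_death_edss6: float = 0.0
    half_cycle: bool = False
    discount_ly: bool = True
    ci_method: str = "quantile"

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ValidationError("horizon_cycles must be >= 1")
        for rate_name in ("discount_cost_annual", "discount_outcome_annual"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{rate_name} must be in [0, 1], got {rate}")
        if not 0.0 <= self.p_death_edss6 <= 1.0:
            raise ValidationError("p_death_edss6 must be in [0, 1]")
        for key, choices in _CONVENTION_CHOICES.items():
            if getattr(self, key) not in choices:
                raise ValidationError(
                    f"{key} must be one of {choices}, got {getattr(self, key)!r}"
                )

    def replace(self, **kwargs) -> "ModelSettings":
        return dataclasses.replace(self, **kwargs)


# extra cross-parameter checks applied when a full set is assembled
_UTILITY_ORDER = (("u_rel0", "u_edss0"), ("u_rel3", "u_edss3"))


class ParameterSet:
    """The full input table plus settings; single source of truth.

    ``values`` maps every parameter name to its current value — the table
    means for the base case, or one sampled realization during PSA.  The specs
    (distribution metadata) are shared between base and sampled sets.
    """

    def __init__(
        self,
        specs: Mapping[str, ParamSpec],
        settings: ModelSettings | None = None,
        values: Mapping[str, float] | None = None,
    ) -> None:
        missing = [n for n in PARAM_NAMES if n not in specs]
        if missing:
            raise ValidationError(f"missing parameter(s): {', '.join(missing)}")
        self.specs = dict(specs)
        self.settings = settings if settings is not None else ModelSettings()
        if values is None:
            values = {n: s.mean for n, s in self.specs.items()}
        self.values = {n: float(values[n]) for n in self.specs}
        self._check()

    def _check(self) -> None:
        for name in PARAM_NAMES:
            spec = self.specs[name]
            v = self.values[name]
            if spec.family == "beta" and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}: value {v} outside [0, 1]")
            if spec.family in ("gamma", "fixed") and v < 0:
                raise ValidationError(f"{name}: value {v} is negative")
        for lo_name, hi_name in _UTILITY_ORDER:
            if self.values[lo_name] > self.values[hi_name] + 1e-12:
                raise ValidationError(
                    f"relapse utility {lo_name} exceeds its band utility {hi_name}"
                )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.specs)

    def spec(self, name: str) -> ParamSpec:
        return self.specs[name]

    def with_values(self, values: Mapping[str, float]) -> "ParameterSet":
        """New set sharing specs/settings, with some values overridden."""
        merged = dict(self.values)
        merged.update(values)
        return ParameterSet(self.specs, self.settings, merged)

    def with_settings(self, **kwargs) -> "ParameterSet":
        return ParameterSet(self.specs, self.settings.replace(**kwargs), self.values)

    # -- convenience vectors used by the engine ---------------------------

    def expected_ae_cost_per_cycle(self) -> float:
        """Expected adverse-event cost per monthly cycle on treatment.

        Annual event probabilities times unit costs, divided by 12.
        """
        pairs = (
            ("p_infusion_reaction", "c_infusion_reaction"),
            ("p_minor_infection", "c_minor_infection"),
            ("p_agranulocytosis", "c_agranulocytosis"),
            ("p_pneumonia", "c_pneumonia"),
        )
        return sum(self.values[p] * self.values[c] for p, c in pairs) / 12.0

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        doc: dict = {}
        for section, names in SECTIONS.items():
            doc[section] = {}
            for n in names:
                s = self.specs[n]
                row = {"family": s.family, "mean": s.mean, "sd": s.sd, "source": s.source}
                doc[section][n] = row
        doc["settings"] = dataclasses.asdict(self.settings)
        return doc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ParameterSet":
        specs: dict[str, ParamSpec] = {}
        for section, names in SECTIONS.items():
            block = doc.get(section)
            if block is None:
                raise ValidationError(f"missing section {section!r}")
            for n in names:
                if n not in block:
                    raise ValidationError(f"missing parameter {section}.{n}")
                row = block[n]
                try:
                    specs[n] = ParamSpec(
                        name=n,
                        family=row["family"],
                        mean=float(row["mean"]),
                        sd=float(row.get("sd", 0.0)),
                        source=str(row.get("source", "")),
                    )
                except KeyError as exc:
                    raise ValidationError(f"{section}.{n}: missing field {exc}") from exc
        settings_doc = dict(doc.get("settings", {}))
        known = {f.name for f in dataclasses.fields(ModelSettings)}
        unknown = set(settings_doc) - known
        if unknown:
            raise ValidationError(f"unknown settings field(s): {', '.join(sorted(unknown))}")
        settings = ModelSettings(**settings_doc)
        return cls(specs, settings)


def load_parameters(config_path: str | Path) -> ParameterSet:
    """Load and validate a parameter file (YAML, sections as in the schema)."""
    with open(config_path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValidationError(f"{config_path}: not a mapping document")
    return ParameterSet.from_dict(doc)


def default_parameters() -> ParameterSet:
    """The bundled Thai RRMS base case (2022 THB)."""
    from importlib.resources import files

    path = files("mscua").joinpath("data/thailand_rrms_2022.yaml")
    return ParameterSet.from_dict(yaml.safe_load(path.read_text()))
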