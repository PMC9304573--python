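"""Model inputs: definition, validation, loading and uncertainty specification.

Every quantity the decision model reads — transition probabilities, mortality
ratios, per-state annual costs, one-off costs, utilities — is carried as a
:class:`ParameterSpec` with a base-case value, a standard error (or explicit
bounds) and a distribution family used by the probabilistic analysis:

* ``beta`` for probabilities and utilities (support [0, 1]),
* ``gamma`` for costs (support [0, inf)),
* ``fixed`` for quantities held constant between draws.

A packaged default configuration reproduces the Siriraj Hospital inputs
(2020 USD) so ``load_parameters()`` with no arguments yields the base case.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "ParameterError",
    "ParameterSpec",
    "ParameterSet",
    "load_parameters",
    "save_parameters",
    "default_config_path",
    "dsa_bounds",
    "fit_beta_moments",
    "fit_gamma_moments",
    "REQUIRED_PARAMETERS",
]

_FAMILIES = {"beta", "gamma", "fixed"}
_ROLES = {"probability", "cost", "utility", "ratio", "rate-config"}

#: Names the three strategies and the mortality model require.
REQUIRED_PARAMETERS: tuple[str, ...] = (
    "p_dialysis_to_kt_lrkt",
    "p_dialysis_to_kt_ddkt",
    "p_graft_loss_year1",
    "p_graft_loss_subsequent",
    "smr_50_59",
    "smr_60_69",
    "smr_70_79",
    "smr_80_plus",
    "eskd_vs_kt_mortality_ratio",
    "cost_dialysis",
    "cost_direct_nonmedical",
    "cost_kt_plrkt",
    "cost_post1_plrkt",
    "cost_subsequent_plrkt",
    "cost_waiting_plrkt",
    "cost_kt_nplrkt",
    "cost_post1_nplrkt",
    "cost_subsequent_nplrkt",
    "cost_kt_npddkt",
    "cost_post1_npddkt",
    "cost_subsequent_npddkt",
    "utility_dialysis",
    "utility_kt",
    "utility_post1",
    "utility_subsequent",
)


class ParameterError(ValueError):
    """Invalid parameter value, uncertainty specification, or configuration."""


@dataclass(frozen=True)
class ParameterSpec:
    """One model input with its base-case value and uncertainty."""

    name: str
    value: float
    se: float | None = None
    low: float | None = None
    high: float | None = None
    family: str = "fixed"
    units: str = ""
    role: str = "rate-config"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(f"{self.name}: unknown family {self.family!r}")
        if self.role not in _ROLES:
            raise ParameterError(f"{self.name}: unknown role {self.role!r}")
        if self.value < 0:
            raise ParameterError(f"{self.name}: value must be >= 0, got {self.value}")
        if self.se is not None and self.se < 0:
            raise ParameterError(f"{self.name}: se must be >= 0, got {self.se}")
        if self.family == "beta":
            if not 0.0 <= self.value <= 1.0:
                raise ParameterError(
                    f"{self.name}: beta-family value must lie in [0, 1], got {self.value}"
                )
            if self.se and 0.0 < self.value < 1.0:
                if self.se**2 >= self.value * (1.0 - self.value):
                    raise ParameterError(
                        f"{self.name}: se^2 = {self.se**2:.6g} >= value*(1-value) = "
                        f"{self.value * (1 - self.value):.6g}; beta moments undefined"
                    )
        if self.family == "gamma" and self.value <= 0:
            raise ParameterError(f"{self.name}: gamma-family value must be > 0")
        if self.low is not None and self.high is not None:
            if not self.low <= self.value <= self.high:
                raise ParameterError(
                    f"{self.name}: require low <= value <= high, got "
                    f"({self.low}, {self.value}, {self.high})"
                )


@dataclass
class ParameterSet:
    """The full input configuration of the decision model."""

    specs: dict[str, ParameterSpec]
    discount_rate: float = 0.03
    wtp: float = 5113.0
    start_age: int = 50
    kt_stop_age: int = 65
    max_age: int = 100
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate <= 0.06:
            raise ParameterError(
                f"discount_rate must lie in [0, 0.06], got {self.discount_rate}"
            )
        if self.wtp <= 0:
            raise ParameterError(f"wtp must be positive, got {self.wtp}")
        if not self.start_age < self.kt_stop_age < self.max_age:
            raise ParameterError(
                "require start_age < kt_stop_age < max_age, got "
                f"({self.start_age}, {self.kt_stop_age}, {self.max_age})"
            )
        missing = [n for n in REQUIRED_PARAMETERS if n not in self.specs]
        if missing:
            raise ParameterError(f"missing required parameters: {', '.join(missing)}")

    def spec(self, name: str) -> ParameterSpec:
        try:
            return self.specs[name]
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    def value(self, name: str) -> float:
        return self.spec(name).value

    def with_values(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with selected base-case values replaced.

        Validation of the beta moment condition is relaxed for overridden
        values (sensitivity analyses may push a value to its bound).
        """
        specs = dict(self.specs)
        for name, value in overrides.items():
            old = self.spec(name)
            new = object.__new__(ParameterSpec)
            object.__setattr__(new, "name", old.name)
            object.__setattr__(new, "value", float(value))
            for f in ("se", "low", "high", "family", "units", "role"):
                object.__setattr__(new, f, getattr(old, f))
            specs[name] = new
        out = copy.copy(self)
        out.specs = specs
        return out

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        settings = dict(self.settings)
        settings.update(
            discount_rate=self.discount_rate,
            wtp=self.wtp,
            start_age=self.start_age,
            kt_stop_age=self.kt_stop_age,
            max_age=self.max_age,
        )
        params = []
        for s in self.specs.values():
            d = {"name": s.name, "value": s.value, "family": s.family, "role": s.role}
            if s.se is not None:
                d["se"] = s.se
            if s.low is not None:
                d["low"] = s.low
            if s.high is not None:
                d["high"] = s.high
            if s.units:
                d["units"] = s.units
            params.append(d)
        return {"settings": settings, "parameters": params}

    @classmethod
    def from_dict(cls, data: Mapping) -> "ParameterSet":
        try:
            raw_settings = dict(data["settings"])
            raw_params = data["parameters"]
        except KeyError as exc:
            raise ParameterError(f"config missing top-level section {exc}") from None
        specs: dict[str, ParameterSpec] = {}
        for block in raw_params:
            allowed = {"name", "value", "se", "low", "high", "family", "units", "role"}
            extra = set(block) - allowed
            if extra:
                raise ParameterError(
                    f"parameter block {block.get('name', '?')}: unknown fields {sorted(extra)}"
                )
            spec = ParameterSpec(**block)
            if spec.name in specs:
                raise ParameterError(f"duplicate parameter {spec.name!r}")
            specs[spec.name] = spec
        kwargs = {
            k: raw_settings.pop(k)
            for k in ("discount_rate", "wtp", "start_age", "kt_stop_age", "max_age")
            if k in raw_settings
        }
        return cls(specs=specs, settings=raw_settings, **kwargs)


def default_config_path():
    """Path to the packaged Siriraj base-case configuration."""
    return resources.files("ktcea.data") / "params_siriraj_2020usd.yaml"


def load_parameters(path=None) -> ParameterSet:
    """Load and validate a parameter configuration (packaged default if ``path`` is None)."""
    if path is None:
        text = default_config_path().read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ParameterError("config file does not parse to a mapping")
    return ParameterSet.from_dict(data)


def save_parameters(params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def dsa_bounds(spec: ParameterSpec) -> tuple[float, float]:
    """Deterministic-sensitivity range for one parameter.

    Explicit bounds win; otherwise the 95% confidence interval (value
    +/- 1.96 se); otherwise +/-15% of the base-case value.  Probabilities and
    utilities are clamped to [0, 1]; costs to >= 0.
    """
    if spec.low is not None and spec.high is not None:
        low, high = float(spec.low), float(spec.high)
    elif spec.se:
        low, high = spec.value - 1.96 * spec.se, spec.value + 1.96 * spec.se
    else:
        low, high = spec.value * 0.85, spec.value * 1.15
    if spec.role in ("probability", "utility") or spec.family == "beta":
        low, high = max(low, 0.0), min(high, 1.0)
    elif spec.role == "cost" or spec.family == "gamma":
        low = max(low, 0.0)
    low = min(low, spec.value)
    high = max(high, spec.value)
    return low, high


def fit_beta_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta parameters for a given mean and standard error."""
    if not 0.0 < mean < 1.0 or se <= 0:
        raise ParameterError(f"beta moments need 0 < mean < 1 and se > 0, got ({mean}, {se})")
    if se**2 >= mean * (1.0 - mean):
        raise ParameterError(
            f"se^2 = {se**2:.6g} >= mean*(1-mean) = {mean * (1 - mean):.6g}; "
            "beta distribution with these moments does not exist"
        )
    k = mean * (1.0 - mean) / se**2 - 1.0
    return mean * k, (1.0 - mean) * k


def fit_gamma_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale) for a given mean and standard error."""
    if mean <= 0 or se <= 0:
        raise ParameterError(f"gamma moments need mean > 0 and se > 0, got ({mean}, {se})")
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return shape, scale


def effective_beta_se(mean: float, se: float, name: str = "") -> float:
    """Standard error usable for beta sampling; shrinks an infeasible se.

    Utilities near 1 with a large printed SE can violate the moment condition
    se^2 < mean*(1-mean); the sampler then uses 0.99 * sqrt(mean*(1-mean)) and
    warns, keeping the probabilistic analysis runnable with printed inputs.
    """
    limit = math.sqrt(mean * (1.0 - mean))
    if se >= limit:
        adjusted = 0.99 * limit
        warnings.warn(
            f"{name or 'parameter'}: se {se:.4g} infeasible for beta mean {mean:.4g}; "
            f"using {adjusted:.4g}",
            stacklevel=2,
        )
        return adjusted
    return se
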