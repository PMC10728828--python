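"""Small declarative distribution specs used by the cohort generator.

A spec is a plain mapping, e.g. ``{"name": "lognormal", "median": 4e9,
"sigma": 1.0}``, so it can round-trip through YAML/JSON config files
unchanged. Sampling goes through :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError

_SUPPORTED = ("lognormal", "beta", "uniform", "constant")


@dataclass(frozen=True)
class DistSpec:
    """A named univariate distribution with keyword parameters.

    Supported names and parameters:

    ``lognormal``
        ``median`` (>0) and ``sigma`` (sd of natural log, >=0), or
        ``mean_log``/``sigma`` directly.
    ``beta``
        shape parameters ``a`` and ``b`` (both >0), support [0, 1].
    ``uniform``
        ``low`` < ``high``.
    ``constant``
        ``value``.
    """

    name: str
    params: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def from_config(cls, obj, field_name: str) -> "DistSpec":
        """Build and validate a spec from a config mapping.

        Raises :class:`ConfigurationError` naming ``field_name`` on any
        invalid or unknown input.
        """
        if isinstance(obj, DistSpec):
            spec = obj
        elif isinstance(obj, Mapping):
            d = dict(obj)
            name = d.pop("name", None)
            if name is None:
                raise ConfigurationError(field_name, "distribution spec needs a 'name'")
            spec = cls(str(name), d)
        else:
            raise ConfigurationError(
                field_name, f"expected a distribution mapping, got {type(obj).__name__}"
            )
        spec._validate(field_name)
        return spec

    def _validate(self, field_name: str) -> None:
        p = self.params
        for key, value in p.items():
            if not np.isfinite(value):
                raise ConfigurationError(field_name, f"parameter {key!r} is not finite")
        if self.name == "lognormal":
            if "median" in p:
                if p["median"] <= 0:
                    raise ConfigurationError(field_name, "lognormal median must be > 0")
            elif "mean_log" not in p:
                raise ConfigurationError(
                    field_name, "lognormal needs 'median' or 'mean_log'"
                )
            if p.get("sigma", 0.0) < 0:
                raise ConfigurationError(field_name, "lognormal sigma must be >= 0")
        elif self.name == "beta":
            if p.get("a", 0) <= 0 or p.get("b", 0) <= 0:
                raise ConfigurationError(field_name, "beta needs shapes a > 0 and b > 0")
        elif self.name == "uniform":
            if not p.get("low", 0) < p.get("high", 0):
                raise ConfigurationError(field_name, "uniform needs low < high")
        elif self.name == "constant":
            if "value" not in p:
                raise ConfigurationError(field_name, "constant needs 'value'")
        else:
            raise ConfigurationError(
                field_name,
                f"unknown distribution {self.name!r}; supported: {', '.join(_SUPPORTED)}",
            )

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.name == "lognormal":
            mean_log = p.get("mean_log", np.log(p["median"]) if "median" in p else 0.0)
            return rng.lognormal(mean=mean_log, sigma=p.get("sigma", 0.0), size=size)
        if self.name == "beta":
            return rng.beta(p["a"], p["b"], size=size)
        if self.name == "uniform":
            return rng.uniform(p["low"], p["high"], size=size)
        if self.name == "constant":
            return np.full(size, float(p["value"]))
        raise ConfigurationError(self.name, "unvalidated spec")  # pragma: no cover
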