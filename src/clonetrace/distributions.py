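"""Count-distribution specifications used by the simulator.

A :class:`DistSpec` names a distribution family plus its parameters and can
sample positive integers from a :class:`numpy.random.Generator`.  Families are
the ones that come up when modelling molecule/cell counts:

``fixed``
    Degenerate distribution at ``value``.
``ztpoisson``
    Zero-truncated Poisson.  Parameterized either by the Poisson rate ``mu``
    or by the *post-truncation* ``mean`` (the rate is then solved
    numerically), so a target mean such as 4.5 cells per clone can be stated
    directly.
``ztnbinom``
    Zero-truncated negative binomial with post-truncation ``mean`` (or raw
    ``mu``) and shape ``size`` (inverse dispersion; larger = closer to
    Poisson).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy import optimize, stats

_FAMILIES = ("fixed", "ztpoisson", "ztnbinom")


def _zt_mean_poisson(mu: float) -> float:
    # E[X | X>0] for Poisson(mu)
    return mu / (1.0 - np.exp(-mu))


def _zt_mean_nbinom(mu: float, size: float) -> float:
    p0 = (size / (size + mu)) ** size
    return mu / (1.0 - p0)


def _solve_rate(target_mean: float, zt_mean, **kw) -> float:
    """Invert the post-truncation mean for the underlying rate ``mu``."""
    if target_mean <= 1.0:
        raise ValueError(f"zero-truncated mean must exceed 1, got {target_mean}")
    lo, hi = 1e-9, max(10.0 * target_mean, 10.0)
    return float(optimize.brentq(lambda m: zt_mean(m, **kw) - target_mean, lo, hi))


@dataclass(frozen=True)
class DistSpec:
    """A positive-integer distribution: ``family`` plus ``params``."""

    family: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        p = dict(self.params)
        if self.family == "fixed":
            v = p.get("value")
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError("fixed family needs integer params['value'] >= 1")
        else:
            if ("mu" in p) == ("mean" in p):
                raise ValueError(f"{self.family} needs exactly one of 'mu' or 'mean'")
            if "mean" in p and not float(p["mean"]) > 1.0:
                raise ValueError("zero-truncated mean must exceed 1")
            if "mu" in p and not float(p["mu"]) > 0.0:
                raise ValueError("rate 'mu' must be positive")
            if self.family == "ztnbinom" and not p.get("size", 0) > 0:
                raise ValueError("ztnbinom needs params['size'] > 0")

    # -- resolved underlying rate ------------------------------------------
    def _mu(self) -> float:
        p = dict(self.params)
        if "mu" in p:
            return float(p["mu"])
        if self.family == "ztpoisson":
            return _solve_rate(float(p["mean"]), _zt_mean_poisson)
        return _solve_rate(float(p["mean"]), _zt_mean_nbinom, size=float(p["size"]))

    @property
    def mean(self) -> float:
        """Post-truncation mean of the distribution."""
        if self.family == "fixed":
            return float(self.params["value"])
        mu = self._mu()
        if self.family == "ztpoisson":
            return _zt_mean_poisson(mu)
        return _zt_mean_nbinom(mu, float(self.params["size"]))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` integers >= 1."""
        if n < 0:
            raise ValueError("n must be non-negative")
        if self.family == "fixed":
            return np.full(n, int(self.params["value"]), dtype=np.int64)
        mu = self._mu()
        if self.family == "ztpoisson":
            # inverse-CDF on the truncated distribution: exact and vectorized
            u = rng.random(n)
            p0 = stats.poisson.cdf(0, mu)
            return stats.poisson.ppf(p0 + u * (1.0 - p0), mu).astype(np.int64)
        size = float(self.params["size"])
        u = rng.random(n)
        p0 = stats.nbinom.cdf(0, size, size / (size + mu))
        return stats.nbinom.ppf(p0 + u * (1.0 - p0), size, size / (size + mu)).astype(
            np.int64
        )

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DistSpec":
        return cls(family=d["family"], params=dict(d.get("params", {})))
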