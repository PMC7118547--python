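"""Small parametric-distribution spec used throughout the synthetic cohort config.

A ``Dist`` is a named family plus parameters, sampled through a
``numpy.random.Generator`` so the whole cohort is reproducible from one seed.
Families cover what the generator needs: heavy-tailed bout durations
(lognormal), memoryless alternatives (exponential), truncated normals for
covariates, bounded integer counts, and degenerate point masses for
oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

_FAMILIES = {
    "lognormal": ("mu", "sigma"),
    "exponential": ("mean",),
    "normal": ("mean", "sd"),
    "truncnormal": ("mean", "sd", "low", "high"),
    "uniform_int": ("low", "high"),
    "degenerate": ("value",),
    "shifted_exponential": ("shift", "mean"),
}


@dataclass(frozen=True)
class Dist:
    """A parametric distribution: ``family`` name plus keyword ``params``."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ConfigError(
                f"unknown distribution family {self.family!r}; "
                f"known: {sorted(_FAMILIES)}"
            )
        required = _FAMILIES[self.family]
        missing = [k for k in required if k not in self.params]
        if missing:
            raise ConfigError(f"{self.family} distribution missing params {missing}")
        p = self.params
        if self.family == "lognormal" and p["sigma"] <= 0:
            raise ConfigError("lognormal sigma must be > 0")
        if self.family == "exponential" and p["mean"] <= 0:
            raise ConfigError("exponential mean must be > 0")
        if self.family in ("normal", "truncnormal") and p["sd"] < 0:
            raise ConfigError("normal sd must be >= 0")
        if self.family == "truncnormal" and p["low"] >= p["high"]:
            raise ConfigError("truncnormal requires low < high")
        if self.family == "uniform_int" and p["low"] > p["high"]:
            raise ConfigError("uniform_int requires low <= high")
        if self.family == "shifted_exponential" and (p["mean"] <= 0 or p["shift"] < 0):
            raise ConfigError("shifted_exponential requires mean > 0 and shift >= 0")

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Draw ``size`` samples (or a scalar when size is None)."""
        p = self.params
        if self.family == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], size)
        if self.family == "exponential":
            return rng.exponential(p["mean"], size)
        if self.family == "normal":
            return rng.normal(p["mean"], p["sd"], size)
        if self.family == "truncnormal":
            # rejection sampling; fine for the mild truncations used here
            n = 1 if size is None else int(size)
            out = np.empty(n)
            filled = 0
            while filled < n:
                draw = rng.normal(p["mean"], p["sd"], max(n - filled, 16))
                ok = draw[(draw >= p["low"]) & (draw <= p["high"])]
                take = min(ok.size, n - filled)
                out[filled : filled + take] = ok[:take]
                filled += take
            return out[0] if size is None else out
        if self.family == "uniform_int":
            return rng.integers(p["low"], p["high"] + 1, size)
        if self.family == "degenerate":
            v = p["value"]
            return v if size is None else np.full(size, v)
        if self.family == "shifted_exponential":
            return p["shift"] + rng.exponential(p["mean"], size)
        raise AssertionError("unreachable")

    def mean(self) -> float:
        """Analytic mean, used for renewal-calibration checks."""
        p = self.params
        if self.family == "lognormal":
            return float(np.exp(p["mu"] + p["sigma"] ** 2 / 2))
        if self.family == "exponential":
            return float(p["mean"])
        if self.family in ("normal", "truncnormal"):
            return float(p["mean"])  # truncation shift ignored (mild truncations)
        if self.family == "uniform_int":
            return (p["low"] + p["high"]) / 2
        if self.family == "degenerate":
            return float(p["value"])
        if self.family == "shifted_exponential":
            return float(p["shift"] + p["mean"])
        raise AssertionError("unreachable")


def duration_minutes(dist: Dist, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw bout durations in whole minutes: rounded up, minimum 1."""
    raw = np.asarray(dist.sample(rng, size), dtype=float)
    if np.any(raw < 0):
        raise ConfigError("duration distribution produced negative values")
    return np.maximum(1, np.ceil(raw)).astype(np.int64)
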