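"""Seeded synthetic groundwater-concentration tables.

The study data (53 field samples, eight elements) are not deposited, so
this module generates tables with the same marginal structure: each
element is drawn from a lognormal whose parameters are moment-matched to
the published per-element mean and coefficient of variation, optionally
contaminated by multiplicative "hotspots" (a point-source pattern: a
small random subset of samples multiplied by a constant), then clipped to
the published observed range.

Moment matching in natural space::

    sd_log   = sqrt(ln(1 + CV²))
    mean_log = ln(mean) − sd_log² / 2

so that E[X] = mean and SD[X]/E[X] = CV exactly for the untruncated
lognormal.  All published CVs exceed 1 with large positive skewness and
kurtosis, which a lognormal reproduces; the true field distribution is
unknown.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .io_config import SampleTable

__all__ = ["ElementSpec", "SURVEY_PRESET", "lognormal_params", "generate_samples"]


@dataclass(frozen=True)
class ElementSpec:
    """Marginal-distribution targets for one element (concentrations in μg/L)."""

    element: str
    target_mean: float
    target_cv: float
    min_clip: float
    max_clip: float
    hotspot_fraction: float = 0.0
    hotspot_multiplier: float = 1.0

    def __post_init__(self) -> None:
        # max_clip may be +inf (no upper clip); everything else must be finite
        vals = (self.target_mean, self.target_cv, self.min_clip,
                self.hotspot_fraction, self.hotspot_multiplier)
        if not all(math.isfinite(v) for v in vals) or math.isnan(self.max_clip):
            raise ConfigurationError(f"{self.element}: non-finite spec value")
        if self.target_mean <= 0 or self.target_cv <= 0:
            raise ConfigurationError(f"{self.element}: target mean and CV must be positive")
        if not self.min_clip < self.max_clip:
            raise ConfigurationError(f"{self.element}: min_clip must be < max_clip")
        if not 0 <= self.hotspot_fraction <= 1:
            raise ConfigurationError(f"{self.element}: hotspot_fraction outside [0, 1]")
        if self.hotspot_multiplier < 1:
            raise ConfigurationError(f"{self.element}: hotspot_multiplier must be >= 1")


def _spec(el, mean, cv, lo, hi):
    return ElementSpec(el, mean, cv, lo, hi)


#: Per-element marginal targets matching the published summary statistics
#: of the 53-sample survey (mean, CV and observed min/max, μg/L).
SURVEY_PRESET: dict[str, ElementSpec] = {
    "Al": _spec("Al", 233.0, 1.06, 0.96, 997.0),
    "As": _spec("As", 21.0, 1.84, 0.82, 176.0),
    "Cd": _spec("Cd", 0.35, 2.52, 0.01, 5.50),
    "Cu": _spec("Cu", 32.0, 2.45, 1.24, 530.0),
    "Mn": _spec("Mn", 180.0, 1.29, 0.23, 1047.0),
    "Pb": _spec("Pb", 6.0, 1.37, 0.25, 45.90),
    "Se": _spec("Se", 7.0, 1.91, 0.0, 97.30),
    "Zn": _spec("Zn", 156.0, 1.23, 0.90, 944.0),
}


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """Moment-matched (mean_log, sd_log) for a lognormal with given mean and CV."""
    sd_log = math.sqrt(math.log1p(cv * cv))
    mean_log = math.log(mean) - sd_log * sd_log / 2.0
    return mean_log, sd_log


def _element_rng(seed: int, element: str) -> np.random.Generator:
    # Per-element substream: adding or removing an element never perturbs
    # the draws of the others.
    import zlib

    return np.random.default_rng(np.random.SeedSequence((int(seed), zlib.crc32(element.encode()))))


def generate_samples(
    n: int,
    specs: Mapping[str, ElementSpec] | Sequence[ElementSpec] | None = None,
    seed: int = 0,
    coordinates: bool = True,
) -> SampleTable:
    """Generate ``n`` synthetic samples (default: the eight-element preset).

    For each element: lognormal draws moment-matched to
    (target_mean, target_cv), a ``hotspot_fraction`` subset multiplied by
    ``hotspot_multiplier``, then clipping to [min_clip, max_clip].
    Identical seed ⇒ identical table.  Coordinates, when emitted, are
    uniform on a 1 km × 1 km square (no spatial autocorrelation model).
    """
    if n < 2:
        raise InputError("need at least 2 samples")
    if specs is None:
        specs = SURVEY_PRESET
    if not isinstance(specs, Mapping):
        specs = {s.element: s for s in specs}

    width = len(str(n))
    data = {"sample_id": [f"S{i + 1:0{width}d}" for i in range(n)]}
    if coordinates:
        rng_xy = _element_rng(seed, "__coords__")
        data["x"] = rng_xy.uniform(0.0, 1000.0, n)
        data["y"] = rng_xy.uniform(0.0, 1000.0, n)

    for el, spec in specs.items():
        rng = _element_rng(seed, el)
        mu, sd = lognormal_params(spec.target_mean, spec.target_cv)
        values = rng.lognormal(mean=mu, sigma=sd, size=n)
        n_hot = int(round(spec.hotspot_fraction * n))
        if n_hot > 0:
            hot = rng.choice(n, size=n_hot, replace=False)
            values[hot] *= spec.hotspot_multiplier
        data[el] = np.clip(values, spec.min_clip, spec.max_clip)

    return SampleTable(pd.DataFrame(data), list(specs))
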