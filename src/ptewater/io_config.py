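"""Tabular I/O, domain containers and built-in constants.

The package works in μg/L throughout.  Regulatory thresholds (the Chinese
Class III groundwater standard, GB/T 14848—2017) are stored in μg/L as
well; the single μg/L → mg/L conversion required by the dose equations
happens once, inside the chronic-daily-intake functions in
:mod:`ptewater.exposure_risk`.  Keeping exactly one conversion point
avoids the classic double-conversion bug when mixing water-quality tables
(μg/L) with toxicological reference values (mg/kg/d).

Built-in constants
------------------
* ``DEFAULT_STANDARDS`` — Class III thresholds per element (μg/L).
* ``DEFAULT_TOXICITY`` — oral/dermal reference doses (mg/kg/d) and oral
  carcinogenic slope factors ((mg/kg/d)⁻¹; As and Cd only).
* ``DEFAULT_ADULT`` / ``DEFAULT_CHILD`` — drinking-water exposure
  parameters for the two cohorts, with triangular ranges for exposure
  frequency EF and dermal event time ET.
* ``DETECTION_LIMITS`` — ICP-MS detection limits (μg/L), used for the
  half-detection-limit substitution of non-detects before distribution
  fitting.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigurationError, InputError

#: The eight elements assessed by default.
ELEMENTS: tuple[str, ...] = ("Al", "As", "Cd", "Cu", "Mn", "Pb", "Se", "Zn")

#: Elements with an oral carcinogenic slope factor.
CARCINOGENS: tuple[str, ...] = ("As", "Cd")

#: Class III groundwater-quality thresholds, μg/L.
DEFAULT_STANDARDS: dict[str, float] = {
    "Al": 200.0,
    "As": 10.0,
    "Cd": 5.0,
    "Cu": 1000.0,
    "Mn": 100.0,
    "Pb": 10.0,
    "Se": 10.0,
    "Zn": 1000.0,
}

#: ICP-MS detection limits, μg/L.
DETECTION_LIMITS: dict[str, float] = {
    "Al": 1.15,
    "As": 0.12,
    "Cd": 0.05,
    "Cu": 0.08,
    "Mn": 0.12,
    "Pb": 0.09,
    "Se": 0.41,
    "Zn": 0.67,
}


@dataclass(frozen=True)
class Toxicity:
    """Toxicological reference values for one element.

    ``rfd_oral`` and ``rfd_dermal`` are reference doses in mg/kg/d;
    ``sf_oral`` is the oral carcinogenic slope factor in (mg/kg/d)⁻¹ and
    is ``None`` for non-carcinogens.
    """

    rfd_oral: float
    rfd_dermal: float
    sf_oral: float | None = None

    def __post_init__(self) -> None:
        if self.rfd_oral <= 0 or self.rfd_dermal <= 0:
            raise ConfigurationError("reference doses must be positive")
        if self.sf_oral is not None and self.sf_oral <= 0:
            raise ConfigurationError("slope factor must be positive when present")


DEFAULT_TOXICITY: dict[str, Toxicity] = {
    "Al": Toxicity(0.14, 0.14),
    "As": Toxicity(0.003, 0.000285, sf_oral=1.5),
    "Cd": Toxicity(0.0005, 0.000025, sf_oral=6.1),
    "Cu": Toxicity(0.04, 0.012),
    "Mn": Toxicity(0.046, 0.0018),
    "Pb": Toxicity(0.0014, 0.00042),
    "Se": Toxicity(0.001, 0.0015),
    "Zn": Toxicity(0.3, 0.06),
}


@dataclass(frozen=True)
class DistributionSpec:
    """A univariate sampling distribution for a stochastic input.

    families
        ``point``       params = (value,)
        ``triangular``  params = (min, mode, max)
        ``lognormal``   params = (mean_log, sd_log)
        ``uniform``     params = (low, high)

    ``truncation`` optionally restricts support to [lower, upper] via
    inverse-CDF sampling, so truncated draws remain exact (no rejection).
    """

    family: str
    params: tuple[float, ...]
    truncation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("point", "triangular", "lognormal", "uniform"):
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if not all(np.isfinite(p)):
            raise ConfigurationError("distribution parameters must be finite")
        if self.family == "point" and len(p) != 1:
            raise ConfigurationError("point family takes a single value")
        if self.family == "triangular":
            if len(p) != 3 or not (p[0] <= p[1] <= p[2]):
                raise ConfigurationError("triangular requires min <= mode <= max")
        if self.family == "lognormal":
            if len(p) != 2 or p[1] <= 0:
                raise ConfigurationError("lognormal requires sd_log > 0")
        if self.family == "uniform" and (len(p) != 2 or p[0] >= p[1]):
            raise ConfigurationError("uniform requires low < high")
        if self.truncation is not None:
            lo, hi = self.truncation
            if not lo < hi:
                raise ConfigurationError("truncation lower bound must be < upper")
            object.__setattr__(self, "truncation", (float(lo), float(hi)))

    def _frozen(self):
        if self.family == "triangular":
            lo, mode, hi = self.params
            if hi == lo:
                return None
            return stats.triang(c=(mode - lo) / (hi - lo), loc=lo, scale=hi - lo)
        if self.family == "lognormal":
            mu, sd = self.params
            return stats.lognorm(s=sd, scale=np.exp(mu))
        if self.family == "uniform":
            lo, hi = self.params
            return stats.uniform(loc=lo, scale=hi - lo)
        return None

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` values with ``rng``; reproducible for a fixed rng state."""
        if self.family == "point":
            return np.full(size, self.params[0])
        dist = self._frozen()
        if dist is None:  # degenerate triangular
            return np.full(size, self.params[0])
        u = rng.random(size)
        if self.truncation is not None:
            lo, hi = self.truncation
            a, b = dist.cdf(lo), dist.cdf(hi)
            u = a + u * (b - a)
        return dist.ppf(u)

    def mean(self) -> float:
        """Analytic mean (ignoring truncation) — used in sanity checks."""
        if self.family == "point":
            return self.params[0]
        if self.family == "triangular":
            return sum(self.params) / 3.0
        if self.family == "lognormal":
            mu, sd = self.params
            return float(np.exp(mu + sd**2 / 2))
        lo, hi = self.params
        return (lo + hi) / 2.0


@dataclass(frozen=True)
class ExposureParameters:
    """Cohort-specific drinking-water exposure parameters.

    Units: ir L/d; ef d/yr; ed yr; bw kg; at_nc, at_c days; sa cm²;
    pc cm/h per element; et h/event; cf L/cm³.  ``ef_spec`` / ``et_spec``
    carry the stochastic ranges used by the Monte Carlo layer; the point
    values are used by the deterministic engine.
    """

    cohort: str
    ir: float
    ef: float
    ed: float
    bw: float
    at_nc: float
    at_c: float
    sa: float
    pc: Mapping[str, float]
    et: float
    cf: float
    ef_spec: DistributionSpec | None = None
    et_spec: DistributionSpec | None = None

    def __post_init__(self) -> None:
        for name in ("ir", "ef", "ed", "bw", "at_nc", "at_c", "sa", "et", "cf"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError(f"{name} must be positive and finite")
        if self.at_c < self.at_nc:
            raise ConfigurationError("carcinogenic averaging time must be >= non-carcinogenic")
        if any(v <= 0 for v in self.pc.values()):
            raise ConfigurationError("dermal permeability coefficients must be positive")
        object.__setattr__(self, "pc", dict(self.pc))

    def averaging_time(self, averaging: str) -> float:
        if averaging == "non_carcinogenic":
            return self.at_nc
        if averaging == "carcinogenic":
            return self.at_c
        raise ConfigurationError(f"unknown averaging mode {averaging!r}")


_PC_DEFAULT = {el: (6e-4 if el == "Zn" else 1e-3) for el in ELEMENTS}
_EF_SPEC = DistributionSpec("triangular", (180.0, 350.0, 365.0))
_ET_SPEC = DistributionSpec("triangular", (0.13, 0.20, 0.33))

DEFAULT_ADULT = ExposureParameters(
    cohort="adult", ir=1.8, ef=350.0, ed=24.0, bw=70.0,
    at_nc=8760.0, at_c=25550.0, sa=16600.0, pc=_PC_DEFAULT,
    et=0.20, cf=0.001, ef_spec=_EF_SPEC, et_spec=_ET_SPEC,
)

DEFAULT_CHILD = ExposureParameters(
    cohort="child", ir=0.70, ef=350.0, ed=6.0, bw=21.2,
    at_nc=2190.0, at_c=25550.0, sa=8000.0, pc=_PC_DEFAULT,
    et=0.20, cf=0.001, ef_spec=_EF_SPEC, et_spec=_ET_SPEC,
)


class Defaults(NamedTuple):
    standards: dict[str, float]
    toxicity: dict[str, Toxicity]
    adult: ExposureParameters
    child: ExposureParameters


def load_defaults(config: str | Path | Mapping | None = None) -> Defaults:
    """Return the built-in constants, optionally overridden by a config.

    ``config`` may be a YAML/JSON file path or a mapping with any of the
    keys ``standards`` (element → μg/L), ``toxicity``
    (element → {rfd_oral, rfd_dermal, sf_oral}) and ``exposure``
    (cohort → field → value).  Unmentioned fields keep their defaults.
    """
    standards = dict(DEFAULT_STANDARDS)
    toxicity = dict(DEFAULT_TOXICITY)
    cohorts = {"adult": DEFAULT_ADULT, "child": DEFAULT_CHILD}

    if config is not None:
        if not isinstance(config, Mapping):
            text = Path(config).read_text()
            config = yaml.safe_load(text) if str(config).endswith((".yaml", ".yml")) else json.loads(text)
        for el, thr in (config.get("standards") or {}).items():
            if thr <= 0:
                raise ConfigurationError(f"threshold for {el} must be positive")
            standards[el] = float(thr)
        for el, tox in (config.get("toxicity") or {}).items():
            base = dataclasses.asdict(toxicity[el]) if el in toxicity else {}
            base.update(tox)
            toxicity[el] = Toxicity(**base)
        for cohort, fields in (config.get("exposure") or {}).items():
            if cohort not in cohorts:
                raise ConfigurationError(f"unknown cohort {cohort!r}")
            cohorts[cohort] = dataclasses.replace(cohorts[cohort], **fields)

    return Defaults(standards, toxicity, cohorts["adult"], cohorts["child"])


_META_COLUMNS = ("sample_id", "x", "y")


@dataclass
class SampleTable:
    """A sample-by-element concentration table (μg/L).

    ``data`` holds one row per groundwater sample with a unique
    ``sample_id``, optional planar ``x``/``y`` coordinates and one
    non-negative concentration column per element.
    """

    data: pd.DataFrame
    elements: list[str]

    def __post_init__(self) -> None:
        missing = [el for el in self.elements if el not in self.data.columns]
        if missing:
            raise ConfigurationError(f"missing element column(s): {', '.join(missing)}")
        if self.data["sample_id"].duplicated().any():
            dup = self.data["sample_id"][self.data["sample_id"].duplicated()].iloc[0]
            raise InputError(f"duplicate sample_id {dup!r}")
        conc = self.data[self.elements]
        neg = conc.lt(0)
        if neg.any().any():
            col = neg.any()[neg.any()].index[0]
            row = int(neg[col].idxmax())
            raise InputError(
                f"negative concentration in column {col!r}, row {row}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def concentrations(self) -> pd.DataFrame:
        """Element columns indexed by sample_id."""
        return self.data.set_index("sample_id")[self.elements]


def read_sample_table(path: str | Path, element_list: Sequence[str] | None = None) -> SampleTable:
    """Read a samples CSV (header row: sample_id[, x, y], elements...).

    When ``element_list`` is omitted every non-metadata column is treated
    as an element.  Unparseable cells raise :class:`InputError` naming the
    offending row and column; a requested element without a column raises
    :class:`ConfigurationError`.
    """
    raw = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in raw.columns:
        raise ConfigurationError("missing required column: sample_id")
    elements = list(element_list) if element_list is not None else [
        c for c in raw.columns if c not in _META_COLUMNS
    ]
    missing = [el for el in elements if el not in raw.columns]
    if missing:
        raise ConfigurationError(f"missing element column(s): {', '.join(missing)}")
    for col in elements:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise InputError(f"unparseable value in column {col!r}, row {row}: {raw[col][row]!r}")
        raw[col] = parsed
    return SampleTable(raw, elements)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    """Write a samples CSV; values round-trip at full float precision."""
    table.data.to_csv(path, index=False)
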