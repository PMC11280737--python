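"""Pollution indices: descriptive summaries, single-factor and Nemerow indices.

The single-factor index of element *i* is the measured content divided by
its regulatory threshold, ``I_i = M_i / S_i``; values above 1 flag
exceedance.  The Nemerow composite index of one sample,

    NI = sqrt((I_max² + I_mean²) / 2),

combines the worst single-factor index with the mean, deliberately
over-weighting the worst element.  Both are classified on a five-level
scale: no (< 0.7), slight (0.7–1], low (1–2], moderate (2–3] and
high (> 3) pollution.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .io_config import SampleTable

__all__ = [
    "POLLUTION_CLASSES",
    "summarize_contents",
    "single_factor_index",
    "nemerow_index",
    "classify_pollution",
    "pollution_pipeline",
    "PollutionResult",
]

log = logging.getLogger(__name__)

POLLUTION_CLASSES = (
    "no pollution",
    "slight pollution",
    "low pollution",
    "moderate pollution",
    "high pollution",
)


def summarize_contents(samples: SampleTable, standards: Mapping[str, float]) -> pd.DataFrame:
    """Per-element descriptive statistics and threshold-exceedance ratio.

    Returns a DataFrame indexed by element with columns mean, sd, min,
    max (μg/L), cv, skewness, kurtosis (dimensionless, bias-corrected
    sample statistics; kurtosis is excess) and exceed_ratio (% of samples
    strictly above the threshold).  A constant column reports sd = cv = 0
    and NaN skewness/kurtosis.
    """
    if len(samples) < 2:
        raise InputError("need at least 2 samples to summarize")
    rows = {}
    for el in samples.elements:
        if el not in standards:
            raise ConfigurationError(f"no threshold configured for element {el!r}")
        values = samples.concentrations[el].dropna().to_numpy(dtype=float)
        n = values.size
        mean = values.mean()
        sd = values.std(ddof=1)
        if sd == 0:
            skew = kurt = np.nan
            cv = 0.0
        else:
            skew = stats.skew(values, bias=False)
            kurt = stats.kurtosis(values, bias=False)  # excess
            cv = sd / mean
        rows[el] = {
            "mean": mean,
            "sd": sd,
            "min": values.min(),
            "max": values.max(),
            "cv": cv,
            "skewness": skew,
            "kurtosis": kurt,
            "exceed_ratio": 100.0 * np.count_nonzero(values > standards[el]) / n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def single_factor_index(content, threshold: float):
    """Single-factor pollution index ``content / threshold`` (both μg/L).

    ``content`` may be a scalar or array.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    content = np.asarray(content, dtype=float)
    if (content < 0).any():
        raise InputError("content must be non-negative")
    out = content / threshold
    return float(out) if out.ndim == 0 else out


def nemerow_index(indices) -> float:
    """Composite index sqrt((I_max² + I_mean²)/2) over one sample's indices."""
    indices = np.asarray(indices, dtype=float)
    indices = indices[~np.isnan(indices)]
    if indices.size == 0:
        raise InputError("need at least one single-factor index")
    if (indices < 0).any():
        raise InputError("single-factor indices must be non-negative")
    i_max = indices.max()
    i_mean = indices.mean()
    return float(np.sqrt((i_max**2 + i_mean**2) / 2.0))


def classify_pollution(value: float) -> str:
    """Five-class pollution label for a single-factor or Nemerow index.

    Boundaries are lower-exclusive / upper-inclusive; a value of exactly
    0.7 falls in the "no pollution" class.
    """
    if value < 0 or not np.isfinite(value):
        raise InputError("index value must be non-negative and finite")
    if value <= 0.7:
        return POLLUTION_CLASSES[0]
    if value <= 1:
        return POLLUTION_CLASSES[1]
    if value <= 2:
        return POLLUTION_CLASSES[2]
    if value <= 3:
        return POLLUTION_CLASSES[3]
    return POLLUTION_CLASSES[4]


@dataclass
class PollutionResult:
    """Per-sample indices and the Table-4-style summary.

    ``per_sample`` — one row per sample: I_<element> columns, ``NI`` and
    ``NI_class``.  ``summary`` — rows Minimum/Maximum/Mean/CV, one column
    per element plus ``NI``.  ``classes`` — per-element label of the mean
    single-factor index.
    """

    per_sample: pd.DataFrame
    summary: pd.DataFrame
    classes: pd.Series


def pollution_pipeline(samples: SampleTable, standards: Mapping[str, float]) -> PollutionResult:
    """Single-factor indices, per-sample Nemerow index and summary table."""
    conc = samples.concentrations
    idx = pd.DataFrame(index=conc.index)
    for el in samples.elements:
        if el not in standards:
            raise ConfigurationError(f"no threshold configured for element {el!r}")
        idx[f"I_{el}"] = conc[el] / standards[el]

    if idx.isna().any().any():
        n_bad = int(idx.isna().any(axis=1).sum())
        log.warning(
            "%d sample(s) have missing element values; their Nemerow index "
            "uses the remaining elements", n_bad,
        )
    ni = idx.apply(lambda row: nemerow_index(row.to_numpy()), axis=1)

    per_sample = idx.copy()
    per_sample["NI"] = ni
    per_sample["NI_class"] = ni.map(classify_pollution)

    cols = {f"I_{el}": el for el in samples.elements}
    summary = pd.DataFrame(
        {
            "Minimum": idx.min(),
            "Maximum": idx.max(),
            "Mean": idx.mean(),
            "CV": idx.std(ddof=1) / idx.mean(),
        }
    ).T.rename(columns=cols)
    summary["NI"] = [ni.min(), ni.max(), ni.mean(), ni.std(ddof=1) / ni.mean()]

    classes = summary.loc["Mean"].map(classify_pollution)
    return PollutionResult(per_sample, summary, classes)
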