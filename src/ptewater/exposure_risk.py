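"""Deterministic exposure and risk engine (EPA drinking-water model).

Chronic daily intake (CDI, mg/kg/d) of an element through two routes:

    CDI_oral = (C × IR × EF × ED) / (BW × AT)
    CDI_derm = (C × SA × PC × ET × EF × ED × CF) / (BW × AT)

with C the concentration (converted μg/L → mg/L here, the package's
single conversion point), IR ingestion rate (L/d), EF exposure frequency
(d/yr), ED exposure duration (yr), BW body weight (kg), AT averaging
time (d; non-carcinogenic or carcinogenic), SA skin surface area (cm²),
PC dermal permeability (cm/h), ET event time (h/event) and CF the
volume conversion 0.001 L/cm³.  EF·ED yields days, matching AT in days.

Non-carcinogenic risk: HQ = CDI / RfD per route, summed over routes per
element, and HI = Σ HQ over elements; HI > 1 flags a potential risk.
Carcinogenic risk: CR = CDI_oral(carcinogenic averaging) × SF for the
elements with an oral slope factor (As, Cd), TCR = Σ CR.  No dermal
slope factors exist for these elements, so CR is oral-route only.

All functions accept scalars or numpy arrays for the concentration (and
for EF/ET overrides), so the Monte Carlo layer can push whole draw
vectors through the same code path.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .io_config import CARCINOGENS, ExposureParameters, SampleTable, Toxicity

__all__ = [
    "CR_CLASSES",
    "cdi_oral",
    "cdi_dermal",
    "hazard_quotient",
    "hazard_index",
    "carcinogenic_risk",
    "total_cr",
    "classify_cr",
    "classify_hi",
    "RiskResult",
    "assess_risk",
]

_UG_TO_MG = 1e-3  # μg/L → mg/L, applied once, inside the CDI functions

CR_CLASSES = (
    "very low carcinogenic risk",
    "low carcinogenic risk",
    "moderate carcinogenic risk",
    "high carcinogenic risk",
    "extremely high carcinogenic risk",
)


def cdi_oral(
    content,
    params: ExposureParameters,
    averaging: str = "non_carcinogenic",
    *,
    ef=None,
):
    """Chronic daily intake via ingestion, mg/kg/d.

    ``content`` in μg/L; ``ef`` optionally overrides the point exposure
    frequency (used by the Monte Carlo layer).  ``averaging`` selects the
    non-carcinogenic or carcinogenic averaging time.
    """
    at = params.averaging_time(averaging)
    ef = params.ef if ef is None else ef
    content = np.asarray(content, dtype=float)
    out = (content * _UG_TO_MG * params.ir * np.asarray(ef) * params.ed) / (params.bw * at)
    return float(out) if out.ndim == 0 else out


def cdi_dermal(
    content,
    element: str,
    params: ExposureParameters,
    averaging: str = "non_carcinogenic",
    *,
    ef=None,
    et=None,
):
    """Chronic daily intake via dermal contact during bathing, mg/kg/d."""
    if element not in params.pc:
        raise ConfigurationError(f"no dermal permeability coefficient for {element!r}")
    at = params.averaging_time(averaging)
    ef = params.ef if ef is None else ef
    et = params.et if et is None else et
    content = np.asarray(content, dtype=float)
    out = (
        content * _UG_TO_MG * params.sa * params.pc[element]
        * np.asarray(et) * np.asarray(ef) * params.ed * params.cf
    ) / (params.bw * at)
    return float(out) if out.ndim == 0 else out


def hazard_quotient(cdi, rfd: float):
    """HQ = CDI / RfD (dimensionless)."""
    if rfd <= 0:
        raise ConfigurationError("reference dose must be positive")
    out = np.asarray(cdi, dtype=float) / rfd
    return float(out) if out.ndim == 0 else out


def hazard_index(hqs: Iterable):
    """HI = Σ HQ over elements; empty input gives 0."""
    hqs = list(hqs)
    if not hqs:
        return 0.0
    out = np.sum(np.asarray(hqs, dtype=float), axis=0)
    return float(out) if np.ndim(out) == 0 else out


def carcinogenic_risk(cdi_oral_carcinogenic, sf: float | None):
    """CR = CDI(oral, carcinogenic averaging) × SF."""
    if sf is None or sf <= 0:
        raise ConfigurationError("element has no oral slope factor")
    out = np.asarray(cdi_oral_carcinogenic, dtype=float) * sf
    return float(out) if out.ndim == 0 else out


def total_cr(crs: Iterable):
    """TCR = Σ CR over carcinogens; empty input gives 0."""
    crs = list(crs)
    if not crs:
        return 0.0
    out = np.sum(np.asarray(crs, dtype=float), axis=0)
    return float(out) if np.ndim(out) == 0 else out


def classify_cr(cr: float) -> str:
    """Five-class carcinogenic-risk label.

    < 1e-6 very low; [1e-6, 1e-4) low; [1e-4, 1e-3) moderate;
    [1e-3, 0.1] high; > 0.1 extremely high.
    """
    if cr < 0 or not np.isfinite(cr):
        raise InputError("carcinogenic risk must be non-negative and finite")
    if cr < 1e-6:
        return CR_CLASSES[0]
    if cr < 1e-4:
        return CR_CLASSES[1]
    if cr < 1e-3:
        return CR_CLASSES[2]
    if cr <= 0.1:
        return CR_CLASSES[3]
    return CR_CLASSES[4]


def classify_hi(hi: float) -> str:
    """Binary non-carcinogenic label: acceptable below HI = 1."""
    if hi < 0 or not np.isfinite(hi):
        raise InputError("hazard index must be non-negative and finite")
    return "acceptable (no non-carcinogenic risk)" if hi < 1 else "potential non-carcinogenic risk"


@dataclass
class RiskResult:
    """Deterministic risk outputs.

    ``per_element`` — one row per cohort × element with cdi_oral,
    cdi_dermal (mg/kg/d), hq_oral, hq_dermal, hq_total and cr (NaN for
    non-carcinogens).  ``hi`` / ``tcr`` — per-cohort totals.
    ``hi_class`` / ``tcr_class`` — labels.
    """

    per_element: pd.DataFrame
    hi: dict[str, float]
    tcr: dict[str, float]
    hi_class: dict[str, str]
    tcr_class: dict[str, str]


def assess_risk(
    contents: Mapping[str, float] | SampleTable,
    cohorts: Mapping[str, ExposureParameters],
    toxicity: Mapping[str, Toxicity],
) -> RiskResult:
    """Deterministic risk for each cohort from element concentrations.

    ``contents`` is either a mapping element → concentration (μg/L) or a
    :class:`SampleTable`, in which case per-element mean concentrations
    are assessed (the usual deterministic screening convention).
    """
    if isinstance(contents, SampleTable):
        contents = contents.concentrations.mean().to_dict()

    rows = []
    hi: dict[str, float] = {}
    tcr: dict[str, float] = {}
    for cohort, params in cohorts.items():
        hqs, crs = [], []
        for el, conc in contents.items():
            if el not in toxicity:
                raise ConfigurationError(f"no toxicity values configured for element {el!r}")
            tox = toxicity[el]
            oral = cdi_oral(conc, params, "non_carcinogenic")
            derm = cdi_dermal(conc, el, params, "non_carcinogenic")
            hq_o = hazard_quotient(oral, tox.rfd_oral)
            hq_d = hazard_quotient(derm, tox.rfd_dermal)
            cr = np.nan
            if el in CARCINOGENS and tox.sf_oral is not None:
                cr = carcinogenic_risk(cdi_oral(conc, params, "carcinogenic"), tox.sf_oral)
                crs.append(cr)
            hqs.append(hq_o + hq_d)
            rows.append(
                {
                    "cohort": cohort,
                    "element": el,
                    "cdi_oral": oral,
                    "cdi_dermal": derm,
                    "hq_oral": hq_o,
                    "hq_dermal": hq_d,
                    "hq_total": hq_o + hq_d,
                    "cr": cr,
                }
            )
        hi[cohort] = hazard_index(hqs)
        tcr[cohort] = total_cr(crs)

    per_element = pd.DataFrame(rows)
    return RiskResult(
        per_element=per_element,
        hi=hi,
        tcr=tcr,
        hi_class={c: classify_hi(v) for c, v in hi.items()},
        tcr_class={c: classify_cr(v) for c, v in tcr.items()},
    )
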