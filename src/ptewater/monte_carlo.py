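"""Monte Carlo uncertainty layer over the deterministic risk engine.

Each iteration draws the stochastic inputs — one concentration per
element, the exposure frequency EF and the dermal event time ET — and
pushes them through the exposure/risk equations for both cohorts.  The
default stochastic model follows the study design:

* concentration per element ~ lognormal moment-matched to the sample
  mean and CV, truncated to the observed range (or, in ``empirical``
  mode, resampled from the observed values);
* EF ~ triangular(180, 350, 365) d/yr;
* ET ~ triangular(0.13, 0.20, 0.33) h/event;
* 10,000 iterations.

Cohorts share the concentration/EF/ET draws within an iteration, so
child-versus-adult comparisons are paired.  One master seed spawns an
independent substream per input, keyed by the input's name: adding an
element leaves every other input's draws unchanged.
"""

from __future__ import annotations

import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .exposure_risk import (
    carcinogenic_risk,
    cdi_dermal,
    cdi_oral,
    hazard_quotient,
)
from .io_config import (
    CARCINOGENS,
    DETECTION_LIMITS,
    DistributionSpec,
    ExposureParameters,
    SampleTable,
    Toxicity,
)

__all__ = ["MCConfig", "MCSummary", "fit_content_distribution", "sample_inputs", "run_monte_carlo"]

#: Exceedance thresholds reported for each output family.
HQ_THRESHOLDS = (1.0,)
CR_THRESHOLDS = (1e-6, 1e-4, 1e-3)


def fit_content_distribution(
    values,
    detection_limit: float | None = None,
) -> DistributionSpec:
    """Fit a truncated lognormal to observed concentrations (μg/L).

    Moment matching on the sample mean and CV gives
    ``sd_log = sqrt(ln(1 + CV²))`` and ``mean_log = ln(mean) − sd_log²/2``;
    the support is truncated to the observed [min, max].  Zeros
    (non-detects) are replaced by half the detection limit before
    fitting; constant positive vectors yield a point spec.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise InputError("need at least 2 values to fit")
    if (values < 0).any():
        raise InputError("concentrations must be non-negative")
    if (values == 0).all():
        raise InputError("all values are zero; nothing to fit")
    if (values == 0).any():
        if detection_limit is None:
            raise ConfigurationError("zeros present but no detection limit supplied")
        values = np.where(values == 0, detection_limit / 2.0, values)

    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return DistributionSpec("point", (mean,))
    cv = sd / mean
    sd_log = np.sqrt(np.log1p(cv * cv))
    mean_log = np.log(mean) - sd_log**2 / 2.0
    return DistributionSpec(
        "lognormal", (mean_log, sd_log), truncation=(values.min(), values.max())
    )


@dataclass
class MCConfig:
    """Configuration of one Monte Carlo run."""

    conc_specs: Mapping[str, DistributionSpec]
    ef_spec: DistributionSpec
    et_spec: DistributionSpec
    n_iter: int = 10_000
    seed: int = 0
    #: "parametric" samples conc_specs; "empirical" resamples observations.
    conc_mode: str = "parametric"
    empirical_values: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be >= 1")
        if self.conc_mode not in ("parametric", "empirical"):
            raise ConfigurationError(f"unknown concentration mode {self.conc_mode!r}")
        if self.conc_mode == "empirical" and self.empirical_values is None:
            raise ConfigurationError("empirical mode requires the observed values")

    @classmethod
    def from_samples(
        cls,
        samples: SampleTable,
        n_iter: int = 10_000,
        seed: int = 0,
        conc_mode: str = "parametric",
        ef_spec: DistributionSpec | None = None,
        et_spec: DistributionSpec | None = None,
    ) -> "MCConfig":
        """Fit concentration specs from a sample table; default EF/ET triangles."""
        specs = {
            el: fit_content_distribution(
                samples.concentrations[el], DETECTION_LIMITS.get(el)
            )
            for el in samples.elements
        }
        return cls(
            conc_specs=specs,
            ef_spec=ef_spec or DistributionSpec("triangular", (180.0, 350.0, 365.0)),
            et_spec=et_spec or DistributionSpec("triangular", (0.13, 0.20, 0.33)),
            n_iter=n_iter,
            seed=seed,
            conc_mode=conc_mode,
            empirical_values={
                el: samples.concentrations[el].dropna().to_numpy() for el in samples.elements
            }
            if conc_mode == "empirical"
            else None,
        )


def _input_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), zlib.crc32(name.encode()))))


def sample_inputs(config: MCConfig) -> pd.DataFrame:
    """Draw the per-iteration stochastic inputs.

    Returns a DataFrame with one row per iteration and columns
    ``C_<element>`` (μg/L), ``EF`` (d/yr) and ``ET`` (h/event);
    reproducible under a fixed seed.
    """
    n = config.n_iter
    draws = {}
    for el in config.conc_specs:
        rng = _input_rng(config.seed, f"conc:{el}")
        if config.conc_mode == "empirical":
            obs = np.asarray(config.empirical_values[el], dtype=float)
            draws[f"C_{el}"] = rng.choice(obs, size=n, replace=True)
        else:
            draws[f"C_{el}"] = config.conc_specs[el].sample(rng, n)
    draws["EF"] = config.ef_spec.sample(_input_rng(config.seed, "EF"), n)
    draws["ET"] = config.et_spec.sample(_input_rng(config.seed, "ET"), n)
    return pd.DataFrame(draws)


def _summary_row(x: np.ndarray, thresholds: Sequence[float]) -> dict[str, float]:
    row = {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "p5": float(np.percentile(x, 5)),
        "p50": float(np.percentile(x, 50)),
        "p95": float(np.percentile(x, 95)),
    }
    for t in thresholds:
        row[f"P(>{t:g})"] = float(np.mean(x > t))
    return row


@dataclass
class MCSummary:
    """Summary of the risk distributions produced by one Monte Carlo run.

    ``table`` — one row per (cohort, output), where output is
    ``HQ_<element>``, ``HI``, ``CR_<element>`` or ``TCR``; columns are
    mean, sd, percentiles 5/50/95 and the exceedance probabilities
    (P(HQ or HI > 1); P(CR or TCR > 1e-6, 1e-4, 1e-3)).
    ``inputs`` / ``outputs`` — the raw draw matrices, retained when
    ``keep_draws`` is requested (inputs always kept: the sensitivity
    stage needs them).
    """

    table: pd.DataFrame
    inputs: pd.DataFrame
    outputs: dict[str, pd.DataFrame] = field(default_factory=dict)

    def exceedance(self, cohort: str, output: str, threshold: float) -> float:
        """Fraction of iterations with the output above ``threshold``."""
        return float(np.mean(self.outputs[cohort][output].to_numpy() > threshold))


def run_monte_carlo(
    samples_or_config: SampleTable | MCConfig,
    cohorts: Mapping[str, ExposureParameters],
    toxicity: Mapping[str, Toxicity],
    n_iter: int = 10_000,
    seed: int = 0,
    keep_draws: bool = True,
) -> MCSummary:
    """Run the probabilistic risk assessment.

    Accepts either a :class:`SampleTable` (concentration distributions
    are then fitted from it) or a ready :class:`MCConfig`.  Within one
    iteration all cohorts see the same concentration, EF and ET draws.
    """
    if isinstance(samples_or_config, MCConfig):
        config = samples_or_config
    else:
        config = MCConfig.from_samples(samples_or_config, n_iter=n_iter, seed=seed)

    inputs = sample_inputs(config)
    ef = inputs["EF"].to_numpy()
    et = inputs["ET"].to_numpy()
    elements = list(config.conc_specs)

    rows = []
    outputs: dict[str, pd.DataFrame] = {}
    for cohort, params in cohorts.items():
        out = {}
        hq_sum = np.zeros(config.n_iter)
        cr_sum = np.zeros(config.n_iter)
        for el in elements:
            if el not in toxicity:
                raise ConfigurationError(f"no toxicity values configured for element {el!r}")
            conc = inputs[f"C_{el}"].to_numpy()
            tox = toxicity[el]
            hq = hazard_quotient(
                cdi_oral(conc, params, "non_carcinogenic", ef=ef), tox.rfd_oral
            ) + hazard_quotient(
                cdi_dermal(conc, el, params, "non_carcinogenic", ef=ef, et=et),
                tox.rfd_dermal,
            )
            out[f"HQ_{el}"] = hq
            hq_sum = hq_sum + hq
            if el in CARCINOGENS and tox.sf_oral is not None:
                cr = carcinogenic_risk(
                    cdi_oral(conc, params, "carcinogenic", ef=ef), tox.sf_oral
                )
                out[f"CR_{el}"] = cr
                cr_sum = cr_sum + cr
        out["HI"] = hq_sum
        out["TCR"] = cr_sum
        frame = pd.DataFrame(out)
        outputs[cohort] = frame
        for name, series in frame.items():
            thresholds = CR_THRESHOLDS if name.startswith(("CR", "TCR")) else HQ_THRESHOLDS
            rows.append(
                {"cohort": cohort, "output": name, **_summary_row(series.to_numpy(), thresholds)}
            )

    table = pd.DataFrame(rows).set_index(["cohort", "output"])
    return MCSummary(table=table, inputs=inputs, outputs=outputs if keep_draws else {})
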