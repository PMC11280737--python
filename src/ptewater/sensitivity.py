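"""Rank-correlation sensitivity analysis of the Monte Carlo risk outputs.

For each stochastic input the Spearman rank correlation ρ with the
endpoint draws (HI for the non-carcinogenic endpoint, TCR for the
carcinogenic one) is computed, and the contribution of input *i* is the
normalized absolute correlation

    contribution_i = 100 · |ρ_i| / Σ_j |ρ_j|   (%),

with the sign of ρ reported separately.  This is the de-facto standard
sensitivity measure in Monte Carlo health-risk software (e.g. the
Crystal Ball family); a contribution-to-variance variant that normalizes
ρ² instead is available via ``mode="squared"``.  Rank correlation makes
the measure invariant to monotone rescaling of any input.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = ["sensitivity_analysis"]


def sensitivity_analysis(
    inputs: pd.DataFrame,
    endpoint: np.ndarray | pd.Series,
    mode: str = "abs",
) -> pd.DataFrame:
    """Attribute endpoint variation to each stochastic input.

    Parameters
    ----------
    inputs
        Draw matrix, one column per stochastic input, one row per
        Monte Carlo iteration (at least 100).
    endpoint
        Endpoint draws (same length).
    mode
        ``"abs"`` normalizes \\|ρ\\|, ``"squared"`` normalizes ρ²
        (contribution to variance).

    Returns
    -------
    DataFrame indexed by input with columns ``rho`` (Spearman),
    ``sign`` (+1/-1/0) and ``contribution`` (%, sums to 100).
    """
    if mode not in ("abs", "squared"):
        raise InputError(f"unknown mode {mode!r}")
    endpoint = np.asarray(endpoint, dtype=float)
    if len(inputs) != endpoint.size:
        raise InputError("inputs and endpoint must have the same number of iterations")
    if len(inputs) < 100:
        raise InputError("need at least 100 iterations for a stable ranking")
    if inputs.shape[1] < 1:
        raise InputError("need at least one stochastic input")
    if np.all(endpoint == endpoint[0]):
        raise InputError("endpoint is constant; nothing to attribute")

    rho = {}
    for col in inputs.columns:
        x = inputs[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            warnings.warn(f"input {col!r} is constant; contribution set to 0", stacklevel=2)
            rho[col] = 0.0
        else:
            rho[col] = float(stats.spearmanr(x, endpoint).statistic)

    rho_s = pd.Series(rho, name="rho")
    weight = rho_s.abs() if mode == "abs" else rho_s**2
    total = weight.sum()
    contribution = 100.0 * weight / total if total > 0 else weight * 0.0
    return pd.DataFrame(
        {"rho": rho_s, "sign": np.sign(rho_s).astype(int), "contribution": contribution}
    )
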