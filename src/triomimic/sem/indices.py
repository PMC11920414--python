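"""Nested model comparison and global fit indices."""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import chi2

from .fit import FitResult

logger = logging.getLogger(__name__)


def chisq_diff(restricted: FitResult, general: FitResult) -> tuple[float, int, float]:
    """Chi-square difference test between structurally nested fits.

    Nesting is verified from the constraint lists, never assumed.  For
    scaled statistics the Satorra-Bentler style scaled difference is
    used; a negative scaled difference is floored at 0 with a warning.
    """
    if restricted.spec is not general.spec and not restricted.spec.is_nested_in(
        general.spec
    ):
        raise ValueError("restricted model is not nested in the general model")
    ddf = restricted.df - general.df
    if ddf < 0:
        raise ValueError("restricted model has more free parameters")
    if ddf == 0:
        return 0.0, 0, 1.0
    c_r, c_g = restricted.scale_factor, general.scale_factor
    if np.isclose(c_r, 1.0) and np.isclose(c_g, 1.0):
        stat = restricted.stat_raw - general.stat_raw
    else:
        cd = (restricted.df * c_r - general.df * c_g) / ddf
        cd = max(cd, 1e-12)
        stat = (restricted.stat_raw - general.stat_raw) / cd
    if stat < 0:
        logger.warning("negative chi-square difference (%.3g); floored at 0", stat)
        stat = 0.0
    return float(stat), int(ddf), float(chi2.sf(stat, ddf))


def fit_indices(result: FitResult, baseline: FitResult | None = None):
    """(CFI, RMSEA, SRMR) from a fit and its independence baseline.

    When ``baseline`` is omitted, the independence statistic stored on
    the result at fit time is used.
    """
    if baseline is not None:
        base_stat, base_df = baseline.stat, baseline.df
    else:
        base_stat, base_df = result.baseline_stat, result.baseline_df
    T, df, n = result.stat, result.df, result.n
    delta = max(T - df, 0.0)
    delta_b = max(base_stat - base_df, 0.0)
    denom = max(delta_b, delta)
    cfi = 1.0 if denom == 0 else float(np.clip(1.0 - delta / denom, 0.0, 1.0))
    rmsea = float(np.sqrt(delta / (df * max(n, 2.0)))) if df > 0 else 0.0
    return cfi, rmsea, result.srmr
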