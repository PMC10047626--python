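"""Publication-bias diagnostics: time trend, small-study test, adjusted mean.

Two multilevel meta-regressions share the machinery of the main model:

* the *test* model regresses Zr on mean-centered publication year and the
  standard error sqrt(v_i), with no intercept — a multilevel Egger-type
  funnel-asymmetry test plus a time-trend test in one fit;
* the *adjustment* model regresses Zr on mean-centered year and the sampling
  variance v_i, with the intercept included; the back-transformed intercept
  is the bias-adjusted mean correlation.  The adjustment is always computed,
  whether or not either test is significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .data_io import Dataset
from .meta_model import (DEFAULT_RANDOM_LEVELS, MetaFit, build_custom_model,
                         fit_reml, prediction_interval)

logger = logging.getLogger("matemeta.publication_bias")

__all__ = ["BiasResult", "bias_test", "adjusted_mean", "funnel_data"]


@dataclass
class BiasResult:
    """Slopes and Wald tests for the bias models, plus the adjusted mean."""

    slope_year: float | None = None
    z_year: float | None = None
    p_year: float | None = None
    slope_se_or_v: float | None = None
    z_se: float | None = None
    p_se: float | None = None
    adjusted_mean_r: float | None = None
    adjusted_ci_r: tuple[float, float] | None = None
    adjusted_pi_r: tuple[float, float] | None = None
    warnings: list[str] = None
    fit: MetaFit | None = None

    def __post_init__(self) -> None:
        if self.warnings is None:
            self.warnings = []


def _covariates(data: Dataset):
    years = np.array([e.publication_year for e in data.effects], float)
    v = np.array([e.v for e in data.effects])
    return years - years.mean(), v


def bias_test(data: Dataset, include_intercept: bool = False,
              random_levels=DEFAULT_RANDOM_LEVELS,
              fixed_sigma2=None) -> BiasResult:
    """Time-trend and small-study (funnel-asymmetry) test.

    Fits the multilevel model with mean-centered publication year and the
    standard error as fixed covariates and, by default, no intercept.
    ``include_intercept=True`` restores the conventional all-in Egger form.
    """
    year_c, v = _covariates(data)
    warnings: list[str] = []
    if np.ptp(year_c) == 0:
        raise ValueError("need at least 2 distinct publication years")
    se = np.sqrt(v)
    if np.ptp(se) == 0:
        warnings.append("standard error is constant across effects; "
                        "small-study slope is not identifiable")
        logger.warning(warnings[-1])
    spec = build_custom_model(
        data, {"year_c": year_c, "se": se},
        include_intercept=include_intercept, random_levels=random_levels)
    fit = fit_reml(spec, fixed_sigma2=fixed_sigma2)
    out = BiasResult(warnings=warnings, fit=fit)
    for name, (slope_attr, z_attr, p_attr) in {
        "year_c": ("slope_year", "z_year", "p_year"),
        "se": ("slope_se_or_v", "z_se", "p_se"),
    }.items():
        if name in fit.colnames:
            i = fit.colnames.index(name)
            setattr(out, slope_attr, float(fit.beta[i]))
            setattr(out, z_attr, float(fit.zval[i]))
            setattr(out, p_attr, float(fit.pval[i]))
    return out


def adjusted_mean(data: Dataset, random_levels=DEFAULT_RANDOM_LEVELS,
                  fixed_sigma2=None) -> BiasResult:
    """Bias-adjusted mean effect from the intercept-included adjustment model.

    Covariates are mean-centered year and the sampling variance v_i; the
    intercept (the expected effect at the mean year and v = 0, i.e. an
    infinitely precise study at the average publication date — in practice
    centering makes it the covariate-adjusted mean) is back-transformed to
    the correlation scale with its CI and PI.  Constant covariate columns
    are dropped, so a degenerate design collapses to the unadjusted fit.
    """
    year_c, v = _covariates(data)
    columns = {"year_c": year_c, "v": v}
    spec = build_custom_model(data, columns, include_intercept=True,
                              random_levels=random_levels)
    fit = fit_reml(spec, fixed_sigma2=fixed_sigma2)
    i0 = fit.colnames.index("intercept")
    lo, hi = fit.ci_zr()[i0]
    out = BiasResult(
        adjusted_mean_r=math.tanh(float(fit.beta[i0])),
        adjusted_ci_r=(math.tanh(float(lo)), math.tanh(float(hi))),
        adjusted_pi_r=prediction_interval(fit, index=i0),
        fit=fit,
    )
    for name, (slope_attr, z_attr, p_attr) in {
        "year_c": ("slope_year", "z_year", "p_year"),
        "v": ("slope_se_or_v", "z_se", "p_se"),
    }.items():
        if name in fit.colnames:
            i = fit.colnames.index(name)
            setattr(out, slope_attr, float(fit.beta[i]))
            setattr(out, z_attr, float(fit.zval[i]))
            setattr(out, p_attr, float(fit.pval[i]))
    return out


def funnel_data(data: Dataset):
    """(r, 1/SE) pairs for funnel plotting, one row per effect."""
    import pandas as pd
    return pd.DataFrame({
        "record_id": [e.record_id for e in data.effects],
        "r": [e.r for e in data.effects],
        "inv_se": [1.0 / math.sqrt(e.v) for e in data.effects],
    })
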