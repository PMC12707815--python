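"""Statistical layer: mass x speed regressions, stress-EMA power law,
tertile grouping.

Outcomes are modelled by ordinary least squares on body mass and speed with
their interaction considered first and dropped when non-significant
(p >= 0.05), each hop treated as an independent observation.  The
stress-EMA relation is fitted as a power law by OLS on log-log axes (the
multiplicative-error convention), with R^2 reported on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import PipelineError, PipelineWarning

ALPHA = 0.05


@dataclass
class Term:
    name: str
    coefficient: float
    standard_error: float
    p_value: float


@dataclass
class RegressionResult:
    terms: List[Term]
    r_squared: float
    interaction_included: bool
    n: int
    df_resid: int

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _ols(y: np.ndarray, X: np.ndarray, names: Sequence[str]):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PipelineError("singular_design",
                            "design matrix is rank deficient "
                            "(constant or collinear predictor)")
    return sm.OLS(y, X).fit()


def fit_mass_speed_model(y: Sequence[float], mass: Sequence[float],
                         speed: Sequence[float],
                         alpha: float = ALPHA) -> RegressionResult:
    """y ~ mass + speed (+ mass:speed), pruning a non-significant interaction.

    The full model with the interaction is fitted first; if the interaction
    p-value is >= alpha the additive model is refitted and reported.
    """
    y = np.asarray(y, float)
    mass = np.asarray(mass, float)
    speed = np.asarray(speed, float)
    if len(y) < 8:
        raise PipelineError("too_few_trials", f"n={len(y)} < 8")
    if np.isnan(y).any() or np.isnan(mass).any() or np.isnan(speed).any():
        raise PipelineError("missing_values", "NaN in regression inputs")

    if np.ptp(y) == 0:  # constant outcome: slopes zero by construction
        terms = [Term("const", float(y[0]), 0.0, 0.0),
                 Term("mass", 0.0, 0.0, 1.0), Term("speed", 0.0, 0.0, 1.0)]
        return RegressionResult(terms=terms, r_squared=0.0,
                                interaction_included=False, n=len(y),
                                df_resid=len(y) - 3)

    X_full = np.column_stack([np.ones_like(y), mass, speed, mass * speed])
    names_full = ["const", "mass", "speed", "mass:speed"]
    fit = _ols(y, X_full, names_full)
    interaction = True
    names = names_full
    if fit.pvalues[3] >= alpha:
        X_red = X_full[:, :3]
        names = names_full[:3]
        fit = _ols(y, X_red, names)
        interaction = False
    terms = [Term(nm, float(c), float(se), float(p))
             for nm, c, se, p in zip(names, fit.params, fit.bse, fit.pvalues)]
    return RegressionResult(terms=terms, r_squared=float(fit.rsquared),
                            interaction_included=interaction, n=len(y),
                            df_resid=int(fit.df_resid))


@dataclass
class PowerLawFit:
    """y = a * x**b fitted on log-log axes."""

    a: float
    b: float
    r_squared: float  # on the log-log scale
    n: int


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> PowerLawFit:
    """OLS of log(y) on log(x): a = exp(intercept), b = slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2:
        raise PipelineError("too_few_trials", "need at least 2 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise PipelineError("log_domain_error", "x and y must be positive")
    lx, ly = np.log(x), np.log(y)
    X = np.column_stack([np.ones_like(lx), lx])
    if np.linalg.matrix_rank(X) < 2:
        raise PipelineError("singular_design", "x values are all equal")
    fit = sm.OLS(ly, X).fit()
    r2 = float(fit.rsquared)
    if np.ptp(ly) == 0:
        r2 = 1.0  # exact (degenerate) fit of a constant
    return PowerLawFit(a=float(np.exp(fit.params[0])), b=float(fit.params[1]),
                       r_squared=r2, n=len(x))


def predict_power_law(fit: PowerLawFit, x) -> np.ndarray | float:
    """Stress (or any outcome) predicted at x: a * x**b."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise PipelineError("log_domain_error", "x must be positive")
    out = fit.a * x**fit.b
    return float(out) if out.ndim == 0 else out


def group_tertiles(values: Sequence[float],
                   labels: Sequence[str] = ("low", "mid", "high")) -> np.ndarray:
    """Tertile labels split at the 33.3/66.7 percentiles, stable under ties."""
    values = np.asarray(values, float)
    if len(values) < 3:
        raise PipelineError("too_few_trials", "need at least 3 values")
    q1, q2 = np.percentile(values, [100 / 3, 200 / 3])
    if q1 == q2:
        warnings.warn("tertile cut points coincide; grouping is degenerate",
                      PipelineWarning)
    out = np.where(values <= q1, labels[0],
                   np.where(values <= q2, labels[1], labels[2]))
    return out
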