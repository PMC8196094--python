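"""Maximum-likelihood fit of the first-stage mixed model (no second stage).

Sensitivity comparator: the same linear mixed-effects regression with all
exposures entered simultaneously, fit by REML with Wald 95% confidence
intervals, so hierarchical-model shrinkage can be judged against the
unpenalized multivariable fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import StudyDesign
from .sampler import handle_missing_outcomes

__all__ = ["MLFit", "fit_ml_mixed"]


@dataclass
class MLFit:
    """REML estimates with Wald intervals, mirroring the posterior layout."""

    table: pd.DataFrame  # index parameter; columns estimate, lower, upper, se
    sigma2: float
    sigma_u2: float
    converged: bool

    def __post_init__(self) -> None:
        t = self.table
        ok = (t["lower"] <= t["estimate"]) & (t["estimate"] <= t["upper"])
        if not ok.all():
            raise ValueError("Wald bounds must bracket the estimates")

    def beta(self, x_names) -> pd.Series:
        return self.table.loc[[f"beta[{n}]" for n in x_names], "estimate"]


def fit_ml_mixed(design: StudyDesign, reml: bool = True) -> MLFit:
    """Fit Y = alpha + X beta + W gamma + u + eps by (RE)ML.

    The subject random intercept is retained even when every subject has a
    single row (the variance then collapses toward zero and estimates match
    ordinary least squares).  Non-convergence is flagged, not raised.
    """
    design = handle_missing_outcomes(design)
    names = ["alpha"] + [f"beta[{n}]" for n in design.x_names] + [
        f"gamma[{n}]" for n in design.w_names
    ]
    D = np.column_stack([np.ones(design.n_rows), design.X, design.W])
    exog = pd.DataFrame(D, columns=names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(design.y, exog, groups=design.subject)
        try:
            res = model.fit(reml=reml, method=["lbfgs", "powell"])
            converged = bool(res.converged)
        except Exception:
            res = model.fit(reml=reml, method="powell", maxiter=500)
            converged = False
    fe = res.fe_params
    se = res.bse_fe
    zcrit = 1.959963984540054
    table = pd.DataFrame(
        {
            "estimate": fe,
            "lower": fe - zcrit * se,
            "upper": fe + zcrit * se,
            "se": se,
        }
    )
    table.index.name = "parameter"
    return MLFit(
        table=table,
        sigma2=float(res.scale),
        sigma_u2=float(np.asarray(res.cov_re)[0, 0]),
        converged=converged,
    )
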