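"""Simulation studies validating the estimator's operating characteristics.

Two reusable studies, each simulating complete cohorts from the first-stage
model with exposure coefficients drawn from the class-structured second-stage
prior and refitting them:

* :func:`coverage_study` — empirical frequentist coverage of the 95%
  credible intervals for the exposure coefficients under the correctly
  specified hierarchy (should sit near the nominal level).
* :func:`shrinkage_study` — mean squared error and interval width of the
  hierarchical posterior medians against the REML mixed-model comparator
  fitted without a second stage (shrinkage should not lose accuracy, and
  hierarchical intervals should be narrower on average).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import catalog as cat
from .design import PriorConfig, assemble_design, build_design_z
from .frequentist import fit_ml_mixed
from .sampler import MCMCConfig, run_mcmc
from .simulate import SimulationConfig, simulate_study

__all__ = ["CoverageResult", "ShrinkageResult", "coverage_study", "shrinkage_study"]


@dataclass(frozen=True)
class CoverageResult:
    coverage: float  # pooled over studies and coefficients
    n_intervals: int
    n_studies: int
    level: float = 0.95


@dataclass(frozen=True)
class ShrinkageResult:
    mse_bhm: float
    mse_ml: float
    mean_width_bhm: float
    mean_width_ml: float
    n_studies: int


def _study_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(2 * n) % (2**31)


def coverage_study(
    n_studies: int = 200,
    n_subjects: int = 600,
    n_iter: int = 5_000,
    n_burn: int = 1_000,
    tau: float = 2.5,
    seed: int = 1,
    level: float = 0.95,
) -> CoverageResult:
    """Interval coverage for exposure coefficients under the assumed model.

    Each replicate draws a fresh cohort (correlated exposures, two visits,
    second-visit attrition) with beta from the class-structured prior at
    ``tau``, fits the two-stage model with the matching tau, and checks
    whether each equal-tailed credible interval contains its true beta.
    """
    pests = cat.prenatal_pesticides()
    catalog = cat.default_catalog()
    seeds = _study_seeds(seed, n_studies)
    priors = PriorConfig(tau=tau)
    alpha_tail = (1.0 - level) / 2.0
    hits = total = 0
    for rep in range(n_studies):
        study = simulate_study(
            SimulationConfig(n_subjects=n_subjects, tau_true=tau, seed=int(seeds[rep]))
        )
        design = assemble_design(
            study.exposures, study.covariates, study.outcomes,
            "prenatal", "maternal", "score", pests,
        )
        z = build_design_z(design.x_names, catalog, variant="primary")
        chains = run_mcmc(
            design, z, priors,
            MCMCConfig(n_iter=n_iter, n_burn=n_burn, seed=int(seeds[n_studies + rep])),
        )
        beta = chains[0].draws["beta"]
        lo, hi = np.quantile(beta, [alpha_tail, 1.0 - alpha_tail], axis=0)
        truth = np.array([study.truth["beta"][p] for p in pests])
        hits += int(((lo <= truth) & (truth <= hi)).sum())
        total += len(pests)
    return CoverageResult(hits / total, total, n_studies, level)


def shrinkage_study(
    n_studies: int = 200,
    n_subjects: int = 300,
    n_iter: int = 2_500,
    n_burn: int = 500,
    tau: float = 2.5,
    seed: int = 2,
) -> ShrinkageResult:
    """Hierarchical medians vs REML estimates under class-structured truths."""
    pests = cat.prenatal_pesticides()
    catalog = cat.default_catalog()
    seeds = _study_seeds(seed, n_studies)
    priors = PriorConfig(tau=tau)
    se_bhm = se_ml = 0.0
    w_bhm = w_ml = 0.0
    n_coef = 0
    for rep in range(n_studies):
        study = simulate_study(
            SimulationConfig(n_subjects=n_subjects, tau_true=tau, seed=int(seeds[rep]))
        )
        design = assemble_design(
            study.exposures, study.covariates, study.outcomes,
            "prenatal", "maternal", "score", pests,
        )
        z = build_design_z(design.x_names, catalog, variant="primary")
        chains = run_mcmc(
            design, z, priors,
            MCMCConfig(n_iter=n_iter, n_burn=n_burn, seed=int(seeds[n_studies + rep])),
        )
        beta = chains[0].draws["beta"]
        med = np.median(beta, axis=0)
        lo, hi = np.quantile(beta, [0.025, 0.975], axis=0)
        truth = np.array([study.truth["beta"][p] for p in pests])
        ml = fit_ml_mixed(design)
        ml_est = ml.beta(pests).to_numpy()
        ml_tab = ml.table.loc[[f"beta[{p}]" for p in pests]]
        se_bhm += float(((med - truth) ** 2).sum())
        se_ml += float(((ml_est - truth) ** 2).sum())
        w_bhm += float((hi - lo).sum())
        w_ml += float((ml_tab["upper"] - ml_tab["lower"]).sum())
        n_coef += len(pests)
    return ShrinkageResult(
        mse_bhm=se_bhm / n_coef,
        mse_ml=se_ml / n_coef,
        mean_width_bhm=w_bhm / n_coef,
        mean_width_ml=w_ml / n_coef,
        n_studies=n_studies,
    )
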