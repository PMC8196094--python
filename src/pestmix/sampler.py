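"""Block-Gibbs sampler for the two-stage hierarchical linear mixed model.

First stage:  y = alpha + X beta + W gamma + u_subject + eps, with
eps ~ N(0, sigma2) and u ~ N(0, sigma_u2).  Second stage: hierarchical
exposure coefficients get beta ~ N(Z pi, tau^2), the rest a vague normal
prior; alpha, gamma and pi are vague; the variances get inverse-gamma
hyperpriors; tau is fixed a priori.

Every full conditional is conjugate, so the sampler is a plain Gibbs scan:
a joint multivariate-normal update of (alpha, beta, gamma), a vectorized
normal update of the subject intercepts, a normal update of pi given the
hierarchical betas, and inverse-gamma updates for the two variances.
This keeps each update testable against its closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import linalg

from .design import PriorConfig, StudyDesign, ZMatrix

__all__ = [
    "MCMCConfig",
    "Chain",
    "PosteriorSummary",
    "RankDeficientDesignError",
    "gibbs_lmm",
    "handle_missing_outcomes",
    "run_mcmc",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 50_000
    n_burn: int = 10_000
    n_chains: int = 1
    thin: int = 1
    seed: int = 0
    store_u: bool = False
    missing: str = "drop"  # drop | impute

    def __post_init__(self) -> None:
        if self.n_iter < 0 or self.n_burn < 0:
            raise ValueError("iteration counts must be nonnegative")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be >= 1")
        if self.missing not in ("drop", "impute"):
            raise ValueError("missing must be 'drop' or 'impute'")


@dataclass
class Chain:
    """Post-burn-in draws from one chain; arrays are (n_draws,) or (n_draws, p)."""

    draws: dict[str, np.ndarray]
    beta_names: list[str]
    gamma_names: list[str]
    pi_names: list[str]
    tau: float

    @property
    def n_draws(self) -> int:
        return len(self.draws["alpha"])

    def named(self) -> pd.DataFrame:
        """Flat draw matrix with one labeled column per scalar parameter."""
        cols: dict[str, np.ndarray] = {"alpha": self.draws["alpha"]}
        for label, key, names in (
            ("beta", "beta", self.beta_names),
            ("gamma", "gamma", self.gamma_names),
            ("pi", "pi", self.pi_names),
        ):
            arr = self.draws[key]
            for j, name in enumerate(names):
                cols[f"{label}[{name}]"] = arr[:, j]
        cols["sigma2"] = self.draws["sigma2"]
        if "sigma_u2" in self.draws:
            cols["sigma_u2"] = self.draws["sigma_u2"]
        return pd.DataFrame(cols)


class RankDeficientDesignError(ValueError):
    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


def _check_rank(D: np.ndarray, names: Sequence[str]) -> None:
    _, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(D.shape) * np.finfo(float).eps * 100
    bad = [names[i] for i in np.where(diag < tol)[0]]
    if bad:
        raise RankDeficientDesignError(bad)


def gibbs_lmm(
    y: np.ndarray,
    D: np.ndarray,
    prior_prec: np.ndarray,
    rng: np.random.Generator,
    n_iter: int,
    n_burn: int,
    thin: int = 1,
    subject: Optional[np.ndarray] = None,
    hier_idx: Optional[np.ndarray] = None,
    Zh: Optional[np.ndarray] = None,
    tau: Optional[float] = None,
    pi_prior_var: float = 1e6,
    a0: float = 0.001,
    b0: float = 0.001,
    fixed_sigma2: Optional[float] = None,
    fixed_sigma_u2: Optional[float] = None,
    missing_mask: Optional[np.ndarray] = None,
    store_u: bool = False,
) -> dict[str, np.ndarray]:
    """Low-level Gibbs scan; returns raw draws keyed theta/pi/u/sigma2/sigma_u2.

    ``prior_prec`` is the diagonal prior precision of the coefficient block
    theta (columns of D); rows listed in ``hier_idx`` take their prior mean
    from Zh @ pi with SD ``tau`` (their entries of prior_prec must equal
    1/tau^2).  ``missing_mask`` marks rows of y treated as latent and
    redrawn from the predictive each iteration.
    """
    y = np.asarray(y, dtype=float).copy()
    D = np.asarray(D, dtype=float)
    n, p = D.shape
    has_u = subject is not None
    if has_u:
        subject = np.asarray(subject)
        k = int(subject.max()) + 1
        counts = np.bincount(subject, minlength=k).astype(float)
    hier = hier_idx is not None and len(hier_idx) > 0
    if hier:
        q = Zh.shape[1]
        ZtZ = Zh.T @ Zh

    DtD = D.T @ D
    theta = np.zeros(p)
    pi = np.zeros(q) if hier else np.zeros(0)
    u = np.zeros(k) if has_u else None
    sigma2 = fixed_sigma2 if fixed_sigma2 is not None else float(np.nanvar(y) or 1.0)
    sigma_u2 = fixed_sigma_u2 if fixed_sigma_u2 is not None else 1.0
    mis = missing_mask if missing_mask is not None and missing_mask.any() else None
    if mis is not None:
        y[mis] = np.nanmean(y[~mis])

    n_keep = n_iter // thin
    out = {
        "theta": np.empty((n_keep, p)),
        "pi": np.empty((n_keep, len(pi))),
        "sigma2": np.empty(n_keep),
    }
    if has_u:
        out["sigma_u2"] = np.empty(n_keep)
        if store_u:
            out["u"] = np.empty((n_keep, k))

    kept = 0
    for it in range(n_burn + n_iter):
        # theta = (alpha, beta, gamma) | . : joint MVN update
        m0_prec = np.zeros(p)
        if hier:
            m0_prec[hier_idx] = (Zh @ pi) / tau**2
        resid_u = y - u[subject] if has_u else y
        prec = DtD / sigma2 + np.diag(prior_prec)
        b = D.T @ resid_u / sigma2 + m0_prec
        c, low = linalg.cho_factor(prec, lower=True, check_finite=False)
        mean = linalg.cho_solve((c, low), b, check_finite=False)
        theta = mean + linalg.solve_triangular(
            c, rng.standard_normal(p), lower=True, trans="T", check_finite=False
        )

        fitted = D @ theta
        resid = y - fitted

        # subject random intercepts | . : independent normal updates
        if has_u:
            prec_u = counts / sigma2 + 1.0 / sigma_u2
            mean_u = np.bincount(subject, weights=resid, minlength=k) / sigma2 / prec_u
            u = mean_u + rng.standard_normal(k) / np.sqrt(prec_u)
            resid = resid - u[subject]

        # pi | beta_h : conjugate normal regression of beta on Z
        if hier:
            prec_pi = ZtZ / tau**2 + np.eye(q) / pi_prior_var
            b_pi = Zh.T @ theta[hier_idx] / tau**2
            cpi, lowpi = linalg.cho_factor(prec_pi, lower=True, check_finite=False)
            mean_pi = linalg.cho_solve((cpi, lowpi), b_pi, check_finite=False)
            pi = mean_pi + linalg.solve_triangular(
                cpi, rng.standard_normal(q), lower=True, trans="T", check_finite=False
            )

        # variance components | . : inverse-gamma updates
        if fixed_sigma2 is None:
            sigma2 = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + resid @ resid / 2.0))
        if has_u and fixed_sigma_u2 is None:
            sigma_u2 = 1.0 / rng.gamma(a0 + k / 2.0, 1.0 / (b0 + u @ u / 2.0))

        # latent missing outcomes | . : predictive draws
        if mis is not None:
            mu_mis = fitted[mis] + (u[subject[mis]] if has_u else 0.0)
            y[mis] = mu_mis + np.sqrt(sigma2) * rng.standard_normal(mis.sum())

        if it >= n_burn and (it - n_burn) % thin == 0:
            out["theta"][kept] = theta
            out["pi"][kept] = pi
            out["sigma2"][kept] = sigma2
            if has_u:
                out["sigma_u2"][kept] = sigma_u2
                if store_u:
                    out["u"][kept] = u
            kept += 1
    return out


def handle_missing_outcomes(design: StudyDesign) -> StudyDesign:
    """Drop rows with missing Y; subjects keeping >= 1 row stay in the model.

    Under the first-stage model, missing outcomes are ignorable: dropping
    their rows from the likelihood gives the same posterior (up to Monte
    Carlo error) as treating them as latent draws from the predictive.
    """
    obs = ~np.isnan(design.y)
    if obs.all():
        return design
    subj = design.subject[obs]
    kept_codes = np.unique(subj)
    recode = {old: new for new, old in enumerate(kept_codes)}
    removed = design.n_subjects - len(kept_codes)
    if removed:
        logger.info("removed %d subject(s) with no observed outcome rows", removed)
    return replace(
        design,
        y=design.y[obs],
        X=design.X[obs],
        W=design.W[obs],
        subject=np.array([recode[s] for s in subj]),
        subject_ids=[design.subject_ids[c] for c in kept_codes],
        sex_girl=design.sex_girl[obs],
    )


def run_mcmc(
    design: StudyDesign,
    z: ZMatrix,
    priors: PriorConfig = PriorConfig(),
    cfg: MCMCConfig = MCMCConfig(),
) -> list[Chain]:
    """Fit the two-stage model; returns one Chain per requested chain."""
    if list(z.coef_names) != list(design.x_names):
        raise ValueError("Z matrix rows must match the design's exposure columns")

    if cfg.missing == "drop":
        design = handle_missing_outcomes(design)
        missing_mask = None
        y = design.y
    else:
        y = design.y
        missing_mask = np.isnan(y)

    n = design.n_rows
    p_x = len(design.x_names)
    p_w = len(design.w_names)
    D = np.column_stack([np.ones(n), design.X, design.W])
    names = ["alpha"] + design.x_names + design.w_names
    _check_rank(D, names)

    hier_mask, Zh, pi_names = z.hier_block()
    hier_idx = np.where(np.concatenate([[False], hier_mask, np.zeros(p_w, bool)]))[0]

    prior_prec = np.full(1 + p_x + p_w, 1.0 / priors.vague_variance)
    prior_prec[hier_idx] = 1.0 / priors.tau**2

    chains = []
    for ss in np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains):
        rng = np.random.default_rng(ss)
        raw = gibbs_lmm(
            y,
            D,
            prior_prec,
            rng,
            n_iter=cfg.n_iter,
            n_burn=cfg.n_burn,
            thin=cfg.thin,
            subject=design.subject,
            hier_idx=hier_idx if len(hier_idx) else None,
            Zh=Zh if len(hier_idx) else None,
            tau=priors.tau,
            pi_prior_var=priors.vague_variance,
            a0=priors.a0,
            b0=priors.b0,
            missing_mask=missing_mask,
            store_u=cfg.store_u,
        )
        draws = {
            "alpha": raw["theta"][:, 0],
            "beta": raw["theta"][:, 1 : 1 + p_x],
            "gamma": raw["theta"][:, 1 + p_x :],
            "pi": raw["pi"],
            "sigma2": raw["sigma2"],
            "sigma_u2": raw["sigma_u2"],
        }
        if cfg.store_u:
            draws["u"] = raw["u"]
        chains.append(
            Chain(
                draws=draws,
                beta_names=list(design.x_names),
                gamma_names=list(design.w_names),
                pi_names=list(pi_names),
                tau=priors.tau,
            )
        )
    return chains


@dataclass
class PosteriorSummary:
    """Posterior medians and equal-tailed 95% intervals per parameter."""

    table: pd.DataFrame  # index: parameter; columns: median, lower, upper, ess

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["lower"] <= t["median"]) & (t["median"] <= t["upper"])).all():
            raise ValueError("credible bounds must bracket the median")

    def formatted(self, decimals: int = 1) -> pd.Series:
        """Rows formatted as 'median (lower, upper)'."""
        t = self.table.round(decimals)
        return t.apply(
            lambda r: f"{r['median']:.{decimals}f} ({r['lower']:.{decimals}f}, "
            f"{r['upper']:.{decimals}f})",
            axis=1,
        )


def _ess(x: np.ndarray) -> float:
    """Effective sample size from pairwise-summed autocorrelations (Geyer)."""
    n = len(x)
    x = x - x.mean()
    var = x @ x / n
    if var == 0:
        return float(n)
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    rho = acov / var
    s = 0.0
    for t in range(1, n - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def summarize(
    chains: Union[Chain, Sequence[Chain]],
    params: Optional[Sequence[str]] = None,
    level: float = 0.95,
) -> PosteriorSummary:
    """Pool chains and report median, equal-tailed interval, and ESS.

    ``params`` selects labeled columns (e.g. ``beta[chlorpyrifos]``); prefix
    selections like ``beta`` expand to all matching columns.
    """
    if isinstance(chains, Chain):
        chains = [chains]
    if not chains or chains[0].n_draws == 0:
        raise ValueError("no draws to summarize")
    total = sum(c.n_draws for c in chains)
    if total < 100:
        raise ValueError(f"need at least 100 retained draws, got {total}")
    frames = [c.named() for c in chains]
    pooled = pd.concat(frames, axis=0, ignore_index=True)
    if params is not None:
        cols: list[str] = []
        for sel in params:
            if sel in pooled.columns:
                cols.append(sel)
            else:
                matches = [c for c in pooled.columns if c.startswith(sel + "[")]
                if not matches:
                    raise KeyError(f"no parameter matches {sel!r}")
                cols.extend(matches)
        pooled = pooled[cols]
    alpha_tail = (1.0 - level) / 2.0
    qs = pooled.quantile([alpha_tail, 0.5, 1.0 - alpha_tail])
    table = pd.DataFrame(
        {
            "median": qs.loc[0.5],
            "lower": qs.loc[alpha_tail],
            "upper": qs.loc[1.0 - alpha_tail],
            "ess": [
                sum(_ess(f[c].to_numpy()) for f in frames if c in f)
                for c in pooled.columns
            ],
        }
    )
    table.index.name = "parameter"
    return PosteriorSummary(table)
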