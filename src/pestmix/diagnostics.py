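"""MCMC convergence diagnostics: Geweke z, Gelman-Rubin R-hat, autocorrelation.

Numbers are the contract; the plotting helpers (trace, autocorrelation,
density panels) are auxiliary conveniences for visual checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sampler import Chain

__all__ = [
    "geweke_z",
    "gelman_rubin",
    "autocorrelation",
    "DiagnosticReport",
    "diagnostic_report",
    "plot_chain_panels",
]

GEWEKE_Z_THRESHOLD = 1.96
RHAT_THRESHOLD = 1.1


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density of a segment at frequency zero.

    Bartlett-windowed autocovariance sum with lag truncation L = n^(1/3);
    fixed here for reproducibility.  For iid input this reduces to the
    sample variance up to small-order noise.
    """
    n = len(x)
    x = x - x.mean()
    L = max(1, int(round(n ** (1.0 / 3.0))))
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[: L + 1].real / n
    w = 1.0 - np.arange(1, L + 1) / (L + 1.0)
    return float(acov[0] + 2.0 * (w * acov[1 : L + 1]).sum())


def geweke_z(chain: np.ndarray, frac_a: float = 0.1, frac_b: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late segment means.

    The difference between the mean of the first ``frac_a`` and the last
    ``frac_b`` of the chain, standardized by the spectral-density-at-zero
    estimates of each segment's variance of the mean.  |z| above ~1.96
    suggests the chain's mean drifted between the segments.
    """
    chain = np.asarray(chain, dtype=float)
    if not (0 < frac_a and 0 < frac_b and frac_a + frac_b <= 1):
        raise ValueError("need 0 < frac_a, frac_b and frac_a + frac_b <= 1")
    n = len(chain)
    na = int(n * frac_a)
    nb = int(n * frac_b)
    if na < 10 or nb < 10:
        raise ValueError("segments must contain at least 10 draws")
    a = chain[:na]
    b = chain[n - nb :]
    denom2 = _spectral_density_zero(a) / na + _spectral_density_zero(b) / nb
    diff = a.mean() - b.mean()
    # numerically constant segments: means agree to machine precision
    tol = 1e-12 * max(1.0, abs(a.mean()), abs(b.mean()))
    if abs(diff) < tol:
        return 0.0
    if denom2 <= 0:
        return float(np.inf) * np.sign(diff)
    return float(diff / np.sqrt(denom2))


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor from between/within-chain variances.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) over m >= 2 equal-length chains;
    values near 1 indicate the chains explore the same distribution.
    """
    arrs = [np.asarray(c, dtype=float) for c in chains]
    if len(arrs) < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    n = len(arrs[0])
    if n < 10 or any(len(a) != n for a in arrs):
        raise ValueError("chains must share a common length of at least 10")
    stacked = np.stack(arrs)
    W = stacked.var(axis=1, ddof=1).mean()
    B_over_n = stacked.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else float(np.inf)
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def autocorrelation(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag (lag 0 is 1 by definition)."""
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n <= max_lag:
        raise ValueError("chain must be longer than max_lag")
    x = chain - chain.mean()
    var = x @ x
    out = np.zeros(max_lag + 1)
    out[0] = 1.0
    if var == 0:
        return out
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[: max_lag + 1].real
    return acov / acov[0]


@dataclass
class DiagnosticReport:
    """Per-parameter convergence table with conventional pass flags."""

    table: pd.DataFrame  # geweke_z, rhat, lag1_acf, geweke_ok, rhat_ok

    def all_ok(self) -> bool:
        flags = self.table[[c for c in ("geweke_ok", "rhat_ok") if c in self.table]]
        return bool(flags.fillna(True).all().all())

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def diagnostic_report(
    chains: Sequence[Chain], params: Optional[Sequence[str]] = None
) -> DiagnosticReport:
    """Geweke (first chain), R-hat (if >= 2 chains), lag-1 autocorrelation."""
    frames = [c.named() for c in chains]
    cols = list(frames[0].columns)
    if params is not None:
        cols = [c for c in cols if c in params or c.split("[")[0] in params]
    rows = {}
    for cname in cols:
        first = frames[0][cname].to_numpy()
        z = geweke_z(first)
        rhat = (
            gelman_rubin([f[cname].to_numpy() for f in frames]) if len(frames) >= 2 else np.nan
        )
        lag1 = autocorrelation(first, 1)[1]
        rows[cname] = {
            "geweke_z": z,
            "rhat": rhat,
            "lag1_acf": lag1,
            "geweke_ok": bool(abs(z) < GEWEKE_Z_THRESHOLD),
            "rhat_ok": bool(rhat < RHAT_THRESHOLD) if np.isfinite(rhat) else None,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"
    return DiagnosticReport(table)


def plot_chain_panels(chains: Sequence[Chain], param: str, path, max_lag: int = 50) -> None:
    """Save a trace / autocorrelation / density panel for one parameter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(11, 3))
    for i, chain in enumerate(chains):
        x = chain.named()[param].to_numpy()
        axes[0].plot(x, lw=0.4, label=f"chain {i}")
        axes[1].plot(autocorrelation(x, min(max_lag, len(x) - 1)), lw=0.8)
        axes[2].hist(x, bins=50, density=True, alpha=0.5)
    axes[0].set_title(f"trace: {param}")
    axes[1].set_title("autocorrelation")
    axes[2].set_title("density")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
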