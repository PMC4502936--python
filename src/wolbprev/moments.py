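"""Moment-based estimators of mean prevalence and incidence.

The sample prevalences y_i = k_i/n_i of a group of screens have expectation
μ (the mean of the prevalence distribution) but inflated variance: each y_i
carries binomial sampling noise on top of the between-species variance σ².
The moment estimator subtracts an estimate of the average sampling variance
from the between-screen variance:

    μ̂  = mean(y_i)
    σ̂² = Var(y_i)  −  (1/S) Σ_i  y_i(1−y_i)/(n_i − 1)

(Var is the empirical between-screen variance of the y_i.)

(y(1−y)/(n−1) is the unbiased within-screen variance estimate; screens with
n_i = 1 carry no information about their own variance and contribute
μ̂(1−μ̂) instead).  Matching beta moments gives α̂ and β̂, and the beta tail
gives the incidence x̂_c.  When sampling noise dominates, σ̂² can come out
negative or exceed μ̂(1−μ̂); the estimate is then flagged invalid and no
beta parameters or incidence are produced — a real feature of the method,
not a numerical failure.

Confidence intervals are percentile bootstrap over populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .screen_data import ScreenTable

__all__ = ["MomentEstimate", "BootstrapInterval", "moment_fit", "moment_incidence", "bootstrap_ci"]


class InvalidMomentEstimate(ValueError):
    """Raised when a functional of an invalid (negative-variance) estimate is requested."""


@dataclass(frozen=True)
class MomentEstimate:
    mu_hat: float
    sigma2_hat: float
    n_populations: int
    valid: bool
    alpha_hat: float | None = None
    beta_hat: float | None = None

    def incidence(self, c: float) -> float:
        return moment_incidence(self, c)


def _moment_core(y: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """(mu_hat, sigma2_hat) for sample prevalences y with sample sizes n."""
    mu = float(np.mean(y))
    var_between = float(np.var(y))
    with np.errstate(divide="ignore", invalid="ignore"):
        samp = np.where(n > 1, y * (1.0 - y) / (n - 1.0), mu * (1.0 - mu))
    return mu, var_between - float(np.mean(samp))


def moment_fit(table: ScreenTable, weight_by_n: bool = False) -> MomentEstimate:
    """Moment estimate of the prevalence distribution from a group of screens.

    ``weight_by_n`` switches μ̂ to the individual-weighted mean Σk/Σn;
    the default weights populations equally.
    """
    if len(table) < 2:
        raise ValueError("moment estimation needs at least 2 populations")
    k, n = table.counts
    y = k / n
    mu, sigma2 = _moment_core(y, n.astype(float))
    if weight_by_n:
        mu = float(k.sum() / n.sum())

    valid = bool(0.0 < sigma2 < mu * (1.0 - mu)) and 0.0 < mu < 1.0
    alpha = beta = None
    if valid:
        scale = mu * (1.0 - mu) / sigma2 - 1.0
        alpha = mu * scale
        beta = (1.0 - mu) * scale
    return MomentEstimate(
        mu_hat=mu,
        sigma2_hat=sigma2,
        n_populations=len(table),
        valid=valid,
        alpha_hat=alpha,
        beta_hat=beta,
    )


def moment_incidence(est: MomentEstimate, c: float) -> float:
    """x̂_c = 1 − I_c(α̂, β̂); raises on an invalid estimate."""
    if not est.valid:
        raise InvalidMomentEstimate(
            f"moment estimate invalid (sigma2_hat={est.sigma2_hat:.4g}); incidence not computable"
        )
    if not 0.0 < c < 1.0:
        raise ValueError(f"threshold c must lie in (0, 1), got {c}")
    return float(1.0 - special.betainc(est.alpha_hat, est.beta_hat, c))


@dataclass(frozen=True)
class BootstrapInterval:
    low: float
    high: float
    n_boot: int
    n_invalid: int
    unreliable: bool = field(default=False)


def bootstrap_ci(
    table: ScreenTable,
    statistic="mu",
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> BootstrapInterval:
    """Percentile bootstrap interval for a moment statistic.

    ``statistic`` is ``"mu"`` or ``("incidence", c)``.  Populations are
    resampled with replacement; resamples where the moment estimate is
    invalid (negative corrected variance) cannot yield an incidence and are
    dropped from the percentile computation but counted; the interval is
    flagged unreliable when more than half the resamples are invalid.
    """
    if len(table) == 0:
        raise ValueError("cannot bootstrap an empty table")
    k, n = table.counts
    y = k / n
    nf = n.astype(float)
    S = len(y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, S, size=(n_boot, S))
    yb = y[idx]
    nb = nf[idx]

    mu_b = yb.mean(axis=1)
    var_b = yb.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        samp = np.where(nb > 1, yb * (1.0 - yb) / (nb - 1.0), (mu_b * (1.0 - mu_b))[:, None])
    sigma2_b = var_b - samp.mean(axis=1)
    valid = (sigma2_b > 0) & (sigma2_b < mu_b * (1.0 - mu_b)) & (mu_b > 0) & (mu_b < 1)

    if statistic == "mu":
        vals = mu_b
        keep = np.ones(n_boot, dtype=bool)
    elif isinstance(statistic, tuple) and statistic[0] == "incidence":
        c = statistic[1]
        keep = valid
        scale = np.where(valid, mu_b * (1.0 - mu_b) / np.where(valid, sigma2_b, 1.0) - 1.0, np.nan)
        a_b = mu_b * scale
        b_b = (1.0 - mu_b) * scale
        vals = np.full(n_boot, np.nan)
        if keep.any():
            vals[keep] = 1.0 - special.betainc(a_b[keep], b_b[keep], c)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    n_invalid = int(n_boot - keep.sum())
    if keep.sum() == 0:
        return BootstrapInterval(np.nan, np.nan, n_boot, n_invalid, unreliable=True)
    lo, hi = np.percentile(vals[keep], [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
    return BootstrapInterval(
        float(lo), float(hi), n_boot, n_invalid, unreliable=n_invalid > n_boot / 2
    )
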