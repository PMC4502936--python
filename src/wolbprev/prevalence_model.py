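"""Likelihood-based estimation of the across-species prevalence distribution.

The model: each host species carries the symbiont at an (unobserved)
prevalence q; across species q follows either a beta(α, β) distribution or a
doubly-inflated beta with extra point masses at q=0 (weight φγ, never
infected) and q=1 (weight φ(1−γ), fixed infection).  A screen of n
individuals from one population then yields k positives with k | q ~
Binomial(n, q), so the marginal distribution of k is beta-binomial (plus the
point-mass terms for the inflated family).  Maximizing the product of these
marginals over populations estimates the prevalence distribution, from which
two functionals are reported:

* mean prevalence  μ = ∫ q·pdf(q) dq — the expected fraction of infected
  individuals in a random species;
* incidence  x_c = ∫_c^1 pdf(q) dq — the fraction of species infected above
  a threshold prevalence c (by convention the point mass at q=1 counts and
  the mass at q=0 never does).

Confidence intervals come from the curvature of the log-likelihood surface
(observed information on the unconstrained parameter scale, delta method for
the functionals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from statsmodels.tools import numdiff

from .screen_data import ScreenTable

__all__ = [
    "BetaParams",
    "InflatedBetaParams",
    "FitResult",
    "beta_pdf",
    "marginal_pmf",
    "log_likelihood",
    "fit_ml",
    "mean_prevalence",
    "incidence",
    "curvature_ci",
    "expected_bin_fractions",
]

DEFAULT_THRESHOLDS = (0.001, 0.0001)

# clip for logit-scale parameters so point masses never hit exactly 0 or 1
_EPS = 1e-10


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a beta distribution of prevalence q."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"alpha and beta must be positive, got {self.alpha}, {self.beta}")

    @property
    def n_parameters(self) -> int:
        return 2


@dataclass(frozen=True)
class InflatedBetaParams:
    """Doubly-inflated beta: point masses φγ at q=0 and φ(1−γ) at q=1,
    continuous beta(α, β) mass 1−φ in between."""

    alpha: float
    beta: float
    gamma: float
    phi: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"alpha and beta must be positive, got {self.alpha}, {self.beta}")
        if not (0.0 <= self.gamma <= 1.0 and 0.0 <= self.phi <= 1.0):
            raise ValueError(f"gamma and phi must lie in [0, 1], got {self.gamma}, {self.phi}")

    @property
    def n_parameters(self) -> int:
        return 4

    @property
    def mass_at_zero(self) -> float:
        return self.phi * self.gamma

    @property
    def mass_at_one(self) -> float:
        return self.phi * (1.0 - self.gamma)


PrevalenceModel = BetaParams | InflatedBetaParams


def beta_pdf(q, params: BetaParams | InflatedBetaParams):
    """Continuous beta density at q in (0, 1).

    For the inflated family this is the *continuous branch* only, scaled by
    its total mass 1−φ; the point masses at 0 and 1 are not densities.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0.0) or np.any(q >= 1.0):
        raise ValueError("q must lie strictly inside (0, 1)")
    a, b = params.alpha, params.beta
    logpdf = (
        special.gammaln(a + b)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(q)
        + (b - 1.0) * np.log1p(-q)
    )
    dens = np.exp(logpdf)
    if isinstance(params, InflatedBetaParams):
        dens = (1.0 - params.phi) * dens
    return dens if dens.ndim else float(dens)


def _log_betabinom(k, n, alpha: float, beta: float):
    """log C(n,k) + log B(k+α, n−k+β) − log B(α, β), vectorized."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    return (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + special.betaln(k + alpha, n - k + beta)
        - special.betaln(alpha, beta)
    )


def marginal_pmf(k, n, model: PrevalenceModel):
    """P(k positives out of n) marginalized over the prevalence distribution.

    Beta family: the closed-form beta-binomial pmf.  Inflated family: the
    point masses contribute φγ at k=0 and φ(1−γ) at k=n on top of (1−φ)
    times the beta-binomial.  Sums to 1 over k = 0..n.
    """
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    if np.any(n_arr < 1) or np.any(k_arr < 0) or np.any(k_arr > n_arr):
        raise ValueError("require 0 <= k <= n and n >= 1")
    bb = np.exp(_log_betabinom(k_arr, n_arr, model.alpha, model.beta))
    if isinstance(model, BetaParams):
        out = bb
    else:
        out = (1.0 - model.phi) * bb
        out = out + np.where(k_arr == 0, model.mass_at_zero, 0.0)
        out = out + np.where(k_arr == n_arr, model.mass_at_one, 0.0)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def _loglik_counts(k: np.ndarray, n: np.ndarray, w: np.ndarray, model: PrevalenceModel) -> float:
    """Weighted log-likelihood over unique (k, n) cells with multiplicities w."""
    bb = _log_betabinom(k, n, model.alpha, model.beta)
    if isinstance(model, BetaParams):
        return float(np.dot(w, bb))
    mix = (1.0 - model.phi) * np.exp(bb)
    mix = mix + np.where(k == 0, model.mass_at_zero, 0.0)
    mix = mix + np.where(k == n, model.mass_at_one, 0.0)
    with np.errstate(divide="ignore"):
        return float(np.dot(w, np.log(mix)))


def _unique_counts(table: ScreenTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k, n = table.counts
    cells, w = np.unique(np.column_stack([k, n]), axis=0, return_counts=True)
    return cells[:, 0].astype(float), cells[:, 1].astype(float), w.astype(float)


def log_likelihood(table: ScreenTable, model: PrevalenceModel) -> float:
    """Σ_i log P(k_i | n_i, model), binomial coefficients included."""
    if len(table) == 0:
        raise ValueError("log-likelihood of an empty table is undefined")
    k, n, w = _unique_counts(table)
    return _loglik_counts(k, n, w, model)


# ---------------------------------------------------------------------------
# parameter transforms: optimization runs unconstrained on
# theta = (log α, log β[, logit γ, logit φ])

def _sigmoid(x):
    return special.expit(x)


def _theta_to_model(theta: np.ndarray, family: str) -> PrevalenceModel:
    a = float(np.exp(np.clip(theta[0], -30, 30)))
    b = float(np.exp(np.clip(theta[1], -30, 30)))
    if family == "beta":
        return BetaParams(a, b)
    g = float(np.clip(_sigmoid(theta[2]), _EPS, 1 - _EPS))
    p = float(np.clip(_sigmoid(theta[3]), _EPS, 1 - _EPS))
    return InflatedBetaParams(a, b, g, p)


@dataclass
class FitResult:
    """Maximum-likelihood fit of a prevalence distribution to a screen table."""

    model: PrevalenceModel
    log_likelihood: float
    aic: float
    n_parameters: int
    mu: float
    incidence_by_threshold: dict[float, float]
    ci_mu: tuple[float, float] | None
    ci_incidence: dict[float, tuple[float, float]]
    converged: bool
    message: str
    n_populations: int
    family: str
    theta: np.ndarray = field(repr=False)
    cov_theta: np.ndarray | None = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "parameters": {
                f: getattr(self.model, f)
                for f in ("alpha", "beta", "gamma", "phi")
                if hasattr(self.model, f)
            },
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_parameters": self.n_parameters,
            "mu": self.mu,
            "ci_mu": self.ci_mu,
            "incidence": {str(c): x for c, x in self.incidence_by_threshold.items()},
            "ci_incidence": {str(c): ci for c, ci in self.ci_incidence.items()},
            "converged": self.converged,
            "message": self.message,
            "n_populations": self.n_populations,
        }
        return d


def mean_prevalence(model: PrevalenceModel) -> float:
    """μ = ∫ q·pdf(q) dq: α/(α+β) for the beta family; the inflated family
    adds the q=1 point mass and rescales the continuous part."""
    m = model.alpha / (model.alpha + model.beta)
    if isinstance(model, InflatedBetaParams):
        return model.mass_at_one + (1.0 - model.phi) * m
    return m


def incidence(model: PrevalenceModel, c: float) -> float:
    """x_c = ∫_c^1 pdf(q) dq: the fraction of species with prevalence above c.

    The point mass at q=1 always exceeds any threshold c < 1 and therefore
    counts; the point mass at q=0 never does.
    """
    if not 0.0 < c < 1.0:
        raise ValueError(f"threshold c must lie in (0, 1), got {c}")
    tail = 1.0 - special.betainc(model.alpha, model.beta, c)
    if isinstance(model, InflatedBetaParams):
        return (1.0 - model.phi) * tail + model.mass_at_one
    return float(tail)


def _moment_start(table: ScreenTable) -> tuple[float, float] | None:
    """Beta-parameter start point from the moment estimator, if valid."""
    from .moments import moment_fit

    try:
        est = moment_fit(table)
    except ValueError:
        return None
    if est.valid:
        return est.alpha_hat, est.beta_hat
    return None


def fit_ml(
    table: ScreenTable,
    family: str = "beta",
    n_restarts: int = 10,
    seed: int | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    compute_ci: bool = True,
) -> FitResult:
    """Fit the beta or doubly-inflated prevalence distribution by ML.

    Optimization runs unconstrained on (log α, log β, logit γ, logit φ) with
    multi-start: one start from the moment estimator (when valid) plus
    dispersed random restarts; best optimum kept.  AIC = 2p − 2lnL.  When
    ``compute_ci`` the observed-information (curvature) intervals for μ and
    each x_c are filled in via :func:`curvature_ci`.
    """
    if family not in ("beta", "doubly_inflated"):
        raise ValueError(f"unknown family {family!r}")
    n_par = 2 if family == "beta" else 4
    if len(table) < n_par:
        raise ValueError(f"need at least {n_par} records to fit the {family} family")
    k, n, w = _unique_counts(table)

    if np.all(k == 0):
        import warnings

        warnings.warn(
            "all screens are negative; the fit will sit on a degenerate boundary",
            stacklevel=2,
        )

    def nll(theta: np.ndarray) -> float:
        model = _theta_to_model(theta, family)
        ll = _loglik_counts(k, n, w, model)
        return np.inf if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    mom = _moment_start(table)
    base = np.log([mom[0], mom[1]]) if mom else np.array([0.0, 0.0])
    if family == "beta":
        starts.append(base)
        for _ in range(max(0, n_restarts - 1)):
            starts.append(rng.normal(0.0, 1.5, size=2))
    else:
        # seed gamma from the share of all-negative screens, phi modest
        frac0 = float(np.dot(w, (k == 0)) / w.sum())
        starts.append(np.concatenate([base, [special.logit(np.clip(frac0, 0.05, 0.95)), special.logit(0.2)]]))
        for _ in range(max(0, n_restarts - 1)):
            starts.append(
                np.concatenate([rng.normal(0.0, 1.5, size=2), rng.normal(0.0, 1.5, size=2)])
            )

    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
        res = optimize.minimize(nll, res.x, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    model = _theta_to_model(best.x, family)
    ll = -float(best.fun)
    aic = 2.0 * n_par - 2.0 * ll
    converged = bool(np.isfinite(ll))
    message = best.message if isinstance(best.message, str) else str(best.message)

    cov = None
    if compute_ci and converged:
        try:
            hess = numdiff.approx_hess1(best.x, nll)
            cov = np.linalg.inv(hess)
            if not np.all(np.linalg.eigvalsh(hess) > 0):
                cov = None
                message += "; Hessian not positive definite, curvature CIs unavailable"
        except np.linalg.LinAlgError:
            cov = None
            message += "; singular Hessian, curvature CIs unavailable"

    fit = FitResult(
        model=model,
        log_likelihood=ll,
        aic=aic,
        n_parameters=n_par,
        mu=mean_prevalence(model),
        incidence_by_threshold={c: incidence(model, c) for c in thresholds},
        ci_mu=None,
        ci_incidence={},
        converged=converged,
        message=message,
        n_populations=len(table),
        family=family,
        theta=best.x,
        cov_theta=cov,
    )
    if compute_ci and cov is not None:
        fit.ci_mu = curvature_ci(fit, "mu")
        fit.ci_incidence = {c: curvature_ci(fit, ("incidence", c)) for c in thresholds}
    return fit


def curvature_ci(fit: FitResult, functional, level: float = 0.95) -> tuple[float, float] | None:
    """Delta-method CI for μ or x_c from the log-likelihood curvature.

    The covariance of the unconstrained parameters is the inverse observed
    information; the functional's gradient on that scale gives its standard
    error.  Endpoints are truncated to [0, 1].  Returns None when the
    information matrix was not positive definite.
    """
    if fit.cov_theta is None:
        return None
    if functional == "mu":
        g = lambda th: mean_prevalence(_theta_to_model(th, fit.family))  # noqa: E731
    elif isinstance(functional, tuple) and functional[0] == "incidence":
        c = functional[1]
        g = lambda th: incidence(_theta_to_model(th, fit.family), c)  # noqa: E731
    else:
        raise ValueError(f"unknown functional {functional!r}")
    grad = numdiff.approx_fprime(fit.theta, lambda th: np.atleast_1d(g(th)))
    grad = np.ravel(grad)
    var = float(grad @ fit.cov_theta @ grad)
    if not np.isfinite(var) or var < 0:
        return None
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    center = g(fit.theta)
    half = z * np.sqrt(var)
    return (max(0.0, center - half), min(1.0, center + half))


def expected_bin_fractions(
    table: ScreenTable, model: PrevalenceModel, bin_width: float = 0.1
) -> np.ndarray:
    """Model-expected fraction of screens per sample-prevalence bin.

    For each record's n_i the marginal pmf over k = 0..n_i is computed and
    k/n_i assigned to the same upper-bound bins as the observed histogram;
    averaging over records gives the expected histogram at the observed
    design (not the raw continuous pdf).
    """
    n_bins = round(1.0 / bin_width)
    out = np.zeros(n_bins)
    _, n_arr = table.counts
    for n_i, mult in zip(*np.unique(n_arr, return_counts=True)):
        ks = np.arange(n_i + 1)
        pmf = marginal_pmf(ks, np.full(n_i + 1, n_i), model)
        idx = np.clip(np.ceil((ks / n_i) / bin_width).astype(int) - 1, 0, n_bins - 1)
        out += mult * np.bincount(idx, weights=pmf, minlength=n_bins)
    return out / len(table)
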