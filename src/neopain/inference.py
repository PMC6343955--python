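"""Developmental statistics: windowed proportions, logit GLMs over age,
paired duration comparison, and Gaussian-process divergence-age estimation.

The centrepiece is a Gaussian-process model of the probability that an
infant responds to a stimulus as a function of gestational age: a
squared-exponential (ARD; one input dimension, so a plain SE) covariance
with characteristic lengthscale 3.5 weeks and signal SD 1, a probit
(error-function) likelihood, and expectation-propagation (EP) inference
with fixed hyperparameters. Fitting one model per stimulus (noxious /
innocuous) and comparing the predictive response probabilities over an age
grid gives, via a Gaussian (delta-method) approximation to the standard
error of each probability, an approximate one-sided p-value per age for
"noxious response probability exceeds innocuous". The *divergence age* at
level alpha is the earliest grid age after which that p-value stays below
alpha. These p-values are descriptive model summaries, not independent
tests.

Proportions over age use 2-week windows stepping by 1 week from 28 weeks,
half-open ``[a, a+2)``, each required to contain at least 12 infants
(under-full windows are merged forward). The paired facial-duration
comparison uses the Wilcoxon signed-rank test (exact null distribution for
n <= 25, normal approximation with tie/zero corrections above) with the
Hodges-Lehmann estimate (median of Walsh averages) and its distribution-free
confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .maturity import GLMResult, _binary_logit_fit

__all__ = [
    "AgeWindowProportion",
    "GPConfig",
    "DivergenceProfile",
    "PairedDurationResult",
    "EPConvergenceError",
    "windowed_proportions",
    "glm_age_trend",
    "GaussianProcessProbit",
    "gp_fit",
    "divergence_profile",
    "paired_duration_test",
    "signed_rank_null_pmf",
]


# ---------------------------------------------------------------------------
# Windowed proportions and GLM age trend.

@dataclass
class AgeWindowProportion:
    """Responder proportion in one (possibly merged) age window [lo, hi)."""

    window: tuple[float, float]
    n: int
    k: int
    merged: bool = False

    @property
    def proportion(self) -> float:
        return self.k / self.n

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.window[0] + self.window[1])


def windowed_proportions(
    ages,
    responded,
    width: float = 2.0,
    step: float = 1.0,
    start: float = 28.0,
    min_n: int = 12,
) -> list[AgeWindowProportion]:
    """Responder proportions in overlapping half-open age windows.

    Windows are ``[a, a+width)`` for a = start, start+step, ...; a window
    holding fewer than ``min_n`` infants is merged forward (its end extended
    by ``step`` at a time) until it reaches ``min_n``. Trailing windows that
    cannot reach ``min_n`` even after extension are dropped.
    """
    ages = np.asarray(ages, dtype=float)
    responded = np.asarray(responded, dtype=bool)
    if ages.size == 0:
        raise ValueError("empty cohort")
    if ages.size != responded.size:
        raise ValueError("ages and responses must be paired")
    max_age = ages.max()
    out: list[AgeWindowProportion] = []
    a = start
    while a <= max_age:
        hi = a + width
        merged = False
        while True:
            mask = (ages >= a) & (ages < hi)
            n = int(mask.sum())
            if n >= min_n or hi > max_age:
                break
            hi += step
            merged = True
        if n >= min_n:
            out.append(
                AgeWindowProportion(
                    window=(a, hi), n=n, k=int(responded[mask].sum()), merged=merged
                )
            )
            if merged:
                warnings.warn(
                    f"window starting at {a} merged forward to [{a}, {hi}) to "
                    f"reach n >= {min_n}",
                    stacklevel=2,
                )
        a += step
    return out


def glm_age_trend(windows: list[AgeWindowProportion]) -> GLMResult:
    """Binomial logit GLM of windowed counts against window-midpoint age.

    Overlapping windows induce correlated observations; as in the source
    analysis this is ignored in fitting (the slope is descriptive).
    """
    import statsmodels.api as sm

    if len(windows) < 3:
        raise ValueError("need at least 3 windows for an age trend")
    mid = np.array([w.midpoint for w in windows])
    counts = np.array([[w.k, w.n - w.k] for w in windows], dtype=float)
    X = sm.add_constant(mid)
    fit = sm.GLM(counts, X, family=sm.families.Binomial()).fit()
    ci = fit.conf_int()
    separation = bool(np.abs(fit.params).max() > 1e2)
    return GLMResult(
        slope=float(fit.params[1]),
        ci=(float(ci[1][0]), float(ci[1][1])),
        pvalue=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        separation=separation,
    )


def glm_binary_trend(x, y) -> GLMResult:
    """Per-observation Bernoulli logit GLM (used for per-infant responses)."""
    return _binary_logit_fit(np.asarray(x, float), np.asarray(y, float))


# ---------------------------------------------------------------------------
# Gaussian-process probit model with expectation propagation.

class EPConvergenceError(RuntimeError):
    """EP failed to converge even after a damped retry."""


@dataclass
class GPConfig:
    """Hyperparameters of the age-response GP (fixed, not optimised)."""

    lengthscale: float = 3.5  # weeks
    signal_sd: float = 1.0
    jitter: float = 1e-8
    max_sweeps: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lengthscale <= 0 or self.signal_sd <= 0:
            raise ValueError("lengthscale and signal_sd must be positive")


class GaussianProcessProbit(BaseEstimator):
    """GP binary-response model: SE kernel, probit likelihood, EP inference.

    The latent response propensity f(age) has a zero-mean GP prior with
    covariance ``signal_sd^2 * exp(-(a-a')^2 / (2*lengthscale^2))``; a
    response y in {-1, +1} has likelihood ``Phi(y * f)``. EP approximates
    the posterior with Gaussian site terms, iterated until the largest
    site-parameter change falls below ``tol`` or ``max_sweeps`` is reached;
    on non-convergence one damped retry (damping 0.5) is made before a hard
    error. Hyperparameters are fixed (no marginal-likelihood optimisation).

    Fitted attributes: ``X_``, ``y_`` (coded +/-1), ``tau_site_``,
    ``nu_site_``, ``n_sweeps_``, ``converged_``, ``damping_used_``.

    The predictive response probability is
    ``p(a) = Phi( mu*(a) / sqrt(1 + v*(a)) )`` with (mu*, v*) the latent
    predictive mean and variance; with no training data this is the prior
    predictive 0.5 everywhere.
    """

    def __init__(
        self,
        lengthscale: float = 3.5,
        signal_sd: float = 1.0,
        jitter: float = 1e-8,
        max_sweeps: int = 100,
        tol: float = 1e-6,
    ):
        self.lengthscale = lengthscale
        self.signal_sd = signal_sd
        self.jitter = jitter
        self.max_sweeps = max_sweeps
        self.tol = tol

    # -- kernel ------------------------------------------------------------
    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        d = A[:, None] - B[None, :]
        return self.signal_sd**2 * np.exp(-(d**2) / (2.0 * self.lengthscale**2))

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("ages must be a 1-D array (or column vector)")
        return X

    # -- EP ----------------------------------------------------------------
    def _ep_sweeps(self, K: np.ndarray, y: np.ndarray, damping: float):
        n = y.size
        tau = np.zeros(n)
        nu = np.zeros(n)
        Sigma = K.copy()
        mu = np.zeros(n)
        for sweep in range(self.max_sweeps):
            max_delta = 0.0
            for i in range(n):
                tau_cav = 1.0 / Sigma[i, i] - tau[i]
                nu_cav = mu[i] / Sigma[i, i] - nu[i]
                if tau_cav <= 0:
                    continue  # pathological cavity; skip this site this sweep
                mu_cav = nu_cav / tau_cav
                s2_cav = 1.0 / tau_cav
                denom = np.sqrt(1.0 + s2_cav)
                z = y[i] * mu_cav / denom
                ratio = np.exp(norm.logpdf(z) - norm.logcdf(z))
                mu_hat = mu_cav + y[i] * s2_cav * ratio / denom
                s2_hat = s2_cav - s2_cav**2 * ratio * (z + ratio) / (1.0 + s2_cav)
                if s2_hat <= 0:
                    continue
                dtau = (1.0 / s2_hat - tau_cav) - tau[i]
                dnu = (mu_hat / s2_hat - nu_cav) - nu[i]
                dtau *= damping
                dnu *= damping
                max_delta = max(max_delta, abs(dtau), abs(dnu))
                tau[i] += dtau
                nu[i] += dnu
                # rank-1 posterior update
                si = Sigma[:, i]
                Sigma -= (dtau / (1.0 + dtau * Sigma[i, i])) * np.outer(si, si)
                mu = Sigma @ nu
            # stable recompute of (K^-1 + diag(tau))^-1 from scratch
            Sigma, mu, _L = self._posterior_from_sites(K, tau, nu)
            if max_delta < self.tol:
                return tau, nu, sweep + 1, True
        return tau, nu, self.max_sweeps, False

    def _posterior_from_sites(self, K, tau, nu):
        n = tau.size
        srt = np.sqrt(np.maximum(tau, 0.0))
        B = np.eye(n) + (srt[:, None] * K) * srt[None, :]
        L = np.linalg.cholesky(B)
        V = np.linalg.solve(L, srt[:, None] * K)
        Sigma = K - V.T @ V
        mu = Sigma @ nu
        return Sigma, mu, L

    def fit(self, X, y):
        """Fit to per-infant ages X and binary responses y ({0,1} or {-1,+1})."""
        X = self._as_1d(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.size != y.size:
            raise ValueError("X and y must have the same length")
        y = np.where(y > 0, 1.0, -1.0) if y.size else y
        self.X_ = X
        self.y_ = y
        n = X.size
        if n == 0:
            self.tau_site_ = np.zeros(0)
            self.nu_site_ = np.zeros(0)
            self.n_sweeps_ = 0
            self.converged_ = True
            self.damping_used_ = 1.0
            return self
        K = self._kernel(X, X) + self.jitter * np.eye(n)
        tau, nu, sweeps, ok = self._ep_sweeps(K, y, damping=1.0)
        damping = 1.0
        if not ok:
            warnings.warn(
                "EP did not converge undamped; retrying with damping 0.5",
                stacklevel=2,
            )
            tau, nu, sweeps, ok = self._ep_sweeps(K, y, damping=0.5)
            damping = 0.5
            if not ok:
                raise EPConvergenceError(
                    f"EP failed to converge in {self.max_sweeps} sweeps even "
                    "with damping 0.5"
                )
        self.K_ = K
        self.tau_site_ = tau
        self.nu_site_ = nu
        self.n_sweeps_ = sweeps
        self.converged_ = ok
        self.damping_used_ = damping
        return self

    def predict_latent(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and variance of the latent propensity at ages X."""
        check_is_fitted(self, "X_")
        Xs = self._as_1d(X)
        kss = np.full(Xs.size, self.signal_sd**2)
        if self.X_.size == 0:
            return np.zeros(Xs.size), kss
        Ks = self._kernel(self.X_, Xs)  # (n, m)
        srt = np.sqrt(np.maximum(self.tau_site_, 0.0))
        n = self.X_.size
        B = np.eye(n) + (srt[:, None] * self.K_) * srt[None, :]
        L = np.linalg.cholesky(B)
        # mu* = k*^T (nu - sqrt(tau) B^-1 sqrt(tau) K nu)
        z = srt * np.linalg.solve(
            L.T, np.linalg.solve(L, srt * (self.K_ @ self.nu_site_))
        )
        mu_star = Ks.T @ (self.nu_site_ - z)
        v = np.linalg.solve(L, srt[:, None] * Ks)
        var_star = kss - np.sum(v**2, axis=0)
        return mu_star, np.maximum(var_star, 0.0)

    def response_probability(self, X) -> np.ndarray:
        """P(response | age) on the probability scale."""
        mu, var = self.predict_latent(X)
        return norm.cdf(mu / np.sqrt(1.0 + var))

    def response_probability_sd(self, X) -> np.ndarray:
        """Delta-method SD of the predictive response probability.

        With z = mu*/sqrt(1+v*), the latent-mean uncertainty sqrt(v*)
        propagates to the probability scale as phi(z) * sqrt(v*/(1+v*)).
        """
        mu, var = self.predict_latent(X)
        z = mu / np.sqrt(1.0 + var)
        return norm.pdf(z) * np.sqrt(var / (1.0 + var))

    def predict_proba(self, X) -> np.ndarray:
        p = self.response_probability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.response_probability(X) >= 0.5).astype(int)


def gp_fit(ages, responses, config: GPConfig | None = None) -> GaussianProcessProbit:
    """Fit the probit GP to per-infant binary responses."""
    cfg = config or GPConfig()
    model = GaussianProcessProbit(
        lengthscale=cfg.lengthscale,
        signal_sd=cfg.signal_sd,
        jitter=cfg.jitter,
        max_sweeps=cfg.max_sweeps,
        tol=cfg.tol,
    )
    return model.fit(ages, responses)


# ---------------------------------------------------------------------------
# Divergence of the two stimulus models.

@dataclass
class DivergenceProfile:
    """Per-age approximate p-values for (p_nox > p_innoc) and divergence ages."""

    ages: np.ndarray
    pvalues: np.ndarray
    divergence_age: dict[float, float | None] = field(default_factory=dict)

    def age_at(self, confidence: float) -> float | None:
        """Divergence age at e.g. confidence 0.95 (i.e. alpha = 0.05)."""
        return self.divergence_age[round(1.0 - confidence, 10)]


def default_age_grid(start: float = 28.0, stop: float = 41.0, step: float = 0.1):
    return np.round(np.arange(start, stop + step / 2, step), 10)


def divergence_profile(
    model_nox: GaussianProcessProbit,
    model_innoc: GaussianProcessProbit,
    grid=None,
    alphas: tuple[float, ...] = (0.05, 0.01),
) -> DivergenceProfile:
    """Approximate p-values for the divergence of the two response curves.

    At each grid age the two predictive response probabilities are treated
    as independent Gaussians (mean = predictive probability, SD by the
    delta method from the latent predictive variance); the one-sided
    p-value for the null "p_nox <= p_innoc" is ``Phi(-(d)/sd(d))`` with d
    the difference of means. The divergence age at level alpha is the
    earliest grid age after which the p-value stays below alpha (None if it
    never does).
    """
    grid = default_age_grid() if grid is None else np.asarray(grid, dtype=float)
    p1 = model_nox.response_probability(grid)
    s1 = model_nox.response_probability_sd(grid)
    p2 = model_innoc.response_probability(grid)
    s2 = model_innoc.response_probability_sd(grid)
    d = p1 - p2
    sd = np.sqrt(s1**2 + s2**2)
    pvals = np.where(sd > 0, norm.cdf(-d / np.where(sd > 0, sd, 1.0)), np.where(d > 0, 0.0, np.where(d < 0, 1.0, 0.5)))
    div: dict[float, float | None] = {}
    for alpha in alphas:
        below = pvals < alpha
        # earliest age from which every later grid point is below alpha
        age = None
        for i in range(below.size - 1, -1, -1):
            if not below[i]:
                break
            age = float(grid[i])
        div[round(alpha, 10)] = age
    return DivergenceProfile(ages=grid, pvalues=pvals, divergence_age=div)


# ---------------------------------------------------------------------------
# Wilcoxon signed rank + Hodges-Lehmann.

@dataclass
class PairedDurationResult:
    """Paired comparison of facial-response durations (noxious - innocuous)."""

    median_difference: float  # Hodges-Lehmann estimate, seconds
    ci: tuple[float, float]
    pvalue: float
    n_pairs: int
    statistic: float  # W+ (sum of positive midranks)
    method: str


def signed_rank_null_pmf(n: int) -> np.ndarray:
    """Exact null pmf of W+ for n untied pairs (support 0..n(n+1)/2)."""
    total = n * (n + 1) // 2
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in range(1, n + 1):
        nxt = pmf.copy()
        nxt[r:] += pmf[:-r] if r > 0 else 0
        pmf = nxt
    return pmf / 2.0**n


def _exact_midrank_cdf(ranks2: np.ndarray):
    """DP over doubled midranks: returns pmf over W2+ = sum of doubled ranks."""
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = pmf.copy()
        nxt[r:] += pmf[: pmf.size - r]
        pmf = nxt
    return pmf / 2.0 ** len(ranks2)


def _midranks(absd: np.ndarray) -> np.ndarray:
    order = np.argsort(absd, kind="mergesort")
    ranks = np.empty(absd.size, dtype=float)
    sorted_abs = absd[order]
    i = 0
    while i < absd.size:
        j = i
        while j + 1 < absd.size and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def paired_duration_test(
    durations_nox,
    durations_innoc,
    alpha: float = 0.05,
    exact_max_n: int = 25,
) -> PairedDurationResult:
    """Wilcoxon signed-rank test with Hodges-Lehmann estimate and CI.

    Zero differences are discarded for the test (standard Wilcoxon
    convention); midranks handle ties. For n (non-zero pairs) <=
    ``exact_max_n`` the two-sided p-value comes from the exact null
    distribution (dynamic programming over doubled midranks); above it a
    normal approximation with tie correction and continuity correction is
    used. The HL estimate is the median of the n(n+1)/2 Walsh averages of
    all paired differences; its distribution-free CI uses the exact (or
    normal-approximate) signed-rank critical value.
    """
    x = np.asarray(durations_nox, dtype=float)
    y = np.asarray(durations_innoc, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size == 0:
        raise ValueError("no pairs")
    d = x - y
    n_all = d.size

    # Walsh averages over all differences (zeros included) for HL + CI.
    walsh = np.sort([(d[i] + d[j]) / 2.0 for i in range(n_all) for j in range(i, n_all)])
    hl = float(np.median(walsh))

    dz = d[d != 0]
    n = dz.size
    if n == 0:
        return PairedDurationResult(
            median_difference=hl, ci=(0.0, 0.0), pvalue=1.0, n_pairs=n_all,
            statistic=0.0, method="degenerate (all differences zero)",
        )

    ranks = _midranks(np.abs(dz))
    w_plus = float(ranks[dz > 0].sum())

    if n <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(int)
        pmf = _exact_midrank_cdf(ranks2)
        w2 = int(round(2 * w_plus))
        p_le = float(pmf[: w2 + 1].sum())
        p_ge = float(pmf[w2:].sum())
        pvalue = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        tie_counts = np.unique(np.abs(dz), return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        zstat = (w_plus - mu - np.sign(w_plus - mu) * 0.5) / np.sqrt(var)
        pvalue = float(2 * norm.sf(abs(zstat)))
        method = "normal approximation"

    # Distribution-free CI for the HL estimate from the untied null.
    M = walsh.size
    n_ci = n_all
    if n_ci <= 50:
        pmf0 = signed_rank_null_pmf(n_ci)
        cdf0 = np.cumsum(pmf0)
        c_arr = np.flatnonzero(cdf0 <= alpha / 2.0)
        c = int(c_arr[-1]) if c_arr.size else -1
    else:
        mu0 = n_ci * (n_ci + 1) / 4.0
        sd0 = np.sqrt(n_ci * (n_ci + 1) * (2 * n_ci + 1) / 24.0)
        c = int(np.floor(mu0 - norm.ppf(1 - alpha / 2.0) * sd0 - 0.5))
    # CI endpoints A_(c+1) and A_(M-c), 1-indexed Walsh order statistics.
    lo = walsh[c] if 0 <= c < M else walsh[0]
    hi = walsh[M - 1 - c] if 0 <= M - 1 - c < M else walsh[-1]
    return PairedDurationResult(
        median_difference=hl,
        ci=(float(lo), float(hi)),
        pvalue=pvalue,
        n_pairs=n_all,
        statistic=w_plus,
        method=method,
    )
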