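"""Maximum-likelihood probit dose-response fitting and LC estimation.

The model is P(death) = Phi(alpha + beta * log10 dose) with a grouped
binomial likelihood, fitted by Fisher scoring (IRLS).  Confidence limits for
LC quantiles use Fieller's theorem, falling back to the delta method when
the Fieller g-statistic reaches 1.  Overdispersion inflates the covariance
by the Pearson heterogeneity factor (chi-square / df) when it exceeds 1, in
which case the critical value switches from the normal to the t
distribution, following classic bioassay-package behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "DoseResponseDataset",
    "ProbitFit",
    "NonConvergenceError",
    "abbott_correct",
    "fit_probit",
    "lc_quantile",
]


class NonConvergenceError(RuntimeError):
    """Probit fit failed to converge (degenerate or separated data)."""


@dataclass(frozen=True)
class DoseResponseDataset:
    """Grouped mortality counts; ``groups`` holds (dose, n_exposed, n_dead).

    The optional control group (dose 0) is kept separately and only used
    for Abbott correction.
    """

    groups: tuple[tuple[float, float, float], ...]
    control: tuple[float, float] | None = None  # (n_exposed, n_dead)

    def __post_init__(self):
        doses = [g[0] for g in self.groups]
        if any(d <= 0 for d in doses):
            raise ValueError("doses must be strictly positive")
        if len(set(doses)) < 2:
            raise ValueError("need at least 2 distinct positive doses")
        for d, n, y in self.groups:
            if not 0 <= y <= n:
                raise ValueError(f"invalid counts at dose {d}: {y}/{n}")

    @property
    def control_mortality(self) -> float:
        if self.control is None:
            return 0.0
        n, y = self.control
        return y / n


def abbott_correct(ds: DoseResponseDataset) -> DoseResponseDataset:
    """Rescale treated mortalities by control mortality: (p - c)/(1 - c).

    Corrected kills may be fractional; the binomial likelihood treats them
    as effective counts.  No-op when control mortality is zero.
    """
    c = ds.control_mortality
    if c >= 1.0:
        raise ValueError("control mortality of 1 leaves no information")
    if c == 0.0:
        return ds
    groups = []
    for d, n, y in ds.groups:
        p = y / n
        p_corr = min(max((p - c) / (1.0 - c), 0.0), 1.0)
        groups.append((d, n, p_corr * n))
    return replace(ds, groups=tuple(groups))


@dataclass(frozen=True)
class ProbitFit:
    alpha: float
    beta: float
    lc50: float
    lc50_ci: tuple[float, float]
    loglik: float
    converged: bool
    cov: np.ndarray = field(repr=False)
    heterogeneity: float = 1.0
    ci_method: str = "fieller"
    n_groups: int = 0
    warnings: tuple[str, ...] = ()


def _start_values(x: np.ndarray, n: np.ndarray, y: np.ndarray):
    """Least-squares line through empirical probits of non-extreme groups."""
    p = y / n
    keep = (p > 0) & (p < 1)
    if keep.sum() >= 2:
        probits = stats.norm.ppf(p[keep])
        beta, alpha = np.polyfit(x[keep], probits, 1)
        if beta > 0:
            return alpha, beta
    # fallback: unit slope through the midpoint
    return -np.median(x), 1.0


def fit_probit(ds: DoseResponseDataset, max_iter: int = 100,
               tol: float = 1e-8, level: float = 0.95) -> ProbitFit:
    """Fit the two-parameter probit model by Fisher scoring."""
    x = np.log10([g[0] for g in ds.groups])
    n = np.array([g[1] for g in ds.groups], dtype=float)
    y = np.array([g[2] for g in ds.groups], dtype=float)

    if y.sum() == 0 or (n - y).sum() == 0:
        raise NonConvergenceError(
            "all-extreme response (0% or 100% mortality everywhere)")

    alpha, beta = _start_values(x, n, y)
    X = np.column_stack([np.ones_like(x), x])
    converged = False
    for _ in range(max_iter):
        eta = alpha + beta * x
        p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
        phi = stats.norm.pdf(eta)
        w = n * phi**2 / (p * (1 - p))
        grad = X.T @ ((y - n * p) * phi / (p * (1 - p)))
        if not np.all(np.isfinite(grad)):
            raise NonConvergenceError("non-finite gradient (separation?)")
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        info = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise NonConvergenceError("singular information matrix") from exc
        alpha += step[0]
        beta += step[1]
        if abs(beta) > 1e3 or abs(alpha) > 1e6:
            raise NonConvergenceError("diverging estimates (separation?)")

    if not converged and np.linalg.norm(grad) > 1e-4:
        raise NonConvergenceError(
            f"no convergence in {max_iter} iterations (|grad|="
            f"{np.linalg.norm(grad):.2e})")

    warnings_ = ()
    if beta <= 0:
        warnings_ += ("non-positive slope: monotone dose-response violated",)

    eta = alpha + beta * x
    p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
    phi = stats.norm.pdf(eta)
    w = n * phi**2 / (p * (1 - p))
    info = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(info)

    # heterogeneity factor (Pearson chi2 / df) inflates the covariance
    df = len(x) - 2
    het = 1.0
    crit_dist: stats.rv_continuous | object = stats.norm
    if df > 0:
        chi2 = float(((y - n * p) ** 2 / (n * p * (1 - p))).sum())
        if chi2 / df > 1.0:
            het = chi2 / df
            cov = cov * het
            crit_dist = stats.t(df)

    loglik = float((y * np.log(p) + (n - y) * np.log(1 - p)).sum())
    crit = float(crit_dist.ppf(0.5 + level / 2.0))

    m, (lo, hi), method = _ratio_ci(alpha, beta, cov, 0.0, crit)
    fit = ProbitFit(
        alpha=float(alpha), beta=float(beta),
        lc50=10.0 ** m, lc50_ci=(10.0 ** lo, 10.0 ** hi),
        loglik=loglik, converged=True, cov=cov, heterogeneity=het,
        ci_method=method, n_groups=len(x), warnings=warnings_,
    )
    return fit


def _ratio_ci(alpha: float, beta: float, cov: np.ndarray,
              probit_target: float, crit: float):
    """Fieller interval for m = (probit_target - alpha)/beta on log10 dose."""
    a = probit_target - alpha  # m = a / beta
    m = a / beta
    v11, v12, v22 = cov[0, 0], cov[0, 1], cov[1, 1]
    cov_ab = -v12  # Cov(target - alpha, beta)
    g = crit**2 * v22 / beta**2
    if g < 1.0:
        # roots of (a - m*beta)^2 = crit^2 * Var(a - m*beta)
        qa = beta**2 - crit**2 * v22
        qb = a * beta - crit**2 * cov_ab
        qc = a * a - crit**2 * v11
        disc = qb * qb - qa * qc
        if disc >= 0:
            lo = (qb - math.sqrt(disc)) / qa
            hi = (qb + math.sqrt(disc)) / qa
            return m, (min(lo, hi), max(lo, hi)), "fieller"
    # delta-method fallback (flagged by method name)
    var_m = (v11 + 2 * m * v12 + m * m * v22) / beta**2
    half = crit * math.sqrt(max(var_m, 0.0))
    return m, (m - half, m + half), "delta"


def lc_quantile(fit: ProbitFit, p: float, level: float = 0.95):
    """Concentration killing fraction ``p`` with its confidence interval."""
    if not 0.0 < p < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    crit = float(stats.norm.ppf(0.5 + level / 2.0))
    if fit.heterogeneity > 1.0 and fit.n_groups > 2:
        crit = float(stats.t(fit.n_groups - 2).ppf(0.5 + level / 2.0))
    target = float(stats.norm.ppf(p))
    m, (lo, hi), method = _ratio_ci(fit.alpha, fit.beta, fit.cov, target, crit)
    return 10.0 ** m, (10.0 ** lo, 10.0 ** hi), method
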