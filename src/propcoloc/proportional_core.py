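"""Fieller-statistic proportionality test, theta-posterior, and ppp.

Under a shared causal variant the two traits' joint regression coefficients
are proportional, ``beta1 = beta2 / eta``.  The Fieller chi-squared statistic

    T(eta)^2 = u' V^{-1} u,   u = b1 - b2/eta,   V = V1 + V2/eta^2

is computed here in the angular parametrisation ``theta = atan(eta)``:

    u(theta) = b1 sin(theta) - b2 cos(theta)
    V(theta) = V1 sin^2(theta) + V2 cos^2(theta)

which is algebraically identical (multiply u by sin(theta)) but finite at
eta = 0 and eta = +/-inf.  Two inferential routes are provided:

* a profile test — minimise T(theta)^2 over theta, refer the minimum to
  chi-squared on q-1 degrees of freedom; and
* a posterior predictive p-value — average the chi-squared(q) tail p-value
  of T(theta)^2 over the posterior of theta given (b1, b2), obtained by
  analytically marginalising the common coefficient vector beta under a flat
  prior.  The prior on theta is induced by a Cauchy(0, k) prior on eta,
  uniform when k = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from propcoloc.association import RegressionFit

logger = logging.getLogger(__name__)

DEFAULT_N_GRID = 1001
_COND_LIMIT = 1e12


class NumericalError(RuntimeError):
    pass


@dataclass
class ThetaPosterior:
    """Posterior density of theta = atan(eta) on a grid spanning (-pi/2, pi/2].

    The density is normalised to integrate to one by the trapezoid rule;
    ``prior_scale`` is the Cauchy scale k of the prior on eta (k = 1 implies
    a uniform prior on theta).
    """

    grid: np.ndarray
    density: np.ndarray
    prior_scale: float = 1.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("negative posterior density")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("theta grid must be strictly increasing")

    @property
    def mode(self) -> float:
        return float(self.grid[np.argmax(self.density)])


@dataclass
class PropTestResult:
    """Full output of one proportionality test."""

    eta_hat: float
    stat: float
    df: int
    p_profile: float
    ppp: float
    posterior: ThetaPosterior
    eta_ci: tuple
    ci_level: float
    contains_zero: bool
    contains_one: bool
    n_components: int = None
    extra: dict = None

    def to_record(self) -> dict:
        """Flat key-value record for serialisation."""
        rec = {
            "stat": self.stat,
            "df": self.df,
            "p_profile": self.p_profile,
            "ppp": self.ppp,
            "eta_hat": self.eta_hat,
            "ci_level": self.ci_level,
            "ci_low": self.eta_ci[0],
            "ci_high": self.eta_ci[1],
            "ci_contains_zero": int(self.contains_zero),
            "ci_contains_one": int(self.contains_one),
            "n_grid": len(self.posterior.grid),
            "prior_scale": self.posterior.prior_scale,
        }
        if self.n_components is not None:
            rec["n_components"] = self.n_components
        return rec


def make_theta_grid(n_grid: int = DEFAULT_N_GRID) -> np.ndarray:
    """Equally spaced theta values on the closed interval [-pi/2, pi/2].

    The statistic and the posterior are pi-periodic and the two endpoints
    describe the same model (eta = -inf and +inf), so the closed grid covers
    exactly one full period and trapezoid quadrature over it is the periodic
    quadrature rule.
    """
    return np.linspace(-np.pi / 2, np.pi / 2, n_grid)


def _as_arrays(b1, V1, b2, V2):
    b1 = np.atleast_1d(np.asarray(b1, float))
    b2 = np.atleast_1d(np.asarray(b2, float))
    V1 = np.atleast_2d(np.asarray(V1, float))
    V2 = np.atleast_2d(np.asarray(V2, float))
    q = b1.shape[0]
    if b2.shape[0] != q or V1.shape != (q, q) or V2.shape != (q, q):
        raise ValueError("dimension mismatch between coefficient systems")
    return b1, V1, b2, V2


def fieller_stat(b1, V1, b2, V2, theta) -> float:
    """T(theta)^2 = u(theta)' V(theta)^{-1} u(theta); scalar or vectorised.

    Accepts a scalar theta or an array; returns matching shape.
    """
    b1, V1, b2, V2 = _as_arrays(b1, V1, b2, V2)
    th = np.atleast_1d(np.asarray(theta, float))
    s, c = np.sin(th), np.cos(th)
    u = np.outer(s, b1) - np.outer(c, b2)                  # (m, q)
    Vt = (s ** 2)[:, None, None] * V1 + (c ** 2)[:, None, None] * V2
    try:
        x = np.linalg.solve(Vt, u[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        conds = [np.linalg.cond(Vt[i]) for i in range(len(th))]
        raise NumericalError(
            f"singular V(theta); condition numbers up to {max(conds):.3e}"
        ) from exc
    out = np.einsum("ij,ij->i", u, x)
    out = np.maximum(out, 0.0)
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(out[0])
    return out


def _check_pair(f1: RegressionFit, f2: RegressionFit):
    if list(f1.snp_or_component_ids) != list(f2.snp_or_component_ids):
        raise ValueError("the two fits must cover identical regressors in "
                         "identical order")
    return f1.q


def profile_test(f1: RegressionFit, f2: RegressionFit,
                 n_grid: int = DEFAULT_N_GRID):
    """Profile-likelihood proportionality test.

    The statistic T(theta)^2 is minimised over a coarse grid on
    (-pi/2, pi/2] and refined by bounded scalar minimisation to tolerance
    1e-8; the minimum is referred to chi-squared on q-1 degrees of freedom.

    Returns
    -------
    (eta_hat, stat, p_profile)
    """
    q = _check_pair(f1, f2)
    if q == 1:
        logger.warning("profile test undefined for q=1 (statistic identically "
                       "0 at eta_hat); returning p=1")
        eta = (f2.b[0] / f1.b[0]) if f1.b[0] != 0 else np.inf
        return float(eta), 0.0, 1.0
    grid = make_theta_grid(n_grid)
    vals = fieller_stat(f1.b, f1.V, f2.b, f2.V, grid)
    i = int(np.argmin(vals))
    step = np.pi / (n_grid - 1)
    lo, hi = grid[i] - step, grid[i] + step
    res = optimize.minimize_scalar(
        lambda t: fieller_stat(f1.b, f1.V, f2.b, f2.V, t),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    theta_hat, stat = (res.x, res.fun) if res.fun <= vals[i] else (grid[i], vals[i])
    theta_hat = float(theta_hat)
    stat = float(stat)
    p = float(stats.chi2.sf(stat, q - 1))
    return float(np.tan(theta_hat)), stat, p


def _theta_prior_log(grid: np.ndarray, k: float) -> np.ndarray:
    # Cauchy(0, k) on tan(theta) => p(theta) propto k / (k^2 cos^2 + sin^2)
    return np.log(k) - np.log(k ** 2 * np.cos(grid) ** 2 + np.sin(grid) ** 2)


def theta_posterior(f1: RegressionFit, f2: RegressionFit,
                    prior_scale: float = 1.0,
                    n_grid: int = DEFAULT_N_GRID) -> ThetaPosterior:
    """Posterior of theta with the common coefficient beta marginalised.

    The stacked estimate (b1; b2) is Gaussian with mean
    (beta cos(theta); beta sin(theta)) and block covariance diag(V1, V2);
    integrating beta against a flat (improper) prior gives, up to a constant,

        log m(theta) = -1/2 log det A(theta) + 1/2 m' A^{-1} m
        A = cos^2 V1^{-1} + sin^2 V2^{-1},
        m = cos V1^{-1} b1 + sin V2^{-1} b2.

    The result is multiplied by the theta prior induced by Cauchy(0, k) on
    eta and normalised by the trapezoid rule.
    """
    _check_pair(f1, f2)
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    grid = make_theta_grid(n_grid)
    V1i = np.linalg.inv(f1.V)
    V2i = np.linalg.inv(f2.V)
    c, s = np.cos(grid), np.sin(grid)
    A = (c ** 2)[:, None, None] * V1i + (s ** 2)[:, None, None] * V2i
    m = np.outer(c, V1i @ f1.b) + np.outer(s, V2i @ f2.b)
    sign, logdet = np.linalg.slogdet(A)
    if np.any(sign <= 0):
        raise NumericalError("non-positive-definite precision in beta "
                             "marginalisation")
    x = np.linalg.solve(A, m[..., None])[..., 0]
    quad = np.einsum("ij,ij->i", m, x)
    logpost = -0.5 * logdet + 0.5 * quad + _theta_prior_log(grid, prior_scale)
    if not np.all(np.isfinite(logpost)):
        raise NumericalError("non-finite marginal likelihood on theta grid")
    dens = np.exp(logpost - logpost.max())
    z = np.trapezoid(dens, grid)
    return ThetaPosterior(grid=grid, density=dens / z, prior_scale=prior_scale)


def ppp_value(posterior: ThetaPosterior, f1: RegressionFit,
              f2: RegressionFit) -> float:
    """Posterior predictive p-value: E_theta[ chi2_q tail of T(theta)^2 ].

    If theta were known, T(theta)^2 would be chi-squared on q degrees of
    freedom; the tail p-value T*(theta) is averaged over the posterior of
    theta by trapezoid quadrature.
    """
    q = _check_pair(f1, f2)
    stat = fieller_stat(f1.b, f1.V, f2.b, f2.V, posterior.grid)
    tstar = stats.chi2.sf(stat, q)
    val = np.trapezoid(tstar * posterior.density, posterior.grid)
    return float(np.clip(val, 0.0, 1.0))


def _recentred(posterior: ThetaPosterior):
    """Roll the periodic grid so the posterior mode sits centrally.

    The closed grid's duplicate endpoint is dropped before rolling and the
    period is re-closed afterwards, so the returned grid again spans one
    full period around the mode.
    """
    g, d = posterior.grid[:-1], posterior.density[:-1]
    n = len(g)
    i = int(np.argmax(d))
    shift = n // 2 - i
    g2 = np.roll(g, shift).copy()
    d2 = np.roll(d, shift).copy()
    if shift > 0:
        g2[:shift] -= np.pi
    elif shift < 0:
        g2[shift:] += np.pi
    g2 = np.append(g2, g2[0] + np.pi)
    d2 = np.append(d2, d2[0])
    return g2, d2


def eta_credible_interval(posterior: ThetaPosterior, level: float = 0.95):
    """Central credible interval for eta via quantiles of theta.

    The periodic theta grid is recentred on the posterior mode before taking
    the cumulative-distribution quantiles at (1-level)/2 and 1-(1-level)/2,
    which are then mapped through tan.  Flags report whether eta = 0 and
    eta = 1 fall inside the interval (checked on the theta scale, so an
    interval straddling +/-pi/2 is handled correctly; in that case the
    reported numeric bounds wrap through infinity).

    Returns
    -------
    (lower, upper, contains_zero, contains_one)
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    g, d = _recentred(posterior)
    cum = np.concatenate([[0.0], np.cumsum(np.diff(g) * (d[:-1] + d[1:]) / 2)])
    cum /= cum[-1]
    alpha = (1 - level) / 2
    theta_lo = float(np.interp(alpha, cum, g))
    theta_hi = float(np.interp(1 - alpha, cum, g))

    def _inside(target):
        for wrap in (-np.pi, 0.0, np.pi):
            if theta_lo <= target + wrap <= theta_hi:
                return True
        return False

    return (float(np.tan(theta_lo)), float(np.tan(theta_hi)),
            _inside(0.0), _inside(np.pi / 4))


def proportional_test(f1: RegressionFit, f2: RegressionFit,
                      prior_scale: float = 1.0,
                      n_grid: int = DEFAULT_N_GRID,
                      ci_level: float = 0.95) -> PropTestResult:
    """Run the full proportionality pipeline on a pair of fits.

    Combines the profile test, the theta posterior, the posterior predictive
    p-value and the eta credible interval into one result.
    """
    q = _check_pair(f1, f2)
    eta_hat, stat, p_profile = profile_test(f1, f2, n_grid=n_grid)
    post = theta_posterior(f1, f2, prior_scale=prior_scale, n_grid=n_grid)
    ppp = ppp_value(post, f1, f2)
    lo, hi, has0, has1 = eta_credible_interval(post, ci_level)
    return PropTestResult(
        eta_hat=eta_hat,
        stat=stat,
        df=max(q - 1, 0),
        p_profile=p_profile,
        ppp=ppp,
        posterior=post,
        eta_ci=(lo, hi),
        ci_level=ci_level,
        contains_zero=has0,
        contains_one=has1,
    )
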