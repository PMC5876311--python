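"""Box-Cox power exponential (BCPE) and Box-Cox t (BCT) distribution families.

Both families describe a positive response ``y`` through four parameters:

* ``mu``    -- location (> 0), the median of the distribution;
* ``sigma`` -- relative dispersion (> 0, dimensionless);
* ``nu``    -- Box-Cox skew power (any real);
* ``tau``   -- kurtosis shape (> 0): the power-exponential exponent for BCPE,
  the Student-t degrees of freedom for BCT.

The Box-Cox transform maps ``y`` to a standardized deviate ``z``:

    z = ((y/mu)**nu - 1) / (nu * sigma)      (nu != 0)
    z = ln(y/mu) / sigma                     (nu == 0)

``z`` then follows a standardized kernel: for BCPE a power-exponential
standardized to unit variance (so ``tau = 2`` is exactly standard normal),
for BCT an unscaled Student t with ``tau`` degrees of freedom.  The positive
support truncation (``y > 0``) is ignored for quantiles/CDF/z-scores --
negligible whenever ``sigma * |nu|`` is small -- but an exact renormalization
is available for the density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "BCPE",
    "BCT",
    "FamilyParams",
    "CentilePoint",
    "DomainError",
    "TailTruncationError",
    "CentileFitError",
    "boxcox_z",
    "inverse_boxcox_z",
    "quantile",
    "cdf",
    "pdf",
    "zscore",
    "sample",
    "fit_params_to_centiles",
]

BCPE = "BCPE"
BCT = "BCT"

#: below this magnitude nu is treated as zero (log branch) for continuity
_NU_EPS = 1e-5

#: z-score clamp applied when the CDF under/overflows in an extreme tail
_Z_CLAMP = 8.0


class DomainError(ValueError):
    """Raised when an argument is outside the mathematical domain."""


class TailTruncationError(DomainError):
    """Requested quantile lies beyond the y > 0 truncation point.

    Carries the breach deviate ``z_breach = -1 / (sigma * nu)``.
    """

    def __init__(self, message: str, z_breach: float):
        super().__init__(message)
        self.z_breach = z_breach


class CentileFitError(RuntimeError):
    """Inverse centile fit failed; carries the best residual achieved."""

    def __init__(self, message: str, best_residual: float):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class FamilyParams:
    """The four distribution parameters of a BCPE or BCT model at one age."""

    family: str
    mu: float
    sigma: float
    nu: float
    tau: float

    def __post_init__(self):
        if self.family not in (BCPE, BCT):
            raise DomainError(f"unknown family {self.family!r}")
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise DomainError(f"mu must be finite and > 0, got {self.mu}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise DomainError(f"sigma must be finite and > 0, got {self.sigma}")
        if not np.isfinite(self.nu):
            raise DomainError(f"nu must be finite, got {self.nu}")
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise DomainError(f"tau must be finite and > 0, got {self.tau}")


@dataclass(frozen=True)
class CentilePoint:
    """A (centile rank, value) pair, e.g. one cell of a reference table row."""

    p: float
    value: float

    def __post_init__(self):
        if not 0.0 < self.p < 100.0:
            raise DomainError(f"centile rank must lie in (0, 100), got {self.p}")
        if not (np.isfinite(self.value) and self.value > 0):
            raise DomainError(f"value must be finite and > 0, got {self.value}")


# ---------------------------------------------------------------------------
# standardized kernels
# ---------------------------------------------------------------------------

def _pe_scale(tau):
    """gennorm scale that makes the power-exponential kernel unit variance.

    With c = sqrt(2**(-2/tau) * Gamma(1/tau) / Gamma(3/tau)) the GAMLSS
    power-exponential density exp(-0.5*|z/c|**tau) equals scipy's
    ``gennorm(beta=tau, scale=c * 2**(1/tau))``; tau = 2 gives N(0, 1).
    """
    tau = np.asarray(tau, dtype=float)
    log_c = -np.log(2.0) / tau + 0.5 * (
        special.gammaln(1.0 / tau) - special.gammaln(3.0 / tau)
    )
    return np.exp(log_c + np.log(2.0) / tau)


def _kernel(family, tau):
    if family == BCPE:
        return stats.gennorm(beta=tau, scale=_pe_scale(tau))
    return stats.t(df=tau)


def _kernel_cdf(family, tau, z):
    return _kernel(family, tau).cdf(z)

def _kernel_ppf(family, tau, q):
    return _kernel(family, tau).ppf(q)

def _kernel_logpdf(family, tau, z):
    return _kernel(family, tau).logpdf(z)


# ---------------------------------------------------------------------------
# Box-Cox transform and its inverse
# ---------------------------------------------------------------------------

def _validate_y(y):
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)) or np.any(y <= 0):
        raise DomainError("y must be finite and > 0")
    return y


def boxcox_z(y, params: FamilyParams):
    """Standardized Box-Cox deviate of ``y`` under ``params``.

    Strictly increasing in ``y``; maps ``mu`` to 0.  Scalar in, scalar out.
    """
    y = _validate_y(y)
    scalar = y.ndim == 0
    r = y / params.mu
    if abs(params.nu) < _NU_EPS:
        z = np.log(r) / params.sigma
    else:
        z = np.expm1(params.nu * np.log(r)) / (params.nu * params.sigma)
    return float(z) if scalar else z


def inverse_boxcox_z(z, params: FamilyParams):
    """Map a kernel deviate ``z`` back to the response scale (inverse of
    :func:`boxcox_z`).  Raises :class:`TailTruncationError` when the power
    argument ``1 + nu*sigma*z`` is not positive."""
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 0
    nu, sigma, mu = params.nu, params.sigma, params.mu
    if abs(nu) < _NU_EPS:
        y = mu * np.exp(sigma * z)
    else:
        arg = 1.0 + nu * sigma * z
        if np.any(arg <= 0):
            z_breach = -1.0 / (sigma * nu)
            raise TailTruncationError(
                "requested deviate lies beyond the y > 0 truncation point "
                f"z = {z_breach:.6g}",
                z_breach=z_breach,
            )
        y = mu * np.exp(np.log(arg) / nu)
    return float(y) if scalar else y


# truncation point of the kernel deviate implied by y > 0 (None when nu ~ 0)
def _z_truncation(params: FamilyParams):
    if abs(params.nu) < _NU_EPS:
        return None
    return -1.0 / (params.sigma * params.nu)


# ---------------------------------------------------------------------------
# distribution functions
# ---------------------------------------------------------------------------

def quantile(params: FamilyParams, p):
    """Value of the vital sign at centile rank ``p`` (in percent, (0, 100)).

    ``quantile(params, 50) == mu`` exactly for both families.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 100)):
        raise DomainError("centile rank must lie strictly within (0, 100)")
    z = _kernel_ppf(params.family, params.tau, p / 100.0)
    return inverse_boxcox_z(z, params)


def cdf(params: FamilyParams, y):
    """P(Y <= y); the exact inverse of :func:`quantile`."""
    z = boxcox_z(y, params)
    return _kernel_cdf(params.family, params.tau, z)


def pdf(params: FamilyParams, y, *, renormalize: bool = False):
    """Density at ``y``.

    By default the y > 0 truncation constant is omitted (the standard
    centile-construction convention); with ``renormalize=True`` the density
    is divided by the kernel mass on the admissible z-range so that it
    integrates to one over (0, inf).
    """
    y = _validate_y(y)
    scalar = y.ndim == 0
    z = boxcox_z(y, params)
    # |dz/dy| = y**(nu-1) / (mu**nu * sigma)
    log_jac = (
        (params.nu - 1.0) * np.log(y)
        - params.nu * np.log(params.mu)
        - np.log(params.sigma)
    )
    logf = _kernel_logpdf(params.family, params.tau, z) + log_jac
    if renormalize:
        z0 = _z_truncation(params)
        if z0 is not None:
            mass = _kernel_cdf(params.family, params.tau, z0)
            norm = 1.0 - mass if params.nu > 0 else mass
            logf = logf - np.log(norm)
    out = np.exp(logf)
    return float(out) if scalar else out


def zscore(params: FamilyParams, y):
    """Standard-normal equivalent deviate of ``y``: Phi^-1(cdf(y)).

    Extreme-tail CDF under/overflow is clamped at +/- 8 SD with a warning.
    """
    c = np.asarray(cdf(params, y), dtype=float)
    scalar = c.ndim == 0
    z = stats.norm.ppf(c)
    clipped = np.abs(z) > _Z_CLAMP
    if np.any(clipped) or np.any(~np.isfinite(z)):
        warnings.warn(
            f"z-score clamped at +/-{_Z_CLAMP} SD (extreme-tail CDF underflow)",
            RuntimeWarning,
            stacklevel=2,
        )
        z = np.clip(np.nan_to_num(z, nan=0.0, posinf=_Z_CLAMP, neginf=-_Z_CLAMP),
                    -_Z_CLAMP, _Z_CLAMP)
    return float(z) if scalar else z


def sample(params: FamilyParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` independent values by inverse-CDF of uniform variates.

    ``seed`` may be an int or a ``numpy.random.Generator``; a fixed int seed
    reproduces the sequence exactly.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    z = _kernel_ppf(params.family, params.tau, u)
    z0 = _z_truncation(params)
    if z0 is not None:
        # resolve truncation breaches by redrawing (mass is negligible here)
        bad = (z <= z0) if params.nu > 0 else (z >= z0)
        while np.any(bad):
            z[bad] = _kernel_ppf(params.family, params.tau,
                                 rng.uniform(size=int(bad.sum())))
            bad = (z <= z0) if params.nu > 0 else (z >= z0)
    return inverse_boxcox_z(z, params)


# ---------------------------------------------------------------------------
# inverse fitting: centile points -> FamilyParams
# ---------------------------------------------------------------------------

def _tau_bounds(family):
    return (0.5, 200.0) if family == BCPE else (1.0, 1e6)


def _quantile_residuals(x, family, p, values):
    """Residuals quantile(params(x), p) - values in the internal
    (ln mu, ln sigma, nu, ln tau) parametrization; truncation breaches are
    mapped to large finite residuals so the optimizer steers away."""
    mu, sigma, nu, tau = np.exp(x[0]), np.exp(x[1]), x[2], np.exp(x[3])
    z = _kernel_ppf(family, tau, p / 100.0)
    if abs(nu) < _NU_EPS:
        y = mu * np.exp(sigma * z)
    else:
        arg = 1.0 + nu * sigma * z
        y = np.where(arg > 1e-12, mu * np.exp(np.log(np.maximum(arg, 1e-12)) / nu),
                     np.where(nu > 0, 0.0, np.inf))
        y = np.nan_to_num(y, posinf=1e12)
    return y - values


def fit_params_to_centiles(
    points: Iterable[CentilePoint] | Sequence[tuple],
    family: str = BCPE,
    log_scale: bool = False,
    *,
    residual_tol: float = 1e-8,
) -> FamilyParams:
    """Recover the four family parameters from a set of centile points.

    With exactly four points the 4x4 system ``quantile(params, p_i) = v_i``
    is solved to ``residual_tol`` on the value scale; with more points the
    sum of squared quantile residuals is minimized over
    ``(ln mu, ln sigma, nu, ln tau)``.  When ``log_scale`` is set the values
    are log-transformed before fitting (the fitted ``mu`` is then in
    log-units and downstream quantiles must be exponentiated).
    """
    pts = [pt if isinstance(pt, CentilePoint) else CentilePoint(*pt) for pt in points]
    if len(pts) < 4:
        raise DomainError("need at least 4 centile points")
    p = np.array([pt.p for pt in pts], dtype=float)
    v = np.array([pt.value for pt in pts], dtype=float)
    order = np.argsort(p)
    p, v = p[order], v[order]
    if len(np.unique(p)) != len(p):
        raise DomainError("centile ranks must be distinct")
    # integer-rounded published rows may contain ties; tolerate them in
    # least-squares mode but never a decrease
    if np.any(np.diff(v) < 0):
        raise DomainError("values must be non-decreasing in centile rank")
    if len(pts) == 4 and np.any(np.diff(v) <= 0):
        raise DomainError("values must be strictly increasing for an exact 4-point solve")
    if family not in (BCPE, BCT):
        raise DomainError(f"unknown family {family!r}")

    if log_scale:
        v = np.log(v)

    # normal-case moment-match start: regress v on Phi^-1(p) for mu, sigma
    zn = stats.norm.ppf(p / 100.0)
    slope, intercept = np.polyfit(zn, v, 1)
    mu0 = max(intercept, 1e-6)
    sigma0 = max(abs(slope) / mu0, 1e-4)
    tau0 = 2.0 if family == BCPE else 10.0
    x0 = np.array([np.log(mu0), np.log(sigma0), 1.0, np.log(tau0)])

    tlo, thi = _tau_bounds(family)
    lo = np.array([np.log(mu0) - 5.0, np.log(sigma0) - 5.0, -10.0, np.log(tlo)])
    hi = np.array([np.log(mu0) + 5.0, np.log(sigma0) + 5.0, 10.0, np.log(thi)])
    x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)

    res = optimize.least_squares(
        _quantile_residuals, x0, args=(family, p, v),
        bounds=(lo, hi), method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=2000,
    )
    best = float(np.max(np.abs(res.fun)))
    if len(pts) == 4 and best > residual_tol:
        raise CentileFitError(
            f"4-point system not solved to {residual_tol:g} "
            f"(max residual {best:.3g} on the value scale)",
            best_residual=best,
        )
    if not res.success and len(pts) > 4:
        raise CentileFitError(
            f"centile fit did not converge (max residual {best:.3g})",
            best_residual=best,
        )
    mu, sigma, nu, tau = np.exp(res.x[0]), np.exp(res.x[1]), res.x[2], np.exp(res.x[3])
    return FamilyParams(family=family, mu=float(mu), sigma=float(sigma),
                        nu=float(nu), tau=float(tau))
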