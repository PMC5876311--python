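"""Penalized B-spline fitting of age-smooth BCPE/BCT models.

Each of the four distribution parameters (mu, sigma, nu, tau) is a smooth
function of power-transformed age, represented by a cubic B-spline with a
second-order difference penalty (a P-spline).  Fitting maximizes the
penalized log-likelihood by cyclic backfitting: per cycle, each parameter's
spline coefficients are updated with one penalized weighted least-squares
step on its working variable (Newton scoring with numeric derivatives),
with step-halving so the penalized deviance never increases.  Smoothing
strength per parameter is set by a target effective-degrees-of-freedom
(edf) value; model selection searches the age-power exponent ("zeta") and
the per-parameter edf grids for the lowest Schwarz Bayesian Criterion
SBC = -2 logLik + ln(n) * total edf.

Respiratory-rate data get a dedicated preprocessing step: zero-mean
Gaussian dither truncated at +/-2 breaths/min (to break digit preference)
followed by a natural-log transform; the model is then fitted on the log
scale and downstream quantiles are exponentiated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

from vitalcentiles.distributions import (
    BCPE, FamilyParams, _kernel_logpdf, _NU_EPS,
)

__all__ = [
    "FitConfig",
    "ParamSmooth",
    "CentileModel",
    "FitError",
    "transform_age",
    "rr_preprocess",
    "fit_model",
    "select_model",
    "predict_params",
    "save_model",
    "load_model",
]

_PARAMS = ("mu", "sigma", "nu", "tau")

#: inverse-link and link per distribution parameter (log keeps mu/sigma/tau
#: positive; nu is unconstrained)
_LINKS = {"mu": "log", "sigma": "log", "nu": "identity", "tau": "log"}

# eta clamps keep the numeric scoring away from overflow regions
_ETA_BOUNDS = {
    "mu": (-20.0, 20.0),
    "sigma": (np.log(1e-4), np.log(10.0)),
    "nu": (-10.0, 10.0),
    "tau": (np.log(0.51), np.log(1e6)),
}


class FitError(RuntimeError):
    """Backfitting failure; carries the deviance trace when available."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


@dataclass
class FitConfig:
    """Knobs of the smooth fit and of model selection."""

    zeta_grid: tuple = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    edf: dict = field(default_factory=lambda: {
        "mu": 5.0, "sigma": 3.0, "nu": 2.0, "tau": 2.0})
    edf_grid: dict = field(default_factory=lambda: {
        "mu": (2.0, 3.0, 5.0, 8.0, 12.0),
        "sigma": (2.0, 3.0, 5.0, 8.0, 12.0),
        "nu": (2.0, 3.0, 5.0),
        "tau": (2.0, 3.0, 5.0)})
    n_interior_knots: int = 20
    penalty_order: int = 2
    tol: float = 0.01            # absolute penalized-deviance change
    max_iter: int = 100
    search_edf: bool = True      # coordinate search over edf_grid in select_model
    dither_seed: int = 0

    def __post_init__(self):
        if not self.zeta_grid:
            raise ValueError("zeta grid must be non-empty")
        if any(not (0.01 <= z <= 1.0) for z in self.zeta_grid):
            raise ValueError("zeta values must lie in [0.01, 1]")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class ParamSmooth:
    """One fitted P-spline: full knot vector, coefficients, effective df."""

    knots: np.ndarray
    coef: np.ndarray
    edf: float
    lam: float

    def __call__(self, t):
        t = np.clip(np.asarray(t, dtype=float), self.knots[3], self.knots[-4])
        return BSpline(self.knots, self.coef, 3, extrapolate=False)(t)


@dataclass
class CentileModel:
    """A fitted age-smooth four-parameter distribution model."""

    family: str
    log_scale: bool
    zeta: float
    smooths: dict            # name -> ParamSmooth
    n_fit: float
    sbc: float
    deviance: float
    age_range: tuple         # (min, max) fitted age in years
    dither_seed: int | None = None
    deviance_trace: list = field(default_factory=list)

    @property
    def total_edf(self) -> float:
        return float(sum(s.edf for s in self.smooths.values()))


def transform_age(age, zeta: float):
    """Power transform of age: ``age**zeta`` (zeta in [0.01, 1], 1 = identity)."""
    if not 0.01 <= zeta <= 1.0:
        raise ValueError(f"zeta must lie in [0.01, 1], got {zeta}")
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be > 0")
    out = age ** zeta
    return float(out) if out.ndim == 0 else out


def rr_preprocess(rr, seed) -> np.ndarray:
    """Dither and log-transform raw respiratory rates.

    Adds zero-mean Gaussian noise truncated at +/-2 breaths/min (standard
    normal truncated to [-2, 2]); values pushed to <= 0 are redrawn (only
    possible for rr <= 2).  Returns the natural log of the dithered values.
    """
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("rr must be > 0")
    rng = np.random.default_rng(seed)
    noise = stats.truncnorm.ppf(rng.uniform(size=rr.shape), -2.0, 2.0)
    out = rr + noise
    bad = out <= 0
    while np.any(bad):
        out[bad] = rr[bad] + stats.truncnorm.ppf(
            rng.uniform(size=int(bad.sum())), -2.0, 2.0)
        bad = out <= 0
    return np.log(out)


# ---------------------------------------------------------------------------
# likelihood plumbing
# ---------------------------------------------------------------------------

def _loglik_terms(family, y, log_y, mu, sigma, nu, tau):
    """Per-observation log density of the Box-Cox family (no truncation)."""
    r = y / mu
    log_r = log_y - np.log(mu)
    z = np.where(np.abs(nu) < _NU_EPS,
                 log_r / sigma,
                 np.expm1(nu * log_r) / (np.where(np.abs(nu) < _NU_EPS, 1.0, nu) * sigma))
    log_jac = (nu - 1.0) * log_y - nu * np.log(mu) - np.log(sigma)
    return _kernel_logpdf(family, tau, z) + log_jac


def _eta_to_param(name, eta):
    return np.exp(eta) if _LINKS[name] == "log" else eta


def _clip_eta(name, eta):
    lo, hi = _ETA_BOUNDS[name]
    return np.clip(eta, lo, hi)


class _Fitter:
    """State of one backfitting run on aggregated (x, y, w) data."""

    def __init__(self, family, t, y, w, config: FitConfig):
        self.family = family
        self.y = y
        self.log_y = np.log(y)
        self.w = w
        self.n = float(np.sum(w))
        self.config = config

        tmin, tmax = float(np.min(t)), float(np.max(t))
        if tmax <= tmin:
            tmax = tmin + 1e-6
        interior = np.linspace(tmin, tmax, config.n_interior_knots + 2)
        self.knots = np.concatenate([
            [tmin] * 3, interior, [tmax] * 3])
        self.B = BSpline.design_matrix(
            np.clip(t, tmin, tmax), self.knots, 3).toarray()
        self.ncoef = self.B.shape[1]
        D = np.diff(np.eye(self.ncoef), n=config.penalty_order, axis=0)
        self.P = D.T @ D
        self.coef = {}
        self.lam = {}

    # -- linear algebra helpers -------------------------------------------

    def _weighted_cross(self, wvec):
        Bw = self.B * wvec[:, None]
        return self.B.T @ Bw

    def _edf_of(self, BtWB, lam):
        A = BtWB + lam * self.P + 1e-9 * np.eye(self.ncoef)
        return float(np.trace(np.linalg.solve(A, BtWB)))

    def _lambda_for_edf(self, BtWB, target):
        """Bisection on log10(lambda) for tr(H) = target edf."""
        lo, hi = -8.0, 14.0
        f_lo = self._edf_of(BtWB, 10.0 ** lo)
        f_hi = self._edf_of(BtWB, 10.0 ** hi)
        if target >= f_lo:
            return 10.0 ** lo
        if target <= f_hi:
            return 10.0 ** hi
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if self._edf_of(BtWB, 10.0 ** mid) > target:
                lo = mid
            else:
                hi = mid
        return 10.0 ** (0.5 * (lo + hi))

    # -- likelihood -------------------------------------------------------

    def _params_from(self, coef):
        eta = {k: _clip_eta(k, self.B @ coef[k]) for k in _PARAMS}
        return {k: _eta_to_param(k, eta[k]) for k in _PARAMS}

    def loglik(self, coef=None):
        p = self._params_from(coef if coef is not None else self.coef)
        ll = _loglik_terms(self.family, self.y, self.log_y,
                           p["mu"], p["sigma"], p["nu"], p["tau"])
        ll = np.where(np.isfinite(ll), ll, -1e10)
        return float(np.sum(self.w * ll))

    def deviance(self, coef=None):
        return -2.0 * self.loglik(coef)

    def penalized_deviance(self, coef=None):
        coef = coef if coef is not None else self.coef
        pen = sum(self.lam[k] * float(coef[k] @ self.P @ coef[k])
                  for k in _PARAMS)
        return self.deviance(coef) + pen

    # -- scoring ----------------------------------------------------------

    def _score(self, name):
        """Numeric first/second derivatives of the log-lik wrt eta_name."""
        p = self._params_from(self.coef)
        eta0 = self.B @ self.coef[name]
        h = 1e-4

        def ll_at(eta):
            q = dict(p)
            q[name] = _eta_to_param(name, _clip_eta(name, eta))
            ll = _loglik_terms(self.family, self.y, self.log_y,
                               q["mu"], q["sigma"], q["nu"], q["tau"])
            return np.where(np.isfinite(ll), ll, -1e10)

        l0, lp, lm = ll_at(eta0), ll_at(eta0 + h), ll_at(eta0 - h)
        u = (lp - lm) / (2.0 * h)
        wq = -(lp - 2.0 * l0 + lm) / h ** 2
        # fall back to squared-score weights where curvature is not usable
        floor = 1e-4
        bad = ~np.isfinite(wq) | (wq <= floor)
        wq = np.where(bad, np.maximum(u * u, floor), wq)
        return eta0, u, wq

    def init_coef(self):
        """Starting coefficients: smooth log-mean for mu, flat elsewhere."""
        cfg = self.config
        target = self.log_y if _LINKS["mu"] == "log" else self.y
        BtWB = self._weighted_cross(self.w)
        lam0 = self._lambda_for_edf(BtWB, cfg.edf["mu"])
        A = BtWB + lam0 * self.P + 1e-9 * np.eye(self.ncoef)
        rhs = self.B.T @ (self.w * target)
        self.coef["mu"] = np.linalg.solve(A, rhs)

        mu_hat = np.exp(self.B @ self.coef["mu"])
        resid = self.log_y - np.log(mu_hat)
        s0 = max(float(np.sqrt(np.average(resid ** 2, weights=self.w))), 1e-3)
        flat = np.ones(self.ncoef)
        self.coef["sigma"] = flat * np.log(s0)
        self.coef["nu"] = flat * 1.0
        self.coef["tau"] = flat * np.log(2.0 if self.family == BCPE else 10.0)

    def set_lambdas(self):
        """Fix each parameter's lambda from its target edf at current weights."""
        for name in _PARAMS:
            _, _, wq = self._score(name)
            BtWB = self._weighted_cross(self.w * wq)
            self.lam[name] = self._lambda_for_edf(BtWB, self.config.edf[name])

    def update_param(self, name):
        """One penalized-WLS Newton step with step-halving."""
        eta0, u, wq = self._score(name)
        z = eta0 + u / wq
        ww = self.w * wq
        BtWB = self._weighted_cross(ww)
        A = BtWB + self.lam[name] * self.P + 1e-9 * np.eye(self.ncoef)
        rhs = self.B.T @ (ww * z)
        new = np.linalg.solve(A, rhs)

        old = self.coef[name]
        base = self.penalized_deviance()
        step = 1.0
        for _ in range(12):
            trial = dict(self.coef)
            trial[name] = old + step * (new - old)
            if self.penalized_deviance(trial) <= base + 1e-9 * (abs(base) + 1.0):
                self.coef = trial
                return
            step *= 0.5
        # no improving step: keep old coefficients

    def final_edf(self, name):
        _, _, wq = self._score(name)
        BtWB = self._weighted_cross(self.w * wq)
        return self._edf_of(BtWB, self.lam[name])

    def run(self):
        cfg = self.config
        self.init_coef()
        self.set_lambdas()
        trace = [self.penalized_deviance()]
        for _ in range(cfg.max_iter):
            for name in _PARAMS:   # stepwise order: mu, sigma, nu, tau
                self.update_param(name)
            trace.append(self.penalized_deviance())
            if abs(trace[-2] - trace[-1]) < cfg.tol:
                break
        else:
            raise FitError(
                f"backfitting did not converge in {cfg.max_iter} cycles",
                trace=trace,
            )
        return trace


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def _prepare(observations, weights):
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError("observations must be an (n, 2) array of (age, value)")
    age, y = obs[:, 0], obs[:, 1]
    if np.any(age <= 0):
        raise ValueError("ages must be > 0")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != y.shape or np.any(w <= 0):
        raise ValueError("weights must be positive and match observations")
    if np.sum(w) < 200:
        raise ValueError("need >= 200 (weighted) observations for a stable "
                         "4-parameter fit")
    if len(np.unique(age)) < 2:
        warnings.warn("single distinct age: age smooth degenerates to a "
                      "constant", RuntimeWarning, stacklevel=3)
    return age, y, w


def fit_model(observations, family=BCPE, log_scale=False, config=None, *,
              weights=None, zeta=None, dither_seed=None) -> CentileModel:
    """Fit the four-parameter smooth model at a fixed age-power ``zeta``.

    ``observations`` is an (n, 2) array of (age-in-years, value-on-model-
    scale) rows, optionally with frequency ``weights``.  For RR pass the
    output of :func:`rr_preprocess` and ``log_scale=True``.
    """
    config = config or FitConfig()
    zeta = config.zeta_grid[-1] if zeta is None else zeta
    age, y, w = _prepare(observations, weights)
    t = transform_age(age, zeta)

    fitter = _Fitter(family, t, y, w, config)
    trace = fitter.run()

    smooths = {}
    for name in _PARAMS:
        smooths[name] = ParamSmooth(
            knots=fitter.knots.copy(),
            coef=fitter.coef[name].copy(),
            edf=fitter.final_edf(name),
            lam=fitter.lam[name],
        )
    dev = fitter.deviance()
    n = fitter.n
    total_edf = sum(s.edf for s in smooths.values())
    model = CentileModel(
        family=family, log_scale=bool(log_scale), zeta=float(zeta),
        smooths=smooths, n_fit=n, sbc=dev + np.log(n) * total_edf,
        deviance=dev, age_range=(float(np.min(age)), float(np.max(age))),
        dither_seed=dither_seed, deviance_trace=trace,
    )
    _check_links(model)
    return model


def _check_links(model: CentileModel):
    ages = np.linspace(model.age_range[0], model.age_range[1], 50)
    for a in ages:
        p = predict_params(model, float(a), warn_extrapolation=False)
        if not (p.mu > 0 and p.sigma > 0 and p.tau > 0):
            raise FitError(f"link breach: non-positive parameter at age {a:.3f}")


def select_model(observations, family=BCPE, log_scale=False, config=None, *,
                 weights=None, dither_seed=None) -> CentileModel:
    """SBC-driven search over the zeta grid and per-parameter edf grids.

    For every zeta in the grid a model is fitted at the default edf targets;
    at the best zeta a single coordinate pass over each parameter's edf grid
    refines the smoothing (when ``config.search_edf``).  The model with the
    lowest SBC among all evaluated candidates is returned; the search is
    deterministic given data and config.
    """
    config = config or FitConfig()
    candidates = []
    failures = []

    def try_fit(cfg, zeta):
        try:
            m = fit_model(observations, family, log_scale, cfg,
                          weights=weights, zeta=zeta, dither_seed=dither_seed)
            candidates.append(m)
            return m
        except (FitError, np.linalg.LinAlgError) as exc:
            failures.append((zeta, str(exc)))
            return None

    for zeta in config.zeta_grid:
        try_fit(config, zeta)
    if not candidates:
        raise FitError(f"every grid point failed: {failures}")

    best = min(candidates, key=lambda m: m.sbc)
    if config.search_edf:
        edf = dict(config.edf)
        for name in _PARAMS:
            for value in config.edf_grid.get(name, ()):
                if value == edf[name]:
                    continue
                trial_edf = dict(edf, **{name: value})
                cfg = replace(config, edf=trial_edf)
                m = try_fit(cfg, best.zeta)
                if m is not None and m.sbc < best.sbc:
                    best, edf = m, trial_edf
    return best


def predict_params(model: CentileModel, age: float, *,
                   warn_extrapolation: bool = True) -> FamilyParams:
    """Evaluate the fitted smooths at one age (years) -> FamilyParams.

    Outside the fitted age range the smooths are clamped to the boundary and
    a warning is emitted.
    """
    lo, hi = model.age_range
    if warn_extrapolation and not (lo - 1e-9 <= age <= hi + 1e-9):
        warnings.warn(
            f"age {age} outside fitted range [{lo:.3f}, {hi:.3f}]; "
            "boundary value used", RuntimeWarning, stacklevel=2)
    t = transform_age(np.clip(age, lo, hi), model.zeta)
    values = {}
    for name in _PARAMS:
        eta = _clip_eta(name, float(model.smooths[name](t)))
        values[name] = float(_eta_to_param(name, eta))
    return FamilyParams(family=model.family, **values)


# ---------------------------------------------------------------------------
# serialization (self-describing JSON text file)
# ---------------------------------------------------------------------------

def save_model(model: CentileModel, path):
    doc = {
        "format": "vitalcentiles-model-v1",
        "family": model.family,
        "log_scale": model.log_scale,
        "zeta": model.zeta,
        "n_fit": model.n_fit,
        "sbc": model.sbc,
        "deviance": model.deviance,
        "age_range": list(model.age_range),
        "dither_seed": model.dither_seed,
        "smooths": {
            name: {
                "knots": s.knots.tolist(),
                "coef": s.coef.tolist(),
                "edf": s.edf,
                "lam": s.lam,
            } for name, s in model.smooths.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> CentileModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "vitalcentiles-model-v1":
        raise ValueError("not a vitalcentiles model file")
    smooths = {
        name: ParamSmooth(
            knots=np.asarray(s["knots"], dtype=float),
            coef=np.asarray(s["coef"], dtype=float),
            edf=float(s["edf"]), lam=float(s["lam"]),
        ) for name, s in doc["smooths"].items()
    }
    return CentileModel(
        family=doc["family"], log_scale=doc["log_scale"], zeta=doc["zeta"],
        smooths=smooths, n_fit=doc["n_fit"], sbc=doc["sbc"],
        deviance=doc["deviance"], age_range=tuple(doc["age_range"]),
        dither_seed=doc.get("dither_seed"),
    )
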