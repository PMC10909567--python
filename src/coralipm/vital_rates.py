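"""Size-dependent vital-rate regressions fitted from survey tables.

All rates are functions of z = ln(colony surface area in cm^2):

* survival sigma(z): logistic, linear in z
* growth gamma(z'|z): Gaussian with polynomial mean (default quadratic) and
  constant (or log-linear) residual sd; fitted on surviving, non-fragmenting
  colonies only
* fragmentation kappa(z): polynomial logistic (default quadratic)
* remnant count kappa_b(z): zero-truncated Poisson, log-linear in parent z
  (count = 1 + Poisson mean)
* remnant size kappa_z0(z'|z): Gaussian, polynomial mean in parent z
* fecundity phi_f(z): log-linear polynomial (default quadratic), fitted by
  ordinary least squares on log larval output
* settlement phi: per-year recruits divided by total predicted larval
  output, interpreted as a per-larva establishment probability
* recruit sizes C0: Gaussian on the log scale with an sd floor

Fits go through statsmodels; a numpy IRLS engine (``engine="irls"``) produces
identical estimates and is used inside resampling loops for speed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .data_io import ColonyObservation, observations_frame

__all__ = [
    "PolyLogistic", "PolyGaussian", "RemnantCountModel", "FecundityModel",
    "Settlement", "RecruitSizeDist", "VitalRateSet",
    "fit_survival", "fit_growth", "fit_fragmentation", "fit_fecundity",
    "estimate_settlement", "fit_recruit_sizes", "fit_all",
    "rates_from_params", "SeparationWarning",
]

RECRUIT_SD_FLOOR = 0.05


class SeparationWarning(UserWarning):
    """Complete separation detected in a logistic fit; penalized fallback used."""


def _design(z: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(np.asarray(z, dtype=float), degree + 1, increasing=True)


def _irls(X, y, family: str, ridge: float = 0.0, max_iter: int = 200,
          tol: float = 1e-12):
    """Newton/IRLS for logistic ('binomial') or log-link Poisson GLMs.

    Returns (coef, cov, converged). With ridge=0 this solves the same score
    equations as statsmodels GLM and agrees to solver tolerance.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    beta = np.zeros(p)
    if family == "binomial":
        beta[0] = np.log((y.mean() + 1e-8) / (1 - y.mean() + 1e-8))
    elif family == "poisson":
        beta[0] = np.log(y.mean() + 1e-8)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        if family == "binomial":
            mu = expit(eta)
            w = np.maximum(mu * (1 - mu), 1e-10)
        else:
            mu = np.exp(eta)
            w = np.maximum(mu, 1e-10)
        zwork = eta + (y - mu) / w
        Xw = X * w[:, None]
        H = X.T @ Xw
        if ridge:
            H = H + ridge * np.eye(p)
        new = np.linalg.solve(H, Xw.T @ zwork)
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    if family == "binomial":
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
    else:
        mu = np.exp(eta)
        w = np.maximum(mu, 1e-10)
    H = X.T @ (X * w[:, None])
    if ridge:
        H = H + ridge * np.eye(p)
    cov = np.linalg.inv(H)
    return beta, cov, converged


@dataclass
class PolyLogistic:
    """Logistic regression of a binary outcome on a polynomial in z."""

    coef: np.ndarray
    cov: np.ndarray | None = None
    degree: int = 1
    separation: bool = False

    def logit(self, z):
        return _design(np.atleast_1d(z), self.degree) @ self.coef

    def prob(self, z):
        return np.clip(expit(self.logit(z)), 0.0, 1.0)

    def se(self):
        return np.sqrt(np.diag(self.cov)) if self.cov is not None else None


@dataclass
class PolyGaussian:
    """Gaussian conditional z' | z with polynomial mean.

    sd_model: 'constant' (one residual sd) or 'loglinear'
    (log sd^2 linear in z, fitted from log squared residuals with the
    chi-square-1 bias correction E[log chi2_1] = -1.27036...).

    ``upper_truncated`` marks a distribution truncated above at the parent
    size z (used for remnant sizes: a remnant cannot exceed the colony it
    broke from); such models are fitted by truncated-normal maximum
    likelihood, since ordinary least squares is biased under truncation.
    """

    coef: np.ndarray
    cov: np.ndarray | None = None
    degree: int = 2
    sd_model: str = "constant"
    sd_coef: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    upper_truncated: bool = False

    def mean(self, z):
        return _design(np.atleast_1d(z), self.degree) @ self.coef

    def sd(self, z):
        z = np.atleast_1d(z)
        if self.sd_model == "constant":
            return np.full(z.shape, float(self.sd_coef[0]))
        log_var = self.sd_coef[0] + self.sd_coef[1] * z
        return np.exp(0.5 * log_var)


@dataclass
class RemnantCountModel:
    """Zero-truncated remnant production: count = 1 + Poisson(exp(d0+d1 z)).

    ``cap`` bounds the predicted mean count when extrapolating beyond the
    observed fragmentation events (set from the data at fit time); without
    it a noisy slope estimate can imply absurd remnant production at the
    upper end of the size domain.
    """

    coef: np.ndarray
    cov: np.ndarray | None = None
    empirical: bool = False
    cap: float = float("inf")

    def mean_count(self, z):
        z = np.atleast_1d(z)
        mean = 1.0 + np.exp(np.clip(self.coef[0] + self.coef[1] * z, -30, 30))
        return np.minimum(mean, self.cap)


@dataclass
class FecundityModel:
    """log E[larvae] polynomial in z; predictions always non-negative."""

    coef: np.ndarray
    cov: np.ndarray | None = None
    degree: int = 2

    def expected(self, z):
        return np.exp(np.clip(_design(np.atleast_1d(z), self.degree)
                              @ self.coef, -300, 300))


@dataclass
class Settlement:
    """Per-larva establishment probabilities, yearly and pooled."""

    yearly: dict[int, float]
    pooled: float
    lo: float
    hi: float


@dataclass
class RecruitSizeDist:
    """Recruit log-size distribution C0 (renormalized over the mesh later)."""

    mu: float
    sd: float


@dataclass
class VitalRateSet:
    """Complete fitted (or generative) rate set for one assemblage."""

    survival: PolyLogistic
    growth: PolyGaussian
    fragmentation: PolyLogistic
    remnant_count: RemnantCountModel | None
    remnant_size: PolyGaussian | None
    fecundity: FecundityModel
    settlement: Settlement
    recruit_size: RecruitSizeDist
    size_range: tuple[float, float]  # raw cm^2 (min, max) observed

    def to_json(self, path) -> None:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        doc = {
            "survival": {"coef": arr(self.survival.coef),
                         "cov": arr(self.survival.cov),
                         "degree": self.survival.degree,
                         "separation": self.survival.separation},
            "growth": {"coef": arr(self.growth.coef),
                       "cov": arr(self.growth.cov),
                       "degree": self.growth.degree,
                       "sd_model": self.growth.sd_model,
                       "sd_coef": arr(self.growth.sd_coef)},
            "fragmentation": {"coef": arr(self.fragmentation.coef),
                              "cov": arr(self.fragmentation.cov),
                              "degree": self.fragmentation.degree},
            "remnant_count": None if self.remnant_count is None else
                {"coef": arr(self.remnant_count.coef),
                 "cov": arr(self.remnant_count.cov),
                 "empirical": self.remnant_count.empirical,
                 "cap": self.remnant_count.cap},
            "remnant_size": None if self.remnant_size is None else
                {"coef": arr(self.remnant_size.coef),
                 "cov": arr(self.remnant_size.cov),
                 "degree": self.remnant_size.degree,
                 "sd_model": self.remnant_size.sd_model,
                 "sd_coef": arr(self.remnant_size.sd_coef),
                 "upper_truncated": self.remnant_size.upper_truncated},
            "fecundity": {"coef": arr(self.fecundity.coef),
                          "cov": arr(self.fecundity.cov),
                          "degree": self.fecundity.degree},
            "settlement": {"yearly": {str(k): v for k, v in
                                      self.settlement.yearly.items()},
                           "pooled": self.settlement.pooled,
                           "lo": self.settlement.lo, "hi": self.settlement.hi},
            "recruit_size": {"mu": self.recruit_size.mu,
                             "sd": self.recruit_size.sd},
            "size_range": list(self.size_range),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "VitalRateSet":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)

        def arr(a):
            return None if a is None else np.asarray(a, float)

        rc = d["remnant_count"]
        rs = d["remnant_size"]
        return cls(
            survival=PolyLogistic(arr(d["survival"]["coef"]),
                                  arr(d["survival"]["cov"]),
                                  d["survival"]["degree"],
                                  d["survival"]["separation"]),
            growth=PolyGaussian(arr(d["growth"]["coef"]),
                                arr(d["growth"]["cov"]), d["growth"]["degree"],
                                d["growth"]["sd_model"],
                                arr(d["growth"]["sd_coef"])),
            fragmentation=PolyLogistic(arr(d["fragmentation"]["coef"]),
                                       arr(d["fragmentation"]["cov"]),
                                       d["fragmentation"]["degree"]),
            remnant_count=None if rc is None else RemnantCountModel(
                arr(rc["coef"]), arr(rc["cov"]), rc["empirical"],
                rc.get("cap", float("inf"))),
            remnant_size=None if rs is None else PolyGaussian(
                arr(rs["coef"]), arr(rs["cov"]), rs["degree"],
                rs["sd_model"], arr(rs["sd_coef"]),
                rs.get("upper_truncated", False)),
            fecundity=FecundityModel(arr(d["fecundity"]["coef"]),
                                     arr(d["fecundity"]["cov"]),
                                     d["fecundity"]["degree"]),
            settlement=Settlement({int(k): v for k, v in
                                   d["settlement"]["yearly"].items()},
                                  d["settlement"]["pooled"],
                                  d["settlement"]["lo"], d["settlement"]["hi"]),
            recruit_size=RecruitSizeDist(**d["recruit_size"]),
            size_range=tuple(d["size_range"]),
        )


# ---------------------------------------------------------------------------
# helpers


def _as_frame(obs) -> pd.DataFrame:
    if isinstance(obs, pd.DataFrame):
        return obs
    return observations_frame(obs)


def _fit_logistic(z, y, degree, engine, site=None):
    X = _design(z, degree)
    y = np.asarray(y, float)
    separated = False
    if y.min() == y.max():
        separated = True
    if separated:
        warnings.warn("complete separation in logistic fit; using a ridge-"
                      "penalized fit", SeparationWarning, stacklevel=3)
        coef, cov, _ = _irls(X, y, "binomial", ridge=1e-2)
        return PolyLogistic(coef, cov, degree, separation=True)
    if engine == "irls":
        coef, cov, conv = _irls(X, y, "binomial")
        if not conv or np.max(np.abs(coef)) > 25:
            warnings.warn("quasi-separation in logistic fit; using a ridge-"
                          "penalized fit", SeparationWarning, stacklevel=3)
            coef, cov, _ = _irls(X, y, "binomial", ridge=1e-2)
            return PolyLogistic(coef, cov, degree, separation=True)
        return PolyLogistic(coef, cov, degree)
    if site is not None:
        codes, _ = pd.factorize(np.asarray(site))
        vc = np.zeros((len(y), codes.max() + 1))
        vc[np.arange(len(y)), codes] = 1.0
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
        model = BinomialBayesMixedGLM(y, X, vc, ident=np.zeros(vc.shape[1],
                                                               dtype=int))
        res = model.fit_vb()
        coef = np.asarray(res.fe_mean)
        cov = np.diag(np.asarray(res.fe_sd) ** 2)
        return PolyLogistic(coef, cov, degree)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except Exception:
            res = None
    if res is None or not np.all(np.isfinite(res.bse)) \
            or np.max(np.abs(res.params)) > 25:
        warnings.warn("separation detected in logistic fit; using a ridge-"
                      "penalized fit", SeparationWarning, stacklevel=3)
        coef, cov, _ = _irls(X, y, "binomial", ridge=1e-2)
        return PolyLogistic(coef, cov, degree, separation=True)
    return PolyLogistic(np.asarray(res.params), np.asarray(res.cov_params()),
                        degree)


def _fit_truncated_gaussian(z, y, degree: int = 1,
                            compute_cov: bool = True) -> PolyGaussian:
    """MLE for y ~ Normal(poly(z), sd) truncated above at z.

    Used for remnant log-sizes, whose upper bound is the parent log-size
    (ordinary least squares is biased under truncation). Covariance of the
    mean coefficients comes from the inverse observed information
    (central-difference Hessian).
    """
    from scipy.optimize import minimize
    from scipy.special import log_ndtr

    _LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

    z = np.asarray(z, float)
    y = np.asarray(y, float)
    X = _design(z, degree)
    coef0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef0
    sd0 = max(float(resid.std(ddof=degree + 1)), 1e-3)
    p0 = np.concatenate([coef0, [np.log(sd0)]])

    def nll_grad(p):
        mu = X @ p[:-1]
        s = np.exp(p[-1])
        u = (y - mu) / s
        a = (z - mu) / s  # upper truncation point in standard units
        lcdf = log_ndtr(a)
        val = float(np.sum(0.5 * u ** 2 + np.log(s) + lcdf))
        lam = np.exp(-0.5 * a * a - _LOG_SQRT_2PI - lcdf)  # phi(a)/Phi(a)
        g_mu = (-u - lam) / s
        g_c = X.T @ g_mu
        g_t = float(np.sum(1.0 - u ** 2 - a * lam))
        return val, np.concatenate([g_c, [g_t]])

    def nll(p):
        return nll_grad(p)[0]

    res = minimize(nll_grad, p0, jac=True, method="BFGS",
                   options={"gtol": 1e-9, "maxiter": 500})
    p = res.x
    if not compute_cov:
        return PolyGaussian(p[:-1], None, degree, "constant",
                            np.array([np.exp(p[-1])]), upper_truncated=True)
    # observed information by central differences
    k = p.size
    h = 1e-4 * np.maximum(np.abs(p), 1.0)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = p.copy(); pp[i] += h[i]; pp[j] += h[j]; fpp = nll(pp)
            pm = p.copy(); pm[i] += h[i]; pm[j] -= h[j]; fpm = nll(pm)
            mp = p.copy(); mp[i] -= h[i]; mp[j] += h[j]; fmp = nll(mp)
            mm = p.copy(); mm[i] -= h[i]; mm[j] -= h[j]; fmm = nll(mm)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov_full = np.linalg.inv(H)
        cov = cov_full[: degree + 1, : degree + 1]
    except np.linalg.LinAlgError:
        cov = None
    return PolyGaussian(p[:-1], cov, degree, "constant",
                        np.array([np.exp(p[-1])]), upper_truncated=True)


def _fit_gaussian(z, y, degree, sd_model, engine, site=None) -> PolyGaussian:
    X = _design(z, degree)
    y = np.asarray(y, float)
    if len(y) <= degree + 1:
        raise ValueError("not enough rows to fit the polynomial mean")
    if site is not None and engine == "statsmodels":
        codes, _ = pd.factorize(np.asarray(site))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=codes).fit(reml=True)
        coef = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[: degree + 1, : degree + 1]
        resid = y - X @ coef
    elif engine == "statsmodels":
        res = sm.OLS(y, X).fit()
        coef = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        resid = np.asarray(res.resid)
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = max(len(y) - (degree + 1), 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
    if sd_model == "constant":
        dof = max(len(y) - (degree + 1), 1)
        sd = float(np.sqrt(resid @ resid / dof))
        sd_coef = np.array([sd])
    elif sd_model == "loglinear":
        # E[log chi2_1] bias correction for log squared residuals
        ly = np.log(np.maximum(resid ** 2, 1e-300)) + 1.27036284546147
        Xs = _design(z, 1)
        sd_coef, *_ = np.linalg.lstsq(Xs, ly, rcond=None)
    else:
        raise ValueError(f"unknown sd_model {sd_model!r}")
    return PolyGaussian(coef, cov, degree, sd_model, sd_coef)


# ---------------------------------------------------------------------------
# public fitting operations


def fit_survival(obs, *, engine: str = "statsmodels",
                 site_random_intercept: bool = False) -> PolyLogistic:
    """Logistic survival as a function of log colony size."""
    df = _as_frame(obs)
    y = df["survived"].to_numpy(float)
    if len(np.unique(y)) < 2 and len(y) < 2:
        raise ValueError("need at least 2 outcomes to fit survival")
    z = np.log(df["size_t"].to_numpy(float))
    site = df["site"].to_numpy() if site_random_intercept else None
    return _fit_logistic(z, y, 1, engine, site)


def fit_growth(obs, *, degree: int = 2, sd_model: str = "constant",
               engine: str = "statsmodels",
               site_random_intercept: bool = False) -> PolyGaussian:
    """Polynomial Gaussian growth on the log scale.

    Only survivors that did not fragment contribute; fragmenting colonies'
    parent-to-largest-remnant transitions are excluded.
    """
    df = _as_frame(obs)
    keep = df["survived"].to_numpy(bool) & ~df["fragmented"].to_numpy(bool) \
        & np.isfinite(df["size_t1"].to_numpy(float))
    if keep.sum() < 10:
        raise ValueError("need >= 10 surviving non-fragmenting rows for growth")
    z = np.log(df.loc[keep, "size_t"].to_numpy(float))
    z1 = np.log(df.loc[keep, "size_t1"].to_numpy(float))
    site = df.loc[keep, "site"].to_numpy() if site_random_intercept else None
    return _fit_gaussian(z, z1, degree, sd_model, engine, site)


def fit_fragmentation(obs, *, degree: int = 2, engine: str = "statsmodels"):
    """Fragmentation probability, remnant count and remnant size models.

    Returns ``(kappa, kappa_b, kappa_z0)``. With no fragmentation events the
    probability model is identically zero and the count/size models are None
    (the kernel then reduces to pure survival/growth). With fewer than 5
    events the count/size models fall back to empirical constants.
    """
    df = _as_frame(obs)
    surv = df["survived"].to_numpy(bool)
    frag = df["fragmented"].to_numpy(bool)
    z = np.log(df["size_t"].to_numpy(float))
    if frag.sum() == 0:
        warnings.warn("no fragmentation events; kappa(z) set to 0 everywhere",
                      stacklevel=2)
        kappa = PolyLogistic(np.concatenate([[-np.inf],
                                             np.zeros(degree)]), None, degree)
        return kappa, None, None
    # fragmentation is conditional on surviving the interval; with few
    # events a quadratic logit extrapolates wildly, so the polynomial degree
    # backs off to linear below 30 events and intercept-only below 10
    kz = z[surv]
    ky = frag[surv].astype(float)
    eff_degree = degree if frag.sum() >= 30 else (1 if frag.sum() >= 10 else 0)
    kappa = _fit_logistic(kz, ky, min(degree, eff_degree), engine)

    fz = z[frag]
    counts = df.loc[frag, "n_remnants"].to_numpy(float)
    if frag.sum() < 5:
        warnings.warn("fewer than 5 fragmentation events; remnant count and "
                      "size fall back to empirical constants", stacklevel=2)
        extra = max(counts.mean() - 1.0, 1e-12)
        kb = RemnantCountModel(np.array([np.log(extra), 0.0]), None,
                               empirical=True,
                               cap=float(max(2.0 * counts.max(), 2.0)))
    else:
        X = _design(fz, 1)
        y = np.maximum(counts - 1.0, 0.0)  # zero-truncated: model the excess
        cap = float(max(2.0 * counts.max(), 2.0))
        if engine == "irls" or y.max() == 0:
            if y.max() == 0:
                kb = RemnantCountModel(np.array([-30.0, 0.0]), None,
                                       empirical=True, cap=cap)
            else:
                coef, cov, _ = _irls(X, y, "poisson")
                kb = RemnantCountModel(coef, cov, cap=cap)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            kb = RemnantCountModel(np.asarray(res.params),
                                   np.asarray(res.cov_params()), cap=cap)
    # remnant sizes: one row per remnant, parent z as predictor
    parent_z, rem_logs = _remnant_rows(obs, df, frag)
    if len(rem_logs) < 5:
        mu = float(np.mean(rem_logs)) if len(rem_logs) else float(np.mean(fz)) - 1.0
        kz0 = PolyGaussian(np.array([mu, 0.0]), None, 1, "constant",
                           np.array([max(np.std(rem_logs), 0.25)
                                     if len(rem_logs) else 0.5]),
                           upper_truncated=True)
    else:
        kz0 = _fit_truncated_gaussian(parent_z, rem_logs, 1)
    return kappa, kb, kz0


def _remnant_rows(obs, df, frag_mask):
    if isinstance(obs, pd.DataFrame):
        pz = obs.attrs.get("remnant_parent_z")
        rl = obs.attrs.get("remnant_log_sizes")
        if pz is not None:
            return np.asarray(pz, float), np.asarray(rl, float)
        raise ValueError("DataFrame input needs remnant_parent_z/"
                         "remnant_log_sizes in .attrs for remnant-size fits")
    parent, logs = [], []
    for o in obs:
        if o.fragmented:
            for s in o.remnant_sizes:
                parent.append(np.log(o.size_t))
                logs.append(np.log(s))
    return np.asarray(parent), np.asarray(logs)


def fit_fecundity(records, *, degree: int = 2) -> FecundityModel:
    """Polynomial log-larval-output model, least squares on the log scale."""
    if isinstance(records, pd.DataFrame):
        sizes = records["colony_size"].to_numpy(float)
        out = records["larval_output"].to_numpy(float)
    else:
        sizes = np.array([r.colony_size for r in records], float)
        out = np.array([r.larval_output for r in records], float)
    if len(out) < 10:
        raise ValueError("need >= 10 fecundity records")
    pos = out > 0
    if not pos.any():
        raise ValueError("degenerate fecundity table: all outputs are zero")
    z = np.log(sizes[pos])
    X = _design(z, degree)
    coef, *_ = np.linalg.lstsq(X, np.log(out[pos]), rcond=None)
    resid = np.log(out[pos]) - X @ coef
    dof = max(pos.sum() - (degree + 1), 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return FecundityModel(coef, cov, degree)


def estimate_settlement(recruit_surveys, fecundity: FecundityModel,
                        obs) -> Settlement:
    """Per-year recruits / total predicted larval output.

    The ratio is read as a per-larva establishment probability. Recruit
    surveys are matched to the transition-start year of the colonies whose
    reproduction produced them.
    """
    df = _as_frame(obs)
    z = np.log(df["size_t"].to_numpy(float))
    years = df["year_t"].to_numpy(int)
    larvae_by_year: dict[int, float] = {}
    for yr in np.unique(years):
        larvae_by_year[int(yr)] = float(np.sum(fecundity.expected(z[years == yr])))
    recruits_by_year: dict[int, int] = {}
    for r in recruit_surveys:
        recruits_by_year[r.year] = recruits_by_year.get(r.year, 0) + r.n_new
    yearly = {}
    for yr, larv in larvae_by_year.items():
        n_new = recruits_by_year.get(yr)
        if n_new is None:
            continue
        if larv <= 0:
            if n_new > 0:
                raise ValueError(
                    f"year {yr}: zero predicted larval output with {n_new} "
                    "recruits; settlement ratio undefined")
            continue
        yearly[yr] = n_new / larv
    if not yearly:
        raise ValueError("no year with positive predicted larval output")
    vals = np.array(list(yearly.values()))
    if vals.max() == 0:
        warnings.warn("zero recruits observed; settlement phi = 0 and the "
                      "reproduction kernel vanishes", stacklevel=2)
    return Settlement(yearly, float(vals.mean()), float(vals.min()),
                      float(vals.max()))


def fit_recruit_sizes(recruit_surveys) -> RecruitSizeDist:
    """Gaussian log-size distribution of new colonies, with an sd floor."""
    sizes = [s for r in recruit_surveys for s in r.new_sizes]
    if len(sizes) < 5:
        raise ValueError("need >= 5 recruit sizes; pool surveys across sites "
                         "or years")
    logs = np.log(np.asarray(sizes, float))
    return RecruitSizeDist(float(logs.mean()),
                           float(max(logs.std(ddof=1), RECRUIT_SD_FLOOR)))


def fit_all(obs, recruit_surveys, fecundity_records, *,
            growth_degree: int = 2, frag_degree: int = 2,
            fecundity_degree: int = 2, sd_model: str = "constant",
            engine: str = "statsmodels",
            site_random_intercept: bool = False) -> VitalRateSet:
    """Fit every vital rate for one assemblage and bundle the results."""
    df = _as_frame(obs)
    survival = fit_survival(df, engine=engine,
                            site_random_intercept=site_random_intercept)
    growth = fit_growth(df, degree=growth_degree, sd_model=sd_model,
                        engine=engine,
                        site_random_intercept=site_random_intercept)
    kappa, kb, kz0 = fit_fragmentation(obs, degree=frag_degree, engine=engine)
    fecundity = fit_fecundity(fecundity_records)
    settlement = estimate_settlement(recruit_surveys, fecundity, df)
    recruit_size = fit_recruit_sizes(recruit_surveys)
    sizes = df["size_t"].to_numpy(float)
    all_sizes = np.concatenate([
        sizes, df["size_t1"].to_numpy(float)[np.isfinite(
            df["size_t1"].to_numpy(float))]])
    return VitalRateSet(
        survival=survival, growth=growth, fragmentation=kappa,
        remnant_count=kb, remnant_size=kz0, fecundity=fecundity,
        settlement=settlement, recruit_size=recruit_size,
        size_range=(float(all_sizes.min()), float(all_sizes.max())),
    )


def rates_from_params(params, size_range: tuple[float, float]) -> VitalRateSet:
    """True VitalRateSet implied by a generative parameter set.

    ``size_range`` is the raw (min, max) cm^2 over which the kernel domain
    will be built; pass the observed range of a simulated dataset to compare
    fitted and generative kernels on the same mesh.
    """
    p = params
    return VitalRateSet(
        survival=PolyLogistic(np.array([p.a0, p.a1]), None, 1),
        growth=PolyGaussian(np.array([p.b0, p.b1, p.b2]), None, 2,
                            "constant", np.array([p.growth_sd])),
        fragmentation=PolyLogistic(np.array([p.c0, p.c1, p.c2]), None, 2),
        remnant_count=RemnantCountModel(np.array([p.d0, p.d1]), None),
        remnant_size=PolyGaussian(np.array([p.e0, p.e1]), None, 1,
                                  "constant", np.array([p.remnant_sd]),
                                  upper_truncated=True),
        fecundity=FecundityModel(np.array([p.f0, p.f1, p.f2]), None, 2),
        settlement=Settlement({}, p.phi_true, p.phi_true, p.phi_true),
        recruit_size=RecruitSizeDist(p.recruit_mu, p.recruit_sd),
        size_range=size_range,
    )
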