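"""Analytic rate surface, common-contact factor and equilibrium model.

The jump rate between two stepping stones is modelled as a product of
logistic sigmoids in the descriptor differences

    ln k(A->B) = ln k_max - ln(1 + e^{ alpha_HB * dE_HB })
                          - ln(1 + e^{ -alpha_c * dN_c })
                          + ln G(q_AB)

with dE_HB = E_HB^B - E_HB^A, dN_c = N_c^B - N_c^A, and a symmetric
common-contact factor G(q) = sigma(alpha_q (q - q_mid)) normalized so
G(1) = 1.  With both sigmoid midpoints pinned at zero the log rate ratio
factorizes exactly,

    ln k_AB - ln k_BA = -alpha_HB * dE_HB + alpha_c * dN_c,

so detailed balance holds with equilibrium probabilities

    P_X \\propto exp(-alpha_HB * E_HB^X + alpha_c * N_c^X),

the designability of structure X: it grows with hydrogen-bond count and
with compactness.  The fit is exposed as a scikit-learn style estimator
(:class:`RateSurfaceModel`) over rows X = [dE_HB, dN_c, q], y = k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logsumexp

from .structgen import Structure

__all__ = [
    "RateObservation",
    "RateSurfaceParams",
    "RateSurfaceModel",
    "log_rate",
    "log_common_contact_factor",
    "fit_rate_surface",
    "fit_common_contact_factor",
    "plane_fit_log_ratio",
    "equilibrium_probabilities",
    "observations_to_arrays",
]


@dataclass(frozen=True)
class RateObservation:
    """One measured pair: descriptor differences (B minus A) and both rates."""

    de_hb: float
    dn_c: float
    q: float
    k_ab: float
    k_ba: float
    se_ab: float | None = None
    se_ba: float | None = None

    def reversed(self) -> "RateObservation":
        return RateObservation(
            de_hb=-self.de_hb,
            dn_c=-self.dn_c,
            q=self.q,
            k_ab=self.k_ba,
            k_ba=self.k_ab,
            se_ab=self.se_ba,
            se_ba=self.se_ab,
        )


@dataclass
class RateSurfaceParams:
    """Fitted parameters of the logistic rate family.

    ``alpha_hb`` is per reduced energy unit, ``alpha_c`` per contact,
    ``alpha_q``/``q_mid`` shape the common-contact sigmoid (G(1) = 1 by
    normalization, making ``g_scale`` a derived quantity).
    """

    log_k_max: float
    alpha_hb: float
    alpha_c: float
    alpha_q: float = 0.0
    q_mid: float = 0.5

    @property
    def g_scale(self) -> float:
        return float(1.0 / expit(self.alpha_q * (1.0 - self.q_mid)))

    def to_dict(self) -> dict:
        return {
            "log_k_max": self.log_k_max,
            "alpha_hb": self.alpha_hb,
            "alpha_c": self.alpha_c,
            "alpha_q": self.alpha_q,
            "q_mid": self.q_mid,
        }


def _softplus(x):
    # ln(1 + e^x), overflow-safe
    return np.logaddexp(0.0, x)


def log_common_contact_factor(q, alpha_q: float, q_mid: float):
    """ln G(q) with the G(1) = 1 normalization; identically 0 if alpha_q = 0."""
    q = np.asarray(q, dtype=float)
    return -_softplus(-alpha_q * (q - q_mid)) + _softplus(-alpha_q * (1.0 - q_mid))


def log_rate(params: RateSurfaceParams, de_hb, dn_c, q=1.0):
    """ln k(A->B) under the fitted family."""
    de_hb = np.asarray(de_hb, dtype=float)
    dn_c = np.asarray(dn_c, dtype=float)
    return (
        params.log_k_max
        - _softplus(params.alpha_hb * de_hb)
        - _softplus(-params.alpha_c * dn_c)
        + log_common_contact_factor(q, params.alpha_q, params.q_mid)
    )


class RateSurfaceModel:
    """Weighted nonlinear least squares of ln k on [dE_HB, dN_c, q].

    scikit-learn estimator conventions: constructor stores hyperparameters
    untouched, :meth:`fit` validates and sets trailing-underscore
    attributes, :meth:`predict` returns rates on the linear scale.

    Parameters
    ----------
    fit_common_contact : bool
        Fit the sigmoidal G(q) factor; otherwise G is fixed to 1.
    min_q_spread : float
        Minimum standard deviation of q for G to be identifiable; below
        it a warning is raised and G is fixed to 1.
    """

    def __init__(self, fit_common_contact: bool = True, min_q_spread: float = 0.02):
        self.fit_common_contact = fit_common_contact
        self.min_q_spread = min_q_spread

    def get_params(self, deep: bool = True) -> dict:
        return {
            "fit_common_contact": self.fit_common_contact,
            "min_q_spread": self.min_q_spread,
        }

    def set_params(self, **kwargs) -> "RateSurfaceModel":
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must have columns [dE_HB, dN_c, q]")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        keep = y > 0
        if not np.all(keep):
            warnings.warn(f"dropping {np.sum(~keep)} observations with k <= 0")
        X, y = X[keep], y[keep]
        if len(y) < 6:
            raise ValueError("need at least 6 observations with k > 0")
        for col, name in ((0, "dE_HB"), (1, "dN_c")):
            if np.all(X[:, col] >= 0) or np.all(X[:, col] <= 0):
                raise ValueError(
                    f"observations do not span both signs of {name}; fit is rank-deficient"
                )
        return X, y

    def fit(self, X, y, sample_weight=None) -> "RateSurfaceModel":
        """Fit ln k; ``sample_weight`` are inverse-variance weights on ln k."""
        X, y = self._validate(X, y)
        log_k = np.log(y)
        if sample_weight is None:
            sw = np.ones_like(log_k)
        else:
            sw = np.asarray(sample_weight, dtype=float)[: len(log_k)]
        sqrt_w = np.sqrt(sw)

        fit_g = self.fit_common_contact and float(np.std(X[:, 2])) >= self.min_q_spread
        if self.fit_common_contact and not fit_g:
            warnings.warn("insufficient q spread; common-contact factor fixed to 1")

        de, dn, q = X[:, 0], X[:, 1], X[:, 2]

        def unpack(theta):
            log_k_max, log_a_hb, log_a_c = theta[:3]
            p = RateSurfaceParams(
                log_k_max=log_k_max,
                alpha_hb=np.exp(log_a_hb),
                alpha_c=np.exp(log_a_c),
            )
            if fit_g:
                p.alpha_q = np.exp(theta[3])
                p.q_mid = theta[4]
            return p

        def resid(theta):
            p = unpack(theta)
            return sqrt_w * (log_rate(p, de, dn, q) - log_k)

        theta0 = [float(np.max(log_k)), 0.0, 0.0]
        if fit_g:
            theta0 += [np.log(5.0), 0.5]
        sol = least_squares(resid, theta0, method="lm", max_nfev=20_000)
        self.params_ = unpack(sol.x)
        self.n_obs_ = len(log_k)
        dof = max(self.n_obs_ - len(sol.x), 1)
        s2 = 2.0 * sol.cost / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov_theta = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate fit
            cov_theta = np.full((len(sol.x),) * 2, np.nan)
        # delta method: alphas are fitted on the log scale
        scale = np.ones(len(sol.x))
        scale[1] = self.params_.alpha_hb
        scale[2] = self.params_.alpha_c
        if fit_g:
            scale[3] = self.params_.alpha_q
        self.covariance_ = cov_theta * np.outer(scale, scale)
        self.stderr_ = dict(
            zip(
                ["log_k_max", "alpha_hb", "alpha_c", "alpha_q", "q_mid"][: len(sol.x)],
                np.sqrt(np.diag(self.covariance_)),
            )
        )
        self.residual_rms_ = float(np.sqrt(np.mean((log_rate(self.params_, de, dn, q) - log_k) ** 2)))
        return self

    def predict(self, X) -> np.ndarray:
        """Rates k on the linear scale for rows [dE_HB, dN_c, q]."""
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        return np.exp(log_rate(self.params_, X[:, 0], X[:, 1], X[:, 2]))


def observations_to_arrays(
    observations: list[RateObservation],
    directions: str = "both",
    ln_variance_floor: float = 0.25,
):
    """(X, y, w) arrays from observations; ``directions='both'`` stacks the
    A->B and B->A rows so the fit sees both signs of each difference.

    Weights are inverse variances of ln k, var(ln k) ~ (se/k)^2, with an
    additive variance floor: without it the near-saturated rates (k ~ 1
    measured to a fraction of a percent) would outweigh the informative
    small rates by many orders of magnitude and the fit would be dominated
    by model error rather than measurement error.
    """
    rows = []
    for o in observations:
        rows.append(o)
        if directions == "both":
            rows.append(o.reversed())
    X = np.array([[o.de_hb, o.dn_c, o.q] for o in rows])
    y = np.array([o.k_ab for o in rows])
    se = np.array([o.se_ab if o.se_ab else np.nan for o in rows])
    var_ln = np.where(np.isfinite(se) & (y > 0), (se / np.maximum(y, 1e-300)) ** 2, 0.0)
    w = 1.0 / (var_ln + ln_variance_floor)
    return X, y, w


def fit_rate_surface(
    observations: list[RateObservation],
    fit_common_contact: bool = True,
    alpha_from_ratio: bool = True,
    min_q_spread: float = 0.02,
):
    """Fit the full rate family; returns (params, diagnostics).

    Default is a two-stage fit that respects the family's detailed-balance
    factorization: the log rate *ratios* of each pair depend only on
    (alpha_HB, alpha_c) — every symmetric factor cancels — so those are
    estimated first by the plane regression on ln k_AB - ln k_BA, and the
    symmetric part (log k_max and the common-contact sigmoid) is then fit
    on the stacked ln k with the alphas held fixed.  The equilibrium model
    built from the fitted alphas is thereby consistent with the measured
    fluxes by construction.  ``alpha_from_ratio=False`` falls back to the
    one-stage :class:`RateSurfaceModel` least squares.
    """
    if not alpha_from_ratio:
        X, y, w = observations_to_arrays(observations)
        model = RateSurfaceModel(fit_common_contact=fit_common_contact).fit(
            X, y, sample_weight=w
        )
        return model.params_, {
            "stderr": model.stderr_,
            "covariance": model.covariance_,
            "residual_rms": model.residual_rms_,
            "n_obs": model.n_obs_,
        }

    plane = plane_fit_log_ratio(observations)
    a_hb, a_c = -plane.c_hb, plane.c_c
    if a_hb <= 0 or a_c <= 0:
        warnings.warn(
            "ratio fit produced a non-positive slope; falling back to the one-stage fit"
        )
        return fit_rate_surface(
            observations, fit_common_contact=fit_common_contact, alpha_from_ratio=False
        )

    X, y, w = observations_to_arrays(observations)
    keep = y > 0
    X, y, w = X[keep], y[keep], w[keep]
    de, dn, q = X[:, 0], X[:, 1], X[:, 2]
    target = np.log(y) + _softplus(a_hb * de) + _softplus(-a_c * dn)
    sqrt_w = np.sqrt(w)
    fit_g = fit_common_contact and float(np.std(q)) >= min_q_spread
    if fit_common_contact and not fit_g:
        warnings.warn("insufficient q spread; common-contact factor fixed to 1")

    if fit_g:

        def resid(theta):
            return sqrt_w * (
                theta[0] + log_common_contact_factor(q, np.exp(theta[1]), theta[2]) - target
            )

        sol = least_squares(resid, [float(np.mean(target)), np.log(5.0), 0.5],
                            method="lm", max_nfev=20_000)
        log_k_max, alpha_q, q_mid = float(sol.x[0]), float(np.exp(sol.x[1])), float(sol.x[2])
        n_stage2 = 3
    else:
        log_k_max = float(np.average(target, weights=w))
        alpha_q, q_mid = 0.0, 0.5
        n_stage2 = 1
    params = RateSurfaceParams(
        log_k_max=log_k_max, alpha_hb=a_hb, alpha_c=a_c, alpha_q=alpha_q, q_mid=q_mid
    )
    resid_ln = log_rate(params, de, dn, q) - np.log(y)
    dof = max(len(y) - n_stage2, 1)
    se_k_max = float(
        np.sqrt(np.sum(w * resid_ln**2) / dof / np.sum(w))
    )
    return params, {
        "stderr": {
            "log_k_max": se_k_max,
            "alpha_hb": plane.stderr[0],
            "alpha_c": plane.stderr[1],
        },
        "plane_fit": plane,
        "residual_rms": float(np.sqrt(np.mean(resid_ln**2))),
        "n_obs": len(y),
    }


def fit_common_contact_factor(
    observations: list[RateObservation],
    base_params: RateSurfaceParams,
    min_q_spread: float = 0.02,
) -> RateSurfaceParams:
    """Fit only the G(q) sigmoid with the base surface held fixed."""
    X, y, w = observations_to_arrays(observations)
    keep = y > 0
    X, y, w = X[keep], y[keep], w[keep]
    q = X[:, 2]
    if float(np.std(q)) < min_q_spread:
        warnings.warn("insufficient q spread; common-contact factor fixed to 1")
        return RateSurfaceParams(
            log_k_max=base_params.log_k_max,
            alpha_hb=base_params.alpha_hb,
            alpha_c=base_params.alpha_c,
            alpha_q=0.0,
            q_mid=0.5,
        )
    base = RateSurfaceParams(base_params.log_k_max, base_params.alpha_hb, base_params.alpha_c)
    target = np.log(y) - log_rate(base, X[:, 0], X[:, 1], 1.0)

    def resid(theta):
        return np.sqrt(w) * (log_common_contact_factor(q, np.exp(theta[0]), theta[1]) - target)

    sol = least_squares(resid, [np.log(5.0), 0.5], method="lm", max_nfev=20_000)
    return RateSurfaceParams(
        log_k_max=base_params.log_k_max,
        alpha_hb=base_params.alpha_hb,
        alpha_c=base_params.alpha_c,
        alpha_q=float(np.exp(sol.x[0])),
        q_mid=float(sol.x[1]),
    )


@dataclass
class PlaneFit:
    c_hb: float
    c_c: float
    r_squared: float
    stderr: tuple[float, float] = (np.nan, np.nan)
    n_obs: int = 0
    excluded: int = 0


def plane_fit_log_ratio(
    observations: list[RateObservation],
    weighted: bool = True,
    ln_variance_floor: float = 0.25,
) -> PlaneFit:
    """Least squares of ln k_AB - ln k_BA on (dE_HB, dN_c) through the
    origin; the detailed-balance consistency check requires c_HB close to
    -alpha_HB and c_c close to +alpha_c.  Weights are inverse variances of
    the log ratio (propagated from both rates' standard errors) with an
    additive variance floor."""
    rows = [o for o in observations if o.k_ab > 0 and o.k_ba > 0]
    excluded = len(observations) - len(rows)
    if excluded:
        warnings.warn(f"excluded {excluded} observations with a zero rate")
    if len(rows) < 2:
        raise ValueError("need at least 2 usable observations")
    A = np.array([[o.de_hb, o.dn_c] for o in rows])
    y = np.array([np.log(o.k_ab) - np.log(o.k_ba) for o in rows])
    if weighted:
        var = np.array(
            [
                ((o.se_ab / o.k_ab) ** 2 if o.se_ab else 0.0)
                + ((o.se_ba / o.k_ba) ** 2 if o.se_ba else 0.0)
                for o in rows
            ]
        )
        w = 1.0 / (var + ln_variance_floor)
    else:
        w = np.ones_like(y)
    aw = A * w[:, None]
    coef = np.linalg.solve(A.T @ aw, aw.T @ y)
    pred = A @ coef
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(y) - 2, 1)
    s2 = float(np.sum(w * (y - pred) ** 2) / dof)
    try:
        cov = s2 * np.linalg.inv(A.T @ aw)
        se = tuple(np.sqrt(np.diag(cov)))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = (np.nan, np.nan)
    return PlaneFit(
        c_hb=float(coef[0]),
        c_c=float(coef[1]),
        r_squared=r2,
        stderr=se,
        n_obs=len(rows),
        excluded=excluded,
    )


def equilibrium_probabilities(structures: list[Structure], params: RateSurfaceParams) -> np.ndarray:
    """P_X proportional to exp(-alpha_HB E_HB^X + alpha_c N_c^X), normalized."""
    if not structures:
        raise ValueError("empty structure set")
    logits = np.array(
        [-params.alpha_hb * s.hb_energy + params.alpha_c * s.n_contacts for s in structures]
    )
    return np.exp(logits - logsumexp(logits))
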