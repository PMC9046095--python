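"""Random-effects pooling of jurisdiction log-odds-ratios.

Model: y_i = x_i'beta + u_i + e_i with u_i ~ N(0, tau^2) and
e_i ~ N(0, v_i), v_i the squared within-jurisdiction standard error.
The design is an intercept, optionally plus a narrow-definition
indicator (the definition-type moderator).  tau^2 is estimated by REML
(default; profile maximisation of the restricted likelihood) or by the
DerSimonian-Laird moment estimator generalised to meta-regression.
Coefficients are weighted least squares with weights 1/(v_i + tau^2).

Heterogeneity: Cochran's Q is the weighted residual sum of squares of
the fixed-effect (tau^2 = 0) fit; ``i2`` is the Q-based statistic
max(0, (Q - df)/Q) * 100, and ``i2_tau2`` the tau^2-based variant
100 * tau^2 / (tau^2 + s^2) with s^2 the typical within-study variance
(the form meta-analysis software usually prints).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

_Z95 = stats.norm.ppf(0.975)


class InsufficientStudiesError(ValueError):
    """Too few studies for the requested pooling."""


@dataclass(frozen=True)
class StudyEstimate:
    """One jurisdiction's log-OR with its standard error."""

    jurisdiction: str
    log_or: float
    se: float
    definition_type: str = "broad"  # "broad" | "narrow"

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")
        if self.definition_type not in ("broad", "narrow"):
            raise ValueError(f"unknown definition_type {self.definition_type!r}")


@dataclass
class PooledLevel:
    """Pooled log-OR at one moderator level (or overall)."""

    log_or: float
    se: float

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci(self) -> tuple[float, float]:
        return (
            math.exp(self.log_or - _Z95 * self.se),
            math.exp(self.log_or + _Z95 * self.se),
        )


@dataclass
class MetaResult:
    pooled: dict[str, PooledLevel]  # "overall" or {"broad", "narrow"}
    tau2: float
    Q: float
    df: int
    i2: float
    i2_tau2: float
    k: int
    method: str
    moderator_coef: float | None = None
    moderator_se: float | None = None
    weights: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "tau2": self.tau2,
            "Q": self.Q,
            "df": self.df,
            "i2": self.i2,
            "i2_tau2": self.i2_tau2,
            "k": self.k,
            "method": self.method,
            "moderator_coef": self.moderator_coef,
            "moderator_se": self.moderator_se,
        }
        for level, p in self.pooled.items():
            lo, hi = p.ci
            out[f"or_{level}"] = p.or_
            out[f"or_{level}_ci"] = [lo, hi]
        return out


def se_from_ci(or_: float, ci_low: float, ci_high: float, conf: float = 0.95) -> float:
    """Back-derive the log-OR standard error from a printed symmetric CI.

    se = (ln hi - ln lo) / (2 z); needed to pool published tables that
    print only OR (lo-hi).
    """
    if not (0 < ci_low <= or_ <= ci_high):
        raise ValueError("need 0 < ci_low <= or <= ci_high")
    z = stats.norm.ppf(0.5 + conf / 2)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * z)
    if se <= 0:
        raise ValueError("degenerate CI: zero-width on the log scale")
    return se


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted LS: returns (beta, cov(beta), weighted residual SS)."""
    XtW = X.T * w
    M = XtW @ X
    Minv = np.linalg.inv(M)
    beta = Minv @ (XtW @ y)
    resid = y - X @ beta
    rss = float(resid @ (w * resid))
    return beta, Minv, rss


def _reml_tau2(X: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    """Profile the restricted log-likelihood over tau^2 >= 0."""

    def neg_restricted_ll(log_tau2):
        tau2 = math.exp(log_tau2)
        w = 1.0 / (v + tau2)
        _, Minv, rss = _wls(X, y, w)
        sign, logdet = np.linalg.slogdet(np.linalg.inv(Minv))
        return 0.5 * (np.sum(np.log(v + tau2)) + logdet + rss)

    # tau2=0 boundary handled by comparing with an interior optimum.
    res = minimize_scalar(
        neg_restricted_ll, bounds=(math.log(1e-10), math.log(1e3)), method="bounded",
        options={"xatol": 1e-12},
    )
    tau2_hat = math.exp(res.x)
    if neg_restricted_ll(math.log(1e-12)) <= res.fun:
        return 0.0
    return 0.0 if tau2_hat < 1e-9 else tau2_hat


def _dl_tau2(X: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    """Moment (DerSimonian-Laird) estimator, meta-regression form.

    tau^2 = max(0, (Q_E - (k - p)) / tr(P)) with W = diag(1/v),
    P = W - W X (X'WX)^-1 X'W and Q_E the weighted residual SS.
    """
    k, p = X.shape
    w = 1.0 / v
    _, Minv, rss = _wls(X, y, w)
    W = np.diag(w)
    P = W - W @ X @ Minv @ X.T @ W
    denom = float(np.trace(P))
    return max(0.0, (rss - (k - p)) / denom)


def pool_random_effects(
    estimates: list[StudyEstimate],
    moderator: bool = False,
    method: str = "REML",
    allow_single_study: bool = False,
    fixed_tau2: float | None = None,
) -> MetaResult:
    """Random-effects pooling, optionally moderated by definition type.

    With the moderator on, the model is a meta-regression on a narrow-
    definition indicator and the per-definition pooled ORs are the fitted
    values at each moderator level (broad: intercept; narrow: intercept +
    moderator coefficient), each with its delta-method CI.
    """
    k = len(estimates)
    min_k = (3 if moderator else 2) if not allow_single_study else 1
    if k < min_k:
        raise InsufficientStudiesError(f"need at least {min_k} studies, got {k}")
    if method not in ("REML", "DL"):
        raise ValueError(f"unknown tau2 estimator {method!r}")

    y = np.array([e.log_or for e in estimates])
    v = np.array([e.se**2 for e in estimates])
    narrow = np.array([1.0 if e.definition_type == "narrow" else 0.0 for e in estimates])
    X = np.column_stack([np.ones(k), narrow]) if moderator else np.ones((k, 1))
    if moderator and (narrow.min() == narrow.max()):
        raise ValueError("moderator requested but all studies share one definition type")
    p = X.shape[1]
    if fixed_tau2 is not None:
        if fixed_tau2 < 0:
            raise ValueError("fixed_tau2 must be non-negative")
        tau2 = fixed_tau2
    elif k == 1:
        tau2 = 0.0
    else:
        tau2 = _reml_tau2(X, y, v) if method == "REML" else _dl_tau2(X, y, v)

    w = 1.0 / (v + tau2)
    beta, cov, _ = _wls(X, y, w)

    # Heterogeneity from the fixed-effect (tau2 = 0) residuals.
    _, _, Q = _wls(X, y, 1.0 / v)
    df = k - p
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 1e-10 else 0.0
    # Typical within-study variance: s^2 = (k - p) / tr(P), the Higgins-
    # Thompson form generalised to meta-regression.
    if k > p:
        W0 = np.diag(1.0 / v)
        Pmat = W0 - W0 @ X @ np.linalg.inv(X.T @ W0 @ X) @ X.T @ W0
        s2 = (k - p) / float(np.trace(Pmat))
    else:
        s2 = float(np.mean(v))
    i2_tau2 = 100.0 * tau2 / (tau2 + s2) if (tau2 + s2) > 0 else 0.0

    if moderator:
        var_narrow = cov[0, 0] + cov[1, 1] + 2 * cov[0, 1]
        pooled = {
            "broad": PooledLevel(float(beta[0]), math.sqrt(cov[0, 0])),
            "narrow": PooledLevel(float(beta[0] + beta[1]), math.sqrt(var_narrow)),
        }
        mod_coef, mod_se = float(beta[1]), math.sqrt(cov[1, 1])
    else:
        pooled = {"overall": PooledLevel(float(beta[0]), math.sqrt(cov[0, 0]))}
        mod_coef = mod_se = None

    return MetaResult(
        pooled=pooled,
        tau2=float(tau2),
        Q=float(Q),
        df=df,
        i2=float(i2),
        i2_tau2=float(i2_tau2),
        k=k,
        method=method,
        moderator_coef=mod_coef,
        moderator_se=mod_se,
        weights={e.jurisdiction: float(wi) for e, wi in zip(estimates, w)},
    )
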