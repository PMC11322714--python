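"""Poisson log-link regression by IRLS with robust (sandwich) covariance.

This is the "modified Poisson" workhorse: a Poisson GLM applied to binary
(or count) outcomes, paired with a heteroskedasticity-robust sandwich
variance so that exponentiated coefficients are valid incidence rate
ratios even though a 0/1 outcome is not Poisson distributed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DesignMatrix",
    "PoissonFit",
    "WaldResult",
    "fit_poisson",
    "sandwich_cov",
    "cluster_cov",
    "wald",
]

_Z975 = stats.norm.ppf(0.975)  # 1.959964...


class SeparationWarning(UserWarning):
    """Fitted mean exceeded 1 for a binary outcome at convergence."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class DesignMatrix:
    """Named design matrix for the segmented-regression fits.

    Columns are rejected if collinear: silent dropping would reorder the
    meaning of downstream coefficient positions.
    """

    X: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        if X.ndim != 2 or X.shape[1] != len(self.names):
            raise ValueError("design shape does not match column names")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient (collinear columns)")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            return self.X[:, self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown coefficient name: {name!r}") from None


@dataclass
class PoissonFit:
    """Converged IRLS fit with model-based and sandwich covariances."""

    beta: np.ndarray
    names: tuple[str, ...]
    cov_model: np.ndarray
    cov_robust: np.ndarray
    mu: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    deviance: float
    n_obs: int
    offset: np.ndarray | None = None
    cov_cluster: np.ndarray | None = None
    deviance_trace: list[float] = field(default_factory=list, repr=False)

    def se(self, robust: bool = True) -> np.ndarray:
        cov = self.cov_robust if robust else self.cov_model
        return np.sqrt(np.diag(cov))

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(self.names, self.beta.tolist())),
            "cov_model": self.cov_model.tolist(),
            "cov_robust": self.cov_robust.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "loglik": self.loglik,
            "deviance": self.deviance,
            "n_obs": self.n_obs,
        }


def _poisson_loglik(y, mu):
    # constant term (log y!) omitted from deviance comparisons but kept for loglik
    from scipy.special import gammaln

    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _poisson_deviance(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_poisson(
    design: DesignMatrix,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    cov_type: str = "HC0",
    clusters: np.ndarray | None = None,
) -> PoissonFit:
    """Maximize the Poisson log-likelihood with log link by IRLS.

    Parameters
    ----------
    design : DesignMatrix
        Full-rank named design matrix.
    y : array
        Non-negative outcomes; binary person-day indicators or day counts.
    offset : array, optional
        Log-exposure offset (e.g. ``log(n_users)`` for day-aggregated counts).
    tol : float
        Relative deviance-change convergence tolerance.
    cov_type : {"HC0", "HC1"}
        Flavor of the sandwich covariance stored in ``cov_robust``.
    clusters : array, optional
        Cluster labels (one per row); if given, a cluster-robust covariance
        is stored in ``cov_cluster`` as a sensitivity variance.
    """
    X = design.X
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length does not match design")
    if np.any(y < 0):
        raise ValueError("negative outcome values")
    if n <= p:
        raise ValueError("more parameters than observations")
    if not np.any(y > 0):
        raise ValueError("no events: Poisson fit undefined (log of zero mean)")
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if off.shape != (n,):
        raise ValueError("offset length does not match design")

    # start at intercept = log(mean rate), slopes 0
    beta = np.zeros(p)
    ybar = float(np.mean(y)) / float(np.mean(np.exp(off)))
    beta[0] = np.log(ybar) if "intercept" not in design.names else 0.0
    if "intercept" in design.names:
        beta[design.names.index("intercept")] = np.log(ybar)

    eta = X @ beta + off
    mu = np.exp(eta)
    dev = _poisson_deviance(y, mu)
    trace = [dev]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # working response and weights for the log link: W = mu, z = eta + (y-mu)/mu
        z = (eta - off) + (y - mu) / mu
        WX = X * mu[:, None]
        XtWX = X.T @ WX
        XtWz = WX.T @ z
        try:
            beta = np.linalg.solve(XtWX, XtWz)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular IRLS system at iteration {n_iter}", trace) from exc
        eta = X @ beta + off
        if np.any(eta > 500):
            raise ConvergenceError(f"diverging linear predictor at iteration {n_iter}", trace)
        mu = np.exp(eta)
        dev_new = _poisson_deviance(y, mu)
        trace.append(dev_new)
        # relative deviance criterion, with unit floor so an exact fit
        # (deviance at rounding level) terminates
        if abs(dev_new - dev) <= tol * (abs(dev) + 1.0):
            converged = True
            dev = dev_new
            break
        dev = dev_new
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations (deviance trace attached)", trace
        )
    if np.max(y) <= 1 and np.any(mu > 1 + 1e-12):
        warnings.warn(
            "fitted mean exceeds 1 for a binary outcome (log link permits this)",
            SeparationWarning,
            stacklevel=2,
        )

    bread_inv = np.linalg.inv(X.T @ (X * mu[:, None]))
    cov_model = bread_inv
    fit = PoissonFit(
        beta=beta,
        names=design.names,
        cov_model=cov_model,
        cov_robust=np.empty((p, p)),
        mu=mu,
        converged=converged,
        n_iter=n_iter,
        loglik=_poisson_loglik(y, mu),
        deviance=dev,
        n_obs=n,
        offset=offset,
        deviance_trace=trace,
    )
    fit.cov_robust = sandwich_cov(fit, design, y, flavor=cov_type)
    if clusters is not None:
        fit.cov_cluster = cluster_cov(fit, design, y, clusters)
    return fit


def sandwich_cov(
    fit: PoissonFit, design: DesignMatrix, y: np.ndarray, flavor: str = "HC0"
) -> np.ndarray:
    """Heteroskedasticity-robust covariance B⁻¹ M B⁻¹.

    Bread B = Σ μᵢ xᵢxᵢᵀ (the information), meat M = Σ (yᵢ−μᵢ)² xᵢxᵢᵀ
    (squared score contributions). HC1 applies the n/(n−p) degrees-of-freedom
    inflation; HC0 is the default since person-day samples are large.
    """
    X, mu = design.X, fit.mu
    y = np.asarray(y, dtype=float)
    resid2 = (y - mu) ** 2
    bread = X.T @ (X * mu[:, None])
    if np.linalg.cond(bread) > 1e12:
        raise np.linalg.LinAlgError("singular bread matrix in sandwich estimator")
    meat = X.T @ (X * resid2[:, None])
    bread_inv = np.linalg.inv(bread)
    cov = bread_inv @ meat @ bread_inv
    if flavor == "HC1":
        n, p = X.shape
        cov = cov * n / (n - p)
    elif flavor != "HC0":
        raise ValueError(f"unknown sandwich flavor {flavor!r}")
    return 0.5 * (cov + cov.T)


def cluster_cov(
    fit: PoissonFit, design: DesignMatrix, y: np.ndarray, clusters: np.ndarray
) -> np.ndarray:
    """Cluster-robust sandwich: meat from summed within-cluster scores."""
    X, mu = design.X, fit.mu
    resid = np.asarray(y, dtype=float) - mu
    scores = X * resid[:, None]
    labels, inverse = np.unique(np.asarray(clusters), return_inverse=True)
    g = np.zeros((labels.size, X.shape[1]))
    np.add.at(g, inverse, scores)
    meat = g.T @ g
    bread_inv = np.linalg.inv(X.T @ (X * mu[:, None]))
    cov = bread_inv @ meat @ bread_inv
    return 0.5 * (cov + cov.T)


@dataclass(frozen=True)
class WaldResult:
    name: str
    estimate: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float

    def exp(self) -> "WaldResult":
        """Map to the IRR scale (exponentiate estimate and CI)."""
        return WaldResult(
            self.name,
            float(np.exp(self.estimate)),
            self.se,
            self.z,
            self.p,
            float(np.exp(self.ci_low)),
            float(np.exp(self.ci_high)),
        )


def wald(
    fit: PoissonFit,
    coefficient: str,
    null_value: float = 0.0,
    robust: bool = True,
) -> WaldResult:
    """Normal-approximation Wald test and 95% CI for one coefficient."""
    if coefficient not in fit.names:
        raise KeyError(f"unknown coefficient name: {coefficient!r}")
    i = fit.names.index(coefficient)
    est = float(fit.beta[i])
    se = float(fit.se(robust=robust)[i])
    z = (est - null_value) / se if se > 0 else (0.0 if est == null_value else np.inf)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return WaldResult(coefficient, est, se, float(z), p, est - _Z975 * se, est + _Z975 * se)


def linear_combo_wald(fit: PoissonFit, weights: dict[str, float], robust: bool = True) -> WaldResult:
    """Wald inference for a linear combination Σ wⱼβⱼ (delta method)."""
    w = np.zeros(len(fit.names))
    for name, val in weights.items():
        if name not in fit.names:
            raise KeyError(f"unknown coefficient name: {name!r}")
        w[fit.names.index(name)] = val
    cov = fit.cov_robust if robust else fit.cov_model
    est = float(w @ fit.beta)
    se = float(np.sqrt(w @ cov @ w))
    z = est / se if se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    label = "+".join(f"{v:g}*{k}" for k, v in weights.items())
    return WaldResult(label, est, se, float(z), p, est - _Z975 * se, est + _Z975 * se)
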