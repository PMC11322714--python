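"""Segmented Poisson regression-discontinuity model for person-day panels.

The model for the daily event probability is

    log p(t) = b0 + b1 * (t - c) + b2 * D(t) + b3 * (t - c) * D(t)

with D(t) = 1 at/after the cutoff day c, fitted on person-days within a
symmetric bandwidth window around c. ``exp(b2)`` is the incidence rate
ratio at the lockdown, ``exp(b1)`` the prelockdown daily trend IRR, and
``exp(b1 + b3)`` the lockdown daily trend IRR. Robust (sandwich) standard
errors make the IRRs valid effect measures for the binary outcomes.

Organized statsmodels-style: :class:`PoissonRDD` is the model object,
:meth:`PoissonRDD.fit` returns :class:`RDDResults` with estimates,
uncertainties, a summary table, and recovery/sensitivity/plot methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm
from .bandwidth import BandwidthResult, ik_bandwidth
from .glm import DesignMatrix, PoissonFit, WaldResult
from .panel import AGE_GROUPS, PersonDayPanel

__all__ = [
    "PoissonRDD",
    "RDDResults",
    "fit_rdd",
    "irr_to_percent_change",
    "sensitivity_scan",
]

COLUMN_NAMES = ("intercept", "time_c", "lockdown", "time_c:lockdown")


def irr_to_percent_change(irr: float) -> float:
    """Signed percent decrease implied by an IRR: (1 - irr) * 100, to 1 dp.

    0.4152 -> 58.5 (% decrease); values above 1 come out negative
    (an increase)."""
    if irr <= 0:
        raise ValueError(f"IRR must be positive, got {irr}")
    return round((1.0 - irr) * 100.0, 1)


def _window_days(cutoff_day: int, bandwidth_days: int, study_days: int) -> np.ndarray:
    lo = max(0, cutoff_day - bandwidth_days)
    hi = min(study_days - 1, cutoff_day + bandwidth_days)
    return np.arange(lo, hi + 1)


def _design_for_days(days: np.ndarray, cutoff_day: int) -> DesignMatrix:
    t_c = days.astype(float) - cutoff_day
    lock = (days >= cutoff_day).astype(float)
    X = np.column_stack([np.ones(days.size), t_c, lock, t_c * lock])
    return DesignMatrix(X, COLUMN_NAMES)


def _binary_sandwich_from_days(
    fit: PoissonFit, design: DesignMatrix, counts: np.ndarray, n_users: int,
    flavor: str = "HC0",
) -> np.ndarray:
    """Exact person-day HC0/HC1 sandwich from day-level sufficient statistics.

    For binary person-day outcomes with fitted means constant within a day
    (the design only has day-level covariates), the person-day meat is
    Σ_t x_t x_tᵀ [Y_t (1 - 2 p_t) + n p_t²]; the bread coincides with the
    day-count bread.
    """
    X = design.X
    mu_day = fit.mu  # fitted day-level count means
    p = mu_day / n_users
    meat_w = counts * (1.0 - 2.0 * p) + n_users * p**2
    bread = X.T @ (X * mu_day[:, None])
    meat = X.T @ (X * meat_w[:, None])
    bread_inv = np.linalg.inv(bread)
    cov = bread_inv @ meat @ bread_inv
    if flavor == "HC1":
        n_pd = n_users * X.shape[0]
        cov = cov * n_pd / (n_pd - X.shape[1])
    return 0.5 * (cov + cov.T)


@dataclass
class RDDResults:
    """Estimates from one outcome x bandwidth x stratum discontinuity fit."""

    outcome: str
    stratum: str
    bandwidth_days: int
    cutoff_day: int
    fit: PoissonFit
    n_users: int
    irr_baseline: WaldResult        # rate at day 0, extrapolated to study start
    irr_local_intercept: WaldResult  # exp(b0): rate on the last pre-cutoff day scale
    irr_jump: WaldResult
    irr_pre_trend: WaldResult
    irr_post_trend: WaldResult
    p_trend_change: float
    p_trend_change_model: float
    bandwidth_info: BandwidthResult | None = None

    # -- convenience accessors -------------------------------------------------
    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.fit.names, self.fit.beta))

    @property
    def bse_robust(self) -> dict[str, float]:
        return dict(zip(self.fit.names, self.fit.se(robust=True)))

    @property
    def percent_change_at_lockdown(self) -> float:
        return irr_to_percent_change(self.irr_jump.estimate)

    def recovery(self, horizon_days: float = 999.0):
        """Days after the cutoff until the fitted post curve crosses the
        extrapolated prelockdown counterfactual."""
        from .recovery import crossing_time

        b = self.params
        return crossing_time(
            b["lockdown"], b["time_c:lockdown"], horizon_days=horizon_days,
            outcome=self.outcome, stratum=self.stratum,
        )

    def to_dict(self) -> dict:
        def _w(w: WaldResult) -> dict:
            return {"irr": w.estimate, "ci_low": w.ci_low, "ci_high": w.ci_high,
                    "p": w.p}

        return {
            "outcome": self.outcome,
            "stratum": self.stratum,
            "bandwidth_days": self.bandwidth_days,
            "cutoff_day": self.cutoff_day,
            "n_users": self.n_users,
            "coefficients": self.params,
            "robust_se": self.bse_robust,
            "irr_baseline": _w(self.irr_baseline),
            "irr_jump": _w(self.irr_jump),
            "irr_pre_trend": _w(self.irr_pre_trend),
            "irr_post_trend": _w(self.irr_post_trend),
            "p_trend_change": self.p_trend_change,
            "p_trend_change_model": self.p_trend_change_model,
            "percent_change_at_lockdown": self.percent_change_at_lockdown,
        }

    def summary(self) -> str:
        rows = [
            ("IRR at baseline (day 0)", self.irr_baseline),
            ("IRR at the lockdown", self.irr_jump),
            ("IRR per day (prelockdown)", self.irr_pre_trend),
            ("IRR per day (lockdown)", self.irr_post_trend),
        ]
        lines = [
            f"Poisson RDD fit — outcome={self.outcome}, stratum={self.stratum}",
            f"bandwidth={self.bandwidth_days} days, cutoff=day {self.cutoff_day}, "
            f"users={self.n_users}",
            "-" * 72,
            f"{'quantity':<28}{'IRR':>10}{'95% CI':>22}{'p':>10}",
        ]
        for label, w in rows:
            ci = f"({w.ci_low:.4f}, {w.ci_high:.4f})"
            lines.append(f"{label:<28}{w.estimate:>10.4f}{ci:>22}{w.p:>10.2g}")
        lines.append(
            f"{'change at lockdown':<28}{self.percent_change_at_lockdown:>9.1f}% decrease"
        )
        lines.append(f"p (slope change, robust) = {self.p_trend_change:.3g}")
        return "\n".join(lines)

    def plot(self, panel: PersonDayPanel | None = None, ax=None):
        """Daily counts with the fitted segmented curve and the extrapolated
        prelockdown counterfactual."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        b = self.params
        c = self.cutoff_day
        t = np.arange(0, c + 2 * self.bandwidth_days)
        pre = np.exp(b["intercept"] + b["time_c"] * (t - c))
        post = np.exp(
            b["intercept"] + b["lockdown"]
            + (b["time_c"] + b["time_c:lockdown"]) * (t - c)
        )
        if panel is not None:
            counts = panel.daily_counts(self.stratum)
            n = panel.stratum_size(self.stratum)
            ax.plot(np.arange(counts.size), counts / n, ".", ms=3, alpha=0.5,
                    label="daily rate")
        ax.plot(t[t < c], pre[t < c], "r-", label="fitted (pre)")
        ax.plot(t[t >= c], post[t >= c], "r-", label="fitted (lockdown)")
        ax.plot(t[t >= c], pre[t >= c], "k--", lw=1, label="counterfactual")
        ax.axvline(c, color="b", ls=":", lw=1)
        ax.set_xlabel("day of study")
        ax.set_ylabel("events per person-day")
        ax.set_title(f"{self.outcome} ({self.stratum}), h={self.bandwidth_days}d")
        ax.legend(fontsize=8)
        return ax


class PoissonRDD:
    """Regression-discontinuity-in-time model for one outcome panel.

    Parameters
    ----------
    panel : PersonDayPanel
        Dense binary person-day panel for a single outcome.
    cutoff_day : int, optional
        Zero-based first lockdown day; defaults to the panel's cutoff.
    bandwidth : int or "ik"
        Symmetric window half-width in days, or "ik" for data-driven
        Imbens-Kalyanaraman selection on the daily rate series.
    stratum : str
        "all" or one of the age groups.
    """

    def __init__(
        self,
        panel: PersonDayPanel,
        cutoff_day: int | None = None,
        bandwidth: int | str = "ik",
        stratum: str = "all",
    ):
        self.panel = panel
        self.cutoff_day = panel.cutoff_day if cutoff_day is None else int(cutoff_day)
        self.bandwidth = bandwidth
        self.stratum = stratum
        self._bandwidth_info: BandwidthResult | None = None

    def select_bandwidth(self, kernel: str = "uniform") -> BandwidthResult:
        n = self.panel.stratum_size(self.stratum)
        rates = self.panel.daily_counts(self.stratum) / n
        self._bandwidth_info = ik_bandwidth(rates, self.cutoff_day, kernel=kernel)
        return self._bandwidth_info

    def fit(
        self,
        cov_type: str = "HC0",
        engine: str = "aggregate",
        cluster_by_user: bool = False,
    ) -> RDDResults:
        if self.bandwidth == "ik":
            bw = self.select_bandwidth().h_opt
        else:
            bw = int(self.bandwidth)
            if bw <= 0:
                raise ValueError("bandwidth must be positive")
        return self._fit_at(bw, cov_type=cov_type, engine=engine,
                            cluster_by_user=cluster_by_user)

    def _fit_at(self, bandwidth_days: int, cov_type: str = "HC0",
                engine: str = "aggregate", cluster_by_user: bool = False) -> RDDResults:
        panel, c = self.panel, self.cutoff_day
        days = _window_days(c, bandwidth_days, panel.study_days)
        mask = panel._mask(self.stratum)
        n_users = int(mask.sum())
        if n_users == 0:
            raise ValueError(f"no users in stratum {self.stratum!r}")
        y_sub = panel.y[mask][:, days]
        counts = y_sub.sum(axis=0).astype(float)
        pre, post = days < c, days >= c
        if counts[pre].sum() == 0 or counts[post].sum() == 0:
            raise ValueError(
                f"zero {panel.outcome} events on one side of the cutoff "
                f"within bandwidth {bandwidth_days}"
            )
        design = _design_for_days(days, c)
        if engine == "aggregate":
            if cluster_by_user:
                raise ValueError("cluster-by-user variance needs engine='persondays'")
            offset = np.full(days.size, np.log(n_users))
            fit = glm.fit_poisson(design, counts, offset=offset, cov_type=cov_type)
            fit.cov_robust = _binary_sandwich_from_days(
                fit, design, counts, n_users, flavor=cov_type
            )
        elif engine == "persondays":
            Xd = design.X
            X_full = np.repeat(Xd, n_users, axis=0)
            y_full = y_sub.T.ravel().astype(float)  # day-major to match repeat
            clusters = None
            if cluster_by_user:
                clusters = np.tile(np.arange(n_users), days.size)
            design_full = DesignMatrix(X_full, COLUMN_NAMES)
            fit = glm.fit_poisson(design_full, y_full, cov_type=cov_type,
                                  clusters=clusters)
        else:
            raise ValueError(f"unknown engine {engine!r}")

        irr_jump = glm.wald(fit, "lockdown").exp()
        irr_pre = glm.wald(fit, "time_c").exp()
        irr_post = glm.linear_combo_wald(
            fit, {"time_c": 1.0, "time_c:lockdown": 1.0}
        ).exp()
        # extrapolate the pre-segment to day 0 (running variable = -cutoff)
        irr_base = glm.linear_combo_wald(
            fit, {"intercept": 1.0, "time_c": -float(c)}
        ).exp()
        irr_local = glm.wald(fit, "intercept").exp()
        w_inter = glm.wald(fit, "time_c:lockdown")
        w_inter_model = glm.wald(fit, "time_c:lockdown", robust=False)
        res = RDDResults(
            outcome=panel.outcome,
            stratum=self.stratum,
            bandwidth_days=bandwidth_days,
            cutoff_day=c,
            fit=fit,
            n_users=n_users,
            irr_baseline=irr_base,
            irr_local_intercept=irr_local,
            irr_jump=irr_jump,
            irr_pre_trend=irr_pre,
            irr_post_trend=irr_post,
            p_trend_change=w_inter.p,
            p_trend_change_model=w_inter_model.p,
            bandwidth_info=self._bandwidth_info,
        )
        return res


def fit_rdd(
    panel: PersonDayPanel,
    cutoff_day: int | None = None,
    bandwidth_days: int | str = "ik",
    stratum: str = "all",
    cov_type: str = "HC0",
    engine: str = "aggregate",
) -> RDDResults:
    """Functional entry point: build a :class:`PoissonRDD` and fit it."""
    model = PoissonRDD(panel, cutoff_day=cutoff_day, bandwidth=bandwidth_days,
                       stratum=stratum)
    return model.fit(cov_type=cov_type, engine=engine)


def sensitivity_scan(
    panel: PersonDayPanel,
    cutoff_day: int | None = None,
    h_opt: int | None = None,
    delta: int = 20,
    step: int = 5,
    stratum: str = "all",
    cov_type: str = "HC0",
) -> pd.DataFrame:
    """Refit across bandwidths h_opt-delta ... h_opt+delta.

    Returns one row per bandwidth with the jump IRR, its CI, and a flag for
    sign changes of the log-jump relative to the h_opt fit. Individual refit
    failures are recorded (status column) and the scan continues.
    """
    model = PoissonRDD(panel, cutoff_day=cutoff_day, bandwidth="ik", stratum=stratum)
    if h_opt is None:
        h_opt = model.select_bandwidth().h_opt
    if h_opt - delta < 2:
        raise ValueError(f"h_opt - delta = {h_opt - delta} below minimum viable bandwidth")
    ref_sign = None
    rows = []
    for h in range(h_opt - delta, h_opt + delta + 1, max(step, 1)):
        row: dict = {"bandwidth_days": h, "is_h_opt": h == h_opt}
        try:
            res = model._fit_at(h, cov_type=cov_type)
        except Exception as exc:  # record and continue per contract
            row.update(status=f"failed: {exc}", irr_jump=np.nan,
                       ci_low=np.nan, ci_high=np.nan, p=np.nan, sign_flip=False)
            rows.append(row)
            continue
        lj = np.log(res.irr_jump.estimate)
        if ref_sign is None:
            ref_sign = np.sign(lj)
        row.update(
            status="ok",
            irr_jump=res.irr_jump.estimate,
            ci_low=res.irr_jump.ci_low,
            ci_high=res.irr_jump.ci_high,
            p=res.irr_jump.p,
            percent_change=irr_to_percent_change(res.irr_jump.estimate),
            sign_flip=bool(np.sign(lj) != ref_sign and lj != 0),
        )
        rows.append(row)
    return pd.DataFrame(rows)
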