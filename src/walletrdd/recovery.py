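"""Counterfactual recovery times after the lockdown discontinuity.

The prelockdown fitted log-rate extrapolated past the cutoff is the
counterfactual; the post-cutoff fitted log-rate differs from it by
b2 + b3 * s at s days after the cutoff. The curves cross at

    s* = -b2 / b3

when the jump and the slope change have opposite signs and s* is within
the horizon; otherwise the outcome never recovers. Non-recovery is
exported with the sentinel 999 (which is also the default horizon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import AGE_GROUPS, PersonDayPanel

__all__ = ["RecoveryResult", "crossing_time", "recovery_by_age", "NEVER_CODE"]

NEVER_CODE = 999


@dataclass(frozen=True)
class RecoveryResult:
    outcome: str
    stratum: str
    crossing_days_after_cutoff: float | None  # None = never
    method: str  # "closed_form" or "numeric"
    horizon_days: float = float(NEVER_CODE)

    @property
    def never(self) -> bool:
        return self.crossing_days_after_cutoff is None

    @property
    def export_value(self) -> float:
        """Tabular encoding: crossing days, or the 999 sentinel for never."""
        return float(NEVER_CODE) if self.never else self.crossing_days_after_cutoff


def _crossing_closed_form(beta2: float, beta3: float, horizon: float) -> float | None:
    if beta2 == 0.0:
        return 0.0
    if beta3 == 0.0:
        return None  # parallel lines never meet
    s = -beta2 / beta3
    if s < 0 or s > horizon:
        return None
    return float(s)


def _crossing_numeric(beta2: float, beta3: float, horizon: float) -> float | None:
    """Bisection on the log-rate gap g(s) = beta2 + beta3 * s over [0, horizon]."""
    if beta2 == 0.0:
        return 0.0
    g0 = beta2
    g1 = beta2 + beta3 * horizon
    if g0 * g1 > 0:
        return None
    lo, hi = 0.0, float(horizon)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        gm = beta2 + beta3 * mid
        if gm == 0.0:
            return mid
        if np.sign(gm) == np.sign(g0):
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    return 0.5 * (lo + hi)


def crossing_time(
    beta2: float,
    beta3: float,
    horizon_days: float = float(NEVER_CODE),
    method: str = "closed_form",
    outcome: str = "",
    stratum: str = "all",
) -> RecoveryResult:
    """Days after the cutoff at which the post-cutoff fitted rate crosses
    the extrapolated prelockdown counterfactual."""
    if not (np.isfinite(beta2) and np.isfinite(beta3)):
        raise ValueError("coefficients must be finite")
    if horizon_days <= 0:
        raise ValueError("horizon must be positive")
    if method == "closed_form":
        s = _crossing_closed_form(beta2, beta3, horizon_days)
    elif method == "numeric":
        s = _crossing_numeric(beta2, beta3, horizon_days)
    else:
        raise ValueError(f"unknown method {method!r}")
    return RecoveryResult(outcome, stratum, s, method, float(horizon_days))


def recovery_by_age(
    panels: dict[str, PersonDayPanel],
    cutoff_day: int | None = None,
    bandwidths: dict[str, int] | str = "auto",
    horizon_days: float = float(NEVER_CODE),
    reselect_per_stratum: bool = False,
    cov_type: str = "HC0",
) -> pd.DataFrame:
    """Recovery table per outcome x stratum (pooled row included).

    ``bandwidths`` maps outcome name to a fixed half-width, or "auto" for
    IK selection on the pooled daily rates per outcome. Age-stratified fits
    reuse the pooled bandwidth unless ``reselect_per_stratum``. Strata where
    the fit is impossible (no events on one side) are recorded with status
    "inestimable" — distinct from the 999 never sentinel.
    """
    from .rdd import PoissonRDD

    rows = []
    for outcome, panel in panels.items():
        if bandwidths == "auto":
            h = PoissonRDD(panel, cutoff_day=cutoff_day).select_bandwidth().h_opt
        else:
            h = int(bandwidths[outcome])
        for stratum in ("all", *AGE_GROUPS):
            h_strat = h
            row = {"outcome": outcome, "stratum": stratum, "bandwidth_days": h_strat}
            try:
                model = PoissonRDD(panel, cutoff_day=cutoff_day, bandwidth=h_strat,
                                   stratum=stratum)
                if reselect_per_stratum and stratum != "all":
                    h_strat = model.select_bandwidth().h_opt
                    model.bandwidth = h_strat
                    row["bandwidth_days"] = h_strat
                res = model.fit(cov_type=cov_type)
            except (ValueError, RuntimeError) as exc:
                row.update(status="inestimable", detail=str(exc),
                           crossing_days=np.nan, export_code=np.nan)
                rows.append(row)
                continue
            rec = res.recovery(horizon_days=horizon_days)
            row.update(
                status="ok",
                detail="",
                crossing_days=np.nan if rec.never else rec.crossing_days_after_cutoff,
                export_code=rec.export_value,
                irr_jump=res.irr_jump.estimate,
                irr_pre_trend=res.irr_pre_trend.estimate,
                irr_post_trend=res.irr_post_trend.estimate,
            )
            rows.append(row)
    return pd.DataFrame(rows)
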