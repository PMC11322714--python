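"""Synthetic person-day event panels with a known discontinuity.

The generator emulates the structure of a fixed maternal-health-wallet
cohort (~3416 users over 240 days) whose daily event probability is
piecewise log-linear in time with a multiplicative jump at the lockdown
cutoff (day 82):

    p(t) = b * g_pre^t                          for t < c
    p(t) = b * g_pre^c * J * g_post^(t - c)     for t >= c

Events are independent Bernoulli draws per (user, day) given p(t), with
the wallet-system constraints enforced (at most one payment per user over
the study period, at most one voucher per user per day). The generating
coefficients are returned alongside the panel so parameter recovery can be
tested against exact ground truth.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .panel import AGE_GROUPS, OUTCOMES, PersonDayPanel, assign_age_group
from .stringency import INDICATOR_BOUNDS, INDICATOR_NAMES, StringencySeries

__all__ = [
    "OutcomeParams",
    "AgeModel",
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_panel",
    "simulate_stringency",
    "write_transaction_log",
    "write_registry",
]

DEFAULT_START = dt.date(2020, 1, 1)


@dataclass(frozen=True)
class OutcomeParams:
    """Piecewise log-linear rate parameters for one outcome."""

    baseline_rate: float  # probability per person-day at day 0
    pre_trend_irr: float  # daily multiplicative trend before the cutoff
    jump_irr: float       # multiplicative level change at the cutoff
    post_trend_irr: float  # daily multiplicative trend at/after the cutoff

    def __post_init__(self):
        if not 0 < self.baseline_rate < 1:
            raise ValueError(f"baseline_rate must be in (0,1): {self.baseline_rate}")
        for name in ("pre_trend_irr", "jump_irr", "post_trend_irr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rate_curve(self, study_days: int, cutoff_day: int) -> np.ndarray:
        t = np.arange(study_days)
        pre = self.baseline_rate * self.pre_trend_irr ** t
        post = (
            self.baseline_rate
            * self.pre_trend_irr ** cutoff_day
            * self.jump_irr
            * self.post_trend_irr ** (t - cutoff_day)
        )
        return np.where(t < cutoff_day, pre, post)


#: Defaults reproduce the published pooled estimates for the three outcomes.
DEFAULT_OUTCOME_PARAMS: dict[str, OutcomeParams] = {
    "saving": OutcomeParams(0.0090, 1.0124, 0.4152, 1.0113),
    "payment": OutcomeParams(0.0026, 1.0111, 0.5412, 1.0054),
    "voucher": OutcomeParams(0.0051, 1.0034, 0.5047, 1.0067),
}


@dataclass(frozen=True)
class AgeModel:
    """Discretized log-normal age distribution calibrated to median and IQR."""

    median_years: float = 26.0
    iqr_years: float = 9.0
    group_boundaries: tuple[int, int] = (25, 30)

    def lognormal_params(self) -> tuple[float, float]:
        # median = exp(mu); IQR = 2 * median * sinh(0.6745 * sigma)
        mu = float(np.log(self.median_years))
        z75 = 0.6744897501960817
        sigma = float(np.arcsinh(self.iqr_years / (2.0 * self.median_years)) / z75)
        return mu, sigma

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        mu, sigma = self.lognormal_params()
        ages = np.rint(rng.lognormal(mu, sigma, size=n)).astype(int)
        return np.clip(ages, 13, 55)


@dataclass
class SimulationConfig:
    n_users: int = 3416
    study_days: int = 240
    cutoff_day: int = 82
    outcomes: dict[str, OutcomeParams] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_PARAMS)
    )
    age_model: AgeModel = field(default_factory=AgeModel)
    #: per-age-group multiplicative overrides, e.g. {"<25": {"jump_irr": 0.3}}
    age_group_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    max_payments_per_user: int = 1
    max_vouchers_per_user_day: int = 1
    #: when True each user gets an enrollment day uniform on [0, cutoff_day]
    #: and contributes structural zeros before it (ongoing-enrollment convention)
    simulate_enrollment: bool = False
    start_date: dt.date = DEFAULT_START
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        if self.n_users <= 0 or self.study_days <= 0:
            raise ValueError("n_users and study_days must be positive")
        if not 0 <= self.cutoff_day < self.study_days:
            raise ValueError("cutoff_day must lie inside the study window")
        for group in self.age_group_overrides:
            if group not in AGE_GROUPS:
                raise ValueError(f"unknown age group in overrides: {group!r}")

    def group_params(self, outcome: str, group: str) -> OutcomeParams:
        base = self.outcomes[outcome]
        override = self.age_group_overrides.get(group, {})
        fields_ = {k: getattr(base, k) for k in
                   ("baseline_rate", "pre_trend_irr", "jump_irr", "post_trend_irr")}
        for key, val in override.items():
            if key not in fields_:
                raise ValueError(f"unknown override parameter {key!r}")
            fields_[key] = val
        return OutcomeParams(**fields_)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = dict(raw)
        if "outcomes" in kwargs:
            kwargs["outcomes"] = {
                k: OutcomeParams(**v) for k, v in kwargs["outcomes"].items()
            }
        if "age_model" in kwargs:
            am = dict(kwargs["age_model"])
            if "group_boundaries" in am:
                am["group_boundaries"] = tuple(am["group_boundaries"])
            kwargs["age_model"] = AgeModel(**am)
        if "start_date" in kwargs and isinstance(kwargs["start_date"], str):
            kwargs["start_date"] = dt.date.fromisoformat(kwargs["start_date"])
        known = cls.__dataclass_fields__.keys()
        unknown = set(kwargs) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass(frozen=True)
class TruthBlock:
    """Generating log-linear coefficients for one outcome/age-group cell."""

    intercept: float
    pre_slope: float
    log_jump: float
    post_slope: float

    @property
    def crossing_day(self) -> float | None:
        """Implied day (post-cutoff) where the post curve meets the
        extrapolated pre-cutoff counterfactual, if it exists."""
        delta = self.post_slope - self.pre_slope
        if self.log_jump == 0:
            return 0.0
        if delta == 0 or np.sign(self.log_jump) == np.sign(delta):
            return None
        return float(-self.log_jump / delta)


@dataclass(frozen=True)
class SimulatedTruth:
    """Exact generating coefficients per outcome (pooled and by age group)."""

    blocks: dict[tuple[str, str], TruthBlock]  # key: (outcome, group or "all")

    def block(self, outcome: str, group: str = "all") -> TruthBlock:
        return self.blocks[(outcome, group)]


def _truth_from_params(p: OutcomeParams) -> TruthBlock:
    return TruthBlock(
        intercept=float(np.log(p.baseline_rate)),
        pre_slope=float(np.log(p.pre_trend_irr)),
        log_jump=float(np.log(p.jump_irr)),
        post_slope=float(np.log(p.post_trend_irr)),
    )


def _substream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def simulate_panel(config: SimulationConfig):
    """Draw the per-outcome person-day panels.

    Returns ``(panels, truth)`` where ``panels`` maps outcome name to a
    :class:`PersonDayPanel` (shared user registry) and ``truth`` carries the
    exact generating coefficients. Identical config + seed give a
    byte-identical result.
    """
    rng_ages = _substream(config.seed, 0)
    ages = config.age_model.draw(config.n_users, rng_ages)
    users = pd.DataFrame(
        {
            "user_id": [f"u{i:05d}" for i in range(config.n_users)],
            "age_years": ages,
            "age_group": [assign_age_group(a, config.age_model.group_boundaries)
                          for a in ages],
        }
    )
    enroll_day = np.zeros(config.n_users, dtype=int)
    if config.simulate_enrollment:
        rng_enroll = _substream(config.seed, 1)
        enroll_day = rng_enroll.integers(0, config.cutoff_day + 1, size=config.n_users)

    panels: dict[str, PersonDayPanel] = {}
    blocks: dict[tuple[str, str], TruthBlock] = {}
    for k, outcome in enumerate(OUTCOMES):
        if outcome not in config.outcomes:
            continue
        rng = _substream(config.seed, 10 + k)
        p_matrix = np.empty((config.n_users, config.study_days))
        blocks[(outcome, "all")] = _truth_from_params(config.outcomes[outcome])
        for group in AGE_GROUPS:
            params = config.group_params(outcome, group)
            curve = params.rate_curve(config.study_days, config.cutoff_day)
            if np.any(curve >= 1.0):
                bad = int(np.argmax(curve >= 1.0))
                raise ValueError(
                    f"{outcome}/{group}: event probability reaches "
                    f"{curve[bad]:.3f} >= 1 at day {bad}"
                )
            mask = users["age_group"].to_numpy() == group
            p_matrix[mask] = curve
            blocks[(outcome, group)] = _truth_from_params(params)
        y = (rng.random((config.n_users, config.study_days)) < p_matrix).astype(np.uint8)
        if config.simulate_enrollment:
            day_grid = np.arange(config.study_days)[None, :]
            y[day_grid < enroll_day[:, None]] = 0
        if outcome == "payment" and config.max_payments_per_user == 1:
            # keep-first suppression: zero everything after a user's first payment
            first = np.cumsum(y, axis=1)
            y = ((y == 1) & (first == 1)).astype(np.uint8)
        panels[outcome] = PersonDayPanel(
            users=users, y=y, outcome=outcome,
            cutoff_day=config.cutoff_day, start_date=config.start_date,
        )
    return panels, SimulatedTruth(blocks)


def simulate_stringency(
    cutoff_day: int,
    study_days: int,
    pre_levels=(0,) * 8,
    post_levels=INDICATOR_BOUNDS,
    start_date: dt.date = DEFAULT_START,
) -> StringencySeries:
    """Step-function policy series: pre_levels before the cutoff day,
    post_levels at and after it."""
    for label, levels in (("pre", pre_levels), ("post", post_levels)):
        if len(levels) != 8:
            raise ValueError(f"{label}_levels must have 8 entries")
        for name, bound, v in zip(INDICATOR_NAMES, INDICATOR_BOUNDS, levels):
            if not (0 <= int(v) <= bound) or int(v) != v:
                raise ValueError(f"{label} level for {name} out of range [0,{bound}]: {v}")
    daily = [tuple(pre_levels) if t < cutoff_day else tuple(post_levels)
             for t in range(study_days)]
    return StringencySeries.from_levels(start_date, daily)


def write_transaction_log(panels: dict[str, PersonDayPanel], path) -> None:
    """Emit the delimited transaction log the panel module consumes
    (UTF-8, header row, ISO-8601 dates; one row per event)."""
    rows = []
    for outcome, panel in panels.items():
        users_arr = panel.users["user_id"].to_numpy()
        uu, tt = np.nonzero(panel.y)
        for u, t in zip(uu, tt):
            rows.append(
                {
                    "user_id": users_arr[u],
                    "date": (panel.start_date + dt.timedelta(days=int(t))).isoformat(),
                    "event_type": outcome,
                    "amount": "",
                }
            )
    df = pd.DataFrame(rows, columns=["user_id", "date", "event_type", "amount"])
    df = df.sort_values(["date", "user_id", "event_type"]).reset_index(drop=True)
    df.to_csv(path, index=False)


def write_registry(panels: dict[str, PersonDayPanel], path,
                   enrollment_date: dt.date | None = None) -> None:
    panel = next(iter(panels.values()))
    out = panel.users[["user_id", "age_years"]].copy()
    out["enrollment_date"] = (enrollment_date or panel.start_date).isoformat()
    out.to_csv(path, index=False)
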