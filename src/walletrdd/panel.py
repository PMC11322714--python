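"""Person-day panel construction from transaction logs and a user registry.

The unit of analysis is the person-day: every (user, day) cell of a fixed
cohort observed over the full study window carries a binary indicator per
outcome (saving / payment / voucher). Days without a recorded event are
structural zeros — the panel is dense by construction, so there are no
missing cells.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OUTCOMES",
    "AGE_GROUPS",
    "TransactionEvent",
    "UserRecord",
    "PersonDayPanel",
    "load_events",
    "load_registry",
    "validate_constraints",
    "binarize",
    "assign_age_group",
    "summarize",
]

log = logging.getLogger(__name__)

OUTCOMES = ("saving", "payment", "voucher")
AGE_GROUPS = ("<25", "25-30", ">30")
DEFAULT_START = dt.date(2020, 1, 1)
DEFAULT_STUDY_DAYS = 240
DEFAULT_CUTOFF_DAY = 82  # 2020-03-23, zero-based from 2020-01-01


@dataclass(frozen=True)
class TransactionEvent:
    user_id: str
    date: dt.date
    event_type: str
    amount: float | None = None

    def __post_init__(self):
        if self.event_type not in OUTCOMES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.amount is not None and self.amount < 0:
            raise ValueError("negative amount")


def assign_age_group(age_years: int, boundaries: tuple[int, int] = (25, 30)) -> str:
    """Map integer age to its stratum: <25, 25-30 (closed interval), >30."""
    if age_years <= 0:
        raise ValueError(f"non-positive age: {age_years}")
    if age_years < 10 or age_years > 60:
        warnings.warn(f"implausible age {age_years} for a maternal-health cohort", stacklevel=2)
    lo, hi = boundaries
    if age_years < lo:
        return AGE_GROUPS[0]
    if age_years <= hi:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


@dataclass(frozen=True)
class UserRecord:
    user_id: str
    age_years: int
    age_group: str = ""

    def __post_init__(self):
        group = self.age_group or assign_age_group(self.age_years)
        if group != assign_age_group(self.age_years):
            raise ValueError(
                f"age_group {self.age_group!r} inconsistent with age {self.age_years}"
            )
        object.__setattr__(self, "age_group", group)


@dataclass
class PersonDayPanel:
    """Dense binary outcome matrix: rows = users, columns = day indices.

    ``y`` has shape (n_users, study_days) with values in {0, 1}. Day indices
    are zero-based from the study start (day 82 = first lockdown day, which
    belongs to the lockdown side).
    """

    users: pd.DataFrame  # columns: user_id, age_years, age_group
    y: np.ndarray
    outcome: str
    cutoff_day: int = DEFAULT_CUTOFF_DAY
    start_date: dt.date = DEFAULT_START

    def __post_init__(self):
        self.y = np.ascontiguousarray(self.y, dtype=np.uint8)
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.y.shape[0] != len(self.users):
            raise ValueError("y rows do not match registry")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("panel values must be binary")
        if not 0 <= self.cutoff_day < self.study_days:
            raise ValueError("cutoff_day outside study window")

    @property
    def n_users(self) -> int:
        return self.y.shape[0]

    @property
    def study_days(self) -> int:
        return self.y.shape[1]

    @property
    def n_person_days(self) -> int:
        return self.y.size

    def daily_counts(self, stratum: str | None = None) -> np.ndarray:
        """Event count per day, optionally within one age group."""
        return self.y[self._mask(stratum)].sum(axis=0)

    def stratum_size(self, stratum: str | None = None) -> int:
        return int(self._mask(stratum).sum())

    def _mask(self, stratum: str | None) -> np.ndarray:
        if stratum is None or stratum == "all":
            return np.ones(self.n_users, dtype=bool)
        if stratum not in AGE_GROUPS:
            raise ValueError(f"unknown stratum {stratum!r}")
        return (self.users["age_group"] == stratum).to_numpy()

    def to_long(self) -> pd.DataFrame:
        """Long format (user_id, day_index, outcome, y) for export."""
        uid = np.repeat(self.users["user_id"].to_numpy(), self.study_days)
        day = np.tile(np.arange(self.study_days), self.n_users)
        return pd.DataFrame(
            {"user_id": uid, "day_index": day, "outcome": self.outcome, "y": self.y.ravel()}
        )


def load_registry(path) -> pd.DataFrame:
    """Read the user registry (user_id, age_years[, enrollment_date])."""
    df = pd.read_csv(path)
    if "user_id" not in df.columns or "age_years" not in df.columns:
        raise ValueError("registry must have user_id and age_years columns")
    df = df.copy()
    df["user_id"] = df["user_id"].astype(str)
    df["age_years"] = df["age_years"].astype(int)
    df["age_group"] = [assign_age_group(a) for a in df["age_years"]]
    if df["user_id"].duplicated().any():
        dupes = df.loc[df["user_id"].duplicated(), "user_id"].tolist()
        raise ValueError(f"duplicate user ids in registry: {dupes[:5]}")
    return df


def load_events(
    path,
    start_date: dt.date = DEFAULT_START,
    study_days: int = DEFAULT_STUDY_DAYS,
) -> list[TransactionEvent]:
    """Parse the transaction log; rows outside the study window are dropped
    (with a logged count), malformed rows raise with their row number."""
    df = pd.read_csv(path)
    for col in ("user_id", "date", "event_type"):
        if col not in df.columns:
            raise ValueError(f"transaction log missing column {col!r}")
    end_date = start_date + dt.timedelta(days=study_days - 1)
    events: list[TransactionEvent] = []
    n_dropped = 0
    for rownum, rec in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            date = dt.date.fromisoformat(str(rec.date))
        except ValueError as exc:
            raise ValueError(f"row {rownum}: unparseable date {rec.date!r}") from exc
        etype = str(rec.event_type)
        if etype not in OUTCOMES:
            raise ValueError(f"row {rownum}: unknown event_type {etype!r}")
        if date < start_date or date > end_date:
            n_dropped += 1
            continue
        amount = getattr(rec, "amount", None)
        if amount is not None and pd.isna(amount):
            amount = None
        events.append(TransactionEvent(str(rec.user_id), date, etype, amount))
    if n_dropped:
        log.warning("dropped %d events outside the study window", n_dropped)
    return events


def validate_constraints(events: list[TransactionEvent]):
    """Enforce the wallet-system rules, reporting (not raising) violations.

    Payments: at most one per user for the whole period — later payments are
    excluded (keep-first, chronological). Vouchers: at most one per user per
    day — same-day duplicates collapse to one. Savings are unrestricted.
    """
    kept: list[TransactionEvent] = []
    violations: list[dict] = []
    paid: set[str] = set()
    voucher_seen: set[tuple[str, dt.date]] = set()
    for ev in sorted(events, key=lambda e: (e.date, e.user_id)):
        if ev.event_type == "payment":
            if ev.user_id in paid:
                violations.append(
                    {"user_id": ev.user_id, "date": ev.date.isoformat(),
                     "rule": "max_1_payment_per_user"}
                )
                continue
            paid.add(ev.user_id)
        elif ev.event_type == "voucher":
            key = (ev.user_id, ev.date)
            if key in voucher_seen:
                violations.append(
                    {"user_id": ev.user_id, "date": ev.date.isoformat(),
                     "rule": "max_1_voucher_per_user_day"}
                )
                continue
            voucher_seen.add(key)
        kept.append(ev)
    return kept, violations


def binarize(
    events: list[TransactionEvent],
    users: pd.DataFrame,
    study_days: int = DEFAULT_STUDY_DAYS,
    outcome: str = "saving",
    cutoff_day: int = DEFAULT_CUTOFF_DAY,
    start_date: dt.date = DEFAULT_START,
) -> PersonDayPanel:
    """Dense binary panel: y(u, t) = 1 iff >=1 event of `outcome` that day."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    uindex = {uid: i for i, uid in enumerate(users["user_id"])}
    unknown = sorted({e.user_id for e in events if e.user_id not in uindex})
    if unknown:
        raise ValueError(f"events reference users absent from registry: {unknown[:10]}")
    y = np.zeros((len(users), study_days), dtype=np.uint8)
    for ev in events:
        if ev.event_type != outcome:
            continue
        t = (ev.date - start_date).days
        if 0 <= t < study_days:
            y[uindex[ev.user_id], t] = 1
    return PersonDayPanel(users=users.reset_index(drop=True), y=y, outcome=outcome,
                          cutoff_day=cutoff_day, start_date=start_date)


def summarize(panel: PersonDayPanel) -> dict:
    """Descriptive pre/post summaries: totals, per-day rates, age distribution."""
    if panel.n_person_days == 0:
        raise ValueError("empty panel")
    c = panel.cutoff_day
    daily = panel.daily_counts()
    pre_total = int(daily[:c].sum())
    post_total = int(daily[c:].sum())
    n = panel.n_users
    summary = {
        "outcome": panel.outcome,
        "n_users": n,
        "study_days": panel.study_days,
        "cutoff_day": c,
        "person_days": panel.n_person_days,
        "events_total": pre_total + post_total,
        "events_pre": pre_total,
        "events_post": post_total,
        "rate_per_person_day_pre": pre_total / (n * c) if c else 0.0,
        "rate_per_person_day_post": post_total / (n * (panel.study_days - c)),
        "age_distribution": panel.users["age_group"].value_counts().to_dict(),
        "age_median": float(panel.users["age_years"].median()),
        "age_iqr": float(
            panel.users["age_years"].quantile(0.75) - panel.users["age_years"].quantile(0.25)
        ),
    }
    return summary


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
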