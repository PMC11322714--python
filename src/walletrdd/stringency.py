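"""Containment stringency index from OxCGRT-style policy indicators.

The eight "containment and closure" indicators (C1 school closing ... C8
international travel controls) are ordinal severity scores with codebook
maxima (3, 3, 2, 4, 2, 3, 2, 4). Their per-day sum forms an index ranging
0-23; the analysis cutoff is the first lockdown day, verified (not chosen)
by thresholding this index.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "INDICATOR_BOUNDS",
    "INDICATOR_NAMES",
    "StringencySeries",
    "containment_index",
    "parse_policy_file",
    "median_index",
    "detect_cutoff",
]

log = logging.getLogger(__name__)

INDICATOR_NAMES = ("C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8")
#: ordinal maxima per the OxCGRT codebook; sum = 23
INDICATOR_BOUNDS = (3, 3, 2, 4, 2, 3, 2, 4)
MAX_INDEX = sum(INDICATOR_BOUNDS)


def containment_index(indicator_levels) -> int:
    """Sum the eight ordinal containment-and-closure levels (range 0-23)."""
    levels = list(indicator_levels)
    if len(levels) != 8:
        raise ValueError(f"expected 8 indicator levels, got {len(levels)}")
    total = 0
    for name, bound, value in zip(INDICATOR_NAMES, INDICATOR_BOUNDS, levels):
        v = _check_ordinal(value, name, bound)
        total += v
    return total


def _check_ordinal(value, name: str, bound: int) -> int:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError(f"missing value for indicator {name}")
    f = float(value)
    if f != int(f):
        raise ValueError(f"indicator {name} is not an integer: {value!r}")
    v = int(f)
    if v < 0 or v > bound:
        raise ValueError(f"indicator {name} out of range [0, {bound}]: {v}")
    return v


@dataclass(frozen=True)
class StringencySeries:
    """Daily indicator levels and their 0-23 index over a gap-free window."""

    frame: pd.DataFrame  # columns: date, C1..C8, index, missing_any

    def __post_init__(self):
        df = self.frame
        required = ["date", *INDICATOR_NAMES, "index", "missing_any"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"stringency frame missing columns: {missing}")
        dates = pd.to_datetime(df["date"]).dt.normalize()
        if len(dates) > 1:
            deltas = dates.diff().dropna().dt.days
            if not (deltas == 1).all():
                raise ValueError("stringency series dates must be consecutive days")
        idx = df["index"].to_numpy()
        if np.any(idx < 0) or np.any(idx > MAX_INDEX):
            raise ValueError(f"index outside [0, {MAX_INDEX}]")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.Series:
        return pd.to_datetime(self.frame["date"])

    @property
    def index_values(self) -> np.ndarray:
        return self.frame["index"].to_numpy()

    def to_csv(self, path) -> None:
        """Tidy per-day table: date, eight levels, index."""
        out = self.frame.copy()
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StringencySeries":
        df = pd.read_csv(path)
        df["date"] = pd.to_datetime(df["date"])
        return cls(df)

    @classmethod
    def from_levels(cls, start_date, daily_levels, missing_flags=None) -> "StringencySeries":
        """Build a series from an iterable of 8-tuples starting at start_date."""
        start = pd.Timestamp(start_date)
        rows = []
        for i, levels in enumerate(daily_levels):
            idx = containment_index(levels)
            rows.append(
                {
                    "date": start + pd.Timedelta(days=i),
                    **dict(zip(INDICATOR_NAMES, (int(v) for v in levels))),
                    "index": idx,
                    "missing_any": bool(missing_flags[i]) if missing_flags is not None else False,
                }
            )
        return cls(pd.DataFrame(rows))


def _find_indicator_columns(columns) -> dict[str, str]:
    """Map C1..C8 to actual column names, skipping geographic-scope flag columns."""
    mapping: dict[str, str] = {}
    for name in INDICATOR_NAMES:
        pattern = re.compile(rf"^{name}[EM]?([_ ].*)?$")
        candidates = [
            c for c in columns if pattern.match(c.strip()) and "flag" not in c.lower()
        ]
        if len(candidates) == 1:
            mapping[name] = candidates[0]
        elif len(candidates) > 1:
            # prefer the bare or M-suffixed ordinal column
            candidates.sort(key=len)
            mapping[name] = candidates[0]
        else:
            raise ValueError(f"no column found for indicator {name}")
    return mapping


def parse_policy_file(path, country_code: str, date_range=None) -> StringencySeries:
    """Parse an OxCGRT compact national CSV into a StringencySeries.

    Expects CountryCode, Date (YYYYMMDD or ISO) and the eight ordinal
    containment columns (bare ``C1`` or prefixed like ``C1M_School closing``).
    Missing indicator values are imputed as 0 (least severe) with a logged
    warning and a per-day ``missing_any`` flag.
    """
    df = pd.read_csv(path)
    if "CountryCode" in df.columns:
        df = df[df["CountryCode"].astype(str) == str(country_code)]
        if df.empty:
            raise ValueError(f"country {country_code!r} absent from policy file")
    elif country_code:
        log.warning("no CountryCode column; assuming single-country file")
    date_col = next((c for c in ("Date", "date") if c in df.columns), None)
    if date_col is None:
        raise ValueError("policy file has no Date column")
    raw = df[date_col]
    if pd.api.types.is_integer_dtype(raw) or raw.astype(str).str.fullmatch(r"\d{8}").all():
        dates = pd.to_datetime(raw.astype(str), format="%Y%m%d")
    else:
        dates = pd.to_datetime(raw)
    df = df.assign(_date=dates).sort_values("_date")
    if date_range is not None:
        lo, hi = pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])
        df = df[(df["_date"] >= lo) & (df["_date"] <= hi)]
    if df.empty:
        raise ValueError("no rows in requested date range")

    colmap = _find_indicator_columns(df.columns)
    rows = []
    n_missing = 0
    for rownum, (_, rec) in enumerate(df.iterrows()):
        levels = []
        missing_any = False
        for name, bound in zip(INDICATOR_NAMES, INDICATOR_BOUNDS):
            val = rec[colmap[name]]
            if pd.isna(val):
                levels.append(0)
                missing_any = True
                n_missing += 1
                continue
            try:
                levels.append(_check_ordinal(val, name, bound))
            except ValueError as exc:
                raise ValueError(f"row {rownum} ({rec['_date'].date()}): {exc}") from exc
        rows.append(
            {
                "date": rec["_date"],
                **dict(zip(INDICATOR_NAMES, levels)),
                "index": sum(levels),
                "missing_any": missing_any,
            }
        )
    if n_missing:
        log.warning("imputed %d missing indicator values as 0", n_missing)
    return StringencySeries(pd.DataFrame(rows))


def median_index(series: StringencySeries, window=None) -> float:
    """Median of the daily index over a closed date window (whole series if None)."""
    df = series.frame
    if window is not None:
        lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        dates = pd.to_datetime(df["date"])
        df = df[(dates >= lo) & (dates <= hi)]
    if df.empty:
        raise ValueError("empty window for median_index")
    return float(np.median(df["index"].to_numpy()))


def detect_cutoff(series: StringencySeries, threshold: int = 10):
    """Zero-based index of the first day with index >= threshold, or None.

    A verification aid: the analysis cutoff is configuration-supplied (the
    known policy date), and this checks that the policy series agrees.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    idx = series.index_values
    hits = np.nonzero(idx >= threshold)[0]
    return int(hits[0]) if hits.size else None
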