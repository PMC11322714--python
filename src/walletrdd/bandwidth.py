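"""Imbens-Kalyanaraman plug-in bandwidth selection for the discontinuity fit.

The selector runs on the daily aggregate event-rate series (for a fixed
cohort this is numerically equivalent to running it on the person-day
records: the variance-to-sample-size ratios that enter every step are
identical). The estimation stage uses an unweighted hard window, i.e. a
uniform (rectangular) kernel, so the kernel constant is derived for the
uniform boundary equivalent kernel:

    K*(u) = 4 - 6u on [0, 1],  C1 = |∫ u² K*| = 1/6,  C2 = ∫ K*² = 4,
    C_K = (2 C2 / C1²)^(1/5) = 288^(1/5) ≈ 3.1051.

The plug-in is h = C_K [σ²(c) / (f(c) ((m″₊-m″₋)² + r₊ + r₋))]^(1/5) N^(-1/5)
with pilot second derivatives from one-sided local quadratic fits and the
regularization terms r preventing degenerate (zero-curvature) blowup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BandwidthResult", "ik_bandwidth", "KERNEL_CONSTANTS"]

# (C1, C2) for the boundary equivalent kernel of a local linear fit
KERNEL_CONSTANTS = {
    "uniform": (1.0 / 6.0, 4.0),
    "triangular": (0.1, 4.8),
}


@dataclass(frozen=True)
class BandwidthResult:
    h_opt: int
    h_raw: float
    kernel: str
    sigma2: float          # conditional variance of the rate at the cutoff
    f_cutoff: float        # density of the running variable at the cutoff
    m2_left: float         # curvature estimate, pre side
    m2_right: float        # curvature estimate, post side
    m3: float              # pooled third-derivative pilot estimate
    h1: float              # rule-of-thumb pilot bandwidth
    h2_left: float
    h2_right: float
    reg_left: float        # regularization terms
    reg_right: float
    n: int

    def __post_init__(self):
        if self.h_opt <= 0:
            raise ValueError("optimal bandwidth must be positive")


def _polyfit(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """Least-squares polynomial coefficients in increasing order."""
    X = np.vander(x, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def ik_bandwidth(
    daily_rates: np.ndarray,
    cutoff_day: int,
    x: np.ndarray | None = None,
    kernel: str = "uniform",
    min_side_points: int = 4,
) -> BandwidthResult:
    """Select the MSE-optimal window (in days) for the discontinuity fit.

    Parameters
    ----------
    daily_rates : array
        Per-day aggregate event rate (events / users at risk).
    cutoff_day : int
        Zero-based day index of the first post-cutoff day.
    x : array, optional
        Running-variable values per observation; defaults to 0..N-1 day grid.
    kernel : {"uniform", "triangular"}
        Kernel whose boundary constant enters the plug-in; uniform matches
        the hard-window estimation stage.
    """
    y = np.asarray(daily_rates, dtype=float)
    if x is None:
        x = np.arange(y.size, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    if np.all(y == y[0]):
        raise ValueError(
            "degenerate rate series (exactly constant): curvature and "
            "regularization are both zero; select a bandwidth manually"
        )
    d = x - float(cutoff_day)
    left, right = d < 0, d >= 0
    n_left, n_right = int(left.sum()), int(right.sum())
    if n_left < 10 or n_right < 10:
        raise ValueError("need at least 10 observations on each side of the cutoff")
    N = y.size
    c1, c2 = KERNEL_CONSTANTS[kernel]
    ck = (2.0 * c2 / c1**2) ** 0.2
    span_left = float(-d[left].min())
    span_right = float(d[right].max())
    h_max = min(span_left, span_right)

    # --- step 1: pilot variance and density at the cutoff
    h1 = 1.84 * float(np.std(d)) * N ** (-0.2)
    in1_left = left & (d >= -h1)
    in1_right = right & (d <= h1)
    n1_left, n1_right = int(in1_left.sum()), int(in1_right.sum())
    if n1_left < 2 or n1_right < 2:
        raise ValueError("pilot window too narrow; series too short")
    resid_left = y[in1_left] - y[in1_left].mean()
    resid_right = y[in1_right] - y[in1_right].mean()
    sigma2 = float((resid_left @ resid_left + resid_right @ resid_right)
                   / (n1_left + n1_right))
    f_c = (n1_left + n1_right) / (2.0 * N * h1)

    # --- step 2: third derivative from a global cubic (with jump dummy)
    med_left = float(np.median(d[left]))
    med_right = float(np.median(d[right]))
    sel = (d >= med_left) & (d <= med_right)
    dd, yy = d[sel], y[sel]
    X3 = np.column_stack(
        [np.ones(dd.size), (dd >= 0).astype(float), dd, dd**2, dd**3]
    )
    coef3, *_ = np.linalg.lstsq(X3, yy, rcond=None)
    m3 = float(6.0 * coef3[4])
    m3_sq = m3**2 if m3 != 0.0 else 1e-300

    # pilot bandwidths for the curvature fits
    h2_right = 3.56 * (sigma2 / (f_c * m3_sq)) ** (1 / 7) * n_right ** (-1 / 7)
    h2_left = 3.56 * (sigma2 / (f_c * m3_sq)) ** (1 / 7) * n_left ** (-1 / 7)

    def _side_curvature(side_mask, h2, side_d_abs):
        h2 = min(h2, side_d_abs)
        sel_side = side_mask & (np.abs(d) <= h2)
        # widen until the quadratic fit is identified
        while int(sel_side.sum()) < min_side_points and h2 < side_d_abs:
            h2 *= 1.5
            sel_side = side_mask & (np.abs(d) <= min(h2, side_d_abs))
        n2 = int(sel_side.sum())
        if n2 < min_side_points:
            raise ValueError("too few points for the curvature pilot fit")
        coef = _polyfit(d[sel_side], y[sel_side], 2)
        return float(2.0 * coef[2]), min(h2, side_d_abs), n2

    m2_left, h2_left, n2_left = _side_curvature(left, h2_left, span_left)
    m2_right, h2_right, n2_right = _side_curvature(right, h2_right, span_right)

    # --- step 3: regularization and plug-in
    reg_left = 2160.0 * sigma2 / (n2_left * h2_left**4)
    reg_right = 2160.0 * sigma2 / (n2_right * h2_right**4)
    denom = (m2_right - m2_left) ** 2 + reg_left + reg_right
    if denom <= 0:
        raise ValueError(
            "degenerate curvature and zero regularization; "
            "select a bandwidth manually"
        )
    h_raw = ck * (sigma2 / (f_c * denom)) ** 0.2 * N ** (-0.2)
    h_trunc = float(np.clip(h_raw, 2.0, h_max))
    return BandwidthResult(
        h_opt=int(round(h_trunc)),
        h_raw=float(h_raw),
        kernel=kernel,
        sigma2=sigma2,
        f_cutoff=float(f_c),
        m2_left=m2_left,
        m2_right=m2_right,
        m3=m3,
        h1=float(h1),
        h2_left=float(h2_left),
        h2_right=float(h2_right),
        reg_left=float(reg_left),
        reg_right=float(reg_right),
        n=N,
    )
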