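"""Multiplex bead-array QC and quantification, plus censoring rules.

QC follows standard Luminex practice: wells with too few counted beads are
unreliable and flagged; replicate wells whose MFI coefficient of variation
exceeds a threshold (25% here) are excluded. Quantification fits a
log2(MFI)-on-log2(concentration) regression to the plate's serial-dilution
standards and inverts it for sample wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MIN_BEADS = 35
DEFAULT_MAX_CV_PCT = 25.0


@dataclass
class QCReport:
    """Flagged wells (one primary reason each) and replicate-group CVs."""

    flagged: pd.DataFrame      # columns: well, reason, cv_pct
    cv_by_group: pd.DataFrame  # columns: replicate, cv_pct
    passed: pd.DataFrame       # surviving wells, original columns


def replicate_cv_pct(mfi) -> float:
    """Coefficient of variation in percent, sample (n-1) standard deviation."""
    mfi = np.asarray(mfi, dtype=float)
    if mfi.size < 2:
        return 0.0
    mean = mfi.mean()
    if mean == 0:
        return 0.0
    return float(mfi.std(ddof=1) / mean * 100.0)


def qc_filter(wells: pd.DataFrame, min_beads: int = DEFAULT_MIN_BEADS,
              max_cv_pct: float = DEFAULT_MAX_CV_PCT) -> QCReport:
    """Flag low-bead wells, then high-CV replicate groups.

    Bead count is the primary reason: a well failing both criteria is
    recorded once, as ``low_beads``. CV is computed within each replicate
    group over the wells that survive the bead filter.
    """
    if len(wells) == 0:
        raise ValueError("empty plate")
    if min_beads < 0 or max_cv_pct < 0:
        raise ValueError("thresholds must be non-negative")
    wells = wells.reset_index(drop=True)
    low_beads = wells["bead_count"] < min_beads
    flagged_rows = [
        {"well": w, "reason": "low_beads", "cv_pct": np.nan}
        for w in wells.loc[low_beads, "well"]
    ]
    surviving = wells.loc[~low_beads]
    cv_rows = []
    high_cv_idx = []
    for group, sub in surviving.groupby("replicate", sort=True):
        cv = replicate_cv_pct(sub["mfi"].to_numpy())
        cv_rows.append({"replicate": group, "cv_pct": cv})
        if cv > max_cv_pct:
            high_cv_idx.extend(sub.index.tolist())
            flagged_rows.extend(
                {"well": w, "reason": "high_cv", "cv_pct": cv}
                for w in sub["well"])
    passed = surviving.drop(index=high_cv_idx)
    flagged = pd.DataFrame(flagged_rows, columns=["well", "reason", "cv_pct"])
    cv_by_group = pd.DataFrame(cv_rows, columns=["replicate", "cv_pct"])
    return QCReport(flagged=flagged, cv_by_group=cv_by_group, passed=passed)


@dataclass
class StandardCurve:
    """Calibration fit in log2-log2 space: log2(MFI) = poly(log2(conc)).

    ``coeffs`` are numpy polynomial coefficients, highest degree first.
    The fitted curve must be monotone increasing over ``fit_range`` (the
    observed span of standard MFIs); a non-monotone fit is rejected.
    """

    analyte: str
    coeffs: np.ndarray
    fit_range: tuple[float, float]          # (min, max) of standard MFI
    conc_range: tuple[float, float]         # (min, max) of log2 standard conc
    residual_sd: float
    degree: int = 1
    warnings: list[str] = field(default_factory=list)


def fit_standard_curve(standards: pd.DataFrame, analyte: str | None = None,
                       degree: int = 1) -> StandardCurve:
    """Least-squares fit of log2(MFI) on log2(known concentration)."""
    if analyte is not None:
        standards = standards[standards["analyte"] == analyte]
    else:
        uniq = standards["analyte"].unique()
        if len(uniq) != 1:
            raise ValueError("standards span several analytes; pass analyte=")
        analyte = str(uniq[0])
    conc = standards["known_conc"].to_numpy(dtype=float)
    mfi = standards["mfi"].to_numpy(dtype=float)
    if np.unique(conc).size < 4:
        raise ValueError("need >= 4 standards with distinct concentrations")
    if np.any(conc <= 0) or np.any(mfi <= 0):
        raise ValueError("standards must have positive MFI and concentration")
    x = np.log2(conc)
    y = np.log2(mfi)
    coeffs = np.polyfit(x, y, deg=degree)
    resid = y - np.polyval(coeffs, x)
    dof = max(x.size - (degree + 1), 1)
    curve = StandardCurve(
        analyte=analyte, coeffs=coeffs,
        fit_range=(float(mfi.min()), float(mfi.max())),
        conc_range=(float(x.min()), float(x.max())),
        residual_sd=float(np.sqrt(resid @ resid / dof)), degree=degree)
    # monotonicity over the standard span (derivative positive)
    grid = np.linspace(x.min(), x.max(), 201)
    deriv = np.polyval(np.polyder(coeffs), grid)
    if np.any(deriv <= 0):
        curve.warnings.append("non-monotone fit rejected")
        raise ValueError(f"fitted curve for {analyte} is not monotone "
                         "increasing over the standard range")
    return curve


def estimate_concentration(mfi, curve: StandardCurve):
    """Invert the calibration to log2 concentration; flag extrapolation.

    Returns ``(log2_conc, out_of_range)`` arrays. For the default linear
    curve the inverse is closed-form; higher degrees invert by root-finding
    restricted to the standard concentration span.
    """
    mfi = np.asarray(mfi, dtype=float)
    if np.any(mfi <= 0):
        raise ValueError("MFI must be positive")
    y = np.log2(mfi)
    if curve.degree == 1:
        slope, intercept = curve.coeffs
        x = (y - intercept) / slope
    else:
        lo, hi = curve.conc_range
        span = hi - lo
        x = np.empty_like(y)
        for i, yi in enumerate(y.ravel()):
            roots = np.roots(np.polysub(curve.coeffs, [yi]))
            real = roots[np.isreal(roots)].real
            in_span = real[(real >= lo - span) & (real <= hi + span)]
            x.ravel()[i] = (in_span[np.argmin(np.abs(in_span - (lo + hi) / 2))]
                            if in_span.size else np.nan)
    out_of_range = (mfi < curve.fit_range[0]) | (mfi > curve.fit_range[1])
    return x, out_of_range


def quantify_plate(wells: pd.DataFrame, min_beads: int = DEFAULT_MIN_BEADS,
                   max_cv_pct: float = DEFAULT_MAX_CV_PCT,
                   degree: int = 1) -> tuple[pd.DataFrame, QCReport]:
    """QC a raw plate and estimate log2 concentrations for sample wells.

    Returns a tidy table (replicate, analyte, log2_conc, out_of_range) with
    replicate wells averaged on the log2 scale, plus the QC report.
    """
    report = qc_filter(wells, min_beads=min_beads, max_cv_pct=max_cv_pct)
    passed = report.passed
    rows = []
    for analyte, sub in passed.groupby("analyte", sort=True):
        std = sub[sub["is_standard"] == 1]
        samples = sub[sub["is_standard"] == 0]
        if len(std) == 0 or len(samples) == 0:
            continue
        curve = fit_standard_curve(std, analyte=analyte, degree=degree)
        conc, oor = estimate_concentration(samples["mfi"].to_numpy(), curve)
        tmp = samples[["replicate"]].copy()
        tmp["analyte"] = analyte
        tmp["log2_conc"] = conc
        tmp["out_of_range"] = oor
        rows.append(tmp)
    if not rows:
        return (pd.DataFrame(columns=["replicate", "analyte", "log2_conc",
                                      "out_of_range"]), report)
    tidy = pd.concat(rows, ignore_index=True)
    agg = (tidy.groupby(["replicate", "analyte"], sort=True)
           .agg(log2_conc=("log2_conc", "mean"),
                out_of_range=("out_of_range", "any"))
           .reset_index())
    return agg, report


def censor_at_horizon(time: float, event: int, horizon: float = 5.0):
    """Apply administrative censoring: follow-up beyond the horizon becomes
    (horizon, censored); times at or below the horizon keep their status."""
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if time <= 0:
        raise ValueError("time must be > 0")
    if time > horizon:
        return horizon, 0
    return time, int(event)


def censor_frame(patients: pd.DataFrame, horizon: float = 5.0) -> pd.DataFrame:
    out = patients.copy()
    over = out["time"] > horizon
    out.loc[over, "time"] = horizon
    out.loc[over, "event"] = 0
    return out
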