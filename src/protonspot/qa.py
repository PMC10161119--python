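"""Agreement between detector-measured and log-recorded spot positions.

Per-axis disagreement is Delta = recorded - measured (mm).  The summary
statistics mirror routine QA reporting: per-axis mean and sample SD, the
root-mean-square disagreement RMS = sqrt(sum(Delta_i^2)/n) per axis, and
the combined planar RMS_xy = sqrt(RMS_x^2 + RMS_y^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .synthetic import QaSession


@dataclass
class DeltaStats:
    delta_x_mm: np.ndarray
    delta_y_mm: np.ndarray
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    n_spots: int


@dataclass
class RmsSummary:
    rms_x: float
    rms_y: float
    rms_xy: float
    n_spots: int


@dataclass
class MatchedSpots:
    nominal_mm: np.ndarray
    recorded_mm: np.ndarray
    measured_mm: np.ndarray
    unmatched: np.ndarray  # indices of recorded spots beyond tolerance


def match_spots(qa: QaSession, tolerance_mm: float = 5.0) -> MatchedSpots:
    """Pair each recorded spot with its nearest nominal grid point.

    Pairs farther than ``tolerance_mm`` are flagged unmatched; two recorded
    spots claiming the same grid point raise an ambiguity error.
    """
    tree = cKDTree(qa.nominal_mm)
    dist, idx = tree.query(qa.recorded_mm)
    ok = dist <= tolerance_mm
    claimed = idx[ok]
    if len(np.unique(claimed)) != len(claimed):
        dup = int(np.unique(claimed, return_counts=True)[0][
            np.unique(claimed, return_counts=True)[1] > 1][0])
        raise ValueError(f"ambiguous pairing: nominal grid point {dup} claimed twice")
    return MatchedSpots(qa.nominal_mm[idx[ok]], qa.recorded_mm[ok], qa.measured_mm[ok],
                        np.flatnonzero(~ok))


def delta_stats(pairs: MatchedSpots) -> DeltaStats:
    """Per-axis mean and sample SD (n-1) of recorded-minus-measured."""
    if len(pairs.recorded_mm) == 0:
        raise ValueError("no matched spots")
    d = pairs.recorded_mm - pairs.measured_mm
    n = len(d)
    return DeltaStats(
        delta_x_mm=d[:, 0], delta_y_mm=d[:, 1],
        mean_x=float(np.mean(d[:, 0])),
        sd_x=float(np.std(d[:, 0], ddof=1)) if n > 1 else 0.0,
        mean_y=float(np.mean(d[:, 1])),
        sd_y=float(np.std(d[:, 1], ddof=1)) if n > 1 else 0.0,
        n_spots=n,
    )


def rms(deltas: np.ndarray) -> float:
    """Root-mean-square of a list of disagreements: sqrt(sum(d_i^2)/n)."""
    deltas = np.asarray(deltas, float)
    if deltas.size == 0:
        raise ValueError("rms of empty input")
    return float(np.sqrt(np.mean(deltas ** 2)))


def rms_combined(rms_x: float, rms_y: float) -> float:
    """Planar RMS from the per-axis values (quadrature sum)."""
    if rms_x < 0 or rms_y < 0:
        raise ValueError("RMS inputs must be non-negative")
    return float(np.sqrt(rms_x ** 2 + rms_y ** 2))


def rms_summary(stats_: DeltaStats) -> RmsSummary:
    rx = rms(stats_.delta_x_mm)
    ry = rms(stats_.delta_y_mm)
    return RmsSummary(rx, ry, rms_combined(rx, ry), stats_.n_spots)


def gaussianity_summary(deltas: np.ndarray, test: str = "normaltest") -> dict:
    """Descriptive Gaussianity report: skewness, excess kurtosis, p-value.

    Purely descriptive — no pass/fail gate is applied; a constant sample is
    reported as non-testable.
    """
    deltas = np.asarray(deltas, float)
    if deltas.size < 20:
        raise ValueError("need at least 20 values for a normality summary")
    if np.ptp(deltas) == 0.0:
        return {"testable": False, "skewness": 0.0, "excess_kurtosis": float("nan"),
                "p_value": float("nan"), "n": int(deltas.size)}
    skew = float(stats.skew(deltas))
    kurt = float(stats.kurtosis(deltas))  # excess (Fisher)
    if test == "normaltest":
        p = float(stats.normaltest(deltas).pvalue)
    elif test == "shapiro":
        p = float(stats.shapiro(deltas).pvalue)
    else:
        raise ValueError(f"unknown normality test {test!r}")
    return {"testable": True, "skewness": skew, "excess_kurtosis": kurt,
            "p_value": p, "n": int(deltas.size)}


def agreement_table(sessions: list[QaSession], tolerance_mm: float = 5.0) -> pd.DataFrame:
    """QA agreement summary, one column per gantry angle.

    Rows: mean_dx, sd_dx, mean_dy, sd_dy, rms_x, rms_y, rms_xy, n_spots.
    The SD rows are sample SDs of the per-spot disagreements.
    """
    cols = {}
    for qa in sessions:
        st = delta_stats(match_spots(qa, tolerance_mm))
        rm = rms_summary(st)
        cols[f"{qa.gantry_angle_deg:g}"] = {
            "mean_dx_mm": st.mean_x, "sd_dx_mm": st.sd_x,
            "mean_dy_mm": st.mean_y, "sd_dy_mm": st.sd_y,
            "rms_x_mm": rm.rms_x, "rms_y_mm": rm.rms_y, "rms_xy_mm": rm.rms_xy,
            "n_spots": st.n_spots,
        }
    return pd.DataFrame(cols)
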