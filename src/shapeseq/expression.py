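"""Structure-function coupling: fluorescence normalisation, fold changes,
and the sliding-window ribosome-binding-site (RBS) reactivity scan.

Gene expression is read out as blank-corrected fluorescence per optical
density (FL/OD) with the autofluorescence of a reporter-free control
culture subtracted.  On the structure side, the dominant Shine-Dalgarno
hexamer is located by summing reactivities over a six-nucleotide sliding
window in the translationally ON and OFF states and taking the window
with the largest ON - OFF difference; the ratio of window sums is the
RBS reactivity fold change that pairs with the expression fold change.
Positions are numbered from the transcription start of the sense RNA
(position 1), matching the reactivity profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ExpressionMeasurement:
    """One culture's raw plate-reader readings and its controls."""

    fl_raw: float
    od_raw: float
    blank_fl: float = 0.0
    blank_od: float = 0.0
    autofluor_flod: float = 0.0


def normalize_flod(m: ExpressionMeasurement) -> float:
    """Blank-corrected, OD-normalised, autofluorescence-subtracted FL/OD."""
    od = m.od_raw - m.blank_od
    if od <= 0:
        raise ValueError(
            f"corrected OD must be positive (got {od:g}): culture too dilute "
            "or blank mismatch"
        )
    return (m.fl_raw - m.blank_fl) / od - m.autofluor_flod


def expression_fold_change(flod_state_a: Sequence[float],
                           flod_state_b: Sequence[float]) -> dict[str, float]:
    """Fold change mean(A)/mean(B) and percent repression of A relative to B.

    Replicate corrected FL/OD values are averaged first, then the ratio is
    taken (ratio of means, not mean of ratios).  ``percent_repression``
    reads state A as the repressed state: 100 * (1 - mean(A)/mean(B)).
    """
    mean_a = float(np.mean(flod_state_a))
    mean_b = float(np.mean(flod_state_b))
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("fold change needs positive replicate means")
    fold = mean_a / mean_b
    return {"fold": fold, "percent_repression": 100.0 * (1.0 - fold)}


@dataclass
class WindowScanResult:
    """All window sums for both states plus the best ON-OFF window."""

    window_length: int
    sums_on: np.ndarray
    sums_off: np.ndarray
    best_start: int  # 1-based start of the maximal-difference window
    best_diff: float


def _window_sums(values: np.ndarray, w: int, missing_policy: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    nan = np.isnan(x)
    if missing_policy == "zero":
        x = np.where(nan, 0.0, x)
        sums = np.convolve(x, np.ones(w), mode="valid")
    elif missing_policy == "skip":
        sums = np.convolve(np.where(nan, 0.0, x), np.ones(w), mode="valid")
        has_nan = np.convolve(nan.astype(float), np.ones(w), mode="valid") > 0
        sums[has_nan] = np.nan
    else:
        raise ValueError("missing_policy must be 'zero' or 'skip'")
    return sums


def sd_window_scan(rho_on: Sequence[float], rho_off: Sequence[float],
                   window_length: int = 6,
                   missing_policy: str = "zero") -> WindowScanResult:
    """Sliding-window Shine-Dalgarno scan.

    Computes every ``window_length`` sum of both profiles and returns the
    window with the largest (ON - OFF) sum difference; ties go to the
    smallest start index.  Missing values (NaN) contribute 0 by default;
    ``missing_policy="skip"`` drops windows containing any missing value.
    """
    on = np.asarray(rho_on, dtype=float)
    off = np.asarray(rho_off, dtype=float)
    if len(on) != len(off):
        raise ValueError("ON and OFF profiles must have equal length")
    if len(on) < window_length:
        raise ValueError("profiles shorter than the window")
    sums_on = _window_sums(on, window_length, missing_policy)
    sums_off = _window_sums(off, window_length, missing_policy)
    diff = sums_on - sums_off
    if np.isnan(diff).all():
        raise ValueError("every window contains missing values")
    best_idx = int(np.nanargmax(diff))  # nanargmax returns the first maximum
    return WindowScanResult(
        window_length=window_length,
        sums_on=sums_on,
        sums_off=sums_off,
        best_start=best_idx + 1,
        best_diff=float(diff[best_idx]),
    )


def window_fold_change(rho_on: Sequence[float], rho_off: Sequence[float],
                       start: int, end: int,
                       missing_policy: str = "zero") -> float:
    """Ratio of reactivity sums over a 1-based inclusive window."""
    on = np.asarray(rho_on, dtype=float)
    off = np.asarray(rho_off, dtype=float)
    if not 1 <= start <= end <= min(len(on), len(off)):
        raise ValueError(f"window [{start}, {end}] out of range or reversed")
    sl = slice(start - 1, end)
    if missing_policy == "zero":
        sum_on = np.nansum(on[sl])
        sum_off = np.nansum(off[sl])
    else:
        sum_on = on[sl].sum()
        sum_off = off[sl].sum()
    if not sum_off > 0:
        raise ValueError(
            "off-state window sum is zero; report absolute window sums "
            "instead of a fold change"
        )
    return float(sum_on / sum_off)


# ---------------------------------------------------------------------------
# plate-reader table I/O and reporting


def read_plate_table(path: str | Path) -> pd.DataFrame:
    """Plate-reader CSV with columns: sample, fl, od, role.

    ``role`` is one of ``culture``, ``blank``, ``autofluor-control``.
    """
    df = pd.read_csv(path)
    required = {"sample", "fl", "od", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate table must have columns {sorted(required)}")
    return df


def corrected_flod_by_sample(df: pd.DataFrame) -> dict[str, list[float]]:
    """Per-sample corrected FL/OD replicate lists from a plate table.

    Blank wells are averaged into a single correction; autofluorescence
    control wells are blank-corrected, normalised and averaged, then
    subtracted from every culture.
    """
    blanks = df[df["role"] == "blank"]
    blank_fl = float(blanks["fl"].mean()) if len(blanks) else 0.0
    blank_od = float(blanks["od"].mean()) if len(blanks) else 0.0
    auto = df[df["role"] == "autofluor-control"]
    if len(auto):
        auto_flod = float(np.mean(
            [(r.fl - blank_fl) / (r.od - blank_od) for r in auto.itertuples()]
        ))
    else:
        auto_flod = 0.0
    out: dict[str, list[float]] = {}
    for row in df[df["role"] == "culture"].itertuples():
        m = ExpressionMeasurement(row.fl, row.od, blank_fl, blank_od, auto_flod)
        out.setdefault(str(row.sample), []).append(normalize_flod(m))
    return out


def structure_function_report(
    scan: WindowScanResult,
    rho_on: Sequence[float],
    rho_off: Sequence[float],
    expression_on: Sequence[float],
    expression_off: Sequence[float],
) -> dict:
    """Joint structure-function summary for one regulator pair."""
    w = scan.window_length
    best_end = scan.best_start + w - 1
    return {
        "window_length": w,
        "best_window": [scan.best_start, best_end],
        "best_window_diff": scan.best_diff,
        "window_fold_change": window_fold_change(
            rho_on, rho_off, scan.best_start, best_end
        ),
        "expression": expression_fold_change(expression_on, expression_off),
    }
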