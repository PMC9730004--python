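"""Per-participant statistics: exclusion filter, block regression,
indifference point, and the VE/CV error decomposition.

All analyses work on a tidy trial table with columns ``participant``,
``retention_s``, ``sample_ms`` and ``reproduced_ms`` (plus any others,
which are carried through untouched).
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_dataset",
    "log_transform",
    "exclude_outlier_participants",
    "ExclusionReport",
    "fit_block_regression",
    "indifference_point",
    "block_fits",
    "normalize_reproductions",
    "vertical_error",
    "coefficient_of_variation",
    "error_stats",
    "SLOPE_UNITY_TOL",
]

REQUIRED_COLUMNS = ("participant", "retention_s", "sample_ms", "reproduced_ms")

#: |a - 1| below this counts as parallel to the unity line (undefined I).
SLOPE_UNITY_TOL = 1e-9


def validate_dataset(df: pd.DataFrame) -> None:
    """Check the trial-table schema; raise ValueError naming problems."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    for col in ("sample_ms", "reproduced_ms", "retention_s"):
        bad = df.index[~(df[col] > 0)]
        if len(bad):
            raise ValueError(
                f"column {col!r} must be positive; offending rows: {list(bad[:5])}"
            )


def log_transform(df: pd.DataFrame) -> pd.DataFrame:
    """Append ``log10_sample`` and ``log10_reproduced`` columns.

    Raises a validation error naming the offending row if any duration
    is non-positive.
    """
    validate_dataset(df)
    out = df.copy()
    out["log10_sample"] = np.log10(out["sample_ms"].to_numpy(float))
    out["log10_reproduced"] = np.log10(out["reproduced_ms"].to_numpy(float))
    return out


@dataclass
class ExclusionReport:
    """Outcome of the outlier-participant filter."""

    flag_counts: dict[str, int]
    removed: list[str]
    ratio_threshold: float
    trial_threshold: int

    def to_text(self) -> str:
        lines = [
            f"ratio_threshold: {self.ratio_threshold}",
            f"trial_threshold: {self.trial_threshold}",
            f"removed: {','.join(self.removed) if self.removed else '(none)'}",
            "flag_counts:",
        ]
        lines += [f"  {p}: {c}" for p, c in sorted(self.flag_counts.items())]
        return "\n".join(lines)


def exclude_outlier_participants(
    df: pd.DataFrame, ratio_threshold: float = 5.0, trial_threshold: int = 30
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop participants with too many wildly off reproductions.

    A trial is flagged when the reproduction is more than
    ``ratio_threshold`` times away from the sample in either direction;
    a participant is removed when their flagged-trial count strictly
    exceeds ``trial_threshold``.
    """
    if ratio_threshold <= 0 or trial_threshold <= 0:
        raise ValueError("thresholds must be positive")
    validate_dataset(df)
    ratio = df["reproduced_ms"].to_numpy(float) / df["sample_ms"].to_numpy(float)
    flagged = (ratio > ratio_threshold) | (ratio < 1.0 / ratio_threshold)
    counts = (
        pd.Series(flagged, index=df["participant"].to_numpy())
        .groupby(level=0)
        .sum()
        .astype(int)
    )
    removed = sorted(counts.index[counts > trial_threshold])
    report = ExclusionReport(counts.to_dict(), list(removed), ratio_threshold, trial_threshold)
    return df[~df["participant"].isin(removed)].copy(), report


def fit_block_regression(trials: pd.DataFrame) -> tuple[float, float]:
    """OLS of log10(reproduced) on log10(sample) for one participant-condition cell.

    Returns ``(a, b)``: slope (dimensionless) and intercept (log10 ms).
    Requires at least two distinct sample intervals.
    """
    x = np.log10(trials["sample_ms"].to_numpy(float))
    y = np.log10(trials["reproduced_ms"].to_numpy(float))
    if len(np.unique(x)) < 2:
        raise ValueError("block regression needs >= 2 distinct sample intervals")
    a, b = np.polyfit(x, y, 1)
    return float(a), float(b)


def indifference_point(a: float, b: float) -> float:
    """Where the fitted line crosses the unity (veridical) line, in ms.

    In log10 space the crossing is at ``x* = b / (1 - a)``; the result
    is ``10**x*``.  A slope within ``SLOPE_UNITY_TOL`` of 1 makes the
    line parallel to unity: returns NaN (undefined flag), not an error.
    """
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("slope and intercept must be finite")
    if abs(a - 1.0) < SLOPE_UNITY_TOL:
        return float("nan")
    return 10.0 ** (b / (1.0 - a))


def block_fits(df: pd.DataFrame) -> pd.DataFrame:
    """Per participant x retention condition regressions and indifference points.

    Returns a tidy table with columns ``participant``, ``retention_s``,
    ``slope``, ``intercept``, ``indifference_ms`` (NaN when the slope is
    at unity) and ``n_trials``.
    """
    validate_dataset(df)
    rows = []
    for (p, ret), cell in df.groupby(["participant", "retention_s"], sort=True):
        a, b = fit_block_regression(cell)
        rows.append(
            {
                "participant": p,
                "retention_s": ret,
                "slope": a,
                "intercept": b,
                "indifference_ms": indifference_point(a, b),
                "n_trials": len(cell),
            }
        )
    return pd.DataFrame(rows)


def _cell_values(trials: pd.DataFrame, scale: str) -> tuple[np.ndarray, np.ndarray]:
    s = trials["sample_ms"].to_numpy(float)
    r = trials["reproduced_ms"].to_numpy(float)
    if scale == "log10":
        return np.log10(s), np.log10(r)
    if scale == "linear_ms":
        return s, r
    raise ValueError(f"scale must be 'linear_ms' or 'log10', got {scale!r}")


def normalize_reproductions(trials: pd.DataFrame, scale: str = "linear_ms") -> np.ndarray:
    """Recenter reproductions on the mean sample interval.

    For one participant x condition cell, ``R'_{i,n} = R_{i,n} - Rbar + Sbar``
    where ``Rbar`` is the mean reproduction and ``Sbar`` the mean sample
    over all trials of the cell.  The mean of the result equals ``Sbar``
    exactly, so between-participant offsets are removed before the error
    decomposition.
    """
    if len(trials) == 0:
        raise ValueError("normalize_reproductions needs a non-empty cell")
    s, r = _cell_values(trials, scale)
    return r - r.mean() + s.mean()


def vertical_error(r_prime: np.ndarray, s: np.ndarray, s_bar: float) -> float:
    """Accuracy term for one interval: |mean(R'_i) - S_i| / Sbar."""
    return float(abs(np.mean(r_prime) - s) / s_bar)


def coefficient_of_variation(r_prime: np.ndarray, s_bar: float) -> float:
    """Precision term for one interval: population SD of R'_i over Sbar."""
    r_prime = np.asarray(r_prime, dtype=float)
    return float(np.sqrt(np.mean((r_prime - r_prime.mean()) ** 2)) / s_bar)


def error_stats(df: pd.DataFrame, scale: str = "linear_ms") -> pd.DataFrame:
    """VE and CV per participant x retention condition x sample interval.

    VE (vertical error) is the normalized absolute deviation of the mean
    recentered reproduction from the true interval — an accuracy
    measure.  CV is the population SD of the recentered reproductions
    over the mean interval — a precision measure.  Both are computed on
    the chosen scale (``linear_ms`` default, ``log10`` available).
    """
    validate_dataset(df)
    rows = []
    for (p, ret), cell in df.groupby(["participant", "retention_s"], sort=True):
        s, _ = _cell_values(cell, scale)
        s_bar = s.mean()
        r_prime = normalize_reproductions(cell, scale)
        cell = cell.assign(_s=s, _rp=r_prime)
        for s_i, grp in cell.groupby("_s", sort=True):
            rp = grp["_rp"].to_numpy()
            rows.append(
                {
                    "participant": p,
                    "retention_s": ret,
                    "sample_ms": float(grp["sample_ms"].iloc[0]),
                    "ve": vertical_error(rp, s_i, s_bar),
                    "cv": coefficient_of_variation(rp, s_bar),
                    "n_reps": len(grp),
                    "scale": scale,
                }
            )
    return pd.DataFrame(rows)
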