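"""Summary statistics for per-cell comet and γH2AX assay data.

Reduces scored single-cell tables to the study-style summaries: median
%DNA-in-tail time-courses with IQRs and bootstrap confidence intervals,
differences of medians from the pre-treatment baseline with permutation
p-values, pooled time-courses, and γH2AX positivity / foci-per-nucleus
summaries with the overlap-capping rule (raw counts above 10 are
recorded as 25 foci, reflecting uncountable merged foci at early
time-points).

Quartiles use linear interpolation (numpy default); confidence
intervals are seeded percentile bootstraps (2000 resamples by default);
significance is a seeded two-sided permutation test on the difference of
medians.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model_fitting import ObservationSeries

__all__ = [
    "CometCellRecord",
    "FociCellRecord",
    "TimecourseSummary",
    "TIMEPOINT_MINUTES",
    "summarize_comet",
    "differences_from_baseline",
    "pool_timecourses",
    "apply_foci_cap",
    "summarize_h2ax",
    "read_comet_csv",
    "read_foci_csv",
]

logger = logging.getLogger(__name__)

#: study sampling schedule: minutes relative to completion of irradiation;
#: the pre-next-fraction sample is its own label (days later), never merged
#: with T0.
TIMEPOINT_MINUTES = {
    "T0": -15.0,
    "T15": 15.0,
    "T30": 30.0,
    "T60": 60.0,
    "T120": 120.0,
    "T360": 360.0,
    "pre_next": float("nan"),
}

COMET_COLUMNS = ["patient", "fraction", "timepoint", "minutes", "cell",
                 "tail_intensity"]
FOCI_COLUMNS = ["patient", "timepoint", "cell", "foci_raw"]

FOCI_CAP_THRESHOLD = 10
FOCI_CAP_VALUE = 25


@dataclass(frozen=True)
class CometCellRecord:
    """One scored comet-assay cell."""

    patient: str
    fraction: int
    timepoint: str
    minutes: float
    cell: int
    tail_intensity: float  # %DNA in tail

    def __post_init__(self) -> None:
        if not (0.0 <= self.tail_intensity <= 100.0):
            raise ValueError("tail intensity must lie in [0, 100]")
        expected = TIMEPOINT_MINUTES.get(self.timepoint)
        if expected is not None and not np.isnan(expected) and expected != self.minutes:
            raise ValueError(
                f"timepoint {self.timepoint} inconsistent with minutes {self.minutes}")


@dataclass(frozen=True)
class FociCellRecord:
    """One scored γH2AX cell (raw and capped focus count)."""

    patient: str
    timepoint: str
    cell: int
    foci_raw: int

    def __post_init__(self) -> None:
        if self.foci_raw < 0:
            raise ValueError("raw focus count must be >= 0")

    @property
    def foci_capped(self) -> int:
        return apply_foci_cap(self.foci_raw)


@dataclass
class TimecourseSummary:
    """Per-group median/IQR/CI summary backed by a tidy DataFrame.

    Columns: the grouping keys, ``timepoint``, ``minutes``, ``n``,
    ``median``, ``q1``, ``q3``, ``ci_low``, ``ci_high``.
    """

    data: pd.DataFrame
    grouping: str = "per-sample"
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.data.to_csv(path, index=False)


def _as_frame(records, columns) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [r.__dict__ if hasattr(r, "__dict__") else r for r in records]
    df = pd.DataFrame(rows)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"records missing column(s): {', '.join(missing)}")
    return df


def _boot_median_ci(x: np.ndarray, rng: np.random.Generator,
                    n_boot: int = 2000, level: float = 0.95):
    x = np.sort(x)  # resampling a sorted copy makes the CI order-invariant
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    meds = np.median(x[idx], axis=1)
    a = 100.0 * (1.0 - level) / 2.0
    lowhigh = np.percentile(meds, [a, 100.0 - a])
    return float(lowhigh[0]), float(lowhigh[1])


def _timepoint_sort_key(tp: str) -> float:
    m = TIMEPOINT_MINUTES.get(tp)
    return float("inf") if m is None or np.isnan(m) else m


def summarize_comet(records, grouping: str = "per-sample",
                    n_boot: int = 2000, seed: int = 0) -> TimecourseSummary:
    """Median/IQR/95%-CI of %DNA in tail per timepoint and group.

    grouping
        ``per-sample`` — each (patient, fraction) series separately;
        ``per-patient`` — fractions of a patient pooled;
        ``per-fraction`` — patients pooled within each fraction index.
    """
    df = _as_frame(records, COMET_COLUMNS[:3] + ["tail_intensity"])
    if df.empty:
        raise ValueError("no records to summarize")
    bad = df[(df["tail_intensity"] < 0) | (df["tail_intensity"] > 100)]
    if len(bad):
        raise ValueError("tail intensity outside [0, 100]")
    group_cols = {
        "per-sample": ["patient", "fraction"],
        "per-patient": ["patient"],
        "per-fraction": ["fraction"],
    }.get(grouping)
    if group_cols is None:
        raise ValueError(f"unknown grouping: {grouping!r}")
    group_cols = [c for c in group_cols if c in df.columns]
    rng = np.random.default_rng(seed)
    rows = []
    keys = group_cols + ["timepoint"]
    for gk, sub in df.groupby(keys, sort=True):
        x = sub["tail_intensity"].to_numpy(dtype=float)
        if x.size == 0:
            raise ValueError(f"empty group {gk}")
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        lo, hi = _boot_median_ci(x, rng, n_boot=n_boot)
        gk = gk if isinstance(gk, tuple) else (gk,)
        row = dict(zip(keys, gk))
        tp = row["timepoint"]
        row.update({
            "minutes": (float(sub["minutes"].iloc[0]) if "minutes" in sub
                        else TIMEPOINT_MINUTES.get(tp, float("nan"))),
            "n": int(x.size), "median": float(med),
            "q1": float(q1), "q3": float(q3),
            "ci_low": lo, "ci_high": hi,
        })
        rows.append(row)
    out = pd.DataFrame(rows)
    out["_order"] = out["timepoint"].map(_timepoint_sort_key)
    out = (out.sort_values(group_cols + ["_order"])
           .drop(columns="_order").reset_index(drop=True))
    return TimecourseSummary(data=out, grouping=grouping,
                             metadata={"n_boot": n_boot, "seed": seed})


def permutation_test_median_diff(x0, xk, n_perm: int = 10_000,
                                 seed: int = 0) -> tuple:
    """Two-sided permutation test on the difference of group medians.

    Returns ``(difference, p_value)`` where difference is
    ``median(xk) - median(x0)`` and the p-value carries the standard
    +1 correction (never exactly zero).
    """
    x0 = np.asarray(x0, dtype=float)
    xk = np.asarray(xk, dtype=float)
    if x0.size < 2 or xk.size < 2:
        raise ValueError("permutation test needs at least 2 values per group")
    rng = np.random.default_rng(seed)
    diff = float(np.median(xk) - np.median(x0))
    return diff, _perm_median_diff_p(x0, xk, diff, rng, n_perm=n_perm)


def _perm_median_diff_p(x0: np.ndarray, xk: np.ndarray, observed: float,
                        rng: np.random.Generator, n_perm: int = 10_000) -> float:
    pool = np.sort(np.concatenate([x0, xk]))  # order-invariant permutations
    n0 = x0.size
    # vectorised label permutation in manageable chunks
    count = 0
    chunk = max(1, min(n_perm, int(2e6 // max(pool.size, 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        mat = np.tile(pool, (m, 1))
        mat = rng.permuted(mat, axis=1)
        diffs = np.median(mat[:, n0:], axis=1) - np.median(mat[:, :n0], axis=1)
        count += int(np.sum(np.abs(diffs) >= abs(observed) - 1e-12))
        done += m
    return (1.0 + count) / (n_perm + 1.0)


def differences_from_baseline(records, n_boot: int = 2000,
                              n_perm: int = 10_000, seed: int = 0,
                              baseline: str = "T0") -> pd.DataFrame:
    """Difference of median tail intensity of each timepoint vs baseline.

    Cells are pooled per timepoint across patients and fractions.  The
    CI is a percentile bootstrap of the difference of medians; the
    p-value is a two-sided permutation test on the same statistic.  For
    degenerate groups (n = 1 on either side) the difference is still
    computed but CI and p are flagged unavailable (NaN).
    """
    df = _as_frame(records, ["timepoint", "tail_intensity"])
    if baseline not in set(df["timepoint"]):
        raise ValueError(f"baseline timepoint {baseline!r} missing")
    rng = np.random.default_rng(seed)
    x0 = np.sort(df.loc[df["timepoint"] == baseline,
                        "tail_intensity"].to_numpy(dtype=float))
    rows = []
    tps = sorted((tp for tp in df["timepoint"].unique() if tp != baseline),
                 key=_timepoint_sort_key)
    for tp in tps:
        xk = np.sort(df.loc[df["timepoint"] == tp,
                            "tail_intensity"].to_numpy(dtype=float))
        diff = float(np.median(xk) - np.median(x0))
        if x0.size < 2 or xk.size < 2:
            lo = hi = p = float("nan")
        else:
            i0 = rng.integers(0, x0.size, size=(n_boot, x0.size))
            ik = rng.integers(0, xk.size, size=(n_boot, xk.size))
            boots = np.median(xk[ik], axis=1) - np.median(x0[i0], axis=1)
            lo, hi = (float(v) for v in np.percentile(boots, [2.5, 97.5]))
            p = _perm_median_diff_p(x0, xk, diff, rng, n_perm=n_perm)
        rows.append({"timepoint": tp, "difference": diff,
                     "ci_low": lo, "ci_high": hi, "p_value": p,
                     "n_baseline": int(x0.size), "n_timepoint": int(xk.size)})
    return pd.DataFrame(rows)


def pool_timecourses(series: Sequence[ObservationSeries]) -> ObservationSeries:
    """Average per-fraction median time-courses point-wise.

    All series must share the same timepoints; medians (and quartiles,
    when present in every series) are pooled as arithmetic means.
    Symmetric in the input order.
    """
    if not series:
        raise ValueError("no series to pool")
    t0 = series[0].times
    for s in series[1:]:
        if len(s) != len(series[0]) or not np.allclose(s.times, t0):
            raise ValueError("series timepoints do not match")
    medians = np.mean([s.medians for s in series], axis=0)
    q1 = q3 = None
    if all(s.q1 is not None for s in series):
        q1 = np.mean([s.q1 for s in series], axis=0)
    if all(s.q3 is not None for s in series):
        q3 = np.mean([s.q3 for s in series], axis=0)
    return ObservationSeries(times=t0.copy(), medians=medians, q1=q1, q3=q3,
                             metadata={"pooled": True, "n_series": len(series)})


def apply_foci_cap(raw):
    """Overlap-capping rule for γH2AX focus counts: counts above 10 are
    recorded as 25 foci per cell (merged foci cannot be resolved); counts
    of 10 or fewer are kept verbatim.  Idempotent on already-capped data.
    """
    arr = np.asarray(raw)
    if np.any(arr < 0):
        raise ValueError("focus counts must be >= 0")
    capped = np.where(arr > FOCI_CAP_THRESHOLD, FOCI_CAP_VALUE, arr)
    if np.isscalar(raw) or getattr(raw, "ndim", 1) == 0:
        return type(raw)(capped.item()) if isinstance(raw, (int, float)) else capped.item()
    return capped


def summarize_h2ax(records, threshold: int = 1, group_col: str = "timepoint",
                   n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Per-group %positive cells and median capped foci per nucleus.

    A cell is positive when its capped count reaches ``threshold`` foci
    (the positivity criterion is a configurable choice; 1 focus by
    default).  Pass ``group_col='tumor_type'`` for baseline summaries
    over tumour histologies.  CIs are seeded percentile bootstraps.
    """
    df = _as_frame(records, ["foci_raw"])
    if group_col not in df.columns:
        raise ValueError(f"records lack grouping column {group_col!r}")
    if df.empty:
        raise ValueError("no records to summarize")
    rng = np.random.default_rng(seed)
    rows = []
    groups = sorted(df[group_col].unique(),
                    key=_timepoint_sort_key if group_col == "timepoint" else str)
    for g in groups:
        sub = df.loc[df[group_col] == g]
        capped = apply_foci_cap(sub["foci_raw"].to_numpy(dtype=int))
        positive = capped >= threshold
        pct = 100.0 * positive.mean()
        med = float(np.median(capped))
        idx = rng.integers(0, capped.size, size=(n_boot, capped.size))
        boot = capped[idx]
        pct_lo, pct_hi = np.percentile(100.0 * (boot >= threshold).mean(axis=1),
                                       [2.5, 97.5])
        med_lo, med_hi = np.percentile(np.median(boot, axis=1), [2.5, 97.5])
        rows.append({
            group_col: g, "n": int(capped.size),
            "pct_positive": float(pct),
            "pct_positive_ci_low": float(pct_lo),
            "pct_positive_ci_high": float(pct_hi),
            "median_foci": med,
            "median_foci_ci_low": float(med_lo),
            "median_foci_ci_high": float(med_hi),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV dialect of the scoring software: header row, comma separator,
# decimal point.  strict=False skips malformed rows with a warning.


def _read_csv_tolerant(path, required, numeric, strict):
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    bad_mask = np.zeros(len(df), dtype=bool)
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_mask |= coerced.isna().to_numpy()
        df[col] = coerced
    if bad_mask.any():
        lines = (np.nonzero(bad_mask)[0] + 2).tolist()  # header is line 1
        msg = f"{path}: malformed row(s) at line(s) {lines}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + " — skipped")
        logger.warning(msg)
        df = df.loc[~bad_mask]
    return df.reset_index(drop=True)


def read_comet_csv(path: Union[str, Path], strict: bool = True) -> pd.DataFrame:
    """Read a per-cell comet scoring table (columns as in COMET_COLUMNS)."""
    df = _read_csv_tolerant(path, ["patient", "timepoint", "tail_intensity"],
                            ["tail_intensity"], strict)
    out_of_range = (df["tail_intensity"] < 0) | (df["tail_intensity"] > 100)
    if out_of_range.any():
        lines = (np.nonzero(out_of_range.to_numpy())[0] + 2).tolist()
        msg = f"{path}: tail intensity outside [0, 100] at line(s) {lines}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + " — skipped")
        df = df.loc[~out_of_range].reset_index(drop=True)
    return df


def read_foci_csv(path: Union[str, Path], strict: bool = True) -> pd.DataFrame:
    """Read a per-cell γH2AX focus-count table (columns as in FOCI_COLUMNS)."""
    df = _read_csv_tolerant(path, ["patient", "timepoint", "foci_raw"],
                            ["foci_raw"], strict)
    neg = df["foci_raw"] < 0
    if neg.any():
        lines = (np.nonzero(neg.to_numpy())[0] + 2).tolist()
        msg = f"{path}: negative focus count at line(s) {lines}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + " — skipped")
        df = df.loc[~neg].reset_index(drop=True)
    df["foci_raw"] = df["foci_raw"].astype(int)
    return df
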