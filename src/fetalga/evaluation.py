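"""Agreement statistics over (predicted GA, reference GA) pairs.

The evaluation battery: mean absolute error within gestational-age bands,
paired Wilcoxon signed-rank comparison of absolute errors against a
comparator (biometry), Bland-Altman limits of agreement, the empirical
distribution of time-to-prediction on videos, and the shuffle-consistency
fraction for re-shuffled clip pairs.  The unit of analysis is the scan:
aggregate to one record per scan before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

#: Default GA band breakpoints in weeks (half-open [lo, hi) intervals):
#: 10-14, 14-18, 18-24, 24-30, 30-36.
DEFAULT_BAND_WEEKS = (10, 14, 18, 24, 30, 36)

SHUFFLE_CONSISTENCY_THRESHOLD_DAYS = 3.0


def band_label(edges_weeks: Sequence[float], i: int) -> str:
    return f"{edges_weeks[i]:g}-{edges_weeks[i + 1]:g}"


def assign_band(
    reference_ga_days, edges_weeks: Sequence[float] = DEFAULT_BAND_WEEKS
) -> np.ndarray:
    """Band index of each reference GA; -1 when outside every band.

    Bands are half-open [lo, hi) in weeks of reference GA.
    """
    edges = np.asarray(edges_weeks, dtype=float) * 7.0
    if not np.all(np.diff(edges) > 0):
        raise ValueError("band breakpoints must be strictly increasing")
    ga = np.asarray(reference_ga_days, dtype=float)
    idx = np.searchsorted(edges, ga, side="right") - 1
    idx[(ga < edges[0]) | (ga >= edges[-1])] = -1
    return idx


def mae_by_band(
    records: pd.DataFrame,
    edges_weeks: Sequence[float] = DEFAULT_BAND_WEEKS,
    predicted_col: str = "predicted_ga_days",
    reference_col: str = "reference_ga_days",
) -> pd.DataFrame:
    """Per-band scan count and MAE (days) of predicted vs reference GA.

    Empty bands report n = 0 and a missing MAE.
    """
    if records.empty:
        raise ValueError("no records")
    idx = assign_band(records[reference_col], edges_weeks)
    abs_err = np.abs(
        records[predicted_col].to_numpy(float) - records[reference_col].to_numpy(float)
    )
    rows = []
    for b in range(len(edges_weeks) - 1):
        sel = idx == b
        rows.append(
            {
                "band_weeks": band_label(edges_weeks, b),
                "n": int(sel.sum()),
                "mae_days": float(abs_err[sel].mean()) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float
    n_effective: int
    degenerate: bool  # all paired differences were zero


def paired_wilcoxon(
    abs_err_model: Sequence[float], abs_err_comparator: Sequence[float]
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired absolute errors.

    Zero differences are dropped (Wilcoxon's original rule).  The exact null
    distribution is used for n <= 25 effective pairs; above that, the normal
    approximation with continuity correction.  If every difference is zero
    the test is degenerate and p = 1 is reported with a flag.
    """
    a = np.asarray(abs_err_model, dtype=float)
    b = np.asarray(abs_err_comparator, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0.0]
    if len(d) == 0:
        return WilcoxonResult(p_value=1.0, statistic=0.0, n_effective=0, degenerate=True)
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(
        d, correction=True, alternative="two-sided", method=method
    )
    return WilcoxonResult(
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        n_effective=int(len(d)),
        degenerate=False,
    )


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    loa_low: Optional[float]
    loa_high: Optional[float]
    sd_difference: Optional[float]
    differences: np.ndarray
    means: np.ndarray


def bland_altman(
    predicted: Sequence[float], reference: Sequence[float]
) -> BlandAltman:
    """Bland-Altman agreement: differences (predicted - reference), their
    mean, and 95% limits of agreement (mean +/- 1.96 SD).  Limits are
    undefined for fewer than 3 pairs."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("predicted and reference must be equal-length, non-empty")
    diffs = p - r
    means = (p + r) / 2.0
    mean_diff = float(diffs.mean())
    if p.size < 3:
        return BlandAltman(mean_diff, None, None, None, diffs, means)
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        mean_difference=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        sd_difference=sd,
        differences=diffs,
        means=means,
    )


@dataclass(frozen=True)
class TimeToPredictionCDF:
    times_s: np.ndarray       # sorted unique reached times
    cdf: np.ndarray           # fraction of ALL videos predicted by each time
    median_s: Optional[float] # None if fewer than half ever reached
    n_total: int
    n_censored: int

    def at(self, t: float) -> float:
        """CDF evaluated at time t."""
        i = np.searchsorted(self.times_s, t, side="right")
        return float(self.cdf[i - 1]) if i > 0 else 0.0


def time_to_prediction_cdf(
    times_s: Sequence[Optional[float]],
) -> TimeToPredictionCDF:
    """Empirical CDF of time to a confident prediction.

    ``None`` entries are videos where confidence was never reached; they are
    right-censored — counted in the denominator, never as reached.  The
    median is the smallest time at which the CDF reaches 0.5 (undefined if
    it never does).
    """
    arr = list(times_s)
    if not arr:
        raise ValueError("no times")
    reached = np.sort([t for t in arr if t is not None])
    n = len(arr)
    cdf = np.arange(1, len(reached) + 1) / n
    # collapse ties to the last occurrence
    times, last_idx = np.unique(reached, return_index=True)
    counts = np.diff(np.append(last_idx, len(reached)))
    cdf_u = np.cumsum(counts) / n
    median = None
    hit = np.nonzero(cdf_u >= 0.5)[0]
    if hit.size:
        median = float(times[hit[0]])
    return TimeToPredictionCDF(
        times_s=times,
        cdf=cdf_u,
        median_s=median,
        n_total=n,
        n_censored=n - len(reached),
    )


def shuffle_consistency(
    estimates_a: Sequence[float],
    estimates_b: Sequence[float],
    threshold_days: float = SHUFFLE_CONSISTENCY_THRESHOLD_DAYS,
) -> float:
    """Fraction of re-shuffled clip pairs whose GA estimates differ by
    strictly less than the threshold (default 3 days)."""
    a = np.asarray(estimates_a, dtype=float)
    b = np.asarray(estimates_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired estimates must be equal-length, non-empty")
    return float(np.mean(np.abs(a - b) < threshold_days))


def evaluate_records(
    records: pd.DataFrame,
    edges_weeks: Sequence[float] = DEFAULT_BAND_WEEKS,
) -> dict:
    """The full battery on a records table.

    Expects columns predicted_ga_days and reference_ga_days; optionally
    comparator_ga_days (biometry) and time_to_prediction_s.  Returns a
    JSON-serialisable dict mirroring the banded-MAE table structure, with
    Wilcoxon model-vs-comparator p-values per band where a comparator
    exists, overall Bland-Altman agreement, and the time-to-prediction
    distribution when available.
    """
    out: dict = {}
    table = mae_by_band(records, edges_weeks)
    has_comp = "comparator_ga_days" in records.columns and records[
        "comparator_ga_days"
    ].notna().any()
    if has_comp:
        idx = assign_band(records["reference_ga_days"], edges_weeks)
        err_m = np.abs(
            records["predicted_ga_days"].to_numpy(float)
            - records["reference_ga_days"].to_numpy(float)
        )
        err_c = np.abs(
            records["comparator_ga_days"].to_numpy(float)
            - records["reference_ga_days"].to_numpy(float)
        )
        comp_mae, pvals = [], []
        for b in range(len(edges_weeks) - 1):
            sel = (idx == b) & records["comparator_ga_days"].notna().to_numpy()
            if sel.any():
                comp_mae.append(float(err_c[sel].mean()))
                pvals.append(paired_wilcoxon(err_m[sel], err_c[sel]).p_value)
            else:
                comp_mae.append(np.nan)
                pvals.append(np.nan)
        table["comparator_mae_days"] = comp_mae
        table["wilcoxon_p"] = pvals
    out["mae_by_band"] = table.to_dict(orient="records")
    ba = bland_altman(records["predicted_ga_days"], records["reference_ga_days"])
    out["bland_altman"] = {
        "mean_difference_days": ba.mean_difference,
        "loa_low_days": ba.loa_low,
        "loa_high_days": ba.loa_high,
    }
    if "time_to_prediction_s" in records.columns:
        times = [
            None if pd.isna(t) else float(t) for t in records["time_to_prediction_s"]
        ]
        c = time_to_prediction_cdf(times)
        out["time_to_prediction"] = {
            "median_s": c.median_s,
            "n_total": c.n_total,
            "n_censored": c.n_censored,
        }
    return out
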