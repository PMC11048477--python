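"""Breath-hold statistical pipeline: windowing, ANOVA, post hoc t-tests, correlations.

The analysis convention: each trace is epoched from −5 s (baseline) to +45 s
around task onset, averaged in ten half-open 5-s windows, and
baseline-subtracted so the (−5, 0) window is exactly zero.  Trials (not
subjects) are the observations pooled into the group analysis; a one-way
ANOVA across the ten windows is followed, when significant, by one-sample
two-tailed t-tests against zero per post-onset window, with no
multiple-testing correction by default (Bonferroni/FDR flags are available).
Windows are treated as independent groups (no repeated-measures correction);
this mirrors the device-study convention and is noted in the report.

Pearson correlations among the hemodynamic signals are computed on the
group-mean baseline-subtracted window series by default (10 points per
signal), with a pooled per-trial option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .io import Recording

__all__ = [
    "WINDOW_STARTS",
    "AnovaResult",
    "TTestResult",
    "SnrResult",
    "StatReport",
    "epoch_windows",
    "baseline_subtract",
    "oneway_anova",
    "one_sample_t",
    "pearson",
    "snr_screen",
    "window_table",
    "group_analysis",
]

#: window start times (s relative to onset) for the −5…45 s analysis range
WINDOW_STARTS = tuple(float(x) for x in range(-5, 45, 5))

SIGNALS = ("hbo_3cm", "hbo_4cm", "sto2_srs", "sto2_ssds_3cm", "sto2_ssds_4cm")


class AnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


@dataclass
class SnrResult:
    passed: bool
    metrics: dict[str, float]
    threshold: float


@dataclass
class StatReport:
    """Group statistics: per-signal ANOVA, per-window t-tests, correlations."""

    anova: dict[str, AnovaResult]
    ttests: dict[str, dict[float, TTestResult]]
    correlations: pd.DataFrame
    group_means: pd.DataFrame
    n_trials: int
    notes: tuple[str, ...] = (
        "windows treated as independent groups (no repeated-measures correction)",
        "post hoc t-test p-values are uncorrected by default",
    )


def epoch_windows(
    time: np.ndarray,
    values: np.ndarray,
    onset: float,
    window_s: float = 5.0,
    t_range: tuple[float, float] = (-5.0, 45.0),
    qc_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean of ``values`` in half-open windows [t0, t0+window_s) around onset.

    QC-flagged or non-finite samples are excluded from the means.  A window
    with no usable samples is an error naming the window.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    rel = time - onset
    usable = np.isfinite(values)
    if qc_mask is not None:
        usable &= ~np.asarray(qc_mask, dtype=bool)
    starts = np.arange(t_range[0], t_range[1], window_s)
    means = np.empty(starts.size)
    for i, t0 in enumerate(starts):
        sel = (rel >= t0) & (rel < t0 + window_s) & usable
        if not np.any(sel):
            raise ValidationError(
                f"window [{t0:g}, {t0 + window_s:g}) s has no usable samples"
            )
        means[i] = values[sel].mean()
    return means


def baseline_subtract(window_means: np.ndarray) -> np.ndarray:
    """Subtract the first (baseline) window; baseline becomes exactly zero.

    Shift-invariant and idempotent.
    """
    w = np.asarray(window_means, dtype=float)
    if w.size == 0:
        raise ValidationError("no windows to baseline-subtract")
    return w - w[0]


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Single-factor one-way ANOVA: between/within mean-square ratio."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValidationError("ANOVA needs ≥2 groups with ≥2 values each")
    n_total = sum(a.size for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0:
        raise ValidationError("zero within-group variance; F is undefined")
    res = sps.f_oneway(*arrays)
    return AnovaResult(
        F=float(res.statistic),
        df1=len(arrays) - 1,
        df2=n_total - len(arrays),
        p=float(res.pvalue),
    )


def one_sample_t(values: Sequence[float], mu: float = 0.0) -> TTestResult:
    """Two-tailed one-sample t-test of the mean against ``mu``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("t-test needs at least two values")
    if np.ptp(x) == 0:
        raise ValidationError("zero sample variance; t is undefined")
    res = sps.ttest_1samp(x, popmean=mu)
    return TTestResult(t=float(res.statistic), df=x.size - 1, p=float(res.pvalue))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient ρ ∈ [−1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson needs equal-length inputs with n ≥ 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance input to correlation")
    return float(sps.pearsonr(x, y).statistic)


def snr_screen(
    recording: Recording,
    threshold: float = 20.0,
    smooth_window_s: float = 0.5,
) -> SnrResult:
    """Per-channel SNR screen: mean intensity over high-frequency residual sd.

    The residual is the signal minus a moving-average trend (window
    ``smooth_window_s``), so slow physiology does not count as noise.  The
    recording fails if any channel's metric falls below ``threshold``.  The
    criterion is a configurable stand-in for a device-specific screen.
    """
    n_smooth = max(1, int(round(smooth_window_s * recording.fs)))
    kernel = np.ones(n_smooth) / n_smooth
    metrics: dict[str, float] = {}
    for col in recording.frame.columns:
        if col == "time_s":
            continue
        x = recording.frame[col].to_numpy(dtype=float)
        pad = n_smooth // 2
        trend = np.convolve(np.pad(x, pad, mode="edge"), kernel, mode="same")[
            pad:pad + x.size
        ]
        resid_sd = float(np.std(x - trend))
        mean_level = float(np.mean(x))
        metrics[col] = np.inf if resid_sd == 0 else mean_level / resid_sd
    passed = all(m >= threshold for m in metrics.values())
    return SnrResult(passed=passed, metrics=metrics, threshold=threshold)


# ---------------------------------------------------------------------------
# group-level analysis
# ---------------------------------------------------------------------------

def window_table(
    trials: Sequence[tuple[str, pd.DataFrame, float]],
    signals: Sequence[str] = SIGNALS,
    window_s: float = 5.0,
    t_range: tuple[float, float] = (-5.0, 45.0),
) -> pd.DataFrame:
    """Tidy baseline-subtracted window means from processed worksheets.

    ``trials`` is a sequence of (trial id, processed frame, onset) tuples;
    each processed frame follows the processed-worksheet schema (NaN where a
    sample was QC-flagged).  Returns columns trial, signal, window_start,
    value.
    """
    rows = []
    for trial_id, frame, onset in trials:
        t = frame["time_s"].to_numpy(dtype=float)
        for sig in signals:
            if sig not in frame.columns:
                continue
            means = epoch_windows(
                t, frame[sig].to_numpy(dtype=float), onset, window_s, t_range
            )
            values = baseline_subtract(means)
            starts = np.arange(t_range[0], t_range[1], window_s)
            for t0, v in zip(starts, values):
                rows.append(
                    {"trial": trial_id, "signal": sig,
                     "window_start": float(t0), "value": float(v)}
                )
    return pd.DataFrame(rows)


def group_analysis(
    windows: pd.DataFrame,
    correlation_mode: str = "group_mean",
    mt_correction: str | None = None,
) -> StatReport:
    """Pooled-trial group statistics from a tidy window table.

    Each trial is one observation (the trial-pooling convention).  The ANOVA
    spans all windows including baseline; post hoc t-tests cover post-onset
    windows only (the baseline window is identically zero by construction).
    ``mt_correction`` ∈ {None, "bonferroni", "fdr_bh"} adjusts t-test p-values.
    """
    required = {"trial", "signal", "window_start", "value"}
    if not required <= set(windows.columns):
        raise ValidationError(f"window table must have columns {sorted(required)}")
    if correlation_mode not in ("group_mean", "pooled"):
        raise ValidationError(f"unknown correlation mode '{correlation_mode}'")
    n_trials = windows["trial"].nunique()
    if n_trials < 2:
        raise ValidationError("group analysis needs at least two trials")

    anova: dict[str, AnovaResult] = {}
    ttests: dict[str, dict[float, TTestResult]] = {}
    mean_rows = []
    signals = list(dict.fromkeys(windows["signal"]))
    for sig in signals:
        sub = windows[windows["signal"] == sig]
        groups = [
            sub.loc[sub["window_start"] == t0, "value"].to_numpy()
            for t0 in sorted(sub["window_start"].unique())
        ]
        anova[sig] = oneway_anova(groups)
        per_window: dict[float, TTestResult] = {}
        for t0 in sorted(sub["window_start"].unique()):
            vals = sub.loc[sub["window_start"] == t0, "value"].to_numpy()
            mean_rows.append(
                {"signal": sig, "window_start": t0, "mean": vals.mean(),
                 "se": vals.std(ddof=1) / np.sqrt(vals.size), "n": vals.size}
            )
            if t0 >= 0:  # baseline window is identically zero
                per_window[float(t0)] = one_sample_t(vals)
        if mt_correction:
            per_window = _adjust_pvalues(per_window, mt_correction)
        ttests[sig] = per_window

    group_means = pd.DataFrame(mean_rows)

    # correlations among signals
    corr = pd.DataFrame(np.eye(len(signals)), index=signals, columns=signals)
    for i, si in enumerate(signals):
        for j, sj in enumerate(signals):
            if j <= i:
                continue
            if correlation_mode == "group_mean":
                xi = group_means.query("signal == @si").sort_values("window_start")["mean"]
                xj = group_means.query("signal == @sj").sort_values("window_start")["mean"]
                rho = pearson(xi.to_numpy(), xj.to_numpy())
            else:
                pi = windows[windows["signal"] == si].pivot_table(
                    index="trial", columns="window_start", values="value"
                )
                pj = windows[windows["signal"] == sj].pivot_table(
                    index="trial", columns="window_start", values="value"
                )
                common = pi.index.intersection(pj.index)
                rho = pearson(
                    pi.loc[common].to_numpy().ravel(),
                    pj.loc[common].to_numpy().ravel(),
                )
            corr.loc[si, sj] = corr.loc[sj, si] = rho

    return StatReport(
        anova=anova,
        ttests=ttests,
        correlations=corr,
        group_means=group_means,
        n_trials=int(n_trials),
    )


def _adjust_pvalues(
    per_window: dict[float, TTestResult], method: str
) -> dict[float, TTestResult]:
    keys = list(per_window)
    p = np.array([per_window[k].p for k in keys])
    if method == "bonferroni":
        p_adj = np.minimum(p * p.size, 1.0)
    elif method == "fdr_bh":
        order = np.argsort(p)
        ranked = p[order] * p.size / (np.arange(p.size) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        p_adj = np.empty_like(p)
        p_adj[order] = np.minimum(ranked, 1.0)
    else:
        raise ValidationError(f"unknown multiple-testing correction '{method}'")
    return {
        k: TTestResult(t=per_window[k].t, df=per_window[k].df, p=float(pa))
        for k, pa in zip(keys, p_adj)
    }
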