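"""Benchmarking reference-based vs population-averaged VEP scores against
annotation tables: paired Spearman correlations, the win rate, and the
three-parameter logistic allele-frequency fit."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit


@dataclass
class AnnotationBenchmarkRow:
    name: str
    n: int
    r_ref: float
    p_ref: float
    r_mean: float
    p_mean: float
    eligible: bool  # both correlations significant at p < 0.05
    win: bool | None  # |r_mean| > |r_ref| strictly; None if not eligible


def annotation_correlations(
    vep_ref,
    vep_mean,
    annotation_table: pd.DataFrame,
    p_threshold: float = 0.05,
    min_pairs: int = 3,
) -> list[AnnotationBenchmarkRow]:
    """Spearman correlations (mid-rank ties, two-sided p) of both score
    vectors against each annotation column, pairwise-complete.

    Annotations with fewer than ``min_pairs`` complete pairs are skipped.
    Eligibility requires both correlations significant at ``p_threshold``;
    a win is a strict |r_mean| > |r_ref|.
    """
    ref = np.asarray(vep_ref, dtype=float)
    mean = np.asarray(vep_mean, dtype=float)
    if ref.shape != mean.shape or len(ref) != len(annotation_table):
        raise ValueError("score vectors and annotation table must align")
    rows = []
    for name in annotation_table.columns:
        ann = annotation_table[name].to_numpy(dtype=float)
        mask = ~(np.isnan(ann) | np.isnan(ref) | np.isnan(mean))
        if mask.sum() < min_pairs:
            continue
        r_ref, p_ref = stats.spearmanr(ref[mask], ann[mask])
        r_mean, p_mean = stats.spearmanr(mean[mask], ann[mask])
        eligible = bool(p_ref < p_threshold and p_mean < p_threshold)
        win = bool(abs(r_mean) > abs(r_ref)) if eligible else None
        rows.append(AnnotationBenchmarkRow(
            name=name, n=int(mask.sum()),
            r_ref=float(r_ref), p_ref=float(p_ref),
            r_mean=float(r_mean), p_mean=float(p_mean),
            eligible=eligible, win=win,
        ))
    return rows


def win_rate(rows: list[AnnotationBenchmarkRow]):
    """Proportion of eligible annotations won by the population average;
    ties (|r_mean| == |r_ref|) count as neither win nor loss but stay in
    the denominator.  Returns None when no row is eligible."""
    eligible = [r for r in rows if r.eligible]
    if not eligible:
        return None
    wins = sum(1 for r in eligible if abs(r.r_mean) > abs(r.r_ref))
    return wins / len(eligible)


def _logistic(x, L, k, x0):
    return L / (1.0 + np.exp(-k * (x - x0)))


@dataclass
class LogisticFit:
    L: float
    k: float
    x0: float
    covariance: np.ndarray
    r2: float
    f_stat: float
    f_p: float
    ci95: dict[str, tuple[float, float]]
    converged: bool
    residual_ss: float


def _start_points(x: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    span = float(y.max() - y.min()) or 1.0
    ymax = float(np.max(np.abs(y))) or 1.0
    xmid = float(np.median(x))
    xrange = float(np.ptp(x)) or 1.0
    slope_sign = 1.0 if np.polyfit(x, y, 1)[0] >= 0 else -1.0
    return [
        (float(y.max()), slope_sign * 4.0 / xrange, xmid),
        (span, slope_sign * 1.0, xmid),
        (ymax, slope_sign * 0.5, float(x.mean())),
        (2 * span, slope_sign * 2.0 / xrange, xmid),
        (float(y.max()) or 1.0, -slope_sign * 1.0, xmid),
    ]


def fit_logistic_af(vep_scores, allele_frequencies) -> LogisticFit:
    """Three-parameter logistic fit f(x) = L / (1 + exp(-k (x - x0))) of
    VEP scores on allele frequencies by nonlinear least squares.

    Five deterministic multi-starts; Wald 95% CIs from the estimate
    covariance; R^2 plus an overall F-test against the intercept-only
    model.  Non-convergence of every start yields ``converged=False``.
    """
    x = np.asarray(allele_frequencies, dtype=float)
    y = np.asarray(vep_scores, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points")
    if (x <= 0).any() or (x > 1).any():
        raise ValueError("allele frequencies must lie in (0, 1]")
    best = None
    for p0 in _start_points(x, y):
        try:
            popt, pcov = curve_fit(_logistic, x, y, p0=p0, maxfev=20_000)
        except (RuntimeError, TypeError):
            continue
        rss = float(((y - _logistic(x, *popt)) ** 2).sum())
        if np.isfinite(rss) and (best is None or rss < best[2]):
            best = (popt, pcov, rss)
    n = x.size
    if best is None:
        return LogisticFit(
            L=np.nan, k=np.nan, x0=np.nan, covariance=np.full((3, 3), np.nan),
            r2=np.nan, f_stat=np.nan, f_p=np.nan, ci95={}, converged=False,
            residual_ss=float(((y - y.mean()) ** 2).sum()),
        )
    popt, pcov, rss = best
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    df_model, df_resid = 2, n - 3
    if tss > rss and df_resid > 0 and rss > 0:
        f_stat = ((tss - rss) / df_model) / (rss / df_resid)
        f_p = float(stats.f.sf(f_stat, df_model, df_resid))
    else:
        f_stat, f_p = np.nan, np.nan
    se = np.sqrt(np.diag(pcov))
    z = stats.norm.ppf(0.975)
    names = ("L", "k", "x0")
    ci95 = {
        name: (float(popt[i] - z * se[i]), float(popt[i] + z * se[i]))
        for i, name in enumerate(names)
    }
    return LogisticFit(
        L=float(popt[0]), k=float(popt[1]), x0=float(popt[2]),
        covariance=pcov, r2=float(r2), f_stat=float(f_stat) if np.isfinite(f_stat) else np.nan,
        f_p=f_p, ci95=ci95, converged=True, residual_ss=rss,
    )


def benchmark_frame(rows: list[AnnotationBenchmarkRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "annotation": r.name, "n": r.n, "r_ref": r.r_ref, "p_ref": r.p_ref,
        "r_mean": r.r_mean, "p_mean": r.p_mean, "eligible": r.eligible,
        "win": r.win,
    } for r in rows])
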