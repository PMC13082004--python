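"""Per-variant pVEP score-distribution characterization.

Representativeness of the reference-background score, normality and
modality of the population distribution, pathogenic boundary inference,
effect-class entropy, dispersion, and group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import BayesianGaussianMixture

from pvep.scoring import EFFECT_CLASSES


@dataclass
class ModalityFit:
    n_modes: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    zero_variance: bool = False


@dataclass
class VepDistributionSummary:
    focal_id: str
    n_haplotypes: int
    vep_ref: float
    vep_mean: float
    representativeness: float  # percentile in [0, 100]
    normality_stat: float | None = None
    normality_p: float | None = None
    normality_q: float | None = None
    untestable: bool = False
    n_modes: int | None = None
    mixture: ModalityFit | None = None
    mad: float = 0.0
    entropy: float | None = None  # splice only


def representativeness_percentile(vep_ref: float, scores) -> float:
    """Mid-rank percentile of the reference score within the population
    scores (the reference score itself is not appended)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    below = np.count_nonzero(scores < vep_ref)
    ties = np.count_nonzero(scores == vep_ref)
    return 100.0 * (below + 0.5 * ties) / scores.size


def bin_representativeness(summaries: list[VepDistributionSummary] | pd.DataFrame
                           ) -> pd.DataFrame:
    """Stacked-proportion table: vep_mean deciles (Q1..Q10) x percentile
    quintiles (edges at 0/20/40/60/80/100); per-decile proportions sum to 1.
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries[["vep_mean", "representativeness"]].copy()
    else:
        df = pd.DataFrame({
            "vep_mean": [s.vep_mean for s in summaries],
            "representativeness": [s.representativeness for s in summaries],
        })
    df = df.dropna()
    if len(df) < 10:
        raise ValueError("need at least 10 variants with defined vep_mean")
    codes = pd.qcut(df.vep_mean, 10, labels=False, duplicates="drop")
    deciles = pd.Categorical(
        [f"Q{int(c) + 1}" for c in codes],
        categories=[f"Q{i}" for i in range(1, 11)],
    )
    quintile_labels = ["0-20", "20-40", "40-60", "60-80", "80-100"]
    quintiles = pd.cut(df.representativeness, bins=[0, 20, 40, 60, 80, 100],
                       labels=quintile_labels, include_lowest=True)
    table = pd.crosstab(deciles, quintiles, normalize="index", dropna=False)
    table = table.reindex(columns=quintile_labels, fill_value=0.0)
    return table.loc[table.sum(axis=1) > 0]  # drop deciles emptied by ties


def test_normality(scores, min_n: int = 20):
    """D'Agostino-Pearson omnibus normality test.

    Returns (statistic, p) or None when untestable (n < min_n or zero
    variance).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < min_n or np.ptp(scores) == 0:
        return None
    stat, p = stats.normaltest(scores)
    return float(stat), float(p)


def _count_density_modes(means: np.ndarray, sds: np.ndarray,
                         weights: np.ndarray, grid_points: int = 2048) -> int:
    """Local maxima of the fitted mixture density: heavily overlapping
    components merge into a single mode."""
    lo = float((means - 4 * sds).min())
    hi = float((means + 4 * sds).max())
    if hi <= lo:
        return 1
    x = np.linspace(lo, hi, grid_points)
    dens = np.zeros_like(x)
    for m, s, w in zip(means, sds, weights):
        dens += w * stats.norm.pdf(x, m, max(s, 1e-12))
    interior = dens[1:-1]
    maxima = (interior > dens[:-2]) & (interior >= dens[2:])
    return max(int(maxima.sum()), 1)


def fit_modality(scores, max_components: int = 50, seed: int = 0,
                 weight_floor: float = 0.01) -> ModalityFit:
    """Variational Bayes Gaussian mixture modality estimate.

    Components retaining posterior mixing weight >= ``weight_floor`` are
    kept (Dirichlet concentration prior 1/max_components empties the
    rest); the mode count is the number of local maxima of the fitted
    mixture density, so overlapping surviving components are not
    double-counted.
    """
    scores = np.asarray(scores, dtype=float).reshape(-1, 1)
    n = scores.shape[0]
    if n < 20:
        raise ValueError("modality requires at least 20 observations")
    if np.ptp(scores) == 0:
        return ModalityFit(n_modes=1, means=np.array([scores[0, 0]]),
                           sds=np.array([0.0]), weights=np.array([1.0]),
                           zero_variance=True)
    k = min(max_components, n)
    gmm = BayesianGaussianMixture(
        n_components=k,
        weight_concentration_prior=1.0 / max_components,
        covariance_type="diag",
        tol=1e-3,
        max_iter=500,
        n_init=1,
        random_state=seed,
    )
    gmm.fit(scores)
    weights = gmm.weights_
    keep = weights >= weight_floor
    order = np.argsort(gmm.means_[keep, 0])
    means = gmm.means_[keep, 0][order]
    sds = np.sqrt(gmm.covariances_[keep, 0])[order]
    w = weights[keep][order]
    return ModalityFit(
        n_modes=_count_density_modes(means, sds, w),
        means=means, sds=sds, weights=w,
    )


def equal_density_crossing(m1: float, s1: float, w1: float,
                           m2: float, s2: float, w2: float):
    """Point strictly between two component means where the weighted
    component densities are equal, or None if no crossing lies between."""
    from scipy.optimize import brentq

    lo, hi = sorted((m1, m2))
    if lo == hi:
        return None

    def diff(x):
        return w1 * stats.norm.pdf(x, m1, s1) - w2 * stats.norm.pdf(x, m2, s2)

    if diff(lo) * diff(hi) > 0:
        return None
    return float(brentq(diff, lo, hi))


def infer_pathogenic_boundary(scores, seed: int = 0,
                              collapse_factor: float = 0.1):
    """Empirical benign/pathogenic boundary from a 2-component variational
    Gaussian mixture: the point between the component means where the
    weighted component densities are equal.  Returns None (no-boundary)
    when the components collapse (|mu1 - mu2| < pooled sd * collapse_factor).
    """
    scores = np.asarray(scores, dtype=float).reshape(-1, 1)
    if scores.shape[0] < 40:
        raise ValueError("boundary inference requires at least 40 observations")
    gmm = BayesianGaussianMixture(
        n_components=2, covariance_type="diag", tol=1e-3, max_iter=500,
        random_state=seed,
    )
    gmm.fit(scores)
    (m1, m2) = gmm.means_[:, 0]
    (s1, s2) = np.sqrt(gmm.covariances_[:, 0])
    (w1, w2) = gmm.weights_
    pooled = np.sqrt((s1**2 + s2**2) / 2)
    if abs(m1 - m2) < pooled * collapse_factor:
        return None
    return equal_density_crossing(m1, s1, w1, m2, s2, w2)


def effect_class_entropy(class_assignments, base: float = np.e) -> float:
    """Shannon entropy (nats by default) of the per-haplotype splice effect
    classes; zero means every haplotype shares the same predicted
    consequence."""
    assignments = list(class_assignments)
    if not assignments:
        raise ValueError("class_assignments must be non-empty")
    counts = np.array([
        sum(1 for a in assignments if a == c) for c in EFFECT_CLASSES
    ], dtype=float)
    if counts.sum() != len(assignments):
        unknown = set(assignments) - set(EFFECT_CLASSES)
        raise ValueError(f"unknown effect classes: {sorted(unknown)}")
    p = counts / counts.sum()
    return float(stats.entropy(p, base=base))


def dispersion_mad(scores) -> float:
    """Unscaled median absolute deviation."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    return float(np.median(np.abs(scores - np.median(scores))))


def compare_groups(scores_a, scores_b, test: str = "mannwhitney"):
    """Two-sided group comparison: Mann-Whitney U or Welch-free t-test."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    if test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ttest":
        res = stats.ttest_ind(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def summarize_variant(
    focal_id: str,
    scores,
    vep_ref: float,
    seed: int = 0,
    min_n_normality: int = 20,
    class_assignments=None,
) -> VepDistributionSummary:
    """Full per-variant distribution summary (normality q-values are filled
    in later across variants via :func:`attach_qvalues`)."""
    scores = np.asarray(scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    if scores.size == 0:
        raise ValueError(f"{focal_id}: no scores")
    summary = VepDistributionSummary(
        focal_id=focal_id,
        n_haplotypes=int(scores.size),
        vep_ref=float(vep_ref),
        vep_mean=float(scores.mean()),
        representativeness=representativeness_percentile(vep_ref, scores),
        mad=dispersion_mad(scores),
    )
    norm = test_normality(scores, min_n=min_n_normality)
    if norm is None:
        summary.untestable = True
    else:
        summary.normality_stat, summary.normality_p = norm
    if scores.size >= 20:
        fit = fit_modality(scores, seed=seed)
        summary.mixture = fit
        summary.n_modes = fit.n_modes
    if class_assignments is not None:
        summary.entropy = effect_class_entropy(class_assignments)
    return summary


def attach_qvalues(summaries: list[VepDistributionSummary]) -> None:
    """BH-adjust normality p-values across testable variants, in place."""
    testable = [s for s in summaries if s.normality_p is not None]
    if not testable:
        return
    qs = bh_qvalues([s.normality_p for s in testable])
    for s, q in zip(testable, qs):
        s.normality_q = float(q)


def summaries_frame(summaries: list[VepDistributionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "focal_id": s.focal_id, "n_haplotypes": s.n_haplotypes,
            "vep_ref": s.vep_ref, "vep_mean": s.vep_mean,
            "representativeness": s.representativeness,
            "normality_stat": s.normality_stat, "normality_p": s.normality_p,
            "normality_q": s.normality_q, "untestable": s.untestable,
            "n_modes": s.n_modes, "mad": s.mad, "entropy": s.entropy,
        })
    return pd.DataFrame(rows)
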