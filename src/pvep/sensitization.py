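"""Ridge surrogate models relating background-variant presence to pVEP
scores: variant sensitization maps, marginal effects, local (windowed)
single-target surrogates, and background x clinical non-additivity tests
with BH-FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge

from pvep.distributions import bh_qvalues as adjust_fdr  # noqa: F401 (re-export)


@dataclass
class DesignMatrix:
    haplotype_ids: list[str]
    variant_ids: list[str]
    X: np.ndarray  # (haplotypes, background variants), binary
    constant_columns: np.ndarray = field(default=None)  # bool flags

    def __post_init__(self):
        X = np.asarray(self.X)
        if not np.isin(X, (0, 1)).all():
            raise ValueError("design entries must be 0/1")
        self.X = X.astype(float)
        self.constant_columns = np.ptp(self.X, axis=0) == 0


def build_design(haplotypes, background_variants: list[str],
                 strict: bool = True) -> DesignMatrix:
    """Binary haplotype x background-variant presence matrix.

    ``haplotypes`` is a sequence of objects with ``id`` and ``variants``
    attributes (e.g. ProteinHaplotype) or (id, variant-id-iterable) pairs.
    With ``strict=True``, a haplotype variant absent from the catalog
    raises; otherwise it is ignored (catalog restriction).
    """
    catalog = {v: i for i, v in enumerate(background_variants)}
    if len(catalog) != len(background_variants):
        raise ValueError("duplicate ids in background catalog")
    hap_ids, rows = [], []
    for h in haplotypes:
        if isinstance(h, tuple):
            hid, variants = h
        else:
            hid, variants = h.id, h.variants
        row = np.zeros(len(catalog))
        for v in variants:
            if v in catalog:
                row[catalog[v]] = 1.0
            elif strict:
                raise KeyError(f"haplotype {hid}: unknown variant id {v!r}")
        hap_ids.append(hid)
        rows.append(row)
    X = np.array(rows) if rows else np.zeros((0, len(catalog)))
    return DesignMatrix(haplotype_ids=hap_ids,
                        variant_ids=list(background_variants), X=X)


@dataclass
class SensitizationMap:
    background_ids: list[str]
    clinical_ids: list[str]
    beta: np.ndarray  # (background, clinical)
    intercepts: np.ndarray  # per clinical target
    r2: np.ndarray  # per target, NaN where not fitted
    mse: np.ndarray
    pooled_r2: float
    pooled_mse: float
    fitted: np.ndarray  # bool per target
    alpha: float
    seed: int

    def coefficient(self, background_id: str, clinical_id: str) -> float:
        return float(self.beta[self.background_ids.index(background_id),
                               self.clinical_ids.index(clinical_id)])


def fit_sensitization_map(
    X,
    Y,
    alpha: float = 1.0,
    seed: int = 42,
    background_ids: list[str] | None = None,
    clinical_ids: list[str] | None = None,
) -> SensitizationMap:
    """Ridge fit of per-haplotype scores on background-variant presence.

    Columns are centered via the unpenalized intercept (standard ridge
    with ``fit_intercept=True``); missing Y cells are masked per target.
    Sign convention: a negative coefficient means the background variant
    pushes the predicted score toward pathogenicity (more negative).
    """
    if isinstance(X, DesignMatrix):
        background_ids = background_ids or X.variant_ids
        X = X.X
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    n_b, n_t = X.shape[1], Y.shape[1]
    background_ids = background_ids or [f"bg{i}" for i in range(n_b)]
    clinical_ids = clinical_ids or [f"clin{j}" for j in range(n_t)]
    beta = np.zeros((n_b, n_t))
    intercepts = np.zeros(n_t)
    r2 = np.full(n_t, np.nan)
    mse = np.full(n_t, np.nan)
    fitted = np.zeros(n_t, dtype=bool)
    ss_res_total = ss_tot_total = 0.0
    n_cells = 0
    for j in range(n_t):
        mask = ~np.isnan(Y[:, j])
        if mask.sum() == 0:
            continue
        Xj, yj = X[mask], Y[mask, j]
        model = Ridge(alpha=alpha, fit_intercept=True, random_state=seed)
        model.fit(Xj, yj)
        beta[:, j] = model.coef_
        intercepts[j] = model.intercept_
        pred = model.predict(Xj)
        res = float(((yj - pred) ** 2).sum())
        tot = float(((yj - yj.mean()) ** 2).sum())
        mse[j] = res / mask.sum()
        r2[j] = 1.0 - res / tot if tot > 0 else (1.0 if res == 0 else np.nan)
        fitted[j] = True
        ss_res_total += res
        ss_tot_total += tot
        n_cells += int(mask.sum())
    pooled_r2 = (1.0 - ss_res_total / ss_tot_total) if ss_tot_total > 0 else np.nan
    pooled_mse = ss_res_total / n_cells if n_cells else np.nan
    return SensitizationMap(
        background_ids=list(background_ids), clinical_ids=list(clinical_ids),
        beta=beta, intercepts=intercepts, r2=r2, mse=mse,
        pooled_r2=pooled_r2, pooled_mse=pooled_mse, fitted=fitted,
        alpha=alpha, seed=seed,
    )


def marginal_effects(smap: SensitizationMap, axis: str = "clinical") -> pd.Series:
    """Mean absolute joint effect per variant along one axis."""
    if axis == "clinical":
        values = np.abs(smap.beta).mean(axis=0)
        return pd.Series(values, index=smap.clinical_ids, name="marginal")
    if axis == "background":
        values = np.abs(smap.beta).mean(axis=1)
        return pd.Series(values, index=smap.background_ids, name="marginal")
    raise ValueError("axis must be 'clinical' or 'background'")


def fit_local_surrogate(
    focal_pos: int,
    y,
    design: DesignMatrix,
    background_positions: dict[str, int],
    window: int = 5000,
    alpha: float = 1.0,
    seed: int = 42,
) -> SensitizationMap | None:
    """Single-target surrogate restricted to background variants within
    +/- ``window`` bp of the focal position (inclusive boundary).  Returns
    None when no background variant falls in the window."""
    keep = [i for i, v in enumerate(design.variant_ids)
            if abs(background_positions[v] - focal_pos) <= window]
    if not keep:
        return None
    X = design.X[:, keep]
    ids = [design.variant_ids[i] for i in keep]
    return fit_sensitization_map(X, np.asarray(y, dtype=float), alpha=alpha,
                                 seed=seed, background_ids=ids,
                                 clinical_ids=["focal"])


def individual_effects(smap: SensitizationMap, aggregate: str = "median"
                       ) -> pd.Series:
    """Per-background-variant individual (additive) effect aggregated
    across clinical targets.

    The aggregate is the robust median by default: a handful of strongly
    epistatic pairs would otherwise leak into the shared additive estimate
    and bias the interaction test on the remaining pairs for that
    background variant (``aggregate="mean"`` restores plain averaging).
    """
    if aggregate == "median":
        values = np.median(smap.beta, axis=1)
    elif aggregate == "mean":
        values = smap.beta.mean(axis=1)
    else:
        raise ValueError("aggregate must be 'median' or 'mean'")
    return pd.Series(values, index=smap.background_ids, name="effect")


def estimate_individual_effects(X, Y, aggregate: str = "median",
                                alpha: float = 1e-8,
                                background_ids: list[str] | None = None
                                ) -> pd.Series:
    """Individual effects for the interaction test from a near-OLS
    multi-target surrogate refit.

    The reported sensitization map keeps ridge alpha = 1.0, but its
    shrinkage (a few percent of each coefficient) would bias the additive
    expectation and inflate the interaction test's type-I error, so the
    effects entering the F-test come from an unshrunk refit.
    """
    smap = fit_sensitization_map(X, Y, alpha=alpha,
                                 background_ids=background_ids)
    return individual_effects(smap, aggregate=aggregate)


@dataclass
class InteractionResult:
    background_id: str
    clinical_id: str
    beta2: float  # excess joint effect beyond the additive expectation
    f_stat: float
    df: tuple[int, int]
    p: float
    q: float | None
    testable: bool
    reason: str
    n: int
    n_carriers: int
    n_noncarriers: int


def test_nonadditivity(
    g,
    y,
    individual_effect: float,
    additive_prediction=None,
    min_n: int = 10,
    background_id: str = "bg",
    clinical_id: str = "clin",
) -> InteractionResult:
    """Test whether a background x clinical pair deviates from additivity.

    The per-haplotype deviation from the additive expectation is
    d_h = y_h - yhat_h, where yhat is the expected additive score.  By
    default yhat_h = mu_clin + e_bg * g_h (non-carrier mean plus the
    tested variant's surrogate-derived individual effect); passing
    ``additive_prediction`` (per-haplotype, typically X @ effects from the
    multi-target surrogate) also removes the other background variants'
    additive contributions, which otherwise dominate the residual variance
    and mask real interactions.  The nested OLS comparison d ~ 1 versus
    d ~ 1 + g yields an F(1, n-2) statistic; beta2 is the fitted carrier
    excess.  Untestable pairs (too few haplotypes, a missing carrier
    group, or an exactly-additive noiseless fit) are returned flagged,
    never raised.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    pred = (None if additive_prediction is None
            else np.asarray(additive_prediction, dtype=float)[mask])
    g, y = g[mask], y[mask]
    n = y.size
    n1 = int(g.sum())
    n0 = n - n1

    def untestable(reason: str) -> InteractionResult:
        return InteractionResult(
            background_id=background_id, clinical_id=clinical_id,
            beta2=np.nan, f_stat=np.nan, df=(1, max(n - 2, 0)), p=np.nan,
            q=None, testable=False, reason=reason, n=n,
            n_carriers=n1, n_noncarriers=n0,
        )

    if n < min_n:
        return untestable("n_below_minimum")
    if n1 == 0 or n0 == 0:
        return untestable("missing_carrier_group")
    if pred is None:
        mu_clin = y[g == 0].mean()
        d = y - (mu_clin + individual_effect * g)
    else:
        d = y - pred
    m1 = d[g == 1].mean()
    m0 = d[g == 0].mean()
    rss1 = float(((d[g == 1] - m1) ** 2).sum() + ((d[g == 0] - m0) ** 2).sum())
    dbar = d.mean()
    rss0 = float(((d - dbar) ** 2).sum())
    if rss1 <= 0:
        if rss0 - rss1 <= 0:
            return untestable("constant_interaction_regressor")
        return untestable("zero_residual_variance")
    f = (rss0 - rss1) / (rss1 / (n - 2))
    p = float(stats.f.sf(f, 1, n - 2))
    return InteractionResult(
        background_id=background_id, clinical_id=clinical_id,
        beta2=float(m1 - m0), f_stat=float(f), df=(1, n - 2), p=p,
        q=None, testable=True, reason="", n=n,
        n_carriers=n1, n_noncarriers=n0,
    )


def interaction_scan(
    X,
    Y,
    effects,
    min_n: int = 10,
    background_ids: list[str] | None = None,
    clinical_ids: list[str] | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Vectorized non-additivity scan over all background x clinical pairs.

    The additive expectation per haplotype is X @ effects (every
    background variant's individual effect), so each pair's deviation is
    tested against residual noise rather than the other variants' additive
    signal.  Equivalent to :func:`test_nonadditivity` with
    ``additive_prediction`` per pair, plus BH q-values over the testable
    pairs and a ``significant`` flag at q < ``fdr_alpha``.
    """
    if isinstance(X, DesignMatrix):
        background_ids = background_ids or X.variant_ids
        X = X.X
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n_b, n_t = X.shape[1], Y.shape[1]
    background_ids = background_ids or [f"bg{i}" for i in range(n_b)]
    clinical_ids = clinical_ids or [f"clin{j}" for j in range(n_t)]
    effects = np.asarray(effects, dtype=float)
    additive = X @ effects  # per-haplotype expected additive background sum
    rows = []
    has_nan = np.isnan(Y).any()
    for i in range(n_b):
        g = X[:, i]
        if not has_nan:
            n = Y.shape[0]
            n1 = int(g.sum())
            n0 = n - n1
            if n < min_n or n1 == 0 or n0 == 0:
                for j in range(n_t):
                    rows.append((background_ids[i], clinical_ids[j], np.nan,
                                 np.nan, np.nan, False,
                                 "n_below_minimum" if n < min_n
                                 else "missing_carrier_group", n, n1, n0))
                continue
            D = Y - additive[:, None]
            m1 = D[g == 1].mean(axis=0)
            ss_c = ((D[g == 1] - m1[None, :]) ** 2).sum(axis=0)
            m0 = D[g == 0].mean(axis=0)
            ss_nc = ((D[g == 0] - m0[None, :]) ** 2).sum(axis=0)
            rss1 = ss_c + ss_nc
            dbar = D.mean(axis=0)
            rss0 = ((D - dbar[None, :]) ** 2).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (rss0 - rss1) / (rss1 / (n - 2))
            p = stats.f.sf(f, 1, n - 2)
            for j in range(n_t):
                if rss1[j] <= 0:
                    rows.append((background_ids[i], clinical_ids[j], np.nan,
                                 np.nan, np.nan, False,
                                 "constant_interaction_regressor", n, n1, n0))
                else:
                    rows.append((background_ids[i], clinical_ids[j],
                                 float(m1[j] - m0[j]), float(f[j]),
                                 float(p[j]), True, "", n, n1, n0))
        else:
            for j in range(n_t):
                res = test_nonadditivity(
                    g, Y[:, j], float(effects[i]),
                    additive_prediction=additive, min_n=min_n,
                    background_id=background_ids[i],
                    clinical_id=clinical_ids[j],
                )
                rows.append((res.background_id, res.clinical_id, res.beta2,
                             res.f_stat, res.p, res.testable, res.reason,
                             res.n, res.n_carriers, res.n_noncarriers))
    df = pd.DataFrame(rows, columns=[
        "background_id", "clinical_id", "beta2", "f_stat", "p", "testable",
        "reason", "n", "n_carriers", "n_noncarriers",
    ])
    df["q"] = np.nan
    testable = df.testable.to_numpy()
    if testable.any():
        df.loc[testable, "q"] = adjust_fdr(df.loc[testable, "p"].to_numpy())
    df["significant"] = df.q < fdr_alpha
    return df
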