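"""Association statistics for atypicality-outcome analyses.

Partial Spearman correlations (Pearson on rank residuals, the ``ppcor``
convention), tie-corrected Kruskal-Wallis, Benjamini-Hochberg FDR and
standardized multiple linear regression, plus the battery that runs the
region-by-outcome correlation screen with FDR correction within each
outcome's family of regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import MODELLED_REGIONS


def spearman_partial(x, y, covariate) -> dict:
    """Partial Spearman correlation of x and y controlling a covariate.

    All three vectors are rank-transformed (average ranks for ties); the
    covariate's ranks are removed from x's and y's by linear regression
    and the Pearson correlation of the residuals is returned, with the
    t-approximation p-value on n - 3 degrees of freedom.  Rows with any
    missing value are dropped pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    n = int(keep.sum())
    if n < 5:
        raise ValueError("need >= 5 complete (x, y, covariate) triples")
    rx, ry, rc = (stats.rankdata(v[keep]) for v in (x, y, c))
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return {"rho": np.nan, "p_value": np.nan, "n": n}
    design = np.column_stack([np.ones(n), rc])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    rho = float(np.corrcoef(res_x, res_y)[0, 1])
    df = n - 3
    rho_ = np.clip(rho, -0.9999999, 0.9999999)
    t = rho_ * np.sqrt(df / (1.0 - rho_**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return {"rho": rho, "p_value": p, "n": n}


def kruskal_wallis(groups) -> dict:
    """Tie-corrected Kruskal-Wallis H across >= 2 non-empty groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    arrs = [a[np.isfinite(a)] for a in arrs]
    if len(arrs) < 2 or any(len(a) == 0 for a in arrs):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:  # all observations identical
        return {"H": 0.0, "p_value": 1.0}
    H, p = stats.kruskal(*arrs)
    return {"H": float(H), "p_value": float(p)}


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)


def ols_standardized(
    y,
    predictors: pd.DataFrame,
    r2_ci: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Multiple linear regression on z-scored outcome and predictors.

    Returns standardized coefficients with per-coefficient p-values, R^2,
    adjusted R^2, the overall F statistic with its p-value, and (optionally)
    a seeded bootstrap percentile CI for R^2.  Complete cases only.
    """
    X = pd.DataFrame(predictors).astype(float)
    yv = np.asarray(y, dtype=float)
    keep = np.isfinite(yv) & np.isfinite(X.to_numpy()).all(axis=1)
    X, yv = X.loc[keep], yv[keep]
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > p + 1 complete cases (n={n}, p={k})")
    if (X.std(ddof=1) == 0).any() or np.linalg.matrix_rank(_zscore(X.to_numpy())) < k:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if k > 1 else (X.columns[0],)
        raise ValueError(f"rank-deficient design; collinear columns: {worst}")
    Xz = sm.add_constant(pd.DataFrame(_zscore(X.to_numpy()), columns=X.columns))
    fit = sm.OLS(_zscore(yv), Xz).fit()
    out = {
        "beta": fit.params.drop("const").to_dict(),
        "p": fit.pvalues.drop("const").to_dict(),
        "r2": float(fit.rsquared),
        "adj_r2": float(fit.rsquared_adj),
        "f_stat": float(fit.fvalue),
        "f_p": float(fit.f_pvalue),
        "df_model": int(fit.df_model),
        "df_resid": int(fit.df_resid),
        "n": n,
    }
    if r2_ci:
        rng = np.random.default_rng(seed)
        r2s = np.empty(n_boot)
        Xn, yn = X.to_numpy(), yv
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Xb, yb = Xn[idx], yn[idx]
            if np.any(Xb.std(axis=0, ddof=1) == 0) or np.std(yb, ddof=1) == 0:
                r2s[b] = np.nan
                continue
            Xbz = np.column_stack([np.ones(n), _zscore(Xb)])
            beta, *_ = np.linalg.lstsq(Xbz, _zscore(yb), rcond=None)
            resid = _zscore(yb) - Xbz @ beta
            r2s[b] = 1.0 - resid @ resid / (n - 1)
        lo, hi = np.nanpercentile(r2s, [2.5, 97.5])
        out["r2_ci"] = (float(lo), float(hi))
    return out


def association_battery(
    ai: pd.DataFrame,
    cohort: pd.DataFrame,
    outcomes: tuple[str, ...] = ("bayley_cognitive", "bayley_motor"),
    covariate: str = "imd_score",
    regions: tuple[str, ...] | None = None,
    term_subset: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Region x outcome partial-Spearman screen with per-family FDR.

    ``ai`` holds per-subject atypicality indices (subjects x regions,
    indexed by subject_id).  For each outcome, every region's AI is
    correlated with the outcome controlling the covariate; BH-FDR is
    applied within that outcome's family of regions.  With ``term_subset``
    the screen is repeated on infants born >= 37 weeks.  Missing data are
    removed pairwise per analysis, so n varies across rows (stroke-masked
    cortical volumes, missed follow-ups).
    """
    regions = tuple(regions) if regions is not None else tuple(
        r for r in MODELLED_REGIONS if r in ai.columns
    )
    meta = cohort.set_index("subject_id").reindex(ai.index)
    samples = {"whole": np.ones(len(ai), dtype=bool)}
    if term_subset:
        samples["term37"] = meta["ga_birth"].to_numpy(dtype=float) >= 37.0
    rows = []
    for sample, mask in samples.items():
        for outcome in outcomes:
            fam = []
            for region in regions:
                res = spearman_partial(
                    ai[region].to_numpy()[mask],
                    meta[outcome].to_numpy(dtype=float)[mask],
                    meta[covariate].to_numpy(dtype=float)[mask],
                )
                fam.append(
                    {
                        "sample": sample,
                        "outcome": outcome,
                        "region": region,
                        "statistic": "rho",
                        "value": res["rho"],
                        "p_value": res["p_value"],
                        "n": res["n"],
                        "covariates": covariate,
                    }
                )
            ps = np.array([r["p_value"] for r in fam])
            ok = np.isfinite(ps)
            adj = np.full(len(ps), np.nan)
            if ok.any():
                adj[ok] = bh_fdr(ps[ok])
            for r, a in zip(fam, adj):
                r["p_fdr"] = a
                r["significant"] = bool(np.isfinite(a) and a < alpha)
            rows.extend(fam)
    return pd.DataFrame(rows)
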