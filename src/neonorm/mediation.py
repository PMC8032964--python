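"""Linear-structural-equation causal mediation with sensitivity analysis.

The question: is lower cerebral oxygen delivery (treatment T) associated
with poorer cognitive outcome (Y) *through* reduced regional brain growth
(mediator M, an atypicality index)?  Three ordinary-least-squares models
are fitted:

    (a)  Y ~ T + M + covariates      (outcome model)
    (b)  Y ~ M + covariates          (reported for completeness)
    (c)  M ~ T                       (mediator model)

With no treatment-mediator interaction the average causal mediation
effect (ACME) is the product of the T coefficient of (c) and the M
coefficient of (a).  Uncertainty comes from the quasi-Bayesian device:
coefficient vectors are drawn from the asymptotic sampling distributions
of the two fitted models, the per-draw product gives a percentile
interval and a two-sided p-value.  By default treatment, mediator and
outcome are z-scored, so the ACME is in outcome SDs per treatment SD,
matching the standardized path-diagram convention.

Sensitivity analysis asks how strongly an unmeasured confounder of the
mediator-outcome relation (error correlation rho between the mediator
and outcome equations) would have to act to overturn the ACME.  The
linear-case closed form adjusts the mediator->outcome path by

    ACME(rho) = ACME(0) - b_TM * (s1/s2) * rho * sqrt((1-r~^2)/(1-rho^2))

where s1, s2 are residual SDs of the reduced outcome model (Y ~ T +
covariates) and the mediator model, and r~ is the correlation of their
residuals.  The *critical rho* is the root of this curve: with no actual
unmeasured confounding it coincides with the residual correlation r~.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import bh_fdr


@dataclass
class MediationSpec:
    """Variable roles and simulation settings for one mediation analysis."""

    treatment: str = "cdo2"
    mediator: str = "latent_deep_gm_ai"
    outcome: str = "bayley_cognitive"
    covariates: tuple[str, ...] = ("imd_score",)
    draws: int = 1000
    level: float = 0.95
    seed: int = 0
    standardize: bool = True

    def __post_init__(self):
        if self.draws < 100:
            raise ValueError("need >= 100 simulation draws")
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must lie in (0, 1)")


@dataclass
class MediationModels:
    """Fitted OLS models plus the data they were fitted on."""

    spec: MediationSpec
    data: pd.DataFrame            # complete cases, possibly standardized
    outcome_model: object         # (a) Y ~ T + M + covariates
    completeness_model: object    # (b) Y ~ M + covariates
    mediator_model: object        # (c) M ~ T
    reduced_outcome_model: object  # Y ~ T + covariates (for sensitivity)
    n: int = 0


@dataclass
class MediationResult:
    """ACME with quasi-Bayesian interval, direct effect and sensitivity."""

    label: str
    acme: float
    ci: tuple[float, float]
    p_value: float
    ade: float                    # average direct effect (T coefficient of (a))
    ade_ci: tuple[float, float]
    path_treatment_mediator: float
    path_mediator_outcome: float
    n: int
    critical_rho: float | None
    sensitivity: pd.DataFrame = field(repr=False, default=None)
    p_fdr: float = np.nan


def fit_mediation_models(data: pd.DataFrame, spec: MediationSpec) -> MediationModels:
    """Fit models (a), (b), (c) and the reduced outcome model on complete cases."""
    cols = [spec.treatment, spec.mediator, spec.outcome, *spec.covariates]
    d = data[cols].apply(pd.to_numeric).dropna().reset_index(drop=True)
    n = len(d)
    if n < 10:
        raise ValueError(f"need >= 10 complete cases for mediation, got {n}")
    if spec.standardize:
        for c in (spec.treatment, spec.mediator, spec.outcome, *spec.covariates):
            sd = d[c].std(ddof=1)
            if sd == 0:
                raise ValueError(f"constant column {c!r}")
            d[c] = (d[c] - d[c].mean()) / sd
    X_a = sm.add_constant(d[[spec.treatment, spec.mediator, *spec.covariates]])
    if np.linalg.matrix_rank(X_a.to_numpy()) < X_a.shape[1]:
        raise ValueError("collinear design in outcome model")
    model_a = sm.OLS(d[spec.outcome], X_a).fit()
    model_b = sm.OLS(
        d[spec.outcome], sm.add_constant(d[[spec.mediator, *spec.covariates]])
    ).fit()
    model_c = sm.OLS(d[spec.mediator], sm.add_constant(d[[spec.treatment]])).fit()
    reduced = sm.OLS(
        d[spec.outcome], sm.add_constant(d[[spec.treatment, *spec.covariates]])
    ).fit()
    return MediationModels(spec, d, model_a, model_b, model_c, reduced, n)


def acme_point(models: MediationModels) -> float:
    """Product-of-coefficients ACME for the linear no-interaction case."""
    spec = models.spec
    b_tm = models.mediator_model.params[spec.treatment]
    b_my = models.outcome_model.params[spec.mediator]
    return float(b_tm * b_my)


def _coef_draws(fit, rng, draws):
    mean = fit.params.to_numpy()
    cov = fit.cov_params().to_numpy()
    L = np.linalg.cholesky(cov + 1e-15 * np.eye(len(mean)))
    return mean + rng.standard_normal((draws, len(mean))) @ L.T


def acme_quasibayes(models: MediationModels, spec: MediationSpec | None = None) -> dict:
    """Quasi-Bayesian ACME interval and p-value from coefficient draws.

    Coefficients of the mediator and outcome models are drawn from their
    asymptotic normal sampling distributions; each draw's ACME is the
    product of its two path coefficients.  The two-sided p-value is twice
    the smaller tail fraction of draws on either side of zero.
    """
    spec = spec or models.spec
    rng = np.random.default_rng(spec.seed)
    idx_t = list(models.mediator_model.params.index).index(spec.treatment)
    idx_m = list(models.outcome_model.params.index).index(spec.mediator)
    idx_dt = list(models.outcome_model.params.index).index(spec.treatment)
    d_c = _coef_draws(models.mediator_model, rng, spec.draws)
    d_a = _coef_draws(models.outcome_model, rng, spec.draws)
    acmes = d_c[:, idx_t] * d_a[:, idx_m]
    ades = d_a[:, idx_dt]
    tail = 100.0 * (1.0 - spec.level) / 2.0
    lo, hi = np.percentile(acmes, [tail, 100.0 - tail])
    p = 2.0 * min(np.mean(acmes <= 0.0), np.mean(acmes >= 0.0))
    alo, ahi = np.percentile(ades, [tail, 100.0 - tail])
    return {
        "acme": acme_point(models),
        "ci": (float(lo), float(hi)),
        "p_value": float(min(p, 1.0)),
        "ade": float(models.outcome_model.params[spec.treatment]),
        "ade_ci": (float(alo), float(ahi)),
        "draws": acmes,
    }


def sensitivity_curve(
    models: MediationModels, rho_grid: np.ndarray | None = None
) -> tuple[pd.DataFrame, float | None]:
    """ACME(rho) over a grid plus the critical rho where it changes sign.

    The curve is anchored at the unadjusted point estimate (ACME(0) equals
    ``acme_point`` exactly) and the root is refined by bisection to 1e-4.
    When the curve does not change sign on the grid the critical rho is
    reported as None.
    """
    if rho_grid is None:
        rho_grid = np.round(np.arange(-0.9, 0.9001, 0.05), 10)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any(np.abs(rho_grid) >= 0.99):
        raise ValueError("rho grid must lie within (-0.99, 0.99)")
    spec = models.spec
    b_tm = float(models.mediator_model.params[spec.treatment])
    r1 = models.reduced_outcome_model.resid.to_numpy()
    r2 = models.mediator_model.resid.to_numpy()
    s1, s2 = np.std(r1, ddof=1), np.std(r2, ddof=1)
    r_tilde = float(np.corrcoef(r1, r2)[0, 1])
    base = acme_point(models)
    scale = b_tm * (s1 / s2) * np.sqrt(max(1.0 - r_tilde**2, 1e-12))

    def curve(rho):
        return base - scale * rho / np.sqrt(1.0 - rho**2)

    values = curve(rho_grid)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite sensitivity values")
    frame = pd.DataFrame({"rho": rho_grid, "acme": values})

    critical = None
    sign = np.sign(values)
    changes = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if abs(scale) > 0 and len(changes) > 0:
        i = changes[0]
        lo, hi = rho_grid[i], rho_grid[i + 1]
        while hi - lo > 1e-4:
            mid = 0.5 * (lo + hi)
            if curve(lo) * curve(mid) <= 0:
                hi = mid
            else:
                lo = mid
        critical = float(0.5 * (lo + hi))
    elif np.any(sign == 0):
        critical = float(rho_grid[np.flatnonzero(sign == 0)[0]])
    return frame, critical


def mediate(data: pd.DataFrame, spec: MediationSpec, label: str | None = None) -> MediationResult:
    """Full mediation analysis for one mediator variable."""
    models = fit_mediation_models(data, spec)
    qb = acme_quasibayes(models)
    curve, critical = sensitivity_curve(models)
    return MediationResult(
        label=label or spec.mediator,
        acme=qb["acme"],
        ci=qb["ci"],
        p_value=qb["p_value"],
        ade=qb["ade"],
        ade_ci=qb["ade_ci"],
        path_treatment_mediator=float(models.mediator_model.params[spec.treatment]),
        path_mediator_outcome=float(models.outcome_model.params[spec.mediator]),
        n=models.n,
        critical_rho=critical,
        sensitivity=curve,
    )


def mediation_battery(
    data: pd.DataFrame,
    mediators: tuple[str, ...],
    spec: MediationSpec | None = None,
) -> list[MediationResult]:
    """One mediation analysis per gated mediator, with BH-FDR on ACME p-values.

    ``mediators`` is the set of columns that passed the association screen
    (regions whose AI correlated with both the outcome and the treatment);
    an empty gate set returns an empty list.
    """
    spec = spec or MediationSpec()
    results = []
    for i, med in enumerate(mediators):
        s = MediationSpec(
            treatment=spec.treatment,
            mediator=med,
            outcome=spec.outcome,
            covariates=spec.covariates,
            draws=spec.draws,
            level=spec.level,
            seed=spec.seed + i,
            standardize=spec.standardize,
        )
        results.append(mediate(data, s, label=med))
    if results:
        adj = bh_fdr([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.p_fdr = float(a)
    return results


def battery_summary(results: list[MediationResult]) -> pd.DataFrame:
    """Path-diagram style table: paths, ACME (CI, p), direct effect, critical rho."""
    return pd.DataFrame(
        [
            {
                "mediator": r.label,
                "path_treatment_mediator": r.path_treatment_mediator,
                "path_mediator_outcome": r.path_mediator_outcome,
                "acme": r.acme,
                "acme_ci_low": r.ci[0],
                "acme_ci_high": r.ci[1],
                "acme_p": r.p_value,
                "acme_p_fdr": r.p_fdr,
                "ade": r.ade,
                "critical_rho": r.critical_rho,
                "n": r.n,
            }
            for r in results
        ]
    )
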