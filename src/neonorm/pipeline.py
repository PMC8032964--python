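"""End-to-end orchestration: cohorts -> normative models -> report bundle.

The pipeline mirrors the analysis order of the study it emulates: fit
per-region normative GP models on the healthy cohort (frozen before any
CHD subject is scored, so the normative model never depends on the
clinical cohort), score the CHD cohort into atypicality indices, summarize
regional deviations and extreme-deviation prevalence with pairwise Fisher
tests, compute cerebral oxygen delivery, run the region x outcome
association screen for the whole sample and the term-born (>= 37 weeks)
subset, fit standardized regression models for the significant regions,
and finish with causal mediation plus rho-sensitivity for the regions that
pass the association gate.  A manifest records the seed, a config hash and
software versions; re-running with the same seed reproduces every number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels
from scipy import stats as sps

from . import __version__
from .atypicality import (
    any_extreme_per_subject,
    extreme_threshold,
    subgroup_comparison,
    summarize_regions,
)
from .mediation import MediationSpec, battery_summary, mediation_battery
from .normative import NormativeModel, fit_normative_models, profile_cohort
from .physiology import cdo2_table
from .regions import MODELLED_REGIONS, SKEWED_REGIONS, volume_column
from .stats import association_battery, bh_fdr, kruskal_wallis, ols_standardized
from .synthetic import (
    GeneratorParams,
    generate_chd_cohort,
    generate_normative_cohort,
    read_cohort_csv,
    write_cohort_csv,
)

log = logging.getLogger("neonorm")

REQUIRED_COLUMNS = (
    "subject_id",
    "group",
    "sex",
    "ga_birth",
    "pma_scan",
    "postnatal_days",
)


@dataclass
class PipelineConfig:
    """Run settings; defaults reproduce the study-shaped synthetic report."""

    input_mode: str = "synthetic"          # "synthetic" or "csv"
    normative_csv: str | None = None
    chd_csv: str | None = None
    seed: int = 0
    n_normative: int = 219
    n_chd: int = 66
    per_tail_p: float = 0.005              # extreme deviation tail probability
    term_subset: bool = True               # repeat analyses for ga >= 37 wk
    regions: tuple[str, ...] = MODELLED_REGIONS
    log_regions: tuple[str, ...] = SKEWED_REGIONS
    gp_restarts: int = 5
    gp_maxiter: int = 200
    mediation_draws: int = 1000
    alpha: float = 0.05
    output_dir: str = "neonorm_output"
    generator: GeneratorParams = field(default_factory=GeneratorParams)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_cohort_csv(path) -> tuple[pd.DataFrame, list[dict]]:
    """Read and validate a cohort CSV; returns (cohort, issues).

    Hard failures (missing required columns, duplicate ids, percent-scale
    saturation, non-positive volumes, impossible ages) raise ValueError
    listing the offending rows; soft issues are returned for logging.
    """
    df = read_cohort_csv(path)
    issues: list[dict] = []
    hard: list[str] = []

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")

    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        hard.append(f"duplicate subject_id values: {sorted(set(dup))}")

    def _rows(mask) -> list[int]:
        return (np.flatnonzero(mask.to_numpy()) + 2).tolist()  # 1-based + header

    if "sat_o2" in df.columns:
        bad = df["sat_o2"] > 1.0
        if bad.any():
            hard.append(
                f"sat_o2 > 1 (percent scale?) in rows {_rows(bad)}; "
                "saturation must be a fraction"
            )
    bad = (df["pma_scan"] < 34) | (df["pma_scan"] > 46)
    if bad.any():
        hard.append(f"pma_scan outside [34, 46] in rows {_rows(bad)}")
    bad = df["pma_scan"] < df["ga_birth"]
    if bad.any():
        hard.append(f"pma_scan < ga_birth in rows {_rows(bad)}")
    vol_cols = [c for c in df.columns if c.startswith("vol_")] + (
        ["ttv"] if "ttv" in df.columns else []
    )
    for c in vol_cols:
        bad = df[c] <= 0
        if bad.any():
            hard.append(f"non-positive {c} in rows {_rows(bad)}")

    expect_days = np.round(7.0 * (df["pma_scan"] - df["ga_birth"]))
    off = (df["postnatal_days"] - expect_days).abs() > 1
    if off.any():
        issues.append(
            {
                "severity": "warning",
                "message": f"postnatal_days inconsistent with pma_scan - ga_birth "
                f"in rows {_rows(off)}",
            }
        )
    if hard:
        raise ValueError(f"{path}: " + "; ".join(hard))
    return df, issues


def _load_cohorts(config: PipelineConfig):
    if config.input_mode == "synthetic":
        seeds = np.random.SeedSequence(config.seed).spawn(2)
        s_norm, s_chd = (int(s.generate_state(1)[0] % (2**31)) for s in seeds)
        normative = generate_normative_cohort(config.n_normative, config.generator, s_norm)
        chd = generate_chd_cohort(config.n_chd, config.generator, s_chd)
        return normative, chd
    if config.input_mode != "csv":
        raise ValueError("input_mode must be 'synthetic' or 'csv'")
    normative, issues_n = validate_cohort_csv(config.normative_csv)
    chd, issues_c = validate_cohort_csv(config.chd_csv)
    for issue in issues_n + issues_c:
        log.warning("%s", issue["message"])
    return normative, chd


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _table5_blocks(analysis: pd.DataFrame, regions, covariate="imd_score") -> str:
    """Standardized-regression text blocks, one per significant region."""
    blocks = []
    for region in regions:
        sub = analysis[["bayley_cognitive", region, covariate]].dropna()
        try:
            fit = ols_standardized(
                sub["bayley_cognitive"], sub[[region, covariate]], r2_ci=True
            )
        except ValueError as err:
            blocks.append(f"{region}: not estimable ({err})")
            continue
        lines = [f"cognitive composite ~ {region} AI + IMD  (n={fit['n']})"]
        for name in (region, covariate):
            lines.append(
                f"  beta[{name}] = {fit['beta'][name]:+.2f}  p = {fit['p'][name]:.3f}"
            )
        lo, hi = fit["r2_ci"]
        lines.append(
            f"  R2 = {fit['r2']:.2f} [{lo:.2f}-{hi:.2f}]; adjusted R2 = "
            f"{fit['adj_r2']:.2f}; F({fit['df_model']},{fit['df_resid']}) = "
            f"{fit['f_stat']:.2f}, p = {fit['f_p']:.3g}"
        )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report bundle as a dict of objects.

    Writes the five report artifacts plus cohorts and manifest under
    ``config.output_dir``.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    normative, chd = _load_cohorts(config)
    log.info("cohorts: %d normative, %d chd", len(normative), len(chd))

    # 1. normative models, frozen before any CHD subject is scored
    models = fit_normative_models(
        normative,
        regions=config.regions,
        log_regions=config.log_regions,
        seed=config.seed,
        n_restarts=config.gp_restarts,
        maxiter=config.gp_maxiter,
    )
    threshold = extreme_threshold(config.per_tail_p)
    profiles = profile_cohort(models, chd, threshold)
    log.info("fitted %d normative models in %.1fs", len(models), time.time() - t0)

    subgroups = chd.set_index("subject_id")["chd_subgroup"]

    # 2. regional summary with Kruskal-Wallis across CHD subgroups
    summary = summarize_regions(profiles, subgroups)
    kw_rows = []
    for region in profiles.regions:
        z = profiles.z[region]
        sg = subgroups.reindex(z.index)
        groups = [
            z[(sg == name)].dropna()
            for name in ("abnormal_streaming", "left_sided", "right_sided")
        ]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) >= 2:
            kw = kruskal_wallis(groups)
        else:
            kw = {"H": np.nan, "p_value": np.nan}
        kw_rows.append(kw)
    summary["kruskal_H"] = [r["H"] for r in kw_rows]
    summary["kruskal_p"] = [r["p_value"] for r in kw_rows]
    ok = summary["kruskal_p"].notna()
    summary.loc[ok, "kruskal_p_fdr"] = bh_fdr(summary.loc[ok, "kruskal_p"])

    # 3. extreme-deviation prevalence and pairwise Fisher tests
    prevalence = any_extreme_per_subject(profiles)
    fisher = subgroup_comparison(profiles, subgroups)
    fisher["p_fdr"] = bh_fdr(fisher["p_value"])

    # 4. physiology + association screen
    physiology = cdo2_table(chd)
    analysis = (
        chd.set_index("subject_id")
        .join(profiles.z, rsuffix="_ai")
        .join(physiology.set_index("subject_id")[["cbf", "cdo2", "cdo2_quintile"]])
    )
    associations = association_battery(
        profiles.z, chd, term_subset=config.term_subset, alpha=config.alpha
    )

    # Pearson screen: CDO2 vs regional AI (whole sample), FDR within family
    cdo2_rows = []
    for region in profiles.regions:
        sub = analysis[[region, "cdo2"]].dropna()
        r, p = sps.pearsonr(sub[region], sub["cdo2"]) if len(sub) > 3 else (np.nan, np.nan)
        cdo2_rows.append({"region": region, "r": r, "p_value": p, "n": len(sub)})
    cdo2_assoc = pd.DataFrame(cdo2_rows)
    okp = cdo2_assoc["p_value"].notna()
    cdo2_assoc.loc[okp, "p_fdr"] = bh_fdr(cdo2_assoc.loc[okp, "p_value"])

    # 5. regression blocks + mediation for the gated regions
    sig_cog = associations.query(
        "sample == 'whole' and outcome == 'bayley_cognitive' and significant"
    )["region"].tolist()
    sig_cdo2 = cdo2_assoc.query("p_fdr < @config.alpha")["region"].tolist()
    gated = [r for r in sig_cog if r in sig_cdo2]
    if not gated:
        log.info("association gate empty: no regions significant for both "
                 "cognition and CDO2")
    table5 = _table5_blocks(analysis, sig_cog)
    med_spec = MediationSpec(
        treatment="cdo2",
        outcome="bayley_cognitive",
        covariates=("imd_score",),
        draws=config.mediation_draws,
        seed=config.seed,
    )
    mediation_results = mediation_battery(analysis, tuple(gated), med_spec)
    mediation = battery_summary(mediation_results)

    # -- write report bundle ------------------------------------------------
    write_cohort_csv(normative, out / "cohort_normative.csv")
    write_cohort_csv(chd, out / "cohort_chd.csv")
    _write_csv(summary, out / "atypicality_summary.csv")
    _write_csv(fisher, out / "extreme_subgroup_fisher.csv")
    _write_csv(associations, out / "associations.csv")
    _write_csv(cdo2_assoc, out / "cdo2_associations.csv")
    _write_csv(physiology, out / "physiology.csv")
    _write_csv(profiles.z.reset_index(), out / "atypicality_indices.csv")
    if not mediation.empty:
        _write_csv(mediation, out / "mediation.csv")
    else:
        (out / "mediation.csv").write_text("mediator\n")
    (out / "regression_models.txt").write_text(table5)
    prevalence_text = (
        f"extreme-deviation threshold |z| > {threshold:.4f} "
        f"(per-tail p = {config.per_tail_p})\n"
        f"subjects with >= 1 extreme region: {prevalence['n_with_extreme']} of "
        f"{prevalence['n_subjects']} ({prevalence['pct_with_extreme']:.0f}%)\n"
        f"largest number of extreme regions in one subject: "
        f"{prevalence['max_extreme_regions']}\n"
    )
    (out / "extreme_prevalence.txt").write_text(prevalence_text)
    save_models(models, out / "normative_models.json")

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "threshold": threshold,
        "n_normative": int(len(normative)),
        "n_chd": int(len(chd)),
        "gated_regions": gated,
        "versions": {
            "neonorm": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "runtime_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "normative": normative,
        "chd": chd,
        "models": models,
        "profiles": profiles,
        "threshold": threshold,
        "summary": summary,
        "prevalence": prevalence,
        "fisher": fisher,
        "associations": associations,
        "cdo2_associations": cdo2_assoc,
        "physiology": physiology,
        "table5": table5,
        "mediation": mediation,
        "mediation_results": mediation_results,
        "manifest": manifest,
    }


def save_models(models: dict[str, NormativeModel], path) -> None:
    payload = {region: json.loads(m.to_json()) for region, m in models.items()}
    Path(path).write_text(json.dumps(payload))


def load_models(path) -> dict[str, NormativeModel]:
    payload = json.loads(Path(path).read_text())
    return {
        region: NormativeModel.from_json(json.dumps(d))
        for region, d in payload.items()
    }
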