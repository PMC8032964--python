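"""Synthetic neonatal cohorts with the covariance structure the pipeline assumes.

The study data (a normative sample of healthy term neonates and a presurgical
congenital-heart-disease cohort) are not publicly deposited, so this module
generates statistically matched stand-ins: smooth volume-vs-postmenstrual-age
growth with sex and postnatal-age effects, right-skewed CSF spaces, a CHD
cohort whose regional volume deficits, cerebral oxygen delivery distribution
and Bayley-III outcome scores are centred on the published cohort summaries,
and a built-in oxygen-delivery -> deep-grey-volume -> cognition mediation
chain whose path coefficients are known exactly (``gamma`` and ``kappa``),
so that every downstream estimator can be checked against ground truth.

All draws are vectorised and reproducible: the same seed yields the same
cohort byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .regions import (
    DEEP_GREY_REGIONS,
    SEGMENTED_REGIONS,
    STROKE_MASKED_REGIONS,
    TTV_COMPONENTS,
    volume_column,
)

REFERENCE_PMA = 40.0  # weeks; growth intercepts are anchored here

#: Huefner's constant, mL O2 bound per gram of haemoglobin.
HUFNER = 1.36


@dataclass
class RegionGrowth:
    """Linear growth law and cohort-shift parameters for one region.

    ``intercept`` is the expected volume (cm^3) of a female infant at 40
    weeks postmenstrual age and 0 postnatal days; ``slope`` the gain per
    week of PMA, ``sex_offset`` the male-female difference, ``day_slope``
    the extra gain per ex-utero day.  For skewed regions ``resid_sd`` is
    the log-scale sigma of a multiplicative log-normal residual; otherwise
    an additive SD in cm^3.

    ``delta`` is the CHD-cohort mean deficit in residual-SD units (the
    population atypicality-index target), ``coupling`` selects how the
    region loads on cerebral oxygen delivery ("deep", "tissue" or "none"),
    ``global_loading`` its loading on the shared brain-size factor and
    ``chd_idio_sd`` the CHD idiosyncratic residual SD (in AI units).
    """

    intercept: float
    slope: float
    sex_offset: float
    day_slope: float
    resid_sd: float
    skewed: bool = False
    delta: float = 0.0
    coupling: str = "tissue"
    global_loading: float = 0.5
    chd_idio_sd: float = 0.8


def _default_regions() -> dict[str, RegionGrowth]:
    R = RegionGrowth
    return {
        "cortical_gm": R(160.0, 12.0, 6.0, 0.15, 10.0, delta=-0.58, coupling="tissue", chd_idio_sd=0.659),
        "white_matter": R(170.0, 6.0, 6.0, 0.05, 9.0, delta=-0.59, coupling="tissue", chd_idio_sd=0.800),
        "extracerebral_csf": R(45.0, 2.0, 2.0, 0.10, 0.25, skewed=True, delta=0.57, coupling="none", global_loading=-0.3, chd_idio_sd=1.172),
        "ventricles": R(6.0, 0.20, 0.30, 0.0, 0.30, skewed=True, delta=0.0, coupling="none", global_loading=-0.2, chd_idio_sd=1.406),
        "cerebellum": R(26.0, 1.8, 0.8, 0.05, 2.0, delta=-0.43, coupling="tissue", chd_idio_sd=0.837),
        "brainstem": R(6.5, 0.35, 0.20, 0.01, 0.45, delta=-0.60, coupling="tissue", chd_idio_sd=0.968),
        "thalamus_l": R(4.3, 0.22, 0.12, 0.005, 0.33, delta=-0.57, coupling="deep", chd_idio_sd=0.631),
        "thalamus_r": R(4.3, 0.22, 0.12, 0.005, 0.33, delta=-0.66, coupling="deep", chd_idio_sd=0.568),
        "lentiform_l": R(3.4, 0.18, 0.10, 0.004, 0.28, delta=-0.52, coupling="deep", chd_idio_sd=0.500),
        "lentiform_r": R(3.4, 0.18, 0.10, 0.004, 0.28, delta=-0.16, coupling="deep", chd_idio_sd=0.631),
        "caudate_l": R(1.9, 0.09, 0.05, 0.002, 0.16, delta=-0.71, coupling="deep", chd_idio_sd=0.616),
        "caudate_r": R(1.9, 0.09, 0.05, 0.002, 0.16, delta=-0.76, coupling="deep", chd_idio_sd=0.676),
        "hippocampus_amygdala": R(4.0, 0.20, 0.10, 0.004, 0.35, delta=-0.40, coupling="tissue", chd_idio_sd=0.750),
    }


@dataclass
class GeneratorParams:
    """Everything the two cohort generators need.

    Defaults are calibrated so that, at the study sample sizes, the
    generated cohorts land on the published summaries: normative birth age
    median ~40.1 wk and scan age median ~40.7 wk; CHD birth age median
    ~38.5 wk with a small preterm fraction; CDO2 mean (SD) ~1795 (495)
    mL O2/min built from saturation, haemoglobin and vessel flows; regional
    atypicality-index means at the per-region ``delta`` targets; cognitive
    composite mean (SD) ~93 (10).

    The mediation ground truth is ``gamma`` (deep-grey AI change per SD of
    CDO2) times ``kappa`` (cognitive points per unit of deep-grey AI).
    """

    regions: dict[str, RegionGrowth] = field(default_factory=_default_regions)

    # mediation chain
    gamma: float = 0.45            # CDO2 (per SD) -> deep grey AI
    gamma_tissue: float = 0.30     # CDO2 (per SD) -> other tissue AI
    deep_shared_sd: float = 0.30   # deep-grey factor noise beyond CDO2/global
    kappa: float = 5.0             # cognitive points per unit deep-grey AI
    iota: float = -2.5             # cognitive points per SD of log-IMD
    cognition_mean: float = 93.0
    cognition_noise_sd: float = 8.0
    motor_mean: float = 94.0
    motor_noise_sd: float = 10.0

    # physiology (CHD cohort)
    cdo2_mean: float = 1795.0      # mL O2/min, as printed
    cdo2_sd: float = 495.0
    sat_mean: float = 0.93         # pre-ductal saturation, fraction
    sat_sd: float = 0.05
    sat_lo: float = 0.70
    sat_hi: float = 1.00
    hb_mean: float = 15.0          # g/dL
    hb_sd: float = 1.8
    cbf_lo: float = 30.0           # mL/min floor for total cerebral blood flow
    vessel_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    vessel_concentration: float = 150.0

    # demographics
    normative_ga_mean: float = 40.1
    normative_ga_sd: float = 1.4
    normative_ga_lo: float = 37.0
    normative_ga_hi: float = 43.0
    normative_days_rate: float = 3.2   # postnatal days ~ 1 + Poisson(rate)
    chd_ga_mean: float = 38.5
    chd_ga_sd: float = 0.6
    chd_ga_lo: float = 37.0
    chd_ga_hi: float = 41.0
    chd_days_rate: float = 3.0         # postnatal days ~ 2 + Poisson(rate)
    preterm_fraction: float = 4 / 66
    preterm_ga_lo: float = 34.5
    preterm_ga_hi: float = 36.9
    male_fraction_normative: float = 109 / 219
    male_fraction_chd: float = 39 / 66
    pma_max: float = 45.0

    # CHD labels and missingness
    subgroup_probs: dict[str, float] = field(
        default_factory=lambda: {
            "abnormal_streaming": 32 / 66,
            "left_sided": 18 / 66,
            "right_sided": 16 / 66,
        }
    )
    injury_probs: dict[str, float] = field(
        default_factory=lambda: {
            "none": 39 / 66,
            "wmi_mild": 13 / 66,
            "wmi_moderate": 5 / 66,
            "wmi_severe": 2 / 66,
            "stroke": 3 / 66,
            "cerebellar_haemorrhage": 4 / 66,
        }
    )
    flow_missing_fraction: float = 13 / 66
    followup_fraction: float = 46 / 66
    imd_missing_fraction: float = 1 / 46

    # socioeconomic deprivation (log-normal IMD score)
    imd_log_mean: float = math.log(21.9)
    imd_log_sd: float = 0.50

    # normative outcome scores (healthy infants, Bayley floor at 70)
    bayley_norm_mean: float = 100.0
    bayley_norm_sd: float = 15.0
    bayley_floor: float = 70.0

    @property
    def deep_delta_mean(self) -> float:
        return float(
            np.mean([self.regions[r].delta for r in DEEP_GREY_REGIONS])
        )

    # -- plain-dict / YAML round trip -------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vessel_fractions"] = list(self.vessel_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        if "regions" in d:
            d["regions"] = {
                name: RegionGrowth(**rp) if not isinstance(rp, RegionGrowth) else rp
                for name, rp in d["regions"].items()
            }
        if "vessel_fractions" in d:
            d["vessel_fractions"] = tuple(d["vessel_fractions"])
        return cls(**d)

    def save_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "GeneratorParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# growth curve


def _sex_indicator(sex) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "UO":
        known = np.isin(arr, ("male", "female"))
        if not known.all():
            bad = sorted(set(arr[~known].tolist()))
            raise ValueError(f"sex must be 'male' or 'female', got {bad}")
        return (arr == "male").astype(float)
    return arr.astype(float)


def growth_curve(region, pma_scan, sex, postnatal_days, params: GeneratorParams | None = None):
    """Expected volume (cm^3) on the noiseless normative growth law.

    For skewed regions this is the location (median) of the log-normal
    residual model, not its arithmetic mean.  ``region`` may be any
    segmented region or ``"ttv"``; TTV and the deep-grey total are sums of
    their constituents' curves.  PMA must lie in the modelled 37-45 week
    window.
    """
    params = params or GeneratorParams()
    pma = np.asarray(pma_scan, dtype=float)
    if np.any(pma < 37.0) or np.any(pma > 45.0):
        raise ValueError("pma_scan outside the modelled 37-45 week window")
    if region == "ttv":
        return sum(
            growth_curve(r, pma_scan, sex, postnatal_days, params)
            for r in TTV_COMPONENTS
        )
    if region == "deep_gm_total":
        return sum(
            growth_curve(r, pma_scan, sex, postnatal_days, params)
            for r in DEEP_GREY_REGIONS
        )
    if region not in params.regions:
        raise KeyError(
            f"unknown region {region!r}; valid regions: "
            f"{', '.join(list(params.regions) + ['deep_gm_total', 'ttv'])}"
        )
    rp = params.regions[region]
    male = _sex_indicator(sex)
    days = np.asarray(postnatal_days, dtype=float)
    out = (
        rp.intercept
        + rp.slope * (pma - REFERENCE_PMA)
        + rp.sex_offset * male
        + rp.day_slope * days
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# shared helpers


def _truncnorm_rvs(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _volumes_from_ai(params, pma, male, days, ai: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Map per-region atypicality draws to volumes via the growth law."""
    vols: dict[str, np.ndarray] = {}
    for name, rp in params.regions.items():
        m = (
            rp.intercept
            + rp.slope * (pma - REFERENCE_PMA)
            + rp.sex_offset * male
            + rp.day_slope * days
        )
        if rp.skewed:
            vols[name] = m * np.exp(rp.resid_sd * ai[name])
        else:
            vols[name] = m + rp.resid_sd * ai[name]
    vols["deep_gm_total"] = sum(vols[r] for r in DEEP_GREY_REGIONS)
    return vols


def _assemble(params, ids, group, male, ga, days, vols) -> pd.DataFrame:
    pma = ga + days / 7.0
    df = pd.DataFrame(
        {
            "subject_id": ids,
            "group": group,
            "sex": np.where(male > 0.5, "male", "female"),
            "ga_birth": ga,
            "pma_scan": pma,
            "postnatal_days": days.astype(int),
        }
    )
    for name in SEGMENTED_REGIONS:
        df[volume_column(name)] = vols[name]
    df["ttv"] = sum(vols[r] for r in TTV_COMPONENTS)
    return df


# ---------------------------------------------------------------------------
# normative cohort


def generate_normative_cohort(
    n: int, params: GeneratorParams | None = None, seed: int = 0
) -> pd.DataFrame:
    """Healthy term-born infants scanned between 37 and 45 weeks PMA.

    Regional residuals share a global brain-size factor (loading set per
    region); marginally each region's atypicality draw is standard normal,
    so a well-calibrated normative model scores held-out subjects with
    z ~ N(0, 1).
    """
    if n < 20:
        raise ValueError("need n >= 20 normative subjects for stable model fitting")
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)

    ga = _truncnorm_rvs(
        rng, params.normative_ga_mean, params.normative_ga_sd,
        params.normative_ga_lo, params.normative_ga_hi, n,
    )
    days = 1.0 + rng.poisson(params.normative_days_rate, size=n)
    days = np.minimum(days, np.floor(7.0 * (params.pma_max - ga)))
    male = (rng.random(n) < params.male_fraction_normative).astype(float)
    pma = ga + days / 7.0

    g = rng.standard_normal(n)  # shared brain-size factor
    ai = {}
    for name, rp in params.regions.items():
        e = rng.standard_normal(n)
        gl = rp.global_loading
        ai[name] = gl * g + math.sqrt(max(1.0 - gl**2, 0.0)) * e
    vols = _volumes_from_ai(params, pma, male, days, ai)

    ids = np.array([f"norm_{i:04d}" for i in range(n)])
    df = _assemble(params, ids, "normative", male, ga, days, vols)
    df["chd_subgroup"] = "none"
    df["injury"] = "none"
    for col in ("sat_o2", "haemoglobin", "flow_lica", "flow_rica", "flow_basilar", "imd_score"):
        df[col] = np.nan
    lo = params.bayley_floor
    df["bayley_cognitive"] = _truncnorm_rvs(
        rng, params.bayley_norm_mean, params.bayley_norm_sd, lo, np.inf, n
    )
    df["bayley_motor"] = _truncnorm_rvs(
        rng, params.bayley_norm_mean, params.bayley_norm_sd, lo, np.inf, n
    )
    df["latent_deep_gm_ai"] = np.nan
    df["latent_cdo2_z"] = np.nan
    return df[list(COHORT_COLUMNS)]


# ---------------------------------------------------------------------------
# CHD cohort


def _chd_physiology(params: GeneratorParams, rng, n):
    """Saturation, haemoglobin and total CBF whose product lands on the
    configured CDO2 mean and SD (moment-matched, truncation-aware)."""
    a = (params.sat_lo - params.sat_mean) / params.sat_sd
    b = (params.sat_hi - params.sat_mean) / params.sat_sd
    sat_m, sat_v = truncnorm.stats(
        a, b, loc=params.sat_mean, scale=params.sat_sd, moments="mv"
    )
    cv2_s = float(sat_v) / float(sat_m) ** 2
    cv2_h = (params.hb_sd / params.hb_mean) ** 2
    cv2_t = (params.cdo2_sd / params.cdo2_mean) ** 2
    cv2_c = max((1.0 + cv2_t) / ((1.0 + cv2_s) * (1.0 + cv2_h)) - 1.0, 1e-4)
    cbf_mean = params.cdo2_mean / (HUFNER * float(sat_m) * params.hb_mean)
    cbf_sd = cbf_mean * math.sqrt(cv2_c)

    sat = _truncnorm_rvs(rng, params.sat_mean, params.sat_sd, params.sat_lo, params.sat_hi, n)
    hb = np.clip(rng.normal(params.hb_mean, params.hb_sd, size=n), 8.0, 22.0)
    cbf = _truncnorm_rvs(rng, cbf_mean, cbf_sd, params.cbf_lo, np.inf, n)
    return sat, hb, cbf


def generate_chd_cohort(
    n: int, params: GeneratorParams | None = None, seed: int = 0
) -> pd.DataFrame:
    """Presurgical CHD cohort with known mediation ground truth.

    The treatment variable (CDO2, built multiplicatively from saturation,
    haemoglobin and summed vessel flows) shifts deep-grey atypicality by
    ``gamma`` per SD; the cognitive composite responds to the realised
    deep-grey atypicality mean with slope ``kappa`` and to standardized
    log-IMD with slope ``iota``.  Stroke cases have cortical grey matter,
    white matter and TTV masked at generation time, mirroring how cortical
    segmentations are unusable after an arterial ischaemic stroke.
    """
    if n < 10:
        raise ValueError("need n >= 10 CHD subjects")
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)

    preterm = rng.random(n) < params.preterm_fraction
    ga = _truncnorm_rvs(
        rng, params.chd_ga_mean, params.chd_ga_sd, params.chd_ga_lo, params.chd_ga_hi, n
    )
    ga = np.where(preterm, rng.uniform(params.preterm_ga_lo, params.preterm_ga_hi, n), ga)
    days = (2.0 + rng.poisson(params.chd_days_rate, size=n)).astype(float)
    # preterm infants are scanned once they reach the modelled PMA window
    pma_pre = rng.uniform(37.3, 38.3, size=n)
    days = np.where(preterm, np.round(7.0 * (pma_pre - ga)), days)
    days = np.minimum(days, np.floor(7.0 * (params.pma_max - ga)))
    male = (rng.random(n) < params.male_fraction_chd).astype(float)
    pma = ga + days / 7.0

    subgroups = list(params.subgroup_probs)
    sub_p = np.array([params.subgroup_probs[s] for s in subgroups], dtype=float)
    subgroup = rng.choice(subgroups, size=n, p=sub_p / sub_p.sum())
    injuries = list(params.injury_probs)
    inj_p = np.array([params.injury_probs[s] for s in injuries], dtype=float)
    injury = rng.choice(injuries, size=n, p=inj_p / inj_p.sum())

    sat, hb, cbf = _chd_physiology(params, rng, n)
    cdo2 = sat * hb * HUFNER * cbf
    z = (cdo2 - params.cdo2_mean) / params.cdo2_sd
    props = rng.dirichlet(
        params.vessel_concentration * np.asarray(params.vessel_fractions), size=n
    )
    flows = props * cbf[:, None]

    g = rng.standard_normal(n)                       # brain-size factor
    u = (
        params.gamma * z
        + 0.5 * g
        + params.deep_shared_sd * rng.standard_normal(n)
    )                                                # shared deep-grey factor
    ai: dict[str, np.ndarray] = {}
    for name, rp in params.regions.items():
        e = rng.standard_normal(n)
        if rp.coupling == "deep":
            ai[name] = rp.delta + u + rp.chd_idio_sd * e
        elif rp.coupling == "tissue":
            ai[name] = (
                rp.delta
                + params.gamma_tissue * z
                + rp.global_loading * g
                + rp.chd_idio_sd * e
            )
        else:  # CSF spaces: uncoupled from CDO2, anti-correlated with size
            ai[name] = rp.delta + rp.global_loading * g + rp.chd_idio_sd * e
    vols = _volumes_from_ai(params, pma, male, days, ai)

    ids = np.array([f"chd_{i:04d}" for i in range(n)])
    df = _assemble(params, ids, "chd", male, ga, days, vols)
    df["chd_subgroup"] = subgroup
    df["injury"] = injury

    df["sat_o2"] = sat
    df["haemoglobin"] = hb
    df["flow_lica"] = flows[:, 0]
    df["flow_rica"] = flows[:, 1]
    df["flow_basilar"] = flows[:, 2]

    imd = np.exp(rng.normal(params.imd_log_mean, params.imd_log_sd, size=n))
    z_imd = (np.log(imd) - params.imd_log_mean) / params.imd_log_sd
    df["imd_score"] = imd

    deep_ai = np.mean([ai[r] for r in DEEP_GREY_REGIONS], axis=0)
    df["latent_deep_gm_ai"] = deep_ai
    df["latent_cdo2_z"] = z
    df["bayley_cognitive"] = (
        params.cognition_mean
        + params.kappa * (deep_ai - params.deep_delta_mean)
        + params.iota * z_imd
        + rng.normal(0.0, params.cognition_noise_sd, size=n)
    )
    df["bayley_motor"] = params.motor_mean + rng.normal(
        0.0, params.motor_noise_sd, size=n
    )

    # missingness, applied after every latent quantity is realised
    stroke = df["injury"].to_numpy() == "stroke"
    for col in ("vol_cortical_gm", "vol_white_matter", "ttv"):
        df.loc[stroke, col] = np.nan
    no_flow = rng.random(n) < params.flow_missing_fraction
    df.loc[no_flow, ["flow_lica", "flow_rica", "flow_basilar"]] = np.nan
    attended = rng.random(n) < params.followup_fraction
    df.loc[~attended, ["bayley_cognitive", "bayley_motor", "imd_score"]] = np.nan
    no_imd = attended & (rng.random(n) < params.imd_missing_fraction)
    df.loc[no_imd, "imd_score"] = np.nan
    return df[list(COHORT_COLUMNS)]


# ---------------------------------------------------------------------------
# CSV round trip

COHORT_COLUMNS = (
    ["subject_id", "group", "sex", "ga_birth", "pma_scan", "postnatal_days"]
    + [volume_column(r) for r in SEGMENTED_REGIONS]
    + [
        "ttv",
        "chd_subgroup",
        "injury",
        "sat_o2",
        "haemoglobin",
        "flow_lica",
        "flow_rica",
        "flow_basilar",
        "imd_score",
        "bayley_cognitive",
        "bayley_motor",
        "latent_deep_gm_ai",
        "latent_cdo2_z",
    ]
)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """UTF-8 CSV, empty cells for missing values, 6 significant digits."""
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, float_format="%.6g", encoding="utf-8")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    if "postnatal_days" in df.columns and df["postnatal_days"].notna().all():
        df["postnatal_days"] = df["postnatal_days"].astype(int)
    return df
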