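"""Cerebral blood flow, cerebral oxygen delivery and quintile ranks.

Total cerebral blood flow is the sum of phase-contrast flow in the left
and right internal carotid and basilar arteries.  Cerebral oxygen
delivery follows the study convention

    CDO2 = saturation (fraction) x haemoglobin (g/dL) x 1.36 x CBF (mL/min)

with Huefner's constant 1.36 (mL O2 per gram of haemoglobin).  Note the
product is applied literally with haemoglobin in g/dL, i.e. without the
dL->mL conversion; the resulting scale (cohort mean ~1795) is the one the
field reports under the label mL O2/min, so we keep it rather than
introduce a factor-of-100 disagreement with published values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import HUFNER


def total_cbf(vessel_flows) -> float:
    """Sum of the three vessel flows (mL/min); NaN if any is missing."""
    flows = np.asarray(vessel_flows, dtype=float)
    if flows.shape[-1] != 3:
        raise ValueError("expected exactly three vessel flows (L/R ICA, basilar)")
    if np.any(flows < 0):
        raise ValueError("negative vessel flow; check upstream ROI/aliasing")
    out = flows.sum(axis=-1)
    out = np.where(np.isnan(flows).any(axis=-1), np.nan, out)
    return float(out) if np.ndim(out) == 0 else out


def cdo2(sat_o2, haemoglobin, cbf):
    """Cerebral oxygen delivery, saturation x Hb x 1.36 x CBF.

    Saturation must be a fraction in [0, 1]; percent-scale input is
    rejected rather than silently divided by 100.
    """
    sat = np.asarray(sat_o2, dtype=float)
    hb = np.asarray(haemoglobin, dtype=float)
    flow = np.asarray(cbf, dtype=float)
    if np.any(sat[np.isfinite(sat)] > 1.0):
        raise ValueError(
            "sat_o2 must be a fraction in [0, 1]; divide percent values by 100"
        )
    if np.any(sat[np.isfinite(sat)] < 0.0):
        raise ValueError("sat_o2 must be non-negative")
    if np.any(hb[np.isfinite(hb)] < 0.0) or np.any(flow[np.isfinite(flow)] < 0.0):
        raise ValueError("haemoglobin and cbf must be non-negative")
    out = sat * hb * HUFNER * flow
    return float(out) if np.ndim(out) == 0 else out


def quintile_ranks(values) -> np.ndarray:
    """Quintile rank (1 = lowest fifth) per value, sizes within one of equal.

    Ranks are assigned by position in the stably sorted order, so ties are
    broken by input order and the rank function is monotone in the value.
    Missing values get rank NaN and do not count toward the group sizes.
    """
    x = np.asarray(values, dtype=float)
    present = np.flatnonzero(np.isfinite(x))
    if len(present) < 5:
        raise ValueError("need at least 5 non-missing values for quintiles")
    order = present[np.argsort(x[present], kind="stable")]
    m = len(order)
    ranks = np.full(x.shape, np.nan)
    ranks[order] = np.floor(np.arange(m) * 5 / m) + 1
    return ranks


def cdo2_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject CBF, CDO2 and quintile rank from cohort columns.

    Subjects missing any vessel flow, saturation or haemoglobin have a
    missing CDO2 and no quintile rank.
    """
    flows = cohort[["flow_lica", "flow_rica", "flow_basilar"]].to_numpy(dtype=float)
    cbf = total_cbf(flows)
    delivery = cdo2(
        cohort["sat_o2"].to_numpy(dtype=float),
        cohort["haemoglobin"].to_numpy(dtype=float),
        cbf,
    )
    out = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "cbf": cbf,
            "sat_o2": cohort["sat_o2"].to_numpy(dtype=float),
            "haemoglobin": cohort["haemoglobin"].to_numpy(dtype=float),
            "cdo2": delivery,
        }
    )
    if np.isfinite(delivery).sum() >= 5:
        out["cdo2_quintile"] = quintile_ranks(delivery)
    else:
        out["cdo2_quintile"] = np.nan
    return out
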