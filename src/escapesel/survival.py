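"""Kaplan-Meier estimation and log-rank contrasts of escape groups.

The product-limit estimator and the two-group log-rank test are computed
with lifelines; this module adds the stratified orchestration (immune
category C1-C6 and/or cancer type), small-arm skipping, and BH adjustment
across strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .dnds import bh_adjust


@dataclass
class SurvivalCurve:
    times: np.ndarray  # distinct observed times, increasing
    survival: np.ndarray  # S(t) step values, non-increasing
    at_risk: np.ndarray
    median_survival: float  # NaN when S never reaches 0.5


def km_estimate(records: pd.DataFrame) -> SurvivalCurve:
    """Product-limit survival estimate from (survival_time, event) records.

    Censored records decrement the risk set without a survival drop; the
    median is the first time S(t) <= 0.5 (NaN if never reached).
    """
    if len(records) == 0:
        raise ValueError("no records")
    if (records["survival_time"] <= 0).any():
        raise ValueError("nonpositive survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(records["survival_time"], records["event"])
    tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    at_risk = tbl["at_risk"].to_numpy()
    med = float(kmf.median_survival_time_)
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=at_risk,
        median_survival=med if np.isfinite(med) else np.nan,
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p).

    Undefined (NaN, NaN) when there are no events at all (zero variance).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    if group_a["event"].sum() + group_b["event"].sum() == 0:
        return np.nan, np.nan
    res = _ll_logrank(
        group_a["survival_time"],
        group_b["survival_time"],
        event_observed_A=group_a["event"],
        event_observed_B=group_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def stratified_survival(
    clinical: pd.DataFrame,
    labels: pd.DataFrame,
    strata: list[str] = ("immune_category",),
    min_arm: int = 5,
) -> pd.DataFrame:
    """Per-stratum log-rank of escape+ vs escape-, BH-adjusted across strata.

    ``strata`` is a list of clinical columns (e.g. immune_category,
    cancer_type). Strata with fewer than ``min_arm`` patients in either arm
    are reported as skipped with a reason.
    """
    df = clinical.merge(labels[["patient_id", "status"]], on="patient_id", how="inner")
    strata = list(strata)
    rows = []
    for key, grp in df.groupby(strata, dropna=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        arms = {s: grp[grp["status"] == s] for s in ("escape_neg", "escape_pos")}
        rec = {c: k for c, k in zip(strata, key)}
        rec["n_escape_neg"] = len(arms["escape_neg"])
        rec["n_escape_pos"] = len(arms["escape_pos"])
        if min(len(a) for a in arms.values()) < min_arm:
            rec.update(chi2=np.nan, p=np.nan, skipped=True, reason=f"arm < {min_arm} patients")
        else:
            chi2, p = logrank_test(arms["escape_neg"], arms["escape_pos"])
            med = {s: km_estimate(a).median_survival for s, a in arms.items()}
            rec.update(
                chi2=chi2,
                p=p,
                skipped=False,
                reason="",
                median_escape_neg=med["escape_neg"],
                median_escape_pos=med["escape_pos"],
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def curve_table(records: pd.DataFrame, labels: pd.DataFrame, stratum: str = "all") -> pd.DataFrame:
    """Per-arm KM curve export (stratum, arm, time, survival, at_risk)."""
    df = records.merge(labels[["patient_id", "status"]], on="patient_id", how="inner")
    rows = []
    for arm, grp in df.groupby("status"):
        if len(grp) == 0:
            continue
        curve = km_estimate(grp)
        for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
            rows.append(
                {"stratum": stratum, "arm": arm, "time": t, "survival": s, "at_risk": int(r)}
            )
    return pd.DataFrame(rows)
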