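"""Score-based cohort stratification, Kaplan–Meier curves, log-rank test.

A cohort is a DataFrame indexed by sample with columns ``time``
(non-negative follow-up, months), ``event`` (1 = event, 0 = censored) and
``score`` (the per-sample signature score). Stratification splits the
cohort at the empirical (1 - top_frac) score quantile into a high-score
group (top fraction, boundary ties included) and the remaining low-score
group; Kaplan–Meier estimation and the standard (unweighted) two-group
log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "validate_cohort",
    "stratify_by_score",
    "kaplan_meier",
    "logrank_test",
    "read_clinical",
    "score_stratified_logrank",
]


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in cohort.columns:
            raise ValueError(f"cohort missing column {col!r}")
    if (cohort["time"] < 0).any():
        raise ValueError("follow-up times must be >= 0")
    if not cohort["event"].isin([0, 1]).all():
        raise ValueError("event must be binary (0 censored, 1 event)")
    return cohort


def stratify_by_score(cohort: pd.DataFrame, top_frac: float = 0.25) -> pd.DataFrame:
    """Assign 'high'/'low' strata by signature score.

    high = samples with score >= the empirical (1 - top_frac) quantile,
    computed as the ceil(top_frac * n)-th largest score, so boundary ties
    all go high and |high| >= ceil(top_frac * n). With all scores equal the
    whole cohort is high (a warning is emitted).
    """
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must be in (0, 1)")
    if "score" not in cohort.columns:
        raise ValueError("cohort missing column 'score'")
    validate_cohort(cohort)
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    k = int(np.ceil(top_frac * n))
    cutoff = np.sort(cohort["score"].to_numpy())[::-1][k - 1]
    out = cohort.copy()
    out["stratum"] = np.where(out["score"] >= cutoff, "high", "low")
    if (out["stratum"] == "high").all():
        warnings.warn(
            "all samples fall in the high stratum (degenerate score ties at the "
            "stratification boundary)", stacklevel=2,
        )
    return out


def kaplan_meier(group: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate for one group.

    Returns a step table (time, survival, at_risk) at the observed times,
    beginning at S(0) = 1; censored subjects leave the risk set after
    their time (censoring processed after events at tied times).
    """
    validate_cohort(group)
    kmf = KaplanMeierFitter()
    kmf.fit(group["time"], event_observed=group["event"])
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(), "survival": surv.to_numpy(),
         "at_risk": at_risk.to_numpy()}
    ).reset_index(drop=True)


def logrank_test(high: pd.DataFrame, low: pd.DataFrame) -> dict:
    """Standard two-group log-rank test; chi-square statistic with 1 df.

    Refuses when no events are observed in either group ("no events"),
    since the observed-minus-expected sum is then undefined.
    """
    validate_cohort(high)
    validate_cohort(low)
    if int(high["event"].sum()) + int(low["event"].sum()) == 0:
        raise ValueError("no events in either group; log-rank test undefined")
    res = _ll_logrank(
        high["time"], low["time"],
        event_observed_A=high["event"], event_observed_B=low["event"],
    )
    return {"statistic": float(res.test_statistic), "p": float(res.p_value),
            "n_high": len(high), "n_low": len(low)}


def score_stratified_logrank(cohort: pd.DataFrame, top_frac: float = 0.25) -> dict:
    """Stratify by score, then compare survival of high vs low strata.

    Convenience composition used by the pipeline; returns the log-rank
    result plus median survival per stratum (NaN when never reached).
    """
    strat = stratify_by_score(cohort, top_frac)
    high = strat[strat["stratum"] == "high"]
    low = strat[strat["stratum"] == "low"]
    if len(low) == 0:
        raise ValueError("low stratum is empty (degenerate score distribution)")
    result = logrank_test(high, low)
    for label, grp in (("high", high), ("low", low)):
        km = kaplan_meier(grp)
        below = km[km["survival"] <= 0.5]
        result[f"median_survival_{label}"] = (
            float(below["time"].iloc[0]) if len(below) else float("nan")
        )
    return result


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    df = df.set_index("sample")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return validate_cohort(df)
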