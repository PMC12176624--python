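"""Escape dynamics across the four life stages.

Timepoints are categorical (embryonic, young, adult, aged). A gene is an
age-specific escapee in a group when it escapes in aged samples, is
silenced at every informative earlier timepoint, and at least one earlier
timepoint is informative — absence of evidence never produces an
age-specific call. The gradual biallelic trend (ΔAR = AR_adult − AR_aged
at or above the cutoff, informative at young, adult and aged) is an
orthogonal flag: constitutive escapees can drift toward biallelic
expression too.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .calling import STATUS_ESCAPE, STATUS_NO_ESCAPE
from .config import TIMEPOINTS, AnalysisConfig
from .stats import dunn_test

CLASS_AGE_SPECIFIC = "age_specific"
CLASS_CONSTITUTIVE = "constitutive"
CLASS_OTHER = "other"

_STATUS_CODE = {STATUS_ESCAPE: "E", STATUS_NO_ESCAPE: "N"}


def delta_ar(ar_adult: float, ar_aged: float) -> float:
    """ΔAR = AR_adult − AR_aged; positive = shift toward biallelic with age."""
    if ar_adult is None or ar_aged is None:
        return float("nan")
    return float(ar_adult) - float(ar_aged)


def classify_dynamics(calls: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Integrate per-timepoint escape calls into per gene x group dynamics.

    ``calls`` is the call table (gene_id, group, timepoint, status,
    median_ar). Statuses other than escape / no_escape count as
    non-informative (NI). Returns one row per gene x group with
    ``status_<timepoint>`` columns (E / N / NI), the main classification,
    the gradual flag and ΔAR.
    """
    cutoff = config.delta_ar_cutoff
    sub = calls[["gene_id", "group", "timepoint", "status", "median_ar"]].copy()
    sub["code"] = sub["status"].map(_STATUS_CODE).fillna("NI")
    stat = (
        sub.pivot(index=["gene_id", "group"], columns="timepoint", values="code")
        .reindex(columns=TIMEPOINTS)
        .fillna("NI")
    )
    arp = sub.pivot(
        index=["gene_id", "group"], columns="timepoint", values="median_ar"
    ).reindex(columns=TIMEPOINTS)

    is_e = stat == "E"
    is_inf = stat != "NI"
    earlier = list(TIMEPOINTS[:-1])
    n_earlier_inf = is_inf[earlier].sum(axis=1)
    earlier_all_silenced = ((stat[earlier] == "N") | ~is_inf[earlier]).all(axis=1)
    age_specific = is_e["aged"] & (n_earlier_inf >= 1) & earlier_all_silenced
    n_inf = is_inf.sum(axis=1)
    constitutive = (n_inf >= 2) & (is_e | ~is_inf).all(axis=1)
    d_ar = arp["adult"] - arp["aged"]
    gradual = (
        is_inf[["young", "adult", "aged"]].all(axis=1)
        & (d_ar >= cutoff).fillna(False)
        & ~age_specific
    )
    classification = np.where(
        age_specific, CLASS_AGE_SPECIFIC, np.where(constitutive, CLASS_CONSTITUTIVE, CLASS_OTHER)
    )
    out = stat.reset_index()[["gene_id", "group"]]
    for tp in TIMEPOINTS:
        out[f"status_{tp}"] = stat[tp].to_numpy()
    out["classification"] = classification
    out["gradual_biallelic_trend"] = gradual.to_numpy()
    out["delta_ar"] = d_ar.to_numpy()
    return out


def compare_escape_rates(rates: pd.DataFrame) -> dict:
    """Compare per-organ escape percentages across timepoints.

    ``rates`` needs columns (group, timepoint, percent_escape). Reports a
    one-way ANOVA across timepoints with Tukey HSD pairwise contrasts, and
    co-reports Kruskal–Wallis with Dunn (BH) post hoc tests.
    """
    sub = rates.dropna(subset=["percent_escape"])
    tps = [tp for tp in TIMEPOINTS if tp in set(sub["timepoint"])]
    groups = [sub.loc[sub["timepoint"] == tp, "percent_escape"].to_numpy() for tp in tps]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 timepoints with >= 2 organs each")
    f_stat, anova_p = sps.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(
        sub["percent_escape"].to_numpy(),
        sub["timepoint"].to_numpy(),
        alpha=0.05,
    )
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    kw_stat, kw_p = sps.kruskal(*groups)
    dunn = dunn_test(groups, labels=tps)
    return {
        "anova_F": float(f_stat),
        "anova_p": float(anova_p),
        "tukey": tukey_df,
        "kruskal_H": float(kw_stat),
        "kruskal_p": float(kw_p),
        "dunn": dunn,
    }


def status_matrix(dynamics: pd.DataFrame, timepoints: Sequence[str] = TIMEPOINTS) -> pd.DataFrame:
    """Gene x timepoint E/N/NI matrix for one group (export format)."""
    cols = [f"status_{tp}" for tp in timepoints]
    out = dynamics[["gene_id", "group"] + cols].copy()
    out.columns = ["gene_id", "group"] + list(timepoints)
    return out
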