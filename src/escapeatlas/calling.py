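"""Escape / no-escape classification per gene, group and timepoint.

A gene escapes X inactivation when its median AR over informative female
replicates is at or below the escape cutoff (default 0.9, i.e. >= 10% of
expression from the inactive X). Genes that look biallelic in male
(single-X) samples are excluded as probable false positives, as are
pseudoautosomal genes and a small configured false-positive list.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig
from .stats import FisherResult, fisher_exact_2x2

STATUS_ESCAPE = "escape"
STATUS_NO_ESCAPE = "no_escape"
STATUS_NOT_INFORMATIVE = "not_informative"
STATUS_EXCLUDED_MALE = "excluded_male_biallelic"
STATUS_EXCLUDED_PAR = "excluded_par"


def classify_gene(
    gene_id: str,
    median_ar: float,
    informative: bool,
    male_median_ar: Optional[float],
    excluded_genes: Sequence[str],
    cutoff: float = 0.9,
) -> str:
    """Classify one gene at one group x timepoint.

    Precedence: configured exclusion list, then male-biallelic exclusion
    (male median AR <= cutoff), then informativeness, then the inclusive
    escape comparison median AR <= cutoff.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    if gene_id in set(excluded_genes):
        return STATUS_EXCLUDED_PAR
    if male_median_ar is not None and not np.isnan(male_median_ar):
        if male_median_ar <= cutoff:
            return STATUS_EXCLUDED_MALE
    if not informative or median_ar is None or np.isnan(median_ar):
        return STATUS_NOT_INFORMATIVE
    return STATUS_ESCAPE if median_ar <= cutoff else STATUS_NO_ESCAPE


def _male_reference(male_summary: Optional[pd.DataFrame]):
    """Per gene x group (x timepoint) male medians for the exclusion filter.

    The same-timepoint male median is used when informative; otherwise the
    minimum informative male median across timepoints of the group stands
    in (the exclusion is global in spirit: a gene biallelic in any male
    sample set is suspect).
    """
    if male_summary is None or male_summary.empty:
        return None
    inf = male_summary[male_summary["informative"]]
    if inf.empty:
        return None
    same_tp = inf.set_index(["gene_id", "group", "timepoint"])["median_ar"]
    any_tp = inf.groupby(["gene_id", "group"])["median_ar"].min()
    return same_tp, any_tp


def call_table(
    summary: pd.DataFrame,
    male_summary: Optional[pd.DataFrame],
    config: AnalysisConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every gene x group x timepoint and summarize per group.

    ``summary`` is the female allelic summary from
    :func:`escapeatlas.allelic.summarize_allelic`. Returns ``(calls,
    group_summary)``; ``percent_escape`` uses genes with a defined call
    (escape or no_escape) as the denominator and is NaN when there are
    none.
    """
    calls = summary.copy()
    if "sex" in calls.columns:
        calls = calls[calls["sex"] == "female"].drop(columns=["sex"])
    male_ref = _male_reference(male_summary)
    if male_ref is not None:
        same_tp, any_tp = male_ref
        idx3 = pd.MultiIndex.from_frame(calls[["gene_id", "group", "timepoint"]])
        idx2 = pd.MultiIndex.from_frame(calls[["gene_id", "group"]])
        same = pd.Series(same_tp.reindex(idx3).to_numpy(), index=calls.index)
        fallback = pd.Series(any_tp.reindex(idx2).to_numpy(), index=calls.index)
        calls["male_median_ar"] = same.fillna(fallback)
    else:
        calls["male_median_ar"] = np.nan

    cutoff = config.escape_ar_cutoff
    excluded = set(config.excluded_genes)
    status = np.full(len(calls), STATUS_NOT_INFORMATIVE, dtype=object)
    is_excluded = calls["gene_id"].isin(excluded).to_numpy()
    male_biallelic = (calls["male_median_ar"] <= cutoff).fillna(False).to_numpy()
    informative = calls["informative"].to_numpy()
    escape = (calls["median_ar"] <= cutoff).fillna(False).to_numpy()
    status[informative & escape] = STATUS_ESCAPE
    status[informative & ~escape] = STATUS_NO_ESCAPE
    status[~is_excluded & male_biallelic] = STATUS_EXCLUDED_MALE
    status[is_excluded] = STATUS_EXCLUDED_PAR
    calls["status"] = status
    calls["xi_fraction"] = np.where(
        np.isin(status, [STATUS_ESCAPE, STATUS_NO_ESCAPE]),
        1.0 - calls["median_ar"],
        np.nan,
    )

    grp = calls.groupby(["group", "timepoint"], sort=True)
    rows = []
    for (group, timepoint), sub in grp:
        n_escape = int((sub["status"] == STATUS_ESCAPE).sum())
        n_inf = int(sub["status"].isin([STATUS_ESCAPE, STATUS_NO_ESCAPE]).sum())
        rows.append(
            {
                "group": group,
                "timepoint": timepoint,
                "n_informative_genes": n_inf,
                "n_escape": n_escape,
                "percent_escape": 100.0 * n_escape / n_inf if n_inf else np.nan,
            }
        )
    return calls, pd.DataFrame(rows)


def cutoff_sweep(
    summary: pd.DataFrame,
    male_summary: Optional[pd.DataFrame],
    config: AnalysisConfig,
    cutoffs: Sequence[float],
) -> pd.DataFrame:
    """Percent escape per group x timepoint as a function of the AR cutoff."""
    frames = []
    for c in cutoffs:
        cfg = config.model_copy(update={"escape_ar_cutoff": float(c)})
        _, grp = call_table(summary, male_summary, cfg)
        grp = grp.copy()
        grp["cutoff"] = float(c)
        frames.append(grp)
    return pd.concat(frames, ignore_index=True)


def compare_fc_groups(
    escape_fcs: Sequence[float], nonescape_fcs: Sequence[float]
) -> dict:
    """Two-sided Mann-Whitney U test of sex fold changes, escape vs non-escape."""
    x = np.asarray(list(escape_fcs), dtype=float)
    y = np.asarray(list(nonescape_fcs), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one value")
    method = "exact" if (x.size <= 20 and y.size <= 20) else "auto"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_escape": float(np.median(x)),
        "median_nonescape": float(np.median(y)),
    }


def disease_enrichment(a: int, b: int, c: int, d: int) -> FisherResult:
    """Fisher enrichment of disease-flagged genes among escapees.

    Table layout: a = escapees with flag, b = escapees without, c =
    non-escapees with flag, d = non-escapees without.
    """
    return fisher_exact_2x2(a, b, c, d)
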