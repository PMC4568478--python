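"""Group statistics for paired pre/intra perfusion cohorts.

Reproduces the study design around relative perfusion parameters: paired
two-tailed t-tests of pre versus intra sessions (all subjects and per
group), independent two-sample t-tests across groups on intra values and
on per-subject percentage increases, and Benjamini-Hochberg false
discovery rate control (default q = 0.2) applied per parameter family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .territories import TERRITORIES, percent_increase

__all__ = [
    "TTestResult",
    "CohortResult",
    "paired_ttest",
    "independent_ttest",
    "benjamini_hochberg",
    "build_comparison_tables",
]

PARAMETERS = ("cbf", "cbv", "mtt")
COHORT_COLUMNS = ("All", "CHS", "non-CHS")


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    n: int
    degenerate: bool = False


def paired_ttest(pre, intra) -> TTestResult:
    """Two-tailed paired Student's t-test on per-subject differences.

    Zero-variance differences are reported as a degenerate case: all-zero
    differences give ``t=0, p=1`` (an exact tie); a constant nonzero
    difference gives ``p=0`` with an infinite statistic.
    """
    pre = np.asarray(pre, dtype=float)
    intra = np.asarray(intra, dtype=float)
    if pre.shape != intra.shape or pre.ndim != 1:
        raise ValueError("pre and intra must be 1D arrays of equal length")
    n = pre.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = intra - pre
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TTestResult(0.0, 1.0, n, degenerate=True)
        return TTestResult(float(np.sign(d.mean()) * np.inf), 0.0, n, degenerate=True)
    t, p = sps.ttest_rel(intra, pre)
    return TTestResult(float(t), float(p), n)


def independent_ttest(group_a, group_b, equal_var: bool = True) -> TTestResult:
    """Two-tailed independent-sample t-test (pooled variance by default).

    ``equal_var=False`` switches to the Welch variant.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    n = a.size + b.size
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        if np.allclose(a.mean(), b.mean()):
            return TTestResult(0.0, 1.0, n, degenerate=True)
        return TTestResult(
            float(np.sign(a.mean() - b.mean()) * np.inf), 0.0, n, degenerate=True
        )
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(t), float(p), n)


def benjamini_hochberg(p_values, q: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Sort the m p-values ascending, find the largest k with
    ``p_(k) <= k q / m`` and reject all hypotheses of rank <= k.  Returns
    ``(reject, adjusted)`` in the input order; adjusted values are the
    usual step-up-monotone ``min_{j >= rank} m p_(j) / j`` capped at 1.
    NaN entries (non-computable tests) are passed through unrejected and
    do not count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    if finite.any():
        rej, adj, _, _ = multipletests(p[finite], alpha=q, method="fdr_bh")
        reject[finite] = rej
        adjusted[finite] = adj
    return reject, adjusted


@dataclass(frozen=True)
class CohortResult:
    """Machine twin of the per-parameter summary tables.

    ``stats``: tidy per-(parameter, territory) statistics including raw
    and BH-adjusted p-values.  ``tables``: one report-shaped DataFrame per
    parameter, rows (territory x {Pre, Intra, %increase, P-value
    (Pre vs Intra)}) and columns (All, CHS, non-CHS, P-value (CHS vs
    non-CHS), significant).
    """

    stats: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    q: float

    def to_csv(self, out_dir) -> list:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for parameter, table in self.tables.items():
            path = out / f"table_relative_{parameter}.csv"
            table.to_csv(path)
            paths.append(path)
        stats_path = out / "cohort_stats.csv"
        self.stats.to_csv(stats_path, index=False)
        paths.append(stats_path)
        return paths

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "stats": self.stats.replace({np.nan: None}).to_dict(orient="records"),
        }


def _session_values(summaries: pd.DataFrame, parameter: str, territory: str,
                    session: str, group: str | None) -> pd.Series:
    sel = (summaries.territory == territory) & (summaries.session == session)
    if group is not None:
        sel &= summaries.group == group
    sub = summaries[sel].set_index("subject")[f"relative_{parameter}"]
    return sub.sort_index()


def build_comparison_tables(
    summaries: pd.DataFrame,
    q: float = 0.2,
    equal_var: bool = True,
) -> CohortResult:
    """Assemble the three per-parameter comparison tables with FDR flags.

    ``summaries`` is a long DataFrame with columns ``subject, group,
    session, territory, relative_cbf, relative_cbv, relative_mtt`` and
    sessions ``pre``/``intra`` for every subject.  For each parameter and
    territory: group means of pre, intra and per-subject %increase; paired
    pre-vs-intra tests for All/CHS/non-CHS; across-group independent tests
    on intra values and on %increase.  Benjamini-Hochberg runs per
    parameter over the 15-test family {paired-All, intra-across,
    %increase-across} x 5 territories.  Groups with fewer than two
    subjects get NaN (not-computable) p-values; the tables are still
    emitted.
    """
    required = {"subject", "group", "session", "territory"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    incomplete = [
        subject
        for subject, grp in summaries.groupby("subject")
        if {"pre", "intra"} - set(grp.session)
    ]
    if incomplete:
        raise ValueError(f"subjects missing a pre or intra session: {incomplete}")

    group_of = summaries.drop_duplicates("subject").set_index("subject")["group"]

    def _paired(parameter, territory, group):
        pre = _session_values(summaries, parameter, territory, "pre", group)
        intra = _session_values(summaries, parameter, territory, "intra", group)
        if len(pre) < 2:
            return None, pre, intra
        return paired_ttest(pre.values, intra.values), pre, intra

    records = []
    tables = {}
    for parameter in PARAMETERS:
        rows = {}
        family = {}  # (territory, test) -> p
        for territory in TERRITORIES:
            rec = {"parameter": parameter, "territory": territory}
            pct = {}
            for group, column in ((None, "All"), ("CHS", "CHS"), ("non-CHS", "non-CHS")):
                result, pre, intra = _paired(parameter, territory, group)
                inc = percent_increase(pre.values, intra.values) if len(pre) else np.array([])
                pct[column] = pd.Series(inc, index=pre.index)
                rec[f"pre_mean_{column}"] = pre.mean() if len(pre) else np.nan
                rec[f"intra_mean_{column}"] = intra.mean() if len(intra) else np.nan
                rec[f"pct_increase_{column}"] = inc.mean() if len(inc) else np.nan
                rec[f"p_paired_{column}"] = result.pvalue if result else np.nan
            chs_intra = _session_values(summaries, parameter, territory, "intra", "CHS")
            non_intra = _session_values(summaries, parameter, territory, "intra", "non-CHS")
            if len(chs_intra) >= 2 and len(non_intra) >= 2:
                rec["p_intra_groups"] = independent_ttest(
                    chs_intra.values, non_intra.values, equal_var=equal_var
                ).pvalue
                rec["p_increase_groups"] = independent_ttest(
                    pct["CHS"].values, pct["non-CHS"].values, equal_var=equal_var
                ).pvalue
            else:
                rec["p_intra_groups"] = np.nan
                rec["p_increase_groups"] = np.nan
            family[(territory, "paired_All")] = rec["p_paired_All"]
            family[(territory, "intra_groups")] = rec["p_intra_groups"]
            family[(territory, "increase_groups")] = rec["p_increase_groups"]
            rows[territory] = rec

        keys = list(family)
        reject, adjusted = benjamini_hochberg([family[k] for k in keys], q=q)
        flags = dict(zip(keys, reject))
        adj = dict(zip(keys, adjusted))
        for territory in TERRITORIES:
            rec = rows[territory]
            for test in ("paired_All", "intra_groups", "increase_groups"):
                rec[f"significant_{test}"] = bool(flags[(territory, test)])
                rec[f"p_adjusted_{test}"] = adj[(territory, test)]
            records.append(rec)
        tables[parameter] = _format_table(rows)

    return CohortResult(stats=pd.DataFrame(records), tables=tables, q=q)


def _format_table(rows: dict[str, dict]) -> pd.DataFrame:
    """Shape one parameter's statistics like the published summary tables."""
    index = pd.MultiIndex.from_product(
        [TERRITORIES, ("Pre", "Intra", "%increase", "P-value (Pre vs Intra)")],
        names=["territory", "row"],
    )
    table = pd.DataFrame(
        index=index,
        columns=list(COHORT_COLUMNS) + ["P-value (CHS vs non-CHS)", "significant"],
        dtype=object,
    )
    for territory, rec in rows.items():
        for column in COHORT_COLUMNS:
            table.loc[(territory, "Pre"), column] = rec[f"pre_mean_{column}"]
            table.loc[(territory, "Intra"), column] = rec[f"intra_mean_{column}"]
            table.loc[(territory, "%increase"), column] = rec[f"pct_increase_{column}"]
            table.loc[(territory, "P-value (Pre vs Intra)"), column] = rec[
                f"p_paired_{column}"
            ]
        table.loc[(territory, "Intra"), "P-value (CHS vs non-CHS)"] = rec["p_intra_groups"]
        table.loc[(territory, "%increase"), "P-value (CHS vs non-CHS)"] = rec[
            "p_increase_groups"
        ]
        table.loc[(territory, "Intra"), "significant"] = rec["significant_intra_groups"]
        table.loc[(territory, "%increase"), "significant"] = rec[
            "significant_increase_groups"
        ]
        table.loc[(territory, "P-value (Pre vs Intra)"), "significant"] = rec[
            "significant_paired_All"
        ]
    return table
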