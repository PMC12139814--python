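"""Session-level statistics linking neural metrics to behavior.

The core quantity is the Pearson correlation across sessions between a
neural metric (e.g., baseline-subtracted transient AUC during the
dyskinesia onset window) and a behavioral metric (AIM AUC over the same
window), plus contract-level wrappers around the standard group
comparisons: repeated-measures one-way ANOVA with Tukey post-hoc,
Kruskal-Wallis with Dunn's post-hoc, and two-way repeated-measures ANOVA
with Greenhouse-Geisser correction.  The omnibus tests delegate to scipy /
pingouin; this module owns data reshaping, the listwise missing-data
policy, and report formatting.  Dunn's test is computed here directly
(tie-corrected rank z contrasts with Bonferroni adjustment).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["CorrelationResult", "ComparisonReport", "correlate",
           "compare_timepoints", "dunn_posthoc"]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    n_dropped: int
    defined: bool

    def summary(self) -> str:
        if not self.defined:
            return f"Pearson r undefined (zero variance); n={self.n}"
        return f"Pearson r={self.r:.3f}, p={self.p:.4g}, n={self.n}"


@dataclass
class ComparisonReport:
    design: str
    metric: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame
    dropped_subjects: list

    def summary(self) -> str:
        lines = [f"{self.design} on {self.metric}: "
                 f"stat={self.statistic:.4g}, p={self.p_value:.4g}"]
        if self.dropped_subjects:
            lines.append(f"dropped (incomplete): {self.dropped_subjects}")
        lines.append(self.posthoc.to_string(index=False))
        return "\n".join(lines)


def correlate(table: pd.DataFrame, x: str, y: str) -> CorrelationResult:
    """Pearson correlation between two session-table columns.

    Rows with a missing value in either column are dropped (and counted);
    at least 3 complete pairs are required.  Zero variance in either
    variable leaves r undefined (flagged rather than raised).
    """
    sub = table[[x, y]].dropna()
    n_dropped = len(table) - len(sub)
    if len(sub) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(sub)}")
    xs, ys = sub[x].to_numpy(float), sub[y].to_numpy(float)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        logger.warning("zero variance in %s or %s: correlation undefined",
                       x, y)
        return CorrelationResult(r=float("nan"), p=float("nan"), n=len(sub),
                                 n_dropped=n_dropped, defined=False)
    r, p = stats.pearsonr(xs, ys)
    return CorrelationResult(r=float(r), p=float(p), n=len(sub),
                             n_dropped=n_dropped, defined=True)


def dunn_posthoc(groups: dict, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post-hoc test for pairwise contrasts after Kruskal-Wallis.

    Uses tie-corrected rank z statistics: all observations are ranked
    jointly; for each pair the difference of mean ranks is scaled by
    sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)) with the tie term
    T = sum(t^3 - t) / (12 (N - 1)).  Two-sided normal p-values with
    Bonferroni adjustment by default.
    """
    names = list(groups)
    sizes = {k: len(groups[k]) for k in names}
    pooled = np.concatenate([np.asarray(groups[k], float) for k in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, i0 = {}, 0
    for k in names:
        mean_ranks[k] = ranks[i0:i0 + sizes[k]].mean()
        i0 += sizes[k]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n_total - 1)) \
        if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(p * m, 1.0) if adjust == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": z, "p_unadj": p,
                     "p_adj": p_adj})
    return pd.DataFrame(rows)


def _pcol(row, *names):
    """First finite p-value among candidate column names (pingouin renamed
    its p columns across versions)."""
    for n in names:
        if n in row.index and np.isfinite(row[n]):
            return row[n]
    raise KeyError(f"none of {names} present in ANOVA table")


def _complete_cases(table: pd.DataFrame, metric: str, group: str,
                    subject: str):
    """Listwise deletion for repeated-measures designs: keep subjects with a
    value at every level; log the ids dropped."""
    wide = table.pivot_table(index=subject, columns=group, values=metric,
                             aggfunc="mean")
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        logger.warning("listwise deletion of incomplete subjects: %s",
                       dropped)
    long = complete.reset_index().melt(id_vars=subject, var_name=group,
                                       value_name=metric)
    return long, dropped


def compare_timepoints(table: pd.DataFrame, metric: str, design: str,
                       group: str = "timepoint", subject: str = "subject",
                       group2: str | None = None) -> ComparisonReport:
    """Compare a session metric across treatment timepoints.

    ``design`` selects the procedure:

    * ``rm_anova_tukey`` — repeated-measures one-way ANOVA (pingouin) with a
      Tukey HSD post-hoc;
    * ``kruskal_dunn`` — Kruskal-Wallis omnibus with Dunn's post-hoc;
    * ``rm_two_way_gg`` — two-way repeated-measures ANOVA with
      Greenhouse-Geisser correction (requires ``group2``).

    Repeated-measures designs apply listwise deletion of subjects with
    incomplete timepoint coverage; the dropped ids are reported.
    """
    if design == "kruskal_dunn":
        clean = table[[metric, group]].dropna()
        groups = {k: g[metric].to_numpy(float)
                  for k, g in clean.groupby(group, observed=True)}
        if len(groups) < 2:
            raise ValueError("need >= 2 groups")
        arrays = list(groups.values())
        if np.ptp(np.concatenate(arrays)) == 0:
            stat, p = 0.0, 1.0   # full ties: rank test is degenerate
        else:
            stat, p = stats.kruskal(*arrays)
        post = dunn_posthoc(groups)
        return ComparisonReport(design=design, metric=metric,
                                statistic=float(stat), p_value=float(p),
                                posthoc=post, dropped_subjects=[])

    import pingouin as pg

    if design == "rm_anova_tukey":
        long, dropped = _complete_cases(table, metric, group, subject)
        aov = pg.rm_anova(data=long, dv=metric, within=group,
                          subject=subject, detailed=True)
        row = aov.iloc[0]
        post = pg.pairwise_tukey(data=long, dv=metric, between=group)
        post = post.rename(columns={"A": "group_a", "B": "group_b"})
        return ComparisonReport(design=design, metric=metric,
                                statistic=float(row["F"]),
                                p_value=float(_pcol(row, "p_unc", "p-unc")),
                                posthoc=post, dropped_subjects=dropped)

    if design == "rm_two_way_gg":
        if group2 is None:
            raise ValueError("rm_two_way_gg requires group2")
        clean = table[[metric, group, group2, subject]].dropna()
        aov = pg.rm_anova(data=clean, dv=metric, within=[group, group2],
                          subject=subject, correction=True)
        inter = aov[aov["Source"].str.contains("\\*")].iloc[0]
        p = _pcol(inter, "p_GG_corr", "p-GG-corr", "p_unc", "p-unc")
        post = pg.pairwise_tests(data=clean, dv=metric,
                                 within=[group, group2], subject=subject)
        return ComparisonReport(design=design, metric=metric,
                                statistic=float(inter["F"]),
                                p_value=float(p),
                                posthoc=post, dropped_subjects=[])

    raise ValueError(f"unknown design {design!r}")
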