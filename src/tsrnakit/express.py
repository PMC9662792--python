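"""Normalization, expressed-set (Venn) logic and differential expression.

Differential expression follows the study design it serves: counts are
CPM-normalized, log2(CPM + 1) values are compared between the two groups
with a Welch two-sample t-test, p-values are Benjamini-Hochberg adjusted,
and a tsRNA is called differentially expressed when FDR < 0.05 and the
group-mean fold change is at least 2 (|log2FC| >= 1, boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUP_NORMAL = "normal"
GROUP_IUGR = "IUGR"


class ExpressionMatrix:
    """tsRNA x sample integer counts with per-sample group labels.

    The CPM layer (counts scaled to one million per column) is computed
    lazily and cached.
    """

    def __init__(self, counts: pd.DataFrame, groups: pd.Series):
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(counts.columns) - set(groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        self.counts = counts.astype(np.int64)
        self.groups = groups.loc[counts.columns]
        self._cpm: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tsrna_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples_in(self, group: str) -> list[str]:
        ids = [s for s in self.sample_ids if self.groups[s] == group]
        if not ids:
            raise ValueError(f"no samples in group {group!r}")
        return ids

    @property
    def cpm(self) -> pd.DataFrame:
        if self._cpm is None:
            self._cpm = cpm_normalize(self.counts)
        return self._cpm


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: counts[i,j] / colsum(j) * 1e6."""
    colsums = counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"zero-depth sample(s): {list(zero.index)}")
    return counts / colsums * 1e6


def expressed_sets(
    matrix: ExpressionMatrix, min_group_count: int = 1
) -> dict[str, set[str]]:
    """Partition the catalog by which group(s) express each tsRNA.

    A tsRNA is expressed in a group when its summed counts over that group's
    samples reach ``min_group_count``.  Returns normal_only / iugr_only /
    shared / undetected id sets (the last is non-empty only for rows below
    the threshold in both groups).
    """
    normal_total = matrix.counts[matrix.samples_in(GROUP_NORMAL)].sum(axis=1)
    iugr_total = matrix.counts[matrix.samples_in(GROUP_IUGR)].sum(axis=1)
    in_normal = normal_total >= min_group_count
    in_iugr = iugr_total >= min_group_count
    ids = matrix.counts.index
    return {
        "normal_only": set(ids[in_normal & ~in_iugr]),
        "iugr_only": set(ids[in_iugr & ~in_normal]),
        "shared": set(ids[in_normal & in_iugr]),
        "undetected": set(ids[~in_normal & ~in_iugr]),
    }


def top_share(matrix: ExpressionMatrix, k: int, group: str) -> float:
    """Fraction of a group's mean CPM carried by its k most expressed tsRNAs."""
    if k > len(matrix.tsrna_ids):
        raise ValueError("k exceeds catalog size")
    mean_cpm = matrix.cpm[matrix.samples_in(group)].mean(axis=1)
    total = float(mean_cpm.sum())
    if total == 0:
        raise ValueError(f"group {group!r} has no expression")
    return float(mean_cpm.nlargest(k).sum()) / total


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DEResult:
    tsrna_id: str
    mean_cpm_normal: float
    mean_cpm_iugr: float
    log2fc: float
    p_value: float
    fdr: float
    status: str  # up | down | ns


def differential_expression(
    matrix: ExpressionMatrix,
    pseudocount: float = 1.0,
    fdr_threshold: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Welch-t differential expression of IUGR versus normal.

    log2FC is computed on group-mean CPM with a pseudocount, positive when
    higher in IUGR.  Rows with zero counts in every sample are excluded from
    testing.  Returns one row per tested tsRNA with means, log2FC, p, fdr
    and status (up / down / ns, thresholds inclusive on |log2FC|).
    """
    normal_ids = matrix.samples_in(GROUP_NORMAL)
    iugr_ids = matrix.samples_in(GROUP_IUGR)
    if len(normal_ids) < 2 or len(iugr_ids) < 2:
        raise ValueError("each group needs at least 2 samples for testing")

    keep = matrix.counts.sum(axis=1) > 0
    cpm = matrix.cpm.loc[keep]
    log_cpm = np.log2(cpm + pseudocount)

    a = log_cpm[iugr_ids].values
    b = log_cpm[normal_ids].values
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trigger scipy's catastrophic-cancellation note;
        # their p-values are forced to 1 below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # degenerate rows (zero variance in both groups): the test statistic is
    # undefined; separated means are then trivially significant, equal means
    # trivially not
    nan_p = np.isnan(p)
    sep = np.abs(a.mean(axis=1) - b.mean(axis=1)) > 1e-12
    p = np.where(nan_p, np.where(sep, 0.0, 1.0), p)

    mean_normal = cpm[normal_ids].mean(axis=1)
    mean_iugr = cpm[iugr_ids].mean(axis=1)
    log2fc = np.log2(mean_iugr + pseudocount) - np.log2(mean_normal + pseudocount)

    fdr = benjamini_hochberg(p)
    status = np.where(
        (fdr < fdr_threshold) & (log2fc >= min_abs_log2fc),
        "up",
        np.where((fdr < fdr_threshold) & (log2fc <= -min_abs_log2fc), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "tsrna_id": cpm.index,
            "mean_cpm_normal": mean_normal.values,
            "mean_cpm_iugr": mean_iugr.values,
            "log2fc": log2fc.values,
            "p_value": p,
            "fdr": fdr,
            "status": status,
        }
    ).reset_index(drop=True)
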