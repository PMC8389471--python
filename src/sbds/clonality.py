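"""Read-depth clonality thresholds and replicate concordance.

In an SB screen the read depth supporting an insertion site proxies the
fraction of cells carrying it. A cohort-derived percentile cutoff on the
pooled depth distribution separates *clonal* insertions (depth strictly
above the cutoff; candidates for early, positively selected events) from
*subclonal* ones. The published analyses use a 300-read cutoff (top 5% of
normal-skin reads) for bulk tumors and 200 reads (top 30%) for the lower
depth multi-region libraries; both are derivable here from data and are
shipped only as defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClonalityThreshold",
    "ConcordanceReport",
    "derive_depth_threshold",
    "label_clonality",
    "replicate_concordance",
]

#: default cutoffs for SBCapSeq bulk-tumor and multi-region analyses
DEFAULT_BULK_CUTOFF = 300
DEFAULT_REGIONAL_CUTOFF = 200


@dataclass(frozen=True)
class ClonalityThreshold:
    """A whole-number read-depth cutoff bounding the top (1-percentile)."""

    cutoff_reads: int
    percentile: float
    source_cohort: str = ""


def derive_depth_threshold(
    table: pd.DataFrame, percentile: float, source_cohort: str = ""
) -> ClonalityThreshold:
    """Smallest whole number r with P(read_count > r) <= 1 - percentile.

    The proportion is taken over all insertion records in the (pooled)
    reference cohort. For depths 1..100 and percentile 0.95 the cutoff
    is 95: exactly 5 of 100 records lie strictly above it.
    """
    if table.empty:
        raise ValueError("cannot derive a depth threshold from an empty table")
    if not 0.0 < percentile < 1.0:
        raise ValueError(f"percentile must be in (0, 1), got {percentile}")
    depths = np.asarray(table["read_count"], dtype=np.int64)
    n = depths.size
    alpha = 1.0 - percentile
    # candidate cutoffs: the observed depths (the exceedance count only
    # changes there) plus 0 for the degenerate all-below case
    candidates = np.unique(np.concatenate(([0], depths)))
    exceed = n - np.searchsorted(np.sort(depths), candidates, side="right")
    ok = exceed <= alpha * n + 1e-9
    cutoff = int(candidates[ok][0])
    return ClonalityThreshold(cutoff, percentile, source_cohort)


def label_clonality(
    table: pd.DataFrame, threshold: ClonalityThreshold | int
) -> pd.DataFrame:
    """Label each record clonal iff read_count > cutoff (strict).

    A record at exactly the cutoff is subclonal, matching the ">299
    reads" convention for the 300-read cutoff. Returns a copy with a
    boolean ``clonal`` column.
    """
    cutoff = (
        threshold.cutoff_reads
        if isinstance(threshold, ClonalityThreshold)
        else int(threshold)
    )
    out = table.copy()
    out["clonal"] = out["read_count"] > cutoff
    return out


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between two libraries of the same specimen."""

    pearson_r: float
    spearman_rho: float
    n_shared_sites: int
    jaccard: float
    defined: bool  # correlations defined (>=2 shared sites, non-constant depths)


def replicate_concordance(a: pd.DataFrame, b: pd.DataFrame) -> ConcordanceReport:
    """Correlate log10(read_count + 1) over sites shared by two libraries.

    Sites are keyed by (chrom, pos). Jaccard is the shared fraction of
    the site union. Correlations are reported as NaN (``defined=False``)
    when fewer than two sites are shared or either depth vector is
    constant.
    """
    ka = a.groupby(["chrom", "pos"], sort=False)["read_count"].sum()
    kb = b.groupby(["chrom", "pos"], sort=False)["read_count"].sum()
    shared = ka.index.intersection(kb.index)
    union = ka.index.union(kb.index)
    jaccard = len(shared) / len(union) if len(union) else 0.0
    if len(shared) < 2:
        return ConcordanceReport(np.nan, np.nan, len(shared), jaccard, False)
    xa = np.log10(ka.loc[shared].to_numpy(dtype=float) + 1.0)
    xb = np.log10(kb.loc[shared].to_numpy(dtype=float) + 1.0)
    if np.ptp(xa) == 0.0 or np.ptp(xb) == 0.0:
        return ConcordanceReport(np.nan, np.nan, len(shared), jaccard, False)
    r = float(stats.pearsonr(xa, xb).statistic)
    rho = float(stats.spearmanr(xa, xb).statistic)
    return ConcordanceReport(r, rho, len(shared), jaccard, True)
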