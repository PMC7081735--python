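"""Thickness aggregation: B-scan statistics, discard rule, weighted volume mean.

Per-A-scan thicknesses are summarized per B-scan (mean, sample SD, and the
percentage error, i.e. the within-scan coefficient of variation in percent).
B-scans whose percentage error exceeds a threshold (default 25%) are
discarded; the volume thickness is the average of the retained B-scan means
weighted by the inverse of their SDs, and its uncertainty is the standard
error among the retained B-scan means.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .segmentation import BoundaryTrace

__all__ = [
    "BScanThickness",
    "VolumeThickness",
    "GroupComparison",
    "AnalysisError",
    "summarize_bscan",
    "filter_bscans",
    "volume_mean",
    "group_compare",
    "quantify_traces",
]


class AnalysisError(ValueError):
    """Statistical analysis cannot be carried out on the given input."""


@dataclass
class BScanThickness:
    """Summary of the valid A-scan thicknesses within one B-scan."""

    index: int
    mean: Optional[float]       # um
    sd: Optional[float]         # um, sample SD (ddof=1)
    n_valid: int
    n_total: int
    pct_error: Optional[float]  # 100 * sd / mean
    summarizable: bool
    retained: Optional[bool] = None


@dataclass
class VolumeThickness:
    """Inverse-SD weighted thickness of one volume scan."""

    weighted_mean: Optional[float]  # um
    se: Optional[float]             # um, SE among retained B-scan means
    n_retained: int
    retained_indices: List[int]
    reason: Optional[str] = None    # set when no estimate could be formed


@dataclass
class GroupComparison:
    """One-way ANOVA with Bonferroni-adjusted pairwise comparisons."""

    f: float
    p: float
    df_between: int
    df_within: int
    alpha: float
    pairwise: List[dict]  # group_a, group_b, p_raw, p_adj, significant


def summarize_bscan(
    trace: BoundaryTrace, index: int, min_valid_fraction: float = 0.5
) -> BScanThickness:
    """Mean and sample SD of thickness over the valid A-scans of one B-scan.

    A B-scan with no valid A-scans, or with fewer than ``min_valid_fraction``
    of its A-scans valid, is marked unsummarizable and is treated as
    discarded downstream.
    """
    t = trace.thickness_um[trace.valid]
    n_valid, n_total = t.size, trace.n_ascans
    if n_valid == 0 or n_valid / n_total < min_valid_fraction:
        return BScanThickness(index, None, None, n_valid, n_total, None, False)
    mean = float(np.mean(t))
    sd = float(np.std(t, ddof=1)) if n_valid > 1 else 0.0
    pct_error = 100.0 * sd / mean
    return BScanThickness(index, mean, sd, n_valid, n_total, pct_error, True)


def filter_bscans(
    summaries: Sequence[BScanThickness], threshold: float = 25.0
) -> List[BScanThickness]:
    """Retain summarizable B-scans whose percentage error is <= threshold.

    Discarding is strict ("bigger than" the threshold); a scan exactly at
    the threshold is retained.  ``retained`` flags are set in place and the
    retained subset is returned in order.
    """
    retained = []
    for s in summaries:
        s.retained = bool(s.summarizable and s.pct_error <= threshold)
        if s.retained:
            retained.append(s)
    return retained


def volume_mean(
    retained: Sequence[BScanThickness],
    zero_sd_weight_factor: float = 10.0,
    weight_by_sem: bool = False,
) -> VolumeThickness:
    """Inverse-SD weighted mean of retained B-scan means, with its SE.

    weighted_mean = sum(mean_i / sd_i) / sum(1 / sd_i).  The SE is the
    unweighted sample SD of the retained means divided by sqrt(n), reported
    as None when fewer than two B-scans are retained.  A retained scan with
    sd = 0 would have infinite weight; it instead receives the largest
    finite weight among retained scans multiplied by ``zero_sd_weight_factor``
    (equal weights if every sd is 0).  With ``weight_by_sem`` the weights use
    the standard error of the B-scan mean (sd/sqrt(n_valid)) instead of sd.
    """
    retained = [s for s in retained if s.summarizable]
    if not retained:
        return VolumeThickness(None, None, 0, [], reason="no B-scans retained")

    means = np.array([s.mean for s in retained], dtype=float)
    scales = np.array(
        [s.sd / np.sqrt(s.n_valid) if weight_by_sem else s.sd for s in retained],
        dtype=float,
    )
    weights = np.zeros_like(scales)
    positive = scales > 0
    weights[positive] = 1.0 / scales[positive]
    if (~positive).any():
        if positive.any():
            weights[~positive] = weights[positive].max() * zero_sd_weight_factor
        else:
            weights[:] = 1.0

    wmean = float(np.sum(weights * means) / np.sum(weights))
    if len(retained) >= 2:
        se = float(np.std(means, ddof=1) / np.sqrt(len(retained)))
    else:
        se = None
    return VolumeThickness(
        weighted_mean=wmean, se=se, n_retained=len(retained),
        retained_indices=[s.index for s in retained],
    )


def quantify_traces(traces, params) -> tuple:
    """Summaries + discard rule + weighted mean for one volume's traces.

    Returns ``(summaries, volume_thickness)``.
    """
    summaries = [
        summarize_bscan(tr, i, params.min_valid_fraction) for i, tr in enumerate(traces)
    ]
    retained = filter_bscans(summaries, params.pct_error_threshold)
    return summaries, volume_mean(retained)


def group_compare(groups: Dict[str, Sequence[float]], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA across named groups with Bonferroni post hoc tests.

    Pairwise two-sample t-tests (pooled variance) are adjusted by
    multiplying each raw p by the number of pairs, capped at 1.
    """
    if len(groups) < 2:
        raise AnalysisError("need at least two groups")
    arrays = {name: np.asarray(vals, dtype=float) for name, vals in groups.items()}
    for name, vals in arrays.items():
        if vals.size < 2:
            raise AnalysisError(f"group {name!r} has fewer than two values")

    f, p = stats.f_oneway(*arrays.values())
    n_total = sum(v.size for v in arrays.values())
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)

    pairs = list(combinations(arrays.keys(), 2))
    pairwise = []
    for a, b in pairs:
        t_res = stats.ttest_ind(arrays[a], arrays[b], equal_var=True)
        p_raw = float(t_res.pvalue)
        p_adj = min(1.0, p_raw * len(pairs))
        pairwise.append(
            {
                "group_a": a,
                "group_b": b,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    # degenerate zero-variance case: scipy returns nan; F=0, p=1 by convention
    if np.isnan(f):
        f, p = 0.0, 1.0
    return GroupComparison(
        f=float(f), p=float(p), df_between=df_between, df_within=df_within,
        alpha=alpha, pairwise=pairwise,
    )
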