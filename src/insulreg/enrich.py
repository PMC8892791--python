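"""Interval-feature enrichment at border/facilitator bins.

Fold-change of the fraction of foreground bins overlapping at least one
feature (ChIP-seq peak, motif occurrence) versus the same fraction over a
background bin set, with a binomial p-value.  The unit is the bin
(overlap yes/no), so the statistic is invariant to feature fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .hic_io import BinTable, IntervalSet
from .sim_model import InsulationFit

__all__ = ["EnrichmentResult", "compute_enrichment", "stratified_enrichment"]


@dataclass
class EnrichmentResult:
    feature: str
    fold_change: float
    p_value: float
    fg_overlap: int
    n_fg: int
    bg_overlap: int
    n_bg: int
    defined: bool = True

    @property
    def fg_fraction(self) -> float:
        return self.fg_overlap / self.n_fg

    @property
    def bg_fraction(self) -> float:
        return self.bg_overlap / self.n_bg if self.n_bg else float("nan")


def _bins_overlapping(bins: BinTable, features: IntervalSet) -> np.ndarray:
    """Boolean per-bin: any bp intersection with a feature interval."""
    hit = np.zeros(bins.p, dtype=bool)
    feats = features.for_chrom(bins.chrom)
    if len(feats) == 0:
        return hit
    starts = feats["start"].to_numpy()
    ends = feats["end"].to_numpy()
    # merge intervals so overlap tests reduce to a sorted scan
    order = np.argsort(starts)
    merged = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    ms = np.array([x[0] for x in merged])
    me = np.array([x[1] for x in merged])
    bs, be = bins.starts, bins.ends
    # merged intervals are disjoint and sorted: the first interval ending
    # after the bin start overlaps iff it also starts before the bin end
    k = np.searchsorted(me, bs, side="right")
    valid = k < len(ms)
    hit[valid] = ms[k[valid]] < be[valid]
    return hit


def compute_enrichment(
    foreground_bins,
    bins: BinTable,
    features: IntervalSet,
    background_bins=None,
    feature_name: str = "feature",
) -> EnrichmentResult:
    """Fold-change enrichment of feature overlap at foreground bins.

    fold_change = (foreground overlap fraction) / (background overlap
    fraction); the p-value is a binomial test of the foreground overlap
    count against the background rate.  Background defaults to all bins.
    """
    fg = np.asarray(sorted(set(np.atleast_1d(foreground_bins).tolist())), dtype=int)
    if len(fg) == 0:
        raise ValueError("empty foreground bin set")
    if fg.min() < 0 or fg.max() >= bins.p:
        raise ValueError("foreground bin outside the bin table")
    bg = (
        np.arange(bins.p)
        if background_bins is None
        else np.asarray(sorted(set(np.atleast_1d(background_bins).tolist())), dtype=int)
    )
    hit = _bins_overlapping(bins, features)
    fg_ov = int(hit[fg].sum())
    bg_ov = int(hit[bg].sum())
    if bg_ov == 0:
        return EnrichmentResult(
            feature=feature_name,
            fold_change=float("nan"),
            p_value=float("nan"),
            fg_overlap=fg_ov,
            n_fg=len(fg),
            bg_overlap=0,
            n_bg=len(bg),
            defined=False,
        )
    bg_rate = bg_ov / len(bg)
    fold = (fg_ov / len(fg)) / bg_rate
    pval = binomtest(fg_ov, len(fg), p=bg_rate).pvalue
    return EnrichmentResult(
        feature=feature_name,
        fold_change=float(fold),
        p_value=float(pval),
        fg_overlap=fg_ov,
        n_fg=len(fg),
        bg_overlap=bg_ov,
        n_bg=len(bg),
    )


def stratified_enrichment(
    fit: InsulationFit,
    thresholds,
    features: IntervalSet,
    bins: BinTable | None = None,
    background_bins=None,
    feature_name: str = "feature",
) -> pd.DataFrame:
    """Enrichment per border-strength stratum (beta < threshold).

    ``thresholds`` are negative cutoffs sorted by descending magnitude;
    each stratum is the set of bins with beta below that cutoff.  Empty
    strata are skipped with a note column.
    """
    if bins is None:
        bins = fit.bins
    if bins is None:
        raise ValueError("a BinTable is required")
    thresholds = list(thresholds)
    if any(t >= 0 for t in thresholds):
        raise ValueError("thresholds must be negative (border strata)")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted by descending magnitude")
    rows = []
    for t in thresholds:
        fg = np.flatnonzero(fit.beta < t)
        if len(fg) == 0:
            rows.append(
                {"feature": feature_name, "threshold": t, "note": "empty stratum"}
            )
            continue
        res = compute_enrichment(
            fg, bins, features, background_bins=background_bins, feature_name=feature_name
        )
        rows.append(
            {
                "feature": feature_name,
                "threshold": t,
                "fold_change": res.fold_change,
                "p": res.p_value,
                "n_fg": res.n_fg,
                "n_bg": res.n_bg,
                "note": "",
            }
        )
    return pd.DataFrame(rows)
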