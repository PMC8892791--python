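"""Differential Insulation Model (DIM).

Tests, per retained bin, whether insulation strength differs between two
Hi-C experiments.  Residuals from each experiment's own distance trend are
stacked and regressed (ordinary least squares, no penalty) on the retained
bins' in-betweenness indicators, an experiment indicator e in {0, 1}, and
bin-by-experiment interaction terms:

    E[z | S, e] = b0 + S b_S + b_e e + sum_j b_{s_j e} s_j e

A negative interaction coefficient means stronger insulation in the second
experiment (a gained border), a positive one weaker insulation (lost).
Interaction p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .design import build_insulation_design, build_pair_table
from .hic_io import BinTable, ContactMatrix
from .sim_model import InsulationFit, compute_residuals, fit_distance_trend, run_sim

__all__ = [
    "DifferentialFit",
    "select_union_bins",
    "fit_dim",
    "call_differential_borders",
    "run_dim",
]


@dataclass
class DifferentialFit:
    """Per-retained-bin interaction estimates and adjusted p-values."""

    bins_s: np.ndarray  # retained bin ordinals S
    beta_main: np.ndarray  # main insulation effect per bin in S
    beta_inter: np.ndarray  # bin-by-experiment interaction per bin in S
    se_inter: np.ndarray
    p_inter: np.ndarray
    p_adj: np.ndarray
    beta_e: float
    intercept: float
    dropped: np.ndarray  # bins in S whose interaction column was dropped
    bin_table: BinTable | None = None

    @property
    def q(self) -> int:
        return len(self.bins_s)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin": self.bins_s + 1,
                "beta_main": self.beta_main,
                "beta_interaction": self.beta_inter,
                "se": self.se_inter,
                "p": self.p_inter,
                "p_adj": self.p_adj,
            }
        )
        if self.bin_table is not None:
            df.insert(0, "chrom", self.bin_table.chrom)
            df.insert(1, "start", self.bin_table.starts[self.bins_s])
            df.insert(2, "end", self.bin_table.ends[self.bins_s])
        return df


def select_union_bins(fit1: InsulationFit, fit2: InsulationFit) -> np.ndarray:
    """Union of nonzero-beta bins from two SIM fits, deduplicated.

    Among each run of consecutive (adjacent-ordinal) bins exactly one
    representative is kept: the bin with the larger maximum |beta| across
    the two fits, ties broken toward the lower index.
    """
    if fit1.p != fit2.p:
        raise ValueError("fits must share the same bin table")
    union = np.union1d(fit1.selected, fit2.selected)
    if len(union) == 0:
        raise ValueError("no candidate bins; run SIM with lower lambda")
    strength = np.maximum(np.abs(fit1.beta), np.abs(fit2.beta))
    kept = []
    run = [union[0]]
    for b in union[1:]:
        if b == run[-1] + 1:
            run.append(b)
        else:
            kept.append(max(run, key=lambda x: (strength[x], -x)))
            run = [b]
    kept.append(max(run, key=lambda x: (strength[x], -x)))
    return np.array(sorted(kept), dtype=int)


def fit_dim(
    z_combined: np.ndarray,
    X_s: sp.spmatrix,
    e: np.ndarray,
    bins_s: np.ndarray,
    bin_table: BinTable | None = None,
) -> DifferentialFit:
    """OLS of stacked residuals on [S, e, S x e] with classical SEs.

    ``X_s`` holds the in-betweenness indicators of the retained bins for
    every stacked pair row; ``e`` is the 0/1 experiment indicator per row.
    Interaction columns that carry no information (all zero, or identical
    to their main-effect column because the bin spans pairs in only one
    experiment) are dropped with a warning.  With a constant ``e`` all
    interactions are dropped and reported as exact zeros.
    """
    z = np.asarray(z_combined, dtype=float)
    e = np.asarray(e, dtype=float)
    Xs = np.asarray(X_s.todense() if sp.issparse(X_s) else X_s, dtype=float)
    q = Xs.shape[1]
    if q != len(bins_s):
        raise ValueError("X_s columns must match bins_s")
    inter = Xs * e[:, None]
    keep = []
    for jcol in range(q):
        col = inter[:, jcol]
        degenerate = (
            not col.any()
            or np.array_equal(col, Xs[:, jcol])
            or e.min() == e.max()
        )
        if degenerate:
            warnings.warn(
                f"interaction for bin {bins_s[jcol]} is not estimable; dropped",
                RuntimeWarning,
            )
        else:
            keep.append(jcol)
    keep = np.array(keep, dtype=int)

    design = np.column_stack([np.ones(len(z)), Xs, e, inter[:, keep]])
    res = sm.OLS(z, design).fit()
    params = res.params
    beta_inter = np.zeros(q)
    se_inter = np.zeros(q)
    p_inter = np.ones(q)
    if len(keep):
        beta_inter[keep] = params[q + 2 :]
        se_inter[keep] = res.bse[q + 2 :]
        p_inter[keep] = res.pvalues[q + 2 :]
    p_adj = np.ones(q)
    if len(keep):
        p_adj[keep] = multipletests(p_inter[keep], method="fdr_bh")[1]
    return DifferentialFit(
        bins_s=np.asarray(bins_s, dtype=int),
        beta_main=params[1 : q + 1],
        beta_inter=beta_inter,
        se_inter=se_inter,
        p_inter=p_inter,
        p_adj=p_adj,
        beta_e=float(params[q + 1]),
        intercept=float(params[0]),
        dropped=np.asarray(bins_s, dtype=int)[
            np.setdiff1d(np.arange(q), keep, assume_unique=True)
        ],
        bin_table=bin_table,
    )


def call_differential_borders(dfit: DifferentialFit, alpha: float = 0.05) -> pd.DataFrame:
    """Bins with adjusted p < alpha, labelled by interaction sign.

    Negative interaction -> "gained-in-2" (stronger insulation in the
    second experiment); positive -> "lost-in-2".
    """
    df = dfit.to_frame()
    call = np.where(
        (dfit.p_adj < alpha) & (dfit.beta_inter < 0),
        "gained-in-2",
        np.where((dfit.p_adj < alpha) & (dfit.beta_inter > 0), "lost-in-2", "ns"),
    )
    df["call"] = call
    return df


def run_dim(
    m1: ContactMatrix,
    m2: ContactMatrix,
    max_gap: int = 10,
    alpha: float = 0.05,
    seed: int = 1789,
    fit1: InsulationFit | None = None,
    fit2: InsulationFit | None = None,
    **sim_kwargs,
) -> tuple[DifferentialFit, pd.DataFrame]:
    """Full DIM pipeline: per-condition SIM, union/dedup, stacked OLS.

    Each experiment gets its own distance trend so depth and decay
    differences do not masquerade as differential insulation; the
    experiment main effect absorbs any remaining global offset.
    """
    if m1.p != m2.p or m1.resolution != m2.resolution:
        raise ValueError("matrices must share the same bin table")
    if fit1 is None:
        fit1 = run_sim(m1, max_gap=max_gap, seed=seed, **sim_kwargs)
    if fit2 is None:
        fit2 = run_sim(m2, max_gap=max_gap, seed=seed, **sim_kwargs)
    bins_s = select_union_bins(fit1, fit2)

    rows_z, rows_X, rows_e = [], [], []
    for label, m in ((0, m1), (1, m2)):
        pairs = build_pair_table(m, max_gap=max_gap)
        trend = fit_distance_trend(pairs)
        rows_z.append(compute_residuals(pairs, trend))
        rows_X.append(build_insulation_design(pairs, candidate_bins=bins_s).X)
        rows_e.append(np.full(pairs.n, label, dtype=float))
    z = np.concatenate(rows_z)
    Xs = sp.vstack(rows_X)
    e = np.concatenate(rows_e)
    dfit = fit_dim(z, Xs, e, bins_s, bin_table=m1.bins)
    return dfit, call_differential_borders(dfit, alpha=alpha)
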