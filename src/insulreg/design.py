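"""Pair table and insulation-indicator design matrix construction.

The pair table lists every unmasked upper-triangle bin pair (i, j) with
1 <= j - i <= max_gap, its contact count y and its log genomic distance
d = log((j - i) * resolution).  The insulation design X is the binary
matrix with X[(i, j), k] = 1 iff bin k lies strictly between i and j; a
bin's regression coefficient on this column is its insulation (negative)
or facilitation (positive) effect on log contact frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .hic_io import ContactMatrix

__all__ = ["PairTable", "InsulationDesign", "build_pair_table", "build_insulation_design"]


@dataclass
class PairTable:
    """Long-format upper-triangle contact records within max_gap."""

    i: np.ndarray  # bin ordinal, i < j
    j: np.ndarray
    y: np.ndarray  # contact count (raw or normalized)
    resolution: int
    p: int
    max_gap: int
    normalized: bool = False

    @property
    def gap(self) -> np.ndarray:
        return self.j - self.i

    @property
    def d(self) -> np.ndarray:
        """Log genomic distance in bp."""
        return np.log(self.gap.astype(float) * self.resolution)

    @property
    def n(self) -> int:
        return len(self.i)


@dataclass
class InsulationDesign:
    """Sparse binary in-betweenness design over candidate bins."""

    X: sp.csr_matrix  # n_pairs x n_candidates
    candidate_bins: np.ndarray  # column k of X is bin candidate_bins[k]
    p: int

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_bins)

    def restrict(self, bins) -> "InsulationDesign":
        """Design restricted to a subset of the candidate bins."""
        bins = np.asarray(sorted(set(np.atleast_1d(bins).tolist())), dtype=int)
        pos = {b: k for k, b in enumerate(self.candidate_bins)}
        cols = np.array([pos[b] for b in bins], dtype=int)
        return InsulationDesign(X=self.X[:, cols].tocsr(), candidate_bins=bins, p=self.p)


def build_pair_table(m: ContactMatrix, max_gap: int = 10) -> PairTable:
    """Extract unmasked upper-triangle pairs with 1 <= j - i <= max_gap.

    The diagonal is excluded; gap-1 pairs are retained (no in-between bin,
    but they anchor the distance trend at short range).  Pairs touching a
    masked (zero-coverage) bin are dropped.
    """
    if max_gap < 2:
        raise ValueError("max_gap must be >= 2 (no in-between bins otherwise)")
    p = m.p
    mask = m.mask
    ii, jj = [], []
    for g in range(1, min(max_gap, p - 1) + 1):
        i = np.arange(p - g)
        keep = ~(mask[i] | mask[i + g])
        ii.append(i[keep])
        jj.append(i[keep] + g)
    i = np.concatenate(ii) if ii else np.array([], dtype=int)
    j = np.concatenate(jj) if jj else np.array([], dtype=int)
    order = np.lexsort((j, i))
    i, j = i[order], j[order]
    return PairTable(
        i=i,
        j=j,
        y=m.counts[i, j].copy(),
        resolution=m.resolution,
        p=p,
        max_gap=max_gap,
        normalized=m.normalized,
    )


def build_insulation_design(
    pairs: PairTable, candidate_bins=None
) -> InsulationDesign:
    """Binary design: X[(i,j), k] = 1 iff candidate bin k is strictly between.

    Endpoint bins themselves are not counted; adjacent pairs (j = i + 1)
    get all-zero rows.
    """
    p = pairs.p
    if candidate_bins is None:
        candidate_bins = np.arange(p)
    candidate_bins = np.asarray(sorted(set(np.atleast_1d(candidate_bins).tolist())), dtype=int)
    if len(candidate_bins) and (candidate_bins.min() < 0 or candidate_bins.max() >= p):
        raise ValueError(f"candidate bin outside [0,{p})")

    # row r covers bins i+1 .. j-1; emit (row, bin) coordinates per pair
    counts_between = np.maximum(pairs.gap - 1, 0)
    rows = np.repeat(np.arange(pairs.n), counts_between)
    # strictly-between bins, concatenated in pair order
    offsets = np.concatenate([np.arange(1, g) for g in pairs.gap]) if pairs.n else np.array([], dtype=int)
    cols_bins = np.repeat(pairs.i, counts_between) + offsets

    # keep only candidate columns, remapped to 0..k-1
    col_of_bin = -np.ones(p, dtype=int)
    col_of_bin[candidate_bins] = np.arange(len(candidate_bins))
    keep = col_of_bin[cols_bins] >= 0
    X = sp.csr_matrix(
        (np.ones(keep.sum()), (rows[keep], col_of_bin[cols_bins[keep]])),
        shape=(pairs.n, len(candidate_bins)),
    )
    return InsulationDesign(X=X, candidate_bins=candidate_bins, p=p)
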