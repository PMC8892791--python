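"""Prediction Insulation Model (PIM).

A Poisson GLM of Hi-C counts on log distance plus the per-bin
in-betweenness indicators,

    log E[y | d, X] = b0 + b_d d + X b_X,

fit on wild-type data with no sparsity penalty.  To predict the map after
a chromosomal rearrangement, the distance variable and the indicators are
recomputed on the rearranged bin order (deletions shrink distances and
zero the deleted bins' indicators; inversions flip the bin order within
the interval) and pushed through the trained coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.stats import pearsonr, rankdata, spearmanr

from .design import InsulationDesign, PairTable, build_insulation_design
from .hic_io import BinTable, ContactMatrix

__all__ = [
    "PimFit",
    "Rearrangement",
    "PredictedMatrix",
    "fit_pim",
    "apply_rearrangement",
    "predict_matrix",
    "evaluate_prediction",
]


@dataclass
class PimFit:
    """Trained Poisson regression: intercept, distance slope, per-bin effects."""

    intercept: float
    beta_d: float
    beta_x: np.ndarray  # indexed like candidate_bins
    candidate_bins: np.ndarray  # original bin ordinals with estimable columns
    p: int
    scale: float = 1.0  # quasi-Poisson dispersion diagnostic

    def beta_of_bin(self) -> dict[int, float]:
        return {int(b): float(v) for b, v in zip(self.candidate_bins, self.beta_x)}


@dataclass(frozen=True)
class Rearrangement:
    """Ordered deletion/inversion operations in bin ordinals.

    Each operation is (kind, a, b) over the half-open bin interval [a, b)
    of the genome *as rearranged by the preceding operations* (left to
    right composition).
    """

    operations: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for kind, a, b in self.operations:
            if kind not in ("deletion", "inversion"):
                raise ValueError(f"unknown operation kind {kind!r}")
            if a < 0 or b <= a:
                raise ValueError("operation interval must satisfy 0 <= a < b")
            if kind == "deletion" and b - a < 1:
                raise ValueError("deletion must remove at least one bin")
            if kind == "inversion" and b - a < 2:
                raise ValueError("inversion must cover at least two bins")

    @classmethod
    def from_ops(cls, *ops) -> "Rearrangement":
        return cls(operations=tuple(tuple(o) for o in ops))

    @classmethod
    def from_bp(cls, ops_bp, resolution: int) -> "Rearrangement":
        """Convert bp intervals to bin ordinals, snapping with a warning."""
        out = []
        for kind, start, end in ops_bp:
            if start % resolution or end % resolution:
                warnings.warn(
                    f"{kind} [{start},{end}) not bin-aligned; snapping to bins",
                    RuntimeWarning,
                )
            out.append((kind, int(round(start / resolution)), int(round(end / resolution))))
        return cls.from_ops(*out)

    def bin_order(self, p: int) -> np.ndarray:
        """Surviving original bin ordinals in rearranged order."""
        order = np.arange(p)
        for kind, a, b in self.operations:
            if b > len(order):
                raise ValueError(f"operation interval [{a},{b}) out of range")
            if kind == "deletion":
                order = np.concatenate([order[:a], order[b:]])
            else:
                order = np.concatenate([order[:a], order[a:b][::-1], order[b:]])
        return order


@dataclass
class RearrangedVariables:
    """Pair universe and design on the rearranged bin table."""

    pairs: PairTable  # i, j in NEW ordinals; y unset (zeros)
    design: InsulationDesign  # columns indexed by ORIGINAL bin ordinals
    new_bins: BinTable
    provenance: np.ndarray  # old bin -> new bin ordinal, -1 if deleted
    order: np.ndarray  # new ordinal -> old bin


@dataclass
class PredictedMatrix:
    """Predicted mean contact matrix over the rearranged bin table."""

    matrix: ContactMatrix
    provenance: np.ndarray
    max_gap: int


def fit_pim(
    pairs: PairTable,
    design: InsulationDesign,
    ridge: float = 0.0,
) -> PimFit:
    """Poisson ML fit of counts on [1, d, X]; no sparsity penalty.

    Uses all candidate bins as dense insulation variables; columns that
    span no pair are dropped (their effects are unidentifiable) and
    reported with coefficient zero.  Normalized (non-integer) counts are
    rounded with a warning.  On non-convergence the fit is retried with a
    tiny L2 ridge.
    """
    y = np.asarray(pairs.y, dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(y, np.round(y)):
        warnings.warn("non-integer counts rounded for Poisson fit", RuntimeWarning)
        y = np.round(y)
    X = design.X.tocsr()
    colsum = np.asarray(X.sum(axis=0)).ravel()
    est = np.flatnonzero(colsum > 0)
    Xe = np.asarray(X[:, est].todense(), dtype=float)
    full = np.column_stack([np.ones(pairs.n), pairs.d, Xe])

    def _fit(alpha_l2):
        model = sm.GLM(y, full, family=sm.families.Poisson())
        if alpha_l2 > 0:
            pen = np.full(full.shape[1], alpha_l2)
            pen[0] = 0.0
            return model.fit_regularized(alpha=pen, L1_wt=0.0, maxiter=200)
        return model.fit(maxiter=200)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = _fit(ridge)
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite Poisson parameters")
        except Exception:
            warnings.warn(
                "Poisson fit unstable; refitting with tiny ridge", RuntimeWarning
            )
            res = _fit(max(ridge, 1e-6))

    params = np.asarray(res.params)
    mu = np.exp(full @ params)
    dof = max(pairs.n - full.shape[1], 1)
    scale = float(np.sum((y - mu) ** 2 / np.maximum(mu, 1e-12)) / dof)
    return PimFit(
        intercept=float(params[0]),
        beta_d=float(params[1]),
        beta_x=params[2:].copy(),
        candidate_bins=design.candidate_bins[est].copy(),
        p=design.p,
        scale=scale,
    )


def apply_rearrangement(
    bins: BinTable,
    rearrangement: Rearrangement,
    max_gap: int = 10,
    candidate_bins=None,
) -> RearrangedVariables:
    """Recompute (d', X') and the bin table after deletions/inversions.

    The pair universe is every pair within ``max_gap`` on the NEW bin
    table.  Distances are genomic distances on the rearranged genome (a
    deletion between a pair shrinks their distance by the deleted
    length); the in-betweenness indicators are recomputed on the new bin
    order, with columns still indexed by original bin ordinals so trained
    coefficients carry over (deleted bins' columns are removed).
    """
    p = bins.p
    order = rearrangement.bin_order(p)
    # overlap guard: deletion then touching the same original bins is fine by
    # construction (ops compose on the current genome), but duplicated bins never arise
    new_p = len(order)
    if new_p < 2:
        raise ValueError("rearrangement leaves fewer than two bins")
    provenance = np.full(p, -1, dtype=int)
    provenance[order] = np.arange(new_p)
    new_bins = BinTable(chrom=bins.chrom, resolution=bins.resolution, p=new_p)

    ii, jj = [], []
    for g in range(1, min(max_gap, new_p - 1) + 1):
        i = np.arange(new_p - g)
        ii.append(i)
        jj.append(i + g)
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    o = np.lexsort((j, i))
    i, j = i[o], j[o]
    new_pairs = PairTable(
        i=i,
        j=j,
        y=np.zeros(len(i)),
        resolution=bins.resolution,
        p=new_p,
        max_gap=max_gap,
    )

    if candidate_bins is None:
        candidate_bins = np.arange(p)
    candidate_bins = np.asarray(candidate_bins, dtype=int)
    surviving = candidate_bins[provenance[candidate_bins] >= 0]
    # design over NEW ordinals, then relabel columns to original bins
    new_design = build_insulation_design(new_pairs, candidate_bins=provenance[surviving])
    # build_insulation_design sorts columns by new ordinal; map back
    cols_orig = order[new_design.candidate_bins]
    design = InsulationDesign(X=new_design.X, candidate_bins=cols_orig, p=p)
    return RearrangedVariables(
        pairs=new_pairs,
        design=design,
        new_bins=new_bins,
        provenance=provenance,
        order=order,
    )


def predict_matrix(
    fit: PimFit, rearranged: RearrangedVariables
) -> PredictedMatrix:
    """Entry-wise exp(b0 + b_d d' + X' b_X) assembled symmetrically.

    Pairs beyond max_gap are left at zero (outside the model's range).
    For an empty rearrangement this reproduces the training fitted means.
    """
    beta_map = fit.beta_of_bin()
    cols = rearranged.design.candidate_bins
    beta_cols = np.array([beta_map.get(int(b), 0.0) for b in cols])
    if any(b >= fit.p for b in cols):
        raise ValueError("design columns outside the trained model's bins")
    eta = (
        fit.intercept
        + fit.beta_d * rearranged.pairs.d
        + np.asarray(rearranged.design.X @ beta_cols).ravel()
    )
    mu = np.exp(eta)
    new_p = rearranged.new_bins.p
    counts = np.zeros((new_p, new_p))
    counts[rearranged.pairs.i, rearranged.pairs.j] = mu
    counts[rearranged.pairs.j, rearranged.pairs.i] = mu
    m = ContactMatrix(bins=rearranged.new_bins, counts=counts, normalized=True)
    return PredictedMatrix(
        matrix=m, provenance=rearranged.provenance, max_gap=rearranged.pairs.max_gap
    )


# ---------------------------------------------------------------------------
# evaluation metrics


def _stratum_scc(obs_strata, pred_strata) -> tuple[float, bool]:
    """Stratum-adjusted correlation: per-gap Pearson combined with
    weights proportional to stratum size x rank standard deviations
    (HiCRep-style).  Constant strata are skipped."""
    num = 0.0
    den = 0.0
    used = 0
    for xo, xp in zip(obs_strata, pred_strata):
        # skip (near-)constant strata: correlation undefined there
        tol_o = 1e-10 * (np.abs(xo).max(initial=0.0) + 1.0)
        tol_p = 1e-10 * (np.abs(xp).max(initial=0.0) + 1.0)
        if len(xo) < 2 or np.std(xo) <= tol_o or np.std(xp) <= tol_p:
            continue
        r = pearsonr(xo, xp).statistic
        if not np.isfinite(r):
            continue
        w = len(xo) * np.std(rankdata(xo)) * np.std(rankdata(xp))
        num += w * r
        den += w
        used += 1
    if used < 3 or den == 0:
        return float("nan"), False
    return float(num / den), True


def evaluate_prediction(
    pred: PredictedMatrix | ContactMatrix,
    obs: ContactMatrix,
    max_gap: int | None = None,
) -> dict:
    """Prediction metrics over pairs within max_gap.

    Returns Pearson correlation of log counts (pseudocount 1), Spearman
    correlation of counts, and the stratum-adjusted correlation (SCC)
    computed per distance gap and combined with HiCRep-style weights.
    ``scc_defined`` is False when fewer than 3 usable strata exist.
    """
    if isinstance(pred, PredictedMatrix):
        if max_gap is None:
            max_gap = pred.max_gap
        pred_m = pred.matrix
    else:
        pred_m = pred
    if max_gap is None:
        raise ValueError("max_gap required when pred is a plain matrix")
    if pred_m.p != obs.p:
        raise ValueError("prediction and observation bin tables differ")
    p = pred_m.p
    obs_strata, pred_strata, obs_all, pred_all = [], [], [], []
    for g in range(1, min(max_gap, p - 1) + 1):
        i = np.arange(p - g)
        xo = obs.counts[i, i + g]
        xp = pred_m.counts[i, i + g]
        obs_strata.append(xo)
        pred_strata.append(xp)
        obs_all.append(xo)
        pred_all.append(xp)
    xo = np.concatenate(obs_all)
    xp = np.concatenate(pred_all)
    pearson_log = float(pearsonr(np.log(xo + 1), np.log(xp + 1)).statistic)
    spearman = float(spearmanr(xo, xp).statistic)
    scc, defined = _stratum_scc(obs_strata, pred_strata)
    return {
        "pearson_log": pearson_log,
        "spearman": spearman,
        "scc": scc,
        "scc_defined": defined,
        "n_pairs": int(len(xo)),
    }
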