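"""Read/write binned Hi-C contact matrices and genomic interval files.

All coordinates are 0-based, half-open base pairs; bin ordinals are 0-based
internally and only reported 1-based in human-readable output.  A chromosome
is represented by a :class:`BinTable` of contiguous, uniform-width bins (the
last bin may be short) plus a symmetric, non-negative count matrix.  Rows
with zero coverage are *masked*, never dropped, so bin ordinals stay aligned
with genome coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BinTable",
    "ContactMatrix",
    "IntervalSet",
    "read_contact_matrix",
    "write_contact_matrix",
    "balance_matrix",
    "read_intervals",
    "write_intervals",
]


@dataclass(frozen=True)
class BinTable:
    """Uniform genomic bins of one chromosome."""

    chrom: str
    resolution: int
    p: int
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("need at least one bin")
        if self.resolution < 1:
            raise ValueError("resolution must be positive")
        length = self.chrom_length
        if length is None:
            object.__setattr__(self, "chrom_length", self.p * self.resolution)
        elif not (self.resolution * (self.p - 1) < length <= self.resolution * self.p):
            raise ValueError("chrom_length inconsistent with p and resolution")

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.p, dtype=np.int64) * self.resolution

    @property
    def ends(self) -> np.ndarray:
        ends = self.starts + self.resolution
        ends[-1] = self.chrom_length
        return ends

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.starts, "end": self.ends}
        )


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome binned contact count matrix.

    ``mask`` flags zero-coverage rows; masked bins are excluded from model
    fitting but kept in place so ordinals map to coordinates.
    """

    bins: BinTable
    counts: np.ndarray
    normalized: bool = False
    balanced: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        p = self.bins.p
        if self.counts.shape != (p, p):
            raise ValueError(f"counts must be {p}x{p}, got {self.counts.shape}")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T, rtol=1e-6, atol=1e-8):
            raise ValueError("counts must be symmetric (rtol 1e-6)")

    @property
    def p(self) -> int:
        return self.bins.p

    @property
    def resolution(self) -> int:
        return self.bins.resolution

    @property
    def mask(self) -> np.ndarray:
        """Boolean vector, True for zero-coverage (masked) bins."""
        return self.counts.sum(axis=1) == 0

    def copy(self) -> "ContactMatrix":
        return replace(self, counts=self.counts.copy())


@dataclass
class IntervalSet:
    """Sorted genomic intervals (BED semantics: 0-based half-open)."""

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"])
    )

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if (df["start"] >= df["end"]).any():
            bad = int(np.argmax((df["start"] >= df["end"]).to_numpy()))
            raise ValueError(f"record {bad}: start >= end")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]


# ---------------------------------------------------------------------------
# contact matrix IO


def _read_dense(path, resolution, chrom) -> ContactMatrix:
    mat = np.loadtxt(path, dtype=float, ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("dense matrix is not square")
    if not np.allclose(mat, mat.T, atol=1e-6):
        raise ValueError("dense matrix asymmetric beyond tolerance 1e-6")
    mat = 0.5 * (mat + mat.T)
    bins = BinTable(chrom=chrom, resolution=resolution, p=mat.shape[0])
    return ContactMatrix(bins=bins, counts=mat)


def _read_triplet(path, resolution, chrom, p) -> ContactMatrix:
    if p is None:
        raise ValueError("triplet format requires the number of bins p")
    counts = np.zeros((p, p), dtype=float)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 'i j count', got {line!r}")
            try:
                i, j = int(parts[0]), int(parts[1])
                c = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: unparsable values") from exc
            if not (0 <= i < p and 0 <= j < p):
                raise ValueError(f"line {lineno}: bin index out of range [0,{p})")
            if c < 0:
                raise ValueError(f"line {lineno}: negative count")
            counts[i, j] = c
            counts[j, i] = c
    bins = BinTable(chrom=chrom, resolution=resolution, p=p)
    return ContactMatrix(bins=bins, counts=counts)


def _read_cooler(path, chrom) -> ContactMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        chroms = [c.decode() if isinstance(c, bytes) else c for c in f["bins/chrom"][:]]
        starts = f["bins/start"][:]
        ends = f["bins/end"][:]
        sel = np.array([c == chrom for c in chroms])
        if not sel.any():
            raise ValueError(f"chromosome {chrom!r} not in container")
        idx = np.flatnonzero(sel)
        offset, p = idx[0], len(idx)
        resolution = int(ends[idx[0]] - starts[idx[0]])
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        val = f["pixels/count"][:].astype(float)
    keep = (b1 >= offset) & (b1 < offset + p) & (b2 >= offset) & (b2 < offset + p)
    counts = np.zeros((p, p), dtype=float)
    i = (b1[keep] - offset).astype(int)
    j = (b2[keep] - offset).astype(int)
    counts[i, j] = val[keep]
    counts[j, i] = val[keep]
    bins = BinTable(chrom=chrom, resolution=resolution, p=p)
    return ContactMatrix(bins=bins, counts=counts)


def read_contact_matrix(
    path,
    format: str = "triplet",
    resolution: int = 1,
    chrom: str = "chr1",
    p: int | None = None,
) -> ContactMatrix:
    """Read a per-chromosome contact matrix.

    Parameters
    ----------
    format
        ``dense`` (whitespace-delimited square matrix), ``triplet``
        (0-based ``i j count`` lines, one triangle suffices — symmetry is
        enforced by mirroring), or ``cooler`` (single-resolution
        cooler-style HDF5 container with ``bins/`` and ``pixels/`` groups).
    """
    if format == "dense":
        return _read_dense(path, resolution, chrom)
    if format == "triplet":
        return _read_triplet(path, resolution, chrom, p)
    if format == "cooler":
        return _read_cooler(path, chrom)
    raise ValueError(f"unknown format {format!r}")


def write_contact_matrix(m: ContactMatrix, path, format: str = "triplet") -> None:
    """Write a contact matrix (upper triangle incl. diagonal for triplet)."""
    if format == "dense":
        np.savetxt(path, m.counts, fmt="%.10g")
    elif format == "triplet":
        iu, ju = np.nonzero(np.triu(m.counts))
        with open(path, "w") as fh:
            for i, j in zip(iu, ju):
                fh.write(f"{i} {j} {m.counts[i, j]:.10g}\n")
    elif format == "cooler":
        import h5py

        iu, ju = np.nonzero(np.triu(m.counts))
        with h5py.File(path, "w") as f:
            f.create_dataset(
                "bins/chrom", data=np.array([m.bins.chrom] * m.p, dtype="S32")
            )
            f.create_dataset("bins/start", data=m.bins.starts)
            f.create_dataset("bins/end", data=m.bins.ends)
            f.create_dataset("pixels/bin1_id", data=iu.astype(np.int64))
            f.create_dataset("pixels/bin2_id", data=ju.astype(np.int64))
            f.create_dataset("pixels/count", data=m.counts[iu, ju])
            f.attrs["bin-size"] = m.resolution
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# balancing


def balance_matrix(
    m: ContactMatrix,
    method: str = "ICE",
    max_iter: int = 500,
    rtol: float = 1e-6,
) -> ContactMatrix:
    """Iterative correction (ICE): equalize row sums over unmasked bins.

    Repeatedly divides rows/columns by their relative coverage until all
    unmasked row sums agree.  Total matrix mass is preserved.  On
    non-convergence the best iterate is returned with ``balanced=False``
    and a warning.
    """
    if method != "ICE":
        raise ValueError("only ICE balancing is supported")
    W = m.counts.copy()
    unmasked = ~m.mask
    total = W.sum()
    converged = False
    for _ in range(max_iter):
        s = W.sum(axis=1)
        s_rel = np.ones_like(s)
        mean_s = s[unmasked].mean()
        s_rel[unmasked] = s[unmasked] / mean_s
        if np.abs(s_rel[unmasked] - 1).max() < rtol:
            converged = True
            break
        W /= np.outer(s_rel, s_rel)
    if not converged:
        warnings.warn(
            "ICE balancing did not converge; returning best iterate", RuntimeWarning
        )
    if W.sum() > 0:
        W *= total / W.sum()
    out = replace(m, counts=W)
    out.normalized = True
    out.balanced = converged
    return out


# ---------------------------------------------------------------------------
# interval IO (BED3+)


def read_intervals(path) -> IntervalSet:
    """Read a BED3+ file into a sorted :class:`IntervalSet`."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValueError(f"record {int(np.argmax(bad.to_numpy())) + 1}: start >= end")
    return IntervalSet(df=df)


def write_intervals(ivs: IntervalSet, path) -> None:
    ivs.df.to_csv(path, sep="\t", header=False, index=False)
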