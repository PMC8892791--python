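"""Classical insulation score baseline.

For bin i, M_i is the total count over pairs (a, b) strictly spanning the
bin (a < i < b) with b - a <= max_gap, and

    IS_i = log2(M_i / mean(M)),

the mean taken over unmasked bins.  Low IS marks borders; values above
zero mark regions that aggregate more crossing contacts than average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hic_io import ContactMatrix

__all__ = ["ISProfile", "compute_insulation_score"]


@dataclass
class ISProfile:
    values: np.ndarray  # IS per bin; NaN where undefined
    spanning_counts: np.ndarray  # M_i
    window: int  # max_gap in bins
    mask: np.ndarray  # True where IS undefined (masked or M_i == 0)

    @property
    def p(self) -> int:
        return len(self.values)

    def to_bedgraph(self, bins, path) -> None:
        df = pd.DataFrame(
            {
                "chrom": bins.chrom,
                "start": bins.starts,
                "end": bins.ends,
                "value": self.values,
            }
        )
        df[~self.mask].to_csv(path, sep="\t", header=False, index=False)


def compute_insulation_score(m: ContactMatrix, max_gap: int = 10) -> ISProfile:
    """Insulation score from strictly-spanning pair sums.

    M_i sums counts over pairs (a, b) with a < i < b and b - a <= max_gap
    (endpoints excluded).  IS_i = log2(M_i / mean M), the mean taken over
    bins where M is defined (unmasked and positive — the two terminal
    bins are never spanned, so they are structurally undefined); bins
    with M_i == 0 get NaN and are flagged in ``mask``.
    """
    if max_gap < 2:
        raise ValueError("max_gap must be >= 2")
    p = m.p
    M = np.zeros(p)
    for g in range(2, min(max_gap, p - 1) + 1):
        a = np.arange(p - g)
        c = m.counts[a, a + g]
        # pair (a, a+g) spans bins a+1 .. a+g-1
        for off in range(1, g):
            np.add.at(M, a + off, c)
    unmasked = ~m.mask
    defined = unmasked & (M > 0)
    mean_m = M[defined].mean() if defined.any() else np.nan
    values = np.full(p, np.nan)
    if mean_m and np.isfinite(mean_m) and mean_m > 0:
        values[defined] = np.log2(M[defined] / mean_m)
    return ISProfile(values=values, spanning_counts=M, window=max_gap, mask=~defined)
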