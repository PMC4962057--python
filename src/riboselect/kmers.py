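"""k-mer counting, KPM normalization, KPM_relative enrichment and the 2D grid.

The enrichment statistic is the one used throughout the analysis:

* ``KPM`` (k-mer counts per million): per-sample k-mer count divided by the
  sample's total k-mer count, times 10^6; hence sum(KPM) == 10^6.
* ``KPM_relative = log10(KPM_sample + 1) - log10(KPM_control + 1)``, the
  background-corrected log-scale enrichment against the unselected control
  library.  Missing k-mers enter with KPM 0, consistent with the +1 offset.

For visualization every k-mer maps to a unique cell of a 2^k x 2^k matrix in
chaos-game style: base i (5'->3', most significant first) contributes one bit
to the row and one to the column, with A -> (0,0), C -> (0,1), G -> (1,0),
U -> (1,1) as (row bit, col bit).  Any bijection would preserve the analyses;
this one keeps lexicographic locality and makes the base code equal to
``2*row_bit + col_bit`` (A=0, C=1, G=2, U=3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .designs import ReadSet, encode_sequences
from .thermo import BASE_INDEX, RNA_BASES

__all__ = [
    "KmerTable",
    "KmerGrid",
    "count_kmers",
    "kpm_normalize",
    "kpm_relative",
    "grid_coord",
    "kmer_grid",
    "render_grid",
    "grid_to_rgba",
    "all_kmers",
    "kmer_to_code",
    "code_to_kmer",
    "rolling_codes",
]


def kmer_to_code(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = code * 4 + BASE_INDEX[b]
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(RNA_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in code (lexicographic) order."""
    return ["".join(p) for p in product(RNA_BASES, repeat=k)]


def rolling_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of all k-windows of each row of a (n, L) code matrix."""
    n, L = mat.shape
    if L < k:
        return np.zeros((n, 0), dtype=np.int64)
    codes = np.zeros((n, L - k + 1), dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + mat[:, j : L - k + 1 + j]
    return codes


@dataclass
class KmerTable:
    """Dense per-k-mer counts (and, after normalization, KPM) for one sample.

    ``counts[code]`` is the multiplicity-weighted number of occurrences of the
    k-mer with that base-4 code; "keys" are the k-mers with count > 0.
    """

    k: int
    counts: np.ndarray
    kpm: Optional[np.ndarray] = field(default=None)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def n_keys(self) -> int:
        return int((self.counts > 0).sum())

    def keys(self) -> list[str]:
        return [code_to_kmer(c, self.k) for c in np.flatnonzero(self.counts)]

    def count_of(self, kmer: str) -> float:
        return float(self.counts[kmer_to_code(kmer)])

    def kpm_of(self, kmer: str) -> float:
        if self.kpm is None:
            raise ValueError("table is not KPM-normalized; call kpm_normalize first")
        return float(self.kpm[kmer_to_code(kmer)])

    def to_frame(self, kpm_relative: Optional[np.ndarray] = None) -> pd.DataFrame:
        df = pd.DataFrame({"kmer": all_kmers(self.k), "count": self.counts})
        if self.kpm is not None:
            df["kpm"] = self.kpm
        if kpm_relative is not None:
            df["kpm_relative"] = np.asarray(kpm_relative)
        return df


def count_kmers(readset: ReadSet, k: int = 6) -> KmerTable:
    """Count all overlapping k-windows of every read, multiplicity-weighted.

    Sequences shorter than k contribute no windows.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    counts = np.zeros(4**k, dtype=np.float64)
    if readset.counts:
        _, mat, mult = readset.to_arrays()
        codes = rolling_codes(mat, k)
        if codes.shape[1]:
            w = np.repeat(mult, codes.shape[1])
            counts = np.bincount(codes.ravel(), weights=w, minlength=4**k)
    return KmerTable(k=k, counts=counts)


def kpm_normalize(table: KmerTable) -> KmerTable:
    """KPM_i = 10^6 * count_i / total count."""
    total = table.total
    if total <= 0:
        raise ValueError("cannot KPM-normalize an empty k-mer table")
    return KmerTable(k=table.k, counts=table.counts, kpm=1e6 * table.counts / total)


def _kpm_vector(table: KmerTable) -> np.ndarray:
    if table.kpm is None:
        table = kpm_normalize(table)
    return table.kpm


def kpm_relative(sample: KmerTable, control: KmerTable) -> pd.Series:
    """log10(KPM_sample + 1) - log10(KPM_control + 1), per k-mer.

    Returns a Series indexed by k-mer in code order; absent k-mers read as
    KPM 0 on either side.
    """
    if sample.k != control.k:
        raise ValueError("sample and control use different k")
    values = np.log10(_kpm_vector(sample) + 1.0) - np.log10(_kpm_vector(control) + 1.0)
    return pd.Series(values, index=all_kmers(sample.k), name="kpm_relative")


# ---------------------------------------------------------------------------
# 2^k x 2^k grid projection

def grid_coord(kmer: str) -> tuple[int, int]:
    """Unique (row, col) of a k-mer in the 2^k x 2^k matrix.

    Base i (most significant first) contributes bit i of the row and of the
    column: A=(0,0), C=(0,1), G=(1,0), U=(1,1).
    """
    row = col = 0
    for b in kmer:
        code = BASE_INDEX.get(b)
        if code is None:
            raise ValueError(f"invalid RNA base {b!r} in k-mer")
        row = (row << 1) | (code >> 1)
        col = (col << 1) | (code & 1)
    return row, col


@dataclass
class KmerGrid:
    """2^k x 2^k matrix of per-k-mer values (KPM_relative by default)."""

    k: int
    values: np.ndarray

    @property
    def side(self) -> int:
        return 2**self.k

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values)

    def __neg__(self) -> "KmerGrid":
        return KmerGrid(k=self.k, values=-self.values)


def kmer_grid(values: pd.Series | np.ndarray, k: int = 6) -> KmerGrid:
    """Project a code-ordered per-k-mer vector onto the 2^k x 2^k grid."""
    vec = np.asarray(values, dtype=np.float64)
    if vec.shape != (4**k,):
        raise ValueError(f"expected {4**k} values for k={k}")
    side = 2**k
    grid = np.zeros((side, side))
    codes = np.arange(4**k)
    rows = np.zeros(4**k, dtype=np.int64)
    cols = np.zeros(4**k, dtype=np.int64)
    for i in range(k):
        shift = 2 * (k - 1 - i)
        base = (codes >> shift) & 3
        rows = (rows << 1) | (base >> 1)
        cols = (cols << 1) | (base & 1)
    grid[rows, cols] = vec
    return KmerGrid(k=k, values=grid)


def _symmetric_norm(values: np.ndarray):
    from matplotlib.colors import TwoSlopeNorm

    vmax = float(np.nanmax(np.abs(values)))
    if vmax == 0:
        vmax = 1e-12
    return TwoSlopeNorm(vcenter=0.0, vmin=-vmax, vmax=vmax)


def grid_to_rgba(grid: KmerGrid) -> np.ndarray:
    """RGBA array under the diverging colormap used by :func:`render_grid`."""
    import matplotlib

    norm = _symmetric_norm(grid.values)
    return matplotlib.colormaps["RdBu_r"](norm(grid.values))


def render_grid(grid: KmerGrid, path: Optional[str | Path] = None, title: str = ""):
    """Heat map of the grid: red = enriched vs background, blue = depleted.

    The diverging colormap is centered at 0.  Returns the matplotlib Figure;
    writes PNG/SVG when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(
        grid.values, cmap="RdBu_r", norm=_symmetric_norm(grid.values), origin="upper"
    )
    ax.set_xlabel("column (C/U bits)")
    ax.set_ylabel("row (G/U bits)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="KPM_relative")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
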