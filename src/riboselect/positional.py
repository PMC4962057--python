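"""Positional base preference and second-codon preference vs the blank control.

Positional preference is the per-position base frequency of a selected library
divided by the frequency in the unselected control, so the background
normalizes to 1.  The second-codon analysis applies the same logic at codon
resolution for the N20D design (randomized window at +4..+23, so the codon
directly after AUG is the first 3 nt of the window): per-codon counts are
normalized to frequency per million reads (FPM) and divided by the control
FPM.  No pseudo-counts are used anywhere; cells with zero control frequency
are flagged undefined (NaN) rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .designs import LibraryDesign, ReadSet, get_design
from .thermo import RNA_BASES

__all__ = [
    "PositionalPreferenceMatrix",
    "positional_base_freq",
    "relative_positional_preference",
    "second_codon_table",
    "group_means",
    "repeat_group_means",
    "repeat_correlation",
    "ALL_CODONS",
]

#: The 64 RNA codons in lexicographic (code) order.
ALL_CODONS = ["".join(c) for c in product(RNA_BASES, repeat=3)]


def positional_base_freq(readset: ReadSet) -> np.ndarray:
    """Multiplicity-weighted base frequency per position, shape (4, L).

    Rows are A, C, G, U; every column sums to 1.
    """
    if readset.n_total == 0:
        raise ValueError("positional_base_freq of an empty ReadSet")
    _, mat, mult = readset.to_arrays()
    L = mat.shape[1]
    freq = np.zeros((4, L))
    for b in range(4):
        freq[b] = ((mat == b) * mult[:, None]).sum(axis=0)
    return freq / readset.n_total


@dataclass
class PositionalPreferenceMatrix:
    """4 x L control-normalized base preferences (control = 1)."""

    positions: list[int]  # signed mRNA coordinates of the randomized window
    rel: np.ndarray  # (4, L); NaN where the control frequency is 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rel, index=list(RNA_BASES), columns=self.positions)

    def mean_rel(self, base: str, coords: Sequence[int]) -> float:
        """Mean relative preference of one base over a set of coordinates."""
        row = self.rel[RNA_BASES.index(base)]
        idx = [self.positions.index(c) for c in coords]
        return float(np.nanmean(row[idx]))


def relative_positional_preference(
    sample: ReadSet, control: ReadSet, design: Optional[LibraryDesign] = None
) -> PositionalPreferenceMatrix:
    """rel(b, p) = freq_sample(b, p) / freq_control(b, p); no pseudo-counts."""
    if sample.design != control.design:
        raise ValueError("sample and control must share a library design")
    design = design or get_design(sample.design)
    fs = positional_base_freq(sample)
    fc = positional_base_freq(control)
    if fs.shape != fc.shape:
        raise ValueError("sample and control have different read lengths")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(fc > 0, fs / np.where(fc > 0, fc, 1.0), np.nan)
    if np.isnan(rel).any():
        warnings.warn("control frequency 0 at some (base, position); flagged NaN", stacklevel=2)
    return PositionalPreferenceMatrix(positions=design.window_coords, rel=rel)


# ---------------------------------------------------------------------------
# second-codon preference (N20D)

def _codon_fpm(readset: ReadSet) -> pd.Series:
    """FPM of the codon at the first 3 nt of the randomized window."""
    counts = dict.fromkeys(ALL_CODONS, 0.0)
    for seq, mult in readset.counts.items():
        counts[seq[:3]] += mult
    fpm = pd.Series(counts, name="fpm") * 1e6 / readset.n_total
    return fpm


def second_codon_table(sample: ReadSet, control: ReadSet) -> pd.DataFrame:
    """Relative frequency of all 64 codons directly after AUG.

    Requires the downstream design (randomized window starting at +4).
    Returns a 64-row frame with fpm_sample, fpm_control and
    rel = fpm_sample / fpm_control (NaN-flagged where fpm_control = 0).
    """
    for rs in (sample, control):
        design = get_design(rs.design)
        if design.window[0] != 4:
            raise ValueError(
                "second-codon analysis needs a window starting at +4 (design N20D)"
            )
        if rs.n_total == 0:
            raise ValueError("second_codon_table of an empty ReadSet")
    fpm_s = _codon_fpm(sample)
    fpm_c = _codon_fpm(control)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(fpm_c > 0, fpm_s / fpm_c.replace(0.0, 1.0), np.nan)
    if np.isnan(rel).any():
        warnings.warn("control FPM 0 for some codons; rel flagged NaN", stacklevel=2)
    return pd.DataFrame(
        {"codon": ALL_CODONS, "fpm_sample": fpm_s.values, "fpm_control": fpm_c.values, "rel": rel}
    ).set_index("codon")


def group_means(rel: pd.Series | pd.DataFrame) -> pd.Series:
    """Mean relative frequency of the 16 codons sharing a first base (ANN..UNN)."""
    if isinstance(rel, pd.DataFrame):
        rel = rel["rel"]
    first = rel.index.str[0]
    return rel.groupby(first).mean().reindex(list(RNA_BASES))


def repeat_group_means(rels: Sequence[pd.Series]) -> pd.DataFrame:
    """Group means per repeat, with between-repeat mean and SD (ddof=1).

    With exactly two repeats the SD is the two-repeat standard deviation
    (n-1 = 1 denominator), matching how error bars over duplicate selection
    experiments are reported.
    """
    per_repeat = pd.DataFrame({f"repeat_{i+1}": group_means(r) for i, r in enumerate(rels)})
    out = per_repeat.copy()
    out["mean"] = per_repeat.mean(axis=1)
    out["sd"] = per_repeat.std(axis=1, ddof=1)
    return out


def repeat_correlation(rel_a: Sequence[float], rel_b: Sequence[float]) -> float:
    """Squared Pearson correlation between two relative-preference vectors."""
    a = np.asarray(rel_a, dtype=np.float64)
    b = np.asarray(rel_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("degenerate variance; R^2 undefined", stacklevel=2)
        return float("nan")
    r, _ = stats.pearsonr(a, b)
    return float(r * r)
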