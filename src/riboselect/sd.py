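"""Shine-Dalgarno / anti-SD analyses.

Covers: motif percentage per stage, positional occurrence profiles in the TIR,
spacer arithmetic between a motif and the start codon, enumeration of the
6-mer windows of the anti-SD-containing 13-mer at the 16S rRNA 3' end
(5'-GAUCACCUCCUUA-3'), ungapped RNA/RNA duplex hybridization energies against
that target, and the energy-vs-enrichment correlation over all 4096 6-mers.

Coordinates are signed no-zero mRNA coordinates (A of AUG = +1).  Anti-SD
window numbering follows the figure convention: position n is the offset of
the window's 3'-most base from the 16S rRNA 3' terminus, n = 1 at the
terminus, giving 8 windows for the 13-mer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .designs import LibraryDesign, ReadSet, to_linear, from_linear
from .kmers import all_kmers, kmer_to_code
from .thermo import DUPLEX_INIT, TERMINAL_AU, STACKS, is_pair, RNA_BASES

__all__ = [
    "ANTI_SD_TARGET",
    "AntiSdTarget",
    "AntiSdWindow",
    "MotifPositionProfile",
    "revcomp_rna",
    "antisd_windows",
    "duplex_energy",
    "all_6mer_duplex_energies",
    "motif_fraction",
    "motif_start_profile",
    "spacer_length",
    "relative_preference",
    "energy_preference_r2",
]

#: 13-mer at the 3' end of the 16S rRNA containing the anti-SD sequence,
#: written 5'->3'; its 3' terminus is the rRNA 3' end.
ANTI_SD_TARGET = "GAUCACCUCCUUA"

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AntiSdTarget:
    sequence: str = ANTI_SD_TARGET

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(RNA_BASES)
        if bad:
            raise ValueError(f"target contains non-RNA characters: {sorted(bad)}")


@dataclass(frozen=True)
class AntiSdWindow:
    """6-nt window of the anti-SD target and its mRNA-side complement."""

    position_n: int  # offset of the window's 3'-most base from the 3' terminus
    window_seq: str
    mrna_6mer: str  # reverse complement of window_seq, 5'->3' RNA


def antisd_windows(target: AntiSdTarget | str = ANTI_SD_TARGET, k: int = 6) -> list[AntiSdWindow]:
    """Enumerate the k-mer windows of the target from the 3' terminus inward.

    The 13-mer target yields 8 windows; window n=3 (CCUCCU) pairs the SD
    consensus AGGAGG on the mRNA side.
    """
    seq = target.sequence if isinstance(target, AntiSdTarget) else target
    L = len(seq)
    if L < k:
        raise ValueError(f"target shorter than {k} nt")
    out = []
    for n in range(1, L - k + 2):
        window = seq[L - k - (n - 1) : L - (n - 1)]
        out.append(AntiSdWindow(position_n=n, window_seq=window, mrna_6mer=revcomp_rna(window)))
    return out


# ---------------------------------------------------------------------------
# duplex hybridization energy

def duplex_energy(probe: str, target: AntiSdTarget | str = ANTI_SD_TARGET) -> Optional[float]:
    """Minimum hybridization free energy of a 6-mer against the target.

    Scans all ungapped registers of the probe (5'->3') against the target;
    in each register probe base i opposes target base r+5-i (antiparallel).
    A register is admissible only if all six oppositions form Watson-Crick or
    G.U pairs; its energy is duplex initiation + the five nearest-neighbor
    stack terms + a terminal penalty for each A-U/G-U end pair.  Returns the
    minimum over admissible registers, or None when no register pairs
    throughout (the no-duplex sentinel).
    """
    seq = target.sequence if isinstance(target, AntiSdTarget) else target
    k = len(probe)
    bad = set(probe) - set(RNA_BASES)
    if bad:
        raise ValueError(f"probe contains non-RNA characters: {sorted(bad)}")
    best: Optional[float] = None
    for r in range(len(seq) - k + 1):
        pairs = []
        ok = True
        for i in range(k):
            x, y = probe[i], seq[r + k - 1 - i]
            if not is_pair(x, y):
                ok = False
                break
            pairs.append((x, y))
        if not ok:
            continue
        e = DUPLEX_INIT
        for i in range(k - 1):
            e += STACKS[(pairs[i], pairs[i + 1])]
        for end in (pairs[0], pairs[-1]):
            if end != ("C", "G") and end != ("G", "C"):
                e += TERMINAL_AU
        if best is None or e < best:
            best = e
    return best


@lru_cache(maxsize=8)
def all_6mer_duplex_energies(target: str = ANTI_SD_TARGET) -> np.ndarray:
    """Duplex energies of all 4096 6-mers in code order; NaN = no duplex."""
    energies = np.full(4096, np.nan)
    for kmer in all_kmers(6):
        e = duplex_energy(kmer, target)
        if e is not None:
            energies[kmer_to_code(kmer)] = e
    return energies


# ---------------------------------------------------------------------------
# motif statistics on read sets

def motif_fraction(readset: ReadSet, motif: str = "AGGAGG") -> float:
    """Multiplicity-weighted fraction of reads containing >= 1 motif occurrence.

    A read with several occurrences counts once.
    """
    if readset.n_total == 0:
        raise ValueError("motif_fraction of an empty ReadSet")
    hit = sum(mult for seq, mult in readset.counts.items() if motif in seq)
    return hit / readset.n_total


@dataclass
class MotifPositionProfile:
    """Occurrence counts of a motif by start coordinate in the TIR."""

    motif: str
    counts: dict[int, float] = field(default_factory=dict)
    n_total: int = 0

    @property
    def fractions(self) -> dict[int, float]:
        return {c: v / self.n_total for c, v in self.counts.items()} if self.n_total else {}

    @property
    def mode(self) -> int:
        """Start coordinate with the highest count (smallest coordinate on ties)."""
        if not self.counts:
            raise ValueError("empty profile has no mode")
        return min(self.counts, key=lambda c: (-self.counts[c], c))

    def to_frame(self) -> pd.DataFrame:
        coords = sorted(self.counts, key=to_linear)
        return pd.DataFrame(
            {
                "coordinate": coords,
                "count": [self.counts[c] for c in coords],
                "fraction": [self.fractions[c] for c in coords],
            }
        )


def motif_start_profile(
    readset: ReadSet, design: LibraryDesign, motif: str = "AGGAGG"
) -> MotifPositionProfile:
    """Every motif occurrence contributes at its start coordinate.

    Reads with two or more occurrences contribute each occurrence; overlapping
    occurrences are counted at every start.
    """
    start_lin = to_linear(design.window[0])
    profile = MotifPositionProfile(motif=motif, n_total=readset.n_total)
    for seq, mult in readset.counts.items():
        i = seq.find(motif)
        while i != -1:
            coord = from_linear(start_lin + i)
            profile.counts[coord] = profile.counts.get(coord, 0) + mult
            i = seq.find(motif, i + 1)
    return profile


def spacer_length(start: int, motif_len: int = 6) -> int:
    """Nucleotides strictly between a motif's 3' end and the A of AUG.

    ``start`` is the signed mRNA coordinate of the motif's first base; the
    motif must lie entirely upstream of AUG (start <= -motif_len).
    """
    if start >= 0:
        raise ValueError("motif start must be upstream of AUG (negative coordinate)")
    spacer = -start - motif_len
    if spacer < 0:
        raise ValueError("motif overlaps the AUG codon")
    return spacer


# ---------------------------------------------------------------------------
# enrichment vs energy

def relative_preference(kmer: str, kpm_rel: pd.Series) -> float:
    """Percentage of a k-mer's KPM_relative against the library maximum.

    Ties at the maximum are broken lexicographically for reporting.  When the
    maximum is <= 0 the percentage is undefined (NaN, with a warning); a
    negative KPM_relative against a positive maximum yields a negative
    percentage, reported as-is.
    """
    if kpm_rel.empty:
        raise ValueError("empty KPM_relative table")
    mx = float(kpm_rel.max())
    if mx <= 0:
        warnings.warn("maximum KPM_relative <= 0; relative preference undefined", stacklevel=2)
        return float("nan")
    return 100.0 * float(kpm_rel[kmer]) / mx


def argmax_kmer(kpm_rel: pd.Series) -> str:
    """K-mer with the maximal KPM_relative (lexicographically first on ties)."""
    mx = kpm_rel.max()
    return min(kpm_rel.index[kpm_rel == mx])


def energy_preference_r2(
    kpm_rel: pd.Series | np.ndarray, energies: Optional[np.ndarray] = None
) -> float:
    """Squared Pearson correlation of duplex energy with KPM_relative.

    ``energies`` defaults to the all-4096 table against the canonical anti-SD
    target; no-duplex sentinels (NaN) are mapped to 0 kcal/mol (no binding,
    no stabilization).
    """
    rel = np.asarray(kpm_rel, dtype=np.float64)
    if energies is None:
        energies = all_6mer_duplex_energies()
    e = np.nan_to_num(np.asarray(energies, dtype=np.float64), nan=0.0)
    if rel.shape != e.shape:
        raise ValueError("kpm_relative and energies must have equal length")
    if np.std(rel) == 0 or np.std(e) == 0:
        warnings.warn("degenerate variance; R^2 undefined", stacklevel=2)
        return float("nan")
    r, _ = stats.pearsonr(e, rel)
    return float(r * r)
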