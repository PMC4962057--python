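"""Minimum-free-energy RNA secondary structure and per-library summaries.

The internal engine is a deliberately small stacking-energy dynamic program
("Zuker-lite"): nested structures only, minimum hairpin loop of 3 unpaired
nt, Watson-Crick and G.U pairs, and an energy model in which only stacked
pair steps contribute (loop and multiloop terms are zero).  The minimum over
structures is therefore always <= 0, with 0 attained by the open chain.  The
simulator and every analysis module share this engine so that structure-based
selection signals are self-consistent; an adapter to ViennaRNA's RNAfold is
available for users who want the full Turner model.

Library summaries re-embed each randomized region into the full 52-nt
construct before folding, matching how the construct-level stability analysis
is defined.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .designs import LibraryDesign, ReadSet, encode_sequences
from .thermo import RNA_BASES, pairable_array, stack_array

__all__ = [
    "FoldingEngine",
    "InternalFold",
    "ViennaFold",
    "fold_mfe",
    "MfeSummary",
    "mfe_summary",
    "summarize_repeats",
    "MIN_HAIRPIN",
]

#: Minimum number of unpaired nucleotides in a hairpin loop.
MIN_HAIRPIN = 3

_PAIRABLE = pairable_array()
_STACKS = stack_array()


@njit(cache=True)
def _fold_dp(codes, stacks, pairable, min_hairpin):  # pragma: no cover - numba
    n = codes.shape[0]
    INF = 1e18
    V = np.full((n, n), INF)
    W = np.zeros((n, n))
    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            a = codes[i]
            b = codes[j]
            if pairable[a, b]:
                best = W[i + 1, j - 1]
                if span >= min_hairpin + 3 and pairable[codes[i + 1], codes[j - 1]]:
                    vin = V[i + 1, j - 1]
                    if vin < INF:
                        cand = vin + stacks[a, b, codes[i + 1], codes[j - 1]]
                        if cand < best:
                            best = cand
                V[i, j] = best
            w = W[i + 1, j]
            for k in range(i + min_hairpin + 1, j + 1):
                if V[i, k] < INF:
                    rest = W[k + 1, j] if k + 1 <= j else 0.0
                    cand = V[i, k] + rest
                    if cand < w:
                        w = cand
            W[i, j] = w
    return W[0, n - 1]


class FoldingEngine(Protocol):
    """Deterministic sequence -> MFE predictor."""

    name: str

    def mfe(self, sequence: str) -> float: ...


def _check_rna(sequence: str) -> None:
    bad = set(sequence) - set(RNA_BASES)
    if bad:
        raise ValueError(f"sequence contains non-RNA characters: {sorted(bad)}")


@lru_cache(maxsize=1_000_000)
def _internal_mfe(sequence: str) -> float:
    _check_rna(sequence)
    if len(sequence) < MIN_HAIRPIN + 2:
        return 0.0
    codes = encode_sequences([sequence])[0]
    return float(_fold_dp(codes, _STACKS, _PAIRABLE, MIN_HAIRPIN))


class InternalFold:
    """The built-in stacking-energy dynamic program."""

    name = "internal"

    def mfe(self, sequence: str) -> float:
        return _internal_mfe(sequence)


class ViennaFold:
    """Adapter to ViennaRNA's RNAfold command-line program (optional)."""

    name = "vienna"

    def __init__(self, executable: str = "RNAfold", options: Sequence[str] = ("--noPS",)):
        if shutil.which(executable) is None:
            raise FileNotFoundError(f"{executable} not found on PATH")
        self.executable = executable
        self.options = list(options)

    def mfe(self, sequence: str) -> float:
        _check_rna(sequence)
        out = subprocess.run(
            [self.executable, *self.options],
            input=sequence + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout
        m = re.search(r"\(\s*(-?\d+\.\d+)\)\s*$", out.strip().splitlines()[-1])
        if m is None:
            raise RuntimeError(f"could not parse RNAfold output: {out!r}")
        return float(m.group(1))


_DEFAULT_ENGINE = InternalFold()


def default_engine() -> FoldingEngine:
    return _DEFAULT_ENGINE


def fold_mfe(sequence: str, engine: Optional[FoldingEngine] = None) -> float:
    """Minimum folding free energy (kcal/mol) of one RNA sequence."""
    return (engine or _DEFAULT_ENGINE).mfe(sequence)


# ---------------------------------------------------------------------------
# library summaries

@dataclass
class MfeSummary:
    """Per-read MFE values (unique sequence + multiplicity), histogram, mean."""

    stage: str
    engine: str
    values: np.ndarray  # per unique sequence
    multiplicities: np.ndarray
    bin_width: float = 1.0
    hist_counts: np.ndarray = field(init=False)
    hist_edges: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lo = float(np.floor(self.values.min() / self.bin_width) * self.bin_width)
        hi = float(np.ceil(self.values.max() / self.bin_width) * self.bin_width)
        if hi <= lo:
            hi = lo + self.bin_width
        edges = np.arange(lo, hi + self.bin_width / 2, self.bin_width)
        self.hist_counts, self.hist_edges = np.histogram(
            self.values, bins=edges, weights=self.multiplicities
        )

    @property
    def n(self) -> int:
        return int(self.multiplicities.sum())

    @property
    def mean(self) -> float:
        return float(np.average(self.values, weights=self.multiplicities))

    @property
    def sd(self) -> float:
        """Multiplicity-weighted SD of the per-read values."""
        m = self.mean
        var = np.average((self.values - m) ** 2, weights=self.multiplicities)
        return float(np.sqrt(var))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mfe": self.values, "multiplicity": self.multiplicities})


def mfe_summary(
    readset: ReadSet,
    design: LibraryDesign,
    engine: Optional[FoldingEngine] = None,
    bin_width: float = 1.0,
) -> MfeSummary:
    """Fold every read re-embedded into its full-length construct."""
    if readset.n_total == 0:
        raise ValueError("mfe_summary of an empty ReadSet")
    eng = engine or _DEFAULT_ENGINE
    keys, _, mult = readset.to_arrays()
    values = np.array([eng.mfe(design.assemble(k)) for k in keys])
    return MfeSummary(
        stage=readset.stage,
        engine=eng.name,
        values=values,
        multiplicities=mult,
        bin_width=bin_width,
    )


def summarize_repeats(summaries: Sequence[MfeSummary]) -> tuple[float, float]:
    """Mean of per-repeat means and their SD (ddof=1, as for two repeats)."""
    means = np.array([s.mean for s in summaries])
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else float("nan")
    return float(means.mean()), sd
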