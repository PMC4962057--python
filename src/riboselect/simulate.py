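"""Synthetic control libraries and stage-specific ribosome-selection simulation.

The simulator gives every analysis module a ground-truth input with the
statistical structure the selection experiment assumes.  Selection is modeled
as a single round of equilibrium (Boltzmann) sampling: each library molecule
is drawn with probability proportional to exp(total score), mirroring a
30-minute equilibrium incubation rather than multi-round SELEX.

The per-molecule score combines the recruitment signals observed across
initiation stages:

* ``s_sd``   - best positionally weighted SD/anti-SD duplex strength: the
  maximum over upstream 6-mer start coordinates p of max(0, -dG) times a
  Gaussian positional weight exp(-(p - sd_center)^2 / (2 sd_width^2));
* ``s_s1``   - A/U fraction of the S1-enhancer region (-20..-13);
* ``s_struct`` - folding stability penalty max(0, -MFE) of the full 52-mer;
* ``s_c``    - C fraction of -14..-1, emulating the transient C-rich signal
  of rapid nonspecific 16S rRNA binding in the 30S stage.

``total = beta_sd*s_sd + beta_s1*s_s1 - beta_struct*s_struct + beta_c*s_c``.

Stage presets (control / 30S / 30SIC / 70SIC) fix the betas: the control has
all betas 0; the 30S stage carries the C-rich bonus and only a weak SD term;
the initiation complexes carry SD, S1 and structure terms with the SD weight
growing from 30SIC to 70SIC.  The preset magnitudes are modeling choices (the
experiments publish no quantitative affinity model), chosen once to give
clearly detectable but not saturated enrichment at desk-scale sample sizes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .designs import (
    LibraryDesign,
    ReadSet,
    decode_sequences,
    encode_sequences,
    get_design,
    write_fastq as _write_fastq_records,
)
from .folding import FoldingEngine, default_engine
from .kmers import rolling_codes
from .sd import ANTI_SD_TARGET, all_6mer_duplex_energies, duplex_energy
from .thermo import BASE_INDEX

__all__ = [
    "SelectionModel",
    "SelectionScore",
    "PRESETS",
    "make_control_library",
    "score_sequence",
    "batch_scores",
    "select_reads",
    "select_from_scores",
    "write_fastq",
    "DEFAULT_N_CONTROL",
    "DEFAULT_N_SELECTED",
]

#: Default library sizes for simulated experiments.
DEFAULT_N_CONTROL = 200_000
DEFAULT_N_SELECTED = 50_000

#: S1-enhancer region probed for A/U content.
S1_REGION = (-20, -13)
#: Region probed for the 30S-stage C-rich signal.
C_REGION = (-14, -1)


@dataclass(frozen=True)
class SelectionModel:
    """Stage-specific weights of the selection score."""

    stage: str = "control"
    beta_sd: float = 0.0  # per kcal/mol of positionally weighted duplex strength
    beta_s1: float = 0.0  # per unit A/U fraction in -20..-13
    beta_struct: float = 0.0  # per kcal/mol of folding stability
    beta_c: float = 0.0  # per unit C fraction in -14..-1 (30S stage only)
    sd_center: int = -13  # preferred SD motif start coordinate
    sd_width: float = 3.0  # Gaussian positional width, nt
    anti_sd: str = ANTI_SD_TARGET

    def __post_init__(self) -> None:
        for name in ("beta_sd", "beta_s1", "beta_struct", "beta_c"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.sd_width <= 0:
            raise ValueError("sd_width must be positive")

    @classmethod
    def preset(cls, stage: str) -> "SelectionModel":
        try:
            return PRESETS[stage]
        except KeyError:
            raise KeyError(f"unknown stage preset {stage!r}; known: {sorted(PRESETS)}") from None


PRESETS: dict[str, SelectionModel] = {
    "control": SelectionModel(stage="control"),
    "30S": SelectionModel(stage="30S", beta_sd=0.1, beta_c=2.0),
    "30SIC": SelectionModel(stage="30SIC", beta_sd=0.6, beta_s1=1.5, beta_struct=0.15),
    "70SIC": SelectionModel(stage="70SIC", beta_sd=0.9, beta_s1=1.5, beta_struct=0.15),
}


@dataclass(frozen=True)
class SelectionScore:
    s_sd: float
    s_s1: float
    s_struct: float
    s_c: float
    total: float


# ---------------------------------------------------------------------------
# control libraries

def make_control_library(
    design: LibraryDesign | str, n_reads: int, seed: int
) -> ReadSet:
    """Randomized window drawn i.i.d. uniform over {A,C,G,U}; seeded."""
    if isinstance(design, str):
        design = get_design(design)
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    L = design.random_len
    mat = rng.integers(0, 4, size=(n_reads, L), dtype=np.uint8)
    uniq, counts = np.unique(mat, axis=0, return_counts=True)
    keys = decode_sequences(uniq)
    return ReadSet(
        design=design.name,
        stage="control",
        counts=Counter(dict(zip(keys, (int(c) for c in counts)))),
    )


# ---------------------------------------------------------------------------
# scoring

def _gauss_weights(coords: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((coords - center) ** 2) / (2.0 * width**2))


def _region_columns(design: LibraryDesign, region: tuple[int, int]) -> slice:
    """Construct column slice for a coordinate interval, clipped to the construct."""
    lo = max(0, design.aug_index + region[0])  # negative coords: index = aug + coord
    hi = design.aug_index + region[1] + 1
    return slice(lo, hi)


def score_sequence(
    full_mrna: str,
    model: SelectionModel,
    folding_engine: Optional[FoldingEngine] = None,
    aug_index: Optional[int] = None,
    design: Optional[LibraryDesign] = None,
) -> SelectionScore:
    """Score one assembled construct under a selection model.

    ``aug_index`` is the 0-based index of the A of the start codon; pass it
    (or the design it can be read from) whenever the construct is
    design-assembled — a randomized window may contain spurious AUGs, so the
    first-AUG fallback is only safe for constructs known to lack them.
    """
    if aug_index is None and design is not None:
        aug_index = design.aug_index
    if aug_index is None:
        aug_index = full_mrna.find("AUG")
        if aug_index == -1:
            raise ValueError("construct contains no AUG and aug_index was not given")
    if full_mrna[aug_index : aug_index + 3] != "AUG":
        raise ValueError(f"no AUG at index {aug_index}")
    upstream = full_mrna[:aug_index]

    s_sd = 0.0
    for i in range(len(upstream) - 5):
        e = duplex_energy(upstream[i : i + 6], model.anti_sd)
        if e is None or e >= 0:
            continue
        coord = i - aug_index  # start coordinate (negative, linear == signed here)
        w = float(np.exp(-((coord - model.sd_center) ** 2) / (2 * model.sd_width**2)))
        s_sd = max(s_sd, -e * w)

    def _frac(region: tuple[int, int], bases: set[str]) -> float:
        lo = max(0, aug_index + region[0])
        hi = aug_index + region[1] + 1
        part = full_mrna[lo:hi]
        return sum(b in bases for b in part) / len(part) if part else 0.0

    s_s1 = _frac(S1_REGION, {"A", "U"})
    s_c = _frac(C_REGION, {"C"})
    s_struct = 0.0
    if model.beta_struct != 0.0:
        engine = folding_engine or default_engine()
        s_struct = max(0.0, -engine.mfe(full_mrna))
    total = (
        model.beta_sd * s_sd
        + model.beta_s1 * s_s1
        - model.beta_struct * s_struct
        + model.beta_c * s_c
    )
    return SelectionScore(s_sd=s_sd, s_s1=s_s1, s_struct=s_struct, s_c=s_c, total=total)


def batch_scores(
    readset: ReadSet,
    design: LibraryDesign,
    model: SelectionModel,
    engine: Optional[FoldingEngine] = None,
) -> np.ndarray:
    """Vectorized total scores for every unique sequence of a ReadSet.

    Matches :func:`score_sequence` applied to each assembled construct.
    """
    keys, mat, _ = readset.to_arrays()
    n = len(keys)
    total = np.zeros(n)
    if n == 0:
        return total
    template = encode_sequences([design.assembled_template.replace("N", "A")])[0]
    full = np.tile(template, (n, 1))
    w0 = len(design.five_prime_flank)
    full[:, w0 : w0 + design.random_len] = mat
    aug = design.aug_index

    if model.beta_sd != 0.0:
        up = full[:, :aug]
        if up.shape[1] >= 6:
            codes = rolling_codes(up, 6)
            e = all_6mer_duplex_energies(model.anti_sd)
            bonus = np.nan_to_num(np.maximum(0.0, -e), nan=0.0)
            starts = np.arange(codes.shape[1]) - aug
            gw = _gauss_weights(starts, model.sd_center, model.sd_width)
            total += model.beta_sd * (bonus[codes] * gw).max(axis=1)
    if model.beta_s1 != 0.0:
        cols = _region_columns(design, S1_REGION)
        part = full[:, cols]
        a, u = BASE_INDEX["A"], BASE_INDEX["U"]
        total += model.beta_s1 * ((part == a) | (part == u)).mean(axis=1)
    if model.beta_c != 0.0:
        cols = _region_columns(design, C_REGION)
        part = full[:, cols]
        total += model.beta_c * (part == BASE_INDEX["C"]).mean(axis=1)
    if model.beta_struct != 0.0:
        eng = engine or default_engine()
        mfe = np.array([eng.mfe(design.assemble(k)) for k in keys])
        total -= model.beta_struct * np.maximum(0.0, -mfe)
    return total


# ---------------------------------------------------------------------------
# selection

def select_from_scores(
    control: ReadSet, scores: np.ndarray, stage: str, n_out: int, seed: int
) -> ReadSet:
    """Sample ``n_out`` reads with replacement, weight ~ multiplicity * exp(score).

    The maximum score is subtracted before exponentiation, so the sampled
    distribution is invariant to translating all scores by a constant.
    """
    if n_out < 0:
        raise ValueError("n_out must be non-negative")
    keys, _, mult = control.to_arrays()
    if n_out == 0 or not keys:
        return ReadSet(design=control.design, stage=stage, counts=Counter())
    w = mult * np.exp(scores - scores.max())
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(keys), size=n_out, p=p)
    binned = np.bincount(drawn, minlength=len(keys))
    counts = Counter({k: int(c) for k, c in zip(keys, binned) if c > 0})
    return ReadSet(design=control.design, stage=stage, counts=counts)


def select_reads(
    control: ReadSet,
    model: SelectionModel,
    n_out: int,
    seed: int,
    engine: Optional[FoldingEngine] = None,
    design: Optional[LibraryDesign] = None,
) -> ReadSet:
    """One-round Boltzmann selection of a control library under a stage model."""
    design = design or get_design(control.design)
    scores = batch_scores(control, design, model, engine)
    return select_from_scores(control, scores, model.stage, n_out, seed)


# ---------------------------------------------------------------------------
# output

def write_fastq(
    readset: ReadSet,
    path: str | Path,
    params: Optional[dict] = None,
    full_construct: bool = True,
) -> None:
    """Write a ReadSet as FASTQ (constant quality 'I' = Phred 40 per base).

    By default each randomized region is re-embedded into its full construct,
    so the file behaves like real sequencing output (flank anchors present and
    extractable by QC).  ``full_construct=False`` writes the bare regions.
    Read names encode design/stage/index; simulation parameters, when given,
    are echoed to a YAML sidecar (<path>.yaml) for provenance.
    """
    q = 40
    design = get_design(readset.design) if full_construct else None

    def _records():
        i = 0
        for seq, mult in readset.counts.items():
            out = design.assemble(seq) if design is not None else seq
            for _ in range(mult):
                yield (f"{readset.design}_{readset.stage}_{i}", out, [q] * len(out))
                i += 1

    _write_fastq_records(_records(), path)
    if params is not None:
        with open(f"{path}.yaml", "w") as fh:
            yaml.safe_dump(
                {"design": readset.design, "stage": readset.stage, "n_total": readset.n_total, **params},
                fh,
                sort_keys=True,
            )
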