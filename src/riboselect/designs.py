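"""Library constructs, sequence I/O, randomized-region extraction and QC.

The study's mRNA constructs are 52-nt in vitro transcripts with a randomized
window at a design-specified position relative to the AUG start codon.  mRNA
coordinates are signed 1-based integers with no zero: the A of AUG is +1 and
the base immediately 5' of it is -1.

Five library designs are supported:

=====  ==========  =============================================
name   random nt   randomized window (mRNA coordinates)
=====  ==========  =============================================
N20U   20          -20..-1   (TIR upstream of AUG)
N20D   20          +4..+23   (coding region after AUG; AUG fixed)
N8U    8           -20..-13  (S1 enhancer region)
N8M    8           -14..-7   (SD region)
N8D    8           -8..-1    (spacer region)
=====  ==========  =============================================

The exact fixed flank sequences of the original constructs are not published;
the package ships its own (AUG-free upstream, SD-free) defaults chosen so that
every design assembles to a full-length 52-mer, and all designs share one
layout: a 17-nt 5' leader, a 20-nt window region (randomized in full for N20U,
in an 8-nt slice for the N8 designs), AUG, and a 12-nt 3' filler.  Flanks are
overridable through the pipeline configuration.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .thermo import BASE_INDEX, RNA_BASES

__all__ = [
    "LibraryDesign",
    "ReadSet",
    "QCReport",
    "ParseError",
    "DESIGNS",
    "get_design",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "extract_random_region",
    "qc_filter",
    "to_linear",
    "from_linear",
    "encode_sequences",
    "decode_sequences",
]

# ---------------------------------------------------------------------------
# coordinates

def to_linear(coord: int) -> int:
    """Signed no-zero mRNA coordinate -> contiguous integer (-1 -> -1, +1 -> 0)."""
    if coord == 0:
        raise ValueError("mRNA coordinate 0 does not exist")
    return coord if coord < 0 else coord - 1


def from_linear(linear: int) -> int:
    """Inverse of :func:`to_linear`."""
    return linear if linear < 0 else linear + 1


# ---------------------------------------------------------------------------
# designs

_ANCHOR_LEN = 8

#: 17-nt 5' leader (T7 transcripts start with G); contains no AUG and no SD motif.
DEFAULT_LEADER = "GGGACAACAUCAUACUA"
#: Reference content of the -20..-1 window; fixed portions of the N8 designs
#: are slices of this sequence.
DEFAULT_REF_WINDOW = "ACACUACUACACAACUACAC"
#: 12-nt fixed filler downstream of AUG.
DEFAULT_DOWNSTREAM = "CACCAUCAUCAC"


def _check_rna(seq: str, what: str) -> None:
    bad = set(seq) - set(RNA_BASES)
    if bad:
        raise ValueError(f"{what} contains non-RNA characters: {sorted(bad)}")


@dataclass(frozen=True)
class LibraryDesign:
    """Layout of a library construct: fixed flanks around a randomized window.

    ``window`` is the closed coordinate interval (start, end) of the
    randomized region in signed no-zero mRNA coordinates.  The AUG codon
    (+1..+3) always lies inside a fixed flank.
    """

    name: str
    five_prime_flank: str
    window: tuple[int, int]
    three_prime_flank: str

    def __post_init__(self) -> None:
        _check_rna(self.five_prime_flank, "five_prime_flank")
        _check_rna(self.three_prime_flank, "three_prime_flank")
        start, end = self.window
        if start == 0 or end == 0:
            raise ValueError("randomized window cannot include coordinate 0")
        if to_linear(end) < to_linear(start):
            raise ValueError("window end precedes window start")
        if start < 0 < end:
            raise ValueError("randomized window must not span AUG")
        aug = self.aug_index
        if self.assembled_template[aug : aug + 3] != "AUG":
            raise ValueError("AUG codon not found at +1..+3 of the construct")

    @property
    def random_len(self) -> int:
        start, end = self.window
        return to_linear(end) - to_linear(start) + 1

    @property
    def total_len(self) -> int:
        return len(self.five_prime_flank) + self.random_len + len(self.three_prime_flank)

    @property
    def assembled_template(self) -> str:
        """Construct with the randomized window filled with N placeholders."""
        return self.five_prime_flank + "N" * self.random_len + self.three_prime_flank

    @property
    def aug_index(self) -> int:
        """0-based string index of the A of AUG (= index of coordinate +1)."""
        # window start occupies index len(five_prime_flank)
        return len(self.five_prime_flank) - to_linear(self.window[0])

    def coord_to_index(self, coord: int) -> int:
        """Map a signed mRNA coordinate to a 0-based construct index."""
        idx = self.aug_index + to_linear(coord)
        if not 0 <= idx < self.total_len:
            raise ValueError(f"coordinate {coord} outside construct {self.name}")
        return idx

    def index_to_coord(self, index: int) -> int:
        return from_linear(index - self.aug_index)

    @property
    def window_coords(self) -> list[int]:
        """Ordered coordinates covered by the randomized window."""
        start = to_linear(self.window[0])
        return [from_linear(start + i) for i in range(self.random_len)]

    @property
    def anchor5(self) -> str:
        """Fixed-flank anchor immediately 5' of the randomized window."""
        return self.five_prime_flank[-_ANCHOR_LEN:]

    @property
    def anchor3(self) -> str:
        """Fixed-flank anchor immediately 3' of the randomized window."""
        return self.three_prime_flank[:_ANCHOR_LEN]

    def assemble(self, region: str) -> str:
        """Embed a randomized-region sequence into the full construct."""
        if len(region) != self.random_len:
            raise ValueError(
                f"region length {len(region)} != random_len {self.random_len}"
            )
        _check_rna(region, "region")
        return self.five_prime_flank + region + self.three_prime_flank


def _builtin_designs(
    leader: str = DEFAULT_LEADER,
    ref_window: str = DEFAULT_REF_WINDOW,
    downstream: str = DEFAULT_DOWNSTREAM,
) -> dict[str, LibraryDesign]:
    if len(ref_window) != 20:
        raise ValueError("reference window must be 20 nt")
    aug = "AUG"
    return {
        "N20U": LibraryDesign("N20U", leader, (-20, -1), aug + downstream),
        "N20D": LibraryDesign("N20D", leader + aug, (4, 23), downstream),
        # N8 designs: the non-randomized part of the -20..-1 window is fixed
        # to the corresponding slice of the reference window.
        "N8U": LibraryDesign("N8U", leader, (-20, -13), ref_window[8:] + aug + downstream),
        "N8M": LibraryDesign("N8M", leader + ref_window[:6], (-14, -7), ref_window[14:] + aug + downstream),
        "N8D": LibraryDesign("N8D", leader + ref_window[:12], (-8, -1), aug + downstream),
    }


#: Built-in designs with the package's default flanks.
DESIGNS: dict[str, LibraryDesign] = _builtin_designs()


def get_design(name: str) -> LibraryDesign:
    try:
        return DESIGNS[name]
    except KeyError:
        raise KeyError(f"unknown library design {name!r}; known: {sorted(DESIGNS)}") from None


# ---------------------------------------------------------------------------
# read sets

_ASCII_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _ASCII_TO_CODE[ord(_b)] = _i
_CODE_TO_ASCII = np.frombuffer(RNA_BASES.encode(), dtype=np.uint8)


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length RNA strings into a (n, L) uint8 matrix (A0 C1 G2 U3)."""
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    raw = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    mat = _ASCII_TO_CODE[raw].reshape(len(seqs), L)
    if (mat == 255).any():
        raise ValueError("non-RNA character in sequences")
    return mat


def decode_sequences(mat: np.ndarray) -> list[str]:
    return [b.tobytes().decode() for b in _CODE_TO_ASCII[mat]]


@dataclass
class ReadSet:
    """Randomized-region sequences with multiplicities for one design x stage.

    Identical sequences are aggregated with integer counts; every downstream
    statistic weights by multiplicity.
    """

    design: str
    stage: str
    counts: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.counts}
        if len(lengths) > 1:
            raise ValueError("ReadSet sequences must share one length")
        for s in self.counts:
            _check_rna(s, "read")

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    @property
    def length(self) -> int:
        if not self.counts:
            raise ValueError("empty ReadSet has no sequence length")
        return len(next(iter(self.counts)))

    def to_arrays(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Return (keys, (n_unique, L) uint8 matrix, multiplicity vector)."""
        keys = list(self.counts)
        mult = np.array([self.counts[k] for k in keys], dtype=np.float64)
        return keys, encode_sequences(keys), mult

    @classmethod
    def from_sequences(
        cls, seqs: Iterable[str], design: str, stage: str = "control"
    ) -> "ReadSet":
        return cls(design=design, stage=stage, counts=Counter(seqs))


# ---------------------------------------------------------------------------
# sequence file I/O (Bio.SeqIO behind the module surface)

class ParseError(ValueError):
    """Malformed sequence record; the message names the record index."""


def _infer_format(path: str | Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        f = fmt.lower()
    else:
        suffix = Path(path).suffix.lower()
        f = {"fa": "fasta", "fasta": "fasta", "fq": "fastq", "fastq": "fastq"}.get(
            suffix.lstrip("."), ""
        )
    if f not in ("fasta", "fastq"):
        raise ValueError(f"unsupported sequence format {fmt or suffix!r}")
    return f


def read_sequences(
    path: str | Path, format: Optional[str] = None
) -> list[tuple[str, Optional[list[int]]]]:
    """Read FASTA/FASTQ records as (sequence, phred qualities or None).

    DNA input is transliterated to RNA (T -> U) on ingest; a malformed record
    raises :class:`ParseError` naming the record index.
    """
    fmt = _infer_format(path, format)
    out: list[tuple[str, Optional[list[int]]]] = []
    index = 0
    try:
        with open(path) as handle:
            for index, rec in enumerate(SeqIO.parse(handle, fmt)):
                seq = str(rec.seq).upper().replace("T", "U")
                qual = rec.letter_annotations.get("phred_quality") if fmt == "fastq" else None
                out.append((seq, list(qual) if qual is not None else None))
    except ValueError as exc:
        raise ParseError(f"malformed {fmt} record at index {index}: {exc}") from exc
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as FASTA."""
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(records: Iterable[tuple[str, str, Sequence[int]]], path: str | Path) -> None:
    """Write (name, sequence, phred qualities) triples as Sanger FASTQ."""

    def _gen():
        for name, seq, qual in records:
            rec = SeqRecord(Seq(seq), id=name, description="")
            rec.letter_annotations["phred_quality"] = list(qual)
            yield rec

    SeqIO.write(_gen(), str(path), "fastq")


# ---------------------------------------------------------------------------
# randomized-region extraction

def _find_anchor(read: str, anchor: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (position, mismatches) where anchor matches with <= max_mismatch."""
    la = len(anchor)
    hits = []
    for pos in range(len(read) - la + 1):
        mm = sum(a != b for a, b in zip(read[pos : pos + la], anchor))
        if mm <= max_mismatch:
            hits.append((pos, mm))
    return hits


def extract_random_region(
    read: str, design: LibraryDesign, max_flank_mismatch: int = 0
) -> tuple[Optional[str], str]:
    """Locate the flank anchors and return the intervening randomized region.

    Returns ``(region, "ok")`` on success, else ``(None, reason)`` with reason
    one of ``anchor5_not_found``, ``anchor3_not_found``,
    ``inconsistent_spacing`` (anchors found, but not separated by exactly
    ``random_len`` nt, e.g. an indel inside the window).
    """
    hits5 = _find_anchor(read, design.anchor5, max_flank_mismatch)
    if not hits5:
        return None, "anchor5_not_found"
    hits3 = _find_anchor(read, design.anchor3, max_flank_mismatch)
    if not hits3:
        return None, "anchor3_not_found"
    best: Optional[tuple[int, int, int]] = None  # (total mm, pos5, pos3)
    for pos5, mm5 in hits5:
        for pos3, mm3 in hits3:
            if pos3 - (pos5 + _ANCHOR_LEN) == design.random_len:
                cand = (mm5 + mm3, pos5, pos3)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None, "inconsistent_spacing"
    _, pos5, _ = best
    return read[pos5 + _ANCHOR_LEN : pos5 + _ANCHOR_LEN + design.random_len], "ok"


# ---------------------------------------------------------------------------
# quality control

_QC_REASONS = (
    "low_quality",
    "rrna_contamination",
    "anchor5_not_found",
    "anchor3_not_found",
    "inconsistent_spacing",
)


@dataclass
class QCReport:
    """Per-reason drop counts; reasons partition the rejected reads."""

    n_input: int = 0
    passed: int = 0
    low_quality: int = 0
    rrna_contamination: int = 0
    anchor5_not_found: int = 0
    anchor3_not_found: int = 0
    inconsistent_spacing: int = 0

    @property
    def n_rejected(self) -> int:
        return self.n_input - self.passed

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [("input", self.n_input), ("passed", self.passed)]
        rows += [(r, getattr(self, r)) for r in _QC_REASONS]
        return rows

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reason\tcount\n")
            for reason, count in self.as_rows():
                fh.write(f"{reason}\t{count}\n")


def _reference_kmers(reference: str, k: int) -> set[str]:
    return {reference[i : i + k] for i in range(len(reference) - k + 1)}


def qc_filter(
    reads: Iterable[tuple[str, Optional[Sequence[int]]]],
    design: LibraryDesign,
    *,
    stage: str = "control",
    min_mean_quality: float = 20.0,
    rrna_reference: str = "",
    contaminant_kmer_len: int = 20,
    max_flank_mismatch: int = 0,
) -> tuple[ReadSet, QCReport]:
    """Restrictive QC: quality filter, rRNA-contamination screen, extraction.

    Reads are ``(sequence, qualities or None)`` as produced by
    :func:`read_sequences`.  FASTA input (no qualities) makes the quality
    filter a no-op.  A read sharing any exact ``contaminant_kmer_len``-mer
    with ``rrna_reference`` is dropped as degraded-rRNA contamination; an
    empty reference skips the screen.  Surviving reads must yield a complete
    randomized region via :func:`extract_random_region`.
    """
    report = QCReport()
    counts: Counter = Counter()
    ref = rrna_reference.upper().replace("T", "U")
    ref_kmers = _reference_kmers(ref, contaminant_kmer_len) if ref else set()
    for seq, qual in reads:
        report.n_input += 1
        if qual is not None and len(qual) > 0 and float(np.mean(qual)) < min_mean_quality:
            report.low_quality += 1
            continue
        if ref_kmers and any(
            seq[i : i + contaminant_kmer_len] in ref_kmers
            for i in range(len(seq) - contaminant_kmer_len + 1)
        ):
            report.rrna_contamination += 1
            continue
        region, reason = extract_random_region(seq, design, max_flank_mismatch)
        if region is None:
            setattr(report, reason, getattr(report, reason) + 1)
            continue
        counts[region] += 1
        report.passed += 1
    if report.passed == 0:
        warnings.warn("qc_filter produced an empty ReadSet", stacklevel=2)
    return ReadSet(design=design.name, stage=stage, counts=counts), report
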