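"""Embedded RNA/RNA nearest-neighbor thermodynamic constants.

One small, self-contained parameter set is shared by the duplex-energy
calculation (SD/anti-SD hybridization, :mod:`riboselect.sd`) and the internal
secondary-structure folding engine (:mod:`riboselect.folding`), so that the
selection simulator and every analysis module score base pairing identically.

Stacking free energies (kcal/mol, 37 degC) for Watson-Crick stacks follow the
standard nearest-neighbor literature values; G.U wobble stacks use a
simplified, internally consistent set in which every stack is stabilizing
(<= 0).  The table is declared here as named constants rather than recovered
from any external predictor: no printed energy value is an acceptance target,
and a deterministic embedded table makes hand-summed oracles exact.

Conventions
-----------
A stack is written 5'-x1 x2-3' paired with 3'-y1 y2-5', i.e. pair1 = (x1, y1)
is closed by pair2 = (x2, y2).  By symmetry of the double helix,
E(p1, p2) == E(swap(p2), swap(p1)); the table below stores one representative
per symmetry orbit and :func:`_closure` fills in the mirror entries.
"""

from __future__ import annotations

import numpy as np

RNA_BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}

#: Allowed base pairs (Watson-Crick + G.U wobble).
PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

#: Duplex initiation penalty (intermolecular hybridization only), kcal/mol.
DUPLEX_INIT = 4.09

#: Penalty per terminal A-U or G-U pair of an intermolecular duplex, kcal/mol.
TERMINAL_AU = 0.45

# One representative per symmetry orbit; keys are (pair1, pair2) with
# pair = (strand1 base, strand2 base).  Watson-Crick block first, then wobble.
_BASE_STACKS = {
    (("A", "U"), ("A", "U")): -0.93,  # 5'AA3'/3'UU5'
    (("A", "U"), ("U", "A")): -1.10,  # 5'AU3'/3'UA5'
    (("U", "A"), ("A", "U")): -1.33,  # 5'UA3'/3'AU5'
    (("C", "G"), ("U", "A")): -2.08,  # 5'CU3'/3'GA5'
    (("C", "G"), ("A", "U")): -2.11,  # 5'CA3'/3'GU5'
    (("G", "C"), ("U", "A")): -2.24,  # 5'GU3'/3'CA5'
    (("G", "C"), ("A", "U")): -2.35,  # 5'GA3'/3'CU5'
    (("C", "G"), ("G", "C")): -2.36,  # 5'CG3'/3'GC5'
    (("G", "C"), ("G", "C")): -3.26,  # 5'GG3'/3'CC5'
    (("G", "C"), ("C", "G")): -3.42,  # 5'GC3'/3'CG5'
    # G.U wobble stacks (simplified; all stabilizing by construction)
    (("A", "U"), ("G", "U")): -0.55,
    (("A", "U"), ("U", "G")): -1.36,
    (("U", "A"), ("G", "U")): -1.41,
    (("U", "A"), ("U", "G")): -1.00,
    (("C", "G"), ("G", "U")): -1.41,
    (("C", "G"), ("U", "G")): -2.11,
    (("G", "C"), ("G", "U")): -1.53,
    (("G", "C"), ("U", "G")): -2.51,
    (("G", "U"), ("G", "U")): -0.50,
    (("G", "U"), ("U", "G")): -0.20,
    (("U", "G"), ("G", "U")): -0.30,
}


def _closure(base: dict) -> dict:
    """Symmetric closure: E(p1, p2) = E(swap(p2), swap(p1))."""
    full = {}
    for (p1, p2), e in base.items():
        mirror = ((p2[1], p2[0]), (p1[1], p1[0]))
        for key in ((p1, p2), mirror):
            if key in full and full[key] != e:
                raise ValueError(f"inconsistent stack table at {key}")
            full[key] = e
    return full


#: Complete stack table over all ordered pairs of allowed base pairs.
STACKS = _closure(_BASE_STACKS)


def is_pair(x: str, y: str) -> bool:
    return (x, y) in PAIRS


def pairable_array() -> np.ndarray:
    """4x4 boolean matrix over base codes (A=0, C=1, G=2, U=3)."""
    m = np.zeros((4, 4), dtype=np.bool_)
    for x, y in PAIRS:
        m[BASE_INDEX[x], BASE_INDEX[y]] = True
    return m


def stack_array() -> np.ndarray:
    """Stack energies indexed [p1x, p1y, p2x, p2y] over base codes.

    Entries for non-pairs are 0 and must be masked by pairability checks.
    """
    arr = np.zeros((4, 4, 4, 4), dtype=np.float64)
    for ((x1, y1), (x2, y2)), e in STACKS.items():
        arr[BASE_INDEX[x1], BASE_INDEX[y1], BASE_INDEX[x2], BASE_INDEX[y2]] = e
    return arr


def stack_energy(pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
    """Energy of pair2 stacked on pair1 (5'->3' on strand 1)."""
    return STACKS[(pair1, pair2)]
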