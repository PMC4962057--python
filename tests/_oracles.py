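"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately avoid the package's optimized code paths: the k-mer oracle
slices strings into a Counter, and the folding oracle enumerates every nested
secondary structure explicitly and scores it with the raw stack table.
"""

from collections import Counter

from riboselect.thermo import STACKS, is_pair

MIN_HAIRPIN = 3


def naive_kmer_counts(readset, k: int) -> Counter:
    """Per-window string-slicing k-mer counter (multiplicity-weighted)."""
    counts: Counter = Counter()
    for seq, mult in readset.counts.items():
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += mult
    return counts


def enumerate_structures(seq: str, min_hairpin: int = MIN_HAIRPIN):
    """All nested pair sets of a sequence (Watson-Crick + G.U, hairpin >= 3)."""
    memo: dict[tuple[int, int], list[frozenset]] = {}

    def rec(i: int, j: int) -> list[frozenset]:
        if i >= j:
            return [frozenset()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + min_hairpin + 1, j + 1):
            if is_pair(seq[i], seq[k]):
                for inner in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(inner | right | {(i, k)})
        memo[key] = out
        return out

    return rec(0, len(seq) - 1)


def structure_energy(seq: str, pairs: frozenset) -> float:
    """Stacking-only energy: sum over pair steps (i,j),(i+1,j-1) both present."""
    e = 0.0
    for (i, j) in pairs:
        if (i + 1, j - 1) in pairs:
            e += STACKS[((seq[i], seq[j]), (seq[i + 1], seq[j - 1]))]
    return e


def brute_force_mfe(seq: str, min_hairpin: int = MIN_HAIRPIN) -> float:
    """Exhaustive minimum over all nested structures (empty structure = 0)."""
    return min(structure_energy(seq, s) for s in enumerate_structures(seq, min_hairpin))


def naive_duplex_scan(probe: str, target: str):
    """Register-wise duplex-energy oracle mirroring the printed model directly."""
    from riboselect.thermo import DUPLEX_INIT, TERMINAL_AU

    k = len(probe)
    best = None
    for r in range(len(target) - k + 1):
        opposed = target[r : r + k][::-1]  # antiparallel
        if not all(is_pair(p, t) for p, t in zip(probe, opposed)):
            continue
        pairs = list(zip(probe, opposed))
        e = DUPLEX_INIT + sum(STACKS[(pairs[i], pairs[i + 1])] for i in range(k - 1))
        for end in (pairs[0], pairs[-1]):
            if end not in (("C", "G"), ("G", "C")):
                e += TERMINAL_AU
        if best is None or e < best:
            best = e
    return best
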