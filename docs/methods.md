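# Methods

## Library designs and coordinates

mRNA coordinates are signed 1-based integers with no zero: the A of the AUG
start codon is +1, the base immediately 5' of it is −1.  All five shipped
designs assemble to full-length 52-mers sharing one layout — a 17-nt 5' leader,
the 20-nt region covering −20..−1, AUG, and a 12-nt 3' filler:

| design | randomized window | fixed remainder of −20..−1 |
|--------|-------------------|-----------------------------|
| N20U   | −20..−1 (20 nt)   | —                           |
| N20D   | +4..+23 (20 nt)   | reference window (all 20)   |
| N8U    | −20..−13 (8 nt)   | slice of the reference      |
| N8M    | −14..−7 (8 nt)    | slices of the reference     |
| N8D    | −8..−1 (8 nt)     | slice of the reference      |

The original constructs' exact flank sequences are not published, so the
package ships its own: the leader (`GGGACAACAUCAUACUA`) starts with G (T7
transcription), contains no AUG and no SD-like purine run; the fixed portions
of the −20..−1 window in the N8 designs are slices of one 20-nt reference
sequence (`ACACUACUACACAACUACAC`), also AUG- and SD-free, so that fixed flanks
contribute no spurious motif or start-codon signals.  The downstream design's
randomized window is placed at +4..+23: the start codon is part of a fixed
flank by construction, never of the window.  Flanks are overridable, but the
invariant `total length = 52` and the AUG-at-+1 anchor are enforced.

Randomized regions are recovered from reads by anchoring on the 8 nt of fixed
flank adjacent to each side of the window (default 0 mismatches, matching a
restrictive QC policy); anchors found at a spacing other than the window
length (an indel inside the window) reject the read with a distinct reason
code, and QC reason counts always partition the input.  The rRNA-contamination
screen drops reads sharing any exact 20-mer with a user-supplied rRNA
reference; the quality filter drops FASTQ reads with mean Phred < 20.  The
original study states neither threshold; both are configurable.

## Enrichment statistics

All statistics weight by read multiplicity and are invariant to duplicating
every read k-fold.  No pseudo-counts are used in any ratio: positions or
codons with zero control frequency are flagged NaN rather than imputed
(controls are large enough that such zeros are rare, and the printed
normalizations contain no offsets — with one exception below).

* positional preference: `rel(b,p) = f_sample(b,p) / f_control(b,p)`;
* second codon: `FPM = 10^6 · count / n_reads` per pool, `rel = FPM_s / FPM_c`,
  group means as arithmetic means over the 16 codons sharing a first base;
  between-repeat error bars use the n−1 = 1 SD over two repeats;
* 6-mers: all overlapping windows of every read are counted;
  `KPM = 10^6 · count / total`, and
  `KPM_relative = log10(KPM_s + 1) − log10(KPM_c + 1)` ("lg" read as log10).
  The +1 offset makes absent k-mers well-defined at KPM 0.

K-mers are counted as-is (no reverse-complement canonicalization): the data
are single-stranded mRNA.

### Grid convention

Each k-mer maps to a unique cell of a 2^k × 2^k matrix: base i (5'→3', most
significant first) contributes bit i of the row and of the column with
A=(0,0), C=(0,1), G=(1,0), U=(1,1).  Any bijection preserves the statistics;
this chaos-game-style convention keeps lexicographic locality (A/G-rich
k-mers in the left columns, A/C-rich in the top rows) and makes the base code
equal to `2·row_bit + col_bit`.  Heat maps use a diverging map centered at 0
(red = enriched vs background, blue = depleted).

### Sampling noise of KPM_relative

With n reads of length L, a given 6-mer has ≈ n(L−5)/4096 expected
occurrences; at n = 200,000, L = 20 this is ~732, so resampling noise alone
gives each 6-mer's KPM_relative an SD of ~0.016 under null selection (~0.023
between two independent draws).  The bulk of the null distribution therefore
sits within ±0.05, but the maximum over all 4096 6-mers is ~4 SD and typically
reaches 0.06–0.08.  Thresholds on per-6-mer enrichment should be calibrated
against this extreme-value behaviour, not against the per-k-mer SD.

## SD/anti-SD energetics

The anti-SD analysis uses the 13-mer 5'-GAUCACCUCCUUA-3' at the 16S rRNA
3' end.  Its 6-nt windows are numbered from the 3' terminus inward (n = 1 at
the terminus, 8 windows for the 13-mer); window n = 3 (CCUCCU) pairs the SD
consensus AGGAGG on the mRNA side.  This numbering is declared here because
the schematic it mirrors is not machine-readable.

Duplex hybridization energies are computed over ungapped registers only: a
6-mer probe is slid along the target antiparallel, a register is admissible
only if all six oppositions form Watson-Crick or G·U pairs, and its energy is
`duplex initiation (+4.09) + Σ nearest-neighbor stacks + 0.45 per terminal
A-U/G-U pair`.  If no register pairs throughout, a no-duplex sentinel is
returned, mapped to 0 kcal/mol (no binding, no stabilization) in correlations.
Bulges and interior loops are out of scope.  The stack table embeds standard
Watson-Crick nearest-neighbor values and a simplified, internally consistent
G·U set in which every stack is stabilizing (≤ 0); this makes hand-summed
oracles exact and guarantees that extending a Watson-Crick helix never raises
the energy.  An adapter to an external hybridization predictor is not needed
for any shipped analysis; the same table drives both the simulator and the
analyzers, so recovery tests are self-consistent by construction.

The spacer between a motif starting at coordinate s (s ≤ −motif length) and
AUG is `−s − motif_length` under the no-zero convention: AGGAGG at −17 has an
11-nt spacer, at −10 a 4-nt spacer.

## Folding model

The internal engine is a stacking-energy dynamic program ("Zuker-lite"):
nested structures only, minimum hairpin loop of 3 nt, Watson-Crick and G·U
pairs, and an energy function in which only stacked pair steps (pairs (i,j)
and (i+1,j−1) both present) contribute, using the same table as the duplex
model; loop and multiloop terms are zero.  Consequences: the MFE is always
≤ 0 (the open chain scores 0), isolated pairs are energetically neutral, and
the recursion is exactly checkable against exhaustive enumeration of nested
structures (done in the tests for lengths ≤ 14).  The DP is O(n³) and
numba-compiled; results are memoized per sequence.  This engine intentionally
trades thermodynamic fidelity for determinism and testability; per-sequence
MFE values are not comparable to full Turner-model predictors, but stage-wise
*comparisons* (which pool is more structured) are robust to the simplification
because the same engine scores all pools.  `ViennaFold` wraps RNAfold for
users who want Turner energies; swapping engines changes values only, never
record counts or output schema (its temperature/dangling-end defaults are
RNAfold's own).  Library summaries fold the full 52-mer construct, not the
randomized window alone; histograms use 1 kcal/mol bins.

## Selection simulator

Selection is one round of Boltzmann sampling: reads are drawn with replacement
with probability ∝ multiplicity · exp(score), the maximum score being
subtracted first so the distribution is invariant to translating all scores.
This models a single equilibrium binding incubation, not multi-round SELEX.
The score combines four signals:

| term | definition | emulates |
|------|------------|----------|
| s_sd | max over upstream 6-mer starts p of max(0, −ΔG(6-mer, anti-SD)) · exp(−(p−c)²/2σ²), c = −13, σ = 3 nt | SD/anti-SD pairing with positional preference |
| s_s1 | A/U fraction of −20..−13 | S1-protein enhancer binding |
| s_struct | max(0, −MFE) of the 52-mer | structure penalty on recruitment |
| s_c  | C fraction of −14..−1 | transient nonspecific 16S rRNA complementarity |

`total = β_sd·s_sd + β_s1·s_s1 − β_struct·s_struct + β_c·s_c`.  Stage presets:
control (all β = 0); 30S (β_sd = 0.1, β_c = 2.0) — weak SD signal plus the
C-rich rapid-binding bonus, no structure penalty; 30SIC (β_sd = 0.6) and 70SIC
(β_sd = 0.9), both with β_s1 = 1.5 and β_struct = 0.15 — progressive SD
accumulation, S1 enhancer, and selection against stable structure.  The
C-rich 30S signal is modeled as a C-fraction bonus rather than full 16S-wide
complementarity scanning, since the rRNA-wide pattern data are unavailable.

No quantitative affinity model exists for the real system, so the β
magnitudes are modeling choices, fixed once so that each signal the simulator
exists to emulate is clearly present in its output at desk-scale sample sizes
(10⁴–10⁵ reads) without saturating the pool: with β_sd = 0.6 the simulated
30S-IC pool shows ~1.4× G enrichment at −15..−5 and ~6% AGGAGG-containing
reads, and the positional A/U and C-rich signals sit 5–10% above background.
A caveat inherited from this preset structure: the S1 term is off in the 30S
preset, so simulated 30S pools lack the upstream A/U preference that real 30S
selections already show; the preset isolates the stage-discriminating signals
instead.

The correlation between duplex energy and KPM_relative grows with β_sd only
in the weak-selection regime (β_sd ≲ 0.3 at these sample sizes, R² up to
~0.3, the range the log-scale statistic resolves well); under stronger
selection the selected pool concentrates on few k-mers, enrichment of the
rest is dominated by hitchhiking, and R² declines again.  Trend tests
therefore probe β_sd = 0.05/0.15/0.3.

### What the simulator does and does not emulate

It reproduces: near-uniform control composition; stage-dependent positional
base preferences; SD motif accumulation and its positional profile; the
energy–enrichment correlation; structure-dependent depletion; the transient
C-rich 30S signal; and multiplicity-aggregated read sets.  It does not
emulate: sequencing error or quality variation (simulated FASTQ carries
constant Phred 40), kinetic competition between mRNAs, initiation-factor or
tRNA concentration effects, rRNA contamination, or amplification bias.
Passing planted-signal tests therefore validates the analysis arithmetic and
the qualitative selection logic — not quantitative agreement with any real
selection experiment.

## Problem sizes and determinism

The test suite simulates 40k-read controls with 20k-read selected pools for
planted-signal recovery, 80k/40k for correlation trends, and 200k/200k for
null-selection calibration; these sizes put each tested signal several
standard errors from its null value.  All randomness flows through explicit
integer seeds (numpy Generator); pipeline TSVs are written with 6 significant
digits, making repeated runs with the same configuration bitwise identical.
The pipeline manifest records the configuration, package version, per-file
SHA-256 checksums and timestamps.

## Known limitations

* The folding and duplex energy models are simplified (no loops, bulges,
  dangles, or temperature dependence); absolute energies are
  internally consistent, not thermodynamically calibrated.
* N20D's fixed upstream region makes its SD/S1/C score terms constant across
  reads; selection on that design differentiates reads through the structure
  term (and hence the second codon) only.
* Real-data replicate correlations and energy–preference R² values depend on
  the deposited sequencing data and are out of scope; the package reproduces
  the statistical machinery and its planted-signal behaviour.
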