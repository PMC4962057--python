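"""Shine-Dalgarno motif statistics, anti-SD windows and duplex energetics."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from _oracles import naive_duplex_scan
from riboselect import thermo
from riboselect.designs import ReadSet
from riboselect.kmers import all_kmers, kmer_to_code
from riboselect.sd import (
    ANTI_SD_TARGET,
    antisd_windows,
    all_6mer_duplex_energies,
    argmax_kmer,
    duplex_energy,
    energy_preference_r2,
    motif_fraction,
    motif_start_profile,
    relative_preference,
    revcomp_rna,
    spacer_length,
)


def _rs(seqs, design="N20U"):
    return ReadSet(design=design, stage="x", counts=Counter(seqs))


class TestAntiSdWindows:
    def test_eight_windows_for_printed_target(self):
        windows = antisd_windows(ANTI_SD_TARGET)
        assert len(windows) == 8
        assert [w.position_n for w in windows] == list(range(1, 9))

    def test_position_three_is_sd_consensus(self):
        w3 = antisd_windows(ANTI_SD_TARGET)[2]
        assert w3.window_seq == "CCUCCU"
        assert w3.mrna_6mer == "AGGAGG"

    def test_revcomp_consistency(self):
        for w in antisd_windows(ANTI_SD_TARGET):
            assert revcomp_rna(w.mrna_6mer) == w.window_seq

    def test_minimal_target(self):
        windows = antisd_windows("GGAGGU")
        assert len(windows) == 1 and windows[0].position_n == 1

    def test_too_short(self):
        with pytest.raises(ValueError):
            antisd_windows("ACGUA")


class TestSpacer:
    @pytest.mark.parametrize("start,expected", [(-17, 11), (-10, 4), (-6, 0), (-20, 14)])
    def test_spacer_values(self, start, expected):
        assert spacer_length(start, 6) == expected

    def test_overlap_errors(self):
        with pytest.raises(ValueError):
            spacer_length(-5, 6)
        with pytest.raises(ValueError):
            spacer_length(2, 6)


class TestDuplexEnergy:
    def test_no_complementary_register(self):
        assert duplex_energy("AAAAAA") is None

    def test_aggagg_hand_sum(self):
        """AGGAGG pairs the CCUCCU register; hand-sum its stack terms."""
        pairs = [("A", "U"), ("G", "C"), ("G", "C"), ("A", "U"), ("G", "C"), ("G", "C")]
        expected = thermo.DUPLEX_INIT
        expected += sum(thermo.STACKS[(pairs[i], pairs[i + 1])] for i in range(5))
        expected += thermo.TERMINAL_AU  # one A-U end; the G-C end is free
        assert duplex_energy("AGGAGG") == pytest.approx(expected)
        assert expected == pytest.approx(-8.49)

    def test_register_scan_matches_oracle(self):
        rng = np.random.default_rng(13)
        probes = ["".join(p) for p in rng.choice(list("ACGU"), size=(300, 6))]
        probes += [w.mrna_6mer for w in antisd_windows(ANTI_SD_TARGET)]
        for probe in probes:
            expected = naive_duplex_scan(probe, ANTI_SD_TARGET)
            got = duplex_energy(probe)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_all_stacks_stabilizing(self):
        """Every stack term is <= 0, so extending a duplex by a Watson-Crick
        pair (stack <= -0.93 < terminal penalty 0.45) never raises the energy."""
        assert all(v <= 0 for v in thermo.STACKS.values())
        wc = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
        wc_stacks = [v for (p1, p2), v in thermo.STACKS.items() if p1 in wc and p2 in wc]
        assert max(wc_stacks) <= -thermo.TERMINAL_AU

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            duplex_energy("AGGAGT")

    def test_all_6mer_table(self):
        e = all_6mer_duplex_energies(ANTI_SD_TARGET)
        assert e.shape == (4096,)
        assert np.isnan(e[kmer_to_code("AAAAAA")])
        assert e[kmer_to_code("AGGAGG")] == pytest.approx(-8.49)
        assert np.nanmin(e) < -8  # strong SD-like binders exist


class TestMotifStatistics:
    def test_fraction_counts_reads_once(self):
        rs = _rs(["AGGAGGAGGAGGAGGAGGAG", "A" * 20, "C" * 20, "U" * 20])
        assert motif_fraction(rs, "AGGAGG") == 0.25

    def test_fraction_zero_and_empty(self):
        assert motif_fraction(_rs(["A" * 20]), "AGGAGG") == 0.0
        with pytest.raises(ValueError):
            motif_fraction(_rs([]), "AGGAGG")

    def test_fraction_monotone_under_motif_addition(self):
        rs = _rs(["A" * 20, "C" * 20])
        before = motif_fraction(rs, "AGGAGG")
        rs.counts["AGGAGG" + "A" * 14] += 1
        assert motif_fraction(rs, "AGGAGG") > before

    def test_profile_single_occurrence(self, n20u):
        read = "ACG" + "AGGAGG" + "U" * 11  # motif starts at window index 3 = -17
        profile = motif_start_profile(_rs([read]), n20u)
        assert profile.counts == {-17: 1}
        assert profile.mode == -17

    def test_profile_support_within_window(self, control_n20u, n20u):
        profile = motif_start_profile(control_n20u, n20u, "AGGAGG")
        assert set(profile.counts) <= set(range(-20, -5))

    def test_profile_counts_every_occurrence(self, n20u):
        read = "AGGAGGAGGAGG" + "C" * 8  # overlapping occurrences at -20, -17, -14
        profile = motif_start_profile(_rs([read]), n20u)
        assert profile.counts == {-20: 1, -17: 1, -14: 1}


class TestRelativePreference:
    def _rel(self, values):
        rel = pd.Series(0.0, index=all_kmers(6))
        rel.update(pd.Series(values))
        return rel

    def test_argmax_is_100(self):
        rel = self._rel({"AGGAGG": 0.8, "GGAGGU": 0.4})
        assert relative_preference("AGGAGG", rel) == pytest.approx(100.0)
        assert relative_preference("GGAGGU", rel) == pytest.approx(50.0)
        assert argmax_kmer(rel) == "AGGAGG"

    def test_negative_reported_as_is(self):
        rel = self._rel({"AGGAGG": 0.8, "CCCCCC": -0.4})
        assert relative_preference("CCCCCC", rel) == pytest.approx(-50.0)

    def test_nonpositive_max_flagged(self):
        rel = pd.Series(-0.1, index=all_kmers(6))
        with pytest.warns(UserWarning):
            assert np.isnan(relative_preference("AGGAGG", rel))


class TestEnergyPreferenceR2:
    def test_linear_relation_is_one(self):
        e = np.nan_to_num(all_6mer_duplex_energies(), nan=0.0)
        rel = -0.05 * e + 0.01
        assert energy_preference_r2(rel, all_6mer_duplex_energies()) == pytest.approx(1.0)

    def test_permuted_is_near_zero(self):
        e = all_6mer_duplex_energies()
        rng = np.random.default_rng(21)
        rel = rng.permutation(np.nan_to_num(e, nan=0.0))
        assert energy_preference_r2(rel, e) < 0.01

    def test_degenerate_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(energy_preference_r2(np.zeros(4096)))
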