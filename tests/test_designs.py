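"""Library designs, coordinates, sequence I/O, extraction and QC."""

import pytest
from hypothesis import given, settings, strategies as st

import riboselect as rb
from riboselect.designs import (
    DESIGNS,
    ParseError,
    ReadSet,
    extract_random_region,
    from_linear,
    qc_filter,
    read_sequences,
    to_linear,
    write_fasta,
    write_fastq,
)

RNA = "ACGU"
rna_seq = lambda n: st.text(alphabet=RNA, min_size=n, max_size=n)


class TestDesigns:
    def test_constructs_are_52mers(self):
        for design in DESIGNS.values():
            assert design.total_len == 52
            assert len(design.window_coords) == design.random_len
            full = design.assemble("A" * design.random_len)
            assert len(full) == 52
            assert full[design.aug_index : design.aug_index + 3] == "AUG"

    def test_aug_outside_randomized_window(self):
        for design in DESIGNS.values():
            assert 0 not in design.window_coords
            assert not set(design.window_coords) & {1, 2, 3}

    @pytest.mark.parametrize("coord", [-20, -1, 1, 4, 23])
    def test_coordinate_round_trip(self, coord):
        d = DESIGNS["N20D" if coord > 0 else "N20U"]
        assert d.index_to_coord(d.coord_to_index(coord)) == coord

    def test_no_zero_coordinate(self):
        with pytest.raises(ValueError):
            to_linear(0)
        assert from_linear(to_linear(-1)) == -1
        assert from_linear(to_linear(1)) == 1
        assert to_linear(1) - to_linear(-1) == 1  # adjacent across AUG


class TestExtraction:
    @pytest.mark.parametrize("name", list(DESIGNS))
    def test_exact_construct_recovers_region(self, name):
        design = DESIGNS[name]
        region = ("ACGU" * 6)[: design.random_len]
        got, reason = extract_random_region(design.assemble(region), design)
        assert (got, reason) == (region, "ok")

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(data=st.data())
    def test_planted_region_recovered_for_any_content(self, data):
        name = data.draw(st.sampled_from(sorted(DESIGNS)))
        design = DESIGNS[name]
        region = data.draw(rna_seq(design.random_len))
        got, reason = extract_random_region(design.assemble(region), design)
        assert (got, reason) == (region, "ok")

    def test_anchor_mismatch_rejected_then_tolerated(self, n20u):
        region = "A" * 20
        read = n20u.assemble(region)
        # mutate one base of the 5' anchor (8 nt immediately before the window)
        i = len(n20u.five_prime_flank) - 4
        mutated = read[:i] + ("A" if read[i] != "A" else "C") + read[i + 1 :]
        got, reason = extract_random_region(mutated, n20u, max_flank_mismatch=0)
        assert got is None and reason == "anchor5_not_found"
        got, reason = extract_random_region(mutated, n20u, max_flank_mismatch=1)
        assert (got, reason) == (region, "ok")

    def test_indel_in_window_rejected(self, n20u):
        # anchors present but spaced 19 nt apart for the 20-nt design
        read = n20u.five_prime_flank + "G" * 19 + n20u.three_prime_flank
        got, reason = extract_random_region(read, n20u)
        assert got is None and reason == "inconsistent_spacing"


class TestSequenceIO:
    def test_fasta_read_and_t_to_u(self, tmp_path):
        path = tmp_path / "x.fasta"
        write_fasta([("r1", "ACGU"), ("r2", "GGGG"), ("r3", "AUAU")], path)
        recs = read_sequences(path)
        assert [s for s, _ in recs] == ["ACGU", "GGGG", "AUAU"]
        assert all(q is None for _, q in recs)
        path.write_text(">dna\nACGT\n")
        assert read_sequences(path)[0][0] == "ACGU"

    def test_fastq_roundtrip_identity(self, tmp_path):
        path = tmp_path / "x.fastq"
        seqs = ["ACGU", "UUUU", "ACGU"]
        write_fastq([(f"r{i}", s, [30] * 4) for i, s in enumerate(seqs)], path)
        back = read_sequences(path)
        assert [s for s, _ in back] == seqs
        assert [q for _, q in back] == [[30] * 4] * 3

    def test_truncated_fastq_names_record(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGU\n+\nIIII\n@r1\nACGU\n+\n")
        with pytest.raises(ParseError, match="record"):
            read_sequences(path)

    def test_unsupported_format(self, tmp_path):
        with pytest.raises(ValueError, match="unsupported"):
            read_sequences(tmp_path / "x.bam")


class TestQC:
    def _reads(self, n20u, n=5):
        region = "ACGUACGUACGUACGUACGU"
        return [(n20u.assemble(region), [35] * 52) for _ in range(n)]

    def test_all_pass_conserves_count(self, n20u):
        readset, report = qc_filter(self._reads(n20u, 5), n20u)
        assert readset.n_total == 5 == report.passed
        assert report.n_rejected == 0

    def test_reasons_partition_input(self, n20u):
        good = self._reads(n20u, 3)
        low_q = [(n20u.assemble("A" * 20), [5] * 52)]
        rrna = "G" * 30  # read sharing an exact 20-mer with the rRNA reference
        contaminated = [("AAAA" + rrna[:25] + "AAAA", [35] * 33)]
        junk = [("ACGU" * 13, [35] * 52)]
        readset, report = qc_filter(
            good + low_q + contaminated + junk,
            n20u,
            rrna_reference=rrna,
            contaminant_kmer_len=20,
        )
        assert report.n_input == 6
        assert report.passed == readset.n_total == 3
        assert report.low_quality == 1
        assert report.rrna_contamination == 1
        reasons = (
            report.low_quality
            + report.rrna_contamination
            + report.anchor5_not_found
            + report.anchor3_not_found
            + report.inconsistent_spacing
        )
        assert report.passed + reasons == report.n_input

    def test_fasta_quality_filter_noop(self, n20u):
        reads = [(n20u.assemble("U" * 20), None)]
        readset, report = qc_filter(reads, n20u, min_mean_quality=40)
        assert report.low_quality == 0 and readset.n_total == 1

    def test_report_tsv(self, n20u, tmp_path):
        _, report = qc_filter(self._reads(n20u, 2), n20u)
        out = tmp_path / "qc.tsv"
        report.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "reason\tcount"
        assert len(lines) == 8


class TestReadSet:
    def test_multiplicity_aggregation(self):
        rs = ReadSet.from_sequences(["ACGU", "ACGU", "UUUU"], design="N20U")
        assert rs.n_total == 3 and rs.n_unique == 2

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            ReadSet.from_sequences(["ACGU", "ACG"], design="N20U")

    def test_alphabet_enforced(self):
        with pytest.raises(ValueError):
            ReadSet.from_sequences(["ACGT"], design="N20U")
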