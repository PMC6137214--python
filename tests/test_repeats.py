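"""Tandem-repeat scanner: worked examples, brute-force oracle, properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emastkit.io import SequenceRecord
from emastkit.repeats import (
    FlankedLocus,
    RepeatUnit,
    TandemRepeatLocus,
    extract_flanks,
    find_tandem_repeats,
    repeat_length_spectrum,
    reverse_complement,
    scan_genome,
)


def brute_force_repeats(seq: str, unit: str, min_units: int):
    """Exhaustive oracle: test every offset for >= min_units exact copies,
    keep maximal runs.  Independent of the scanner implementation."""
    k = len(unit)
    out = []
    for i in range(len(seq) - k + 1):
        m = 0
        while seq[i + m * k : i + (m + 1) * k] == unit:
            m += 1
        if m >= min_units and seq[i - k : i] != unit:  # left-maximal
            out.append((i, i + m * k, m))
    return out


class TestRepeatUnit:
    def test_valid_units(self):
        assert RepeatUnit("CTTT").bases == "CTTT"
        assert RepeatUnit("atc").bases == "ATC"  # trinucleotides supported

    @pytest.mark.parametrize("bad", ["AAAA", "ATAT", "AA", "CTTTT", "CTTN", "CT"])
    def test_periodic_or_malformed_units_rejected(self, bad):
        with pytest.raises(ValueError):
            RepeatUnit(bad)

    def test_reverse_complement(self):
        assert RepeatUnit("CTTT").reverse_complement == "AAAG"


class TestFindTandemRepeats:
    def test_simple_embedded_run(self):
        rec = SequenceRecord("c", "AACTTTCTTTGG")
        (loc,) = find_tandem_repeats(rec, "CTTT", 2)
        assert (loc.start, loc.end, loc.n_units) == (2, 10, 2)

    def test_whole_sequence_run(self):
        rec = SequenceRecord("c", "CTTT" * 10)
        (loc,) = find_tandem_repeats(rec, "CTTT", 10)
        assert (loc.start, loc.end, loc.n_units) == (0, 40, 10)

    def test_trailing_partial_unit_not_counted(self):
        rec = SequenceRecord("c", "CTTTCTTTC")
        (loc,) = find_tandem_repeats(rec, "CTTT", 2)
        assert (loc.start, loc.end, loc.n_units) == (0, 8, 2)

    def test_interruption_splits_run(self):
        rec = SequenceRecord("c", "CTTT" * 3 + "A" + "CTTT" * 3)
        loci = find_tandem_repeats(rec, "CTTT", 2)
        assert [(l.start, l.n_units) for l in loci] == [(0, 3), (13, 3)]

    def test_n_never_matches(self):
        rec = SequenceRecord("c", "CTTTCTNTCTTT")
        assert find_tandem_repeats(rec, "CTTT", 2) == []

    def test_rotated_phase_not_reported(self):
        # TTTC run is the same tract in another register; unit matched verbatim
        rec = SequenceRecord("c", "ATTTCTTTCTTTCA")
        loci = find_tandem_repeats(rec, "TTTC", 2)
        assert [(l.start, l.n_units) for l in loci] == [(1, 3)]
        loci = find_tandem_repeats(rec, "CTTT", 2)
        assert [(l.start, l.n_units) for l in loci] == [(4, 2)]

    def test_min_units_below_two_rejected(self):
        with pytest.raises(ValueError):
            find_tandem_repeats(SequenceRecord("c", "ACGT"), "CTTT", 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        # salt with planted runs so the comparison is non-trivial
        for pos in rng.integers(0, 49_000, size=20):
            n = int(rng.integers(2, 14))
            seq = seq[:pos] + "CTTT" * n + seq[pos + 4 * n :]
        rec = SequenceRecord("c", seq)
        got = [(l.start, l.end, l.n_units) for l in find_tandem_repeats(rec, "CTTT", 2)]
        assert got == brute_force_repeats(seq, "CTTT", 2)

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet="ACT", min_size=0, max_size=60), st.integers(2, 4))
    def test_oracle_equivalence_property(self, seq, min_units):
        rec = SequenceRecord("c", seq)
        got = [(l.start, l.end, l.n_units) for l in find_tandem_repeats(rec, "CTT", min_units)]
        assert got == brute_force_repeats(seq, "CTT", min_units)

    @pytest.mark.parametrize("seed", range(5))
    def test_maximality_and_no_overlap(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = "".join(rng.choice(list("CT"), size=20_000))  # CT-rich: many runs
        loci = find_tandem_repeats(SequenceRecord("c", seq), "CTTT", 2)
        prev_end = -1
        for l in loci:
            assert seq[l.start : l.end] == "CTTT" * l.n_units
            assert seq[l.start - 4 : l.start] != "CTTT"
            assert seq[l.end : l.end + 4] != "CTTT"
            assert l.start >= prev_end  # non-overlapping, ascending
            prev_end = l.end


class TestScanGenome:
    def test_forward_loci_across_contigs(self):
        recs = [
            SequenceRecord("chr1", "GG" + "CTTT" * 12 + "AA"),
            SequenceRecord("chr2", "TT" + "CTTT" * 12 + "CC"),
        ]
        loci = scan_genome(recs, "CTTT", 10)
        assert [(l.chrom, l.strand) for l in loci] == [("chr1", "+"), ("chr2", "+")]

    def test_reverse_strand_locus_in_forward_coordinates(self):
        # AAAG on the forward strand is CTTT on the other strand
        rec = SequenceRecord("chr1", "GG" + "AAAG" * 12 + "TT")
        (loc,) = scan_genome([rec], "CTTT", 10, scan_reverse=True)
        assert loc.strand == "-"
        assert (loc.start, loc.end, loc.n_units) == (2, 50, 12)
        assert rec.sequence[loc.start : loc.end] == "AAAG" * 12
        assert reverse_complement(rec.sequence[loc.start : loc.end]) == "CTTT" * 12

    def test_no_reverse_scan_misses_minus_strand_locus(self):
        rec = SequenceRecord("chr1", "GG" + "AAAG" * 12 + "TT")
        assert scan_genome([rec], "CTTT", 10, scan_reverse=False) == []

    def test_empty_record_set_rejected(self):
        with pytest.raises(ValueError):
            scan_genome([], "CTTT", 10)

    def test_planted_fixture_recall_is_total(self, fixture_genome, fixture_truth):
        loci = scan_genome(fixture_genome, "CTTT", 10)
        got = {(l.chrom, l.start, l.end, l.n_units) for l in loci}
        want = {(c, s, e, n) for c, s, e, n, _motif in fixture_truth}
        assert got == want


class TestExtractFlanks:
    def test_interior_locus_has_complete_flanks(self):
        seq = "A" * 30 + "CTTT" * 10 + "G" * 30
        rec = SequenceRecord("c", seq)
        (loc,) = find_tandem_repeats(rec, "CTTT", 10)
        fl = extract_flanks(loc, rec, 25)
        assert fl.upstream_flank == "A" * 25
        assert fl.downstream_flank == "G" * 25
        assert fl.complete_flanks
        assert fl.region == "A" * 25 + "CTTT" * 10 + "G" * 25

    def test_contig_edge_truncates_and_flags(self):
        seq = "A" * 10 + "CTTT" * 10 + "G" * 30
        rec = SequenceRecord("c", seq)
        (loc,) = find_tandem_repeats(rec, "CTTT", 10)
        fl = extract_flanks(loc, rec, 25)
        assert fl.upstream_flank == "A" * 10
        assert not fl.complete_flanks

    def test_mismatched_record_rejected(self):
        loc = TandemRepeatLocus("chr1", 0, 8, RepeatUnit("CTTT"), 2)
        with pytest.raises(ValueError):
            extract_flanks(loc, SequenceRecord("chr2", "CTTTCTTT"))

    def test_minus_strand_flanks_in_locus_orientation(self):
        up, down = "GATTACAGATTACAGATTACAGATT", "CCCGGGACGTACGTAACCGGTTAAC"
        forward = reverse_complement(down) + "AAAG" * 12 + reverse_complement(up)
        rec = SequenceRecord("c", forward)
        (loc,) = scan_genome([rec], "CTTT", 10, scan_reverse=True)
        fl = extract_flanks(loc, rec, 25)
        assert fl.upstream_flank == up
        assert fl.downstream_flank == down
        assert fl.repeat_seq == "CTTT" * 12

    @pytest.mark.parametrize("seed", range(3))
    def test_flanks_equal_slice_oracle(self, seed, fixture_genome):
        by_id = {r.id: r for r in fixture_genome}
        for loc in scan_genome(fixture_genome, "CTTT", 10):
            rec = by_id[loc.chrom]
            fl = extract_flanks(loc, rec, 25)
            assert fl.upstream_flank == rec.sequence[loc.start - 25 : loc.start]
            assert fl.downstream_flank == rec.sequence[loc.end : loc.end + 25]


class TestSpectrum:
    def test_planted_counts(self):
        seq = (
            "AC" + "CTTT" * 10 + "GG" + "CTTT" * 10 + "GACA" + "CTTT" * 12 + "GT"
        )
        spec = repeat_length_spectrum([SequenceRecord("c", seq)], "CTTT", 10, 25)
        assert spec == {("c", 10): 2, ("c", 12): 1}

    def test_empty_genome_all_zero(self):
        assert repeat_length_spectrum([SequenceRecord("c", "ACGT" * 100)], "CTTT") == {}

    def test_overflow_bin(self):
        seq = "AC" + "CTTT" * 30 + "GG"
        spec = repeat_length_spectrum([SequenceRecord("c", seq)], "CTTT", 10, 25)
        assert spec == {("c", "overflow"): 1}

    def test_spectrum_sums_to_scan_total(self, fixture_genome):
        spec = repeat_length_spectrum(fixture_genome, "CTTT", 10, 25)
        total = sum(spec.values())
        assert total == len(scan_genome(fixture_genome, "CTTT", 10))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            repeat_length_spectrum([SequenceRecord("c", "ACGT")], "CTTT", 25, 10)


def test_scan_is_deterministic(fixture_genome):
    a = scan_genome(fixture_genome, "CTTT", 10, scan_reverse=True)
    b = scan_genome(fixture_genome, "CTTT", 10, scan_reverse=True)
    assert a == b
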