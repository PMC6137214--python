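"""Instability calling: reference-table worked examples and properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emastkit.calling import (
    MarkerCounts,
    call_emast,
    call_normal_instability,
    classify_tumors,
    load_table1,
    read_count_table,
    repeat_count_delta,
    summarize_panel,
    write_calls,
)
from emastkit.synthetic import generate_count_table

FLANK_L = "GATTACAGGC"
FLANK_R = "CCATGAGTCA"


def seq_with_units(n, unit="CTTT"):
    return FLANK_L + unit * n + FLANK_R


@pytest.fixture(scope="module")
def table1():
    return {m.marker_id: m for m in load_table1()}


class TestRepeatCountDelta:
    def test_single_unit_contraction(self):
        # reference 18 units vs sample 17, as for the C10R18 normals
        assert repeat_count_delta(seq_with_units(18), seq_with_units(17), "CTTT") == -1

    def test_identical_sequences(self):
        assert repeat_count_delta(seq_with_units(15), seq_with_units(15), "CTTT") == 0

    def test_expansion_positive(self):
        assert repeat_count_delta(seq_with_units(17), seq_with_units(18), "CTTT") == +1

    def test_non_unit_indel_rejected(self):
        ref = seq_with_units(15)
        shorter = FLANK_L + "CTTT" * 14 + "CTT" + FLANK_R  # tract 3 nt short of 15 units
        with pytest.raises(ValueError, match="not a multiple"):
            repeat_count_delta(ref, shorter, "CTTT")

    def test_sequence_without_single_tract_rejected(self):
        with pytest.raises(ValueError):
            repeat_count_delta(seq_with_units(10), FLANK_L + FLANK_R, "CTTT")


class TestNormalInstability:
    def test_single_deviating_mouse_flags_marker(self, table1):
        # C9R17: published 17, one normal of 16
        assert call_normal_instability(table1["C9R17"]) is True

    def test_all_concordant_marker_is_stable(self, table1):
        assert call_normal_instability(table1["C8R17"]) is False

    def test_single_normal_equal_to_published(self):
        m = MarkerCounts("m", 15, normal={"1": 15}, tumor={"1": 15})
        assert call_normal_instability(m) is False

    def test_across_mice_mode(self, table1):
        # both definitions agree on every marker of the reference table
        for marker in table1.values():
            assert call_normal_instability(marker, "vs_published") == call_normal_instability(
                marker, "across_mice"
            )

    def test_no_normals_rejected(self):
        m = MarkerCounts("m", 15, normal={}, tumor={"1": 15})
        with pytest.raises(ValueError):
            call_normal_instability(m)


class TestCallEmast:
    def test_tumor_expansion_called(self, table1):
        assert "5" in call_emast(table1["C8R17"])  # normal 17 -> tumor 18

    def test_equal_counts_not_called(self, table1):
        assert "4" not in call_emast(table1["C9R17"])  # 16 -> 16

    def test_reference_table_bold_cells(self, table1):
        assert call_emast(table1["C6R16"]) == {"2", "4", "6"}
        assert call_emast(table1["C8R17"]) == {"5", "7"}
        assert call_emast(table1["C10R18"]) == {"1", "2"}
        assert call_emast(table1["C14R16"]) == {"1", "2", "5", "6", "7"}
        assert call_emast(table1["C9R17"]) == set()
        assert call_emast(table1["C19R16"]) == set()

    def test_missing_cells_skipped_not_called(self):
        m = MarkerCounts("m", 16, normal={"1": 16, "2": 16}, tumor={"2": 17, "3": 18})
        # mouse 1 has no tumor, mouse 3 no normal: only mouse 2 comparable
        assert call_emast(m) == {"2"}

    def test_all_tumors_missing_rejected(self):
        m = MarkerCounts("m", 16, normal={"1": 16}, tumor={})
        with pytest.raises(ValueError):
            call_emast(m)

    def test_relabeling_mice_relabels_calls(self, table1):
        m = table1["C14R16"]
        relabeled = MarkerCounts(
            m.marker_id, m.published_n_units,
            normal={f"m{k}": v for k, v in m.normal.items()},
            tumor={f"m{k}": v for k, v in m.tumor.items()},
        )
        assert call_emast(relabeled) == {f"m{k}" for k in call_emast(m)}


class TestClassifyTumors:
    def test_reference_table_positive_mice(self, table1):
        # sample 3 has no EMAST call at any marker; all others have >= 1
        positive = classify_tumors(list(table1.values()))
        assert positive == {"1", "2", "4", "5", "6", "7"}
        assert "3" not in positive

    def test_zero_threshold_is_vacuous(self, table1):
        positive = classify_tumors(list(table1.values()), min_unstable_markers=0)
        assert positive == {"1", "2", "3", "4", "5", "6", "7"}

    def test_controls_excluded_by_default(self, table1):
        only_controls = [m for m in table1.values() if not m.algorithm_identified]
        with pytest.raises(ValueError):
            classify_tumors(only_controls)

    def test_planted_truth_recovered(self):
        markers, truth = generate_count_table(
            n_markers=6, n_mice=10, p_normal_instability=0.2, p_emast=0.4, seed=5
        )
        planted = {
            (e["marker"], e["sample"]) for e in truth.instability_events if e["kind"] == "emast"
        }
        called = {(m.marker_id, mouse) for m in markers for mouse in call_emast(m)}
        assert called == planted
        want_positive = {s for _mk, s in planted}
        assert classify_tumors(markers, 1) == want_positive


class TestSummarize:
    def test_reference_table_summary(self, table1):
        s = summarize_panel(list(table1.values()))
        assert s.n_markers == 7
        assert s.n_markers_emast == 5
        assert s.n_markers_normal_instability == 5
        assert s.n_markers_overlap == 4
        assert s.n_markers_any_instability == 6
        assert len(s.control_calls) == 2
        assert s.n_controls_any_instability == 0

    def test_parental_counts_all_stable(self, table1):
        parental = table1["C10R18"].parental
        assert parental is not None and len(parental) == 7
        assert all(v == table1["C10R18"].published_n_units for v in parental.values())

    def test_all_stable_table_summarises_to_zero(self):
        markers, _ = generate_count_table(5, 7, 0.0, 0.0, seed=1)
        s = summarize_panel(markers)
        assert (s.n_markers_emast, s.n_markers_normal_instability,
                s.n_markers_overlap, s.n_markers_any_instability) == (0, 0, 0, 0)
        assert s.emast_positive_mice == frozenset()

    def test_summary_invariant_under_marker_reordering(self, table1):
        markers = list(table1.values())
        a = summarize_panel(markers).to_dict()
        b = summarize_panel(markers[::-1]).to_dict()
        assert a == b

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0, 1), st.floats(0, 1))
    def test_count_invariants_on_random_tables(self, seed, p_norm, p_emast):
        markers, _ = generate_count_table(4, 5, p_norm, p_emast, seed=seed)
        s = summarize_panel(markers)
        assert s.n_markers_overlap <= min(s.n_markers_emast, s.n_markers_normal_instability)
        assert s.n_markers_any_instability >= max(s.n_markers_emast, s.n_markers_normal_instability)
        assert s.n_markers_any_instability <= s.n_markers

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_panel([])


class TestTableIO:
    def test_round_trip_through_tsv(self, tmp_path, table1):
        markers, _ = generate_count_table(3, 4, 0.3, 0.5, seed=9)
        p = tmp_path / "counts.tsv"
        with open(p, "w") as fh:
            fh.write("marker_id\tpublished_n_units\tsample_id\ttissue\tn_units\talgorithm_identified\n")
            for m in markers:
                for s, n in m.normal.items():
                    fh.write(f"{m.marker_id}\t{m.published_n_units}\t{s}\tnormal\t{n}\t1\n")
                for s, n in m.tumor.items():
                    fh.write(f"{m.marker_id}\t{m.published_n_units}\t{s}\ttumor\t{n}\t1\n")
        back = read_count_table(p)
        assert [(m.marker_id, dict(m.normal), dict(m.tumor)) for m in back] == [
            (m.marker_id, dict(m.normal), dict(m.tumor)) for m in markers
        ]

    def test_missing_cell_is_skipped(self, table1):
        # the reference table prints only six normal values for C19R16
        assert len(table1["C19R16"].normal) == 6
        assert len(table1["C19R16"].tumor) == 7

    def test_write_calls_outputs(self, tmp_path, table1):
        import json

        s = summarize_panel(list(table1.values()))
        calls = tmp_path / "calls.tsv"
        summ = tmp_path / "summary.json"
        write_calls(s, calls, summ)
        lines = calls.read_text().splitlines()
        assert len(lines) == 1 + 7 + 2  # header + panel + controls
        data = json.loads(summ.read_text())
        assert data["n_markers_emast"] == 5


def test_emast_rate_recovers_planted_probability():
    """Empirical per-marker EMAST-call rate matches the planted p_emast
    within the binomial 99% CI at n = 500 mice."""
    from scipy.stats import binom

    p_emast = 0.3
    n_mice = 500
    markers, _ = generate_count_table(
        n_markers=6, n_mice=n_mice, p_normal_instability=0.1, p_emast=p_emast, seed=42
    )
    lo, hi = binom.ppf([0.005, 0.995], n_mice, p_emast)
    for m in markers:
        assert lo <= len(call_emast(m)) <= hi
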