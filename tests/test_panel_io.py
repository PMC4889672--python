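import io

import numpy as np
import pandas as pd
import pytest

import nilscape as ns
from nilscape.panel_io import ValidationError
from tests.conftest import make_table


def write_map(tmp_path, rows):
    path = tmp_path / "map.tsv"
    pd.DataFrame(rows, columns=["position", "side"]).to_csv(
        path, sep="\t", index=False)
    return path


class TestMarkerMap:
    def test_minimal_valid_map(self, tmp_path):
        path = write_map(tmp_path, [(100, "left"), (200, "left"),
                                    (900, "right"), (950, "right")])
        m = ns.read_marker_map(path, indel_position=500)
        assert m.n_markers == 4
        assert list(m.side_positions("left")) == [100, 200]
        assert m.shared_span == (100, 950)

    def test_non_monotone_positions_rejected_naming_row(self, tmp_path):
        path = write_map(tmp_path, [(200, "left"), (100, "left"),
                                    (900, "right"), (950, "right")])
        with pytest.raises(ValidationError, match="not increasing.*row 2"):
            ns.read_marker_map(path, indel_position=500)

    def test_side_inconsistent_with_indel_rejected(self, tmp_path):
        path = write_map(tmp_path, [(100, "left"), (600, "left"),
                                    (900, "right"), (950, "right")])
        with pytest.raises(ValidationError, match="indel"):
            ns.read_marker_map(path, indel_position=500)

    def test_intervals_are_within_side_pairs(self, tiny_map):
        grid = tiny_map.intervals()
        assert len(grid) == 10  # 5 per side; no interval spans the indel
        assert (grid["length"] == grid["end"] - grid["start"]).all()
        assert not ((grid["start"] < 500) & (grid["end"] > 500)).any()


class TestCallBreakpoints:
    def strains(self, *calls):
        return [ns.StrainGenotypes(f"S{i}", "faxnil", c)
                for i, c in enumerate(calls)]

    def test_single_clean_transition(self, tiny_map):
        calls = "AAABBB" + "BBBBBB"  # A->B between markers 300 and 350
        iv, qc = ns.call_breakpoints(self.strains(calls), tiny_map)
        assert qc.n_retained == 1
        assert (iv[0].left_bound, iv[0].right_bound) == (300, 350)
        assert iv[0].orientation == "A->B"

    def test_double_recombinant_excluded(self, tiny_map):
        # two sign changes in the call sequence (oracle: count sign changes)
        calls = "AABAAB" + "BBBBBB"
        iv, qc = ns.call_breakpoints(self.strains(calls), tiny_map)
        assert iv == []
        assert qc.excluded == [("S0", "double_recombinant")]

    def test_breakpoint_spans_missing_call(self, tiny_map):
        # transition between nearest non-missing flanking markers
        calls = "AANBBB" + "BBBBBB"
        iv, _ = ns.call_breakpoints(self.strains(calls), tiny_map)
        assert (iv[0].left_bound, iv[0].right_bound) == (200, 350)

    def test_non_recombinant_and_het_and_failures(self, tiny_map):
        aa = "A" * 12
        het = "AAHHBB" + "B" * 6
        many_n = "ANNNBB" + "B" * 6
        iv, qc = ns.call_breakpoints(
            self.strains(aa, het, many_n), tiny_map, max_missing=2)
        assert iv == []
        assert dict(qc.excluded) == {"S0": "non_recombinant",
                                     "S1": "het_stretch",
                                     "S2": "multiple_failures"}

    def test_single_het_at_breakpoint_is_ambiguous(self, tiny_map):
        calls = "AAHBBB" + "B" * 6
        _, qc = ns.call_breakpoints(self.strains(calls), tiny_map)
        assert qc.excluded == [("S0", "ambiguous_at_breakpoint")]

    def test_empty_panel_is_an_error(self, tiny_map):
        with pytest.raises(ValidationError):
            ns.call_breakpoints([], tiny_map)

    def test_order_independent_and_idempotent(self, tiny_map):
        rng = np.random.default_rng(0)
        panel = []
        for i in range(30):
            cut = rng.integers(1, 12)
            calls = np.array(["A"] * cut + ["B"] * (12 - cut), dtype="U1")
            panel.append(ns.StrainGenotypes(f"S{i}", "lonnil", calls))
        iv1, _ = ns.call_breakpoints(panel, tiny_map)
        shuffled = list(panel)
        rng.shuffle(shuffled)
        iv2, _ = ns.call_breakpoints(shuffled, tiny_map)
        key = lambda x: (x.strain_id, x.left_bound)
        assert sorted(iv1, key=key) == sorted(iv2, key=key)


class TestTabulate:
    def test_counts_conserved_in_single_interval(self, tiny_map):
        xos = [ns.CrossoverInterval(f"S{i}", 300, 350, "A->B", "faxnil")
               for i in range(4)]
        t = ns.tabulate_crossovers(xos, tiny_map)
        assert t.total() == 4
        row = t.data[(t.data.start == 300)]
        assert int(row.count_faxnil.iloc[0]) == 4
        assert t.data.count_faxnil.sum() == 4

    def test_span_assigned_to_midpoint_interval(self, tiny_map):
        # bounds (100, 400): midpoint 250 lies in interval [200, 300)
        t = ns.tabulate_crossovers(
            [ns.CrossoverInterval("S0", 100, 400, "A->B", "lonnil")], tiny_map)
        row = t.data[t.data.count_lonnil > 0]
        assert (int(row.start.iloc[0]), int(row.end.iloc[0])) == (200, 300)

    def test_non_marker_bound_rejected(self, tiny_map):
        with pytest.raises(ValidationError, match="marker"):
            ns.tabulate_crossovers(
                [ns.CrossoverInterval("S0", 111, 350, "A->B", "faxnil")],
                tiny_map)

    def test_conservation_matches_retained_strains(self, tiny_map):
        rng = np.random.default_rng(3)
        panel = []
        for i in range(50):
            cut = rng.integers(1, 6) if rng.random() < 0.5 else rng.integers(7, 12)
            calls = np.array(["A"] * cut + ["B"] * (12 - cut), dtype="U1")
            panel.append(ns.StrainGenotypes(
                f"S{i}", "faxnil" if i % 2 else "lonnil", calls))
        iv, qc = ns.call_breakpoints(panel, tiny_map)
        t = ns.tabulate_crossovers(iv, tiny_map)
        assert t.total() == qc.n_retained


class TestMaskAndRebin:
    def test_empty_mask_is_identity(self, two_side_table):
        out = ns.mask_intervals(two_side_table, [])
        pd.testing.assert_frame_equal(out.data, two_side_table.data)

    def test_region_flags_every_overlapping_interval(self):
        t = make_table([1000, 1000, 1000], [5, 5, 5])
        out = ns.mask_intervals(t, [(1500, 2500)])  # overlaps intervals 2 and 3
        assert list(out.data.masked) == [False, True, True]
        assert out.total() == 5  # masked rows retained but excluded

    def test_region_outside_span_rejected(self):
        t = make_table([1000, 1000], [3, 3])
        with pytest.raises(ValidationError, match="outside"):
            ns.mask_intervals(t, [(50_000, 60_000)])

    def test_exact_tiling_gives_two_25kb_bins(self):
        t = make_table([5_000] * 10, [3] * 10)
        out = ns.rebin_25kb(t)
        assert len(out.unmasked()) == 2
        assert list(out.unmasked().length) == [25_000, 25_000]
        assert out.resolution == "25kb"

    def test_min_events_bins_are_merged(self):
        t = make_table([25_000, 25_000, 25_000], [1, 8, 9])
        out = ns.rebin_25kb(t, min_events=3)
        assert (out.unmasked().count_faxnil >= 3).all()
        assert out.total() == t.total()

    def test_rebin_conserves_counts_and_length(self, two_side_table):
        out = ns.rebin_25kb(two_side_table)
        assert out.total() == two_side_table.total()
        assert out.lengths().sum() == two_side_table.lengths().sum()
        # boundaries are unions of original interval boundaries
        orig = set(two_side_table.data.start) | set(two_side_table.data.end)
        assert set(out.data.start).issubset(orig)


class TestRoundTrips:
    def test_table_tsv_round_trip(self, two_side_table, tmp_path):
        path = tmp_path / "t.tsv"
        two_side_table.write_tsv(path)
        back = ns.CrossoverTable.read_tsv(path)
        pd.testing.assert_frame_equal(back.data, two_side_table.data)

    def test_genotype_tsv_round_trip(self, tiny_map, tmp_path):
        panel = [ns.StrainGenotypes("S1", "faxnil", "AAABBB" + "B" * 6),
                 ns.StrainGenotypes("S2", "lonnil", "AAAAAA" + "AANBBB")]
        path = tmp_path / "panel.tsv"
        ns.write_genotypes(panel, path)
        back = ns.read_genotypes(path, tiny_map)
        assert [s.strain_id for s in back] == ["S1", "S2"]
        assert all((a.calls == b.calls).all() for a, b in zip(panel, back))

    def test_marker_map_tsv_round_trip(self, tiny_map, tmp_path):
        path = tmp_path / "map.tsv"
        tiny_map.write_tsv(path)
        back = ns.read_marker_map(path, indel_position=500)
        assert (back.positions == tiny_map.positions).all()
        assert (back.sides == tiny_map.sides).all()
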