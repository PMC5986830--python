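"""Missing/unassigned scanning, padding, and sidechain tagging."""

import numpy as np
import pytest

from nmrcube import (
    CurationError,
    PeakRow,
    PeaklistTable,
    Series,
    pad_tables,
    parse_sequence_spec,
    scan_series,
    tag_sidechains,
)
from nmrcube.peaklist_io import tables_equal


def series_of(tables, labels=None):
    labels = labels or tuple(str(i + 1) for i in range(len(tables)))
    return Series(along="x", fixed={"y": "wt", "z": "apo"},
                  labels=tuple(labels), tables=list(tables))


def simple_tables(n_points=7, residues=(20, 21, 22, 23),
                  drop=None):
    """drop: {residue: 1-based first absent point}"""
    drop = drop or {}
    tables = []
    for point in range(1, n_points + 1):
        rows = []
        for num in residues:
            if num in drop and point >= drop[num]:
                continue
            rows.append(PeakRow(num, "A", "N", "H",
                                120.0 + num * 0.1 + point * 0.01,
                                8.0 + num * 0.01, height=1e7 + point))
        tables.append(PeaklistTable(rows))
    return tables


class TestScanSeries:
    def test_vanishing_residue_is_missing_from_its_vanish_point(self):
        series = series_of(simple_tables(drop={22: 4}))
        scan = scan_series(series)
        col = scan.statuses.loc[22]
        assert list(col[:3]) == ["measured"] * 3
        assert list(col[3:]) == ["missing"] * 4
        # carry source is the last measured point
        assert scan.filled_from.loc[22, "4"] == "3"
        assert scan.filled_from.loc[22, "7"] == "3"

    def test_never_observed_residue_is_unassigned_everywhere(self):
        series = series_of(simple_tables())
        scan = scan_series(series, sequence={n: "" for n in range(20, 26)})
        assert (scan.statuses.loc[25] == "unassigned").all()
        assert (scan.statuses.loc[24] == "unassigned").all()

    def test_full_universe_all_measured(self):
        series = series_of(simple_tables())
        scan = scan_series(series)
        assert (scan.statuses == "measured").all().all()

    def test_status_counts_partition_the_universe(self):
        series = series_of(simple_tables(drop={22: 4, 21: 6}))
        scan = scan_series(series, sequence={n: "" for n in range(20, 30)})
        for label in series.labels:
            counts = scan.counts(label)
            assert sum(counts.values()) == len(scan.universe) == 10

    def test_conflicting_backbone_rows_are_an_error(self):
        bad = PeaklistTable([
            PeakRow(22, "F", "N", "H", 117.0, 9.0),
            PeakRow(22, "F", "N", "H", 117.5, 9.1),
        ])
        with pytest.raises(CurationError, match="22"):
            scan_series(series_of([bad]))


class TestPadTables:
    def test_row_counts_equalized(self):
        series = series_of(simple_tables(drop={22: 4}))
        padded = pad_tables(series)
        counts = {len(t) for t in padded.tables}
        assert counts == {4}

    def test_carry_last_copies_last_measured_values(self):
        series = series_of(simple_tables(drop={22: 5}))
        padded = pad_tables(series)
        src = series.tables[3].frame.set_index("residue_number")
        for i in (4, 5, 6):   # points 5..7, 0-based
            frame = padded.tables[i].frame.set_index("residue_number")
            assert frame.loc[22, "status"] == "missing"
            assert frame.loc[22, "shift_f1"] == src.loc[22, "shift_f1"]
            assert frame.loc[22, "height"] == src.loc[22, "height"]

    def test_carry_is_causal_never_from_later_points(self):
        # residue absent at points 1-2, measured from point 3 on:
        # nothing may be copied backwards
        tables = simple_tables()
        for i in (0, 1):
            frame = tables[i].frame
            tables[i] = tables[i].replace_frame(
                frame[frame["residue_number"] != 22])
        padded = pad_tables(series_of(tables))
        for i in (0, 1):
            frame = padded.tables[i].frame.set_index("residue_number")
            assert frame.loc[22, "status"] == "missing"
            assert np.isnan(frame.loc[22, "shift_f1"])

    def test_blank_policy_leaves_observables_empty(self):
        series = series_of(simple_tables(drop={22: 4}))
        padded = pad_tables(series, fill_policy="blank")
        frame = padded.tables[5].frame.set_index("residue_number")
        assert frame.loc[22, "status"] == "missing"
        assert np.isnan(frame.loc[22, "shift_f1"])

    def test_unassigned_rows_are_empty_placeholders(self):
        series = series_of(simple_tables())
        padded = pad_tables(
            series, scan_series(series, sequence={n: "P" if n == 25 else ""
                                                  for n in range(20, 26)}))
        frame = padded.tables[0].frame.set_index("residue_number")
        assert frame.loc[25, "status"] == "unassigned"
        assert frame.loc[25, "residue_type"] == "P"
        assert np.isnan(frame.loc[25, "shift_f1"])

    def test_idempotent(self):
        series = series_of(simple_tables(drop={22: 4}))
        once = pad_tables(series)
        twice = pad_tables(once)
        for a, b in zip(once.tables, twice.tables):
            assert tables_equal(a, b)

    def test_uniform_series_tables_unchanged_apart_from_status(self):
        series = series_of(simple_tables())
        padded = pad_tables(series)
        for orig, new in zip(series.tables, padded.tables):
            assert tables_equal(orig, new)


class TestSequenceSpec:
    def test_range_spec(self):
        seq = parse_sequence_spec("5:9")
        assert sorted(seq) == [5, 6, 7, 8, 9]

    def test_fasta_single_record(self, tmp_path):
        p = tmp_path / "seq.fasta"
        p.write_text(">prot start=3\nMKPT\n")
        seq = parse_sequence_spec(p)
        assert seq == {3: "M", 4: "K", 5: "P", 6: "T"}

    def test_multi_record_fasta_rejected(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">a\nMK\n>b\nPT\n")
        with pytest.raises(CurationError, match="single record"):
            parse_sequence_spec(p)


class TestSidechains:
    def test_nh2_rows_are_flagged_and_segregated(self, tiny_table):
        backbone, side = tag_sidechains(tiny_table, keep=True)
        assert len(side) == 1
        assert side.rows[0].atom_f1 == "ND2a"
        assert len(backbone) == 3
        assert all(not r.is_sidechain for r in backbone)

    def test_backbone_rows_not_flagged(self):
        table = PeaklistTable([PeakRow(1, "A", "N", "H", 120.0, 8.0)])
        backbone, side = tag_sidechains(table)
        assert len(backbone) == 1 and len(side) == 0

    def test_dropping_logs_the_count(self, caplog):
        table = PeaklistTable([
            PeakRow(18, "Q", "ND2a", "HD2a", 112.5, 7.52),
            PeakRow(18, "Q", "ND2b", "HD2b", 112.5, 6.91),
            PeakRow(19, "A", "N", "H", 120.0, 8.0),
        ])
        with caplog.at_level("INFO"):
            backbone, side = tag_sidechains(table, keep=False)
        assert side is None and len(backbone) == 1
        assert any("2 sidechain" in r.message for r in caplog.records)
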