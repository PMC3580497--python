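"""Plate, layout, library and acute-table IO."""

import numpy as np
import pandas as pd
import pytest

from algscreen import plate_io
from algscreen.plate_io import (
    ROLE_COMPOUND,
    ROLE_CONTROL,
    ROLE_EMPTY,
    AcuteReadout,
    PlateFormatError,
    PlateIOWarning,
    PlateLayout,
    PlateParseError,
    WellRole,
    WellSeries,
    canonical_well,
)

from conftest import make_series


@pytest.mark.parametrize(
    "raw,canon",
    [("A1", "A1"), ("A01", "A1"), ("a01", "A1"), ("H12", "H12"), ("P24", "P24")],
)
def test_well_address_canonicalization(raw, canon):
    assert canonical_well(raw) == canon


@pytest.mark.parametrize("bad", ["Q1", "A0", "A25x", "1A", "", "A001"])
def test_invalid_well_addresses_rejected(bad):
    with pytest.raises(ValueError):
        canonical_well(bad)


class TestPlateLayout:
    def test_geometry_bounds_enforced(self):
        wells = {"I1": WellRole(ROLE_CONTROL)}  # row I does not exist on a 96-well plate
        with pytest.raises(PlateFormatError):
            PlateLayout(plate_id="p", wells=wells, geometry=96)
        PlateLayout(plate_id="p", wells=wells, geometry=384)  # fine on 384

    def test_compound_plate_requires_four_controls(self):
        wells = {
            "A1": WellRole(ROLE_COMPOUND, compound_id="c1"),
            "A2": WellRole(ROLE_CONTROL),
        }
        with pytest.raises(PlateFormatError, match="solvent controls"):
            PlateLayout(plate_id="p", wells=wells)

    def test_duplicate_address_via_dialects_rejected(self):
        # "A1" and "A01" are the same physical well
        wells = {"A1": WellRole(ROLE_CONTROL), "A01": WellRole(ROLE_EMPTY)}
        with pytest.raises(PlateFormatError, match="duplicate"):
            PlateLayout(plate_id="p", wells=wells)

    def test_layout_csv_roundtrip(self, full_96_layout, tmp_path):
        path = tmp_path / "layout.csv"
        plate_io.write_layout(full_96_layout, path)
        back = plate_io.read_layout(path, plate_id="P1")
        assert back.wells == full_96_layout.wells


class TestWellSeries:
    def test_requires_matched_lengths_and_monotone_times(self):
        with pytest.raises(ValueError):
            make_series([0, 1, 2], [0.1, 0.2])
        with pytest.raises(ValueError, match="strictly increasing"):
            make_series([0, 0.5, 0.5], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            make_series([0, 1], [0.1, -0.2])
        with pytest.raises(ValueError):
            make_series([0, 1], [0.1, np.nan])


class TestGrowthTable:
    def _write(self, tmp_path, layout, drop=(), extra=(), header=None, bad_cell=None):
        times = header if header is not None else [0.0, 0.5, 1.0, 1.5]
        rows = []
        wells = [w for w in layout.non_empty_wells() if w not in drop] + list(extra)
        for w in sorted(wells):
            od = [0.1 + 0.01 * k for k in range(len(times))]
            rows.append([w] + od)
        df = pd.DataFrame(rows, columns=["well"] + [str(t) for t in times])
        if bad_cell:
            df.iloc[0, 1] = bad_cell
        path = tmp_path / "plate.csv"
        df.to_csv(path, index=False)
        return path

    def test_full_plate_preserves_shape(self, full_96_layout, tmp_path):
        path = self._write(tmp_path, full_96_layout)
        series = plate_io.read_growth_table(path, full_96_layout)
        assert len(series) == 96
        assert all(s.times.size == 4 for s in series)

    def test_missing_well_reported(self, full_96_layout, tmp_path):
        path = self._write(tmp_path, full_96_layout, drop=("H12",))
        with pytest.warns(PlateIOWarning, match="H12"):
            series = plate_io.read_growth_table(path, full_96_layout)
        assert len(series) == 95

    def test_extraneous_well_rejected(self, full_96_layout, tmp_path):
        # H12 present in file twice under both dialects is impossible; instead
        # supply a well the layout does not mention at all
        small = PlateLayout(
            plate_id="p",
            wells={
                "A1": WellRole(ROLE_COMPOUND, compound_id="c1"),
                **{w: WellRole(ROLE_CONTROL) for w in ("A2", "A3", "A4", "A5")},
            },
        )
        path = self._write(tmp_path, small, extra=("B7",))
        with pytest.warns(PlateIOWarning, match="B7"):
            series = plate_io.read_growth_table(path, small)
        assert {s.well for s in series} == {"A1", "A2", "A3", "A4", "A5"}

    def test_non_monotone_header_is_format_error(self, full_96_layout, tmp_path):
        path = self._write(tmp_path, full_96_layout, header=[0.0, 0.5, 0.5, 1.0])
        with pytest.raises(PlateFormatError, match="increasing"):
            plate_io.read_growth_table(path, full_96_layout)

    def test_non_numeric_cell_names_well_and_time(self, full_96_layout, tmp_path):
        path = self._write(tmp_path, full_96_layout, bad_cell="oops")
        with pytest.raises(PlateParseError, match=r"A1.*t=0"):
            plate_io.read_growth_table(path, full_96_layout)

    def test_minutes_header_converted(self, tmp_path):
        layout = PlateLayout(
            plate_id="p",
            wells={
                "A1": WellRole(ROLE_COMPOUND, compound_id="c1"),
                **{w: WellRole(ROLE_CONTROL) for w in ("A2", "A3", "A4", "A5")},
            },
        )
        path = self._write(tmp_path, layout, header=[0, 30, 60, 90])
        series = plate_io.read_growth_table(path, layout, time_unit="minutes")
        assert np.allclose(series[0].times, [0, 0.5, 1.0, 1.5])

    def test_roundtrip_preserves_full_precision(self, tmp_path, rng):
        layout = PlateLayout(
            plate_id="p",
            wells={
                "A1": WellRole(ROLE_COMPOUND, compound_id="c1"),
                **{w: WellRole(ROLE_CONTROL) for w in ("A2", "A3", "A4", "A5")},
            },
        )
        times = np.sort(rng.uniform(0, 80, size=40))
        times += np.arange(40) * 1e-6  # guarantee strict monotonicity
        series = [
            WellSeries(plate_id="p", well=w, times=times, od=rng.uniform(0, 1.5, 40))
            for w in layout.non_empty_wells()
        ]
        path = tmp_path / "rt.csv"
        plate_io.write_growth_table(series, path)
        back = plate_io.read_growth_table(path, layout)
        orig = {s.well: s for s in series}
        for s in back:
            assert np.array_equal(s.times, orig[s.well].times)
            assert np.array_equal(s.od, orig[s.well].od)


class TestCompoundLibrary:
    def test_csv_read_and_rejection_report(self, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text(
            "compound_id,smiles,library\n"
            "C1,CCO,demo\n"
            "C2,not_a_molecule,demo\n"
            "C3,c1ccccc1,demo\n"
            "C4,CC(=O)O,demo\n"
        )
        with pytest.warns(PlateIOWarning, match="C2"):
            load = plate_io.read_compound_library(path)
        assert [r.compound_id for r in load] == ["C1", "C3", "C4"]
        assert load.n_rejected == 1 and load.rejected == ["C2"]
        assert load.records[0].screen_dose_uM == 25.0  # default screening dose

    def test_duplicate_compound_id_is_error(self, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text("compound_id,smiles\nC1,CCO\nC1,CCN\n")
        with pytest.raises(ValueError, match="duplicate"):
            plate_io.read_compound_library(path)

    def test_plain_smiles_file(self, tmp_path):
        path = tmp_path / "lib.smi"
        path.write_text("CCO\tethanol\nc1ccccc1\tbenzene\n")
        load = plate_io.read_compound_library(path)
        assert [r.compound_id for r in load] == ["ethanol", "benzene"]
        assert load.records[0].smiles == "CCO"


class TestAcuteReadout:
    def test_requires_at_least_one_measurement(self):
        with pytest.raises(ValueError, match="no measurement"):
            AcuteReadout(plate_id="p", well="A1")

    def test_table_roundtrip(self, tmp_path):
        rows = [
            AcuteReadout("p", "A1", fluorescence=120.0, phototaxis_score="no_movement",
                         phototaxis_score_2="no_movement", regrew=False),
            AcuteReadout("p", "A2", fluorescence=95.0, phototaxis_score="away_from_light"),
            AcuteReadout("p", "A3", regrew=True),
        ]
        path = tmp_path / "acute.csv"
        plate_io.write_acute_table(rows, path)
        back = plate_io.read_acute_table(path, plate_id="p")
        assert [r.well for r in back] == ["A1", "A2", "A3"]
        assert back[0].regrew is False and back[2].regrew is True
        assert back[1].phototaxis_score == "away_from_light"
        assert back[2].fluorescence is None
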