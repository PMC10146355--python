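"""Filename convention parsing, plate sorting and result writing."""

from __future__ import annotations

import numpy as np
import pytest
import tifffile
from hypothesis import given, strategies as st

from h2axquant.io import (
    EmptyPlateError,
    FieldImage,
    FieldImageRef,
    MalformedFilenameError,
    PlateLayout,
    compose_field_filename,
    parse_field_filename,
    read_field,
    sort_plate,
    write_results,
)
from h2axquant.measure import NucleusRecord


class TestParseFieldFilename:
    @pytest.mark.parametrize(
        "name, channel, well, position",
        [
            ("DAPI_20230101_B8_0003_01.tif", "DAPI", "B8", "0003"),
            ("Cy3_20230101_C4_0016_01.tif", "Cy3", "C4", "0016"),
            ("cy3_20230101_A12_0001_02.tiff", "Cy3", "A12", "0001"),
        ],
    )
    def test_valid_names(self, name, channel, well, position):
        ref = parse_field_filename(name)
        assert (ref.channel, ref.well, ref.position) == (channel, well, position)

    @pytest.mark.parametrize(
        "name",
        [
            "nuclei.tif",                       # token count != 5
            "DAPI_20230101_B8_0003.tif",        # 4 tokens
            "DAPI_2023_01_01_B8_0003_01.tif",   # 6 tokens
            "DAPI_20230101_Z8_0003_01.tif",     # invalid row
            "DAPI_20230101_B13_0003_01.tif",    # invalid column
            "DAPI_20230101_B0_0003_01.tif",     # invalid column
            "GFP_20230101_B8_0003_01.tif",      # unknown channel
            "DAPI_20230101_B8_0003_01",         # no extension
        ],
    )
    def test_malformed_names_raise(self, name):
        with pytest.raises(MalformedFilenameError):
            parse_field_filename(name)

    def test_channel_aliases_are_configurable(self):
        ref = parse_field_filename(
            "Hoechst33342_20230101_B8_0001_01.tif",
            channel_aliases={"Hoechst33342": "DAPI"},
        )
        assert ref.channel == "DAPI"

    @given(
        channel=st.sampled_from(["DAPI", "Cy3"]),
        date_token=st.text(alphabet="0123456789", min_size=1, max_size=9),
        well=st.sampled_from(
            [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]
        ),
        position=st.text(alphabet="0123456789", min_size=1, max_size=4),
        acq_run=st.text(alphabet="0123456789abc", min_size=1, max_size=3),
    )
    def test_compose_parse_round_trip(self, channel, date_token, well, position, acq_run):
        ref = FieldImageRef(channel=channel, date_token=date_token, well=well,
                            position=position, acq_run=acq_run)
        assert parse_field_filename(compose_field_filename(ref)) == ref


def _touch_plate(folder, wells=("B8", "C4"), positions=16):
    names = []
    for well in wells:
        for p in range(1, positions + 1):
            for channel in ("DAPI", "Cy3"):
                names.append(f"{channel}_20230101_{well}_{p:04d}_01.tif")
    for name in names:
        (folder / name).touch()
    return names


class TestSortPlate:
    def test_groups_and_pairs(self, tmp_path):
        _touch_plate(tmp_path)
        wells = sort_plate(tmp_path)
        assert sorted(wells) == ["B8", "C4"]
        for pairs in wells.values():
            assert len(pairs) == 16
            assert all(p.complete for p in pairs)

    def test_invariant_to_creation_order(self, tmp_path, rng):
        (tmp_path / "a").mkdir()
        names = _touch_plate(tmp_path / "a")
        shuffled = list(names)
        rng.shuffle(shuffled)
        (tmp_path / "b").mkdir()
        for name in shuffled:
            (tmp_path / "b" / name).touch()
        a = sort_plate(tmp_path / "a")
        b = sort_plate(tmp_path / "b")
        assert {w: [(p.position, p.complete) for p in ps] for w, ps in a.items()} == {
            w: [(p.position, p.complete) for p in ps] for w, ps in b.items()
        }

    def test_missing_partner_keeps_dapi_flagged_incomplete(self, tmp_path, caplog):
        _touch_plate(tmp_path, wells=("B8",), positions=4)
        (tmp_path / "Cy3_20230101_B8_0002_01.tif").unlink()
        wells = sort_plate(tmp_path)
        pairs = {p.position: p for p in wells["B8"]}
        assert pairs["0002"].dapi is not None and pairs["0002"].cy3 is None
        assert not pairs["0002"].complete
        assert sum(p.complete for p in wells["B8"].__iter__()) == 3

    def test_non_parseable_files_skipped(self, tmp_path):
        _touch_plate(tmp_path, wells=("B8",), positions=2)
        (tmp_path / "notes.txt").touch()
        wells = sort_plate(tmp_path)
        assert list(wells) == ["B8"]

    def test_empty_folder_raises(self, tmp_path):
        (tmp_path / "readme.md").touch()
        with pytest.raises(EmptyPlateError):
            sort_plate(tmp_path)


class TestReadField:
    def test_reads_uint16_tiff_with_calibration(self, tmp_path):
        pixels = np.arange(12, dtype=np.uint16).reshape(3, 4)
        path = tmp_path / "DAPI_20230101_B8_0001_01.tif"
        tifffile.imwrite(path, pixels)
        ref = parse_field_filename(path.name)
        from dataclasses import replace

        img = read_field(replace(ref, path=path), calibration=2.6)
        assert img.bit_depth == 16
        assert img.calibration == 2.6
        np.testing.assert_array_equal(img.pixels, pixels)

    def test_field_image_validates_range(self):
        with pytest.raises(ValueError):
            FieldImage(pixels=np.array([[300]]), bit_depth=8)


class TestPlateLayout:
    def test_control_lookup(self):
        layout = PlateLayout(conditions={"B2": "ctrl", "B4": "val30"}, control="ctrl")
        assert layout.condition_of("B4") == "val30"
        assert layout.control_for("val30") == "ctrl"
        assert layout.treated_conditions == ["val30"]

    def test_control_without_well_rejected(self):
        with pytest.raises(ValueError):
            PlateLayout(conditions={"B2": "val30"}, control="ctrl")


def _records(well="B8", n=3):
    return [
        NucleusRecord(well=well, field="0001", label=i + 1, area_px=10 + i,
                      area_um2=(10 + i) * 6.76, mfv=float(i))
        for i in range(n)
    ]


class TestWriteResults:
    def test_per_well_csv_rows(self, tmp_path):
        paths = write_results(_records(n=3), [], tmp_path)
        lines = paths["objects_B8"].read_text().strip().splitlines()
        assert len(lines) == 4  # header + 3 rows

    def test_empty_records_header_only(self, tmp_path):
        paths = write_results([], [], tmp_path)
        lines = paths["objects_empty"].read_text().strip().splitlines()
        assert len(lines) == 1

    def test_rerun_is_byte_identical_except_log_timestamp(self, tmp_path):
        a = write_results(_records(), [], tmp_path / "a", log_lines=["x"])
        b = write_results(_records(), [], tmp_path / "b", log_lines=["x"])
        assert a["objects_B8"].read_bytes() == b["objects_B8"].read_bytes()
        strip = lambda p: [
            l for l in p.read_text().splitlines() if not l.startswith("timestamp")
        ]
        assert strip(a["run_log"]) == strip(b["run_log"])
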