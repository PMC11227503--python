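"""Archive schema: calendar, fixture, I/O round trips, integrity rules."""

import numpy as np
import pandas as pd
import pytest

from pspcensus.schema import (MISSING_CAMPAIGN_YEARS, ReferentialIntegrityError,
                              SchemaError, archives_equal,
                              decimal_year, default_campaign_years,
                              load_valuable_species_fixture, read_archive,
                              validate_archive, write_archive)
from tests.conftest import build_archive, mrow


class TestCalendar:
    def test_default_calendar_has_35_campaigns(self):
        years = default_campaign_years()
        assert len(years) == 35
        assert years[0] == 1982 and years[-1] == 2022

    def test_skipped_years_absent(self):
        years = set(default_campaign_years())
        assert years.isdisjoint(MISSING_CAMPAIGN_YEARS)
        assert MISSING_CAMPAIGN_YEARS == {1997, 1999, 2001, 2013, 2014, 2016}

    def test_decimal_year_midmay(self):
        t = decimal_year(pd.Timestamp("2000-05-15"))
        assert 2000.36 < t < 2000.38


class TestValuableSpeciesFixture:
    def test_counts(self):
        fx = load_valuable_species_fixture()
        assert len(fx) == 36
        assert (fx["category"] == "A").sum() == 15
        assert (fx["category"] == "B").sum() == 21

    def test_codes_sequential(self):
        fx = load_valuable_species_fixture()
        assert list(fx["code"]) == [f"{i:02d}" for i in range(1, 37)]

    def test_known_members(self):
        fx = load_valuable_species_fixture().set_index("species")
        assert fx.loc["Entandrophragma cylindricum", "category"] == "A"
        assert fx.loc["Triplochiton scleroxylon", "category"] == "B"
        assert fx.loc["Chlorophora excelsa", "valid_name"] == \
            "Milicia excelsa"


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, small_stand):
        _, archive, _ = small_stand
        write_archive(archive, tmp_path / "a")
        back = read_archive(tmp_path / "a")
        assert archives_equal(archive, back)

    def test_double_write_byte_identical(self, tmp_path, small_stand):
        _, archive, _ = small_stand
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_archive(archive, d1)
        write_archive(read_archive(d1), d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_empty_archive_round_trips(self, tmp_path):
        archive = build_archive([mrow(year=2000, dbh=20.0)], [2000])
        archive.measures = archive.measures.iloc[:0]
        archive.tree = archive.tree.iloc[:0]
        write_archive(archive, tmp_path / "e")
        names = {p.name for p in (tmp_path / "e").iterdir()}
        assert len(names) == 10
        back = read_archive(tmp_path / "e")
        assert len(back.measures) == 0 and len(back.tree) == 0
        assert not validate_archive(back)

    def test_missing_file_named_in_error(self, tmp_path, small_stand):
        _, archive, _ = small_stand
        write_archive(archive, tmp_path / "a")
        (tmp_path / "a" / "measures.csv").unlink()
        with pytest.raises(SchemaError, match="measures.csv"):
            read_archive(tmp_path / "a")

    def test_dangling_measure_fk_raises(self, tmp_path):
        archive = build_archive([mrow(tree=1, year=2000, dbh=20.0)], [2000])
        extra = archive.measures.iloc[[0]].assign(tree_no=999)
        archive.measures = pd.concat([archive.measures, extra],
                                     ignore_index=True)
        write_archive(archive, tmp_path / "a")
        with pytest.raises(ReferentialIntegrityError):
            read_archive(tmp_path / "a")

    def test_ascii_enforced_on_write(self, tmp_path):
        archive = build_archive([mrow(year=2000, dbh=20.0)], [2000])
        archive.taxonomy.loc[0, "sci_name"] = "Lovoa trichilioïdes"
        with pytest.raises(SchemaError, match="sci_name"):
            write_archive(archive, tmp_path / "a")


class TestValidation:
    def test_clean_synthetic_archive_validates(self, small_stand):
        _, archive, _ = small_stand
        assert validate_archive(archive) == []

    def test_coordinate_out_of_range(self):
        archive = build_archive([mrow(year=2000, dbh=20.0)], [2000])
        archive.tree.loc[0, "x_m"] = 250.0
        v = validate_archive(archive)
        assert any(x.rule_id == "COORD_RANGE" and "250" in x.detail
                   for x in v)

    def test_alive_with_mortality_code(self):
        rows = [mrow(year=2000, dbh=20.0, status="alive",
                     mort="standing_death")]
        v = validate_archive(build_archive(rows, [2000]))
        assert any(x.rule_id == "MORTALITY_STATUS_MISMATCH" for x in v)

    def test_recruit_below_threshold_flagged_in_corrected_only(self):
        rows = [mrow(year=2000, dbh=9.8, status="alive")]
        raw = build_archive(rows, [2000])
        assert not any(x.rule_id == "RECRUIT_BELOW_THRESHOLD"
                       for x in validate_archive(raw))
        corrected = build_archive(rows, [2000])
        corrected.measures["provenance"] = "raw"
        v = validate_archive(corrected)
        assert any(x.rule_id == "RECRUIT_BELOW_THRESHOLD" for x in v)

    def test_corrected_method_in_raw_archive(self):
        rows = [mrow(year=2000, dbh=20.0, method="interpolated")]
        v = validate_archive(build_archive(rows, [2000]))
        assert any(x.rule_id == "METHOD_CORRECTED_IN_RAW" for x in v)

    def test_wrong_valuable_category_detected(self):
        archive = build_archive([mrow(year=2000, dbh=20.0)], [2000])
        archive.taxonomy.loc[0, "valuable_category"] = "C"  # fixture says A
        v = validate_archive(archive)
        assert any(x.rule_id == "VALUABLE_CATEGORY_MISMATCH" for x in v)


class TestGeometry:
    def test_plot_and_subplot_areas(self, small_stand):
        _, archive, _ = small_stand
        for p in archive.plots:
            assert abs(p.area_m2() - 40000.0) <= 40.0
        for s in archive.subplots:
            assert abs(s.area_m2() - 10000.0) <= 10.0

    def test_subplots_partition_plot(self, small_stand):
        _, archive, _ = small_stand
        from shapely.geometry import Polygon
        from shapely.ops import unary_union
        for p in archive.plots:
            parts = [Polygon(s.local_ring()) for s in archive.subplots
                     if s.plot_no == p.plot_no]
            union = unary_union(parts)
            assert abs(union.area - Polygon(p.local_ring()).area) < 1.0

    def test_three_control_plots_sum_12_ha(self):
        from pspcensus.simulate import SimulationConfig, simulate_archive
        cfg = SimulationConfig(seed=0, n_plots=3, initial_density_per_ha=5,
                               campaign_years=(1982, 1983))
        archive, _ = simulate_archive(cfg)
        controls = [p for p in archive.plots if p.treatment == "control"]
        assert len(controls) == 3
        assert sum(p.area_ha for p in controls) == pytest.approx(12.0)
        assert sum(p.area_m2() for p in controls) == pytest.approx(
            120000.0, rel=1e-3)
        assert {p.block for p in controls} == \
            {"Boukoko1", "Boukoko2", "LaLole"}
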