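"""Band functions, postal-code resolution, fixtures and CSV round-trips."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import betternest as bn


# Every printed threshold, both sides, plus interior points — the table-driven
# oracle for the half-open band convention ([lower, upper), top band closed).
LEAD_EDGE_CASES = [
    (0.0, 9), (35.0, 9), (41.04, 9),
    (41.05, 7), (45.0, 7), (50.29, 7),
    (50.3, 5), (55.0, 5), (58.79, 5),
    (58.8, 3), (60.0, 3), (69.29, 3),
    (69.3, 1), (75.0, 1), (100.0, 1),
]

AIR_EDGE_CASES = [
    (0.0, 9), (10.0, 9), (11.99, 9),
    (12.0, 5), (13.5, 5), (15.0, 5),
    (15.01, 1), (16.2, 1), (40.0, 1),
]


class TestBands:
    @pytest.mark.parametrize("pct,expected", LEAD_EDGE_CASES)
    def test_lead_band_edges(self, pct, expected):
        assert bn.lead_subscore(pct) == expected

    @pytest.mark.parametrize("pm25,expected", AIR_EDGE_CASES)
    def test_air_band_edges(self, pm25, expected):
        assert bn.air_subscore(pm25) == expected

    def test_lead_monotone_and_surjective_on_dense_grid(self):
        grid = [i / 100 for i in range(0, 10001)]  # 0.00 .. 100.00
        scores = [bn.lead_subscore(x) for x in grid]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert set(scores) == {9, 7, 5, 3, 1}

    def test_air_monotone_and_surjective_on_dense_grid(self):
        grid = [i / 100 for i in range(0, 4001)]  # 0.00 .. 40.00
        scores = [bn.air_subscore(x) for x in grid]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert set(scores) == {9, 5, 1}

    @pytest.mark.parametrize("bad", [-0.1, 100.1, math.nan, math.inf])
    def test_lead_domain_errors(self, bad):
        with pytest.raises(ValueError):
            bn.lead_subscore(bad)

    @pytest.mark.parametrize("bad", [-0.1, math.nan, math.inf])
    def test_air_domain_errors(self, bad):
        with pytest.raises(ValueError):
            bn.air_subscore(bad)

    @settings(derandomize=True, max_examples=200)
    @given(a=st.floats(0, 100), b=st.floats(0, 100))
    def test_lead_monotone_property(self, a, b):
        lo, hi = sorted((a, b))
        assert bn.lead_subscore(lo) >= bn.lead_subscore(hi)


class TestResolve:
    def test_lookup_identity(self, single_county_geo):
        rec = bn.resolve("07043", single_county_geo)
        assert rec.county_id == "essex"

    def test_unknown_postal_code_is_hard_error(self, single_county_geo):
        with pytest.raises(bn.UnknownPostalCode, match="99999"):
            bn.resolve("99999", single_county_geo)

    def test_every_generated_code_resolves(self, geo):
        for postal in geo.crosswalk:
            assert bn.resolve(postal, geo).county_id == geo.crosswalk[postal]


class TestFixtureGenerator:
    def test_deterministic_per_seed(self):
        a = bn.generate_fixture(15, seed=7)
        b = bn.generate_fixture(15, seed=7)
        assert a.counties == b.counties and a.crosswalk == b.crosswalk
        c = bn.generate_fixture(15, seed=8)
        assert c.counties != a.counties

    def test_all_bands_covered_at_15_counties(self):
        g = bn.generate_fixture(15, seed=7)
        lead_bands = {bn.lead_subscore(c.pct_pre1980_housing) for c in g.counties.values()}
        air_bands = {bn.air_subscore(c.pm25_annual) for c in g.counties.values()}
        assert lead_bands == {9, 7, 5, 3, 1}
        assert air_bands == {9, 5, 1}

    def test_single_county_table_valid(self):
        g = bn.generate_fixture(1, seed=0)
        assert len(g.counties) == 1
        assert set(g.crosswalk.values()) == set(g.counties)

    def test_every_county_has_a_postal_code(self, geo):
        assert set(geo.crosswalk.values()) == set(geo.counties)

    def test_rejects_zero_counties(self):
        with pytest.raises(ValueError):
            bn.generate_fixture(0, seed=1)


class TestCsvRoundTrip:
    def test_write_then_load_is_lossless(self, geo, tmp_path):
        bn.write_geotable(geo, tmp_path)
        loaded = bn.load_geotable(tmp_path)
        assert loaded.counties == geo.counties
        assert loaded.crosswalk == geo.crosswalk

    def test_leading_zero_zips_preserved(self, tmp_path):
        county = bn.CountyRecord("c1", 30.0, 8.0)
        g = bn.GeoTable(counties={"c1": county}, crosswalk={"00042": "c1"})
        bn.write_geotable(g, tmp_path)
        assert "00042" in bn.load_geotable(tmp_path).crosswalk

    def test_dangling_crosswalk_detected(self, tmp_path):
        (tmp_path / "counties.csv").write_text(
            "county_id,pct_pre1980_housing,pm25_annual\nc1,30.0,8.0\n"
        )
        (tmp_path / "crosswalk.csv").write_text("postal_code,county_id\n07043,cX\n")
        with pytest.raises(bn.DanglingCrosswalk, match="cX"):
            bn.load_geotable(tmp_path)

    def test_header_only_counties_file(self, tmp_path):
        (tmp_path / "counties.csv").write_text("county_id,pct_pre1980_housing,pm25_annual\n")
        (tmp_path / "crosswalk.csv").write_text("postal_code,county_id\n")
        with pytest.raises(bn.MalformedGeoCSV, match="no county rows"):
            bn.load_geotable(tmp_path)

    def test_out_of_range_value_names_row(self, tmp_path):
        (tmp_path / "counties.csv").write_text(
            "county_id,pct_pre1980_housing,pm25_annual\nc1,30.0,8.0\nc2,130.0,8.0\n"
        )
        (tmp_path / "crosswalk.csv").write_text("postal_code,county_id\n")
        with pytest.raises(bn.MalformedGeoCSV, match="row 2"):
            bn.load_geotable(tmp_path)

    def test_missing_files(self, tmp_path):
        with pytest.raises(bn.MalformedGeoCSV, match="not found"):
            bn.load_geotable(tmp_path)

    def test_duplicate_postal_code_rejected(self, tmp_path):
        (tmp_path / "counties.csv").write_text(
            "county_id,pct_pre1980_housing,pm25_annual\nc1,30.0,8.0\n"
        )
        (tmp_path / "crosswalk.csv").write_text(
            "postal_code,county_id\n07043,c1\n07043,c1\n"
        )
        with pytest.raises(bn.MalformedGeoCSV, match="duplicate postal"):
            bn.load_geotable(tmp_path)
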