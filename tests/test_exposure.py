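import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestmix.catalog import PesticideInfo
from pestmix.exposure import (
    ExposureConfig,
    ExposureWindow,
    Residence,
    SectionApplication,
    Station,
    WindRose,
    area_fraction_in_buffer,
    compute_window_exposure,
    log2_transform,
    nearest_station,
    postnatal_window,
    prenatal_window,
    sector_of_bearing,
    select_pesticides,
    window_wind_frequency,
)

JAN1 = dt.date(2000, 1, 1)
DEC31 = dt.date(2000, 12, 31)
UNIFORM = (0.125,) * 8


def rose(day, freq=UNIFORM, station="A", x=0.0, y=0.0):
    return WindRose(station, x, y, day, freq)


def app(kg, cx=0.0, cy=0.0, day=dt.date(2000, 6, 1), pesticide="chlorpyrifos", side=100.0):
    return SectionApplication("S1", cx, cy, day, pesticide, kg, side)


class TestSectorOfBearing:
    @pytest.mark.parametrize(
        "dx,dy,expected",
        [
            (0, 1000, 0),  # due north
            (1000, 0, 2),  # due east
            (0, -1000, 4),  # due south
            (-1000, 0, 6),  # due west
            (707, 707, 1),  # bearing 45 deg -> NE
            (707, -707, 3),  # SE
            (-707, -707, 5),  # SW
            (-707, 707, 7),  # NW
            (0, 0, 0),  # coincident centroid maps to N by convention
        ],
    )
    def test_axis_and_diagonal_cases(self, dx, dy, expected):
        assert sector_of_bearing(dx, dy) == expected

    @given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_interval_check(self, dx, dy):
        """The returned sector's 45-degree interval contains the bearing."""
        if dx == 0 and dy == 0:
            return
        bearing = math.degrees(math.atan2(dx, dy)) % 360.0
        k = sector_of_bearing(dx, dy)
        lo = (45.0 * k - 22.5) % 360.0
        width = (bearing - lo) % 360.0
        assert 0 <= width < 45.0


class TestAreaFraction:
    def test_fully_contained_section(self, home):
        assert area_fraction_in_buffer(app(1, side=100.0), home, 1000.0) == 1.0

    def test_disjoint_section(self, home):
        far = app(1, cx=10_000.0, cy=0.0, side=1609.0)
        assert area_fraction_in_buffer(far, home, 1000.0) == 0.0

    def test_inscribed_circle_closed_form(self, home):
        """Disc inscribed in the section: fraction is pi r^2 / s^2 = pi/4."""
        sec = app(1, side=2000.0)
        frac = area_fraction_in_buffer(sec, home, 1000.0)
        assert frac == pytest.approx(math.pi / 4.0, abs=1e-4)

    def test_agrees_with_monte_carlo(self, home, rng):
        """Random partially-overlapping squares vs point-in-disc sampling."""
        for _ in range(5):
            cx, cy = rng.uniform(-1500, 1500, 2)
            side = rng.uniform(300, 2500)
            sec = app(1, cx=cx, cy=cy, side=side)
            frac = area_fraction_in_buffer(sec, home, 1000.0)
            pts = rng.uniform(-0.5, 0.5, (100_000, 2)) * side + [cx, cy]
            mc = (np.hypot(pts[:, 0], pts[:, 1]) <= 1000.0).mean()
            assert frac == pytest.approx(mc, abs=0.005)


class TestWindFrequency:
    def test_constant_uniform_days(self, year_window):
        roses = [rose(JAN1 + dt.timedelta(days=i)) for i in range(30)]
        freq = window_wind_frequency(roses, year_window, "A")
        np.testing.assert_allclose(freq, UNIFORM)

    def test_two_point_mean(self, year_window):
        roses = [
            rose(JAN1, (1, 0, 0, 0, 0, 0, 0, 0)),
            rose(dt.date(2000, 1, 2), (0, 1, 0, 0, 0, 0, 0, 0)),
        ]
        freq = window_wind_frequency(roses, year_window, "A")
        np.testing.assert_allclose(freq, [0.5, 0.5, 0, 0, 0, 0, 0, 0])

    def test_random_simplex_mean_sums_to_one(self, year_window, rng):
        days = [JAN1 + dt.timedelta(days=i) for i in range(30)]
        sims = rng.dirichlet(np.ones(8), size=30)
        roses = [rose(d, tuple(f)) for d, f in zip(days, sims)]
        freq = window_wind_frequency(roses, year_window, "A")
        np.testing.assert_allclose(freq, sims.mean(axis=0))
        assert freq.sum() == pytest.approx(1.0, abs=1e-9)

    def test_out_of_window_records_rejected(self, year_window):
        roses = [rose(dt.date(1999, 6, 1))]
        with pytest.raises(ValueError, match="no wind records"):
            window_wind_frequency(roses, year_window, "A")


class TestNearestStation:
    def test_closest_and_tie_rule(self, home):
        stations = [Station("B", 1000, 0), Station("C", 5000, 0)]
        assert nearest_station(home, stations) == "B"
        tied = [Station("B", 1000, 0), Station("A", 0, 1000)]
        assert nearest_station(home, tied) == "A"
        with pytest.raises(ValueError):
            nearest_station(home, [])


class TestComputeWindowExposure:
    def make_roses(self, freq=UNIFORM):
        return [rose(JAN1 + dt.timedelta(days=i), freq) for i in range(366)]

    def test_hand_computed_chain(self, home, year_window):
        """10 kg fully in buffer under uniform wind: 10 * 1 * 1/8 = 1.25 kg."""
        rec = compute_window_exposure(
            [home], [app(10.0)], self.make_roses(), year_window, "chlorpyrifos"
        )
        assert rec.raw_kg == pytest.approx(1.25)
        assert rec.log2_use == pytest.approx(math.log2(2.25), abs=1e-9)

    def test_no_applications_gives_zero(self, home, year_window):
        rec = compute_window_exposure([home], [], self.make_roses(), year_window, "chlorpyrifos")
        assert rec.raw_kg == 0.0 and rec.log2_use == 0.0

    def test_doubling_limit_property(self, home, year_window):
        """Doubling kilograms adds ~1 on the log2 scale for large exposures."""
        roses = self.make_roses()
        small = compute_window_exposure([home], [app(1e4)], roses, year_window, "chlorpyrifos")
        big = compute_window_exposure([home], [app(2e4)], roses, year_window, "chlorpyrifos")
        assert big.log2_use - small.log2_use == pytest.approx(1.0, abs=1e-3)
        assert big.raw_kg == pytest.approx(2.0 * small.raw_kg)

    def test_uniform_wind_equals_unweighted_sum_over_8(self, home, year_window):
        apps = [app(kg, cx=dx) for kg, dx in [(10, 0), (7, 300), (3, -400)]]
        rec = compute_window_exposure([home], apps, self.make_roses(), year_window, "chlorpyrifos")
        unweighted = sum(
            a.kilograms * area_fraction_in_buffer(a, home, 1000.0) for a in apps
        )
        assert rec.raw_kg == pytest.approx(unweighted / 8.0)

    def test_times8_scale_restores_unweighted_total(self, home, year_window):
        cfg = ExposureConfig(wind_weight_scale="times8")
        rec = compute_window_exposure(
            [home], [app(10.0)], self.make_roses(), year_window, "chlorpyrifos", config=cfg
        )
        assert rec.raw_kg == pytest.approx(10.0)

    def test_nonuniform_wind_weights_by_sector(self, home, year_window):
        northerly = (1.0, 0, 0, 0, 0, 0, 0, 0)
        roses = self.make_roses(northerly)
        north = compute_window_exposure(
            [home], [app(10.0, cy=500.0)], roses, year_window, "chlorpyrifos"
        )
        east = compute_window_exposure(
            [home], [app(10.0, cx=500.0)], roses, year_window, "chlorpyrifos"
        )
        assert north.raw_kg == pytest.approx(10.0)
        assert east.raw_kg == 0.0

    def test_multiple_residences_day_of_application_attribution(self, year_window):
        res = [
            Residence("P1", 0, 0, JAN1, dt.date(2000, 6, 30)),
            Residence("P1", 50_000, 0, dt.date(2000, 7, 1), DEC31),
        ]
        apps = [
            app(10.0, day=dt.date(2000, 3, 1)),  # near first home while occupied
            app(10.0, day=dt.date(2000, 9, 1)),  # near first home after moving away
        ]
        rec = compute_window_exposure(res, apps, self.make_roses(), year_window, "chlorpyrifos")
        assert rec.raw_kg == pytest.approx(1.25)

    def test_application_outside_occupancy_skipped(self, year_window, caplog):
        res = [Residence("P1", 0, 0, JAN1, dt.date(2000, 3, 31))]
        window = ExposureWindow("P1", "prenatal", JAN1, DEC31)
        apps = [app(10.0, day=dt.date(2000, 6, 1))]
        with caplog.at_level("INFO", logger="pestmix.exposure"):
            rec = compute_window_exposure(res, apps, self.make_roses(), window, "chlorpyrifos")
        assert rec.raw_kg == 0.0
        assert any("skipped 1" in m for m in caplog.messages)

    @given(st.floats(0.1, 1e5), st.floats(1.01, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_homogeneity_in_kilograms(self, kg, scale):
        home = Residence("P1", 0.0, 0.0, JAN1, DEC31)
        window = ExposureWindow("P1", "prenatal", JAN1, DEC31)
        roses = [rose(JAN1 + dt.timedelta(days=i)) for i in range(366)]
        base = compute_window_exposure([home], [app(kg)], roses, window, "chlorpyrifos")
        scaled = compute_window_exposure([home], [app(kg * scale)], roses, window, "chlorpyrifos")
        assert scaled.raw_kg == pytest.approx(scale * base.raw_kg, rel=1e-9)


class TestLog2Transform:
    @given(st.one_of(st.just(0.0), st.floats(1e-6, 1e9)))
    @settings(max_examples=100, deadline=None)
    def test_zero_iff_zero_and_monotone(self, x):
        v = log2_transform(x)
        assert v >= 0
        assert (v == 0) == (x == 0)
        assert log2_transform(x + 1.0) > v


class TestSelectPesticides:
    def catalog(self):
        def pest(name, cls, neurotoxic, kg):
            return PesticideInfo(name, cls, neurotoxic, None, None, kg, kg)

        return [
            pest("keeper", "carbamate", True, 30_000),
            pest("low_use", "carbamate", True, 4_000),
            pest("rare", "pyrethroid", True, 30_000),
            pest("benign", "herbicide", False, 100_000),
        ]

    def exposures(self, coverage):
        rows = []
        n = 100
        for pest, cov in coverage.items():
            for i in range(n):
                rows.append((f"P{i}", "prenatal", pest, 1.0 if i < cov * n else 0.0, 0.0))
        return pd.DataFrame(
            rows, columns=["participant_id", "window", "pesticide", "raw_kg", "log2_use"]
        )

    def test_three_criteria_jointly_enforced(self):
        exp = self.exposures({"keeper": 0.9, "low_use": 0.9, "rare": 0.49, "benign": 1.0})
        selected = select_pesticides(self.catalog(), exp, 4500.0, 0.5)
        assert selected == ["keeper"]

    def test_coverage_boundary_is_inclusive(self):
        exp = self.exposures({"keeper": 0.5})
        assert select_pesticides(self.catalog(), exp, 4500.0, 0.5) == ["keeper"]

    def test_empty_catalog(self):
        assert select_pesticides([], self.exposures({}), 4500.0, 0.5) == []


class TestWindows:
    def test_prenatal_spans_273_days_to_birth(self):
        w = prenatal_window("P1", dt.date(2000, 10, 1))
        assert (w.end_date - w.start_date).days == 273
        assert w.end_date == dt.date(2000, 10, 1)

    def test_postnatal_spans_birth_to_fifth_birthday(self):
        w = postnatal_window("P1", dt.date(2000, 10, 1))
        assert w.start_date == dt.date(2000, 10, 1)
        assert w.end_date == dt.date(2005, 10, 1)


class TestValidation:
    def test_wind_rose_must_sum_to_one(self):
        with pytest.raises(ValueError):
            WindRose("A", 0, 0, JAN1, (0.5, 0.5, 0.1, 0, 0, 0, 0, 0))

    def test_negative_kilograms_rejected(self):
        with pytest.raises(ValueError):
            SectionApplication("S", 0, 0, JAN1, "x", -1.0, 100.0)

    def test_reversed_occupancy_rejected(self):
        with pytest.raises(ValueError):
            Residence("P", 0, 0, DEC31, JAN1)
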