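"""Data model, table I/O and preprocessing rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from commocc import occdata
from commocc.occdata import (DetectionHistory, SurveyDesign,
                             aggregate_site_lulc, center_coordinates,
                             filter_species, partition_route,
                             read_detection_tables, screen_covariates,
                             write_detection_tables)
from commocc.synth import default_design, simulate_community, simulate_landscape, moderate_truth


class TestPartitionRoute:
    @pytest.mark.parametrize("ppr,pps,n_sites,point,site", [
        (30, 5, 6, 7, 2),     # standard design: point 7 falls in site 2
        (5, 5, 1, 3, 1),      # single-site route
        (30, 3, 10, 30, 10),  # finer partition: last point in last site
    ])
    def test_consecutive_grouping(self, ppr, pps, n_sites, point, site):
        sites = partition_route(ppr, pps)
        assert sites.max() == n_sites
        assert sites[point - 1] == site

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError, match="30.*not divisible.*7|7"):
            partition_route(30, 7)


class TestSurveyDesign:
    def test_derived_quantities(self):
        d = default_design(n_routes=3, n_years=2)
        assert d.sites_per_route == 6
        assert d.n_sites == 18
        assert d.surveyed_matrix().all()

    def test_undeclared_route_year_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            SurveyDesign(routes=("A",), years=(2003,),
                         route_years=frozenset({("B", 2003)}))

    def test_ragged_design_marks_unsurveyed(self):
        d = default_design(n_routes=6, n_years=3, ragged=True)
        sv = d.surveyed_matrix()
        assert not sv[:, 0].all()      # some routes phased in later
        assert sv[:, -1].all()         # all routes active at the end


class TestDetectionTables:
    def _frame(self, detections, routes=("R1", "R2"), years=(2003,),
               species=("spA", "spB"), ppr=30):
        rows = []
        for r in routes:
            for yr in years:
                for p in range(1, ppr + 1):
                    for s in species:
                        rows.append({"route": r, "point": p, "year": yr,
                                     "species": s,
                                     "detection": detections.get((r, p, yr, s), 0)})
        return pd.DataFrame(rows)

    def test_single_detection_transcribed(self, tmp_path):
        df = self._frame({("R1", 7, 2003, "spA"): 1})
        path = tmp_path / "det.csv"
        df.to_csv(path, index=False)
        hist = read_detection_tables([path])
        assert np.nansum(hist.y) == 1
        # point 7 -> site 2 of route R1 (global site index 1), point slot 1
        assert hist.y[1, 1, hist.species.index("spA"), 0] == 1

    def test_unsurveyed_route_year_is_missing_not_zero(self, tmp_path):
        df = self._frame({}, routes=("R1",), years=(2004,))
        extra = self._frame({}, routes=("R2",), years=(2003, 2004))
        path = tmp_path / "det.csv"
        pd.concat([df, extra]).to_csv(path, index=False)
        hist = read_detection_tables([path])
        t2003 = hist.design.years.index(2003)
        r1_sites = slice(0, 6)
        assert np.isnan(hist.y[r1_sites, :, :, t2003]).all()
        assert not np.isnan(hist.y[r1_sites, :, :, 1]).any()

    def test_non_binary_value_rejected_with_location(self, tmp_path):
        df = self._frame({("R1", 3, 2003, "spA"): 2})
        path = tmp_path / "det.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="non-binary"):
            read_detection_tables([path])

    def test_duplicate_record_rejected(self, tmp_path):
        df = self._frame({})
        dup = pd.concat([df, df.iloc[[0]]])
        path = tmp_path / "det.csv"
        dup.to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_detection_tables([path])

    def test_roundtrip_identity(self, tmp_path):
        design = default_design(n_routes=3, n_years=2, ragged=True)
        site_cov, point_cov = simulate_landscape(design, seed=7)
        bundle = simulate_community(design, site_cov, point_cov,
                                    moderate_truth(), n_species=4, seed=8)
        path = tmp_path / "det.csv"
        write_detection_tables(bundle.history, path)
        back = read_detection_tables([path])
        np.testing.assert_array_equal(back.y, bundle.history.y)
        assert back.species == bundle.history.species

    def test_covariate_roundtrip(self, tmp_path):
        design = default_design(n_routes=2, n_years=2)
        site_cov, point_cov = simulate_landscape(design, seed=9)
        occdata.write_site_covariates(site_cov, design, tmp_path / "sc.csv")
        occdata.write_point_covariates(point_cov, design, tmp_path / "pc.csv")
        sc2 = occdata.read_site_covariates(tmp_path / "sc.csv", design)
        pc2 = occdata.read_point_covariates(tmp_path / "pc.csv", design)
        np.testing.assert_allclose(sc2.soy, site_cov.soy, atol=1e-12)
        np.testing.assert_allclose(sc2.lat, site_cov.lat, atol=1e-12)
        np.testing.assert_allclose(pc2.p_fors, point_cov.p_fors, atol=1e-12)


class TestAggregateSiteLulc:
    def test_fully_classified_single_category(self):
        props = np.zeros((5, 4))
        props[:, 0] = 1.0
        out = aggregate_site_lulc(props)
        assert out[0] == pytest.approx(1.0)

    def test_mean_of_fully_classified_points(self):
        props = np.zeros((5, 2))
        props[:, 0] = [0.2, 0.4, 0.6, 0.8, 1.0]
        props[:, 1] = 1 - props[:, 0]
        assert aggregate_site_lulc(props)[0] == pytest.approx(0.6)

    def test_renormalization_by_classified_cover(self):
        # one fully classified point, one half classified
        props = np.array([[0.5, 0.5], [0.25, 0.25]])
        out = aggregate_site_lulc(props)
        assert out[0] == pytest.approx(0.75 / 1.5)

    def test_no_cover_marks_missing(self):
        out = aggregate_site_lulc(np.zeros((5, 3)))
        assert np.isnan(out).all()

    @given(st.integers(0, 2 ** 31 - 1))
    def test_output_sums_to_one_when_cover_recorded(self, seed):
        r = np.random.default_rng(seed)
        props = r.random((5, 4)) / 4
        out = aggregate_site_lulc(props)
        assert out.sum() == pytest.approx(1.0)
        assert ((out >= 0) & (out <= 1)).all()


class TestScreenCovariates:
    def test_duplicated_covariate_lower_mean_discarded(self, rng):
        a = rng.random(100)
        df = pd.DataFrame({"hi": a + 0.3, "lo": a})
        retained, report = screen_covariates(df)
        assert retained == ["hi"]
        assert report.iloc[0]["covariate"] == "lo"

    def test_orthogonal_covariates_all_retained(self, rng):
        df = pd.DataFrame(rng.random((500, 4)), columns=list("abcd"))
        retained, _ = screen_covariates(df)
        assert retained == list("abcd")

    def test_negative_correlation_lower_represented_discarded(self, rng):
        # mirrors discarding a category built as the complement of soybean
        soy = rng.random(200) * 0.8
        other_past = 0.9 - soy + 0.03 * rng.standard_normal(200)
        df = pd.DataFrame({"soy": soy + 0.6, "other_past": other_past})
        retained, report = screen_covariates(df)
        assert retained == ["soy"]
        assert report.iloc[0]["r"] < -0.9

    def test_zero_variance_discarded_with_reason(self, rng):
        df = pd.DataFrame({"flat": np.ones(50), "ok": rng.random(50),
                           "ok2": rng.random(50)})
        retained, report = screen_covariates(df)
        assert "flat" not in retained
        assert "zero variance" in report.iloc[0]["reason"]

    def test_order_independent(self, rng):
        a = rng.random(300)
        df = pd.DataFrame({"x": a + 0.2, "y": a, "z": rng.random(300)})
        r1, _ = screen_covariates(df)
        r2, _ = screen_covariates(df[["z", "y", "x"]])
        assert set(r1) == set(r2)


class TestFilterSpecies:
    def _hist(self, totals, n_sites=60, k=5, n_years=2):
        design = default_design(n_routes=n_sites // 6, n_years=n_years)
        y = np.zeros((n_sites, k, len(totals), n_years))
        for i, tot in enumerate(totals):
            flat = y[:, :, i, :].reshape(-1)
            flat[:tot] = 1.0
            y[:, :, i, :] = flat.reshape(n_sites, k, n_years)
        return DetectionHistory(y=y, species=tuple(f"s{i}" for i in range(len(totals))),
                                design=design)

    def test_threshold_boundary_inclusive(self):
        hist = self._hist([199, 200, 201])
        assert filter_species(hist, min_obs=200) == ["s1", "s2"]

    def test_all_zero_species_excluded(self):
        hist = self._hist([0, 10])
        assert filter_species(hist, min_obs=1) == ["s1"]

    def test_min_obs_must_be_positive(self):
        with pytest.raises(ValueError):
            filter_species(self._hist([5]), min_obs=0)


class TestCenterCoordinates:
    def test_constant_axis_maps_to_zero(self):
        out = center_coordinates(np.full((4, 2), -33.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_two_point_example(self):
        out = center_coordinates(np.array([[-34.0], [-32.0]]))
        np.testing.assert_allclose(out, [[-1.0], [1.0]])

    def test_idempotent_and_mean_zero(self, rng):
        x = rng.normal(-30, 3, size=(20, 3))
        x[3, 1] = np.nan
        c = center_coordinates(x)
        assert abs(np.nanmean(c)) < 1e-12
        np.testing.assert_allclose(center_coordinates(c), c, atol=1e-12)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="all-missing"):
            center_coordinates(np.full((3, 2), np.nan))
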