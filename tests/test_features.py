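"""The 382-feature registry and per-case feature extraction."""

import numpy as np
import pandas as pd
import pytest

from fusimorph import fit_centreline, frenet
from fusimorph.cross_sections import profile_from_area_eccentricity
from fusimorph.features import (
    UnreliableFeatureError,
    build_feature_matrix,
    compute_case_features,
    default_registry,
    endpoint_diameters,
    neck_features,
    ratio_features,
    segment_statistics,
)
from fusimorph.segmentation import SegmentationInput, segment_vessel

#: every feature name the analysis reports on must resolve in the registry
REPORTED_NAMES = [
    "Curvature_mean_PD",
    "Diameter_normalD2",
    "Eccentricity_std_P2",
    "Curvature_integration_P",
    "CrossArea_mean_PD2",
    "Curvature_mean_P",
    "CrossArea_max_PD2",
    "Eccentricity_variation_D2",
    "MajorAxis_mean_D2",
    "Solidity_integration_PD2",
    "Ratio_Dpnordnor1",
    "LineDist",
    "PointDist",
]


class TestRegistry:
    def test_total_and_uniqueness(self):
        reg = default_registry()
        assert len(reg) == 382
        assert len(set(reg.names)) == 382

    def test_reported_names_resolve(self):
        names = set(default_registry().names)
        for name in REPORTED_NAMES:
            assert name in names, name

    def test_no_feature_references_the_aneurysm_segment(self):
        for spec in default_registry().specs:
            if spec.kind != "neck":  # neck features sit at the endpoints a, b
                assert "A" not in spec.segments

    def test_manifest_roundtrip(self, tmp_path):
        reg = default_registry()
        reg.write_manifest(tmp_path / "registry.tsv")
        frame = pd.read_csv(tmp_path / "registry.tsv", sep="\t")
        assert len(frame) == 382
        assert list(frame.columns) == ["name", "kind", "index", "segments", "statistic"]


class TestSegmentStatistics:
    def test_hand_computed_example(self):
        stats = segment_statistics([1.0, 3.0, 2.0], [0.0, 1.0, 2.0], (1, 3))
        assert stats["max"] == 3.0
        assert stats["mean"] == 2.0
        assert stats["integration"] == pytest.approx(4.5)  # (1+3)/2 + (3+2)/2
        assert stats["variation"] == pytest.approx(3.0)  # |3-1| + |2-3|
        assert stats["std"] == pytest.approx(1.0)

    def test_constant_series(self):
        s = np.linspace(0, 7.0, 15)
        stats = segment_statistics(np.full(15, 3.0), s, (1, 15))
        assert stats["integration"] == pytest.approx(3.0 * 7.0)
        assert stats["std"] == 0.0 and stats["variation"] == 0.0

    def test_integration_matches_dense_quadrature_oracle(self):
        rng = np.random.default_rng(8)
        arc = np.sort(rng.uniform(0, 10, 30))
        series = rng.normal(0, 1, 30)
        stats = segment_statistics(series, arc, (5, 25))
        # independent oracle: trapezoid on a 100x-refined piecewise-linear
        # resampling of the same (arc, series) pairs
        fine = np.union1d(np.linspace(arc[4], arc[24], 2001), arc[4:25])
        oracle = np.trapezoid(np.interp(fine, arc[4:25], series[4:25]), fine)
        assert stats["integration"] == pytest.approx(oracle, abs=1e-9)

    def test_flagged_points_excluded(self):
        series = np.array([1.0, 100.0, 1.0, 1.0, 1.0])
        defined = np.array([True, False, True, True, True])
        stats = segment_statistics(series, np.arange(5.0), (1, 5), defined)
        assert stats["max"] == 1.0

    def test_mostly_flagged_raises(self):
        defined = np.array([True, False, False, False, True])
        with pytest.raises(UnreliableFeatureError):
            segment_statistics(np.ones(5), np.arange(5.0), (1, 5), defined)


class TestRatios:
    def test_identical_segments_ratio_one(self):
        stats = {"max": 1.0, "mean": 2.0, "std": 0.5, "integration": 3.0, "variation": 1.0}
        out = ratio_features({"P": stats, "D": dict(stats), "P2": stats, "D2": dict(stats)})
        assert all(v == 1.0 for v in out.values())

    def test_curvature_mean_ratio(self):
        p = {"max": 1, "mean": 0.4, "std": 1, "integration": 1, "variation": 1}
        d = {"max": 1, "mean": 0.2, "std": 1, "integration": 1, "variation": 1}
        out = ratio_features({"P": p, "D": d, "P2": p, "D2": d})
        assert out["mean_PD"] == pytest.approx(2.0)

    def test_zero_denominator_flagged(self):
        p = {"max": 1, "mean": 1, "std": 1, "integration": 1, "variation": 1}
        d = {"max": 1, "mean": 0.0, "std": 1, "integration": 1, "variation": 1}
        with pytest.warns(UserWarning, match="zero denominator"):
            out = ratio_features({"P": p, "D": d, "P2": p, "D2": p}, index="unit-test")
        assert np.isnan(out["mean_PD"])


def tube_case(n=100, a=41, b=60, taper=1.0):
    """Gently curved tube with circular radius-1 sections (+optional taper).

    A wide helix keeps the Frenet frame defined everywhere so torsion
    statistics are computable.
    """
    t = np.linspace(0, 40 / np.sqrt(109), n)
    points = np.c_[10 * np.cos(t), 10 * np.sin(t), 3 * t]
    cl = frenet(fit_centreline(points))
    area = np.full(n, np.pi)
    if taper != 1.0:
        scale = np.linspace(1.0, taper, n - b)
        area[b:] = area[b:] * scale**2
    profile = profile_from_area_eccentricity(area, np.zeros(n), cl.arc_length)
    seg = segment_vessel(SegmentationInput(areas=area, a=a, b=b))
    return cl, profile, seg


class TestEndpointsAndNeck:
    def test_circular_tube_endpoint_diameters(self):
        cl, profile, seg = tube_case()
        diam = endpoint_diameters(profile, seg)
        for value in diam.values():
            assert value == pytest.approx(2.0, rel=1e-9)

    def test_endpoint_equals_profile_maxd_at_index(self):
        cl, profile, seg = tube_case(taper=0.7)
        diam = endpoint_diameters(profile, seg)
        assert diam["Diameter_normalD2"] == profile.max_diameter[seg.D2[1] - 1]
        assert diam["Diameter_normalP2"] == profile.max_diameter[seg.P2[0] - 1]

    def test_tapered_tube_orders_distal_diameters(self):
        cl, profile, seg = tube_case(taper=0.7)
        diam = endpoint_diameters(profile, seg)
        assert diam["Diameter_normalD2"] < diam["Diameter_normalD"]

    def test_straight_vessel_neck_angle_zero(self):
        pts = np.c_[np.zeros(50), np.zeros(50), np.linspace(0, 20, 50)]
        cl = frenet(fit_centreline(pts))
        neck = neck_features(cl, 20, 30)
        assert neck.alpha == pytest.approx(0.0, abs=1e-6)

    def test_right_angle_and_distance(self):
        # quarter circle: tangents at the ends are orthogonal
        theta = np.linspace(0, np.pi / 2, 50)
        pts = np.c_[10 * np.cos(theta), 10 * np.sin(theta), np.zeros_like(theta)]
        cl = frenet(fit_centreline(pts))
        neck = neck_features(cl, 1, 50)
        assert neck.alpha == pytest.approx(90.0, abs=0.5)
        assert neck.d == pytest.approx(10 * np.sqrt(2), rel=1e-3)


class TestFeatureMatrix:
    def test_shape_37_by_384(self, planted_matrix):
        assert planted_matrix.shape == (37, 384)
        assert list(planted_matrix.columns[:2]) == ["identifier", "label"]

    def test_registry_order_preserved(self, planted_matrix):
        assert list(planted_matrix.columns[2:]) == default_registry().names

    def test_duplicated_case_gives_identical_rows(self):
        cl, profile, seg = tube_case(taper=0.8)
        cases = [("a", "ruptured", cl, profile, seg), ("b", "ruptured", cl, profile, seg)]
        matrix, failures = build_feature_matrix(cases)
        assert not failures
        pd.testing.assert_series_equal(
            matrix.iloc[0, 2:].astype(float),
            matrix.iloc[1, 2:].astype(float),
            check_names=False,
        )

    def test_case_failure_reported_not_dropped(self):
        cl, profile, seg = tube_case()
        broken = profile_from_area_eccentricity(
            profile.area[:50], profile.eccentricity[:50], cl.arc_length[:50]
        )
        with pytest.warns(UserWarning, match="failed"):
            matrix, failures = build_feature_matrix(
                [("good", "ruptured", cl, profile, seg), ("bad", "ruptured", cl, broken, seg)]
            )
        assert len(matrix) == 1
        assert failures and failures[0][0] == "bad"


class TestInvariances:
    @staticmethod
    def scaled_case(alpha):
        n, a, b = 100, 41, 60
        rng = np.random.default_rng(12)
        t = np.linspace(0, 4 * np.pi, n)
        pts = alpha * np.c_[2 * np.cos(t), 2 * np.sin(t), t]
        cl = frenet(fit_centreline(pts))
        area = alpha**2 * (7.0 + np.linspace(1, -1, n) + 0.05 * rng.normal(size=n))
        ecc = np.clip(0.4 + 0.05 * rng.normal(size=n), 0, 0.9)
        profile = profile_from_area_eccentricity(area, ecc, cl.arc_length)
        seg = segment_vessel(SegmentationInput(areas=area, a=a, b=b))
        return compute_case_features(cl, profile, seg)

    def test_scale_equivariance(self):
        base = self.scaled_case(1.0)
        scaled = self.scaled_case(2.0)
        # dimensionless features are invariant; lengths scale linearly
        for name in ("Curvature_mean_PD", "CrossArea_mean_PD2", "Eccentricity_std_P2",
                     "Tortuosity_P", "Ratio_Dpnordnor1", "Neck_alpha"):
            assert scaled[name] == pytest.approx(base[name], rel=1e-6), name
        for name in ("Diameter_normalD2", "LineDist", "PointDist", "Neck_d", "ArcLength_P"):
            assert scaled[name] == pytest.approx(2.0 * base[name], rel=1e-6), name
        # curvature scales inversely; its integral over arc is invariant
        assert scaled["Curvature_mean_P"] == pytest.approx(base["Curvature_mean_P"] / 2, rel=1e-6)
        assert scaled["Curvature_integration_P"] == pytest.approx(
            base["Curvature_integration_P"], rel=1e-6
        )
        assert scaled["CrossArea_mean_P2"] == pytest.approx(4 * base["CrossArea_mean_P2"], rel=1e-6)

    def test_aneurysm_interior_is_excluded(self):
        n, a, b = 100, 41, 60
        rng = np.random.default_rng(30)
        t = np.linspace(0, 40 / np.sqrt(109), n)
        pts = np.c_[10 * np.cos(t), 10 * np.sin(t), 3 * t]
        cl = frenet(fit_centreline(pts))
        area = 7.0 + np.linspace(1, -1, n) + 0.05 * rng.normal(size=n)
        ecc = np.clip(0.4 + 0.05 * rng.normal(size=n), 0, 0.9)
        seg = segment_vessel(SegmentationInput(areas=area, a=a, b=b))

        def features(area_series):
            profile = profile_from_area_eccentricity(area_series, ecc, cl.arc_length)
            return compute_case_features(cl, profile, seg)

        perturbed = area.copy()
        perturbed[a : b - 1] += 5.0  # strictly inside (a, b), 0-based a..b-2
        base, changed = features(area), features(perturbed)
        diffs = [k for k in base if not np.isclose(base[k], changed[k], equal_nan=True)]
        assert diffs == []
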