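import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from macrogd.covariates import (
    ENDEMIC_AREA_KM2,
    RangeGeometry,
    classify_position,
    climate_pcs,
    lifehistory_pcs,
    temperature_stability,
)
from macrogd.errors import GeometryError, ZeroVarianceError


def _circle_range(radius_km: float, lat0: float = 10.0, lon0: float = 20.0) -> RangeGeometry:
    """Geodesic circle approximated in the local equal-area plane, mapped back
    to lon/lat via small-angle inversion (adequate for test radii)."""
    # build in projected plane then invert by scaling degrees; use a dense
    # lon/lat polygon whose projected image is a near-perfect circle
    angles = np.linspace(0, 2 * np.pi, 720)
    km_per_deg_lat = 2 * np.pi * 6371.0 / 360.0
    km_per_deg_lon = km_per_deg_lat * np.cos(np.radians(lat0))
    pts = [
        (
            lon0 + radius_km * np.cos(a) / km_per_deg_lon,
            lat0 + radius_km * np.sin(a) / km_per_deg_lat,
        )
        for a in angles
    ]
    return RangeGeometry(Polygon(pts))


class TestLifeHistoryPCs:
    @pytest.fixture
    def traits(self):
        rng = np.random.default_rng(1)
        n = 40
        k_axis = rng.normal(0, 1, n)
        return pd.DataFrame(
            {
                "size": 10 ** (1.0 + 0.5 * k_axis + rng.normal(0, 0.05, n)),
                "longevity": 10 ** (0.8 + 0.5 * k_axis + rng.normal(0, 0.05, n)),
                "fecundity": 10 ** rng.normal(1.5, 0.5, n),
            },
            index=[f"sp{i}" for i in range(n)],
        )

    def test_block_structure_and_signs(self, traits):
        scores, pca = lifehistory_pcs(traits)
        assert pca.loadings.loc["size", "pc_size_longevity"] > 0
        assert pca.loadings.loc["longevity", "pc_size_longevity"] > 0
        assert pca.loadings.loc["fecundity", "pc_fecundity"] > 0
        # PC1 spans the correlated size-longevity axis
        assert abs(pca.loadings.loc["fecundity", "pc_size_longevity"]) < 0.3

    def test_scores_centered(self, traits):
        scores, _ = lifehistory_pcs(traits)
        assert np.all(np.abs(scores.mean()) < 1e-10)

    def test_matches_independent_eigen_oracle(self):
        toy = pd.DataFrame(
            {
                "fecundity": [10.0, 100.0, 30.0, 400.0, 55.0],
                "size": [2.0, 0.5, 1.5, 0.2, 1.0],
                "longevity": [20.0, 5.0, 12.0, 3.0, 8.0],
            },
            index=list("abcde"),
        )
        scores, pca = lifehistory_pcs(toy)
        # oracle: direct eigen-decomposition of the correlation matrix
        logd = np.log10(toy[["fecundity", "size", "longevity"]].to_numpy())
        std = (logd - logd.mean(0)) / logd.std(0, ddof=1)
        vals, vecs = np.linalg.eigh(np.corrcoef(std, rowvar=False))
        order = np.argsort(vals)[::-1]
        oracle = std @ vecs[:, order]
        for j, col in enumerate(["pc_size_longevity", "pc_fecundity"]):
            got = scores[col].to_numpy()
            assert np.allclose(got, oracle[:, j], atol=1e-8) or np.allclose(
                got, -oracle[:, j], atol=1e-8
            )

    def test_too_few_species(self):
        toy = pd.DataFrame({"fecundity": [1.0, 2.0], "size": [1, 2], "longevity": [1, 2]})
        with pytest.raises(ValueError):
            lifehistory_pcs(toy)

    def test_constant_trait_errors(self):
        toy = pd.DataFrame(
            {"fecundity": [1.0, 2.0, 3.0], "size": [1.0, 1.0, 1.0], "longevity": [1, 2, 3]}
        )
        with pytest.raises(ZeroVarianceError):
            lifehistory_pcs(toy)


class TestClimatePCs:
    @pytest.fixture
    def climate(self):
        rng = np.random.default_rng(2)
        n = 60
        t = rng.normal(0, 1, n)
        p = rng.normal(0, 1, n)
        h = rng.normal(0, 1, n)
        return pd.DataFrame(
            {
                "temp_mean": 15 + 8 * t + rng.normal(0, 0.5, n),
                "temp_max": 25 + 7 * t + rng.normal(0, 0.5, n),
                "prec_annual": 900 + 300 * p + rng.normal(0, 20, n),
                "prec_wettest": 200 + 80 * p + rng.normal(0, 5, n),
                "humidity_mean": 60 + 10 * h + rng.normal(0, 1, n),
            }
        )

    def test_labels_orthogonality_ordering(self, climate):
        scores, pca = climate_pcs(climate)
        assert set(scores.columns) == {"temperature_pc", "precipitation_pc", "humidity_pc"}
        corr = np.corrcoef(scores.to_numpy(), rowvar=False)
        assert np.all(np.abs(corr - np.eye(3)) < 1e-10)
        assert np.all(np.diff(pca.explained_variance_ratio) <= 1e-12)

    def test_matches_eigen_oracle_up_to_sign(self, climate):
        scores, pca = climate_pcs(climate.iloc[:, :4])
        std = (climate.iloc[:, :4] - climate.iloc[:, :4].mean()) / climate.iloc[:, :4].std(ddof=1)
        vals, vecs = np.linalg.eigh(np.cov(std.to_numpy(), rowvar=False, ddof=1))
        order = np.argsort(vals)[::-1]
        oracle = std.to_numpy() @ vecs[:, order]
        for j in range(3):
            got = pca.scores.iloc[:, j].to_numpy()
            assert np.allclose(got, oracle[:, j], atol=1e-8) or np.allclose(
                got, -oracle[:, j], atol=1e-8
            )

    def test_reconstruction_with_all_components(self, climate):
        _, pca = climate_pcs(climate)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        assert np.allclose(recon, pca.standardized.to_numpy(), atol=1e-8)

    def test_rank_deficient_lists_columns(self, climate):
        bad = climate.copy()
        bad["temp_dup"] = bad["temp_mean"] * 2.0
        with pytest.raises(ValueError, match="temp_dup|temp_mean"):
            climate_pcs(bad)


class TestTemperatureStability:
    def test_hand_computation(self):
        z = temperature_stability([10.0, 10.0, 10.0], [10.0, 12.0, 14.0])
        assert z == pytest.approx([1.0, 0.0, -1.0])

    def test_zero_difference_is_most_stable(self):
        z = temperature_stability([5.0, 5.0, 5.0], [5.0, 8.0, 3.0])
        assert np.argmax(z) == 0

    def test_additive_shift_invariance(self):
        cur = np.array([3.0, 7.0, 1.0, -2.0])
        past = np.array([4.0, 5.0, 1.5, 2.0])
        assert temperature_stability(cur, past) == pytest.approx(
            temperature_stability(cur + 11.3, past + 11.3)
        )

    def test_degenerate_raises(self):
        with pytest.raises(ZeroVarianceError):
            temperature_stability([1.0, 2.0], [3.0, 4.0])


class TestClassifyPosition:
    def test_endemic_overrides_location(self):
        rng = _circle_range(radius_km=50.0)  # area ~7854 km² < 10000
        assert rng.total_area_km2 < ENDEMIC_AREA_KM2
        assert classify_position(20.0, 10.0, rng) == "endemic"

    def test_island_and_isle(self):
        rng = _circle_range(radius_km=80.0)  # area > 10000
        rng_island = RangeGeometry(rng.geometry, insular_context=50_000.0)
        rng_isle = RangeGeometry(rng.geometry, insular_context=9_000.0)
        assert classify_position(20.0, 10.0, rng_island) == "island"
        assert classify_position(20.0, 10.0, rng_isle) == "isle"

    def test_circle_bands_analytic(self):
        # inner 50%-area disc of a circle has radius R/sqrt(2)
        R = 300.0
        rng = _circle_range(radius_km=R)
        km_per_deg_lat = 2 * np.pi * 6371.0 / 360.0
        def at_frac(f):
            return classify_position(20.0, 10.0 + f * R / km_per_deg_lat, rng)
        assert at_frac(0.2) == "core"
        assert at_frac(0.5) == "core"            # 0.5 < 1/sqrt(2)
        assert at_frac(0.75) == "subedge"        # between sqrt(.5)=.707 and sqrt(.75)=.866
        assert at_frac(0.95) == "edge"
        assert at_frac(1.0) == "edge"            # boundary point is edge

    def test_outside_beyond_tolerance_raises(self):
        rng = _circle_range(radius_km=100.0)
        with pytest.raises(GeometryError):
            classify_position(25.0, 10.0, rng)  # ~545 km east of the centre

    def test_band_area_shares_converge(self):
        # dense grid over a convex shape partitions into ~50/25/25 area shares
        R = 200.0
        rng = _circle_range(radius_km=R)
        km_per_deg_lat = 2 * np.pi * 6371.0 / 360.0
        km_per_deg_lon = km_per_deg_lat * np.cos(np.radians(10.0))
        g = np.linspace(-R * 0.999, R * 0.999, 61)
        counts = {"core": 0, "subedge": 0, "edge": 0}
        total = 0
        for dx in g:
            for dy in g:
                if dx * dx + dy * dy >= R * R * 0.998:
                    continue
                cls = classify_position(
                    20.0 + dx / km_per_deg_lon, 10.0 + dy / km_per_deg_lat, rng
                )
                counts[cls] += 1
                total += 1
        shares = {k: v / total for k, v in counts.items()}
        assert shares["core"] == pytest.approx(0.50, abs=0.02)
        assert shares["subedge"] == pytest.approx(0.25, abs=0.02)
        assert shares["edge"] == pytest.approx(0.25, abs=0.02)

    def test_equal_area_projection_preserves_area(self):
        rng = _circle_range(radius_km=150.0, lat0=45.0)
        assert rng.total_area_km2 == pytest.approx(np.pi * 150.0**2, rel=0.01)
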