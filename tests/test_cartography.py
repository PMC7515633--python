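"""Alignment, spherical conversion, density counting, unwrapping, epiboly %."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

import epibolykit as ek
from epibolykit.cartography import alignment_transform


def brute_force_density(points, radius):
    d = squareform(pdist(points))
    return (d <= radius).sum(axis=1)


class TestAlignEmbryo:
    def test_already_canonical_is_identity_up_to_roll(self, rng):
        axes = ek.EmbryoAxes(center=np.zeros(3), animal_pole=[0, -100, 0], vegetal_pole=[0, 100, 0])
        pts = rng.uniform(-50, 50, (20, 3))
        aligned = ek.align_embryo(pts, axes)
        # y-components preserved; x/z rotated about y only
        assert np.allclose(aligned[:, 1], pts[:, 1])

    def test_rigidity_preserves_pairwise_distances(self, rng):
        axes = ek.EmbryoAxes(
            center=[10.0, -5.0, 3.0], animal_pole=[10, -105, 3], vegetal_pole=[30, 90, -7]
        )
        pts = rng.uniform(-80, 80, (30, 3))
        aligned = ek.align_embryo(pts, axes)
        np.testing.assert_allclose(pdist(aligned), pdist(pts), rtol=1e-9)

    def test_vegetal_pole_lands_on_positive_y(self, rng):
        center = rng.uniform(-20, 20, 3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        vegetal = center + 100 * direction
        animal = center - 100 * direction
        axes = ek.EmbryoAxes(center=center, animal_pole=animal, vegetal_pole=vegetal)
        aligned_vegetal = ek.align_embryo(vegetal[None, :], axes)[0]
        np.testing.assert_allclose(aligned_vegetal, [0.0, 100.0, 0.0], atol=1e-6)

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ValueError):
            ek.EmbryoAxes(center=np.zeros(3), animal_pole=[1, 1, 1], vegetal_pole=[1, 1, 1])
        axes = ek.EmbryoAxes(center=[0, 100, 0], animal_pole=[0, -100, 0], vegetal_pole=[0, 100, 0])
        with pytest.raises(ValueError):
            alignment_transform(axes)


class TestSpherical:
    def test_vegetal_pole_elevation(self):
        sph = ek.to_spherical(np.array([[0.0, 100.0, 0.0]]))
        assert sph["elevation"][0] == pytest.approx(np.pi / 2)
        assert sph["radius_um"][0] == pytest.approx(100.0)

    def test_equator_point(self):
        sph = ek.to_spherical(np.array([[100.0, 0.0, 0.0]]))
        assert sph["azimuth"][0] == pytest.approx(0.0)
        assert sph["elevation"][0] == pytest.approx(0.0)

    def test_ranges(self, rng):
        sph = ek.to_spherical(rng.normal(size=(200, 3)) * 50)
        assert sph["azimuth"].between(-np.pi, np.pi).all()
        assert sph["elevation"].between(-np.pi / 2, np.pi / 2).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_identity(self, seed):
        pts = np.random.default_rng(seed).uniform(-100, 100, (20, 3))
        back = ek.from_spherical(ek.to_spherical(pts))
        np.testing.assert_allclose(back, pts, rtol=1e-9, atol=1e-9)


class TestLocalDensity:
    def test_single_point_counts_itself(self):
        assert ek.local_density(np.zeros((1, 3)), 40.0).tolist() == [1]

    @pytest.mark.parametrize("sep,expected", [(30.0, 2), (50.0, 1)])
    def test_pair_at_distance(self, sep, expected):
        pts = np.array([[0.0, 0, 0], [sep, 0, 0]])
        assert ek.local_density(pts, 40.0).tolist() == [expected, expected]

    def test_equals_brute_force_exactly(self, rng):
        pts = rng.uniform(-100, 100, (300, 3))
        counts = ek.local_density(pts, 40.0)
        np.testing.assert_array_equal(counts, brute_force_density(pts, 40.0))

    def test_kdtree_path_equals_brute_force(self, rng):
        pts = rng.uniform(-150, 150, (1500, 3))  # n > 1000 uses the index
        np.testing.assert_array_equal(
            ek.local_density(pts, 40.0), brute_force_density(pts, 40.0)
        )

    def test_density_sum_identity(self, rng):
        pts = rng.uniform(-80, 80, (200, 3))
        counts = ek.local_density(pts, 40.0)
        n_pairs = int((pdist(pts) <= 40.0).sum())
        assert counts.sum() == 200 + 2 * n_pairs

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            ek.local_density(np.zeros((2, 3)), 0.0)


class TestUnwrapDensity:
    def test_point_mass_fills_single_bin(self):
        per = pd.DataFrame({"azimuth": [0.1] * 5, "elevation": [0.2] * 5, "count": [3] * 5})
        grid, _, _ = ek.unwrap_density(per, n_azimuth=12, n_elevation=6)
        assert np.sum(~np.isnan(grid)) == 1
        assert np.nanmax(grid) == 3.0

    def test_uniform_sphere_fills_most_bins(self, rng):
        v = rng.normal(size=(4000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        sph = ek.to_spherical(v * 100)
        per = pd.DataFrame(
            {"azimuth": sph["azimuth"], "elevation": sph["elevation"], "count": 1}
        )
        grid, _, _ = ek.unwrap_density(per, n_azimuth=18, n_elevation=9)
        assert np.mean(~np.isnan(grid)) > 0.95

    def test_empty_bins_distinct_from_zero(self):
        per = pd.DataFrame({"azimuth": [0.0], "elevation": [0.0], "count": [0]})
        grid, _, _ = ek.unwrap_density(per, n_azimuth=4, n_elevation=2)
        assert np.nansum(grid) == 0.0  # measured zero present
        assert np.isnan(grid).sum() == grid.size - 1  # unmeasured bins NaN


class TestEpibolyPercentage:
    @pytest.fixture()
    def axes(self):
        return ek.EmbryoAxes(
            center=np.zeros(3), animal_pole=[0.0, -120.0, 0.0], vegetal_pole=[0.0, 120.0, 0.0]
        )

    def test_margin_at_animal_pole(self, axes):
        assert ek.epiboly_percentage(axes, [0.0, -120.0, 0.0]) == 0.0

    def test_margin_at_vegetal_pole(self, axes):
        assert ek.epiboly_percentage(axes, [0.0, 120.0, 0.0]) == 100.0

    @pytest.mark.parametrize("f", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_planted_margin_fraction_recovered(self, axes, f):
        theta = np.radians(ek.margin_fraction_to_angle(f))
        margin = 120.0 * np.array([np.sin(theta), -np.cos(theta), 0.0])
        assert ek.epiboly_percentage(axes, margin) == pytest.approx(100 * f, abs=0.5)

    def test_monotone_as_margin_moves_vegetally(self, axes, rng):
        ys = np.sort(rng.uniform(-120, 120, 50))
        pcts = [ek.epiboly_percentage(axes, [30.0, y, -10.0]) for y in ys]
        assert all(b >= a for a, b in zip(pcts, pcts[1:]))

    def test_coincident_poles_rejected(self):
        with pytest.raises(ValueError):
            ek.EmbryoAxes(center=np.zeros(3), animal_pole=[1, 2, 3], vegetal_pole=[1, 2, 3])


class TestArrestedDensityContrast:
    def test_arrested_exceeds_control_at_matched_count(self):
        """Arrest with continuing divisions packs nuclei: mean 40 µm
        density is strictly higher than in spreading controls."""
        for seed in range(3):
            base = dict(
                n_initial_nuclei=150,
                division_interval=25.0,
                n_frames=30,
                epiboly_speed=0.6,
                rng_seed=seed,
            )
            control = ek.simulate_epiboly(ek.SimulationConfig(**base))
            arrested = ek.simulate_epiboly(ek.SimulationConfig(arrest_time=0.0, **base))
            last = control.config.n_frames - 1
            cf, af = control.frame(last), arrested.frame(last)
            assert len(cf) == len(af)  # identical division schedule
            dc = ek.local_density(cf[["x_um", "y_um", "z_um"]].to_numpy())
            da = ek.local_density(af[["x_um", "y_um", "z_um"]].to_numpy())
            assert da.mean() > dc.mean()
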