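"""Statistical and spectral structure of the synthetic leaf data."""

import numpy as np
import pytest

from leafspec.envi import read_envi, read_polygons, write_envi, write_polygons
from leafspec.synthetic import (
    LibraryConfig,
    SceneConfig,
    SpeciesSpec,
    default_species,
    default_wavelength_grid,
    generate_image_cube,
    generate_library,
    generate_trait_table,
    simulate_leaf_spectrum,
    _structural_baseline,
)

ALL_TRAIT_MEANS = dict(
    chl_a=40.0, car=8.0, ca_cb=3.0, dmc=0.25, lma=50.0,
    alpha=0.3, etr_max=60.0, fv_fm=0.75, qp=0.5, qn=0.45,
)


def uniform_cv_species(cv: float, name: str = "test") -> SpeciesSpec:
    return SpeciesSpec(
        name=name,
        trait_means=dict(ALL_TRAIT_MEANS),
        trait_cvs={k: cv for k in ALL_TRAIT_MEANS},
    )


class TestTraitTable:
    def test_shape_and_physical_invariants(self):
        table = generate_trait_table(LibraryConfig(seed=42))
        assert len(table) == 150
        assert table["dmc"].between(0, 1, inclusive="neither").all()
        assert (table["lma"] > 0).all()
        assert (table[["chl_a", "chl_b", "car", "alpha", "etr_max"]] > 0).all().all()

    def test_zero_cv_collapses_to_species_means(self):
        sp = uniform_cv_species(0.0)
        table = generate_trait_table(
            LibraryConfig(species=(sp,), n_per_species=8, seed=1)
        )
        for trait, mean in ALL_TRAIT_MEANS.items():
            if trait == "ca_cb":
                continue
            assert np.allclose(table[trait], mean), trait
        assert np.allclose(table["chl_b"], 40.0 / 3.0)
        assert np.allclose(table["ik"], 60.0 / 0.3)

    def test_monte_carlo_cv_convergence(self):
        """Empirical CVs converge to configured CVs, log-normal and bounded alike."""
        sp = SpeciesSpec(
            name="mc",
            trait_means=dict(ALL_TRAIT_MEANS),
            trait_cvs=dict(chl_a=0.3, car=0.25, dmc=0.2, lma=0.3, fv_fm=0.06),
        )
        table = generate_trait_table(
            LibraryConfig(species=(sp,), n_per_species=10_000, seed=3)
        )
        for trait, cv in dict(chl_a=0.3, car=0.25, dmc=0.2, lma=0.3, fv_fm=0.06).items():
            emp = table[trait].std(ddof=1) / table[trait].mean()
            assert abs(emp - cv) / cv < 0.10, trait
        # the example from the sampling contract: Chl-a CV 0.3 within [0.29, 0.31]
        chl_cv = table["chl_a"].std(ddof=1) / table["chl_a"].mean()
        assert 0.29 < chl_cv < 0.31

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LibraryConfig(n_per_species=0)
        with pytest.raises(ValueError):
            uniform_cv_species(-0.1)
        bad = dict(ALL_TRAIT_MEANS, dmc=1.5)
        with pytest.raises(ValueError):
            SpeciesSpec(name="bad", trait_means=bad, trait_cvs={})


class TestForwardModel:
    def test_pigment_free_visible_equals_baseline(self):
        grid = default_wavelength_grid()
        traits = dict(chl_a=0.0, chl_b=0.0, car=0.0, dmc=0.25, lma=50.0)
        refl = simulate_leaf_spectrum(traits, grid)
        vis = grid < 1000
        assert np.allclose(refl[vis], _structural_baseline(grid)[vis], atol=1e-6)

    def test_more_chlorophyll_darkens_red_band(self):
        grid = default_wavelength_grid()
        i665 = np.argmin(np.abs(grid - 665))
        low = simulate_leaf_spectrum(dict(ALL_TRAIT_MEANS, chl_a=20.0, chl_b=7.0), grid)
        high = simulate_leaf_spectrum(dict(ALL_TRAIT_MEANS, chl_a=40.0, chl_b=7.0), grid)
        assert high[i665] < low[i665]

    def test_reflectance_clipped_to_unit_interval(self):
        grid = default_wavelength_grid()
        traits = dict(chl_a=120.0, chl_b=40.0, car=30.0, dmc=0.05, lma=300.0)
        refl = simulate_leaf_spectrum(traits, grid, noise_sd=0.2, rng=0)
        assert refl.shape == (987,)
        assert refl.min() >= 0.0 and refl.max() <= 1.0

    def test_invalid_traits_rejected(self):
        with pytest.raises(ValueError):
            simulate_leaf_spectrum(
                dict(chl_a=10, chl_b=3, car=2, dmc=1.2, lma=50),
                default_wavelength_grid(),
            )


class TestLibrary:
    def test_determinism_and_shape(self):
        a = generate_library(LibraryConfig(seed=9, n_per_species=5))
        b = generate_library(LibraryConfig(seed=9, n_per_species=5))
        assert np.array_equal(a.reflectance, b.reflectance)
        assert a.traits.equals(b.traits)
        assert a.reflectance.shape == (30, 987)

    def test_different_seeds_differ(self):
        a = generate_library(LibraryConfig(seed=1, n_per_species=3))
        b = generate_library(LibraryConfig(seed=2, n_per_species=3))
        assert not np.array_equal(a.reflectance, b.reflectance)

    def test_planted_chlorophyll_signal(self, library150):
        """Chl-a darkens the 665 nm band strongly across the default library."""
        i665 = np.argmin(np.abs(library150.wavelengths - 665))
        r = np.corrcoef(
            library150.traits["chl_a"], library150.reflectance[:, i665]
        )[0, 1]
        assert r < 0
        assert abs(r) > 0.8

    def test_tabular_round_trip(self, tmp_path):
        lib = generate_library(
            LibraryConfig(seed=4, n_per_species=3,
                          wavelength_grid=np.linspace(400, 2500, 50))
        )
        lib.write(tmp_path / "spectra.tsv", tmp_path / "traits.csv")
        back = lib.read(tmp_path / "spectra.tsv", tmp_path / "traits.csv")
        assert np.allclose(back.reflectance, lib.reflectance, atol=1e-6)
        assert list(back.traits.index) == list(lib.traits.index)
        assert {"species", "site", "date"} <= set(back.traits.columns)


@pytest.fixture(scope="module")
def scene():
    from shapely.geometry import box

    stands = [
        (box(20, 20, 110, 110), "Nuphar lutea"),
        (box(160, 30, 270, 130), "Ludwigia hexapetala"),
        (box(60, 170, 220, 280), "Trapa natans"),
    ]
    cfg = SceneConfig(stands=stands, seed=3)
    return cfg, generate_image_cube(cfg)


class TestScene:
    def test_default_band_grid(self, scene):
        _, (cube, _, _, _) = scene
        assert cube.band_centers.size == 98
        assert cube.band_centers[0] == pytest.approx(425.0)
        assert cube.band_centers[-1] == pytest.approx(905.0)

    def test_species_map_matches_polygons(self, scene):
        import shapely

        cfg, (cube, _, stands, smap) = scene
        x, y = cube.pixel_centers()
        for st in stands:
            inside = shapely.contains_xy(st.polygon, x.ravel(), y.ravel()).reshape(x.shape)
            assert np.array_equal(smap == st.species, inside)

    def test_lai_separates_background(self, scene):
        _, (cube, lai, _, smap) = scene
        background = smap == ""
        assert np.all(lai[background] < 0.67)
        assert np.all(lai[~background] >= 0.67)

    def test_polygon_outside_extent_rejected(self):
        from shapely.geometry import box

        with pytest.raises(ValueError):
            SceneConfig(stands=[(box(-10, 0, 50, 50), "Trapa natans")])

    def test_envi_round_trip(self, scene, tmp_path):
        _, (cube, lai, stands, _) = scene
        path = write_envi(tmp_path / "scene.bsq", cube.data, cube.band_centers,
                          pixel_size=cube.pixel_size)
        data, centers, meta = read_envi(path)
        assert np.allclose(data, cube.data, atol=1e-6)
        assert np.allclose(centers, cube.band_centers, atol=1e-3)
        assert meta["pixel_size"] == cube.pixel_size
        write_polygons(tmp_path / "stands.json", stands)
        back = read_polygons(tmp_path / "stands.json")
        assert [s.species for s in back] == [s.species for s in stands]
        assert back[0].polygon.equals(stands[0].polygon)
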