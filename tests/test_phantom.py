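"""Ground-truth integrity of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from dimorphbone.phantom import (CortexPhantomSpec, CtTableSpec, LacunaPopulation,
                                 CanalPopulation, RamanBand, RamanPhantomSpec,
                                 TibiaPhantomSpec, generate_cortex_volume,
                                 generate_ct_table, generate_raman_dataset,
                                 generate_tibia_stack, pseudo_voigt)
from dimorphbone.phantom.cortex import PlacementError, _ellipsoid_mask
from dimorphbone.stats import ddct_fold


def _clean_spec(**kw):
    base = dict(outer_radius_um=40.0, inner_radius_um=20.0, length_slices=40,
                voxel_size_um=1.0, seed=5)
    base.update(kw)
    spec = CortexPhantomSpec(**base)
    spec.intensity.noise_sigma = 0.0
    return spec


class TestCortexPhantom:
    def test_empty_populations_give_clean_annulus(self):
        vol, truth = generate_cortex_volume(_clean_spec())
        assert len(truth.pores) == 0
        bone = vol.voxels >= 80
        assert np.array_equal(bone, truth.cortex_mask.voxels)

    def test_rasterized_sphere_volume_converges(self):
        for r in (5.0, 8.0, 12.0):
            count = _ellipsoid_mask(np.array([r, r, r]), np.eye(3)).sum()
            expected = 4.0 / 3.0 * np.pi * r ** 3
            assert abs(count - expected) / expected < 0.05

    def test_reproducible_for_identical_seed(self):
        spec = _clean_spec(lacunae=LacunaPopulation(count=10))
        v1, t1 = generate_cortex_volume(spec)
        v2, t2 = generate_cortex_volume(_clean_spec(lacunae=LacunaPopulation(count=10)))
        assert np.array_equal(v1.voxels, v2.voxels)
        pd.testing.assert_frame_equal(t1.pores, t2.pores)

    def test_pore_voxels_conserved_within_cortex(self, small_wt_phantom):
        _, vol, truth = small_wt_phantom
        # every non-bone voxel strictly inside the cortex annulus is a pore
        bone = truth.cortex_mask.voxels & ~truth.pore_mask.voxels
        holes = truth.cortex_mask.voxels & ~bone
        assert int(holes.sum()) == int(truth.pores.n_voxels.sum())
        # and every pore lies inside the annulus
        assert np.all(truth.cortex_mask.voxels[truth.pore_mask.voxels])

    def test_composition_targeting_hits_requested_partition(self, small_wt_phantom):
        spec, _, truth = small_wt_phantom
        got = truth.composition_pct()
        tc = spec.target_composition
        assert got["lacuna"] == pytest.approx(tc.lacuna_pct, abs=0.3)
        assert got["canal"] == pytest.approx(tc.canal_pct, abs=0.3)
        assert got["noise"] == pytest.approx(tc.noise_pct, abs=0.3)

    def test_overfull_population_raises(self):
        spec = _clean_spec(lacunae=LacunaPopulation(
            count=5000, log10_volume_mean=3.0, min_volume_um3=500.0,
            max_volume_um3=1500.0))
        spec.max_tries_per_pore = 30
        with pytest.raises(PlacementError, match="lacuna"):
            generate_cortex_volume(spec)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            CortexPhantomSpec(outer_radius_um=50.0, inner_radius_um=50.0)


class TestTibiaPhantom:
    def test_constant_annulus_slices_identical(self):
        vol, table = generate_tibia_stack(TibiaPhantomSpec(n_slices=5))
        assert all(np.array_equal(vol.voxels[0], vol.voxels[k]) for k in range(5))
        assert table.csa_um2.nunique() == 1

    def test_tapering_annulus_csa_monotone(self):
        spec = TibiaPhantomSpec(n_slices=10, outer_a_um=(100.0, 80.0),
                                outer_b_um=(100.0, 80.0))
        _, table = generate_tibia_stack(spec)
        assert np.all(np.diff(table.csa_um2) < 0)

    def test_rotated_ellipse_principal_axis_recovered(self):
        from dimorphbone.geometry import section_properties
        spec = TibiaPhantomSpec(n_slices=1, image_size=320, outer_a_um=120.0,
                                outer_b_um=60.0, inner_a_um=80.0,
                                inner_b_um=40.0, rotation_deg=30.0)
        vol, _ = generate_tibia_stack(spec)
        mask = vol.voxels[0] >= 100
        ys, xs = np.nonzero(mask)
        dy, dx = ys - ys.mean(), xs - xs.mean()
        cov = np.cov(np.stack([dy, dx]))
        evals, evecs = np.linalg.eigh(cov)
        major = evecs[:, -1]  # (dy, dx) components of the long axis
        angle = np.rad2deg(np.arctan2(major[0], major[1])) % 180.0
        assert angle == pytest.approx(30.0, abs=1.0)

    def test_inner_ellipse_must_fit(self):
        with pytest.raises(ValueError):
            generate_tibia_stack(TibiaPhantomSpec(inner_a_um=120.0))


class TestRamanPhantom:
    def test_baseline_only_spectrum_is_polynomial(self):
        spec = RamanPhantomSpec(bands=[], baseline_coeffs=[1.0, 0.5, -0.2],
                                noise_sigma_rel=0.0)
        spectra, truth = generate_raman_dataset(spec)
        wn = spec.wavenumbers()
        xs = 2 * (wn - wn[0]) / (wn[-1] - wn[0]) - 1
        expected = np.polynomial.polynomial.polyval(xs, [1.0, 0.5, -0.2])
        np.testing.assert_allclose(spectra[0].intensity, expected)

    def test_band_area_matches_numeric_integral(self):
        band = RamanBand("test", 1000.0, area=2.0, sigma_cm1=3.0,
                         gaussian_fraction=1.0)
        spec = RamanPhantomSpec(bands=[band], noise_sigma_rel=0.0,
                                area_jitter_cv=0.0)
        spectra, _ = generate_raman_dataset(spec)
        area = np.trapezoid(spectra[0].intensity, spectra[0].wavenumbers)
        assert area == pytest.approx(2.0, rel=0.01)

    def test_truth_table_fold_is_by_construction(self):
        a = RamanPhantomSpec(bands=[RamanBand("ACP", 950.0, area=1.0)],
                             n_spectra=40, seed=1)
        b = RamanPhantomSpec(bands=[RamanBand("ACP", 950.0, area=3.0)],
                             n_spectra=40, seed=2)
        _, ta = generate_raman_dataset(a)
        _, tb = generate_raman_dataset(b)
        fold = tb.area_ACP.mean() / ta.area_ACP.mean()
        assert fold == pytest.approx(3.0, rel=0.05)

    def test_band_outside_fingerprint_rejected(self):
        with pytest.raises(ValueError):
            RamanBand("bad", 400.0, area=1.0)

    def test_pseudo_voigt_is_area_normalised(self):
        x = np.linspace(-200, 200, 20001)
        y = pseudo_voigt(x, 5.0, 0.0, 3.0, 0.5)
        assert np.trapezoid(y, x) == pytest.approx(5.0, rel=0.01)


class TestCtTable:
    def test_ddct_recovers_designed_folds(self):
        spec = CtTableSpec(true_folds={"Vegfa": 0.25, "Sost": 4.0},
                           ct_sd=0.05, n_per_group=8, seed=3)
        table = generate_ct_table(spec)

        def group_ct(group, gene):
            g = table[(table.group == group) & (table.gene == gene)]
            return g.sort_values("sample_id").ct.to_numpy()

        for gene, fold in spec.true_folds.items():
            folds = ddct_fold(group_ct("test", gene), group_ct("test", "GAPDH"),
                              group_ct("calibrator", gene),
                              group_ct("calibrator", "GAPDH"))
            assert np.mean(folds) == pytest.approx(fold, rel=0.1)
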