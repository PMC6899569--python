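"""Pore labelling, classification, and summary indices."""

import numpy as np
import pandas as pd
import pytest

from dimorphbone import (classify_pores, label_pores, select_separation_threshold,
                         summarize)
from dimorphbone.morphometry import PoreCatalog, CATALOG_COLUMNS
from dimorphbone.phantom.cortex import _capsule_mask, _ellipsoid_mask
from dimorphbone.volumes import BinaryMask

from conftest import flood_fill_label


def _catalog(volumes, elongations=None, extents=None, csv=1e9, vs=1.0):
    n = len(volumes)
    table = pd.DataFrame({
        "pore_id": range(1, n + 1),
        "n_voxels": [max(1, int(v)) for v in volumes],
        "volume_um3": volumes,
        "diameter_um": [(6 * v / np.pi) ** (1 / 3) for v in volumes],
        "centroid_z_um": 0.0, "centroid_y_um": 0.0, "centroid_x_um": 0.0,
        "elongation": elongations if elongations is not None else [1.2] * n,
        "extent_um": extents if extents is not None else [10.0] * n,
        "pore_class": [None] * n,
    })[CATALOG_COLUMNS]
    return PoreCatalog(table=table, voxel_size_um=vs,
                       cortical_solid_volume_um3=csv)


class TestLabelPores:
    def test_empty_mask_gives_empty_catalog(self):
        cat = label_pores(BinaryMask(np.zeros((8, 8, 8), bool), 1.0))
        assert len(cat) == 0

    def test_two_spheres_volumes_and_diameters(self):
        vol = np.zeros((40, 40, 40), bool)
        s3 = _ellipsoid_mask(np.array([3.0, 3.0, 3.0]), np.eye(3))
        s5 = _ellipsoid_mask(np.array([5.0, 5.0, 5.0]), np.eye(3))
        vol[2:2 + s3.shape[0], 2:2 + s3.shape[1], 2:2 + s3.shape[2]] = s3
        vol[20:20 + s5.shape[0], 20:20 + s5.shape[1], 20:20 + s5.shape[2]] = s5
        cat = label_pores(BinaryMask(vol, 1.0))
        assert len(cat) == 2
        got = sorted(cat.table.n_voxels)
        assert got == sorted([int(s3.sum()), int(s5.sum())])
        for _, row in cat.table.iterrows():
            assert row.diameter_um == pytest.approx(
                (6 * row.volume_um3 / np.pi) ** (1 / 3))

    def test_corner_touching_voxels_are_one_pore(self):
        vol = np.zeros((4, 4, 4), bool)
        vol[0, 0, 0] = vol[1, 1, 1] = True
        cat = label_pores(BinaryMask(vol, 1.0))
        assert len(cat) == 1
        assert cat.table.n_voxels.iloc[0] == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48, 48)) < 0.08
        cat = label_pores(BinaryMask(mask, 1.0))
        assert sorted(cat.table.n_voxels) == flood_fill_label(mask)

    def test_capsule_elongation_and_extent(self):
        cap = _capsule_mask(3.0, 40.0, np.array([1.0, 0.0, 0.0]))
        vol = np.zeros(tuple(s + 4 for s in cap.shape), bool)
        vol[2:2 + cap.shape[0], 2:2 + cap.shape[1], 2:2 + cap.shape[2]] = cap
        cat = label_pores(BinaryMask(vol, 1.0))
        row = cat.table.iloc[0]
        assert row.elongation > 3.0
        assert row.extent_um == pytest.approx(46.0, abs=2.0)


class TestSeparationThreshold:
    def test_no_elongated_pores_gives_infinite_threshold(self):
        cat = _catalog([100.0, 200.0], elongations=[1.1, 1.5])
        assert select_separation_threshold(cat) == np.inf

    def test_threshold_just_below_smallest_canal(self):
        cat = _catalog([500.0, 1000.0, 2000.0, 3000.0],
                       elongations=[1.2, 1.3, 4.0, 5.0],
                       extents=[10.0, 12.0, 50.0, 60.0])
        assert select_separation_threshold(cat) == pytest.approx(0.99 * 2000.0)

    def test_shape_criterion_requires_both_conditions(self):
        # elongated but short, and long but round, are not canal candidates
        cat = _catalog([2000.0, 3000.0], elongations=[4.0, 1.5],
                       extents=[20.0, 50.0])
        assert select_separation_threshold(cat) == np.inf


class TestClassify:
    def test_all_lacunae_between_floor_and_threshold(self):
        cat = classify_pores(_catalog([50.0, 100.0, 500.0]), 1000.0, 5.0)
        assert (cat.table.pore_class == "lacuna").all()

    def test_pore_exactly_at_threshold_is_canal(self):
        cat = classify_pores(_catalog([1000.0]), 1000.0, 5.0)
        assert cat.table.pore_class.iloc[0] == "canal"

    def test_below_floor_is_noise(self):
        cat = classify_pores(_catalog([1.0, 100.0]), 1000.0, 5.0)
        assert list(cat.table.pore_class) == ["noise", "lacuna"]

    def test_threshold_not_above_floor_rejected(self):
        with pytest.raises(ValueError):
            classify_pores(_catalog([10.0]), 5.0, 5.0)

    def test_phantom_classification_matches_ground_truth(
            self, small_wt_phantom, small_wt_extraction):
        _, _, truth = small_wt_phantom
        _, _, _, catalog = small_wt_extraction
        got = catalog.table.pore_class.value_counts()
        want = truth.pores.pore_class.value_counts()
        assert got.to_dict() == want.to_dict()
        for cls in ("lacuna", "canal", "noise"):
            got_v = catalog.table[catalog.table.pore_class == cls].volume_um3.sum()
            want_v = truth.pores[truth.pores.pore_class == cls].volume_um3.sum()
            assert got_v == pytest.approx(want_v, rel=1e-9)

    def test_raising_threshold_weakly_decreases_canals(self):
        volumes = list(np.geomspace(10, 5000, 30))
        counts = []
        for thr in (500.0, 1000.0, 2000.0, 4000.0):
            cat = classify_pores(_catalog(volumes), thr, 5.0)
            counts.append((cat.table.pore_class == "canal").sum())
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSummaries:
    def test_density_unit_conversion(self):
        cat = classify_pores(_catalog([100.0] * 10, csv=1e6), 1e4, 5.0)
        s = summarize(cat)
        assert s.lc_dn_per_mm3 == pytest.approx(1.0e4)

    def test_fractions_sum_to_100(self, small_wt_extraction):
        *_, catalog = small_wt_extraction
        s = summarize(catalog)
        assert s.lacuna_pct + s.canal_pct + s.noise_pct == pytest.approx(100.0,
                                                                         abs=0.01)

    def test_single_pore_fraction_is_100(self):
        s = summarize(classify_pores(_catalog([100.0], csv=1e6), 1e4, 5.0))
        assert s.lacuna_pct == pytest.approx(100.0)

    def test_empty_classes_report_missing_means(self):
        s = summarize(classify_pores(_catalog([100.0], csv=1e6), 1e4, 5.0))
        assert np.isnan(s.ca_v_um3) and np.isnan(s.ca_dm_um)
        assert s.ca_dn_per_mm3 == 0.0

    def test_zero_cortical_volume_rejected(self):
        cat = classify_pores(_catalog([100.0], csv=0.0), 1e4, 5.0)
        with pytest.raises(ValueError):
            summarize(cat)

    def test_voxel_size_halving_preserves_mean_lacunar_volume(self):
        # same physical sphere rasterised at 1.0 and 0.5 um voxels
        vols = {}
        for vs in (1.0, 0.5):
            r_vox = 6.0 / vs
            sph = _ellipsoid_mask(np.array([r_vox] * 3), np.eye(3))
            vol = np.zeros(tuple(s + 4 for s in sph.shape), bool)
            vol[2:2 + sph.shape[0], 2:2 + sph.shape[1], 2:2 + sph.shape[2]] = sph
            vols[vs] = label_pores(BinaryMask(vol, vs)).table.volume_um3.iloc[0]
        assert vols[0.5] == pytest.approx(vols[1.0], rel=0.05)
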