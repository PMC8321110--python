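"""Phantom generation: geometry, tumor growth, permittivity assignment."""

import numpy as np
import pytest
from scipy import ndimage

from mwi3d import (AIR, FAT, FIBRO, TUMOR, PhantomSpec, TissueTable,
                   VoxelGrid, assign_permittivity, generate_dataset,
                   grow_tumor, make_breast_geometry, make_prior_background,
                   sample_phantom)

TABLE = {AIR: 1 - 0.001j, FAT: 3 - 0.6j, FIBRO: 20 - 21.6j, TUMOR: 56.3 - 30j}


class TestBreastGeometry:
    def test_fibro_inside_fat_and_nonempty(self, grid2d):
        t = make_breast_geometry(PhantomSpec(grid=grid2d))
        assert t.count(FIBRO) > 0
        fat_or_fibro = (t.labels == FAT) | (t.labels == FIBRO)
        # fibro strictly inside fat: dilating fibro stays within the breast
        fibro_dil = ndimage.binary_dilation(t.labels == FIBRO)
        assert np.all(fat_or_fibro[fibro_dil])

    def test_height_delta_shrinks_fibro_only(self, grid2d):
        t0 = make_breast_geometry(PhantomSpec(grid=grid2d))
        t1 = make_breast_geometry(PhantomSpec(grid=grid2d,
                                              fibro_height_delta=0.009))
        assert t1.count(FIBRO) < t0.count(FIBRO)
        assert t1.count(FIBRO) + t1.count(FAT) == t0.count(FIBRO) + t0.count(FAT)
        assert (t1.labels == AIR).sum() == (t0.labels == AIR).sum()

    def test_degenerate_fibro_raises(self, grid2d):
        with pytest.raises(ValueError):
            make_breast_geometry(PhantomSpec(grid=grid2d,
                                             fibro_semiaxes=(0.0, 0.0)))

    def test_oversized_fat_raises(self, grid2d):
        with pytest.raises(ValueError):
            make_breast_geometry(PhantomSpec(grid=grid2d,
                                             fat_semiaxes=(0.08, 0.08)))


class TestTumorGrowth:
    def test_tiny_threshold_gives_single_voxel(self, grid2d):
        t = make_breast_geometry(PhantomSpec(grid=grid2d))
        rng = np.random.default_rng(0)
        out = grow_tumor(t, rng, d_max=0.5 * grid2d.spacing)
        assert out.count(TUMOR) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_diameter_bound_and_containment(self, grid2d, seed):
        t = make_breast_geometry(PhantomSpec(grid=grid2d))
        rng = np.random.default_rng(seed)
        d_max = rng.uniform(0.011, 0.015)
        out = grow_tumor(t, rng, d_max)
        pts = np.argwhere(out.labels == TUMOR).astype(float)
        diff = pts[:, None] - pts[None]
        diam = np.sqrt((diff ** 2).sum(-1)).max() * grid2d.spacing
        assert diam <= d_max + 2 * grid2d.spacing
        # containment: tumor voxels only replace fibro voxels
        assert np.all(t.labels[out.labels == TUMOR] == FIBRO)

    def test_empty_fibro_raises(self, grid2d):
        t = make_breast_geometry(PhantomSpec(grid=grid2d))
        t.labels[t.labels == FIBRO] = FAT
        with pytest.raises(ValueError):
            grow_tumor(t, np.random.default_rng(0), 0.01)

    def test_diameters_track_sampled_thresholds(self, grid2d):
        """Grown physical diameters fill the sampled 1.1-1.5 cm range."""
        t = make_breast_geometry(PhantomSpec(grid=grid2d))
        rng = np.random.default_rng(42)
        h = grid2d.spacing
        achieved, targets = [], []
        for _ in range(120):
            d_max = rng.uniform(0.011, 0.015)
            out = grow_tumor(t, rng, d_max)
            pts = np.argwhere(out.labels == TUMOR).astype(float)
            diff = pts[:, None] - pts[None]
            achieved.append(np.sqrt((diff ** 2).sum(-1)).max() * h + h)
            targets.append(d_max)
        achieved, targets = np.array(achieved), np.array(targets)
        # growth stops within one voxel step past the threshold
        assert np.all(achieved >= targets)
        assert np.all(achieved <= targets + 2 * h)
        # diameters spread across the sampled range (up to voxel quantization)
        assert achieved.min() < 0.013 and achieved.max() > 0.0155
        assert len(np.unique(np.round(achieved, 4))) >= 4


class TestSamplePhantom:
    @pytest.mark.parametrize("n_tumors,expected", [(0, 0), (1, 1), (2, 2)])
    def test_component_count(self, grid2d, n_tumors, expected):
        t = sample_phantom(PhantomSpec(grid=grid2d, n_tumors=n_tumors,
                                       rng_seed=11))
        assert t.tumor_components() == expected

    def test_determinism(self, grid2d):
        spec = PhantomSpec(grid=grid2d, n_tumors=2, rng_seed=5)
        a, b = sample_phantom(spec), sample_phantom(spec)
        assert np.array_equal(a.labels, b.labels)


class TestPermittivity:
    def test_table_lookup_exact(self, phantom2d):
        vol = assign_permittivity(phantom2d)
        for label, value in TABLE.items():
            voxels = phantom2d.labels == label
            if voxels.any():
                assert np.all(vol.values[voxels] == value)
        assert len(np.unique(vol.values)) <= 4

    def test_all_air_map(self, grid2d):
        from mwi3d.phantoms import TissueMap
        t = TissueMap(grid2d, np.zeros(grid2d.shape, dtype=np.int8))
        vol = assign_permittivity(t)
        assert np.all(vol.values == TABLE[AIR])

    def test_sign_convention_enforced(self):
        with pytest.raises(ValueError):
            TissueTable(tumor=56.3 + 30j)

    def test_prior_background_relabels_and_scales(self, phantom2d):
        truth = assign_permittivity(phantom2d)
        bg0 = make_prior_background(phantom2d, fibro_error_frac=0.0)
        tum = phantom2d.labels == TUMOR
        assert np.all(bg0.values[tum] == TABLE[FIBRO])
        assert np.all(bg0.values[~tum] == truth.values[~tum])
        bg10 = make_prior_background(phantom2d, fibro_error_frac=0.10)
        fib = phantom2d.labels == FIBRO
        assert np.allclose(bg10.values[fib], 1.10 * TABLE[FIBRO])


class TestGenerateDataset:
    def test_half_one_half_two_tumors(self, grid2d):
        items, manifest = generate_dataset(8, PhantomSpec(grid=grid2d), seed=3)
        counts = [r["n_tumors"] for r in manifest["phantoms"]]
        assert counts.count(1) == 4 and counts.count(2) == 4
        for item, rec in zip(items, manifest["phantoms"]):
            assert item["tissue"].tumor_components() == rec["n_tumors"]

    def test_manifest_reproducible(self, grid2d):
        _, m1 = generate_dataset(4, PhantomSpec(grid=grid2d), seed=9)
        items2, m2 = generate_dataset(4, PhantomSpec(grid=grid2d), seed=9)
        assert m1 == m2

    def test_no_tumor_override(self, grid2d):
        items, _ = generate_dataset(2, PhantomSpec(grid=grid2d), seed=1,
                                    n_tumors=0)
        assert all(it["tissue"].count(TUMOR) == 0 for it in items)
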