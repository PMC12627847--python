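import numpy as np
import pandas as pd
import pytest

from thetamark import synthetic
from thetamark.fibers import (EFieldMap, FiberSet, fiber_r_values,
                              fiber_weight, read_nifti_field, read_trk,
                              traverse_voxels, weighted_density_map,
                              write_nifti_field, write_trk)


def _grid_field(values_along_x, voxel_mm=2.0):
    """Field with given magnitudes along the x axis at y=z=0 voxel row."""
    nx = len(values_along_x)
    data = np.zeros((nx, 4, 4))
    data[:, 0, 0] = values_along_x
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return EFieldMap(data=data, affine=affine)


def _axis_fiber(x0, x1, voxel_mm=2.0):
    y = z = voxel_mm / 2
    return np.array([[x0, y, z], [x1, y, z]])


class TestWeight:
    def test_maximum_along_passage(self):
        field = _grid_field([0.1, 3.2, 1.0])
        fiber = _axis_fiber(0.5, 5.5)
        assert fiber_weight(fiber, field) == pytest.approx(3.2)

    def test_zero_field_region_absent(self):
        field = _grid_field([0.0, 0.0, 0.0])
        assert fiber_weight(_axis_fiber(0.5, 5.5), field) is None

    def test_outside_grid_absent(self):
        field = _grid_field([1.0, 1.0])
        fiber = np.array([[100.0, 100.0, 100.0], [120.0, 120.0, 120.0]])
        assert fiber_weight(fiber, field) is None

    def test_traversal_matches_brute_force_enumeration(self):
        # oracle: straight axis-aligned fiber visits exactly the voxels
        # whose x-extent it crosses
        field = _grid_field(np.arange(1.0, 11.0))
        fiber = _axis_fiber(1.0, 17.0)
        vox = traverse_voxels(fiber, field)
        expected = {(i, 0, 0) for i in range(0, 9)}   # 1.0..17.0 mm -> x 0..8
        assert set(map(tuple, vox)) == expected

    def test_reparameterisation_invariance(self):
        field = _grid_field(np.arange(1.0, 9.0))
        f1 = _axis_fiber(0.5, 15.0)
        mids = np.linspace(f1[0], f1[1], 13)          # insert collinear points
        assert fiber_weight(f1, field) == fiber_weight(mids, field)
        assert set(map(tuple, traverse_voxels(f1, field))) == \
            set(map(tuple, traverse_voxels(mids, field)))


class TestRValues:
    def test_noise_free_planted_fiber_r1(self):
        fset, fields, truth = synthetic.gen_fiber_phantom(
            n_fibers=10, n_patients=12, seed=0, weight_noise_sd=0.0)
        w = pd.DataFrame({p: [fiber_weight(f, fields[p]) for f in fset]
                          for p in range(12)})
        tab = fiber_r_values(w, pd.Series(truth.theta))
        assert tab.loc[truth.planted_fiber, "r"] == pytest.approx(1.0)
        assert tab.loc[truth.planted_fiber, "significant"]

    def test_shuffled_pairing_destroys_significance(self):
        fset, fields, truth = synthetic.gen_fiber_phantom(
            n_fibers=10, n_patients=14, seed=1, weight_noise_sd=0.0)
        w = pd.DataFrame({p: [fiber_weight(f, fields[p]) for f in fset]
                          for p in range(14)})
        rng = np.random.default_rng(0)
        shuffled = pd.Series(rng.permutation(truth.theta))
        tab = fiber_r_values(w, shuffled)
        assert abs(tab.loc[truth.planted_fiber, "r"]) < 0.99

    def test_pairwise_deletion_and_min_n(self):
        w = pd.DataFrame([[1.0, 2.0, 3.0, np.nan, 5.0],
                          [np.nan, np.nan, 1.0, 2.0, np.nan]],
                         columns=list("abcde"))
        target = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        tab = fiber_r_values(w, target)
        assert tab.loc[0, "n"] == 4
        assert tab.loc[0, "r"] == pytest.approx(1.0)
        assert np.isnan(tab.loc[1, "r"])       # only 2 defined pairs

    def test_constant_weights_undefined(self):
        w = pd.DataFrame([[2.0] * 6], columns=list("abcdef"))
        target = pd.Series(np.arange(6.0), index=list("abcdef"))
        tab = fiber_r_values(w, target)
        assert np.isnan(tab.loc[0, "r"])


class TestDensityMap:
    def test_single_fiber_holds_weight(self):
        field = _grid_field(np.ones(6))
        fiber = _axis_fiber(0.5, 11.5)
        dens = weighted_density_map(FiberSet([fiber]), [2.5], field)
        vox = traverse_voxels(fiber, field)
        assert np.allclose(dens.data[vox[:, 0], vox[:, 1], vox[:, 2]], 2.5)
        assert dens.data.sum() == pytest.approx(2.5 * len(vox))

    def test_additivity(self):
        field = _grid_field(np.ones(6))
        fiber = _axis_fiber(0.5, 11.5)
        dens = weighted_density_map(FiberSet([fiber, fiber.copy()]),
                                    [1.0, 2.0], field)
        vox = traverse_voxels(fiber, field)
        assert np.allclose(dens.data[vox[:, 0], vox[:, 1], vox[:, 2]], 3.0)

    def test_total_equals_weight_times_voxel_count(self):
        fset, fields, truth = synthetic.gen_fiber_phantom(
            n_fibers=6, n_patients=5, seed=3)
        weights = [1.0 + i for i in range(6)]
        dens = weighted_density_map(fset, weights, fields[0])
        expected = sum(w * len(traverse_voxels(f, fields[0]))
                       for w, f in zip(weights, fset))
        assert dens.data.sum() == pytest.approx(expected)


class TestIO:
    def test_trk_roundtrip(self, tmp_path):
        fset, _, _ = synthetic.gen_fiber_phantom(n_fibers=5, n_patients=3,
                                                 seed=4)
        path = tmp_path / "fibers.trk"
        write_trk(fset, path)
        back = read_trk(path)
        assert len(back) == 5
        for a, b in zip(fset, back):
            assert np.allclose(a, b, atol=1e-3)

    def test_nifti_roundtrip(self, tmp_path):
        _, fields, _ = synthetic.gen_fiber_phantom(n_fibers=3, n_patients=2,
                                                   seed=5)
        path = tmp_path / "field.nii.gz"
        write_nifti_field(fields[0], path)
        back = read_nifti_field(path)
        assert np.allclose(back.data, fields[0].data, atol=1e-5)
        assert np.allclose(back.affine, fields[0].affine)


def test_fiber_set_validation():
    with pytest.raises(ValueError, match="2 three-dimensional"):
        FiberSet([np.array([[0.0, 0.0, 0.0]])])
    with pytest.raises(ValueError, match="finite"):
        FiberSet([np.array([[0.0, 0.0, 0.0], [np.inf, 1.0, 1.0]])])
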