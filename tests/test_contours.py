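"""Segmentation metrics and signed-margin perturbation."""

import math

import numpy as np
import pytest
from scipy import ndimage

from cardiodose.contours import (
    SegMetrics,
    StructureMask,
    dice,
    margins_from_metrics,
    perturb_mask,
    qualify_structure,
    surface_distances,
)

from conftest import random_blob, sphere_mask


def cube_mask(lo, hi, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
    vox = np.zeros(shape, dtype=bool)
    vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return StructureMask(vox, spacing, "cube")


class TestDice:
    def test_identity_is_one(self):
        m = cube_mask((2, 2, 2), (4, 4, 4))
        assert dice(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = cube_mask((0, 0, 0), (2, 2, 2))
        b = cube_mask((4, 4, 4), (6, 6, 6))
        assert dice(a, b) == 0.0

    def test_shifted_cube_half_overlap(self):
        # 2x2x2 cube shifted by one voxel: 4 shared voxels, 2*4/(8+8)=0.5
        a = cube_mask((2, 2, 2), (4, 4, 4))
        b = cube_mask((3, 2, 2), (5, 4, 4))
        assert dice(a, b) == pytest.approx(0.5)
        assert dice(b, a) == dice(a, b)

    def test_both_empty_is_an_error(self):
        m = StructureMask(np.zeros((4, 4, 4), bool), (1, 1, 1), "empty")
        with pytest.raises(ValueError):
            dice(m, m)


class TestSurfaceDistances:
    def test_identical_masks_have_zero_distance(self):
        m = sphere_mask(5.0)
        assert surface_distances(m, m) == (0.0, 0.0)

    def test_parallel_planes(self):
        # two full-extent single-voxel planes 5 mm apart: every boundary
        # voxel is exactly 5 mm from the other surface
        shape = (10, 10, 12)
        a = np.zeros(shape, bool)
        b = np.zeros(shape, bool)
        a[:, :, 3] = True
        b[:, :, 8] = True
        ma = StructureMask(a, (1, 1, 1), "a")
        mb = StructureMask(b, (1, 1, 1), "b")
        msd, hd95 = surface_distances(ma, mb)
        assert msd == pytest.approx(5.0)
        assert hd95 == pytest.approx(5.0)

    def test_spacing_scales_distances(self):
        a = cube_mask((1, 1, 1), (4, 4, 4), shape=(10, 10, 10))
        b = cube_mask((5, 5, 5), (8, 8, 8), shape=(10, 10, 10))
        msd1, hd1 = surface_distances(a, b)
        a2 = StructureMask(a.voxels, (2, 2, 2), "a")
        b2 = StructureMask(b.voxels, (2, 2, 2), "b")
        msd2, hd2 = surface_distances(a2, b2)
        assert msd2 == pytest.approx(2 * msd1)
        assert hd2 == pytest.approx(2 * hd1)

    def test_empty_mask_rejected(self):
        m = sphere_mask(4.0)
        empty = StructureMask(np.zeros_like(m.voxels), m.spacing, "e")
        with pytest.raises(ValueError):
            surface_distances(m, empty)


class TestPerturbMask:
    def test_zero_margin_is_identity(self):
        m = sphere_mask(6.0)
        out = perturb_mask(m, 0.0)
        assert np.array_equal(out.voxels, m.voxels)

    def test_sphere_expansion_volume(self):
        m = sphere_mask(10.0, spacing=(1, 1, 1))
        out = perturb_mask(m, 2.0)
        analytic = 4 / 3 * math.pi * 12.0**3
        assert out.volume_cc() * 1000 == pytest.approx(analytic, rel=0.10)

    @pytest.mark.parametrize("margin", [1.5, 3.0])
    def test_containment_chain(self, rng, margin):
        for _ in range(10):
            m = random_blob(rng)
            exp = perturb_mask(m, margin)
            con = perturb_mask(m, -margin)
            assert not (con.voxels & ~m.voxels).any()
            assert not (m.voxels & ~exp.voxels).any()

    def test_matches_bruteforce_distance_thresholding(self, rng):
        # oracle: per-voxel nearest-surface distance computed exhaustively
        for _ in range(5):
            m = random_blob(rng, shape=(10, 10, 8), spacing=(1.5, 1.0, 2.0))
            pts_in = np.argwhere(m.voxels) * np.array(m.spacing)
            pts_out = np.argwhere(~m.voxels) * np.array(m.spacing)
            margin = 2.5
            exp = perturb_mask(m, margin)
            oracle = m.voxels.copy()
            for idx in np.argwhere(~m.voxels):
                d = np.sqrt((((idx * np.array(m.spacing)) - pts_in) ** 2).sum(1)).min()
                if d <= margin:
                    oracle[tuple(idx)] = True
            assert np.array_equal(exp.voxels, oracle)
            con = perturb_mask(m, -margin)
            oracle_c = np.zeros_like(m.voxels)
            for idx in np.argwhere(m.voxels):
                d = np.sqrt((((idx * np.array(m.spacing)) - pts_out) ** 2).sum(1)).min()
                if d > margin:
                    oracle_c[tuple(idx)] = True
            assert np.array_equal(con.voxels, oracle_c)

    def test_expand_then_contract_covers_original_convex(self):
        m = sphere_mask(8.0, spacing=(1, 1, 1))
        closed = perturb_mask(perturb_mask(m, 3.0), -3.0)
        assert not (m.voxels & ~closed.voxels).any()

    def test_contraction_can_empty_with_warning(self):
        m = sphere_mask(2.0)
        with pytest.warns(UserWarning):
            out = perturb_mask(m, -5.0)
        assert out.is_empty()

    def test_margin_consistency_on_smooth_mask(self):
        # MSD between a large sphere and its expansion is close to the margin
        m = sphere_mask(15.0, spacing=(1.5, 1.5, 1.5))
        margin = 4.0
        exp = perturb_mask(m, margin)
        msd, _ = surface_distances(m, exp)
        diag = math.sqrt(sum(s**2 for s in m.spacing))
        assert abs(msd - margin) <= diag


class TestMarginPolicy:
    def test_symmetric_policy(self):
        spec = margins_from_metrics(SegMetrics(0.9, 3.0, 1.0, 0.5), "LA")
        assert spec.expand_margin_mm == pytest.approx(2.0)
        assert spec.contract_margin_mm == pytest.approx(2.0)

    def test_asymmetric_policy_floors_at_zero(self):
        spec = margins_from_metrics(SegMetrics(0.9, 3.0, 1.0, 0.5), "LA",
                                    policy="asymmetric")
        assert spec.contract_margin_mm == 0.0

    def test_policies_agree_at_zero_sd(self):
        sym = margins_from_metrics(SegMetrics(0.9, 3.0, 1.2, 0.0), "LA")
        asym = margins_from_metrics(SegMetrics(0.9, 3.0, 1.2, 0.0), "LA",
                                    policy="asymmetric")
        assert sym.expand_margin_mm == asym.expand_margin_mm == 1.2
        assert sym.contract_margin_mm == asym.contract_margin_mm == 1.2


@pytest.mark.parametrize("dsc,msd,expected", [
    (0.90, 1.0, True),
    (0.80, 1.0, False),   # "above 0.80" is strict
    (0.95, 2.0, False),   # "< 2 mm" is strict
    (0.81, 1.99, True),
])
def test_structure_inclusion_rule(dsc, msd, expected):
    assert qualify_structure(SegMetrics(dsc, 5.0, msd)) is expected
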