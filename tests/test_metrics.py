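import numpy as np
import pytest
from scipy import ndimage

import gliomaseg as gs
from gliomaseg.metrics import boundary_voxels


def brute_force_hausdorff(a, b):
    """All-pairs max-min distance between boundary voxel sets."""
    A = np.argwhere(boundary_voxels(a)).astype(float)
    B = np.argwhere(boundary_voxels(b)).astype(float)
    d = np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def random_mask(rng, shape=(8, 8, 8)):
    while True:
        mask = np.zeros(shape, bool)
        n = rng.integers(1, 6)
        for _ in range(n):
            c = rng.integers(0, np.array(shape) - 2)
            s = rng.integers(1, 4, size=3)
            mask[c[0]:c[0] + s[0], c[1]:c[1] + s[1], c[2]:c[2] + s[2]] = True
        if mask.any():
            return mask


class TestDice:
    def test_identical_masks(self):
        a = np.zeros((6, 6, 6), bool)
        a[1:4, 1:4, 1:4] = True
        assert gs.dice(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 1), bool)
        b = np.zeros((6, 6, 1), bool)
        a[0, 0, 0] = b[5, 5, 0] = True
        assert gs.dice(a, b) == 0.0

    def test_hand_counted_overlap(self):
        # |A| = 4, |B| = 2, |A ∩ B| = 2 -> 2*2/(4+2)
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[0, 0:4, 0] = True
        b[0, 0:2, 0] = True
        assert gs.dice(a, b) == pytest.approx(2 / 3)

    def test_empty_mask_conventions(self):
        e = np.zeros((3, 3, 3), bool)
        f = e.copy()
        f[1, 1, 1] = True
        assert gs.dice(e, e) == 1.0
        assert gs.dice(e, f) == 0.0

    def test_symmetry_and_shape_check(self):
        rng = np.random.default_rng(0)
        a, b = random_mask(rng), random_mask(rng)
        assert gs.dice(a, b) == gs.dice(b, a)
        with pytest.raises(ValueError):
            gs.dice(a, np.zeros((2, 2, 2), bool))


class TestBoundaryVoxels:
    def test_single_voxel_is_its_own_boundary(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert np.array_equal(boundary_voxels(m), m)

    def test_cube_shell(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        shell = boundary_voxels(m)
        assert shell.sum() == 26          # 3^3 minus the center
        assert not shell[2, 2, 2]

    def test_empty_mask(self):
        assert not boundary_voxels(np.zeros((4, 4, 4), bool)).any()

    def test_mask_touching_volume_edge_counts_as_boundary(self):
        m = np.ones((3, 3, 3), bool)
        assert boundary_voxels(m)[0, 0, 0]


class TestHausdorff:
    def test_identical_masks_zero(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:5, 2:5, 2:5] = True
        assert gs.hausdorff(m, m) == 0.0

    def test_three_four_five_triangle(self):
        a = np.zeros((5, 6, 1), bool)
        b = np.zeros((5, 6, 1), bool)
        a[0, 0, 0] = True
        b[3, 4, 0] = True
        assert gs.hausdorff(a, b) == 5.0

    def test_mm_spacing_scales_distances(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[0, 0, 2] = True
        assert gs.hausdorff(a, b) == 2.0
        assert gs.hausdorff(a, b, spacing=(0.5, 0.5, 6.5)) == pytest.approx(13.0)

    def test_empty_mask_raises_undefined(self):
        m = np.zeros((4, 4, 4), bool)
        f = m.copy()
        f[1, 1, 1] = True
        with pytest.raises(ValueError, match="undefined"):
            gs.hausdorff(m, f)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            a, b = random_mask(rng), random_mask(rng)
            assert gs.hausdorff(a, b) == brute_force_hausdorff(a, b)

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        a, b = random_mask(rng, (6, 6, 6)), random_mask(rng, (6, 6, 6))
        pad = [(2, 2)] * 3
        a2, b2 = np.pad(a, pad), np.pad(b, pad)
        shifted_a = np.roll(a2, (1, 1, 1), axis=(0, 1, 2))
        shifted_b = np.roll(b2, (1, 1, 1), axis=(0, 1, 2))
        assert gs.hausdorff(shifted_a, shifted_b) == gs.hausdorff(a2, b2)
        assert gs.dice(shifted_a, shifted_b) == gs.dice(a2, b2)

    def test_dilation_cannot_decrease_hausdorff_from_gt(self):
        gt = np.zeros((10, 10, 10), bool)
        gt[3:7, 3:7, 3:7] = True
        grown = ndimage.binary_dilation(gt)
        assert gs.hausdorff(grown, gt) >= gs.hausdorff(gt, gt)
        assert gs.hausdorff(grown, gt) <= np.sqrt(3)


class TestVolume:
    def test_solid_block_count(self):
        m = np.zeros((12, 12, 5), bool)
        m[1:11, 1:11, 1:4] = True
        n, mm3 = gs.volume(m)
        assert n == 300 and mm3 is None

    def test_empty(self):
        assert gs.volume(np.zeros((3, 3, 3), bool)) == (0, None)

    def test_mm3_uses_thickness_not_gap(self):
        m = np.zeros((12, 12, 5), bool)
        m[1:11, 1:11, 1:4] = True
        n, mm3 = gs.volume(m, spacing=(0.5, 0.5, 5.0), slice_gap=1.5)
        assert n == 300
        assert mm3 == pytest.approx(375.0)  # 300 * 1.25, gap excluded


class TestEvaluate:
    @staticmethod
    def _masks():
        labels = np.zeros((20, 20, 6), dtype=np.int16)
        labels[5:15, 5:15, 1:5] = 2
        labels[8:12, 8:12, 2:4] = 1
        gt = gs.LabelMask(labels=labels, spacing=(1, 1, 1))
        return gt

    def test_perfect_prediction(self):
        gt = self._masks()
        pred = gs.LabelMask(labels=gt.labels.copy(), spacing=(1, 1, 1))
        rep = gs.evaluate(pred, gt)
        for comp in gs.COMPONENTS:
            assert rep[comp].dsc == 1.0
            assert rep[comp].hausdorff_voxels == 0.0
            assert rep[comp].vol_pred_voxels == rep[comp].vol_gt_voxels

    def test_whole_tumor_only_prediction_marks_components_not_produced(self):
        gt = self._masks()
        pred_labels = np.where(gt.labels >= 1, 2, 0).astype(np.int16)
        pred = gs.LabelMask(labels=pred_labels, spacing=(1, 1, 1),
                            undifferentiated=True)
        rep = gs.evaluate(pred, gt)
        assert rep["whole_tumor"].dsc == 1.0
        assert not rep["edema"].produced and not rep["necrotic"].produced
        frame = rep.to_frame()
        dash_rows = frame[frame["flags"] == "not produced"]
        assert set(dash_rows.component) == {"edema", "necrotic"}
        assert dash_rows.dsc.isna().all()

    def test_dilated_prediction_bounded_hausdorff(self):
        gt = self._masks()
        grown = ndimage.binary_dilation(gt.labels >= 1)
        pred = gs.LabelMask(labels=np.where(grown, 2, 0).astype(np.int16),
                            spacing=(1, 1, 1), undifferentiated=True)
        rep = gs.evaluate(pred, gt)
        assert rep["whole_tumor"].hausdorff_voxels <= np.sqrt(3)

    def test_geometry_mismatch_errors(self):
        gt = self._masks()
        pred = gs.LabelMask(labels=np.zeros((20, 20, 5), np.int16), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="geometry mismatch"):
            gs.evaluate(pred, gt)

    def test_whole_tumor_volume_dominates_subcomponents(self):
        gt = self._masks()
        rep = gs.evaluate(gs.LabelMask(labels=gt.labels.copy(), spacing=(1, 1, 1)), gt)
        assert rep["whole_tumor"].vol_gt_voxels >= rep["edema"].vol_gt_voxels
        assert rep["whole_tumor"].vol_gt_voxels >= rep["necrotic"].vol_gt_voxels


class TestBatchReport:
    @staticmethod
    def _case(dsc_target):
        labels = np.zeros((10, 10, 4), np.int16)
        labels[2:8, 2:8, 1:3] = 2
        gt = gs.LabelMask(labels=labels, spacing=(1, 1, 1))
        pred_labels = np.zeros_like(labels)
        n = int(labels.sum() / 2)  # label-2 voxel count
        coords = np.argwhere(labels == 2)
        keep = int(round(dsc_target / (2 - dsc_target) * len(coords)))
        # fraction f of gt kept with no false positives gives dice 2f/(1+f)
        for x, y, z in coords[:keep]:
            pred_labels[x, y, z] = 2
        return gs.LabelMask(labels=pred_labels, spacing=(1, 1, 1)), gt

    def test_mean_of_two_cases(self):
        p1, g1 = self._case(0.4)
        p2, g2 = self._case(0.8)
        table = gs.batch_report([("a", p1, g1), ("b", p2, g2)])
        mean_row = table[(table.case == "MEAN") & (table.component == "whole_tumor")]
        d1 = table[(table.case == "a") & (table.component == "whole_tumor")].dsc.iloc[0]
        d2 = table[(table.case == "b") & (table.component == "whole_tumor")].dsc.iloc[0]
        assert mean_row.dsc.iloc[0] == pytest.approx((d1 + d2) / 2)

    def test_undefined_hausdorff_excluded_from_mean(self):
        p1, g1 = self._case(0.8)
        empty_pred = gs.LabelMask(labels=np.zeros_like(g1.labels), spacing=(1, 1, 1))
        table = gs.batch_report([("ok", p1, g1), ("empty", empty_pred, g1)])
        mean_row = table[(table.case == "MEAN") & (table.component == "whole_tumor")]
        ok_hd = table[(table.case == "ok") & (table.component == "whole_tumor")]
        assert mean_row.hausdorff_voxels.iloc[0] == ok_hd.hausdorff_voxels.iloc[0]
        assert "excluded: 1" in mean_row["flags"].iloc[0]

    def test_single_case_mean_equals_case(self):
        p, g = self._case(0.8)
        table = gs.batch_report([(p, g)])
        case_dsc = table[(table.case == "case0") & (table.component == "whole_tumor")].dsc.iloc[0]
        mean_dsc = table[(table.case == "MEAN") & (table.component == "whole_tumor")].dsc.iloc[0]
        assert mean_dsc == pytest.approx(case_dsc)

    def test_empty_case_list_errors(self):
        with pytest.raises(ValueError):
            gs.batch_report([])
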