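"""Alignment, enhancement, and segmentation against rendered ground truth."""

import numpy as np
import pytest

from poreflow import (
    RenderSpec,
    align_stack,
    enhance_and_correct,
    load_stack,
    porosity_profile,
    render_stack,
    save_stack,
    segment_two_zone,
)
from poreflow.structure import VoxelStructure


@pytest.fixture(scope="module")
def small_membrane():
    from poreflow import MembraneProfile, generate_membrane

    return generate_membrane(MembraneProfile.default(thickness_um=32 * 7e-3), (32, 32, 32), seed=8)


class TestRender:
    def test_noise_free_render_is_pure_phase_map(self, small_membrane):
        spec = RenderSpec(noise_sd=0.0)
        stack, truth = render_stack(small_membrane, spec, seed=0)
        r0, r1 = stack.membrane_rows
        c0, c1 = stack.membrane_cols
        img = stack.data[:, r0:r1, c0:c1]
        vals = np.unique(img)
        assert set(vals) <= {spec.pore_mean, spec.solid_mean}
        # carbon band present and flat
        assert (stack.data[:, stack.carbon_rows[0] : stack.carbon_rows[1], :] == spec.carbon_mean).all()

    def test_ground_truth_returns_drift_verbatim(self, small_membrane):
        drift = np.zeros((32, 2), int)
        drift[5] = (3, -2)
        stack, truth = render_stack(small_membrane, RenderSpec(drift=drift), seed=0)
        assert np.array_equal(truth["drift"], drift)

    def test_oversized_drift_is_rejected(self, small_membrane):
        drift = np.zeros((32, 2), int)
        drift[3] = (25, 0)
        with pytest.raises(ValueError, match="margin"):
            render_stack(small_membrane, RenderSpec(drift=drift, pad_px=8), seed=0)

    def test_per_slice_threshold_recovers_phases(self, small_membrane):
        """With phase means separated by >= 5 noise sd, a two-class
        threshold on each raw slice recovers labels to < 1% error."""
        from skimage.filters import threshold_otsu

        spec = RenderSpec(noise_sd=10.0)  # separation 110 = 11 sd
        stack, truth = render_stack(small_membrane, spec, seed=3)
        r0, r1 = stack.membrane_rows
        c0, c1 = stack.membrane_cols
        errs = []
        for i in range(stack.n_slices):
            img = stack.data[i, r0:r1, c0:c1]
            t = threshold_otsu(img)
            pore = img < t
            true_pore = small_membrane.grid[i].T[::-1, :]
            errs.append((pore != true_pore).mean())
        assert np.mean(errs) < 0.01

    def test_segmentation_of_aligned_render_roundtrips_geometry(self, small_membrane):
        """Axis conventions: render → segment with no corruption must
        reproduce the structure exactly, voxel for voxel."""
        stack, _ = render_stack(small_membrane, RenderSpec(noise_sd=0.0), seed=0)
        seg = segment_two_zone(stack, manual_thresholds=(95.0, 95.0))
        assert np.array_equal(seg.structure.grid, small_membrane.grid)


class TestAlign:
    def test_zero_drift_recovers_zero(self, small_membrane):
        stack, _ = render_stack(small_membrane, RenderSpec(noise_sd=4.0), seed=1)
        _, trace = align_stack(stack)
        assert np.abs(trace.dx).max() == 0
        assert np.abs(trace.dy).max() == 0

    def test_injected_drift_recovered_within_one_pixel(self, rendered_fixture):
        stack, truth = rendered_fixture
        _, trace = align_stack(stack)
        assert np.abs(trace.dx - truth["drift"][:, 0]).max() <= 1
        assert np.abs(trace.dy - truth["drift"][:, 1]).max() <= 1

    def test_alignment_is_idempotent_within_one_pixel(self, rendered_fixture):
        stack, _ = rendered_fixture
        aligned, _ = align_stack(stack)
        _, residual = align_stack(aligned)
        assert np.abs(residual.dx).max() <= 1
        assert np.abs(residual.dy).max() <= 1

    def test_alignment_preserves_pixel_values(self, rendered_fixture):
        """Integer shifting moves pixels but never alters their values."""
        stack, _ = rendered_fixture
        aligned, _ = align_stack(stack)
        for i in (0, 7, 23):
            vals_in = np.sort(stack.data[i].ravel())
            valid = aligned.valid[i]
            vals_out = np.sort(aligned.data[i][valid])
            # every surviving aligned pixel value exists in the input slice
            assert np.isin(vals_out, vals_in).all()

    def test_featureless_template_is_an_error(self):
        data = np.zeros((4, 40, 40))
        from poreflow import GrayscaleStack

        stack = GrayscaleStack(data, carbon_rows=(5, 10), membrane_rows=(12, 36), membrane_cols=(4, 36))
        with pytest.raises(RuntimeError, match="variance"):
            align_stack(stack)


class TestEnhance:
    def test_constant_stack_passes_through(self):
        from poreflow import GrayscaleStack

        data = np.full((3, 30, 30), 80.0)
        stack = GrayscaleStack(data, carbon_rows=(2, 6), membrane_rows=(8, 26), membrane_cols=(2, 28))
        with pytest.warns(UserWarning):
            out = enhance_and_correct(stack)
        assert np.array_equal(out.data, data)

    def test_depth_gradient_flattened(self, small_membrane):
        spec = RenderSpec(noise_sd=3.0, depth_gradient=np.linspace(1.0, 2.0, 32))
        stack, _ = render_stack(small_membrane, spec, seed=2)
        out = enhance_and_correct(stack)
        means_in = stack.data.mean(axis=(1, 2))
        means_out = out.data.mean(axis=(1, 2))
        cv_in = means_in.std() / means_in.mean()
        cv_out = means_out.std() / means_out.mean()
        assert cv_in / cv_out >= 5.0

    def test_output_range_contract(self, rendered_fixture):
        stack, _ = rendered_fixture
        out = enhance_and_correct(stack)
        assert out.data.min() >= 0.0
        assert out.data.max() <= stack.data.max() + 1e-9


class TestSegment:
    def test_all_bright_with_manual_threshold_is_all_solid(self):
        from poreflow import GrayscaleStack

        data = np.full((6, 40, 30), 200.0)
        stack = GrayscaleStack(
            data, carbon_rows=(2, 6), membrane_rows=(8, 36), membrane_cols=(2, 28)
        )
        seg = segment_two_zone(stack, manual_thresholds=(50.0, 50.0))
        assert not seg.structure.grid.any()

    def test_zone_boundary_must_be_interior(self, rendered_fixture):
        stack, _ = rendered_fixture
        with pytest.raises(ValueError):
            segment_two_zone(stack, zone_boundary=0)

    def test_unimodal_zone_without_manual_threshold_fails(self):
        from poreflow import GrayscaleStack

        rng = np.random.default_rng(0)
        data = rng.normal(150.0, 2.0, size=(6, 40, 30))
        stack = GrayscaleStack(
            data, carbon_rows=(2, 6), membrane_rows=(8, 36), membrane_cols=(2, 28)
        )
        with pytest.raises(RuntimeError, match="manual"):
            segment_two_zone(stack)

    def test_rendered_stack_misclassification_below_2pct(self, rendered_fixture):
        stack, truth = rendered_fixture
        aligned, _ = align_stack(stack)
        enhanced = enhance_and_correct(aligned)
        seg = segment_two_zone(enhanced)
        miss = (seg.structure.grid != truth["structure"].grid) & seg.valid
        assert miss.sum() / seg.valid.sum() < 0.02

    def test_recovered_porosity_profile_within_003(self, rendered_fixture):
        stack, truth = rendered_fixture
        aligned, _ = align_stack(stack)
        seg = segment_two_zone(enhance_and_correct(aligned))
        p_true = porosity_profile(truth["structure"])
        p_seg = porosity_profile(seg.structure, valid=seg.valid)
        assert np.abs(p_true.porosity - p_seg.porosity).max() <= 0.03

    def test_segmentation_is_deterministic(self, rendered_fixture):
        stack, _ = rendered_fixture
        a = segment_two_zone(enhance_and_correct(stack))
        b = segment_two_zone(enhance_and_correct(stack))
        assert np.array_equal(a.structure.grid, b.structure.grid)


class TestStackIO:
    def test_tiff_roundtrip(self, tmp_path, small_membrane):
        stack, _ = render_stack(small_membrane, RenderSpec(noise_sd=2.0), seed=4)
        path = save_stack(tmp_path / "s.tiff", stack)
        back = load_stack(path)
        assert np.allclose(back.data, stack.data, atol=1e-4)  # float32 on disk
        assert back.carbon_rows == stack.carbon_rows
        assert back.membrane_rows == stack.membrane_rows
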