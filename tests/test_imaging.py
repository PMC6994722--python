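"""Projection, clearing, particle detection and colocalization."""

import numpy as np
import pytest

import engramkit as ek
from engramkit import imaging


def disc_image(shape, center, radius, value=100.0):
    img = np.zeros(shape)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] = value
    return img


def fixed(threshold=50.0, **kw):
    return ek.DetectionParams(threshold_mode="fixed", threshold_value=threshold,
                              background_radius=None, **kw)


class TestProjectStack:
    def test_single_plane_zero_background_is_identity(self):
        img = disc_image((64, 64), (32, 32), 5)
        out = imaging.project_stack(img[None], background_radius=None)
        assert np.array_equal(out, img)

    def test_max_over_planes(self):
        p1 = disc_image((64, 64), (32, 32), 5, 40.0)
        p2 = p1 + 10.0
        out = imaging.project_stack(np.stack([p1, p2]), background_radius=None)
        assert np.array_equal(out, p2)

    def test_projection_joins_blob_split_across_planes(self, fixed_params):
        """A nucleus spread over z is one component in the projection even
        where single planes only hold fragments."""
        rp = ek.RenderParams(seed=33, noise_sd=0.0, background_level=0.0,
                             z_sigma_um=1.0)
        bundle, table = ek.render_slice(ek.EnsembleGroundTruth(n_cells=30), rp)
        from skimage.measure import label

        proj = imaging.project_stack(bundle.channels["hoechst"], None)
        assert label(proj > 75.0, connectivity=2).max() == 30
        # at least one single plane under-segments or misses nuclei
        per_plane = [label(p > 75.0, connectivity=2).max()
                     for p in bundle.channels["hoechst"]]
        assert min(per_plane) < 30

    def test_empty_stack_error(self):
        with pytest.raises(ValueError):
            imaging.project_stack(np.zeros((0, 4, 4)))

    def test_background_subtraction_flattens_offset(self):
        img = disc_image((128, 128), (64, 64), 6, 80.0) + 20.0
        out = imaging.subtract_background(img, radius=30)
        # far from the blob the constant offset is removed
        assert abs(out[5, 5]) < 2.0
        assert out[64, 64] > 50.0


class TestClearOutsideRoi:
    def test_full_mask_identity(self):
        img = np.random.default_rng(0).random((16, 16))
        assert np.array_equal(
            imaging.clear_outside_roi(img, np.ones((16, 16), bool)), img
        )

    def test_empty_mask_zeroes(self):
        img = np.ones((8, 8))
        assert imaging.clear_outside_roi(img, np.zeros((8, 8), bool)).sum() == 0

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError):
            imaging.clear_outside_roi(np.ones((8, 8)), np.ones((4, 4), bool))

    def test_blob_straddling_edge_loses_outside_pixels(self):
        img = disc_image((64, 64), (32, 20), 8)
        mask = np.zeros((64, 64), bool)
        mask[:, 20:] = True
        dets = imaging.detect_particles(
            imaging.clear_outside_roi(img, mask), fixed()
        )
        full = imaging.detect_particles(img, fixed())
        in_mask = int(((img > 50) & mask).sum())
        assert dets[0].pixel_area == in_mask < full[0].pixel_area


class TestDetectParticles:
    def test_particle_filter_is_strict_at_the_boundary(self):
        # 49 and exactly min_size pixels must be dropped; min_size+1 kept
        img = np.zeros((32, 32))
        img[2:9, 2:9] = 100.0  # 49 px
        assert imaging.detect_particles(img, fixed(min_particle_size=50)) == []
        img2 = np.zeros((32, 32))
        img2[2:12, 2:7] = 100.0  # 50 px, strict > filter drops it
        assert imaging.detect_particles(img2, fixed(min_particle_size=50)) == []
        img3 = np.zeros((32, 32))
        img3[2:12, 2:7] = 100.0
        img3[12, 2] = 100.0  # 51 px
        assert len(imaging.detect_particles(img3, fixed(min_particle_size=50))) == 1

    def test_blank_image_empty(self):
        assert imaging.detect_particles(np.zeros((32, 32)), fixed()) == []

    def test_nonfinite_pixels_error(self):
        img = np.zeros((8, 8))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            imaging.detect_particles(img, fixed())

    def test_noiseless_render_exact_count(self, noiseless_render, fixed_params):
        bundle, table = noiseless_render
        proj = imaging.clear_outside_roi(
            imaging.project_stack(bundle.channels["hoechst"], None),
            bundle.mask("total"),
        )
        dets = imaging.detect_particles(proj, fixed_params)
        assert len(dets) == len(table)

    def test_raising_threshold_never_adds_detections(self, noisy_render):
        """Monotone in the resolved regime: once every nucleus is a separate
        component, a higher threshold can only shrink or remove particles
        (below the separation threshold merged clusters split and the count
        rises, so monotonicity only holds from the resolving threshold up)."""
        bundle, _ = noisy_render
        proj = imaging.clear_outside_roi(
            imaging.project_stack(bundle.channels["hoechst"], 50.0),
            bundle.mask("total"),
        )
        counts = [
            len(imaging.detect_particles(proj, fixed(thr)))
            for thr in (70.0, 100.0, 120.0, 140.0, 160.0, 180.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_detection_centroids_inside_roi(self, noisy_render):
        bundle, _ = noisy_render
        proj = imaging.clear_outside_roi(
            imaging.project_stack(bundle.channels["hoechst"], 50.0),
            bundle.mask("total"),
        )
        mask = bundle.mask("total")
        for d in imaging.detect_particles(proj, ek.DetectionParams()):
            r, c = int(round(d.centroid[0])), int(round(d.centroid[1]))
            assert mask[r, c]
            assert d.pixel_area > 50


class TestConfirmAndColocalize:
    def two_discs(self, offset):
        a = imaging.detect_particles(
            disc_image((64, 64), (32, 32), 6), fixed(min_particle_size=20)
        )
        b = imaging.detect_particles(
            disc_image((64, 64), (32, 32 + offset), 6), fixed(min_particle_size=20)
        )
        return a, b

    def test_identical_footprints_all_pair(self):
        a, b = self.two_discs(0)
        assert len(imaging.colocalize(a, b, fixed(min_particle_size=20))) == 1

    def test_disjoint_footprints_empty(self):
        a, b = self.two_discs(30)
        assert imaging.colocalize(a, b, fixed(min_particle_size=20)) == []

    def test_pair_count_bounded_and_symmetric(self, noiseless_render,
                                              fixed_params):
        bundle, _ = noiseless_render
        dets = {}
        for ch in ("gfp", "fos"):
            proj = imaging.clear_outside_roi(
                imaging.project_stack(bundle.channels[ch], None),
                bundle.mask("total"),
            )
            dets[ch] = imaging.detect_particles(proj, fixed_params, channel=ch)
        ab = imaging.colocalize(dets["gfp"], dets["fos"], fixed_params)
        ba = imaging.colocalize(dets["fos"], dets["gfp"], fixed_params)
        assert len(ab) == len(ba)
        assert len(ab) <= min(len(dets["gfp"]), len(dets["fos"]))

    def test_colocalized_pairs_match_ground_truth(self, noiseless_render,
                                                  fixed_params):
        bundle, table = noiseless_render
        dets = {}
        for ch in ("gfp", "fos"):
            proj = imaging.clear_outside_roi(
                imaging.project_stack(bundle.channels[ch], None),
                bundle.mask("total"),
            )
            dets[ch] = imaging.detect_particles(proj, fixed_params, channel=ch)
        pairs = imaging.colocalize(dets["gfp"], dets["fos"], fixed_params)
        assert len(pairs) == int((table.gfp & table.fos).sum())

    def test_signal_without_nucleus_removed(self):
        gfp = imaging.detect_particles(
            disc_image((64, 64), (20, 20), 6), fixed(min_particle_size=20)
        )
        assert imaging.confirm_nuclei(gfp, [], fixed(min_particle_size=20)) == []
        hoechst = imaging.detect_particles(
            disc_image((64, 64), (50, 50), 6), fixed(min_particle_size=20)
        )
        assert imaging.confirm_nuclei(gfp, hoechst,
                                      fixed(min_particle_size=20)) == []

    def test_all_signals_on_nuclei_unchanged(self, noiseless_render,
                                             fixed_params):
        bundle, table = noiseless_render
        projs = {
            ch: imaging.clear_outside_roi(
                imaging.project_stack(bundle.channels[ch], None),
                bundle.mask("total"),
            )
            for ch in bundle.channels
        }
        dets = {ch: imaging.detect_particles(projs[ch], fixed_params, channel=ch)
                for ch in projs}
        confirmed = imaging.confirm_nuclei(dets["gfp"], dets["hoechst"],
                                           fixed_params)
        assert len(confirmed) == len(dets["gfp"]) == int(table.gfp.sum())
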