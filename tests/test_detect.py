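"""Unit and property tests for the iterative detector."""

from collections import defaultdict

import numpy as np
import pytest

from dropletquant import (
    DetectConfig,
    ImageStack,
    ROIMask,
    SyntheticSpec,
    delineate_roi,
    deduplicate,
    erase,
    extract_particles,
    generate_stack,
    iterative_detect,
    smooth,
)


def full_roi(shape):
    return ROIMask(np.ones(shape, dtype=bool)).broadcast(1)


class TestSmooth:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 42.0)
        for sigma in (0.5, 1.0, 3.0):
            assert np.allclose(smooth(img, sigma), img)

    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16))
        out = smooth(img, 0)
        assert np.array_equal(out, img)
        assert out is not img  # a copy, not the same buffer

    def test_impulse_mass_conserved(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1000.0
        out = smooth(img, 2.0)
        assert out.sum() == pytest.approx(1000.0, rel=1e-6)


class TestExtractParticles:
    def _binary_two_blobs(self):
        binary = np.zeros((32, 32), dtype=bool)
        binary[2:3, 2:7] = True  # area 5
        binary[10:13, 10:14] = True  # area 12
        return binary

    def test_min_area_filter(self):
        binary = self._binary_two_blobs()
        original = np.where(binary, 100, 0).astype(np.uint8)
        cfg = DetectConfig(min_area=6)
        out = extract_particles(binary, original, np.ones_like(binary), cfg, 0, 1)
        assert len(out) == 1
        assert out[0].pixel_count == 12
        assert out[0].mean_intensity == pytest.approx(100.0)

    def test_centroid_containment_rule(self):
        binary = np.zeros((32, 32), dtype=bool)
        binary[10:14, 10:14] = True
        roi = np.zeros((32, 32), dtype=bool)
        roi[:, 20:] = True  # blob centroid (11.5, 11.5) falls outside
        cfg = DetectConfig(containment="centroid")
        out = extract_particles(binary, binary * 50, roi, cfg, 0, 1)
        assert out == []

    def test_full_containment_rule(self):
        binary = np.zeros((32, 32), dtype=bool)
        binary[10:14, 10:14] = True
        roi = np.zeros((32, 32), dtype=bool)
        roi[10:14, 10:12] = True  # covers only half the blob
        assert extract_particles(
            binary, binary * 50, roi, DetectConfig(containment="full"), 0, 1
        ) == []
        roi[10:14, 10:14] = True
        assert (
            len(
                extract_particles(
                    binary, binary * 50, roi, DetectConfig(containment="full"), 0, 1
                )
            )
            == 1
        )

    def test_all_false_binary_yields_empty_list(self):
        binary = np.zeros((16, 16), dtype=bool)
        out = extract_particles(
            binary, np.zeros_like(binary, dtype=np.uint8),
            np.ones_like(binary), DetectConfig(), 0, 1,
        )
        assert out == []


class TestErase:
    def test_empty_particle_list_is_a_bitwise_noop(self):
        rng = np.random.default_rng(1)
        img = rng.random((16, 16))
        before = img.copy()
        erase(img, [], 0.0)
        assert np.array_equal(img, before)

    def test_fill_zero_erases_exactly_the_particle_pixels(self):
        img = np.full((32, 32), 200.0)
        binary = np.zeros((32, 32), dtype=bool)
        binary[5:10, 5:10] = True
        [p] = extract_particles(
            binary, img.astype(np.uint8), np.ones_like(binary),
            DetectConfig(erase_fill="zero"), 0, 1,
        )
        erase(img, [p], 0.0)
        assert (img == 0).sum() == p.pixel_count == 25

    def test_redetection_never_reuses_erased_pixels(self, two_blob_slice):
        stack = ImageStack(voxels=two_blob_slice[None], bit_depth=8)
        ps = iterative_detect(stack, full_roi(two_blob_slice.shape), DetectConfig())
        seen = set()
        for p in ps.particles:
            px = {tuple(c) for c in p.pixels}
            assert not (px & seen)
            seen |= px


class TestIterativeDetect:
    def test_all_background_stack_yields_no_particles(self):
        stack = ImageStack(
            voxels=np.full((3, 32, 32), 10, dtype=np.uint8), bit_depth=8
        )
        roi = ROIMask(np.ones((32, 32), dtype=bool)).broadcast(3)
        ps = iterative_detect(stack, roi, DetectConfig())
        assert ps.particles == []
        # every slice terminates during its first iteration
        assert all(e["iteration"] == 1 for e in ps.threshold_log)

    def test_detection_is_deterministic(self, benchmark):
        _, stack, _, roi = benchmark
        a = iterative_detect(stack, roi, DetectConfig())
        b = iterative_detect(stack, roi, DetectConfig())
        assert len(a.particles) == len(b.particles)
        for p, q in zip(a.particles, b.particles):
            assert p.centroid == q.centroid
            assert p.pixel_count == q.pixel_count
            assert np.array_equal(p.pixels, q.pixels)
        assert a.threshold_log == b.threshold_log

    def test_brighter_droplets_surface_in_earlier_iterations(self):
        spec = SyntheticSpec(
            shape=(4, 256, 256), tissue_center=(128.0, 128.0),
            tissue_radius=100.0, n_droplets=15, seed=7,
        )
        stack, truth = generate_stack(spec)
        roi = delineate_roi(stack)
        ps = deduplicate(iterative_detect(stack, roi, DetectConfig()))
        centers = np.array([r.center for r in truth.records])
        amps = np.array([r.peak_intensity for r in truth.records])
        amp_by_iter = defaultdict(list)
        for p in ps.kept():
            d = np.hypot(p.centroid[0] - centers[:, 0], p.centroid[1] - centers[:, 1])
            j = int(np.argmin(d))
            if d[j] <= 4:
                amp_by_iter[p.iteration].append(amps[j])
        assert amp_by_iter[1], "no droplets found on the first pass"
        later = [a for it, v in amp_by_iter.items() if it > 1 for a in v]
        assert later, "no droplets surfaced after the first pass"
        assert np.mean(amp_by_iter[1]) > np.mean(later)

    def test_threshold_sequence_non_increasing_per_slice(self, benchmark_particles):
        per_slice = defaultdict(list)
        for e in benchmark_particles.threshold_log:
            if "threshold_value" in e:
                per_slice[e["slice"]].append(e["threshold_value"])
        assert per_slice
        for seq in per_slice.values():
            assert all(a >= b for a, b in zip(seq, seq[1:]))

    def test_pixel_disjointness_across_iterations(self, benchmark_particles):
        per_slice = defaultdict(set)
        for p in benchmark_particles.particles:
            px = {tuple(c) for c in p.pixels}
            assert not (px & per_slice[p.slice_index])
            per_slice[p.slice_index] |= px

    def test_count_conservation_against_threshold_log(self, benchmark_particles):
        logged = sum(
            e.get("n_particles", 0) for e in benchmark_particles.threshold_log
        )
        assert logged == len(benchmark_particles.particles)

    def test_single_slice_stack_is_valid(self, two_blob_slice):
        stack = ImageStack(voxels=two_blob_slice[None], bit_depth=8)
        ps = iterative_detect(stack, full_roi(two_blob_slice.shape), DetectConfig())
        assert len(ps.particles) >= 1
        out = deduplicate(ps)  # dedup on one slice: same-slice links only
        assert len(out.kept()) >= 1


class TestDetectConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_area": 0},
            {"min_area": 50, "max_area": 50},
            {"min_circularity": 1.5},
            {"max_iterations": 0},
            {"sigma": -1},
            {"erase_fill": "nonsense"},
            {"containment": "nonsense"},
            {"erase_margin": -1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectConfig(**kwargs)
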