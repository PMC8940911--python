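"""Percentile segmentation, background estimation, and the two pipelines."""

import numpy as np
import pytest

from somatrace import extraction as ex
from somatrace import synthetic_data as sd
from somatrace.config import PipelineConfig
from somatrace.core import BoundingBox
from somatrace.detection import ReferenceBlobDetector
from somatrace.tracking import IdentityRegistry, update_tracks
from somatrace.detection import DetectionSet
from somatrace.traces import TraceSet


def _manual_percentile(sorted_vals, q):
    """Sort-based linear-interpolation percentile, written independently."""
    pos = q / 100.0 * (len(sorted_vals) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def _segment_oracle(patch, p_low, p_high):
    """Brute-force mask + mean via explicit sorting and looping."""
    flat = sorted(patch.ravel().tolist())
    lo = _manual_percentile(flat, p_low)
    hi = _manual_percentile(flat, p_high)
    selected = [v for v in patch.ravel().tolist() if lo <= v <= hi]
    return lo, hi, selected


class TestSegmentBox:
    def test_permilles_of_0_to_99(self):
        # 100 pixels valued 0..99: P80 = 79.2, P95 = 94.05 -> values 80..94
        frame = np.arange(100.0).reshape(10, 10)
        rng = np.random.default_rng(0)
        frame = rng.permutation(frame.ravel()).reshape(10, 10)
        mask, mean = ex.segment_box(frame, BoundingBox(0, 0, 10, 10))
        assert mask.sum() == 15
        assert sorted(frame[mask].tolist()) == list(range(80, 95))
        assert mean == pytest.approx(87.0)

    def test_constant_box_selects_everything(self):
        frame = np.full((8, 8), 3.5)
        mask, mean = ex.segment_box(frame, BoundingBox(1, 1, 6, 6))
        assert mask.all()
        assert mean == 3.5

    def test_matches_brute_force_oracle_on_random_boxes(self, rng):
        frame = rng.normal(size=(60, 60))
        for _ in range(200):
            x0, y0 = rng.integers(0, 50, size=2)
            w, h = rng.integers(3, 10, size=2)
            box = BoundingBox(int(x0), int(y0), int(x0 + w), int(y0 + h))
            mask, mean = ex.segment_box(frame, box)
            patch = frame[int(y0) : int(y0 + h), int(x0) : int(x0 + w)]
            lo, hi, selected = _segment_oracle(patch, 80, 95)
            assert mask.sum() == len(selected)
            assert mean == pytest.approx(np.mean(selected))

    def test_empty_box_rejected(self):
        frame = np.zeros((10, 10))
        with pytest.raises(ValueError):
            ex.segment_box(frame, BoundingBox(20, 20, 25, 25))


class TestGlobalBackground:
    def test_uniform_frame_any_boxes(self):
        frame = np.full((20, 20), 4.0)
        assert ex.global_background(frame, [BoundingBox(0, 0, 5, 5)]) == 4.0

    def test_box_pixels_excluded(self):
        frame = np.zeros((4, 4))
        frame[1:3, 1:3] = 10.0
        assert ex.global_background(frame, [BoundingBox(1, 1, 3, 3)]) == 0.0

    def test_matches_masked_mean_oracle(self, rng):
        for _ in range(50):
            frame = rng.normal(size=(30, 30))
            boxes = [
                BoundingBox(int(x), int(y), int(x) + 5, int(y) + 5)
                for x, y in rng.integers(0, 25, size=(3, 2))
            ]
            # oracle: explicit per-pixel loop
            total, count = 0.0, 0
            for r in range(30):
                for c in range(30):
                    inside = any(
                        b.x_min <= c < b.x_max and b.y_min <= r < b.y_max for b in boxes
                    )
                    if not inside:
                        total += frame[r, c]
                        count += 1
            assert ex.global_background(frame, boxes) == pytest.approx(total / count)

    def test_full_coverage_rejected(self):
        frame = np.zeros((4, 4))
        with pytest.raises(ValueError, match="background"):
            ex.global_background(frame, [BoundingBox(0, 0, 4, 4)])


class TestLocalBackground:
    def test_isolated_box_in_uniform_frame(self):
        frame = np.full((40, 40), 6.0)
        assert ex.local_background(frame, BoundingBox(15, 15, 25, 25), []) == 6.0

    def test_neighbor_box_pixels_excluded(self):
        frame = np.full((40, 40), 5.0)
        box = BoundingBox(16, 16, 24, 24)
        neighbor = BoundingBox(26, 16, 28, 20)  # inside the doubled surround
        frame[16:20, 26:28] = 1000.0  # outlier values under the neighbor
        with_neighbor = ex.local_background(frame, box, [box, neighbor])
        assert with_neighbor == pytest.approx(5.0)

    def test_doubled_box_clipped_at_fov(self):
        frame = np.full((30, 30), 2.0)
        box = BoundingBox(0, 0, 8, 8)
        assert ex.local_background(frame, box, [box]) == pytest.approx(2.0)

    def test_no_eligible_pixels_gives_nan(self):
        frame = np.zeros((8, 8))
        box = BoundingBox(0, 0, 8, 8)
        assert np.isnan(ex.local_background(frame, box, [box]))


class TestExtractFrame:
    def _registry_with(self, boxes, fov=(32, 32)):
        registry = IdentityRegistry(fov_shape=fov)
        update_tracks(registry, DetectionSet(frame_index=0, boxes=boxes))
        return registry

    def test_uniform_frame_gives_zero_after_subtraction(self):
        registry = self._registry_with([BoundingBox(5, 5, 15, 15)])
        traces = TraceSet()
        ex.extract_frame(np.full((32, 32), 9.0), registry, traces)
        assert traces.trace(0)[0] == 0.0

    def test_common_mode_offset_rejected(self, rng):
        frame = rng.uniform(0, 100, size=(32, 32))
        registry = self._registry_with([BoundingBox(4, 4, 14, 14), BoundingBox(20, 20, 28, 28)])
        a, b = TraceSet(), TraceSet()
        ex.extract_frame(frame, registry, a)
        ex.extract_frame(frame + 55.5, registry, b)
        for ident in (0, 1):
            assert a.trace(ident)[0] == pytest.approx(b.trace(ident)[0], abs=1e-9)

    def test_noiseless_trace_tracks_ground_truth(self, small_movie):
        stack, gt_boxes, gt_traces = small_movie
        registry = self._registry_with(list(gt_boxes), fov=stack.fov_shape)
        traces = TraceSet(frame_rate=stack.frame_rate)
        for frame in stack:
            ex.extract_frame(frame, registry, traces)
        matched = 0
        for ident, box in enumerate(registry.current_boxes()):
            gt_idx = max(
                range(len(gt_boxes)),
                key=lambda j: box.intersection_area(gt_boxes[j]),
            )
            gt = gt_traces.trace(gt_idx)
            if np.std(gt) == 0:
                continue
            r = np.corrcoef(traces.trace(ident), gt)[0, 1]
            assert r > 0.99
            matched += 1
        assert matched > 0


class TestPipelines:
    def test_online_sequential_equals_threaded(self, small_movie):
        stack, _, _ = small_movie
        config = PipelineConfig(n_frames=5, mode="sliding", score_threshold=0.2)
        det = ReferenceBlobDetector()
        seq_traces, seq_reg, _ = ex.run_online(stack, config, detector=det)
        thr_traces, thr_reg, _ = ex.run_online_threaded(stack, config, detector=det)
        assert seq_traces == thr_traces
        assert seq_reg.to_json() == thr_reg.to_json()

    def test_offline_static_movie_constant_soma_means(self, static_movie):
        stack, _, _ = static_movie
        traces, registry = ex.run_offline(stack, PipelineConfig(score_threshold=0.2))
        assert len(registry) > 0
        for ident in traces.identities:
            tr = traces.trace(ident)
            assert np.ptp(tr) == pytest.approx(0.0, abs=1e-9)

    def test_offline_box_set_static_across_frames(self, static_movie):
        stack, _, _ = static_movie
        _, registry = ex.run_offline(stack, PipelineConfig(score_threshold=0.2))
        for identity in registry.identities.values():
            assert len(identity.history) == 1  # single detection, never updated

    def test_online_step_nT_matches_offline_where_defined(self, static_movie):
        stack, _, _ = static_movie
        config = PipelineConfig(
            n_frames=stack.n_frames, mode="step", score_threshold=0.2
        )
        det = ReferenceBlobDetector()
        on_traces, on_reg, _ = ex.run_online(stack, config, detector=det)
        off_traces, off_reg = ex.run_offline(
            stack, PipelineConfig(score_threshold=0.2), detector=det
        )
        # identical final box sets, exactly
        on_boxes = [(b.x_min, b.y_min, b.x_max, b.y_max) for b in on_reg.current_boxes()]
        off_boxes = [(b.x_min, b.y_min, b.x_max, b.y_max) for b in off_reg.current_boxes()]
        assert sorted(on_boxes) == sorted(off_boxes)
        # trace samples agree exactly wherever the online run defines them
        assert on_traces.identities == off_traces.identities
        for ident in on_traces.identities:
            a, b = on_traces.trace(ident), off_traces.trace(ident)
            defined = ~np.isnan(a)
            assert defined.any()
            assert np.array_equal(a[defined], b[defined])

    def test_trace_missing_before_first_detection(self, small_movie):
        stack, _, _ = small_movie
        config = PipelineConfig(n_frames=5, mode="sliding", score_threshold=0.2)
        traces, _, _ = ex.run_online(stack, config, detector=ReferenceBlobDetector())
        for ident in traces.identities:
            first = traces.first_valid[ident]
            assert first >= 4  # buffer warm-up: no detection before frame n-1
            assert np.isnan(traces.trace(ident)[:first]).all()
            assert not np.isnan(traces.trace(ident)[first])

    def test_shape_change_mid_stream_aborts(self):
        frames = [np.zeros((16, 16)), np.zeros((16, 17))]
        with pytest.raises(RuntimeError, match="shape"):
            ex.run_online(iter(frames), PipelineConfig(n_frames=1))


class TestDecorrelation:
    def test_bg_subtraction_removes_common_neuropil(self):
        cfg = sd.default_scene_config(
            n_cells=10, fov_shape=(128, 128), n_frames=120,
            neuropil_amplitude=40.0, noise_sigma=1.0, spike_rate=0.1,
        )
        scene = sd.generate_scene(cfg, seed=33)
        stack, gt_boxes, _ = sd.render_movie(scene)
        registry = IdentityRegistry(fov_shape=stack.fov_shape)
        update_tracks(registry, DetectionSet(frame_index=0, boxes=list(gt_boxes)))
        traces = TraceSet(frame_rate=stack.frame_rate)
        raw = {i: [] for i in range(len(gt_boxes))}
        for frame in stack:
            ex.extract_frame(frame, registry, traces)
            for ident, identity in registry.identities.items():
                _, soma = ex.segment_box(frame, identity.box)
                raw[ident].append(soma)

        def mean_pairwise(series):
            mat = np.corrcoef(np.asarray(series))
            iu = np.triu_indices_from(mat, k=1)
            return float(np.mean(mat[iu]))

        before = mean_pairwise([raw[i] for i in sorted(raw)])
        after = mean_pairwise([traces.trace(i) for i in traces.identities])
        assert before > after
        assert before - after > 0.3
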