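import numpy as np
import pytest

from spaf import (
    FilterSpec,
    SpafConfig,
    count_residues,
    global_paf,
    patch_mask,
    residue_map,
    residue_mask,
    run_spaf,
    spaf_step,
    wrap,
)
from spaf.synthetic import vortex_phase

import _oracles


class TestPatchMask:
    def test_empty_fpr_gives_empty_mask(self):
        assert not patch_mask(np.zeros((10, 10), dtype=bool), 5).any()

    def test_single_center_fpr_wp3(self):
        fpr = np.zeros((11, 11), dtype=bool)
        fpr[5, 5] = True
        mask = patch_mask(fpr, 3)
        assert mask.sum() == 9
        assert mask[4:7, 4:7].all()

    def test_wp2_covers_exactly_the_residue_loop(self):
        fpr = np.zeros((8, 8), dtype=bool)
        fpr[3, 4] = True
        mask = patch_mask(fpr, 2)
        assert set(map(tuple, np.argwhere(mask))) == {(3, 4), (3, 5), (4, 4), (4, 5)}

    def test_clipped_at_borders(self):
        fpr = np.zeros((6, 6), dtype=bool)
        fpr[0, 0] = True
        mask = patch_mask(fpr, 5)
        assert mask.sum() == 9  # 3x3 survives the clip

    def test_overlapping_squares_match_set_union(self):
        fpr = np.zeros((20, 20), dtype=bool)
        fprs = [(9, 8), (9, 10)]  # two FPRs 2 px apart
        for r, c in fprs:
            fpr[r, c] = True
        mask = patch_mask(fpr, 5)
        expected = _oracles.brute_patch_union(fprs, 5, (20, 20))
        assert set(map(tuple, np.argwhere(mask))) == expected

    def test_rejects_nonpositive_wp(self):
        with pytest.raises(ValueError):
            patch_mask(np.zeros((4, 4), dtype=bool), 0)


class TestSpafStep:
    def test_empty_fpr_is_identity(self, small_noisy_phase):
        fpr = np.zeros_like(small_noisy_phase, dtype=bool)
        out = spaf_step(small_noisy_phase, fpr, FilterSpec(3, 3), 3)
        assert np.array_equal(out, small_noisy_phase)

    def test_pixels_outside_patch_bit_identical(self):
        v = vortex_phase((21, 21), [(10.5, 10.5, 1)])
        fpr = residue_mask(residue_map(v))
        out = spaf_step(v, fpr, FilterSpec(3, 3), 3)
        mask = patch_mask(fpr, 3)
        assert np.array_equal(out[~mask], v[~mask])

    def test_equals_masked_blend_of_global_paf(self, small_noisy_phase):
        fpr = residue_mask(residue_map(small_noisy_phase))
        spec = FilterSpec(5, 5)
        out = spaf_step(small_noisy_phase, fpr, spec, 4)
        mask = patch_mask(fpr, 4)
        blend = np.where(mask, global_paf(small_noisy_phase, spec), small_noisy_phase)
        assert np.array_equal(out, blend)


class TestRunSpaf:
    def test_residue_free_input_returned_unchanged(self):
        smooth = wrap(np.fromfunction(lambda i, j: 0.02 * (i + j), (32, 32)))
        out, trace = run_spaf(smooth)
        assert np.array_equal(out, smooth)
        assert trace.status == "residue-free"
        assert len(trace.records) == 1

    def test_vortex_pair_removed_locally(self):
        centers = [(60.5, 62.5), (60.5, 65.5)]
        v = vortex_phase((128, 128), [(r, c, q) for (r, c), q in zip(centers, (1, -1))])
        cfg = SpafConfig()
        out, trace = run_spaf(v, cfg)
        assert trace.status == "residue-free"
        assert count_residues(out) == 0
        rows, cols = np.indices(v.shape)
        dist = np.min(
            [np.hypot(rows - r, cols - c) for r, c in centers], axis=0
        )
        far = dist > cfg.wp_max + cfg.wf_max
        assert np.array_equal(out[far], v[far])

    def test_trace_starts_at_input_residue_count(self, small_noisy_phase):
        out, trace = run_spaf(small_noisy_phase)
        assert trace.records[0].n_residues == count_residues(small_noisy_phase)
        assert trace.final_residues == count_residues(out)

    def test_schedule_is_lexicographically_nondecreasing(self, small_noisy_phase):
        _, trace = run_spaf(small_noisy_phase)
        seq = [(r.wp, r.wf_rows) for r in trace.records]
        assert all(a <= b for a, b in zip(seq, seq[1:]))

    def test_idempotent_at_fixpoint(self, small_noisy_phase):
        out, trace = run_spaf(small_noisy_phase)
        assert trace.status == "residue-free"
        again, trace2 = run_spaf(out)
        assert np.array_equal(again, out)
        assert len(trace2.records) == 1

    def test_each_iteration_changes_only_patch_pixels(self, small_noisy_phase):
        seen = []

        def check(m, before, after, mask):
            changed = before != after
            assert not np.any(changed & ~mask)
            seen.append(m)

        run_spaf(small_noisy_phase, on_iteration=check)
        assert seen  # the callback actually ran

    def test_cap_reached_reported_not_raised(self, rng):
        noise = wrap(rng.uniform(-np.pi, np.pi, (48, 48)))
        out, trace = run_spaf(noise, SpafConfig(wf_max=3, wp_max=2, max_iterations=60))
        assert trace.status in ("cap-reached", "max-iter")
        assert trace.final_residues > 0

    def test_escalate_every_iteration_mode(self, small_noisy_phase):
        out, trace = run_spaf(
            small_noisy_phase, SpafConfig(escalate_on="always", max_iterations=50)
        )
        wfs = [r.wf_rows for r in trace.records[:4]]
        assert wfs[1] < wfs[2] <= wfs[3] or trace.status == "residue-free"

    def test_trace_csv_roundtrip(self, small_noisy_phase, tmp_path):
        _, trace = run_spaf(small_noisy_phase)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        rows = path.read_text().strip().splitlines()
        assert rows[0] == "iteration,wf_rows,wf_cols,wp,n_residues"
        assert len(rows) == len(trace.records) + 1


@pytest.mark.parametrize(
    "kwargs",
    [
        {"wf_start": 5, "wf_max": 3},
        {"wp_start": 9, "wp_max": 5},
        {"wf_start": 2},
        {"wp_start": 0},
        {"max_iterations": 0},
        {"escalate_on": "sometimes"},
        {"filter_mode": "boxcar"},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        SpafConfig(**kwargs)
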