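"""Background subtraction, segmentation, gating, droplet detection, statistics."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import sparkdrop as sd
from sparkdrop.population import simulate_activity, simulate_roster
from sparkdrop.quant import (
    CellMask,
    Droplet,
    DropletSet,
    QuantParams,
    bright_pixel_mask,
    build_trace,
    contrast_score,
    detect_droplets,
    disk_footprint,
    gate_expression,
    normalize_trace,
    rolling_ball_subtract,
    segment_cells,
    spark_stat_area,
    spark_stat_intensity_ratio,
    spark_stat_sd,
)

from conftest import make_single_cell_config


def brute_force_opening(frame: np.ndarray, radius: int) -> np.ndarray:
    """Independent oracle: explicit min-then-max sliding window over a disk."""
    fp = disk_footprint(radius)
    out = frame
    for op in (np.min, np.max):
        pad = np.pad(out, radius, mode="symmetric")
        res = np.empty_like(frame, dtype=float)
        for i in range(frame.shape[0]):
            for j in range(frame.shape[1]):
                res[i, j] = op(pad[i:i + 2 * radius + 1, j:j + 2 * radius + 1][fp])
        out = res
    return out


def toy_mask(labels: np.ndarray) -> CellMask:
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rr, cc = np.nonzero(labels == lab)
        rows.append(
            {"label": int(lab), "area": len(rr), "cy": rr.mean(), "cx": cc.mean(),
             "b_c": 1.0, "gated": True}
        )
    return CellMask(labels=labels, table=pd.DataFrame(rows))


class TestRollingBall:
    def test_constant_frame_maps_to_zero(self):
        out = rolling_ball_subtract(np.full((20, 20), 37.0), 4)
        assert np.all(out == 0.0)

    def test_isolated_punctum_is_preserved_exactly(self):
        frame = np.full((32, 32), 10.0)
        frame[14:17, 14:17] += 50.0
        out = rolling_ball_subtract(frame, 10)
        expected = np.zeros((32, 32))
        expected[14:17, 14:17] = 50.0
        assert np.array_equal(out, expected)

    @pytest.mark.parametrize("radius", [2, 3, 5])
    def test_matches_brute_force_opening(self, radius):
        rng = np.random.default_rng(radius)
        frame = rng.uniform(0, 100, (20, 20))
        mine = rolling_ball_subtract(frame, radius)
        oracle = frame - brute_force_opening(frame, radius)
        assert np.abs(mine - oracle).max() == 0.0

    def test_output_is_nonnegative(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 500, (40, 40))
        assert rolling_ball_subtract(frame, 6).min() >= 0.0

    def test_translation_equivariant_away_from_borders(self):
        rng = np.random.default_rng(1)
        frame = rng.uniform(0, 100, (48, 48))
        shifted = np.roll(frame, (5, 3), axis=(0, 1))
        a = rolling_ball_subtract(frame, 4)
        b = rolling_ball_subtract(shifted, 4)
        inner = slice(12, 36)
        assert np.allclose(np.roll(a, (5, 3), axis=(0, 1))[inner, inner], b[inner, inner])

    def test_background_estimate_is_idempotent(self):
        from scipy import ndimage

        rng = np.random.default_rng(2)
        frame = rng.uniform(0, 100, (32, 32))
        fp = disk_footprint(4)
        opened = ndimage.grey_opening(frame, footprint=fp)
        assert np.allclose(ndimage.grey_opening(opened, footprint=fp), opened)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError, match="exceeds half"):
            rolling_ball_subtract(np.zeros((20, 20)), 11)


class TestSegmentation:
    def test_counts_every_disk(self):
        cfg = sd.SyntheticConfig(
            n_cells=50, frame_shape=(512, 512), cell_radius=10.0, seed=4
        )
        roster = simulate_roster(cfg)
        proto = sd.single_stimulus_protocol("adenosine")
        stack = sd.render_stack(
            roster, simulate_activity(roster, proto),
            sd.OpticsConfig(frame_shape=(512, 512), seed=5), proto,
        )
        mask = segment_cells(stack.baseline_frame(), QuantParams(min_cell_area=40))
        assert mask.n_cells == 50

    def test_blank_frame_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="no cells"):
            segment_cells(rng.normal(100, 3, (128, 128)))

    def test_brightness_proxy_tracks_expression(self):
        # doubling a cell's biosensor level doubles its background-corrected B_c
        b = {}
        for e in (150.0, 300.0):
            cfg = make_single_cell_config(expression_mu=np.log(e))
            roster = simulate_roster(cfg)
            proto = sd.single_stimulus_protocol("adenosine")
            stack = sd.render_stack(
                roster, simulate_activity(roster, proto),
                sd.OpticsConfig(frame_shape=cfg.frame_shape, seed=5), proto,
            )
            b[e] = segment_cells(stack.baseline_frame()).table.b_c.iloc[0]
        assert b[300.0] / b[150.0] == pytest.approx(2.0, rel=0.05)


class TestGating:
    def make_mask(self, b_values):
        labels = np.zeros((8, 8 * len(b_values)), dtype=np.int32)
        rows = []
        for i, b in enumerate(b_values):
            labels[2:6, 8 * i + 2:8 * i + 6] = i + 1
            rows.append({"label": i + 1, "area": 16, "cy": 4.0, "cx": 8.0 * i + 4,
                         "b_c": b, "gated": True})
        return CellMask(labels=labels, table=pd.DataFrame(rows))

    def test_zero_threshold_gates_everyone(self):
        mask = self.make_mask([5.0, 50.0, 500.0])
        gated = gate_expression(mask, QuantParams(expression_threshold=0.0))
        assert gated.table.gated.all()

    def test_above_max_threshold_gates_no_one(self):
        mask = self.make_mask([5.0, 50.0, 500.0])
        gated = gate_expression(mask, QuantParams(expression_threshold=501.0))
        assert not gated.table.gated.any()

    def test_gating_is_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        mask = self.make_mask(list(rng.uniform(1, 100, 12)))
        previous = None
        for thr in (0.0, 10.0, 30.0, 60.0, 90.0, 120.0):
            gated = set(gate_expression(mask, QuantParams(expression_threshold=thr)).gated_labels)
            if previous is not None:
                assert gated <= previous
            previous = gated

    def test_percentile_mode(self):
        mask = self.make_mask([10.0, 20.0, 30.0, 40.0])
        gated = gate_expression(
            mask, QuantParams(expression_threshold=50.0, threshold_mode="percentile")
        )
        assert list(gated.gated_labels) == [3, 4]


class TestDropletDetection:
    def test_single_bright_punctum_is_one_droplet(self):
        rng = np.random.default_rng(0)
        frame = np.abs(rng.normal(0, 1.0, (32, 32)))
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[4:28, 4:28] = 1
        frame[14:17, 14:17] += 50.0  # ~50x the MAD
        drops = detect_droplets(frame, toy_mask(labels), QuantParams())
        assert len(drops.droplets) == 1
        assert drops.droplets[0].area == 9

    def test_droplets_stay_inside_cell_masks(self, adenosine_field):
        res = adenosine_field
        frame = res.stack.frames[-1].astype(float)
        sub = rolling_ball_subtract(frame, 5)
        drops = detect_droplets(sub, res.mask, QuantParams(rolling_ball_radius=5))
        for d in drops.droplets:
            assert np.all(res.mask.labels[d.pixels] == d.label)

    def test_false_positive_rate_below_one_percent_on_noise(self):
        # quiescent population: no droplet mass anywhere, droplets detected
        # across cells x frames must stay < 1 per 100 cells
        cfg = sd.SyntheticConfig(
            n_cells=100, frame_shape=(512, 512), cell_radius=10.0,
            frac_capable=0.0, frac_pka_responsive=0.0, hormone_panel={}, seed=9,
        )
        roster = simulate_roster(cfg)
        proto = sd.single_stimulus_protocol("forskolin", "adenylyl_cyclase_activator",
                                            stim_min=6.0, duration_min=16.0)
        optics = sd.OpticsConfig(frame_shape=(512, 512), frame_interval=2.0, seed=10)
        stack = sd.render_stack(roster, simulate_activity(roster, proto), optics, proto)
        params = QuantParams(rolling_ball_radius=5, min_cell_area=40)
        mask = segment_cells(stack.baseline_frame(), params)
        n_drops = 0
        for j in range(stack.n_frames):
            sub = rolling_ball_subtract(stack.frames[j].astype(float), 5)
            n_drops += len(detect_droplets(sub, mask, params).droplets)
        rate = n_drops / (mask.n_cells * stack.n_frames)
        assert rate < 0.01

    def test_unsubtracted_frame_rejected(self):
        labels = np.ones((8, 8), dtype=np.int32)
        with pytest.raises(ValueError, match="background-subtracted"):
            detect_droplets(np.zeros((8, 8)), toy_mask(labels), subtracted=False)


class TestStatistics:
    def toy_cell(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[1:7, 1:7] = 1
        frame = np.full((8, 8), 10.0)
        return frame, toy_mask(labels)

    def test_ratio_no_droplets_is_zero(self):
        frame, mask = self.toy_cell()
        assert spark_stat_intensity_ratio(frame, mask, 1, np.zeros((8, 8), bool)) == 0.0

    def test_ratio_full_cell_is_one(self):
        frame, mask = self.toy_cell()
        assert spark_stat_intensity_ratio(frame, mask, 1, mask.labels == 1) == 1.0

    def test_ratio_matches_hand_sum(self):
        frame, mask = self.toy_cell()
        frame[2, 2], frame[2, 3] = 60.0, 40.0
        droplet = np.zeros((8, 8), bool)
        droplet[2, 2], droplet[2, 3] = True, True
        total = 34 * 10.0 + 60.0 + 40.0
        assert spark_stat_intensity_ratio(frame, mask, 1, droplet) == pytest.approx(
            100.0 / total
        )

    def test_ratio_zero_intensity_cell_raises(self):
        frame, mask = self.toy_cell()
        with pytest.raises(ValueError, match="zero total intensity"):
            spark_stat_intensity_ratio(np.zeros((8, 8)), mask, 1, None)

    def test_sd_uniform_cell_is_zero(self):
        frame, mask = self.toy_cell()
        assert spark_stat_sd(frame, mask, 1) == 0.0

    def test_sd_two_pixel_closed_form(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0, 0] = labels[0, 1] = 1
        frame = np.zeros((4, 4))
        frame[0, 0], frame[0, 1] = 3.0, 11.0
        assert spark_stat_sd(frame, toy_mask(labels), 1) == pytest.approx(abs(3 - 11) / 2)

    def test_sd_rises_when_punctum_added(self):
        frame, mask = self.toy_cell()
        flat = spark_stat_sd(frame, mask, 1)
        frame[3, 3] += 80.0
        assert spark_stat_sd(frame, mask, 1) > flat

    def test_area_sums_components(self):
        drops = DropletSet(
            droplets=[Droplet(1, a, 0.0) for a in (5, 7, 12)], subtracted=True
        )
        assert spark_stat_area(drops, 1) == 24.0

    def test_area_empty_is_zero(self):
        assert spark_stat_area(DropletSet(droplets=[]), 1) == 0.0

    def test_area_equals_union_pixel_count(self):
        rng = np.random.default_rng(4)
        frame = np.abs(rng.normal(0, 1.0, (32, 32)))
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[2:30, 2:30] = 1
        frame[5:8, 5:9] += 60.0
        frame[20:24, 18:21] += 60.0
        drops = detect_droplets(frame, toy_mask(labels), QuantParams())
        union = np.zeros((32, 32), bool)
        for d in drops.droplets:
            union[d.pixels] = True
        assert drops.total_area(1) == union.sum()

    def test_area_invariant_to_raw_frame_offset_ratio_not(self):
        frame, mask = self.toy_cell()
        rng = np.random.default_rng(5)
        frame = frame + np.abs(rng.normal(0, 1.0, frame.shape))
        frame[3, 3:6] += 50.0
        params = QuantParams()

        def area_of(f):
            sub = rolling_ball_subtract(f, 3)
            return detect_droplets(sub, mask, replace(params, rolling_ball_radius=3)).total_area(1)

        def ratio_of(f):
            bright = bright_pixel_mask(f, mask, 1)
            return spark_stat_intensity_ratio(f, mask, 1, bright)

        assert area_of(frame + 100.0) == area_of(frame)
        assert ratio_of(frame + 100.0) != ratio_of(frame)


class TestTraces:
    def test_nonresponder_area_trace_is_flat_zero(self, forskolin_field):
        res = forskolin_field
        match = sd.match_labels_to_roster(res.mask, res.roster)
        lut = match.set_index("label")["cell_id"].to_dict()
        capable = res.roster.cells.set_index("cell_id")["capable"]
        for lab in res.trace.labels:
            cid = lut[lab]
            if cid >= 0 and not capable[cid]:
                assert np.count_nonzero(res.trace.row(lab)) <= 1  # rare noise blip

    def test_sd_trace_positive_at_baseline(self, forskolin_field):
        res = forskolin_field
        trace = build_trace(res.stack, res.mask, QuantParams(rolling_ball_radius=5), "sd")
        assert (trace.values[:, 0] > 0).all()

    def test_trace_csv_round_trip(self, forskolin_field, tmp_path):
        res = forskolin_field
        res.trace.to_csv(tmp_path / "t.csv")
        back = sd.SparkTrace.from_csv(tmp_path / "t.csv", res.trace.protocol)
        assert np.allclose(back.values, res.trace.values)
        assert np.array_equal(back.labels, res.trace.labels)


class TestNormalization:
    def make_trace(self, values):
        proto = sd.single_stimulus_protocol("a", stim_min=6.0, duration_min=30.0)
        values = np.asarray(values, dtype=float)[None]
        return sd.SparkTrace(
            labels=np.array([1]),
            times=np.linspace(0, 30, values.shape[1]),
            values=values,
            statistic="area",
            protocol=proto,
        )

    def test_constant_trace_to_max_is_all_ones(self):
        out = normalize_trace(self.make_trace([5, 5, 5, 5]), "to_max")
        assert np.all(out.values == 1.0)

    def test_to_t0_fold_change(self):
        out = normalize_trace(self.make_trace([2, 4, 8]), "to_t0")
        assert np.allclose(out.values, [[1, 2, 4]])

    def test_to_t0_zero_baseline_raises(self):
        with pytest.raises(ValueError, match="positive value at the zero time"):
            normalize_trace(self.make_trace([0, 3, 9]), "to_t0")

    def test_contrast_score_uses_eps_floor(self):
        y = np.array([0.0, 0.0, 0.0, 30.0, 20.0])
        assert contrast_score(y, baseline_frames=3, eps=1.0) == 30.0
        with pytest.raises(ValueError, match="zero baseline"):
            contrast_score(y, baseline_frames=3, eps=0.0)
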