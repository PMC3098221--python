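"""Spike ingestion, QC filters, rate estimation and epoch labeling."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from msuaflow import preprocess
from msuaflow.preprocess import (
    RateMatrix,
    SpikeTableError,
    SpikeTrainSet,
    build_epoch_timeline,
    estimate_rates,
    load_spike_table,
    qc_filter_units,
)


# ---------------------------------------------------------------------------
# loading


def _write(tmp_path, text, name="spikes.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadSpikeTable:
    def test_identity_read_through(self, tmp_path):
        p = _write(tmp_path, "unit_id,time_s\nu1,0.5\nu1,1.5\nu2,0.7\nu2,2.0\nu1,3.0\n")
        s = load_spike_table(p, trial_span=(0.0, 5.0))
        assert s.unit_ids == ["u1", "u2"]
        assert s.n_spikes() == {"u1": 3, "u2": 2}

    def test_empty_table(self, tmp_path):
        p = _write(tmp_path, "unit_id,time_s\n")
        s = load_spike_table(p, trial_span=(0.0, 5.0))
        assert s.unit_ids == []

    def test_unsorted_input_matches_sort_oracle(self, tmp_path, rng):
        times = rng.uniform(0, 10, 30)
        rows = "".join(f"u,{t}\n" for t in times)
        p = _write(tmp_path, "unit_id,time_s\n" + rows)
        s = load_spike_table(p, trial_span=(0.0, 10.0))
        np.testing.assert_allclose(s.units["u"], np.sort(times))

    @pytest.mark.parametrize(
        "text,match",
        [
            ("unit_id,wrong\nu,1\n", "missing required column"),
            ("unit_id,time_s\nu,abc\n", "non-numeric"),
            ("unit_id,time_s\nu,99\n", "outside trial span"),
        ],
    )
    def test_parse_errors(self, tmp_path, text, match):
        p = _write(tmp_path, text)
        with pytest.raises(SpikeTableError, match=match):
            load_spike_table(p, trial_span=(0.0, 5.0))


# ---------------------------------------------------------------------------
# QC


class TestQCFilter:
    def test_isi_floor_drops_second_spike(self):
        s = SpikeTrainSet(0, {"a": [1.000, 1.005, 1.100], "b": [0.5, 2.0]}, (0, 3))
        out, report = qc_filter_units(s, isi_floor=0.010, low_rate_frac=0.0)
        np.testing.assert_allclose(out.units["a"], [1.000, 1.100])
        assert report.removed_isi_spikes == {"a": 1}

    def test_perfect_duplicate_removed(self):
        times = np.linspace(0.1, 9.9, 50)
        s = SpikeTrainSet(0, {"a": times, "b": times, "c": times[::2]}, (0, 10))
        out, report = qc_filter_units(s, dup_corr_max=0.9, low_rate_frac=0.0)
        dropped = report.removed_unit_ids()
        assert len(dropped) == 1 and dropped <= {"a", "b"}
        assert "c" in out.units

    def test_low_rate_exclusion_ratio(self):
        # mean rates 10, 5, 0.1 spikes/s over 10 s; 0.1/10 = 0.01 < 0.02
        rng = np.random.default_rng(0)
        units = {
            "hi": np.sort(rng.uniform(0, 10, 100)),
            "mid": np.sort(rng.uniform(0, 10, 50)),
            "lo": np.array([5.0]),
        }
        s = SpikeTrainSet(0, units, (0, 10))
        out, report = qc_filter_units(s, low_rate_frac=0.02, dup_corr_max=1.1)
        assert [u for u, _ in report.removed_low_rate_units] == ["lo"]
        assert set(out.units) == {"hi", "mid"}

    def test_all_removed_raises(self):
        s = SpikeTrainSet(0, {"a": []}, (0, 1))
        with pytest.raises(ValueError, match="no responsive units"):
            qc_filter_units(s, low_rate_frac=2.0)

    def test_spike_conservation(self, rng):
        units = {f"u{k}": np.sort(rng.uniform(0, 20, 60)) for k in range(4)}
        s = SpikeTrainSet(0, units, (0, 20))
        out, report = qc_filter_units(s)
        kept = sum(len(t) for t in out.units.values())
        removed_isi = sum(report.removed_isi_spikes.values())
        removed_units = sum(
            len(s.units[u]) - report.removed_isi_spikes.get(u, 0)
            for u in report.removed_unit_ids()
        )
        assert kept + removed_isi + removed_units == sum(len(t) for t in units.values())


# ---------------------------------------------------------------------------
# rate estimation


class TestEstimateRates:
    def test_no_spikes_zero_row(self):
        s = SpikeTrainSet(0, {"a": [], "b": [1.0]}, (0, 2))
        r = estimate_rates(s, sigma=0.05, bin_width=0.2)
        assert np.all(r.values[:, r.unit_ids.index("a")] == 0)

    def test_single_spike_matches_quadrature(self):
        s = SpikeTrainSet(0, {"a": [1.07]}, (0, 2))
        r = estimate_rates(s, sigma=0.05, bin_width=0.2)
        col = r.unit_ids.index("a")
        for lo in (0.8, 1.0, 1.2):  # bins around the spike
            k = int(np.flatnonzero(np.isclose(r.bin_starts, lo))[0])
            expected = quad(lambda t: norm.pdf(t, 1.07, 0.05), lo, lo + 0.2)[0] / 0.2
            assert abs(r.values[k, col] - expected) < 1e-8

    def test_default_bin_width_is_200ms(self):
        s = SpikeTrainSet(0, {"a": [0.5]}, (0, 2))
        assert estimate_rates(s, sigma=0.05).bin_width == 0.2

    def test_density_integral_matches_spike_count(self, rng):
        times = np.sort(rng.uniform(1.0, 19.0, 200))  # away from edges
        s = SpikeTrainSet(0, {"a": times}, (0, 20))
        r = estimate_rates(s, sigma=0.05, bin_width=0.2)
        integral = r.values.sum() * r.bin_width
        assert abs(integral - 200) / 200 < 0.005

    def test_linearity_in_spike_trains(self, rng):
        t1 = np.sort(rng.uniform(0, 10, 40))
        t2 = np.sort(rng.uniform(0, 10, 40))
        merged = np.sort(np.concatenate([t1, t2]))
        r1 = estimate_rates(SpikeTrainSet(0, {"a": t1}, (0, 10)), sigma=0.05)
        r2 = estimate_rates(SpikeTrainSet(0, {"a": t2}, (0, 10)), sigma=0.05)
        rm = estimate_rates(SpikeTrainSet(0, {"a": merged}, (0, 10)), sigma=0.05)
        np.testing.assert_allclose(rm.values, r1.values + r2.values, atol=1e-10)

    def test_normalize_to_trial_integrates_to_one(self, rng):
        times = np.sort(rng.uniform(1, 9, 50))
        s = SpikeTrainSet(0, {"a": times}, (0, 10))
        r = estimate_rates(s, sigma=0.05, normalize_to_trial=True)
        assert abs(r.values.sum() * r.bin_width - 1.0) < 1e-6

    def test_bad_params(self):
        s = SpikeTrainSet(0, {"a": [1.0]}, (0, 2))
        with pytest.raises(ValueError):
            estimate_rates(s, sigma=-1)
        with pytest.raises(ValueError):
            estimate_rates(s, sigma=0.05, bin_width=0)


def test_rate_matrix_hdf5_round_trip(tmp_path, rng):
    times = np.sort(rng.uniform(0, 10, 50))
    s = SpikeTrainSet("t0", {"a": times, "b": times[::3]}, (0, 10))
    r = estimate_rates(s, sigma=0.05)
    p = tmp_path / "rates.h5"
    preprocess.save_rate_matrix(r, p)
    back = preprocess.load_rate_matrix(p)
    np.testing.assert_allclose(back.values, r.values)
    assert back.unit_ids == r.unit_ids
    assert back.bin_width == r.bin_width
    assert list(back.trial_ids) == [str(t) for t in r.trial_ids]


# ---------------------------------------------------------------------------
# epoch timeline


def _rates_for_timeline(duration=30.0, trial_id=0):
    n_bins = int(duration / 0.2)
    return RateMatrix(
        values=np.zeros((n_bins, 1)),
        bin_width=0.2,
        sigma=0.05,
        bin_starts=0.2 * np.arange(n_bins),
        unit_ids=["a"],
        trial_ids=np.full(n_bins, trial_id, dtype=object),
    )


class TestEpochTimeline:
    def test_food_cup_event_gives_1s_reward_window(self):
        events = pd.DataFrame(
            {"trial_id": [0], "label_or_event": ["train_food_cup"], "start_s": [10.0]}
        )
        tl = build_epoch_timeline(events, _rates_for_timeline())
        wins = [w for w in tl.event_windows if w[0] == "train_reward"]
        assert wins == [("train_reward", 9.8, 10.8, 0)]

    def test_choice_window_clipped_at_next_reward(self):
        events = pd.DataFrame(
            {
                "trial_id": [0, 0],
                "label_or_event": ["test_arm_choice", "test_food_cup"],
                "start_s": [20.0, 20.5],
            }
        )
        tl = build_epoch_timeline(events, _rates_for_timeline())
        win = [w for w in tl.event_windows if w[0] == "test_choice"][0]
        assert win[1] == pytest.approx(18.5)
        assert win[2] == pytest.approx(20.3)  # reward starts at 20.5 - 0.2

    def test_no_events_all_unlabeled(self):
        events = pd.DataFrame(columns=["trial_id", "label_or_event", "start_s"])
        tl = build_epoch_timeline(events, _rates_for_timeline())
        assert np.all(tl.labels == "unlabeled")

    def test_row_order_invariance(self):
        rows = {
            "trial_id": [0, 0, 0],
            "label_or_event": ["delay", "train_food_cup", "train_arm_choice"],
            "start_s": [12.0, 10.0, 5.0],
            "end_s": [25.0, np.nan, np.nan],
        }
        r = _rates_for_timeline()
        tl1 = build_epoch_timeline(pd.DataFrame(rows), r)
        shuffled = pd.DataFrame(rows).iloc[[2, 0, 1]].reset_index(drop=True)
        tl2 = build_epoch_timeline(shuffled, r)
        assert np.array_equal(tl1.labels, tl2.labels)

    def test_majority_overlap_labeling(self):
        # delay window [2.0, 10.0): bins fully inside labeled, boundary bin not
        events = [("delay", 2.0, 10.0, 0)]
        tl = build_epoch_timeline(events, _rates_for_timeline())
        labels = tl.labels
        assert labels[int(5.0 / 0.2)] == "delay"
        assert labels[int(1.0 / 0.2)] == "unlabeled"
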