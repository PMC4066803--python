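"""Filtering, cycle segmentation and rupture detection."""

import warnings

import numpy as np
import pandas as pd
import pytest

from quadpop.simulate import (
    ConditionSpec,
    ProtocolSpec,
    SpeciesSpec,
    bell_evans_k0_for_mean,
    make_condition,
    simulate_fx_dataset,
)
from quadpop.traces import (
    RuptureThresholds,
    detect_ruptures,
    filter_trace,
    segment_cycles,
)

NOISELESS = ProtocolSpec(noise_sd_force=1e-9, noise_sd_extension=1e-9)


def _pure_gq_condition() -> ConditionSpec:
    gq = SpeciesSpec("GQ", 6.0, 0.0, 4.0, bell_evans_k0_for_mean(25.0, 4.0), 0.15)
    return ConditionSpec("no_transcription", {"GQ": 1.0, "none": 0.0}, (gq,))


def _detect_all(traceset, **kwargs):
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for frame in traceset.cycles():
            (cycle,) = segment_cycles(filter_trace(frame))
            out.append((cycle, detect_ruptures(cycle, **kwargs)))
    return out


class TestFilterTrace:
    @staticmethod
    def _frame(force, ext=None, rate=1000.0):
        n = len(force)
        return pd.DataFrame(
            {
                "time_s": np.arange(n) / rate,
                "force_pN": force,
                "extension_nm": ext if ext is not None else np.zeros(n),
            }
        )

    def test_constant_preserved(self):
        raw = self._frame(np.full(1000, 10.0))
        out = filter_trace(raw)
        assert np.allclose(out["force_pN"], 10.0)
        assert len(out) == 100  # decimated 1000 -> 100 Hz

    def test_linear_ramp_preserved(self):
        ramp = 5.5 * np.arange(2000) / 1000.0
        out = filter_trace(self._frame(ramp))
        assert np.allclose(out["force_pN"], ramp[::10], atol=1e-9)

    def test_noise_suppression(self):
        """Monte-Carlo noise gain matches the filter's coefficient norm."""
        from scipy.signal import savgol_coeffs

        rng = np.random.default_rng(0)
        noise = rng.normal(0.0, 0.5, 100_000)
        out = filter_trace(self._frame(noise), window=11, polyorder=2)
        expected_sd = 0.5 * np.linalg.norm(savgol_coeffs(11, 2))
        assert out["force_pN"].std() == pytest.approx(expected_sd, rel=0.05)
        assert out["force_pN"].std() < 0.25

    def test_window_validation(self):
        raw = self._frame(np.zeros(100))
        with pytest.raises(ValueError):
            filter_trace(raw, window=10)
        with pytest.raises(ValueError):
            filter_trace(raw, window=3, polyorder=3)
        with pytest.raises(ValueError):
            filter_trace(raw, decimate_to=2000.0)


class TestSegmentCycles:
    def test_cycle_ids_respected(self):
        ts = simulate_fx_dataset(make_condition("deaza"), n_curves=10, seed=4)
        frame = ts.to_frame()
        cycles = segment_cycles(frame)
        assert len(cycles) == 10
        assert [c.cycle_id for c in cycles] == list(range(10))

    def test_turning_point_segmentation(self):
        """Without cycle ids, force turning points recover the generator's
        cycle boundaries."""
        ts = simulate_fx_dataset(
            make_condition("deaza"), n_curves=3, seed=4, protocol=NOISELESS
        )
        frame = ts.to_frame().drop(columns=["cycle_id", "phase"])
        frame["time_s"] = np.arange(len(frame)) / 1000.0  # one continuous record
        filtered = filter_trace(frame)
        cycles = segment_cycles(filtered)
        assert len(cycles) == 3
        total = sum(len(c.samples) for c in cycles)
        assert total == len(filtered)  # every sample in exactly one cycle

    def test_monotone_ramp_single_cycle(self):
        n = 500
        frame = pd.DataFrame(
            {
                "time_s": np.arange(n) / 100.0,
                "force_pN": np.linspace(1, 40, n),
                "extension_nm": np.zeros(n),
            }
        )
        cycles = segment_cycles(frame)
        assert len(cycles) == 1
        assert set(cycles[0].samples["phase"]) == {"stretch"}

    def test_unsegmentable(self):
        frame = pd.DataFrame(
            {"time_s": [0.0, 0.1], "force_pN": [1.0, 1.0], "extension_nm": [0, 0]}
        )
        with pytest.raises(ValueError):
            segment_cycles(frame)


class TestDetectRuptures:
    def test_noiseless_gq_event(self):
        ts = simulate_fx_dataset(
            _pure_gq_condition(), n_curves=5, seed=6, protocol=NOISELESS
        )
        for cycle, events in _detect_all(ts):
            assert len(events) == 1
            (ev,) = events
            assert ev.delta_L_flank == pytest.approx(6.0, abs=0.1)
            assert ev.delta_L_wlcfit == pytest.approx(6.0, abs=0.1)
            assert ev.nt == 19

    def test_none_cycles_have_no_events(self):
        ts = simulate_fx_dataset(make_condition("mutant"), n_curves=30, seed=7)
        manifest = ts.manifest
        for cycle, events in _detect_all(ts):
            if manifest.loc[cycle.cycle_id, "species"] == "none":
                assert events == []

    def test_recall_and_false_rate(self, transcription_ts, transcription_events):
        manifest = transcription_ts.manifest
        detected = set(transcription_events["cycle_id"])
        folded = manifest[manifest.species != "none"]
        unfolded = manifest[manifest.species == "none"]
        recall = folded.cycle_id.isin(detected).mean()
        false_rate = unfolded.cycle_id.isin(detected).mean()
        assert recall >= 0.95
        assert false_rate <= 0.02

    def test_rupture_force_below_cycle_maximum(self, transcription_ts, transcription_events):
        f_max = transcription_ts.protocol.force_max
        assert (transcription_events["F_rupture_pN"] < f_max).all()

    def test_two_method_agreement_noiseless(self):
        """Flanking-point and WLC-fit contour changes agree within 5%."""
        ts = simulate_fx_dataset(
            make_condition("transcription"), n_curves=80, seed=8, protocol=NOISELESS
        )
        rel = []
        for _, events in _detect_all(ts):
            for ev in events:
                rel.append(abs(ev.delta_L_flank - ev.delta_L_wlcfit) / ev.delta_L_flank)
        assert len(rel) > 10
        assert np.median(rel) <= 0.05

    def test_detection_idempotent(self):
        ts = simulate_fx_dataset(make_condition("transcription"), n_curves=10, seed=9)
        frame = next(iter(ts.cycles()))
        filtered = filter_trace(frame)
        (cycle,) = segment_cycles(filtered)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            first = detect_ruptures(cycle)
            again = detect_ruptures(cycle)
        assert first == again

    def test_requires_loading_phase(self):
        frame = pd.DataFrame(
            {
                "time_s": np.arange(50) / 100.0,
                "force_pN": np.linspace(40, 1, 50),
                "extension_nm": np.zeros(50),
                "phase": "relax",
            }
        )
        from quadpop.traces import ForceExtensionCycle

        with pytest.raises(ValueError):
            detect_ruptures(ForceExtensionCycle(0, frame))

    def test_threshold_validation_window(self):
        th = RuptureThresholds(delta_L_min=0.5, delta_L_max=10.0)
        assert th.delta_L_min < th.delta_L_max
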