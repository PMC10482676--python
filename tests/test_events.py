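import numpy as np
import pytest

import voltphys as vp
from voltphys import events as ve


@pytest.fixture(scope="module")
def ap_only_trace(protocol):
    """Noise-free sweep with spontaneous firing only (15 spikes)."""
    frames = np.linspace(100, 1400, 15).astype(int)
    trace = np.zeros(protocol.n_frames)
    k = vp.synthgen.ap_kernel(3)
    for f in frames:
        vp.synthgen._add_kernel(trace, int(f), k, 5.0)
    return trace, frames


class TestArtifactRemoval:
    def test_injected_artifacts_removed_aps_preserved(self, protocol):
        trace, gt = vp.simulate_trace("locked_single_ap", protocol,
                                      noise_sd=0.0, seed=1, artifacts=True)
        ref, _ = vp.simulate_trace("locked_single_ap", protocol,
                                   noise_sd=0.0, seed=1, artifacts=False)
        clean = ve.remove_stim_artifacts(trace, protocol)
        # reversed-polarity dips replaced; interpolation near an AP shoulder
        # may deviate by a fraction of the spike amplitude
        assert np.allclose(clean[gt.artifact_frames],
                           ref[gt.artifact_frames], atol=1.5)
        assert np.allclose(clean[gt.ap_frames], ref[gt.ap_frames])

    def test_artifact_free_trace_untouched(self, protocol, noisefree_locked):
        trace, _ = noisefree_locked
        clean = ve.remove_stim_artifacts(trace, protocol)
        assert np.max(np.abs(clean - trace)) == 0.0

    def test_negative_transient_away_from_pulses_untouched(self, protocol):
        trace = np.full(protocol.n_frames, 100.0)
        trace[100] -= 8.0                      # far from any pulse onset
        clean = ve.remove_stim_artifacts(trace, protocol)
        assert clean[100] == trace[100]

    def test_idempotent(self, protocol):
        trace, _ = vp.simulate_trace("locked_single_ap", protocol,
                                     noise_sd=0.5, seed=9, artifacts=True)
        once = ve.remove_stim_artifacts(trace, protocol)
        twice = ve.remove_stim_artifacts(once, protocol)
        assert np.allclose(once, twice)


class TestOSub:
    def test_constant_trace_unchanged(self):
        out = ve.compute_osub(np.full(300, 5.0), None, 25)
        assert np.allclose(out.values, 5.0)

    def test_ramp_recovered_under_spikes(self, protocol):
        n = protocol.n_frames
        ramp = np.linspace(0, 10, n)
        trace = ramp.copy()
        frames = np.arange(100, n - 100, 40)
        k = vp.synthgen.ap_kernel(3)
        for f in frames:
            vp.synthgen._add_kernel(trace, int(f), k, 5.0)
        osub = ve.compute_osub(trace, frames, 25)
        rms = np.sqrt(np.mean((osub.values - ramp) ** 2))
        assert rms < 0.02 * np.ptp(ramp)

    def test_full_window_returns_global_mean(self):
        x = np.arange(100.0)
        out = ve.compute_osub(x, None, 100)
        assert np.allclose(out.values, x.mean())

    def test_small_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ve.compute_osub(np.zeros(50), None, 2)

    def test_insensitive_to_masking_any_single_ap(self, ap_only_trace):
        """Masking contract: removing one detected AP barely moves o-Sub."""
        trace, frames = ap_only_trace
        full = ve.compute_osub(trace, frames, 25).values
        drop = ve.compute_osub(trace, frames[:-1], 25).values
        changed = np.abs(full - drop)
        assert changed.max() < 0.5      # leak of one unmasked 5-unit spike


class TestDetectAPs:
    def test_noise_free_exact_recovery(self, ap_only_trace):
        trace, frames = ap_only_trace
        aps, _ = ve.detect_aps_iterative(trace)
        assert np.array_equal(np.array([a.frame for a in aps]), frames)
        for a in aps:
            assert a.amplitude == pytest.approx(5.0, rel=0.1)
            assert 0 < a.half_width_ms < 6.0

    def test_subthreshold_psp_train_gives_zero_detections(self, protocol):
        trace, _ = vp.simulate_trace("subthreshold_only", protocol,
                                     noise_sd=0.0, seed=8, artifacts=False)
        ev, _, _ = ve.detect_events(trace, protocol)
        # EPSP deflections sit below the spike floor and are too wide
        assert len(ev.aps) == 0

    def test_raising_threshold_never_adds_detections(self, protocol):
        trace, _ = vp.simulate_trace("spontaneous_firing", protocol,
                                     noise_sd=1.0, seed=5, artifacts=False)
        osub = ve.percentile_envelope(trace)
        counts = [len(ve.detect_aps(trace, osub, k_mad=k,
                                    baseline=slice(0, 300)))
                  for k in (3.0, 3.5, 4.0, 5.0, 6.0)]
        assert counts == sorted(counts, reverse=True)

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            ve.detect_aps(np.full(100, np.nan), np.zeros(100))

    def test_rate_fidelity_at_125hz(self):
        """Regular trains at the frame-rate limit are recovered within 5%."""
        trace, frames = vp.regular_train(125.0, duration_s=4.0, snr=5.0,
                                         seed=2)
        aps, _ = ve.detect_aps_iterative(trace, baseline=slice(0, 300))
        rate_true = 125.0
        rate_est = len(aps) / 4.0
        assert rate_est == pytest.approx(rate_true, rel=0.05)


class TestDetectPSPs:
    def test_epsp_train_polarity_and_amplitude(self, protocol):
        trace, gt = vp.simulate_trace("subthreshold_only", protocol,
                                      noise_sd=0.0, seed=0, artifacts=False)
        ev, osub, clean = ve.detect_events(trace, protocol)
        assert len(ev.psps) == protocol.n_pulses
        assert all(p.polarity == "E" for p in ev.psps)
        truth = {p: a for p, pol, a in gt.psps}
        for p in ev.psps:
            assert p.amplitude == pytest.approx(truth[p.pulse_index], rel=0.1)
            assert p.latency_ms >= 0

    def test_ipsp_train_polarity(self, protocol):
        trace, _ = vp.simulate_trace("inhibitory", protocol,
                                     noise_sd=0.0, seed=0, artifacts=False)
        ev, _, _ = ve.detect_events(trace, protocol)
        assert len(ev.psps) == protocol.n_pulses
        assert all(p.polarity == "I" for p in ev.psps)

    def test_zero_amplitude_archetype_gives_zero_events(self, protocol):
        trace, _ = vp.simulate_trace("nonconnected", protocol,
                                     noise_sd=0.0, seed=0, artifacts=False)
        ev, _, _ = ve.detect_events(trace, protocol)
        assert len(ev.psps) == 0

    def test_lowering_min_amp_never_decreases_count(self, protocol):
        trace, _ = vp.simulate_trace("facilitating_pp", protocol,
                                     noise_sd=1.0, seed=6, artifacts=False)
        osub = ve.compute_osub(trace, None, 25)
        counts = [len(ve.detect_psps(trace, osub, protocol, min_amp=m))
                  for m in (4.0, 2.0, 1.0, 0.5)]
        assert counts == sorted(counts)

    def test_paired_pulse_direction(self, protocol):
        for name, facil in (("facilitating_pp", True),
                            ("depressing_pp", False)):
            trace, _ = vp.simulate_trace(name, protocol, noise_sd=0.0,
                                         seed=0, artifacts=False)
            ev, _, _ = ve.detect_events(trace, protocol)
            amp = {p.pulse_index: p.amplitude for p in ev.psps}
            ratio = amp[1] / amp[0]
            assert (ratio > 1.0) == facil


class TestDetectBursts:
    def test_burst_archetype_intervals_recovered(self, protocol):
        trace, gt = vp.simulate_trace("rhythmic_burst", protocol,
                                      noise_sd=0.0, seed=0, artifacts=False)
        ev, _, _ = ve.detect_events(trace, protocol)
        assert len(ev.bursts) == len(gt.burst_intervals)
        for b, (s, e) in zip(ev.bursts, gt.burst_intervals):
            # boundaries within one smoothing window of the truth
            assert abs(b.start - s) <= 25 and abs(b.end - e) <= 25
            assert b.n_aps == 5
        # bursts are non-overlapping and ordered
        for a, b in zip(ev.bursts, ev.bursts[1:]):
            assert a.end <= b.start

    def test_tonic_firing_flat_osub_gives_no_bursts(self, protocol):
        n = protocol.n_frames
        trace = np.zeros(n)
        frames = np.arange(50, n - 50, 30)
        k = vp.synthgen.ap_kernel(3)
        for f in frames:
            vp.synthgen._add_kernel(trace, int(f), k, 5.0)
        osub = ve.compute_osub(trace, frames, 25)
        bursts = ve.detect_bursts(trace, osub, frames)
        assert bursts == []

    def test_empty_trace_gives_no_bursts(self, protocol):
        trace = np.zeros(protocol.n_frames)
        osub = ve.compute_osub(trace, None, 25)
        assert ve.detect_bursts(trace, osub, np.array([], int)) == []

    def test_intra_burst_rate_exceeds_sweep_rate(self, protocol):
        trace, _ = vp.simulate_trace("onset_burst", protocol,
                                     noise_sd=0.5, seed=4, artifacts=False)
        ev, osub, _ = ve.detect_events(trace, protocol)
        total = len(ev.aps) / (protocol.n_frames / protocol.frame_rate_hz)
        for b in ev.bursts:
            assert b.rate_hz >= 2 * total


class TestDecompose:
    def test_identical_conditions_cancel(self):
        x = np.sin(np.linspace(0, 20, 500))
        assert np.allclose(ve.decompose_compound(x, x, 25), 0.0)

    def test_recovers_injected_inhibitory_component(self, protocol):
        """Compound (E+I) minus isolated E isolates the I component."""
        comp, _ = vp.simulate_trace("switch", protocol, noise_sd=0.0,
                                    seed=0, sweep_index=1, artifacts=False)
        excit, _ = vp.simulate_trace("nonconnected", protocol, noise_sd=0.0,
                                     seed=0, artifacts=False)
        diff = ve.decompose_compound(comp, excit, 5)
        ipsp_only = comp - excit              # ground-truth component
        rms = np.sqrt(np.mean((diff - ipsp_only) ** 2))
        assert rms < 0.10 * np.max(np.abs(ipsp_only))

    def test_window_one_is_raw_difference(self):
        a, b = np.arange(10.0), np.ones(10)
        assert np.array_equal(ve.decompose_compound(a, b, 1), a - b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ve.decompose_compound(np.zeros(5), np.zeros(6), 3)


class TestEventSetSerialization:
    def test_json_and_dataframe_round_trip(self, protocol, tmp_path):
        trace, _ = vp.simulate_trace("rhythmic_burst", protocol,
                                     noise_sd=0.5, seed=2)
        ev, _, _ = ve.detect_events(trace, protocol)
        ev.to_json(tmp_path / "events.json")
        df = ev.to_dataframe()
        assert (df["kind"] == "ap").sum() == len(ev.aps)
        assert (df["kind"] == "burst").sum() == len(ev.bursts)
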