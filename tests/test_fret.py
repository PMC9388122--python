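"""FRET computation, fiduciary alignment, and fluorescence step detection."""

from dataclasses import replace

import numpy as np
import pytest

from nucspool.data import FluorescenceTrace
from nucspool.fret import (align_noncooperative, align_on_rip, compute_fret,
                           detect_fluorescence_steps, ejection_delay,
                           fret_extension_offset, sigmoid_midpoint)
from nucspool.simulate import (GeneratorConfig, generate_bleach_trace,
                               generate_cycle, generate_ejection_trace)
from nucspool.traces import detect_rips


def _flat_trace(e, n=200, rate=60, seed=0, dt=0.01):
    rng = np.random.default_rng(seed)
    t = (np.arange(n) + 0.5) * dt
    total = rng.poisson(rate, n)
    acc = rng.binomial(total, e)
    return FluorescenceTrace(t, (total - acc).astype(float), acc.astype(float))


class TestComputeFret:
    def test_acceptor_only_gives_e_of_one(self):
        e = compute_fret(np.zeros(5), np.full(5, 50.0))
        assert np.allclose(e, 1.0)

    def test_equal_channels_give_half(self):
        e = compute_fret(np.full(5, 30.0), np.full(5, 30.0))
        assert np.allclose(e, 0.5)

    def test_low_signal_bins_masked(self):
        e = compute_fret(np.array([2.0, 30.0]), np.array([3.0, 30.0]),
                         count_floor=10.0)
        assert np.isnan(e[0]) and e[1] == 0.5

    def test_all_zero_channels_fully_masked(self):
        e = compute_fret(np.zeros(8), np.zeros(8))
        assert np.all(np.isnan(e))

    def test_anticorrelated_step_appears_in_e_at_same_bin(self):
        donor = np.array([10.0] * 10 + [50.0] * 10)
        acceptor = np.array([50.0] * 10 + [10.0] * 10)
        e = compute_fret(donor, acceptor)
        assert np.all(e[:10] > 0.7) and np.all(e[10:] < 0.3)

    def test_e_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        e = compute_fret(rng.poisson(30, 500), rng.poisson(30, 500))
        valid = e[~np.isnan(e)]
        assert np.all((valid >= 0) & (valid <= 1))


@pytest.fixture(scope="module")
def ed2_ensemble():
    cfg = GeneratorConfig(fret_construct="ED2")
    traces, rip_times, truths = [], [], []
    for s in range(12):
        res = generate_cycle(cfg, "nucleosome", seed=500 + s)
        rips = detect_rips(res.pull)
        traces.append(res.fluor_pull)
        rip_times.append(rips[0].t_event if rips else None)
        truths.append(res.truth)
    return traces, rip_times, truths


class TestAlignOnRip:
    def test_mean_e_drops_within_one_bin_of_zero(self, ed2_ensemble):
        traces, rip_times, _ = ed2_ensemble
        ens = align_on_rip(traces, rip_times)
        m = ens.mean_trace
        dt = ens.rel_time[1] - ens.rel_time[0]
        k0 = int(np.searchsorted(ens.rel_time, 0.0))
        pre = np.nanmean(m[k0 - 30:k0 - 1])
        post = np.nanmean(m[k0 + 2:k0 + 30])
        assert pre > 0.7 and post < 0.3
        crossing = ens.rel_time[np.flatnonzero(m < 0.5)[0]]
        assert abs(crossing) <= dt + 1e-9

    def test_flat_ensemble_gives_single_band_histogram(self):
        traces = [_flat_trace(0.8, seed=s) for s in range(6)]
        ens = align_on_rip(traces, [1.0] * 6)
        h, _t, e_edges = ens.histogram
        col_mass = h.sum(axis=0)
        band = (e_edges[:-1] >= 0.6) & (e_edges[:-1] <= 0.95)
        assert col_mass[band].sum() / col_mass.sum() > 0.99

    def test_traces_without_rip_excluded_and_logged(self):
        traces = [_flat_trace(0.8, seed=s) for s in range(3)]
        ens = align_on_rip(traces, [1.0, None, 1.2])
        assert ens.excluded == [1]
        assert ens.matrix.shape[0] == 2

    def test_alignment_is_shift_only(self, ed2_ensemble):
        # within-trace bin spacing and event separations are preserved exactly
        traces, rip_times, _ = ed2_ensemble
        ens = align_on_rip(traces, rip_times)
        kept = [tr for tr, t0 in zip(traces, rip_times) if t0 is not None]
        dt = traces[0].dt
        for row, tr, t0 in zip(ens.matrix, kept, ens.fiduciary_times):
            filled = np.flatnonzero(~np.isnan(row))
            # the block moves as one rigid unit: length and contiguity kept
            assert len(filled) == len(tr)
            assert np.all(np.diff(filled) == 1)
            # and sits at the shifted position up to bin-grid rounding
            assert ens.rel_time[filled[0]] == pytest.approx(tr.time[0] - t0,
                                                            abs=dt / 2 + 1e-9)

    def test_jitter_removed_after_alignment(self):
        # same drop time in trace coordinates, jittered start times
        rng = np.random.default_rng(5)
        traces, t0s = [], []
        for s in range(10):
            jitter = rng.uniform(-0.2, 0.2)
            n = 300
            t = (np.arange(n) + 0.5) * 0.01 + jitter
            e_prof = np.where(t < 1.5, 0.85, 0.1)
            total = rng.poisson(60, n)
            acc = rng.binomial(total, e_prof)
            traces.append(FluorescenceTrace(t, (total - acc).astype(float),
                                            acc.astype(float)))
            t0s.append(1.5)
        ens = align_on_rip(traces, t0s)
        m = ens.mean_trace
        drop = np.flatnonzero(np.nan_to_num(m, nan=1.0) < 0.5)[0]
        assert abs(ens.rel_time[drop]) <= 0.011


class TestAlignNoncooperative:
    def test_random_onset_ramps_aligned_to_common_duration(self):
        rng = np.random.default_rng(2)
        traces, durations = [], []
        for s in range(10):
            n = 400
            t = (np.arange(n) + 0.5) * 0.01
            t_on = rng.uniform(0.8, 2.4)
            dur = 0.5
            ramp = np.clip((t - t_on) / dur, 0, 1)
            e_prof = 0.85 - 0.75 * ramp
            total = rng.poisson(60, n)
            acc = rng.binomial(total, np.clip(e_prof, 0, 1))
            traces.append(FluorescenceTrace(t, (total - acc).astype(float),
                                            acc.astype(float)))
            durations.append(dur)
        ens = align_noncooperative(traces)
        m = ens.mean_trace
        # ramp duration from the slope of the mean trace through midrange E
        mid = ~np.isnan(m) & (m > 0.3) & (m < 0.65)
        slope = np.polyfit(ens.rel_time[mid], m[mid], 1)[0]
        measured = (0.85 - 0.10) / abs(slope)
        assert measured == pytest.approx(np.mean(durations), rel=0.2)

    def test_step_traces_align_consistently_with_rip_alignment(self):
        # limiting case: sigmoid midpoint of a step sits at the step
        rng = np.random.default_rng(3)
        n = 300
        t = (np.arange(n) + 0.5) * 0.01
        e_prof = np.where(t < 1.8, 0.85, 0.1)
        total = rng.poisson(80, n)
        acc = rng.binomial(total, e_prof)
        tr = FluorescenceTrace(t, (total - acc).astype(float),
                               acc.astype(float))
        t0, _w = sigmoid_midpoint(tr.time, compute_fret(tr.donor_counts,
                                                        tr.acceptor_counts))
        assert t0 == pytest.approx(1.8, abs=0.011)

    def test_flat_traces_excluded(self):
        traces = [_flat_trace(0.8, seed=s) for s in range(3)]
        traces.append(_ramp_trace())
        ens = align_noncooperative(traces)
        assert set(ens.excluded) == {0, 1, 2}

    def test_ed1_ensemble_mean_is_gradual(self):
        # noncooperative ED1 construct: the aligned mean has no cooperative step
        cfg = GeneratorConfig(fret_construct="ED1", pulling_speed=25.0,
                              lf_kind_probs=(1.0, 0.0, 0.0))
        traces = [generate_cycle(cfg, "nucleosome", seed=700 + s).fluor_pull
                  for s in range(8)]
        ens = align_noncooperative(traces)
        m = ens.mean_trace
        core = m[np.abs(ens.rel_time) < 1.0]
        assert np.nanmax(np.abs(np.diff(core))) < 0.35  # no single-bin step


def _ramp_trace(seed=9):
    rng = np.random.default_rng(seed)
    n = 300
    t = (np.arange(n) + 0.5) * 0.01
    e_prof = np.clip(0.85 - 0.75 * np.clip((t - 1.0) / 0.6, 0, 1), 0, 1)
    total = rng.poisson(60, n)
    acc = rng.binomial(total, e_prof)
    return FluorescenceTrace(t, (total - acc).astype(float), acc.astype(float))


class TestFretExtensionOffset:
    SLOW = dict(pulling_speed=25.0, lf_kind_probs=(1.0, 0.0, 0.0))

    def test_rotation_first_gives_positive_separation(self):
        cfg = GeneratorConfig(fret_construct="ED1", **self.SLOW)
        seps = []
        for s in range(8):
            res = generate_cycle(cfg, "nucleosome", seed=700 + s)
            _div, _onset, sep = fret_extension_offset(res.pull, res.fluor_pull)
            if sep is not None:
                seps.append(sep)
        assert len(seps) >= 6
        assert all(s > 0 for s in seps)

    def test_simultaneous_onset_gives_near_zero_separation(self):
        cfg = GeneratorConfig(fret_construct="ED1", lf_rotation_fraction=0.0,
                              **self.SLOW)
        seps = []
        for s in range(8):
            res = generate_cycle(cfg, "nucleosome", seed=800 + s)
            _d, _o, sep = fret_extension_offset(res.pull, res.fluor_pull)
            if sep is not None:
                seps.append(sep)
        dt = 0.01
        assert abs(np.mean(seps)) <= dt          # mean within one 10-ms bin
        assert all(abs(s) <= 3 * dt for s in seps)

    def test_separation_varies_across_molecules(self):
        cfg = GeneratorConfig(fret_construct="ED1", **self.SLOW)
        seps = [fret_extension_offset(r.pull, r.fluor_pull)[2]
                for r in (generate_cycle(cfg, "nucleosome", seed=700 + s)
                          for s in range(8))]
        seps = [s for s in seps if s is not None]
        assert np.std(seps) > 0.005

    def test_undetectable_onset_yields_sentinel(self, bare_trace):
        flat = _flat_trace(0.8, n=len(bare_trace.time[::10]))
        div, onset, sep = fret_extension_offset(bare_trace, flat)
        assert sep is None


class TestRewrapRecovery:
    def test_fret_recovers_on_rewrapping(self):
        # relaxation after unwrapping: E returns to its initial high value,
        # which rules out photobleaching of the acceptor
        cfg = GeneratorConfig(fret_construct="ED2")
        recovered = 0
        for s in range(8):
            res = generate_cycle(cfg, "nucleosome", seed=520 + s)
            if res.truth.fret_recovery_time is None:
                continue
            e = compute_fret(res.fluor_relax.donor_counts,
                             res.fluor_relax.acceptor_counts)
            tail = e[res.fluor_relax.time > res.truth.fret_recovery_time + 0.1]
            if len(tail) and np.nanmean(tail) > 0.7:
                recovered += 1
        assert recovered >= 6

    def test_int_construct_always_recovers_at_first_zip(self):
        cfg = GeneratorConfig(fret_construct="INT")
        checked = 0
        for s in range(12):
            res = generate_cycle(cfg, "nucleosome", seed=540 + s)
            if res.truth.fret_recovery_time is None or not res.truth.zip_events:
                continue
            assert res.truth.recovery_zip_index == 0
            checked += 1
        assert checked >= 8


class TestStepsAndEjection:
    def test_two_step_photobleaching_counted(self, gen_config):
        tr, _times = generate_bleach_trace(gen_config, n_steps=2, seed=1101)
        steps = detect_fluorescence_steps(tr.donor_counts, tr.dt)
        down = [s for s in steps if s["level_after"] < s["level_before"]]
        assert len(down) == 2

    def test_constant_trace_has_no_steps(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(40, 400).astype(float)
        assert detect_fluorescence_steps(x, 0.01) == []

    def test_ejection_delay_ensemble_mean_is_113_ms(self, gen_config):
        # delays drawn from Exp(113 ms); the detected sample mean must sit
        # within 2 SEM of the configured mean
        delays = []
        for s in range(80):
            tr, _d = generate_ejection_trace(gen_config, rip_time=1.0,
                                             duration=3.0, seed=900 + s)
            ev = ejection_delay(tr, rip_time=1.0)
            if ev is not None:
                delays.append(ev.delay_after_rip)
        assert len(delays) >= 70
        sem = np.std(delays) / np.sqrt(len(delays))
        assert abs(np.mean(delays) - 0.113) <= 2 * sem + 0.01

    def test_no_drop_yields_sentinel(self):
        rng = np.random.default_rng(2)
        t = (np.arange(300) + 0.5) * 0.01
        tr = FluorescenceTrace(t, rng.poisson(40, 300).astype(float),
                               np.zeros(300))
        assert ejection_delay(tr, rip_time=1.0) is None
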