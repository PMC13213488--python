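"""Transition detection, force quantification and tether validation."""

import logging
from dataclasses import replace

import numpy as np
import pytest

from ripfit.fec_simulator import SimulationConfig, simulate_cycle
from ripfit.rip_analysis import Transition, detect_transitions, transition_force, validate_tether
from ripfit.trace import ForceExtensionTrace, TraceError


def crafted_sweep(jumps, n=400, base_force=5.0, compliance=10.0, trap_k=0.3, noise=0.0, seed=0):
    """Elastic-looking stretch with rips injected at given (index, slack)
    pairs: along the branch dx = C dF; at a rip of slack s the force drops
    by s/(1/k + C) and the measured extension jumps by that drop over k."""
    rng = np.random.default_rng(seed)
    df_branch = 0.05
    f = base_force + df_branch * np.arange(n, dtype=float)
    x = 300.0 + compliance * df_branch * np.arange(n, dtype=float)
    for idx, slack in jumps:
        d_force = slack / (1.0 / trap_k + compliance)
        f[idx + 1 :] -= d_force
        x[idx + 1 :] += d_force / trap_k
    if noise:
        nz = rng.normal(0, noise, n)
        f = f + nz
        x = x - nz / trap_k
    t = np.arange(n) * 0.01
    return ForceExtensionTrace(time=t, extension=x, force=f, sweep="stretch")


class TestDetect:
    def test_noiseless_elastic_sweeps_have_zero_transitions(self):
        cfg = SimulationConfig(unfold_rate0=0.0, force_noise_sd=0.0)
        for seed in range(50):
            stretch, relax, _ = simulate_cycle(cfg, seed)
            assert detect_transitions(stretch) == []
            assert detect_transitions(relax) == []

    def test_min_size_threshold_semantics(self):
        trace = crafted_sweep([(100, 15.0), (250, 8.0)])
        trans = detect_transitions(trace, min_size=10.0)
        assert len(trans) == 1
        assert trans[0].direction == "unfold"
        assert trans[0].extension_jump == pytest.approx(15.0, abs=2.0)
        assert 95 <= trans[0].index_range[0] <= 103

    def test_crafted_sizes_accurate(self):
        trace = crafted_sweep([(100, 20.0), (250, 60.0)], noise=0.2, seed=3)
        trans = detect_transitions(trace)
        assert len(trans) == 2
        assert trans[0].extension_jump == pytest.approx(20.0, abs=4.0)
        assert trans[1].extension_jump == pytest.approx(60.0, abs=6.0)

    def test_refold_direction_on_relax(self):
        trace = crafted_sweep([(200, -30.0)])
        trace.sweep = "relax"
        trans = detect_transitions(trace)
        assert len(trans) == 1
        assert trans[0].direction == "refold"
        assert trans[0].extension_jump == pytest.approx(30.0, abs=3.0)

    def test_recall_on_simulated_truth(self, analyzed_cycles):
        """>= 95% of truth rips with branch offset >= 12 nm are detected at
        default noise."""
        found = missed = 0
        for c in analyzed_cycles:
            det_times = [
                c["stretch"].time[t.index_range[0]]
                for t in c["transitions"]
            ]
            for e in c["truth"].stretch_unfold_events:
                if e.extension_jump_nm < 12.0:
                    continue
                if any(abs(dt - e.time_s) < 0.15 for dt in det_times):
                    found += 1
                else:
                    missed += 1
        assert found + missed >= 60  # enough events for the census
        assert found / (found + missed) >= 0.95

    def test_detected_sizes_match_truth(self, analyzed_cycles):
        errs = []
        for c in analyzed_cycles:
            det = [
                (c["stretch"].time[t.index_range[0]], t.extension_jump)
                for t in c["transitions"]
                if t.direction == "unfold"
            ]
            truth = [
                e for e in c["truth"].stretch_unfold_events if e.extension_jump_nm >= 15
            ]
            # only isolated rips: size mixing is expected when two rips
            # land within the measurement window
            for e in truth:
                near = [
                    o
                    for o in c["truth"].events
                    if o is not e and abs(o.time_s - e.time_s) < 0.25
                ]
                if near:
                    continue
                match = [j for t, j in det if abs(t - e.time_s) < 0.15]
                if match:
                    errs.append(match[0] - e.extension_jump_nm)
        assert len(errs) >= 30
        assert abs(np.median(errs)) < 3.5
        assert np.percentile(np.abs(errs), 80) < 8.0

    @pytest.mark.parametrize("sizes", [(10.0, 14.0, 20.0)])
    def test_threshold_monotonicity(self, sizes, analyzed_cycles):
        for c in analyzed_cycles[:10]:
            counts = [
                len(detect_transitions(c["stretch"], min_size=s)) for s in sizes
            ]
            assert counts == sorted(counts, reverse=True)

    def test_short_trace_rejected(self):
        t = crafted_sweep([], n=40)
        with pytest.raises(TraceError):
            detect_transitions(t)

    def test_non_monotone_time_rejected(self):
        with pytest.raises(TraceError):
            ForceExtensionTrace(
                time=np.array([0.0, 0.2, 0.1]),
                extension=np.zeros(3),
                force=np.zeros(3),
            )


class TestTransitionForce:
    def _with_transition(self, trace, onset):
        return Transition("unfold", (onset, onset + 1), 20.0, np.nan, 0, 1)

    def test_constant_branch(self):
        t = crafted_sweep([])
        t.force[:] = 7.0
        tr = self._with_transition(t, 100)
        assert transition_force(t, tr) == pytest.approx(7.0)

    def test_symmetric_ramp_gives_midpoint(self):
        t = crafted_sweep([])
        # 5 window samples ramp symmetrically around 7 pN
        t.force[95:100] = np.linspace(6.0, 8.0, 5)
        tr = self._with_transition(t, 100)
        assert transition_force(t, tr) == pytest.approx(7.0)

    def test_window_shrinks_with_warning(self, caplog):
        t = crafted_sweep([])
        tr = self._with_transition(t, 2)
        with caplog.at_level(logging.WARNING, logger="ripfit.rip_analysis"):
            val = transition_force(t, tr)
        assert np.isfinite(val)
        assert any("shrunk" in rec.message for rec in caplog.records)

    def test_matches_truth_within_noise_and_ramp(self, analyzed_cycles):
        """Window-averaged force agrees with the instantaneous truth force
        up to noise (3 sigma / sqrt(n)) plus the loading-rate ramp over the
        window."""
        devs = []
        for c in analyzed_cycles:
            for t in c["transitions"]:
                if t.direction != "unfold":
                    continue
                tt = c["stretch"].time[t.index_range[0]]
                match = [
                    e
                    for e in c["truth"].stretch_unfold_events
                    if abs(e.time_s - tt) < 0.08
                ]
                if len(match) == 1:
                    devs.append(t.force_before - match[0].force_pN)
        # loading ~10 pN/s, window centred ~0.035 s before the flip
        ramp = 10.0 * 0.035
        tol = 3 * 0.2 / np.sqrt(5) + ramp
        assert len(devs) >= 40
        assert np.mean(np.abs(devs) < tol + 0.2) > 0.9
        assert abs(np.median(devs) + ramp) < 0.45  # small ramp-consistent bias


class TestValidateTether:
    def test_clean_cycle_valid(self, analyzed_cycles):
        c = analyzed_cycles[0]
        status = validate_tether(
            c["stretch"], c["relax"], c["result"].total_dlc, 200.0
        )
        assert status == "valid"

    def test_doubled_length_is_multi_tether(self, analyzed_cycles):
        c = analyzed_cycles[0]
        assert validate_tether(c["stretch"], c["relax"], 400.0, 200.0) == "multi_tether"

    def test_rupture_is_broken(self):
        t = crafted_sweep([])
        t.force[250:] = np.abs(np.random.default_rng(0).normal(0, 0.05, 150))
        assert validate_tether(t, None, 150.0, 200.0) == "broken"
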