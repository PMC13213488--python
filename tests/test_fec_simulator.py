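"""Kinetic Monte-Carlo pulling simulator: determinism, bookkeeping and the
condition-specific behaviors it must emulate."""

from dataclasses import replace

import numpy as np
import pytest

from ripfit.fec_simulator import (
    CalibrationError,
    SimulationConfig,
    apply_condition,
    calibrate_unfold_kinetics,
    sample_partition,
    simulate_condition,
    simulate_cycle,
)
from ripfit.fec_simulator import _mean_final_unfold_force
from ripfit.rip_analysis import detect_transitions


class TestPartition:
    def test_single_repeat_degenerate(self, sim_config):
        cfg = replace(sim_config, n_repeats=1)
        p = sample_partition(cfg, np.random.default_rng(0))
        assert p.n_blocks == 1
        assert p.block_dlc[0] == pytest.approx(cfg.tether.expected_dlc)

    def test_dlc_conservation(self, sim_config):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = sample_partition(sim_config, rng)
            assert p.block_dlc.sum() == pytest.approx(
                sim_config.tether.expected_dlc, abs=1e-9
            )
            assert np.all(p.block_repeats >= 1)
            assert 1 <= p.n_blocks <= 15

    def test_heterogeneity_across_draws(self, sim_config):
        rng = np.random.default_rng(2)
        counts = {sample_partition(sim_config, rng).n_blocks for _ in range(1000)}
        assert len(counts) >= 2

    def test_sequestered_block(self, sim_config):
        rng = np.random.default_rng(3)
        p = sample_partition(sim_config, rng, sequester_repeats=5)
        assert p.sequestered.sum() == 1
        seq_dlc = p.block_dlc[p.sequestered].sum()
        assert seq_dlc == pytest.approx(5 * sim_config.dlc_per_repeat)
        # recoverable gain excludes the sequestered block
        assert p.expected_dlc == pytest.approx(
            sim_config.tether.expected_dlc - seq_dlc
        )


class TestSimulateCycle:
    def test_deterministic_bit_identical(self, sim_config):
        s1, r1, t1 = simulate_cycle(sim_config, 42)
        s2, r2, t2 = simulate_cycle(sim_config, 42)
        assert np.array_equal(s1.force, s2.force)
        assert np.array_equal(s1.extension, s2.extension)
        assert np.array_equal(r1.force, r2.force)
        assert len(t1.events) == len(t2.events)

    def test_no_kinetics_limit(self, sim_config):
        cfg = replace(sim_config, unfold_rate0=0.0)
        stretch, _, truth = simulate_cycle(cfg, 5)
        assert truth.events == []
        assert detect_transitions(stretch) == []

    def test_truth_dlc_bookkeeping(self, sim_config):
        for seed in range(10):
            _, _, truth = simulate_cycle(sim_config, seed)
            assert truth.net_stretch_dlc == pytest.approx(truth.expected_dlc, abs=1e-9)

    def test_all_repeats_unfold_before_force_max(self, sim_config):
        full = 0
        for seed in range(40):
            _, _, truth = simulate_cycle(sim_config, 400 + seed, skip_relax=True)
            if truth.net_stretch_dlc >= truth.full_dlc - 1e-9:
                full += 1
        assert full >= 0.95 * 40

    def test_stretch_relax_hysteresis(self, sim_config):
        unfold, refold = [], []
        for seed in range(20):
            _, _, truth = simulate_cycle(sim_config, 700 + seed)
            unfold += [e.force_pN for e in truth.stretch_unfold_events]
            refold += [
                e.force_pN for e in truth.events if e.sweep == "relax" and e.dlc_nm < 0
            ]
        assert np.mean(unfold) > np.mean(refold)

    def test_misfolded_cycle_keeps_sequestered_block_folded(self, sim_config):
        _, _, truth = simulate_cycle(sim_config, 11, misfold_repeats=5)
        assert truth.misfold_repeats == 5
        assert truth.expected_dlc == pytest.approx(
            sim_config.tether.expected_dlc - truth.misfold_dlc
        )
        assert truth.net_stretch_dlc == pytest.approx(truth.expected_dlc, abs=1e-9)

    def test_force_ramp_reaches_cap(self, sim_config):
        stretch, relax, _ = simulate_cycle(sim_config, 21)
        assert stretch.force.max() > 0.9 * sim_config.force_max
        assert relax.force[-1] < 2.0


class TestConditions:
    def test_apply_condition_labels(self, sim_config):
        no_smap = apply_condition(replace(sim_config, condition="no_smap"))
        assert no_smap.misfold_prob == 0.22 and no_smap.lock_prob == 0.0
        atux = apply_condition(replace(sim_config, condition="atux"))
        assert atux.misfold_prob == 0.0
        assert atux.unfold_rate0 == pytest.approx(
            sim_config.unfold_rate0 * sim_config.stabilization_factor
        )
        dbk = apply_condition(replace(sim_config, condition="dbk"))
        assert dbk.lock_prob == 0.33 and dbk.misfold_prob == 0.0
        with pytest.raises(ValueError):
            replace(sim_config, condition="other")

    def test_atux_raises_unfolding_forces(self, sim_config):
        base, stab = [], []
        atux = apply_condition(replace(sim_config, condition="atux"))
        for seed in range(25):
            _, _, t0 = simulate_cycle(sim_config, 900 + seed, skip_relax=True)
            _, _, t1 = simulate_cycle(atux, 900 + seed, skip_relax=True)
            base.append(max(e.force_pN for e in t0.stretch_unfold_events))
            stab.append(max(e.force_pN for e in t1.stretch_unfold_events))
        assert np.mean(stab) > np.mean(base)

    def test_no_smap_first_pulls_never_misfold(self, sim_config):
        cfg = apply_condition(replace(sim_config, condition="no_smap"))
        ds = simulate_condition(cfg, 8, 3, seed=31)
        for rec in ds:
            if rec.truth.cycle == 0:
                assert rec.truth.misfold_repeats == 0

    def test_no_smap_misfold_count_matches_rate(self, sim_config):
        cfg = apply_condition(replace(sim_config, condition="no_smap"))
        ds = simulate_condition(cfg, 10, 5, seed=32)
        n_mis = sum(1 for rec in ds if rec.truth.misfold_repeats > 0)
        eligible = 10 * 4
        target = 0.22 * eligible  # 8.8 -> randomized rounding
        assert n_mis in (int(np.floor(target)), int(np.ceil(target)))

    def test_atux_never_misfolds(self, sim_config):
        cfg = apply_condition(replace(sim_config, condition="atux"))
        ds = simulate_condition(cfg, 6, 3, seed=33)
        assert all(rec.truth.misfold_repeats == 0 for rec in ds)

    def test_dbk_locked_traces_have_no_transitions(self, sim_config):
        cfg = replace(
            apply_condition(replace(sim_config, condition="dbk")), lock_prob=1.0
        )
        ds = simulate_condition(cfg, 3, 3, seed=34)
        locked_sweeps = 0
        clean_sweeps = 0
        for rec in ds:
            if rec.truth.locked and rec.truth.start_unfolded:
                assert rec.truth.events == []
                for trace in (rec.stretch, rec.relax):
                    locked_sweeps += 1
                    clean_sweeps += detect_transitions(trace) == []
        # no true transitions; the detector may rarely report a noise blip
        assert locked_sweeps >= 8
        assert clean_sweeps >= 0.8 * locked_sweeps
        # the first (engaging) cycle still unfolds fully
        firsts = [rec.truth for rec in ds if rec.truth.cycle == 0]
        assert all(t.label == "full" for t in firsts)
        assert all(t.locked for t in firsts)  # engaged on the first relax

    def test_lock_count_matches_rate(self, sim_config):
        cfg = apply_condition(replace(sim_config, condition="dbk"))
        ds = simulate_condition(cfg, 20, 2, seed=35)
        target = 0.33 * 20  # randomized rounding of 6.6
        assert len(ds.locked_molecules) in (6, 7)


class TestCalibration:
    def test_rate_monotonicity(self, sim_config):
        slow = _mean_final_unfold_force(sim_config, 30, seed=40)
        fast = _mean_final_unfold_force(
            replace(sim_config, unfold_rate0=sim_config.unfold_rate0 * 10), 30, seed=40
        )
        assert fast < slow

    def test_bad_target_rejected(self, sim_config):
        with pytest.raises(CalibrationError):
            calibrate_unfold_kinetics(sim_config, target_mean_force=0.5)

    def test_non_bracketing_range_rejected(self, sim_config):
        with pytest.raises(CalibrationError):
            calibrate_unfold_kinetics(
                sim_config, target_mean_force=7.2, n_cycles=10,
                log10_bounds=(-3.0, -2.5),
            )

    def test_calibration_reproducible(self, sim_config):
        k1 = calibrate_unfold_kinetics(sim_config, 7.2, n_cycles=60, seed=50)
        k2 = calibrate_unfold_kinetics(sim_config, 7.2, n_cycles=60, seed=51)
        assert abs(np.log10(k1) - np.log10(k2)) < np.log10(1.8)
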