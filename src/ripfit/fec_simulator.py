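"""Kinetic Monte-Carlo simulator of constant-velocity stretch-relax cycles.

Emulates dual-trap pulling of a 15-repeat, 589-residue protein tethered via
two 600 bp DNA handles at 100 nm/s.  Per kinetics step (default 0.1 ms) the
trap separation advances linearly and the tension follows from a quasi-static
force balance between the trap (combined stiffness ``trap_stiffness``) and
the series tether; cooperative blocks of repeats flip between folded and
unfolded with Bell rates

    k_unfold(F) = k0_u * exp(+F * dx_u / kBT)
    k_refold(F) = k0_r * exp(-F * dx_r / kBT)   (allowed below a force gate)

Output is decimated to ``output_rate`` (100 Hz, mimicking 78 kHz acquisition
averaged down) with Gaussian force noise.  Three experimental conditions are
emulated:

* ``no_smap`` - from the second pull onward a stretch may misfold: a
  contiguous run of repeats becomes non-unfoldable, shortening the
  recoverable contour gain;
* ``atux``   - no misfolding; unfolding rates scaled down so every barrier
  is effectively higher (chaperone-like global stabilization);
* ``dbk``    - a fraction of molecules lock in the unfolded state after
  their first complete unfolding: refolding is disabled and subsequent
  cycles show no transitions.

Every cycle carries a ground-truth record of all flips and condition events
so downstream detection/fitting can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .polymer_models import TetherConstants, protein_tether, tether_extension_grid
from .trace import ForceExtensionTrace

__all__ = [
    "SimulationConfig",
    "DomainPartition",
    "FlipEvent",
    "CycleTruth",
    "CycleRecord",
    "SimulatedDataset",
    "SimulationError",
    "CalibrationError",
    "sample_partition",
    "simulate_cycle",
    "simulate_condition",
    "apply_condition",
    "calibrate_unfold_kinetics",
]

CONDITIONS = ("no_smap", "atux", "dbk")

_EXP_CLIP = 500.0  # caps Bell exponent; beyond this a flip is immediate anyway


class SimulationError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic pulling experiment.

    Kinetic parameters are synthetic stand-ins (no per-intermediate rates are
    published for this system); the unfolding prefactor is chosen so the mean
    complete-unfolding force at 100 nm/s is ~7.2 pN (see
    :func:`calibrate_unfold_kinetics`).
    """

    n_repeats: int = 15
    residues_total: int = 589
    pulling_speed: float = 100.0  # nm/s
    trap_stiffness: float = 0.3  # pN/nm, combined
    output_rate: float = 100.0  # Hz
    kinetics_timestep: float = 1e-4  # s
    unfold_rate0: float = 3e-5  # 1/s per cooperative block
    unfold_distance: float = 8.0  # nm
    refold_rate0: float = 2000.0  # 1/s per unfolded block
    refold_distance: float = 8.0  # nm
    refold_max_force: float = 5.0  # pN; refolding gated below this tension
    force_noise_sd: float = 0.2  # pN at the output stage
    start_force: float = 0.25  # pN, sweep start tension (folded tether)
    force_max: float = 30.0  # pN reached by the fully unfolded tether
    condition: str = "no_smap"
    misfold_prob: float = 0.0  # per stretch, cycles >= 2 (set by apply_condition)
    misfold_repeats_min: int = 3
    misfold_repeats_max: int = 8
    lock_prob: float = 0.0  # per molecule (set by apply_condition)
    stabilization_factor: float = 0.1  # unfold-rate scaling under atux
    seed: int = 0
    tether: TetherConstants = field(default_factory=TetherConstants)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if not 0.0 <= self.misfold_prob <= 1.0:
            raise ValueError("misfold_prob must lie in [0, 1]")
        if not 0.0 <= self.lock_prob <= 1.0:
            raise ValueError("lock_prob must lie in [0, 1]")
        for name in ("pulling_speed", "trap_stiffness", "kinetics_timestep",
                     "unfold_distance", "refold_distance", "output_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.unfold_rate0 < 0 or self.refold_rate0 < 0:
            raise ValueError("rates must be >= 0")
        if self.output_rate > 1.0 / self.kinetics_timestep:
            raise ValueError("output_rate cannot exceed the kinetics rate")

    @property
    def dlc_per_repeat(self) -> float:
        return self.tether.expected_dlc / self.n_repeats


def apply_condition(config: SimulationConfig) -> SimulationConfig:
    """Return a copy of ``config`` with the condition-specific knobs set.

    no_smap: misfold probability 0.22 per stretch from the second pull on.
    atux:    no misfolding; unfolding rates scaled by ``stabilization_factor``
             (default x0.1), raising every transition force.
    dbk:     per-molecule lock probability 0.33 after the first complete
             unfolding (refolding disabled from then on).
    """
    c = config.condition
    if c == "no_smap":
        return replace(config, misfold_prob=0.22, lock_prob=0.0)
    if c == "atux":
        return replace(
            config,
            misfold_prob=0.0,
            lock_prob=0.0,
            unfold_rate0=config.unfold_rate0 * config.stabilization_factor,
        )
    if c == "dbk":
        return replace(config, misfold_prob=0.0, lock_prob=0.33)
    raise ValueError(f"unknown condition {c!r}")


# ---------------------------------------------------------------------------
# Domain partition
# ---------------------------------------------------------------------------


@dataclass
class DomainPartition:
    """Cooperative unfolding blocks for one cycle.

    ``block_repeats[i]`` repeats make up block ``i`` with contour gain
    ``block_dlc[i]``; ``sequestered`` blocks cannot unfold (misfold).
    ``block_boundaries`` are the cumulative repeat indices (0..n_repeats).
    """

    block_repeats: np.ndarray
    block_dlc: np.ndarray
    sequestered: np.ndarray

    @property
    def block_boundaries(self) -> np.ndarray:
        return np.concatenate(([0], np.cumsum(self.block_repeats)))

    @property
    def n_blocks(self) -> int:
        return len(self.block_repeats)

    @property
    def expected_dlc(self) -> float:
        """Recoverable contour gain: every non-sequestered block unfolded."""
        return float(self.block_dlc[~self.sequestered].sum())


def _partition_segment(m: int, rng: np.random.Generator, k_min: int, k_max: int) -> list[int]:
    if m == 0:
        return []
    if m == 1:
        return [1]
    k = int(rng.integers(min(k_min, m), min(k_max, m) + 1))
    if k == 1:
        return [m]
    cuts = np.sort(rng.choice(np.arange(1, m), size=k - 1, replace=False))
    edges = np.concatenate(([0], cuts, [m]))
    return list(np.diff(edges))


def sample_partition(
    config: SimulationConfig,
    rng: np.random.Generator,
    sequester_repeats: int = 0,
) -> DomainPartition:
    """Draw a fresh cooperative-block partition of the repeats.

    Resampled independently every cycle so consecutive pulls differ in the
    number and size of intermediates.  If ``sequester_repeats > 0`` a
    contiguous run of that many repeats becomes one non-unfoldable block
    (the misfolded core); the flanking repeats are partitioned normally.
    """
    n = config.n_repeats
    if sequester_repeats < 0 or sequester_repeats > n:
        raise ValueError("sequester_repeats out of range")
    unit = config.dlc_per_repeat
    if sequester_repeats == 0:
        reps = _partition_segment(n, rng, k_min=2, k_max=4)
        seq = [False] * len(reps)
    else:
        start = int(rng.integers(0, n - sequester_repeats + 1))
        left = _partition_segment(start, rng, k_min=1, k_max=2)
        right = _partition_segment(n - start - sequester_repeats, rng, k_min=1, k_max=2)
        reps = left + [sequester_repeats] + right
        seq = [False] * len(left) + [True] + [False] * len(right)
    block_repeats = np.asarray(reps, dtype=int)
    return DomainPartition(
        block_repeats=block_repeats,
        block_dlc=block_repeats * unit,
        sequestered=np.asarray(seq, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Ground truth records
# ---------------------------------------------------------------------------


@dataclass
class FlipEvent:
    time_s: float
    sweep: str  # stretch | relax
    force_pN: float  # tension just before the flip
    dlc_nm: float  # signed contour change (+ unfold, - refold)
    extension_jump_nm: float  # instantaneous end-to-end jump at the flip
    block_repeats: int


@dataclass
class CycleTruth:
    molecule_id: int
    cycle: int
    condition: str
    events: list[FlipEvent]
    misfold_repeats: int = 0
    misfold_dlc: float = 0.0
    locked: bool = False  # True once the lock is engaged (this cycle's relax on)
    start_unfolded: bool = False
    expected_dlc: float = 0.0  # recoverable contour gain for this cycle
    full_dlc: float = 0.0  # contour gain of complete unfolding (no misfold)
    ended_unfolded: bool = False

    @property
    def stretch_unfold_events(self) -> list[FlipEvent]:
        return [e for e in self.events if e.sweep == "stretch" and e.dlc_nm > 0]

    @property
    def final_unfold_force(self) -> float | None:
        ev = self.stretch_unfold_events
        return ev[-1].force_pN if ev else None

    @property
    def net_stretch_dlc(self) -> float:
        return float(sum(e.dlc_nm for e in self.events if e.sweep == "stretch"))

    @property
    def label(self) -> str:
        """Ground-truth class of the stretching trace."""
        if self.locked and self.start_unfolded:
            return "locked"
        if self.misfold_repeats > 0:
            return "misfolded"
        return "full"


@dataclass
class CycleRecord:
    stretch: ForceExtensionTrace
    relax: ForceExtensionTrace | None
    truth: CycleTruth


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    cycles: list[CycleRecord]
    locked_molecules: list[int]

    def __iter__(self):
        return iter(self.cycles)

    def __len__(self) -> int:
        return len(self.cycles)


# ---------------------------------------------------------------------------
# Core sweep engine
# ---------------------------------------------------------------------------


class _BalanceTables:
    """Cache of force-balance tables keyed by the unfolded contour gain.

    For a tether state with unfolded gain ``dlc`` the map
    ``D(F) = x_tether(F) + F / k_trap`` is monotone; tension at any trap
    separation follows by interpolation.
    """

    def __init__(self, config: SimulationConfig):
        self._cfg = config
        self._grid = np.concatenate(
            ([0.0], np.geomspace(1e-3, 250.0, 1200))
        )
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def table(self, dlc: float) -> tuple[np.ndarray, np.ndarray]:
        key = int(round(dlc * 1e6))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        model = protein_tether(dlc, self._cfg.tether)
        x = tether_extension_grid(self._grid, model)
        d = x + self._grid / self._cfg.trap_stiffness
        self._cache[key] = (self._grid, d)
        return self._grid, d

    def force_at(self, dlc: float, separations) -> np.ndarray:
        f_grid, d_grid = self.table(dlc)
        return np.interp(separations, d_grid, f_grid)


@dataclass
class _State:
    partition: DomainPartition
    folded: np.ndarray  # per block

    @property
    def unfolded_dlc(self) -> float:
        return float(self.partition.block_dlc[~self.folded].sum())

    def foldable_blocks(self) -> np.ndarray:
        return np.flatnonzero(self.folded & ~self.partition.sequestered)

    def unfolded_blocks(self) -> np.ndarray:
        return np.flatnonzero(~self.folded)


def _sweep(
    config: SimulationConfig,
    tables: _BalanceTables,
    rng: np.random.Generator,
    state: _State,
    d_start: float,
    d_end: float,
    t0: float,
    sweep: str,
    refold_enabled: bool,
    events: list[FlipEvent],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance one constant-velocity sweep, mutating ``state`` and appending
    truth events.  Returns kinetics-rate (time, separation, force) arrays."""
    dt = config.kinetics_timestep
    v = config.pulling_speed
    n = int(round(abs(d_end - d_start) / v / dt))
    if n < 10:
        raise SimulationError("sweep span too short for the kinetics timestep")
    sgn = 1.0 if d_end >= d_start else -1.0
    d = d_start + sgn * v * dt * np.arange(1, n + 1)
    t = t0 + dt * np.arange(1, n + 1)
    force = np.empty(n)
    kbt = config.tether.thermal_energy

    i = 0
    while i < n:
        dlc = state.unfolded_dlc
        f_seg = tables.force_at(dlc, d[i:])
        n_fold = len(state.foldable_blocks())
        n_unf = len(state.unfolded_blocks())
        haz = np.zeros_like(f_seg)
        if n_fold and config.unfold_rate0 > 0:
            expo = np.clip(f_seg * config.unfold_distance / kbt, None, _EXP_CLIP)
            haz = haz + n_fold * config.unfold_rate0 * np.exp(expo)
        if n_unf and refold_enabled and config.refold_rate0 > 0:
            kr = config.refold_rate0 * np.exp(-f_seg * config.refold_distance / kbt)
            haz = haz + n_unf * kr * (f_seg < config.refold_max_force)
        cum = np.cumsum(haz * dt)
        u = rng.exponential()
        j = int(np.searchsorted(cum, u))
        if j >= len(f_seg):
            force[i:] = f_seg
            break
        force[i : i + j + 1] = f_seg[: j + 1]
        f_here = float(f_seg[j])
        # pick the flip type proportionally to the instantaneous rates
        ku = (
            n_fold
            * config.unfold_rate0
            * math.exp(min(f_here * config.unfold_distance / kbt, _EXP_CLIP))
            if n_fold and config.unfold_rate0 > 0
            else 0.0
        )
        kr = (
            n_unf
            * config.refold_rate0
            * math.exp(-f_here * config.refold_distance / kbt)
            * (f_here < config.refold_max_force)
            if n_unf and refold_enabled and config.refold_rate0 > 0
            else 0.0
        )
        if ku + kr <= 0:  # numerical corner: treat as no flip
            force[i:] = f_seg
            break
        unfold = rng.random() < ku / (ku + kr)
        dlc_before = state.unfolded_dlc
        if unfold:
            block = int(rng.choice(state.foldable_blocks()))
            state.folded[block] = False
            dlc_signed = float(state.partition.block_dlc[block])
        else:
            block = int(rng.choice(state.unfolded_blocks()))
            state.folded[block] = True
            dlc_signed = -float(state.partition.block_dlc[block])
        # rip size as the extension offset between branches at matched force
        # (the slack gained/lost), i.e. what a baseline-referenced detector
        # and the WLC branch fits see
        fg0, dg0 = tables.table(dlc_before)
        fg1, dg1 = tables.table(state.unfolded_dlc)
        ext_jump = float(np.interp(f_here, fg1, dg1) - np.interp(f_here, fg0, dg0))
        events.append(
            FlipEvent(
                time_s=float(t[i + j]),
                sweep=sweep,
                force_pN=f_here,
                dlc_nm=dlc_signed,
                extension_jump_nm=float(ext_jump),
                block_repeats=int(state.partition.block_repeats[block]),
            )
        )
        i = i + j + 1
    return t, d, force


def _decimate(
    config: SimulationConfig,
    rng: np.random.Generator,
    t: np.ndarray,
    d: np.ndarray,
    force: np.ndarray,
    molecule_id: int,
    cycle: int,
    sweep: str,
) -> ForceExtensionTrace:
    decim = int(round(1.0 / (config.output_rate * config.kinetics_timestep)))
    n_out = len(t) // decim
    m = n_out * decim
    f_dec = force[:m].reshape(n_out, decim).mean(axis=1)
    d_dec = d[:m].reshape(n_out, decim).mean(axis=1)
    t_dec = t[:m].reshape(n_out, decim).mean(axis=1)
    noise = rng.normal(0.0, config.force_noise_sd, n_out) if config.force_noise_sd > 0 else 0.0
    f_out = f_dec + noise
    # measured extension uses the measured (noisy) force: x = D - F/k
    x_out = d_dec - f_out / config.trap_stiffness
    return ForceExtensionTrace(
        time=t_dec,
        extension=x_out,
        force=f_out,
        molecule_id=molecule_id,
        cycle=cycle,
        sweep=sweep,
        meta={"trap_separation_start_nm": float(d_dec[0])},
    )


def _sweep_endpoints(config: SimulationConfig, tables: _BalanceTables) -> tuple[float, float]:
    k = config.trap_stiffness
    f_grid, d_folded = tables.table(0.0)
    d0 = float(np.interp(config.start_force, f_grid, d_folded))
    _, d_unfolded = tables.table(config.tether.expected_dlc)
    d1 = float(np.interp(config.force_max, f_grid, d_unfolded))
    return d0, d1


def simulate_cycle(
    config: SimulationConfig,
    seed,
    *,
    molecule_id: int = 0,
    cycle_index: int = 0,
    start_unfolded: bool = False,
    misfold_repeats: int = 0,
    refold_enabled: bool = True,
    lock_on_full_unfold: bool = False,
    skip_relax: bool = False,
    tables: _BalanceTables | None = None,
) -> tuple[ForceExtensionTrace, ForceExtensionTrace | None, CycleTruth]:
    """Simulate one stretch-relax cycle.

    Deterministic given ``(config, seed)`` and the keyword state flags; the
    same inputs reproduce bit-identical traces.  Returns the decimated
    stretch and relax traces plus the ground-truth record.
    """
    rng = np.random.default_rng(seed)
    if tables is None:
        tables = _BalanceTables(config)
    d0, d1 = _sweep_endpoints(config, tables)

    if start_unfolded:
        partition = sample_partition(config, rng, 0)
        folded = np.zeros(partition.n_blocks, dtype=bool)
    else:
        partition = sample_partition(config, rng, misfold_repeats)
        folded = np.ones(partition.n_blocks, dtype=bool)
    state = _State(partition, folded)
    seq_dlc = float(partition.block_dlc[partition.sequestered].sum())

    truth = CycleTruth(
        molecule_id=molecule_id,
        cycle=cycle_index,
        condition=config.condition,
        events=[],
        misfold_repeats=misfold_repeats if not start_unfolded else 0,
        misfold_dlc=seq_dlc,
        locked=start_unfolded and not refold_enabled,
        start_unfolded=start_unfolded,
        expected_dlc=partition.expected_dlc,
        full_dlc=float(partition.block_dlc.sum()),
    )

    t_s, d_s, f_s = _sweep(
        config, tables, rng, state, d0, d1, 0.0, "stretch", refold_enabled, truth.events
    )
    fully_unfolded = len(state.foldable_blocks()) == 0 and truth.misfold_repeats == 0
    if lock_on_full_unfold and fully_unfolded:
        refold_enabled = False
        truth.locked = True
    stretch = _decimate(config, rng, t_s, d_s, f_s, molecule_id, cycle_index, "stretch")

    relax = None
    if not skip_relax:
        t_r, d_r, f_r = _sweep(
            config, tables, rng, state, d1, d0, float(t_s[-1]), "relax",
            refold_enabled, truth.events,
        )
        relax = _decimate(config, rng, t_r, d_r, f_r, molecule_id, cycle_index, "relax")

    truth.ended_unfolded = len(state.unfolded_blocks()) > 0
    return stretch, relax, truth


def _randomized_round(x: float, rng: np.random.Generator) -> int:
    base = int(math.floor(x))
    return base + (1 if rng.random() < (x - base) else 0)


def simulate_condition(
    config: SimulationConfig,
    n_molecules: int,
    n_cycles: int,
    seed: int | None = None,
) -> SimulatedDataset:
    """Simulate a full experimental condition: ``n_molecules`` molecules,
    ``n_cycles`` stretch-relax cycles each.

    Condition events are assigned by randomized systematic sampling:
    the number of misfolding stretches (among cycles >= 2) and of locked
    molecules equals the nominal probability times the number of eligible
    units up to randomized rounding, with the units drawn uniformly.  Each
    event thus keeps its nominal marginal probability while the realized
    fractions match the rate to within one unit, so recovery benchmarks
    measure pipeline error rather than binomial sampling noise.
    """
    if n_molecules < 1 or n_cycles < 1:
        raise ValueError("need at least one molecule and one cycle")
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(ss.spawn(1)[0])
    cycle_seeds = ss.spawn(n_molecules * n_cycles)

    locked_molecules: list[int] = []
    if config.lock_prob > 0:
        n_lock = _randomized_round(config.lock_prob * n_molecules, assign_rng)
        locked_molecules = sorted(
            assign_rng.choice(n_molecules, size=n_lock, replace=False).tolist()
        )
    locked_set = set(locked_molecules)

    misfold_slots: set[tuple[int, int]] = set()
    if config.misfold_prob > 0 and n_cycles > 1:
        eligible = [
            (m, c)
            for m in range(n_molecules)
            if m not in locked_set
            for c in range(1, n_cycles)
        ]
        n_mis = _randomized_round(config.misfold_prob * len(eligible), assign_rng)
        idx = assign_rng.choice(len(eligible), size=n_mis, replace=False)
        misfold_slots = {eligible[int(i)] for i in idx}

    tables = _BalanceTables(config)
    cycles: list[CycleRecord] = []
    for m in range(n_molecules):
        lock_assigned = m in locked_set
        lock_engaged = False
        for c in range(n_cycles):
            mis = 0
            if (m, c) in misfold_slots and not lock_engaged:
                mis = int(
                    np.random.default_rng(cycle_seeds[m * n_cycles + c].spawn(1)[0]).integers(
                        config.misfold_repeats_min, config.misfold_repeats_max + 1
                    )
                )
            stretch, relax, truth = simulate_cycle(
                config,
                cycle_seeds[m * n_cycles + c],
                molecule_id=m,
                cycle_index=c,
                start_unfolded=lock_engaged,
                misfold_repeats=mis,
                refold_enabled=not lock_engaged,
                lock_on_full_unfold=lock_assigned and not lock_engaged,
                tables=tables,
            )
            if truth.locked:
                lock_engaged = True
            cycles.append(CycleRecord(stretch, relax, truth))
    return SimulatedDataset(config=config, cycles=cycles, locked_molecules=locked_molecules)


# ---------------------------------------------------------------------------
# Kinetic calibration
# ---------------------------------------------------------------------------


def _mean_final_unfold_force(
    config: SimulationConfig, n_cycles: int, seed: int
) -> float:
    """Mean force of the last unfolding rip per stretch, measured through the
    detection pipeline (same estimator as downstream analyses)."""
    from .rip_analysis import detect_transitions, transition_force

    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(n_cycles)
    tables = _BalanceTables(config)
    forces = []
    for i in range(n_cycles):
        stretch, _, _ = simulate_cycle(
            config, seeds[i], molecule_id=i, cycle_index=0, skip_relax=True, tables=tables
        )
        trans = [t for t in detect_transitions(stretch) if t.direction == "unfold"]
        if trans:
            forces.append(transition_force(stretch, trans[-1]))
    if not forces:
        return float("inf")
    return float(np.mean(forces))


def calibrate_unfold_kinetics(
    config: SimulationConfig,
    target_mean_force: float = 7.2,
    n_cycles: int = 150,
    seed: int = 0,
    tol: float = 0.1,
    log10_bounds: tuple[float, float] = (-8.0, -2.0),
) -> float:
    """Find the Bell unfolding prefactor ``k0_u`` (1/s) whose simulated mean
    final-unfolding force at the configured pulling speed matches
    ``target_mean_force``.

    Bisection on log10(k0) with common random numbers, so the measured mean
    is monotone in the rate and the search is well behaved.  Raises
    :class:`CalibrationError` if the bounds do not bracket the target.
    """
    if not 1.0 < target_mean_force < 50.0:
        raise CalibrationError("target force must lie in (1, 50) pN")
    base = replace(config, misfold_prob=0.0, lock_prob=0.0)

    def measure(log_k: float) -> float:
        cfg = replace(base, unfold_rate0=10.0 ** log_k)
        return _mean_final_unfold_force(cfg, n_cycles, seed)

    lo, hi = log10_bounds
    f_lo, f_hi = measure(lo), measure(hi)
    # mean force decreases with the rate: f(lo) is the high-force end
    if not (f_hi <= target_mean_force <= f_lo):
        raise CalibrationError(
            f"search range does not bracket the target: mean force "
            f"{f_hi:.2f}..{f_lo:.2f} pN over k0 in 1e{hi:.1f}..1e{lo:.1f} /s"
        )
    # bisect to a fixed rate resolution rather than stopping at the first
    # in-tolerance measurement: the latter would lock in that evaluation's
    # sampling error (0.02 in log10(k0) is ~0.024 pN of mean force)
    while (hi - lo) >= 0.02:
        mid = 0.5 * (lo + hi)
        if measure(mid) > target_mean_force:
            lo = mid  # force too high -> need faster rate
        else:
            hi = mid
    return 10.0 ** (0.5 * (lo + hi))
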