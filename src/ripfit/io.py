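"""File readers/writers, run configuration and the end-to-end pipeline
driver (simulate -> detect -> fit -> classify -> summarize).

Interchange format is plain delimited text: traces as tab-separated
``time_s / extension_nm / force_pN`` with ``#`` metadata headers, transition
and fit tables as TSV, run reports as JSON.  Every output carries the config
hash and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify_aggregate as agg
from . import fec_simulator as sim
from . import rip_analysis as rips
from . import wlc_fitting as wlc
from .polymer_models import TetherConstants
from .trace import ForceExtensionTrace, TraceError

__all__ = [
    "RunConfig",
    "read_trace",
    "write_trace",
    "read_run_config",
    "write_run_config",
    "analyze_dataset",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["time_s", "extension_nm", "force_pN"]


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------


def write_trace(trace: ForceExtensionTrace, path) -> None:
    path = Path(path)
    header = (
        f"# force-extension sweep (units: s, nm, pN)\n"
        f"# molecule_id={trace.molecule_id} cycle={trace.cycle} sweep={trace.sweep}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        trace.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_trace(path) -> ForceExtensionTrace:
    """Read a delimited-text sweep; validates the header columns and the
    monotone-time invariant."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line_no = 0
        while True:
            line = fh.readline()
            line_no += 1
            if not line.startswith("#"):
                fh.seek(pos)
                break
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceError(
            f"{path}: header line {line_no} lacks required column(s) {missing}; "
            f"expected {TRACE_COLUMNS}"
        )
    return ForceExtensionTrace(
        time=df["time_s"].to_numpy(),
        extension=df["extension_nm"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        molecule_id=int(meta.get("molecule_id", 0)),
        cycle=int(meta.get("cycle", 0)),
        sweep=meta.get("sweep", "stretch"),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a full multi-condition run needs.

    Defaults are the study conditions: 100 nm/s pulling, 100 Hz output,
    10 nm minimum rip size, 0.9 x expected-ΔLc full/misfold threshold at a
    20 pN high-force criterion, 5 nm histogram bins.
    """

    conditions: tuple[str, ...] = ("no_smap", "atux", "dbk")
    n_molecules: int = 16
    n_cycles: int = 2
    seed: int = 0
    min_rip_size: float = 10.0  # nm
    full_fraction: float = 0.9
    high_force: float = 20.0  # pN
    bin_width: float = 5.0  # nm
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    output_dir: str | None = None

    def config_hash(self) -> str:
        data = _as_jsonable(self)
        data.pop("output_dir", None)  # where results land is not what they are
        payload = json.dumps(data, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_run_config(config: RunConfig, path) -> None:
    data = _as_jsonable(config)
    with open(path, "w") as fh:
        fh.write("# ripfit run configuration (units: nm / pN / s / pN·nm)\n")
        yaml.safe_dump(data, fh, sort_keys=True)


def read_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    sim_data = data.pop("simulation", {})
    tether = sim_data.pop("tether", None)
    tc = (
        TetherConstants(**tether) if tether is not None else TetherConstants()
    )
    sim_cfg = sim.SimulationConfig(**sim_data, tether=tc)
    data["conditions"] = tuple(data.get("conditions", ()))
    return RunConfig(**data, simulation=sim_cfg)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def analyze_cycle(
    record: sim.CycleRecord,
    config: RunConfig,
) -> tuple[wlc.CycleResult, wlc.CycleResult | None]:
    """Detect, fit and validate one stretch-relax cycle; classification label
    is attached to the stretch result."""
    tc = config.simulation.tether
    results = []
    for trace in (record.stretch, record.relax):
        if trace is None:
            results.append(None)
            continue
        trans = rips.detect_transitions(trace, min_size=config.min_rip_size)
        fits = wlc.fit_cycle_branches(trace, trans, tc)
        res = wlc.cycle_delta_lc(
            trans, fits, trace,
            molecule_id=trace.molecule_id, cycle=trace.cycle, sweep=trace.sweep,
        )
        results.append(res)
    stretch_res, relax_res = results
    total = stretch_res.total_dlc
    stretch_res.tether_status = rips.validate_tether(
        record.stretch, record.relax, total, tc.expected_dlc
    )
    stretch_res.label = agg.classify_cycle(
        stretch_res,
        tc.expected_dlc,
        relax_result=relax_res,
        full_fraction=config.full_fraction,
        high_force=config.high_force,
        min_jump=config.min_rip_size,
    )
    return stretch_res, relax_res


def analyze_dataset(
    dataset: sim.SimulatedDataset, config: RunConfig
) -> dict:
    """Run detection + fitting + classification over a simulated condition.

    Returns the per-cycle stretch results, the ΔLc distribution summary, the
    force-vs-Lc table and classification tallies.
    """
    stretch_results: list[wlc.CycleResult] = []
    relax_results: list[wlc.CycleResult | None] = []
    for record in dataset:
        s_res, r_res = analyze_cycle(record, config)
        stretch_results.append(s_res)
        relax_results.append(r_res)
    tc = config.simulation.tether
    summary = agg.delta_lc_distribution(
        stretch_results, bin_width=config.bin_width, min_cycles=1
    )
    all_results = stretch_results + [r for r in relax_results if r is not None]
    table = wlc.force_vs_lc_table(stretch_results)
    labels = [r.label for r in stretch_results]
    tallies = {lab: labels.count(lab) for lab in sorted({l for l in labels if l})}
    max_unfold_forces = [
        max((t.force_before for t in r.transitions if t.direction == "unfold"), default=np.nan)
        for r in stretch_results
    ]
    return {
        "condition": dataset.config.condition,
        "stretch_results": stretch_results,
        "relax_results": relax_results,
        "distribution": summary,
        "force_vs_lc": table,
        "tallies": tallies,
        "zero_peak_mass": agg.zero_peak_mass(stretch_results, tc.expected_dlc),
        "max_unfold_forces": np.asarray(max_unfold_forces),
    }


def run_pipeline(config: RunConfig) -> dict:
    """End-to-end multi-condition run: simulate each condition, analyze it,
    and assemble a JSON-serializable report (deterministic given the seed).

    If ``config.output_dir`` is set, traces, tables and the report are
    written there.
    """
    if not config.conditions:
        raise ValueError("no conditions configured")
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thresholds": {
            "min_rip_size_nm": config.min_rip_size,
            "full_fraction": config.full_fraction,
            "high_force_pN": config.high_force,
            "bin_width_nm": config.bin_width,
        },
        "conditions": {},
    }
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        write_run_config(config, outdir / "run_config.yaml")

    analyses = {}
    for k, cond in enumerate(config.conditions):
        logger.info("pipeline: simulating condition %s", cond)
        sim_cfg = sim.apply_condition(replace(config.simulation, condition=cond))
        dataset = sim.simulate_condition(
            sim_cfg, config.n_molecules, config.n_cycles,
            seed=config.seed * 1000 + k,
        )
        logger.info("pipeline: analyzing condition %s (%d cycles)", cond, len(dataset))
        cond_cfg = replace(config, simulation=sim_cfg)
        res = analyze_dataset(dataset, cond_cfg)
        analyses[cond] = res
        dist = res["distribution"]
        report["conditions"][cond] = {
            "n_cycles": len(dataset),
            "delta_lc_peak_nm": dist.peak_location,
            "delta_lc_peak_sd_nm": dist.peak_sd,
            "fraction_by_class": dist.fraction_by_class,
            "tallies": res["tallies"],
            "zero_peak_mass": res["zero_peak_mass"],
            "mean_max_unfold_force_pN": float(np.nanmean(res["max_unfold_forces"])),
            "truth_labels": {
                lab: sum(1 for r in dataset if r.truth.label == lab)
                for lab in ("full", "misfolded", "locked")
            },
        }
        if outdir:
            cond_dir = outdir / cond
            cond_dir.mkdir(exist_ok=True)
            res["force_vs_lc"].to_csv(cond_dir / "force_vs_lc.tsv", sep="\t", index=False)
            _write_cycle_table(res["stretch_results"], cond_dir / "cycles.tsv",
                               config.config_hash(), config.seed)
            for record in dataset:
                write_trace(
                    record.stretch,
                    cond_dir / f"m{record.stretch.molecule_id:03d}_c{record.stretch.cycle:02d}_stretch.tsv",
                )
                if record.relax is not None:
                    write_trace(
                        record.relax,
                        cond_dir / f"m{record.relax.molecule_id:03d}_c{record.relax.cycle:02d}_relax.tsv",
                    )
    # condition contrast (pairwise Welch on per-cycle max unfolding force)
    if "no_smap" in analyses and "atux" in analyses:
        a = analyses["atux"]["max_unfold_forces"]
        b = analyses["no_smap"]["max_unfold_forces"]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size >= 2 and b.size >= 2:
            t, p = agg.welch_t_test(a, b)
            report["atux_vs_no_smap_max_force"] = {
                "t": t, "p": p,
                "mean_atux_pN": float(np.mean(a)), "mean_no_smap_pN": float(np.mean(b)),
            }
    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(_as_jsonable(report), fh, indent=2, sort_keys=True)
    return report


def _write_cycle_table(results, path, config_hash: str, seed: int) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "molecule_id": r.molecule_id,
                "cycle": r.cycle,
                "sweep": r.sweep,
                "n_transitions": len(r.transitions),
                "total_dlc_nm": r.total_dlc,
                "max_force_pN": r.max_force,
                "label": r.label,
                "tether_status": r.tether_status,
            }
        )
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
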