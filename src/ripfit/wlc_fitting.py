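"""Per-branch extensible-WLC fitting and contour-length bookkeeping.

Each inter-transition branch of a force-extension sweep is fit with the
series tether model (DNA handles + protein) in force space: the only free
parameter is the protein's unfolded contour-length gain on the
[0, expected_dlc] coordinate (the rigid folded span shrinks proportionally);
the handle and protein elastic constants stay clamped at their configured
values (Lp_DNA = 30 nm, Lp_protein = 0.5 nm, K_DNA = 500 pN,
K_protein = 300 pN by default).  Contour-length changes follow as
differences of fitted branch values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .polymer_models import TetherConstants, protein_tether, tether_extension_grid
from .rip_analysis import Transition
from .trace import ForceExtensionTrace

__all__ = [
    "FitError",
    "BranchFit",
    "CycleResult",
    "fit_branch",
    "fit_cycle_branches",
    "cycle_delta_lc",
    "force_vs_lc_table",
]

logger = logging.getLogger(__name__)

_FORCE_GRID = np.concatenate(([0.0], np.geomspace(5e-3, 80.0, 900)))


class FitError(RuntimeError):
    pass


@dataclass
class BranchFit:
    branch_id: int
    fitted_lc: float  # nm, unfolded contour gain of the branch
    residual_rms: float  # pN
    n_points: int
    converged: bool
    fixed: dict = field(default_factory=dict)  # clamped constants, echoed


@dataclass
class CycleResult:
    """Fit products of one stretch (or relax) sweep."""

    molecule_id: int
    cycle: int
    sweep: str
    branch_fits: list[BranchFit | None]
    transitions: list[Transition]
    delta_lcs: list[float | None]  # per transition, signed
    total_dlc: float  # last minus first fitted branch Lc
    max_force: float
    label: str | None = None
    tether_status: str = "valid"
    partial: bool = False


def _model_extension(dlc: float, constants: TetherConstants) -> np.ndarray:
    model = protein_tether(dlc, constants)
    return tether_extension_grid(_FORCE_GRID, model)


def _sse(dlc, x, f, constants, delta=0.6):
    """Soft-L1 cost on force residuals (delta in pN): behaves as least
    squares near zero but linearizes outliers, so a few samples from a
    brief excursion into another branch cannot drag the fit."""
    x_model = _model_extension(float(dlc), constants)
    f_pred = np.interp(x, x_model, _FORCE_GRID)
    r = (f_pred - f) / delta
    return float(np.sum(delta**2 * 2.0 * (np.sqrt(1.0 + r * r) - 1.0)))


def fit_branch(
    extension: np.ndarray,
    force: np.ndarray,
    constants: TetherConstants,
    branch_id: int = 0,
    min_points: int = 10,
    min_span: float = 1.0,
) -> BranchFit | None:
    """Least-squares eWLC fit of one branch in force space.

    Only the protein's unfolded contour gain is free; all elastic constants
    stay clamped.  Segments with fewer than ``min_points`` samples or less
    than ``min_span`` pN of force range are skipped (returns None) with a
    logged warning.
    """
    x = np.asarray(extension, dtype=float)
    f = np.asarray(force, dtype=float)
    if x.size < min_points or (f.max() - f.min()) < min_span:
        logger.warning(
            "branch %d skipped: %d points spanning %.2f pN", branch_id, x.size,
            float(f.max() - f.min()) if x.size else 0.0,
        )
        return None
    hi = constants.expected_dlc * 1.1
    res = minimize_scalar(
        _sse, bounds=(0.0, hi), args=(x, f, constants), method="bounded",
        options={"xatol": 1e-4},
    )
    if not res.success:
        raise FitError(f"branch {branch_id}: bounded scalar fit failed: {res.message}")
    fitted = max(float(res.x), 0.0)
    rms = float(np.sqrt(res.fun / x.size))
    return BranchFit(
        branch_id=branch_id,
        fitted_lc=fitted,
        residual_rms=rms,
        n_points=int(x.size),
        converged=bool(res.success),
        fixed=constants.to_config(),
    )


def _refit_clean_prefix(
    x: np.ndarray,
    f: np.ndarray,
    fit: BranchFit,
    constants: TetherConstants,
    resid_limit: float = 0.6,
    min_keep: int = 30,
) -> BranchFit:
    """Excise contamination from a baseline branch.

    A rip too small for the detector leaves systematic force residuals in
    the branch fit.  If the smoothed residual exceeds ``resid_limit`` pN
    anywhere, the branch is refit on the samples before the first such
    point (the clean prefix), which removes the contaminated tail."""
    x_model = _model_extension(fit.fitted_lc, constants)
    resid = np.interp(x, x_model, _FORCE_GRID) - f
    if resid.size < min_keep + 10:
        return fit
    kernel = np.ones(9) / 9.0
    smooth = np.convolve(resid, kernel, mode="same")
    smooth[:5] = 0.0
    smooth[-5:] = 0.0
    bad = np.flatnonzero(np.abs(smooth) > resid_limit)
    if bad.size == 0 or bad[0] < min_keep:
        return fit
    refit = fit_branch(x[: bad[0] - 5], f[: bad[0] - 5], constants, branch_id=fit.branch_id)
    return refit if refit is not None else fit


def fit_cycle_branches(
    trace: ForceExtensionTrace,
    transitions: list[Transition],
    constants: TetherConstants,
    exclude_margin: int = 3,
    min_force: float = 0.2,
) -> list[BranchFit | None]:
    """Fit every inter-transition branch of one sweep.

    Samples within ``exclude_margin`` of a rip are dropped (jump
    contamination), as are samples below ``min_force`` where the tether is
    slack and the model uninformative.  On a stretch sweep the baseline
    (first) branch is additionally screened for residual structure left by
    rips below the detection threshold and refit on its clean prefix.
    """
    n = len(trace)
    edges = [0]
    for t in transitions:
        edges.extend([t.index_range[0], t.index_range[1] + 1])
    edges.append(n)
    fits: list[BranchFit | None] = []
    for b in range(len(transitions) + 1):
        lo = edges[2 * b]
        hi = edges[2 * b + 1]
        lo2 = lo + (exclude_margin if b > 0 else 0)
        hi2 = hi - (exclude_margin if b < len(transitions) else 0)
        seg = slice(max(lo2, 0), max(hi2, 0))
        x = trace.extension[seg]
        f = trace.force[seg]
        keep = f >= min_force
        fit = fit_branch(x[keep], f[keep], constants, branch_id=b)
        if b == 0 and trace.sweep == "stretch" and fit is not None:
            fit = _refit_clean_prefix(x[keep], f[keep], fit, constants)
        fits.append(fit)
    return fits


def cycle_delta_lc(
    transitions: list[Transition],
    branch_fits: list[BranchFit | None],
    trace: ForceExtensionTrace | None = None,
    molecule_id: int = 0,
    cycle: int = 0,
    sweep: str = "stretch",
) -> CycleResult:
    """Contour-length changes of one sweep: per-transition ΔLc as the
    difference of flanking branch fits, cycle total as last minus first
    fitted branch Lc.  Missing branch fits flag the result partial."""
    if len(branch_fits) != len(transitions) + 1:
        raise ValueError("need one more branch fit than transitions")
    delta: list[float | None] = []
    partial = False
    for i, t in enumerate(transitions):
        a, b = branch_fits[i], branch_fits[i + 1]
        if a is None or b is None:
            delta.append(None)
            partial = True
        else:
            delta.append(b.fitted_lc - a.fitted_lc)
    valid = [bf for bf in branch_fits if bf is not None]
    if not valid:
        raise FitError("no branch of the sweep could be fitted")
    total = valid[-1].fitted_lc - valid[0].fitted_lc
    max_force = float(np.max(trace.force)) if trace is not None else float("nan")
    return CycleResult(
        molecule_id=molecule_id,
        cycle=cycle,
        sweep=sweep,
        branch_fits=branch_fits,
        transitions=transitions,
        delta_lcs=delta,
        total_dlc=float(total),
        max_force=max_force,
        partial=partial,
    )


def force_vs_lc_table(
    cycles: list[CycleResult], include_misfolded: bool = False
) -> pd.DataFrame:
    """One row per transition: force before the rip vs the absolute contour
    length (protein-only coordinate) of the preceding branch.

    Cycles labelled misfolded are excluded unless ``include_misfolded``;
    unlabelled cycles are kept.  Both unfold and refold rows appear,
    labelled by direction.
    """
    rows = []
    for cr in cycles:
        if not include_misfolded and cr.label == "misfolded":
            continue
        for t, bf in zip(cr.transitions, cr.branch_fits[:-1]):
            if bf is None:
                continue
            rows.append(
                {
                    "molecule_id": cr.molecule_id,
                    "cycle": cr.cycle,
                    "sweep": cr.sweep,
                    "direction": t.direction,
                    "force_before_pN": t.force_before,
                    "lc_nm": bf.fitted_lc,
                    "extension_jump_nm": t.extension_jump,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "molecule_id", "cycle", "sweep", "direction",
            "force_before_pN", "lc_nm", "extension_jump_nm",
        ],
    )
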