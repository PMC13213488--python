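"""Extensible worm-like-chain (eWLC) mechanics for single elements and
series-composed tethers.

The model is the Marko–Siggia interpolation with an enthalpic stretch term:

    F = (kBT / Lp) * [ 1/(4 (1 - x/Lc + F/K)^2) - 1/4 + x/Lc - F/K ]

with persistence length ``Lp``, contour length ``Lc`` and stretch modulus
``K``.  Writing ``z = x/Lc - F/K`` the relation becomes a cubic in ``z`` that
is solved here by (vectorized) bisection, giving a closed-form-quality
extension-given-force evaluation; force-given-extension is a bracketed root
find on top of it.

A dual-trap construct (protein between two DNA handles) is represented as a
:class:`TetherModel`: an ordered series of eWLC elements plus a rigid offset
for the folded core's N–C span.  At a common tension the extensions add.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KBT_ROOM",
    "WLCParams",
    "TetherElement",
    "TetherModel",
    "TetherConstants",
    "ewlc_extension",
    "ewlc_force",
    "tether_extension",
    "tether_force",
    "protein_tether",
]

#: Thermal energy at 298 K in pN·nm, used throughout.
KBT_ROOM = 4.114

#: Hard cap for numeric force inversion (pN).
FORCE_CAP = 200.0


@dataclass(frozen=True)
class WLCParams:
    """Parameters of one extensible worm-like-chain element.

    All lengths in nm, forces in pN, energies in pN·nm.
    """

    persistence_length: float
    contour_length: float
    stretch_modulus: float
    thermal_energy: float = KBT_ROOM

    def __post_init__(self) -> None:
        vals = (
            self.persistence_length,
            self.contour_length,
            self.stretch_modulus,
            self.thermal_energy,
        )
        if not all(math.isfinite(v) and v > 0 for v in vals):
            raise ValueError(f"WLC parameters must be finite and positive, got {self}")
        if self.persistence_length >= self.contour_length:
            raise ValueError(
                "persistence_length must be smaller than contour_length "
                f"(got Lp={self.persistence_length}, Lc={self.contour_length})"
            )


@dataclass(frozen=True)
class TetherElement:
    role: str  # handle | folded_protein | unfolded_polypeptide
    params: WLCParams


@dataclass(frozen=True)
class TetherModel:
    """Ordered series of elastic elements sharing one tension, plus a rigid
    offset (nm) for the folded core's fixed end-to-end span."""

    elements: tuple[TetherElement, ...]
    rigid_offset: float = 0.0

    def __post_init__(self) -> None:
        if len(self.elements) == 0:
            raise ValueError("TetherModel needs at least one element")
        if not math.isfinite(self.rigid_offset) or self.rigid_offset < 0:
            raise ValueError(f"rigid_offset must be finite and >= 0, got {self.rigid_offset}")


def _ms_relative_extension(phi: np.ndarray) -> np.ndarray:
    """Solve the Marko–Siggia relation g(z) = phi for z in [0, 1).

    ``phi = F * Lp / kBT`` and ``g(z) = 1/(4(1-z)^2) - 1/4 + z``.  g is
    strictly increasing on [0, 1) so plain bisection is exact and vectorizes.
    """
    phi = np.asarray(phi, dtype=float)
    lo = np.zeros_like(phi)
    hi = np.full_like(phi, 1.0 - 1e-12)
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        g = 0.25 / (1.0 - mid) ** 2 - 0.25 + mid
        take = g < phi
        lo = np.where(take, mid, lo)
        hi = np.where(take, hi, mid)
    return np.where(phi <= 0.0, 0.0, 0.5 * (lo + hi))


def ewlc_extension(force, params: WLCParams):
    """Extension (nm) of one eWLC element at the given tension (pN).

    Accepts a scalar or array force; strictly increasing and continuous in
    force, 0 at zero force.
    """
    f = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("force must be finite")
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    phi = f * params.persistence_length / params.thermal_energy
    z = _ms_relative_extension(phi)
    x = params.contour_length * (z + f / params.stretch_modulus)
    if np.isscalar(force) or np.ndim(force) == 0:
        return float(x)
    return x


def ewlc_force(extension: float, params: WLCParams, force_cap: float = FORCE_CAP) -> float:
    """Tension (pN) at which one eWLC element reaches the given extension (nm).

    Numeric inverse of :func:`ewlc_extension` by bracketed root finding;
    raises if ``extension`` lies outside the invertible range at ``force_cap``.
    """
    if not math.isfinite(extension):
        raise ValueError("extension must be finite")
    if extension < 0:
        raise ValueError("extension must be >= 0")
    if extension == 0.0:
        return 0.0
    x_cap = ewlc_extension(force_cap, params)
    if extension >= x_cap:
        raise ValueError(
            f"extension {extension:.6g} nm exceeds invertible range "
            f"({x_cap:.6g} nm at the {force_cap:.6g} pN force cap)"
        )
    return float(
        brentq(lambda f: ewlc_extension(f, params) - extension, 0.0, force_cap, xtol=1e-9)
    )


def tether_extension(force, model: TetherModel):
    """Total extension (nm) of a series tether at the given tension (pN):
    sum of element extensions plus the rigid offset."""
    f = np.asarray(force, dtype=float)
    total = np.zeros_like(f) + model.rigid_offset
    for el in model.elements:
        total = total + ewlc_extension(f, el.params)
    if np.isscalar(force) or np.ndim(force) == 0:
        return float(total)
    return total


def tether_force(extension: float, model: TetherModel, force_cap: float = FORCE_CAP) -> float:
    """Tension (pN) at which the series tether reaches the given extension (nm)."""
    if not math.isfinite(extension):
        raise ValueError("extension must be finite")
    if extension <= model.rigid_offset:
        return 0.0
    x_cap = tether_extension(force_cap, model)
    if extension >= x_cap:
        raise ValueError(
            f"extension {extension:.6g} nm exceeds invertible range "
            f"({x_cap:.6g} nm at the {force_cap:.6g} pN force cap)"
        )
    return float(
        brentq(lambda f: tether_extension(f, model) - extension, 0.0, force_cap, xtol=1e-9)
    )


# ---------------------------------------------------------------------------
# The dual-trap construct: protein flanked by DNA handles.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TetherConstants:
    """Fixed mechanical constants of the handle/protein construct.

    Defaults describe a 589-residue, 15-HEAT-repeat protein tethered via two
    600 bp dsDNA handles:

    * handles: Lp = 30 nm, total Lc = 2 x 600 bp x 0.34 nm/bp = 408 nm,
      K = 500 pN (midpoint of the 400-600 pN range used in fitting);
    * unfolded polypeptide: Lp = 0.5 nm, K = 300 pN, contour
      0.365 nm/residue (589 residues -> 215 nm chain);
    * folded core: rigid 15 nm N-C span, so the expected contour-length
      gain for complete unfolding is 215 - 15 = 200 nm.

    The protein state is parameterized by ``unfolded_dlc`` in
    [0, expected_dlc]: the contour-length-change coordinate reported by
    branch fits.  The rigid span shrinks proportionally as repeats unfold.
    """

    handle_lp: float = 30.0
    handle_lc: float = 2 * 600 * 0.34  # 408 nm total for both handles
    handle_k: float = 500.0
    protein_lp: float = 0.5
    protein_k: float = 300.0
    residues_total: int = 589
    contour_per_residue: float = 0.365
    folded_span: float = 15.0
    thermal_energy: float = KBT_ROOM

    @property
    def chain_contour(self) -> float:
        """Contour length (nm) of the fully unfolded polypeptide."""
        return self.residues_total * self.contour_per_residue

    @property
    def expected_dlc(self) -> float:
        """Expected total contour-length gain (nm) for complete unfolding."""
        return self.chain_contour - self.folded_span

    def handle_params(self) -> WLCParams:
        return WLCParams(self.handle_lp, self.handle_lc, self.handle_k, self.thermal_energy)

    def protein_params(self, contour_length: float) -> WLCParams:
        return WLCParams(self.protein_lp, contour_length, self.protein_k, self.thermal_energy)

    def to_config(self) -> dict[str, float]:
        """Flat key = value mapping (units: nm / pN / pN·nm)."""
        return {
            "handle_lp_nm": self.handle_lp,
            "handle_lc_nm": self.handle_lc,
            "handle_k_pN": self.handle_k,
            "protein_lp_nm": self.protein_lp,
            "protein_k_pN": self.protein_k,
            "residues_total": self.residues_total,
            "contour_per_residue_nm": self.contour_per_residue,
            "folded_span_nm": self.folded_span,
            "thermal_energy_pNnm": self.thermal_energy,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "TetherConstants":
        return cls(
            handle_lp=float(cfg["handle_lp_nm"]),
            handle_lc=float(cfg["handle_lc_nm"]),
            handle_k=float(cfg["handle_k_pN"]),
            protein_lp=float(cfg["protein_lp_nm"]),
            protein_k=float(cfg["protein_k_pN"]),
            residues_total=int(cfg["residues_total"]),
            contour_per_residue=float(cfg["contour_per_residue_nm"]),
            folded_span=float(cfg["folded_span_nm"]),
            thermal_energy=float(cfg["thermal_energy_pNnm"]),
        )


def protein_tether(unfolded_dlc: float, constants: TetherConstants) -> TetherModel:
    """Series tether (handles + protein) at a given unfolded contour-length
    gain ``unfolded_dlc`` (nm) on the [0, expected_dlc] coordinate.

    ``unfolded_dlc = 0`` is the fully folded protein (rigid span only);
    ``unfolded_dlc = expected_dlc`` is the fully unfolded chain.
    """
    exp = constants.expected_dlc
    # modest headroom above the full gain is allowed so fits can absorb noise
    if not 0.0 <= unfolded_dlc <= exp * 1.2:
        raise ValueError(f"unfolded_dlc must lie in [0, {1.2 * exp:.6g}], got {unfolded_dlc}")
    frac = unfolded_dlc / exp
    lc_unf = frac * constants.chain_contour
    offset = constants.folded_span * max(1.0 - frac, 0.0)
    elements = [TetherElement("handle", constants.handle_params())]
    if lc_unf > constants.protein_lp * 1.5:  # degenerate tiny chains carry no compliance
        elements.append(
            TetherElement("unfolded_polypeptide", constants.protein_params(lc_unf))
        )
        lc_unf_extra = 0.0
    else:
        # fold the (sub-nm) chain into the rigid offset rather than build an
        # eWLC with Lc < Lp
        lc_unf_extra = lc_unf
    return TetherModel(tuple(elements), rigid_offset=offset + lc_unf_extra)


def tether_extension_grid(forces: np.ndarray, model: TetherModel) -> np.ndarray:
    """Vectorized series extension on a force grid (helper for tabulated
    force-balance solves)."""
    total = np.full(forces.shape, model.rigid_offset, dtype=float)
    for el in model.elements:
        p = el.params
        phi = forces * p.persistence_length / p.thermal_energy
        z = _ms_relative_extension(phi)
        total += p.contour_length * (z + forces / p.stretch_modulus)
    return total
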