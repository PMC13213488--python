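"""Ensemble binding assays: NanoDSF melting-temperature extraction and
fluorescence-polarization (FP) one-site binding fits, with synthetic
generators for both.

NanoDSF monitors intrinsic fluorescence at 350 and 330 nm during a thermal
ramp; the melting temperature is the inflection of the I350/I330 ratio,
located as the extremum of its first derivative (local-quadratic smoothing,
quadratic refinement of the extremum).  FP reports binding through

    P = (I_par - I_perp) / (I_par + I_perp)

and titrations are fit with the one-site model

    P = Pmax * C / (Kd + C)

by nonlinear least squares, after subtracting the protein-only background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter
from scipy.special import expit

__all__ = [
    "MeltCurve",
    "FPTitration",
    "BindingFit",
    "NoTransitionError",
    "BindingFitError",
    "melt_ratio_derivative",
    "extract_tm",
    "polarization",
    "fit_one_site",
    "generate_melt",
    "generate_fp",
]


class NoTransitionError(ValueError):
    """The melt derivative shows no unfolding transition."""


class BindingFitError(RuntimeError):
    pass


@dataclass
class MeltCurve:
    """Thermal melt readout: temperature grid (°C, strictly increasing) and
    fluorescence intensities at 350 and 330 nm (a.u., positive)."""

    temperature: np.ndarray
    intensity_350: np.ndarray
    intensity_330: np.ndarray
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.intensity_350 = np.asarray(self.intensity_350, dtype=float)
        self.intensity_330 = np.asarray(self.intensity_330, dtype=float)
        if not (self.temperature.size == self.intensity_350.size == self.intensity_330.size):
            raise ValueError("temperature and intensities must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if np.any(self.intensity_330 <= 0) or np.any(self.intensity_350 <= 0):
            raise ValueError("intensities must be positive")


@dataclass
class FPTitration:
    """FP titration: titrant concentration (μM) vs polarization (mP by
    default, dimensionless if ``units='P'``)."""

    concentration: np.ndarray
    polarization: np.ndarray
    i_parallel: np.ndarray | None = None
    i_perpendicular: np.ndarray | None = None
    units: str = "mP"
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.polarization = np.asarray(self.polarization, dtype=float)
        if self.concentration.size != self.polarization.size:
            raise ValueError("concentration and polarization must have equal length")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass
class BindingFit:
    """Fit product: Tm for melts, (Kd, Pmax) for titrations."""

    kind: str  # "melt" | "fp"
    tm: float | None = None
    kd: float | None = None
    pmax: float | None = None
    stderr: dict = field(default_factory=dict)
    residual_norm: float = 0.0
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# NanoDSF
# ---------------------------------------------------------------------------


def melt_ratio_derivative(
    curve: MeltCurve, smooth_window: int = 7
) -> tuple[np.ndarray, np.ndarray]:
    """First derivative of the fluorescence ratio I350/I330 with respect to
    temperature (dFIR), smoothed by local quadratic regression
    (Savitzky-Golay) over ``smooth_window`` points."""
    n = curve.temperature.size
    if n < 20:
        raise ValueError("melt curve needs at least 20 points")
    if smooth_window % 2 == 0 or smooth_window >= n // 2:
        raise ValueError("smooth_window must be odd and < n/2")
    ratio = curve.intensity_350 / curve.intensity_330
    dT = np.diff(curve.temperature)
    if np.max(np.abs(dT - dT[0])) > 1e-6 * dT[0] + 1e-9:
        raise ValueError("temperature grid must be uniform")
    deriv = savgol_filter(ratio, smooth_window, polyorder=2, deriv=1, delta=float(dT[0]))
    return curve.temperature, deriv


def extract_tm(temperature: np.ndarray, derivative: np.ndarray) -> float:
    """Melting temperature: the global extremum of the ratio derivative,
    refined by quadratic interpolation of the three neighbouring points.

    The extremum is located on |dFIR/dT - median| so the convention (the
    ratio may rise or the plotted derivative be negated) does not matter.
    Raises :class:`NoTransitionError` when the series is flat or has no
    prominent extremum (e.g. a monotone baseline without a transition).
    """
    t = np.asarray(temperature, dtype=float)
    d = np.asarray(derivative, dtype=float)
    dev = d - np.median(d)
    mag = np.abs(dev)
    mad = float(np.median(np.abs(dev - np.median(dev))))
    i = int(np.argmax(mag))
    if mag[i] <= 5.0 * mad + 1e-12:
        raise NoTransitionError(
            "no prominent derivative extremum: curve shows no melting transition"
        )
    if i == 0 or i == len(d) - 1:
        return float(t[i])
    y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(t[i])
    shift = float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))
    step = t[i] - t[i - 1]
    return float(t[i] + shift * step)


def generate_melt(
    tm: float,
    amplitude: float = 0.3,
    baseline: tuple[float, float] = (0.8, 0.001),
    noise_sd: float = 0.0,
    t_min: float = 20.0,
    t_max: float = 90.0,
    step: float = 0.1,
    width: float = 2.0,
    seed=None,
) -> MeltCurve:
    """Synthetic two-state melt on a 20-90 °C ramp.

    The fluorescence ratio follows ``baseline + amplitude * logistic((T -
    tm)/width)`` (the ratio rises on unfolding); intensities are emitted as
    I330 = 1000 a.u. and I350 = 1000 * ratio, with Gaussian noise of
    ``noise_sd`` on the ratio.  The generating parameters are stored in
    ``truth``.
    """
    if not t_min < tm < t_max:
        raise ValueError("tm must lie inside the temperature grid")
    rng = np.random.default_rng(seed)
    t = np.arange(t_min, t_max + step / 2, step)
    b0, b1 = baseline
    ratio = b0 + b1 * (t - t_min) + amplitude * expit((t - tm) / width)
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, t.size)
    i330 = np.full(t.size, 1000.0)
    return MeltCurve(
        temperature=t,
        intensity_350=1000.0 * ratio,
        intensity_330=i330,
        truth={"tm": tm, "amplitude": amplitude, "baseline": baseline,
               "width": width, "noise_sd": noise_sd},
    )


# ---------------------------------------------------------------------------
# Fluorescence polarization
# ---------------------------------------------------------------------------


def polarization(i_parallel, i_perpendicular, millipolarization: bool = False):
    """P = (I_par - I_perp) / (I_par + I_perp), bounded in [-1, 1]
    (x1000 when ``millipolarization``)."""
    ipar = np.asarray(i_parallel, dtype=float)
    iperp = np.asarray(i_perpendicular, dtype=float)
    if np.any(ipar < 0) or np.any(iperp < 0):
        raise ValueError("intensities must be >= 0")
    total = ipar + iperp
    if np.any(total == 0):
        raise ValueError("polarization undefined: both intensities are zero")
    p = (ipar - iperp) / total
    if millipolarization:
        p = p * 1000.0
    if np.ndim(i_parallel) == 0 and np.ndim(i_perpendicular) == 0:
        return float(p)
    return p


def _one_site(c, pmax, kd):
    return pmax * c / (kd + c)


def fit_one_site(titration: FPTitration, subtract_background: bool = True) -> BindingFit:
    """Nonlinear least-squares fit of the one-site model
    P = Pmax * C / (Kd + C); standard errors from the fit curvature.

    Zero-concentration wells serve as the background control: their mean is
    subtracted from every point before fitting.  Requires at least 5
    concentration points spanning a decade.
    """
    c = titration.concentration
    p = titration.polarization.astype(float).copy()
    pos = c > 0
    if np.unique(c[pos]).size < 5:
        raise ValueError("need at least 5 distinct nonzero concentration points")
    span = c[pos].max() / c[pos].min()
    if span < 10.0:
        raise ValueError("concentrations must span at least one decade")
    if subtract_background and np.any(~pos):
        p = p - float(np.mean(p[~pos]))
    p0 = (max(float(p[pos].max()), 1e-6), float(np.median(c[pos])))
    try:
        popt, pcov = curve_fit(
            _one_site, c, p, p0=p0,
            bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise BindingFitError(f"one-site fit did not converge: {exc}") from exc
    pmax, kd = float(popt[0]), float(popt[1])
    if pmax < 1e-3:
        raise BindingFitError("no binding signal: fitted Pmax is zero")
    if kd <= 1e-8 or kd > 100.0 * c[pos].max():
        raise BindingFitError(
            f"fitted Kd {kd:.3g} μM hit the bounds (data span {c[pos].min():.3g}-"
            f"{c[pos].max():.3g} μM); titration is uninformative"
        )
    perr = np.sqrt(np.diag(pcov))
    resid = p - _one_site(c, *popt)
    return BindingFit(
        kind="fp",
        kd=kd,
        pmax=pmax,
        stderr={"pmax": float(perr[0]), "kd": float(perr[1])},
        residual_norm=float(np.linalg.norm(resid)),
        diagnostics={"n": int(c.size), "background_subtracted": bool(subtract_background)},
    )


def default_fp_concentrations(n_points: int = 12, c_min: float = 0.1, c_max: float = 80.0):
    """0 plus log-spaced titrant concentrations over 0.1-80 μM."""
    return np.concatenate(([0.0], np.geomspace(c_min, c_max, n_points)))


def generate_fp(
    kd: float,
    pmax: float = 100.0,
    concentrations=None,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed=None,
) -> FPTitration:
    """Synthetic FP titration from the one-site model (mP units), with
    optional Gaussian noise and replicate wells."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if concentrations is None:
        concentrations = default_fp_concentrations()
    c = np.tile(np.asarray(concentrations, dtype=float), n_replicates)
    rng = np.random.default_rng(seed)
    p = _one_site(c, pmax, kd)
    if noise_sd > 0:
        p = p + rng.normal(0.0, noise_sd, c.size)
    return FPTitration(
        concentration=c,
        polarization=p,
        truth={"kd": kd, "pmax": pmax, "noise_sd": noise_sd,
               "n_replicates": n_replicates},
    )
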