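"""Boltzmann sigmoid fitting of UV-melting curves.

Thermal denaturation of a nucleic acid assembly is modeled as a
cooperative two-state transition, so absorbance versus temperature
follows a Boltzmann sigmoid

    F(T) = A1 + (A2 - A1) / (1 + exp((Tm - T) / w))

with lower/upper baselines A1 and A2, melting temperature Tm (the
half-transition midpoint, F(Tm) = (A1 + A2) / 2) and transition width w
(the slope scale at Tm).  With w > 0 the curve rises from A1 to A2;
monotone-decreasing (hypochromic) curves are handled by A2 < A1.
Constructs with two distinct transitions (e.g. triangle NANPs) are not
resolved by this single-transition model and show elevated residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .data import NanpError


class DegenerateParameterError(NanpError):
    """w = 0 makes the sigmoid undefined."""


@dataclass
class MeltingCurve:
    """An absorbance-vs-temperature trace (temperatures in deg C)."""

    temperatures: np.ndarray
    absorbance: np.ndarray
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.temperatures.shape != self.absorbance.shape:
            raise ValueError("temperature and absorbance lengths differ")
        if len(self.temperatures) < 6:
            raise ValueError("melting curve needs at least 6 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not np.isfinite(self.absorbance).all():
            raise ValueError("absorbance values must be finite")


@dataclass
class BoltzmannFit:
    A1: float
    A2: float
    Tm: float
    w: float
    residual_rmse: float
    converged: bool
    message: str = ""

    @property
    def amplitude(self) -> float:
        return self.A2 - self.A1


def boltzmann_model(T, A1: float, A2: float, Tm: float, w: float):
    """Evaluate the Boltzmann sigmoid; F(Tm) = (A1 + A2) / 2."""
    if w == 0:
        raise DegenerateParameterError("transition width w must be nonzero")
    T = np.asarray(T, dtype=float)
    return A1 + (A2 - A1) / (1.0 + np.exp((Tm - T) / w))


def fit_boltzmann(curve: MeltingCurve) -> BoltzmannFit:
    """Least-squares Boltzmann fit of one melting curve.

    Initialization: baselines from the low-/high-temperature ends, Tm at
    the half-amplitude crossing, w = temperature range / 10.  Tm is
    constrained to the measured range and w > 0.  Non-convergence (or an
    unidentifiable flat curve) is reported via ``converged=False`` with
    diagnostics rather than an exception.
    """
    T, A = curve.temperatures, curve.absorbance
    n_edge = max(2, len(T) // 10)
    a_lo = float(A[:n_edge].mean())   # low-temperature baseline
    a_hi = float(A[-n_edge:].mean())  # high-temperature baseline
    t_span = float(T[-1] - T[0])
    w0 = t_span / 10.0
    scale = float(A.max() - A.min())

    if scale < 1e-12 * max(1.0, abs(float(A.mean()))) or scale == 0.0:
        # flat trace: amplitude and Tm are unidentifiable
        return BoltzmannFit(
            A1=a_lo, A2=a_hi, Tm=float(T.mean()), w=w0,
            residual_rmse=float(np.sqrt(((A - A.mean()) ** 2).mean())),
            converged=False, message="degenerate flat curve",
        )

    half = 0.5 * (a_lo + a_hi)
    tm0 = float(T[np.argmin(np.abs(A - half))])
    p0 = [a_lo, a_hi, tm0, w0]
    lower = [-np.inf, -np.inf, float(T[0]), 1e-9]
    upper = [np.inf, np.inf, float(T[-1]), np.inf]
    try:
        popt, pcov = curve_fit(
            boltzmann_model, T, A, p0=p0, bounds=(lower, upper), maxfev=20_000
        )
        converged = np.isfinite(pcov).all()
        message = "" if converged else "singular parameter covariance"
    except RuntimeError as exc:
        popt = p0
        converged, message = False, f"optimizer did not converge: {exc}"
    a1, a2, tm, w = (float(v) for v in popt)
    resid = A - boltzmann_model(T, a1, a2, tm, w)
    fit = BoltzmannFit(
        A1=a1, A2=a2, Tm=tm, w=w,
        residual_rmse=float(np.sqrt((resid**2).mean())),
        converged=converged, message=message,
    )
    if converged and abs(fit.amplitude) < 1e-6 * max(1.0, scale):
        fit.converged = False
        fit.message = "degenerate amplitude (flat transition)"
    return fit


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_melting_curves(path: str | Path) -> list[MeltingCurve]:
    """Read curves from CSV: ``temperature_c,absorbance`` for a single
    curve, or long format with a leading ``curve_id`` column."""
    frame = pd.read_csv(path)
    required = {"temperature_c", "absorbance"}
    if not required <= set(frame.columns):
        raise NanpError(
            f"{path}: melting CSV must have columns {sorted(required)}"
        )
    if "curve_id" in frame.columns:
        return [
            MeltingCurve(
                group["temperature_c"].to_numpy(),
                group["absorbance"].to_numpy(),
                curve_id=str(curve_id),
            )
            for curve_id, group in frame.groupby("curve_id", sort=False)
        ]
    return [
        MeltingCurve(
            frame["temperature_c"].to_numpy(),
            frame["absorbance"].to_numpy(),
            curve_id=Path(path).stem,
        )
    ]


def write_fits(fits: list[tuple[str, BoltzmannFit]], path: str | Path) -> None:
    """Write one row per fitted curve to ``melt_fits.csv`` format."""
    pd.DataFrame(
        [
            {
                "curve_id": curve_id,
                "A1": f.A1,
                "A2": f.A2,
                "Tm_c": f.Tm,
                "w_c": f.w,
                "residual_rmse": f.residual_rmse,
                "converged": f.converged,
                "message": f.message,
            }
            for curve_id, f in fits
        ]
    ).to_csv(path, index=False)
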