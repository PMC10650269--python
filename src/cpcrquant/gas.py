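"""In vitro gas-production kinetics.

Cumulative gas volumes from batch-culture syringes are blank-corrected and
fitted with the single-pool exponential model without lag,

    y(t) = V (1 - exp(-k t))

where V is the asymptotic gas volume (mL) and k the fractional rate (h⁻¹).
Derived statistics: half-time T0.5 = ln2/k and the half-time volume
G0.5 = V/2; by construction y(T0.5) = G0.5 exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import MissingBlankError

#: The 11-point manual recording grid (hours) used throughout.
DEFAULT_TIME_GRID = (2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0)


def gas_model(t, V: float, k: float):
    """Exponential gas model without lag: y = V(1 - e^(-kt))."""
    return V * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


@dataclass
class GasCurve:
    """Timed cumulative gas volumes for one syringe."""

    syringe_id: str
    times: np.ndarray
    volumes: np.ndarray
    substrate_mg: float = 500.0
    blank_corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.shape != self.volumes.shape or self.times.ndim != 1:
            raise ValueError("times and volumes must be matching 1-D arrays")
        if not np.all(np.diff(self.times) > 0) or self.times[0] <= 0:
            raise ValueError("times must be strictly increasing and start after 0")
        if not np.all(np.isfinite(self.volumes)):
            raise ValueError("volumes must be finite")


@dataclass
class GasKineticsFit:
    """NLS fit of the exponential model with derived half-time statistics."""

    syringe_id: str
    V: float
    k: float
    T0_5: float
    G0_5: float
    rss: float
    converged: bool
    n_obs: int
    flags: list = field(default_factory=list)

    def predict(self, t):
        return gas_model(t, self.V, self.k)


def assemble_curve(
    readings: pd.DataFrame,
    blanks: pd.DataFrame | None,
    syringe_id: str | None = None,
    require_blanks: bool = True,
    substrate_mg: float = 500.0,
) -> GasCurve:
    """Build a blank-corrected curve for one syringe.

    ``readings``: columns ``time_h``, ``volume_ml`` (optionally filtered to
    ``syringe_id``).  ``blanks``: same columns pooled over the blank
    syringes; their per-time means are subtracted, linearly interpolated
    when the time grids differ.  Early-time values may go slightly negative
    after correction — they are kept (truncating them would bias k).
    """
    df = readings
    if syringe_id is not None and "syringe_id" in df.columns:
        df = df[df["syringe_id"].astype(str) == str(syringe_id)]
    sid = str(syringe_id) if syringe_id is not None else str(
        df["syringe_id"].iloc[0] if "syringe_id" in df.columns else "syringe"
    )
    df = df.sort_values("time_h")
    t = df["time_h"].to_numpy(dtype=float)
    y = df["volume_ml"].to_numpy(dtype=float)

    if blanks is None or len(blanks) == 0:
        if require_blanks:
            raise MissingBlankError(f"syringe {sid}: no blank readings available")
        return GasCurve(sid, t, y, substrate_mg=substrate_mg, blank_corrected=False)

    bmeans = blanks.groupby("time_h")["volume_ml"].mean().sort_index()
    bt = bmeans.index.to_numpy(dtype=float)
    if t.min() < bt.min() or t.max() > bt.max():
        raise MissingBlankError(
            f"syringe {sid}: blank grid [{bt.min()}, {bt.max()}] does not cover "
            f"substrate times [{t.min()}, {t.max()}]"
        )
    correction = np.interp(t, bt, bmeans.to_numpy(dtype=float))
    return GasCurve(sid, t, y - correction, substrate_mg=substrate_mg, blank_corrected=True)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """V0 = 1.05·max(y); k0 from the log-linearised early points.

    ln(1 - y/V0) = -k t for the exact model, so a through-origin slope of
    that transform over points with 0 < y < 0.9·V0 seeds k.
    """
    V0 = 1.05 * float(np.max(y))
    if V0 <= 0:
        V0 = 1.0
    mask = (y > 0) & (y < 0.9 * V0)
    if mask.sum() >= 2:
        z = np.log(1.0 - y[mask] / V0)
        tt = t[mask]
        k0 = -float(np.sum(tt * z) / np.sum(tt * tt))
    else:
        k0 = math.log(2.0) / float(np.median(t))
    k0 = min(max(k0, 1e-4), 2.0)
    return V0, k0


def fit_exponential(curve: GasCurve) -> GasKineticsFit:
    """Nonlinear least squares fit of y = V(1 - e^(-kt)).

    Bounds V ∈ (0, 10·max(y)], k ∈ (0, 2]; trust-region reflective solver
    with ftol 1e-10 / xtol 1e-8.  Non-convergence returns the last iterate
    with ``converged=False``; data with no upward trend is flagged
    ``"not_increasing"`` but still fitted.
    """
    t, y = curve.times, curve.volumes
    if t.size < 4:
        raise ValueError("need >= 4 observations for the two-parameter fit")
    if t[-1] < 2 * t[0]:
        raise ValueError("observations must span at least one doubling of time")

    flags = []
    if np.polyfit(t, y, 1)[0] <= 0:
        flags.append("not_increasing")
    if not curve.blank_corrected:
        flags.append("uncorrected")

    V0, k0 = _initial_guess(t, y)
    ymax = max(float(np.max(y)), 1e-9)
    res = least_squares(
        lambda p: gas_model(t, p[0], p[1]) - y,
        x0=[min(V0, 10 * ymax), k0],
        bounds=([1e-9, 1e-9], [10 * ymax, 2.0]),
        method="trf",
        ftol=1e-10,
        xtol=1e-8,
        gtol=1e-12,
    )
    V, k = float(res.x[0]), float(res.x[1])
    return GasKineticsFit(
        syringe_id=curve.syringe_id,
        V=V,
        k=k,
        T0_5=math.log(2.0) / k,
        G0_5=V / 2.0,
        rss=float(np.sum(res.fun**2)),
        converged=bool(res.success),
        n_obs=int(t.size),
        flags=flags,
    )


def derived_stats(fit: GasKineticsFit, grid=None) -> tuple[float, float, np.ndarray]:
    """Half-time T0.5 = ln2/k, half-time volume G0.5 = V/2, predicted curve."""
    if not fit.converged:
        raise ValueError(f"syringe {fit.syringe_id}: fit did not converge")
    grid = np.asarray(grid if grid is not None else DEFAULT_TIME_GRID, dtype=float)
    return fit.T0_5, fit.G0_5, fit.predict(grid)


def methane_fraction(ch4_volume_ml: float, total_gas_ml: float) -> float:
    """CH4 as a percentage of total gas volume."""
    if total_gas_ml <= 0:
        raise ValueError("total gas must be positive")
    if not 0 <= ch4_volume_ml <= total_gas_ml:
        raise ValueError("CH4 volume must lie in [0, total gas]")
    return 100.0 * ch4_volume_ml / total_gas_ml


def fit_gas_table(
    gas_df: pd.DataFrame, require_blanks: bool = True
) -> tuple[pd.DataFrame, list[GasKineticsFit]]:
    """Fit every non-blank syringe in a tidy gas log.

    ``gas_df``: columns ``syringe_id``, ``is_blank``, ``time_h``,
    ``volume_ml``.  Returns the ``gas_fits`` table and the fit objects.
    """
    blanks = gas_df[gas_df["is_blank"].astype(bool)]
    substrate = gas_df[~gas_df["is_blank"].astype(bool)]
    fits = []
    for sid in substrate["syringe_id"].drop_duplicates():
        curve = assemble_curve(
            substrate, blanks if len(blanks) else None, syringe_id=sid,
            require_blanks=require_blanks,
        )
        fits.append(fit_exponential(curve))
    table = pd.DataFrame(
        [
            {
                "syringe_id": f.syringe_id,
                "V": f.V,
                "k": f.k,
                "T0_5": f.T0_5,
                "G0_5": f.G0_5,
                "rss": f.rss,
                "converged": f.converged,
                "flags": ";".join(f.flags),
            }
            for f in fits
        ]
    )
    return table, fits
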