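"""Peak phase, relative amplitude and mean of the model outputs.

Three output quantities are read off every simulated gene: total mRNA
abundance L+S, the poly(A) length metric L/S, and the long-tailed abundance
L (a rough proxy for translatability). Each is evaluated on a 48-h window
starting at t = 700 h (past the transient), linearly interpolated onto 500
equally spaced points, and summarised as

    mean               = average of the interpolated values
    relative amplitude = (max - min) / (2 * mean)
    peak phase         = mod(t_max + 700, 24)   [t_max window-relative, hr]

A quantity is called rhythmic when its relative amplitude is >= 0.2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .model import Trajectory

WINDOW_START = 700.0
WINDOW_LENGTH = 48.0
N_GRID = 500
RHYTHMIC_THRESHOLD = 0.2

#: Window-relative times of the 500-point analysis grid (left-inclusive).
GRID_REL = np.arange(N_GRID) * (WINDOW_LENGTH / N_GRID)
#: Clock phase (mod 24) of each grid point.
GRID_PHASE = (WINDOW_START + GRID_REL) % 24.0


class Quantity(enum.Enum):
    TOTAL = "L+S"   # total mRNA abundance
    RATIO = "L/S"   # poly(A) length metric
    LONG = "L"      # long-tailed mRNA abundance


@dataclass(frozen=True)
class RhythmFeatures:
    quantity: Quantity
    peak_phase: float        # hours, in [0, 24)
    relative_amplitude: float
    mean_level: float


def is_rhythmic(features: RhythmFeatures) -> bool:
    """True iff the relative amplitude reaches the 0.2 threshold (inclusive)."""
    return features.relative_amplitude >= RHYTHMIC_THRESHOLD


def _quantity_series(traj: Trajectory, quantity: Quantity) -> np.ndarray:
    if quantity is Quantity.TOTAL:
        return traj.L + traj.S
    if quantity is Quantity.LONG:
        return traj.L
    if np.any(traj.S <= 0):
        raise ValueError("S <= 0 in trajectory: L/S undefined (solver failure)")
    return traj.L / traj.S


def features_from_grid(values: np.ndarray, quantity: Quantity) -> RhythmFeatures:
    """Summarise a quantity already evaluated on the 500-point window grid.

    Ties at the maximum resolve to the first grid index, so a flat signal
    reports phase mod(700, 24) = 4 h with amplitude 0 (phase is meaningless
    there; filter on :func:`is_rhythmic` before using phases downstream).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (N_GRID,):
        raise ValueError(f"expected {N_GRID} grid values, got {values.shape}")
    mean = float(values.mean())
    if mean <= 0:
        raise ValueError(f"non-positive window mean ({mean}) for {quantity.value}")
    amp = float((values.max() - values.min()) / (2.0 * mean))
    phase = float(GRID_PHASE[int(np.argmax(values))])
    return RhythmFeatures(quantity, phase, amp, mean)


def extract_features(traj: Trajectory, quantity: Quantity) -> RhythmFeatures:
    """Extract (phase, amplitude, mean) of one quantity from a trajectory.

    The trajectory must cover [700, 748] h; the quantity's time series is
    linearly interpolated onto the 500-point grid before summarising.
    """
    t0, t1 = WINDOW_START, WINDOW_START + WINDOW_LENGTH
    if traj.times[0] > t0 or traj.times[-1] < t1:
        raise ValueError(
            f"trajectory [{traj.times[0]}, {traj.times[-1]}] does not cover "
            f"the analysis window [{t0}, {t1}]")
    series = _quantity_series(traj, quantity)
    grid_values = np.interp(t0 + GRID_REL, traj.times, series)
    return features_from_grid(grid_values, quantity)


#: Column names of the per-gene feature table, 3 features x 3 quantities.
FEATURE_COLUMNS = (
    "mean_total", "amp_total", "phase_total",
    "mean_ratio", "amp_ratio", "phase_ratio",
    "mean_long", "amp_long", "phase_long",
)

_QUANTITY_KEY = {Quantity.TOTAL: "total", Quantity.RATIO: "ratio",
                 Quantity.LONG: "long"}


def feature_columns(quantity: Quantity) -> tuple[str, str, str]:
    """(mean, amplitude, phase) column names for one quantity."""
    key = _QUANTITY_KEY[quantity]
    return (f"mean_{key}", f"amp_{key}", f"phase_{key}")


def batch_features(L_grid: np.ndarray, S_grid: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised feature extraction for many genes at once.

    ``L_grid`` and ``S_grid`` have shape (n_sets, 500): the long/short pools
    already evaluated on the window grid. Returns the nine feature arrays
    keyed by :data:`FEATURE_COLUMNS`. Rows with non-positive S or
    non-positive means yield NaN features (recorded, not raised, so batch
    sweeps can drop failures consistently).
    """
    L_grid = np.asarray(L_grid, dtype=float)
    S_grid = np.asarray(S_grid, dtype=float)
    if L_grid.shape != S_grid.shape or L_grid.ndim != 2 or L_grid.shape[1] != N_GRID:
        raise ValueError("L_grid and S_grid must both have shape (n, 500)")

    out: dict[str, np.ndarray] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        series = {
            Quantity.TOTAL: L_grid + S_grid,
            Quantity.RATIO: np.where(S_grid > 0, L_grid / np.where(S_grid > 0, S_grid, 1.0), np.nan),
            Quantity.LONG: L_grid,
        }
        for q, Y in series.items():
            mean = Y.mean(axis=1)
            bad = ~np.isfinite(mean) | (mean <= 0) | ~np.isfinite(Y).all(axis=1)
            Y_safe = np.where(np.isfinite(Y), Y, 0.0)
            amp = (Y_safe.max(axis=1) - Y_safe.min(axis=1)) / (2.0 * mean)
            phase = GRID_PHASE[np.argmax(Y_safe, axis=1)]
            mean = np.where(bad, np.nan, mean)
            amp = np.where(bad, np.nan, amp)
            phase = np.where(bad, np.nan, phase)
            mcol, acol, pcol = feature_columns(q)
            out[mcol], out[acol], out[pcol] = mean, amp, phase
    return out
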