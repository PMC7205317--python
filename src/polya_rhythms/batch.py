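"""Vectorised batch simulation of the entrained periodic regime.

The model is linear in (L, S) with 24-h-periodic coefficients, so its
entrained orbit can be computed exactly instead of integrating the 700-h
transient: one fixed-step RK4 pass over a single period yields the
fundamental (monodromy) matrix ``Phi`` and the forced response ``p`` from a
zero start, and the periodic initial condition follows from
``(I - Phi) x0 = p``. Because the orbit is asymptotically stable for every
admissible parameter set (degradation and deadenylation rates positive),
``I - Phi`` is nonsingular. The orbit is then read out on the standard
500-point analysis window grid, which is where feature extraction happens —
identical to what :func:`polya_rhythms.model.simulate` converges to after
its lead-in (the test suite cross-validates the two paths).

Everything is vectorised across parameter sets with numpy; tens of
thousands of genes per minute on one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, GRID_PHASE, batch_features
from .model import OMEGA, PARAM_NAMES

PERIOD = 24.0
DEFAULT_STEPS = 500  # RK4 steps per period; h = 0.048 h


def _rates(theta: np.ndarray, t: float) -> np.ndarray:
    """Instantaneous (kappa_trsc, kappa_dgrd, kappa_deA, kappa_polyA), shape (n, 4)."""
    k, A, phi = theta[:, 0:4], theta[:, 4:8], theta[:, 8:12]
    return k * (1.0 + A * np.cos(OMEGA * (t - phi)))


def _deriv(r: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """RHS for the augmented 2x3 state [u1 | u2 | v] per parameter set.

    Columns u1, u2 evolve homogeneously (dY = M(t) Y); the particular column
    v additionally receives the transcription forcing.
    """
    trsc, dgrd, deA, polyA = r[:, 0], r[:, 1], r[:, 2], r[:, 3]
    L, S = Y[:, 0, :], Y[:, 1, :]
    dL = -deA[:, None] * L + polyA[:, None] * S
    dS = deA[:, None] * L - (polyA + dgrd)[:, None] * S
    dL[:, 2] += trsc
    return np.stack([dL, dS], axis=1)


def _periodic_orbit_chunk(theta: np.ndarray, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Periodic orbit of one chunk, sampled at n_steps+1 times over [0, 24]."""
    n = theta.shape[0]
    h = PERIOD / n_steps
    Y = np.zeros((n, 2, 3))
    Y[:, 0, 0] = 1.0  # u1(0) = e1
    Y[:, 1, 1] = 1.0  # u2(0) = e2
    store = np.empty((n, n_steps + 1, 2, 3))
    store[:, 0] = Y
    r_t = _rates(theta, 0.0)
    for i in range(n_steps):
        t = i * h
        r_mid = _rates(theta, t + 0.5 * h)
        r_end = _rates(theta, t + h)
        k1 = _deriv(r_t, Y)
        k2 = _deriv(r_mid, Y + 0.5 * h * k1)
        k3 = _deriv(r_mid, Y + 0.5 * h * k2)
        k4 = _deriv(r_end, Y + h * k3)
        Y = Y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        store[:, i + 1] = Y
        r_t = r_end

    # (I - Phi) x0 = p, solved in closed form per set (2x2).
    Phi = Y[:, :, 0:2]
    p = Y[:, :, 2]
    a = 1.0 - Phi[:, 0, 0]
    b = -Phi[:, 0, 1]
    c = -Phi[:, 1, 0]
    d = 1.0 - Phi[:, 1, 1]
    det = a * d - b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        x0_L = (d * p[:, 0] - b * p[:, 1]) / det
        x0_S = (a * p[:, 1] - c * p[:, 0]) / det

    U = store[:, :, :, 0:2]
    v = store[:, :, :, 2]
    orbit = (U[:, :, :, 0] * x0_L[:, None, None]
             + U[:, :, :, 1] * x0_S[:, None, None] + v)
    return orbit[:, :, 0], orbit[:, :, 1]  # L(t), S(t), shape (n, n_steps+1)


def simulate_batch(theta: np.ndarray, n_steps: int = DEFAULT_STEPS,
                   chunk_size: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """Entrained L and S on the 500-point analysis grid for many genes.

    Parameters
    ----------
    theta
        (n, 12) array of parameter vectors in :data:`PARAM_NAMES` order
        (variant already applied, e.g. k_polyA = 0 rows for the variant
        without cytoplasmic polyadenylation).
    n_steps
        RK4 steps per 24-h period.
    chunk_size
        Sets integrated per vectorised pass (memory knob).

    Returns
    -------
    (L_win, S_win), each of shape (n, 500): the periodic solution evaluated
    at absolute times 700 + j*48/500. Rows that fail to integrate (extreme
    parameter draws destabilising the fixed step) come back as NaN.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[1] != len(PARAM_NAMES):
        raise ValueError(f"theta must have shape (n, {len(PARAM_NAMES)})")
    n = theta.shape[0]
    h = PERIOD / n_steps

    # The window grid times map onto the orbit by clock phase (mod 24).
    pos = GRID_PHASE / h
    idx = np.minimum(pos.astype(int), n_steps - 1)
    w = pos - idx

    L_win = np.empty((n, GRID_PHASE.size))
    S_win = np.empty((n, GRID_PHASE.size))
    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        L_orb, S_orb = _periodic_orbit_chunk(theta[lo:hi], n_steps)
        L_win[lo:hi] = (1.0 - w) * L_orb[:, idx] + w * L_orb[:, idx + 1]
        S_win[lo:hi] = (1.0 - w) * S_orb[:, idx] + w * S_orb[:, idx + 1]

    bad = ~np.isfinite(L_win).all(axis=1) | ~np.isfinite(S_win).all(axis=1)
    if bad.any():
        L_win[bad] = np.nan
        S_win[bad] = np.nan
    return L_win, S_win


def sweep_features(theta: np.ndarray, n_steps: int = DEFAULT_STEPS,
                   chunk_size: int = 2048) -> pd.DataFrame:
    """Simulate a parameter sweep and tabulate parameters plus rhythm features.

    Returns a DataFrame with the 12 parameter columns followed by the nine
    feature columns (mean / relative amplitude / peak phase of L+S, L/S, L).
    Failed rows carry NaN features and are counted in ``df.attrs['n_failed']``.
    """
    theta = np.asarray(theta, dtype=float)
    L_win, S_win = simulate_batch(theta, n_steps=n_steps, chunk_size=chunk_size)
    feats = batch_features(L_win, S_win)
    df = pd.DataFrame({name: theta[:, i] for i, name in enumerate(PARAM_NAMES)})
    for col in FEATURE_COLUMNS:
        df[col] = feats[col]
    df.attrs["n_failed"] = int(np.isnan(feats["mean_total"]).sum())
    return df
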