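"""Variance-based (Sobol) global sensitivity analysis.

Single and total-effect indices are estimated with the classic two-matrix
design: two independent groups A and B of N parameter sets, plus the k
hybrid groups AB(i) that copy A except for column i, which is taken from B.
With f(.) an output quantity of the model,

    Var(Y) ~ 1/(2N) sum [ (f(A_n) - mean_A)^2 + (f(B_n) - mean_B)^2 ]
    S_i    ~ 1/N  sum f(B_n) [ f(AB(i)_n) - f(A_n) ] / Var(Y)
    S_Ti   ~ 1/(2N) sum [ f(AB(i)_n) - f(A_n) ]^2 / Var(Y)

Estimates may come out slightly negative under Monte-Carlo noise; they are
reported raw. Peak phases are treated as plain scalars on [0, 24) for
variance purposes (phases are circular; see the correlation-comparison
experiment for why rank/linear correlation fares worse under circularity,
and the methods note for this caveat).

One analysis evaluates the model on N (k + 2) parameter sets per repeat,
where k = 11, 8 or 9 free parameters depending on the model variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .batch import simulate_batch
from .features import (FEATURE_COLUMNS, RHYTHMIC_THRESHOLD, batch_features,
                       feature_columns)
from .model import Variant
from .sampling import DistributionSpec, sample_free, global_spec


@dataclass(frozen=True)
class SobolDesign:
    """Two independent LHS groups plus the hybrid column-swap structure."""

    spec: DistributionSpec
    group_A: np.ndarray  # (N, k)
    group_B: np.ndarray  # (N, k)

    def __post_init__(self) -> None:
        A, B = np.asarray(self.group_A), np.asarray(self.group_B)
        if A.shape != B.shape or A.ndim != 2 or A.shape[1] != self.spec.k:
            raise ValueError("group_A and group_B must both be (N, k) with "
                             f"k = {self.spec.k}")

    @property
    def N(self) -> int:
        return self.group_A.shape[0]

    @property
    def k(self) -> int:
        return self.spec.k

    def hybrid(self, i: int) -> np.ndarray:
        """AB(i): A with column i replaced by column i of B (0-based)."""
        AB = self.group_A.copy()
        AB[:, i] = self.group_B[:, i]
        return AB

    def stacked(self) -> np.ndarray:
        """All N (k + 2) rows: A, B, AB(0), ..., AB(k-1), in free space."""
        return np.vstack([self.group_A, self.group_B]
                         + [self.hybrid(i) for i in range(self.k)])


def build_design(spec: DistributionSpec, N: int, seed) -> SobolDesign:
    """Draw the two independent Latin-hypercube groups of N parameter sets."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    seed_a, seed_b = seed.spawn(2)
    return SobolDesign(spec, sample_free(spec, N, seed_a),
                       sample_free(spec, N, seed_b))


def total_variance(fA: np.ndarray, fB: np.ndarray) -> float:
    """Pooled variance of the output over groups A and B."""
    fA, fB = np.asarray(fA, dtype=float), np.asarray(fB, dtype=float)
    if fA.shape != fB.shape or fA.ndim != 1:
        raise ValueError("fA and fB must be 1-D of equal length")
    if fA.size < 2:
        raise ValueError("need N >= 2 to estimate a variance")
    return 0.5 * (np.mean((fA - fA.mean()) ** 2) + np.mean((fB - fB.mean()) ** 2))


def single_index(fA: np.ndarray, fB: np.ndarray, fAB_i: np.ndarray,
                 var: float) -> float:
    """First-order index estimator; raw (may be slightly negative)."""
    if var <= 0:
        raise ZeroDivisionError("output variance is zero: index undefined")
    return float(np.mean(fB * (np.asarray(fAB_i) - np.asarray(fA))) / var)


def total_index(fA: np.ndarray, fAB_i: np.ndarray, var: float) -> float:
    """Total-effect index estimator."""
    if var <= 0:
        raise ZeroDivisionError("output variance is zero: index undefined")
    d = np.asarray(fAB_i, dtype=float) - np.asarray(fA, dtype=float)
    return float(0.5 * np.mean(d * d) / var)


def _evaluate_design(design: SobolDesign, n_steps: int,
                     chunk_size: int) -> dict[str, np.ndarray]:
    """Model outputs for every row of every matrix; shape (k + 2, N) each."""
    theta = design.spec.expand(design.stacked())
    L_win, S_win = simulate_batch(theta, n_steps=n_steps, chunk_size=chunk_size)
    feats = batch_features(L_win, S_win)
    return {col: feats[col].reshape(design.k + 2, design.N)
            for col in FEATURE_COLUMNS}


def sobol_indices_one_repeat(design: SobolDesign,
                             outputs: dict[str, np.ndarray] | None = None,
                             rhythmic_only: bool = False,
                             n_steps: int = 500,
                             chunk_size: int = 2048) -> pd.DataFrame:
    """Single and total indices of every (parameter, output) for one design.

    Rows whose model evaluation failed in *any* matrix are dropped from all
    matrices, keeping the estimators paired. With ``rhythmic_only``, phase
    outputs additionally keep only rows rhythmic (amplitude >= 0.2) in every
    matrix; mean and amplitude outputs are never filtered.
    """
    if outputs is None:
        outputs = _evaluate_design(design, n_steps, chunk_size)
    k, N = design.k, design.N
    base_ok = np.ones(N, dtype=bool)
    for col in FEATURE_COLUMNS:
        base_ok &= np.isfinite(outputs[col]).all(axis=0)

    records = []
    for col in FEATURE_COLUMNS:
        ok = base_ok
        if rhythmic_only and col.startswith("phase_"):
            amp = outputs["amp_" + col.removeprefix("phase_")]
            ok = ok & (amp >= RHYTHMIC_THRESHOLD).all(axis=0)
        f = outputs[col][:, ok]
        fA, fB = f[0], f[1]
        var = total_variance(fA, fB)
        for i, pname in enumerate(design.spec.free_parameters):
            records.append({
                "parameter": pname, "output": col,
                "single": single_index(fA, fB, f[2 + i], var),
                "total": total_index(fA, f[2 + i], var),
                "N_effective": int(ok.sum()),
            })
    df = pd.DataFrame.from_records(records)
    df.attrs["n_dropped"] = int(N - base_ok.sum())
    return df


def run_sobol(variant: Variant = Variant.FULL, N: int = 4096,
              repeats: int = 3, seed: int = 0,
              spec: DistributionSpec | None = None,
              rhythmic_only: bool = False, n_steps: int = 500,
              chunk_size: int = 2048) -> pd.DataFrame:
    """Full Sobol table: mean and SD over independent repeats.

    Each repeat draws a fresh design from an independent substream of
    ``seed`` and evaluates N (k + 2) parameter sets. The production scale of
    the study is N = 100,000 with 10 repeats; the desk default (N = 4096,
    3 repeats) reproduces the headline rankings in minutes.

    Returns a tidy DataFrame with one row per (parameter, output):
    columns variant, parameter, output, single_mean, single_sd, total_mean,
    total_sd, N, repeats, n_dropped.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if spec is None:
        spec = global_spec(variant)
    elif spec.variant is not variant:
        raise ValueError("spec variant does not match requested variant")

    per_repeat = []
    n_dropped = 0
    for child in np.random.SeedSequence(seed).spawn(repeats):
        design = build_design(spec, N, child)
        rep = sobol_indices_one_repeat(design, rhythmic_only=rhythmic_only,
                                       n_steps=n_steps, chunk_size=chunk_size)
        n_dropped += rep.attrs["n_dropped"]
        per_repeat.append(rep)

    stacked = pd.concat(per_repeat)
    agg = (stacked.groupby(["parameter", "output"], sort=False)
           .agg(single_mean=("single", "mean"), single_sd=("single", "std"),
                total_mean=("total", "mean"), total_sd=("total", "std"))
           .reset_index())
    if repeats == 1:
        agg[["single_sd", "total_sd"]] = 0.0
    agg.insert(0, "variant", variant.value)
    agg["N"] = N
    agg["repeats"] = repeats
    agg["n_dropped"] = n_dropped
    return agg


def index_of(table: pd.DataFrame, parameter: str, output: str,
             which: str = "single") -> float:
    """Convenience lookup of one mean index from a :func:`run_sobol` table."""
    row = table[(table["parameter"] == parameter) & (table["output"] == output)]
    if row.empty:
        raise KeyError(f"no ({parameter}, {output}) entry in table")
    return float(row[f"{which}_mean"].iloc[0])


def phase_output(quantity) -> str:
    """Feature-column name of a quantity's peak phase (e.g. RATIO -> phase_ratio)."""
    return feature_columns(quantity)[2]
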