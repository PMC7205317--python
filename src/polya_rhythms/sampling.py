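"""Latin-hypercube sampling of model parameters.

The global parameter space follows the study's sampling table: the mean
transcription rate is fixed at 1 (it only rescales abundances), the mean
degradation rate is log-normal with log10(k/hr^-1) ~ N(-1.10, 0.23^2)
(fitted to genome-wide half-life data), the mean deadenylation and
polyadenylation rates are log-normal with log10(k/hr^-1) ~ N(-0.48, 0.23^2),
all relative amplitudes are U(0, 1) and all peak phases U(0, 24).

Scenario samplers replace selected phase marginals with narrow windows
(e.g. deadenylases peaking at ZT 2, 5 and 13) or an empirical-style wrapped
normal (nascent transcription centred at ~ZT 15), used by the
phase-clustering experiments.

All samplers are Latin-hypercube stratified: each 1-D marginal places
exactly one point per equal-probability stratum, which sharpens the Sobol
estimates relative to i.i.d. sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.stats import qmc

from .model import PARAM_NAMES, Variant

# ---------------------------------------------------------------------------
# marginals: each maps LHS uniforms in (0, 1) through its inverse CDF


@dataclass(frozen=True)
class Constant:
    value: float

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(u, dtype=float), self.value)


@dataclass(frozen=True)
class LogNormal10:
    """Rate whose log10 is normal: log10(k) ~ N(mu, sigma^2). Untruncated."""

    mu: float
    sigma: float

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return 10.0 ** stats.norm.ppf(u, loc=self.mu, scale=self.sigma)

    @property
    def median(self) -> float:
        return 10.0 ** self.mu


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"require lo < hi, got [{self.lo}, {self.hi})")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return self.lo + (self.hi - self.lo) * np.asarray(u, dtype=float)


@dataclass(frozen=True)
class PhaseWindows:
    """Equal-weight mixture of narrow uniform phase windows (mod 24).

    Window j covers [center_j - half_width, center_j + half_width); the
    mixture inverse CDF assigns u in [j/m, (j+1)/m) to window j, preserving
    Latin-hypercube stratification across windows.
    """

    centers: tuple[float, ...]
    half_width: float = 0.5

    def __post_init__(self) -> None:
        if not self.centers:
            raise ValueError("need at least one window center")
        if not 0.0 < self.half_width <= 12.0:
            raise ValueError("half_width must lie in (0, 12]")
        for c in self.centers:
            if not 0.0 <= c < 24.0:
                raise ValueError(f"window center {c} outside [0, 24)")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        m = len(self.centers)
        j = np.minimum((u * m).astype(int), m - 1)
        frac = u * m - j
        centers = np.asarray(self.centers)
        return (centers[j] - self.half_width + 2.0 * self.half_width * frac) % 24.0

    def contains(self, phase: np.ndarray) -> np.ndarray:
        """Membership of phases (mod 24) in any window."""
        phase = np.asarray(phase, dtype=float)[..., None]
        centers = np.asarray(self.centers)
        d = np.abs((phase - centers + 12.0) % 24.0 - 12.0)
        return (d <= self.half_width).any(axis=-1)


@dataclass(frozen=True)
class WrappedNormal:
    """Unimodal phase distribution wrapped onto [0, 24)."""

    center: float
    sd: float = 2.0

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return stats.norm.ppf(u, loc=self.center, scale=self.sd) % 24.0


# ---------------------------------------------------------------------------
# distribution spec and LHS driver


_FIXED_BY_VARIANT: dict[Variant, dict[str, float]] = {
    Variant.FULL: {"k_trsc": 1.0},
    Variant.NO_POLYA: {"k_trsc": 1.0, "k_polyA": 0.0, "A_polyA": 0.0,
                       "phi_polyA": 0.0},
    Variant.NO_TRSC_RHYTHM: {"k_trsc": 1.0, "A_trsc": 0.0, "phi_trsc": 0.0},
}


@dataclass(frozen=True)
class DistributionSpec:
    """Marginals of the free parameters for one model variant."""

    variant: Variant
    marginals: Mapping[str, object]

    def __post_init__(self) -> None:
        expected = set(self.variant.free_parameters)
        got = set(self.marginals)
        if expected != got:
            raise ValueError(
                f"marginals {sorted(got)} do not match the free parameters "
                f"{sorted(expected)} of variant {self.variant.value}")

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return self.variant.free_parameters

    @property
    def k(self) -> int:
        return self.variant.n_free

    def replace_marginal(self, name: str, marginal) -> "DistributionSpec":
        new = dict(self.marginals)
        if name not in new:
            raise KeyError(f"{name} is not a free parameter of {self.variant.value}")
        new[name] = marginal
        return DistributionSpec(self.variant, new)

    def from_uniform(self, u: np.ndarray) -> np.ndarray:
        """Map an (n, k) array of uniforms through the marginal inverse CDFs."""
        u = np.asarray(u, dtype=float)
        if u.ndim != 2 or u.shape[1] != self.k:
            raise ValueError(f"expected shape (n, {self.k})")
        out = np.empty_like(u)
        for j, name in enumerate(self.free_parameters):
            out[:, j] = self.marginals[name].ppf(u[:, j])
        return out

    def expand(self, free: np.ndarray) -> np.ndarray:
        """Embed an (n, k) free-parameter matrix into full (n, 12) vectors."""
        free = np.asarray(free, dtype=float)
        n = free.shape[0]
        theta = np.zeros((n, len(PARAM_NAMES)))
        fixed = _FIXED_BY_VARIANT[self.variant]
        for j, name in enumerate(PARAM_NAMES):
            if name in fixed:
                theta[:, j] = fixed[name]
            else:
                theta[:, j] = free[:, self.free_parameters.index(name)]
        return theta


def global_spec(variant: Variant = Variant.FULL) -> DistributionSpec:
    """The study's global sampling distributions for a given variant."""
    global_marginals = {
        "k_dgrd": LogNormal10(-1.10, 0.23),
        "k_deA": LogNormal10(-0.48, 0.23),
        "k_polyA": LogNormal10(-0.48, 0.23),
        "A_trsc": Uniform(0.0, 1.0), "A_dgrd": Uniform(0.0, 1.0),
        "A_deA": Uniform(0.0, 1.0), "A_polyA": Uniform(0.0, 1.0),
        "phi_trsc": Uniform(0.0, 24.0), "phi_dgrd": Uniform(0.0, 24.0),
        "phi_deA": Uniform(0.0, 24.0), "phi_polyA": Uniform(0.0, 24.0),
    }
    return DistributionSpec(
        variant, {name: global_marginals[name] for name in variant.free_parameters})


def sample_free(spec: DistributionSpec, n: int, seed) -> np.ndarray:
    """Latin-hypercube sample of the free parameters, shape (n, k)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = qmc.LatinHypercube(d=spec.k, seed=rng).random(n)
    return spec.from_uniform(u)


def sample_lhs(spec: DistributionSpec, n: int, seed) -> np.ndarray:
    """Latin-hypercube sample expanded to full (n, 12) parameter vectors."""
    return spec.expand(sample_free(spec, n, seed))


def params_to_frame(theta: np.ndarray):
    import pandas as pd

    return pd.DataFrame(np.asarray(theta, dtype=float), columns=list(PARAM_NAMES))


# ---------------------------------------------------------------------------
# phase-clustering scenarios


@dataclass(frozen=True)
class PhaseScenario:
    """One phase-structure experiment: which process peaks in narrow windows.

    ``windowed_process`` is None for the all-uniform control. ``extras``
    carries further phase-marginal overrides (the empirical scenario also
    pins polyadenylation and transcription).
    """

    scenario_id: str
    windowed_process: str | None
    window_centers: tuple[float, ...] = ()
    half_width: float = 0.5
    extras: Mapping[str, object] = field(default_factory=dict)

    def build_spec(self, base: DistributionSpec) -> DistributionSpec:
        spec = base
        if self.windowed_process is not None:
            spec = spec.replace_marginal(
                f"phi_{self.windowed_process}",
                PhaseWindows(self.window_centers, self.half_width))
        for name, marg in self.extras.items():
            spec = spec.replace_marginal(name, marg)
        return spec


def standard_scenarios(half_width: float = 0.5,
                       trsc_sd: float = 2.0) -> dict[str, PhaseScenario]:
    """The six phase-structure scenarios.

    (i)   all four phases uniform around the clock (control);
    (ii)  transcription in three narrow windows at ZT 0, 8, 16;
    (iii) degradation in three narrow windows at ZT 0, 8, 16;
    (iv)  deadenylation in three narrow windows at ZT 0, 8, 16;
    (v)   polyadenylation in three narrow windows at ZT 0, 8, 16;
    (vi)  empirical mouse-liver pattern: deadenylases at ZT 2, 5, 13,
          polyadenylation at ZT 3.5, transcription centred at ~ZT 15
          (wrapped normal), degradation uniform.
    """
    generic = (0.0, 8.0, 16.0)
    return {
        "i": PhaseScenario("i", None),
        "ii": PhaseScenario("ii", "trsc", generic, half_width),
        "iii": PhaseScenario("iii", "dgrd", generic, half_width),
        "iv": PhaseScenario("iv", "deA", generic, half_width),
        "v": PhaseScenario("v", "polyA", generic, half_width),
        "vi": PhaseScenario(
            "vi", "deA", (2.0, 5.0, 13.0), half_width,
            extras={"phi_polyA": PhaseWindows((3.5,), half_width),
                    "phi_trsc": WrappedNormal(15.0, trsc_sd)}),
    }


def sample_scenario(scenario: PhaseScenario | str, n: int, seed,
                    spec: DistributionSpec | None = None,
                    half_width: float = 0.5) -> np.ndarray:
    """Sample full parameter vectors under a phase scenario's rules."""
    if isinstance(scenario, str):
        catalog = standard_scenarios(half_width=half_width)
        if scenario not in catalog:
            raise KeyError(f"unknown scenario {scenario!r}; "
                           f"known: {sorted(catalog)}")
        scenario = catalog[scenario]
    base = spec if spec is not None else global_spec(Variant.FULL)
    return sample_lhs(scenario.build_spec(base), n, seed)
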