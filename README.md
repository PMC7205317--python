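# polya-rhythms

Modeling how rhythmic transcription, deadenylation, polyadenylation and
degradation jointly shape circadian rhythms in mRNA poly(A) tail length and
abundance.

Hundreds of mRNAs in mouse liver show ~24-h rhythms in poly(A) tail length,
and those rhythms track protein expression more closely than mRNA abundance
does. This package implements a parsimonious two-state model of that
system, plus the global analyses needed to ask *which* rhythmic process
controls the output rhythms when parameters vary over the whole
physiological range: Latin-hypercube parameter sweeps, rhythm feature
extraction, variance-based (Sobol) sensitivity analysis, phase-clustering
experiments and partitions of the rhythmicity classes observed in poly(A)
rhythmic (PAR) mRNAs.

## Model

The mRNA pool of one gene is split by poly(A) tail length into long-tailed
(`L`) and short-tailed (`S`) subpopulations:

```
dL/dt = κ_trsc(t) − κ_deA(t)·L + κ_polyA(t)·S
dS/dt = κ_deA(t)·L − κ_polyA(t)·S − κ_dgrd(t)·S
```

Transcription (with nuclear polyadenylation) produces long-tailed mRNA,
cytoplasmic deadenylation shortens tails (L→S), cytoplasmic polyadenylation
re-elongates them (S→L), and degradation consumes short-tailed mRNA only.
Each clock-driven rate is a sinusoid

```
κ(t) = k · (1 + A·cos(ω(t − φ))),   ω = 2π/24 h
```

with mean rate `k`, relative amplitude `A ∈ [0,1]` and peak phase
`φ ∈ [0,24)` h. Outputs are the peak phase, relative amplitude
`(max−min)/(2·mean)` and mean of total abundance `L+S`, the poly(A) length
metric `L/S`, and `L` (a proxy for translatability); a quantity is
*rhythmic* if its relative amplitude is ≥ 0.2.

Mean rates are sampled log-normally (`log10 k_dgrd ~ N(−1.10, 0.23²)`,
`log10 k_deA, k_polyA ~ N(−0.48, 0.23²)`, `k_trsc = 1` fixed), amplitudes
uniformly on [0,1] and phases uniformly on [0,24), by Latin hypercube.
Sobol single (`S_i`) and total (`S_Ti`) indices are estimated with the
two-matrix design (groups A, B and hybrids AB(i)), `N·(k+2)` model
evaluations per repeat with `k` = 11 free parameters (8 without
polyadenylation, 9 without rhythmic transcription).

Because the model is linear in `(L,S)` with periodic coefficients, batch
simulation computes the entrained orbit exactly from a one-period monodromy
pass (~2,000 parameter sets/s on one core), cross-validated in the test
suite against adaptive Runge–Kutta integration through a 700-h transient.

## Worked example

```python
from polya_rhythms import Variant, sample_lhs, global_spec
from polya_rhythms.batch import sweep_features
from polya_rhythms.experiments import phase_lag_analysis
from polya_rhythms.features import Quantity

theta = sample_lhs(global_spec(Variant.FULL), 10_000, seed=1)
sweep = sweep_features(theta)
lag = phase_lag_analysis(sweep, "deA", Quantity.RATIO)
print(f"deA -> L/S offset {lag.lag_magnitude:.2f} h "
      f"(SD {lag.circ_std:.2f} h, n={lag.n})")
```

prints

```
deA -> L/S offset 10.55 h (SD 2.92 h, n=9215)
```

i.e. across 10,000 random parameter sets, 9,215 have a rhythmic poly(A)
length metric, and its peak phase sits 10.6 h (circular offset, tight band)
from the deadenylation peak — the L/S ratio crests shortly after
deadenylation activity bottoms out, almost regardless of the other ten
parameters. The numbered scripts under `analysis/` run the full set of
analyses and write their tables to `results/`:

```
python analysis/01_global_sweep_phase_lags.py   # phase lags per process
python analysis/02_sobol_sensitivity.py         # Sobol indices, both variants
python analysis/03_phase_clustering.py          # scenarios (i)-(vi)
python analysis/04_class_partitions.py          # PAR classes I/II and III/IV
python analysis/05_correlation_comparison.py    # Pearson/Spearman vs Sobol
```

Headline numbers from those runs: the deadenylation peak phase alone
explains ~35–40% of the variance in the L/S peak phase (single Sobol
index; ~75–78% total once interactions are counted, with run-to-run spread
of a few points at desk scale); narrow deadenylase phase windows cluster
the output phases
(capture fraction 0.66–0.75 within ±1.5 h of the predicted centers against
a 0.375 uniform baseline) while windows on any other process do not; and
Class II parameter sets have ~2× slower median degradation than Class I.

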