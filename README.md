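# quadstruct

Analysis tools for the DNA G-quadruplexes (GQs) formed by the `(G4C2)n`
hexanucleotide repeat of *C9orf72*, the most common genetic cause of
ALS/FTD. The repeat's G-rich strand folds into four-stranded structures of
stacked guanine tetrads — planar quartets held together by cyclic Hoogsteen
hydrogen bonds (N1–H···O6 and N2–H···N7) and stabilized by K⁺ ions between
tetrad planes. The package covers the standard desk-side workflow around
these structures:

- **CD spectroscopy** (`quadstruct.cd`): Savitzky–Golay smoothing, topology
  calls from the diagnostic bands (antiparallel GQ-AP: +295/−260 nm;
  parallel GQ-P: +260/−240 nm), and constrained two-component unmixing

  $$S(\lambda) = x\,\mathrm{AP}(\lambda) + y\,\mathrm{P}(\lambda),
  \qquad x + y = 1,$$

  solved in closed form by least squares
  ($x^\* = \sum(S-P)(AP-P) \,/\, \sum(AP-P)^2$).
- **Thermal melts** (`quadstruct.melt`): four-parameter Boltzmann sigmoid
  fits to 295 nm melt curves,
  $S(T) = \mathrm{lo} + (\mathrm{up}-\mathrm{lo})/(1+e^{(T-T_m)/w})$,
  with replicate averaging and an unpaired two-tailed *t*-test on $T_m$ sets.
- **Sequences** (`quadstruct.sequences`): repeat-notation expansion
  (`(GGGGCC)3GGGG` → the 22-mer), CpG-site detection, 5-methylcytosine
  flagging with FASTA + JSON-sidecar serialization.
- **Structural models** (`quadstruct.structure`): PDB read/write, residue
  deletion/mutation, 3′ extension, strand fusion with junction-gap reports,
  5mC methyl placement (DC → 5CM), Hoogsteen tetrad detection, inter-tetrad
  K⁺ placement, an idealized GQ builder for any 4-tract repeat, and clash
  counting (models are deliberately not energy-minimized).
- **Trajectories** (`quadstruct.traj`): multi-model PDB trajectories,
  Kabsch superposition, per-residue RMSD/RMSF, and per-tetrad buckle
  displacement (mean unsigned base-plane/tetrad-plane angle) with
  quartile summaries.
- **Synthetic data** (`quadstruct.synth`): seeded generators for basis
  spectra, crowding titrations, melt curves and rigid-tetrad/mobile-loop
  toy trajectories — every generator parameter doubles as ground truth for
  parameter-recovery tests.

The two fitting tasks follow the statsmodels convention: build a model from
data, call `fit()`, get a results object with estimates, uncertainties and
`summary()` (`SpectralDecomposition(...).fit()`, `MeltCurveModel(...).fit()`).

## Worked example

```python
import numpy as np
from quadstruct import *

# a PEG-crowding titration: AP fraction decreasing 1.0 -> 0.05
basis = gen_basis_spectra()
series = gen_titration_series(basis, [1.0, 0.6, 0.3, 0.05], noise_sd=0.02,
                              seed=7, conditions=["0% PEG", "10% PEG",
                                                  "20% PEG", "30% PEG"])
print(titration_fractions(series, basis).to_string(index=False))

# melt-curve Tm for the methylated 22-mer world (generator midpoint 84.3 C)
curves = gen_melt_curve(84.3, width=2.0, noise_sd=0.0095, seed=21, n_reps=3)
print(fit_melt_curve(average_replicates(curves)).summary())

# idealized antiparallel quadruplex + toy trajectory
gq = build_ideal_gq(c9_22mer())
traj = gen_gq_trajectory(gq, sigma_tetrad=0.2, sigma_loop=1.0,
                         n_frames=200, seed=5)
print(analyze_trajectory(traj).summary())
```

prints

```
condition        x        y  residual_ss
   0% PEG 0.998677 0.001323     0.031768
  10% PEG 0.599608 0.400392     0.031298
  20% PEG 0.301784 0.698216     0.041815
  30% PEG 0.047720 0.952280     0.033107

Boltzmann melt fit  S(T) = lo + (up - lo)/(1 + exp((T - Tm)/w))
----------------------------------------------------------------
n points                 131
Tm (deg C)             84.32  (se 0.0252)
width (deg C)          2.012
...

Trajectory stability statistics
------------------------------------------------
residues                22
tetrads                  4
mean RMSD (A)        0.993
mean RMSF (A)        0.722
tetrad 0 buckle  mean 4.12 deg  [Q1 3.26, med 4.08, Q3 4.88]
...
```

The titration `x` column recovers the generator's AP fractions within the
noise; the fitted `Tm` lands on the generator midpoint to ±0.05 °C; and the
trajectory summary shows what the generator built in: near-planar tetrads
(buckle a few degrees at σ_tetrad = 0.2 Å) and loop cytosines about five
times as mobile as tetrad guanines.

A `quadstruct` console script exposes the same stages
(`simulate {spectra|melt|trajectory}`, `decompose`, `classify`, `melt-fit`,
`build-gq`, `methylate-pdb`, `tetrads`, `traj-stats`); every run writes a
JSON provenance record alongside its outputs.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates, from scratch with the given seed, the package's headline
quantities: the fitted melting temperatures for synthetic 295 nm melt
curves generated at the methylated and nonmethylated 22-mer midpoints
(n = 3 replicates, 1 % noise, averaged before fitting), and the coefficient
sum x + y returned by the constrained spectral decomposition of a noisy
0.4·AP + 0.6·P mixture. The JSON report maps each target id to the computed
value and the problem size used.
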