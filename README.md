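# dnasensor

Machine-learning-guided directed evolution of serotonin-responsive
ssDNA-SWCNT nanosensors, in silico.

Single-walled carbon nanotubes (SWCNTs) wrapped in single-stranded DNA emit
near-infrared fluorescence whose intensity shifts when an analyte adsorbs at
the corona; the ssDNA sequence determines both the sensitivity of that shift
and its selectivity between structurally similar neurotransmitters such as
serotonin (5HT) and dopamine (DA). Finding better sequences by brute-force
assay is impractical — a single round of 3-base substitutions on a 30-mer
already yields 22,032 candidates — so the screen is run as *directed
evolution with a machine-learned surrogate*: enumerate the full mutant
library, rank it with an ensemble predictor, measure only the top 20, and
promote the winner as the next round's parent.

This package implements that whole loop as a tested library plus CLI, with a
calibrated synthetic sequence→response landscape standing in for the wet-lab
assay. It is aimed at people studying ML-guided sequence optimisation
protocols (selection logic, surrogate quality, stopping rules) rather than at
predicting real nanotube photophysics.

## What is implemented

- **Sequence model** — validated 30-mers with fixed (C)₆ flanks and an 18-nt
  variable region; exhaustive exact-*k* substitution libraries
  (`C(18,k)·3^k` members, 22,032 for *k* = 3); mutation diffs; FASTA I/O.
- **Synthetic landscape** — additive position–base weights with optional
  sparse pairwise epistasis, calibrated so the original sensor reproduces
  its published operating point: ΔF/F₀ = 0.949 for serotonin and a 5HT/DA
  selectivity of 0.508. Simulated nIR spectra (950–1350 nm, readout peak at
  1202 nm), Hill-shaped concentration dependence, multiplicative triplicate
  noise.
- **Surrogate ensemble** (`ResponseEnsemble`, a scikit-learn estimator) —
  two support-vector regressors (RBF and sigmoid kernels) on a 72-bit
  one-hot encoding give min/mean/max predicted ΔF/F₀ (`mean_r`), and nine
  small neural-network classifiers vote on "high response"; top-20 selection
  keeps only candidates the classifier majority confirms.
- **Response analysis** — ΔF/F₀ = (F − F₀)/F₀ at the readout wavelength,
  replicate summaries, 5HT/DA selectivity ratio, multi-analyte panel
  (5HT, DA, Ach, GABA, Glu, UA, AA; 100 µM except 10 µM uric acid).
- **Dose–response** (`HillCurveFit`, a scikit-learn estimator) — bounded
  nonlinear least-squares fit of the Hill isotherm
  ΔF/F₀(c) = (ΔF/F₀)ₘₐₓ · cⁿ / (K_dⁿ + cⁿ)
  recovering the dissociation constant K_d, cooperativity n and maximal
  response.
- **Evolution driver** — multi-round enumerate → screen → measure → select
  orchestration for sensitivity and selectivity objectives, with Welch
  t-test saturation detection and full seed-level reproducibility.

## Worked example

```python
import numpy as np
import dnasensor as d
from dnasensor.hill import PROTOCOL_CONCENTRATIONS_UM

orig = d.validate_sequence(d.KNOWN_SENSORS["original"], "original")
land = d.Landscape(seed=1)                      # calibrated synthetic assay
cfg = d.RoundConfig(objective="sensitivity", surrogate="ensemble",
                    seed=1, n_train=500)
trace = d.run_evolution(orig, land, 3, cfg=cfg, noise=d.NoiseModel(seed=1))
print(trace.to_frame().to_string(index=False))

best = trace.rounds[-1].best_sequence
conc = np.array(PROTOCOL_CONCENTRATIONS_UM)
fit = d.fit_hill(conc, [land.response_at(best, "5HT", c) for c in conc])
print(f"Kd={fit.Kd_:.2f} uM  n={fit.n_:.3f}  max={fit.dff0_max_:.3f}")
```

prints

```
 round                         parent                       best_seq  best_stat  parent_stat  p_saturation
     1 CCCCCCAGCCCTTCACCACCAACTCCCCCC CCCCCCAGCCCTTCCGCACCAACGCCCCCC   1.783085     0.795060           NaN
     2 CCCCCCAGCCCTTCCGCACCAACGCCCCCC CCCCCCAACCCTTGCGCACAAACGCCCCCC   2.428806     1.783085      0.000702
     3 CCCCCCAACCCTTGCGCACAAACGCCCCCC CCCCCCAATTCTTGCGCACAAATGCCCCCC   2.817892     2.428806      0.046470
Kd=6.80 uM  n=1.000  max=2.835
```

Reading it: each round the winner's measured serotonin ΔF/F₀ at 100 µM
(`best_stat`) improves on its parent (`parent_stat`); the Welch-test p-value
between consecutive winners (`p_saturation`) creeps toward 0.05, signalling
the campaign is approaching saturation; the final winner's dose–response
curve fits a Hill isotherm with K_d ≈ 6.8 µM (half-saturation concentration)
and no cooperativity (n ≈ 1).

The same pipeline is available from the shell:

```sh
dnasensor enumerate --parent original --k 3 --out library.fasta
dnasensor evolve --objective sensitivity --rounds 3 --seed 1
dnasensor panel --sensor L1-14 --out panel.csv
```

## Scope

The package deliberately does not model nanotube photophysics (exciton
quenching, solvatochromic shifts, chirality assignment), wet-lab fabrication
or surface-immobilised single-sensor microscopy, and it makes no claim to
reproduce any previously trained surrogate's weights — the surrogates here
are trained on the synthetic landscape. See `docs/methods.md` for the model,
its assumptions and its limitations.
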