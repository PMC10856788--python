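# Methods

## The screening procedure

One round of directed evolution is: (1) enumerate every sequence at exact
variable-region Hamming distance 3 from the parent — each of the C(18,3)
position triples substituted to each of the 3 non-parental bases, 22,032
candidates, always exhaustive, never sampled; (2) rank the library with a
surrogate ensemble and keep the top 20 by mean predicted ΔF/F₀ that the
classifier majority also calls "high response"; (3) measure those 20 in
simulated triplicate at the protocol concentration; (4) promote the
candidate with the best objective statistic (mean serotonin ΔF/F₀, or the
5HT/DA ratio of triplicate means for the selectivity objective). Rounds are
chained for a fixed count, with a two-sided Welch t-test between consecutive
winners' replicates reported as a saturation diagnostic (and optionally used
to stop early; off by default, matching the fixed-round protocol the package
emulates).

A note on the mutation rule: substituting "to one of A, C, G, T" would allow
null substitutions and give a different library size; only the
exactly-3-changes rule yields 22,032 = C(18,3)·3³, so that rule is
implemented. Positions are reported 1-based within the 18-nt variable
region (full-sequence offset +6), which makes the known selectivity winner
L1-14 a {4, 7, 11} → A triple relative to the original sensor.

## The synthetic landscape (what the generator emulates)

The wet-lab assay is replaced by a ground-truth map
`true_response(sequence, analyte)` — the *saturating* ΔF/F₀ of that
sensor/analyte pair:

    true_response = Σᵢ w_a(i, baseᵢ) + Σ_pairs ε + offset_a,  floored at −1

- `w_a` is an 18×4 position–base weight table per analyte, drawn
  N(0, 0.15²) for the high-response analytes (5HT, DA, AA) and N(0, 0.02²)
  for the low-response panel members (Ach, GABA, Glu, UA). The largely
  additive default reflects the empirical pattern that recurrent single-base
  changes (mostly to adenine) drive improvement; `epistasis_density`
  optionally adds sparse pairwise interaction terms for harder test
  landscapes.
- The floor at −1 encodes that fluorescence cannot drop below zero
  intensity.
- **Calibration**: per-analyte offsets are solved so the anchors hold
  exactly — the original sensor's serotonin response is 0.949 and its
  5HT/DA selectivity 0.508 (equivalently a dopamine response of
  0.949/0.508). Calibration is idempotent and contradictory anchors raise.

Concentration dependence is a Hill isotherm with n = 1: a measurement at
concentration c reads `true_response · c/(K_d + c)`. Each (sequence,
analyte) pair gets a deterministic log-normal K_d around a 10 µM median
(log-sd 0.3), the regime reported across the sensor lineage; the original
sensor's serotonin K_d is pinned at its published 11.6 µM. Note the
consequence: a 100 µM panel reading of the original sensor is
0.949·(100/111.6) ≈ 0.85, not 0.949 — the anchor pins the saturating
response, and finite-concentration readings are attenuated by the Hill
fraction.

Simulated spectra put four Gaussian peaks at 1000/1130/1202/1270 nm
(widths 10/9/8/9 nm) on a 950–1350 nm, 1-nm grid; only the 1202-nm readout
peak responds to analyte, scaled by `1 + true_response · hill_fraction`.
The widths are kept narrow enough that neighbouring-peak tails at 1202 nm
are numerically negligible, so ΔF/F₀ computed from two spectra agrees with
the direct model value to better than 1e-9. Replicate noise is
multiplicative Gaussian, 5% relative sd, triplicates — the assay protocol
reports triplicate means but no replicate variance, so the 5% figure is this
package's choice, set so that consecutive-round winners separated by ~2% are
usually *not* statistically separable (the saturation behaviour the
procedure is meant to exhibit). Replicate RNG streams are derived from the
noise seed plus the measurement identity (sequence, analyte,
concentration), making panels order-invariant and whole runs byte-for-byte
reproducible under a fixed seed set.

What the generator does **not** emulate: real nanotube photophysics
(quenching mechanisms, solvatochromic shifts, chirality heterogeneity),
sensor-to-sensor fabrication variability, drift, or any guarantee that the
real sequence–response map is near-additive. Passing tests therefore
validate the *screening machinery* — enumeration, ranking, selection,
fitting, stopping — not predictions about physical sensors.

## The surrogate ensemble

Sequences are encoded as 72-bit one-hot vectors (18 variable positions × 4
bases; the constant flanks carry no information). Two support-vector
regressors — RBF kernel (γ = "scale") and sigmoid kernel (γ = 1/72, chosen
in the near-linear tanh regime so the kernel stays monotone on one-hot
inner products) — are averaged into the ranking indicator `mean_r`, with
their min/max reported alongside. Nine MLP classifiers (hidden widths
cycling 8/16/32, distinct seeds) are trained on the binary label
ΔF/F₀ ≥ top-quartile-of-training-labels; a candidate is eligible for
selection only if a majority (≥5 of 9) vote "high". The quartile threshold
and majority rule are this package's choices where the emulated protocol
states only that top-ranked sequences were "also classified as high
response". Ties in `mean_r` break lexicographically by sequence so
selection is deterministic and permutation-invariant.

By default a fresh ensemble is trained each round on a seeded 500-sequence
sample of the round's own library, labelled with simulated triplicate-mean
measurements; a pre-fitted model can be passed instead to mimic a
frozen-surrogate regime. On the default additive landscape the held-out
Spearman correlation between `mean_r` and the true response exceeds 0.99,
so the ensemble route and the exact-oracle route (surrogate replaced by the
landscape itself) give closely agreeing campaigns; the oracle route is used
in tests to verify the selection logic independently of surrogate error.

## Hill fitting

`HillCurveFit` minimises squared residuals of
ΔF/F₀(c) = max · cⁿ/(K_dⁿ + cⁿ) with `scipy.optimize.least_squares`
(trust-region reflective), bounds K_d ∈ [1e-6, 1e4] µM, n ∈ [1e-3, 10],
max ≥ 0, tolerances 1e-12. Initialisation: K_d at the concentration whose
response is nearest half-max, n = 1, max at the largest observed response.
Fitting optionally runs in log-K_d space; on well-conditioned data both
parameterisations reach the same optimum (tested). Convergence is reported
honestly via `converged_`, never assumed. A `variant="literal"` flag
evaluates the alternate typeset denominator `K_d + cⁿ`; the standard form
is the default because it is dimensionally consistent and the two coincide
at n = 1, the regime of every fit the package reproduces. Normalising a
curve by its maximum rescales only the fitted maximum, not K_d or n
(tested).

## Statistics and numerical conventions

- ΔF/F₀ readout: nearest-grid-sample intensity at the configured readout
  wavelength (default 1202 nm), not a local peak fit, which would introduce
  unstated free parameters.
- Baseline F₀ is the DI-water control spectrum; F₀ ≤ 0 raises.
- Replicate summaries: arithmetic mean and sample (n−1) standard deviation;
  sd = 0 for a single replicate.
- Selectivity: ratio of ΔF/F₀ values; the selectivity objective uses the
  ratio of triplicate means (not the mean of ratios). A zero dopamine
  response raises rather than returning ±∞.
- Saturation: Welch two-sample t-test (unequal variances), two-sided,
  α = 0.05 — the minimal-assumption standard for n = 3 comparisons.
- Uric acid is panel-tested at 10 µM (solubility-limited stock), all other
  analytes at 100 µM.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at the sizes the procedure
itself defines: the full 22,032-member library for enumeration, screening
and oracle-equivalence checks; 500 training / 200 held-out sequences for
surrogate quality; 3 evolution rounds; 500 Monte-Carlo fits for noisy K_d
recovery; the seven protocol concentrations (0.1, 1, 5, 10, 30, 70,
100 µM) for every dose–response computation. A handful of Monte-Carlo
checks (replicate unbiasedness, saturation behaviour) use 1,000–10,000
draws, comfortable desk-scale sizes with stable verdicts.

## Known limitations

- All wet-lab magnitudes beyond the calibration anchors (e.g. the evolved
  winners' ΔF/F₀ values) emerge from the synthetic landscape and will not
  numerically match any particular laboratory campaign.
- The landscape's K_d jitter makes measured rankings at 100 µM differ
  slightly from saturating-response rankings; with heavy noise and a flat
  landscape the greedy guarantee holds only in distribution.
- The classifier committee is a stand-in architecture family; no claim is
  made about convolutional architectures or any previously trained model's
  behaviour.
- Insertions, deletions, length changes and non-ACGT chemistries are out of
  scope by design.
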