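# Methods

This note records the models implemented in `ringfit`, the assumptions
behind them, the defaults that matter, and the choices made where the
design was genuinely open.

## Binding model and depletion solve

The core model is a two-site sequential binding isotherm read out by
tryptophan quenching. Writing `D_f` for free ligand (nucleotide
concentration units) the observed quenching is

    TQ(D_f) = (TQ1·K1·D_f + TQ2·K1·K2·D_f²) / (1 + K1·D_f + K1·K2·D_f²)

and total ligand obeys

    D = D_f + P·(K1·D_f + 2·K1·K2·D_f²) / (1 + K1·D_f + K1·K2·D_f²).

Assumptions: two sequential phases on a homogeneous ssDNA lattice; the
ring concentration `P` (default 50 nM, decamer units) is constant during
the titration (total dilution is capped at 5%); no overlap/lattice
statistics (no McGhee–von Hippel treatment — the phases are treated as
two macroscopic binding events). A naming caveat is deliberate: the
phase constants are conventionally called dissociation constants, but in
the expression above they multiply `D_f`, i.e. they act on the
association scale. The package stores them exactly as used and does not
invert them.

The conservation equation's left-hand side is strictly increasing in
`D_f`, so the root in `[0, D]` is unique. The scalar API
(`solve_free_ligand`) uses Brent's method at 1e-10 relative tolerance
and errors loudly on non-convergence; the vectorized path inside
`predict_titration` uses 64 bracketed bisection halvings, and the two
agree to 1e-8 against a 200-step bisection oracle in the tests.

Fitting (`fit_two_site`) is bounded weighted least squares over
`(TQ1, TQ2, K1, K2)` via trust-region reflective, multi-started from
five log-spaced scalings of the initial phase constants (they span
orders of magnitude and the objective has local minima); best RSS wins,
deterministically. Standard errors are asymptotic, from the Jacobian at
the optimum. Parameters can be frozen by name; freezing `TQ2 = K2 = 0`
reduces the model exactly to a one-site depletion isotherm (the
truncated-construct case).

Identifiability caveat: when binding is effectively stoichiometric
(very large `K1·D`), only lower bounds on the phase constants are
recoverable from a titration; the site sizes below are then the robust
quantities. The fit-recovery tests therefore use a moderate-affinity
truth and a geometric ligand schedule that samples the rising phase.

## Occluded site sizes by segmented regression

Site sizes are estimated from the titration curve's geometry, not from
the isotherm fit: continuous piecewise-linear models with 0, 1 or 2
freely placed breakpoints are fitted by exhaustive coarse grid search
over breakpoint positions, a fine grid at 0.5 nt, and Nelder–Mead
polish; for fixed breakpoints the model is linear and solved by OLS.
Breakpoints are reported as cumulative site sizes (the second
breakpoint is the total nucleotides per ring at second saturation).
Both estimators (segmented regression and the isotherm fit) are
provided because the mapping from a fitted isotherm to the printed site
sizes is not uniquely defined; segmented regression is the canonical
one here.

Model count is selected by BIC with each breakpoint charged 8 effective
degrees of freedom (`k = 2 + m + 8m`). Naive BIC (one parameter per
knot) is optimistic for change-point problems — a scanned knot position
extracts far more fit from noise than a regular parameter — and in
simulation it invented corners in monophasic data. With the inflated
penalty, selection was correct in 40/40 seeds for straight-line,
monophasic and biphasic data at both 20 and 30 points. RSS values below
`n·(1e-5·scale)²` are floored so that models fitting noiseless data
exactly tie and the simpler one wins. Candidates leaving fewer than 3
points in any segment are excluded.

Breakpoint standard errors come from a residual bootstrap (default 200
resamples, seed 1): residuals are resampled onto the fitted curve and
breakpoints re-optimized locally with the count fixed. Pair resampling
is avoided because it can empty a segment.

## Signal corrections

* Fluorescence: `F_corr = F_raw·(V/V0)·(1/C)·(f0/f)` per step — dilution,
  inner filter (`C`, default 1, valid when OD ≪ 0.1), photobleaching
  (reference sample `f`). Per-point SEMs propagate through the same
  linear factor (first-order propagation).
* Anisotropy: quantum-yield correction
  `A_c = (r·A_b + A_f)/(1+r)` with `r = ((A−A_f)/(A_b−A))·(Q_f/Q_b)`;
  reduces to the identity when the yields are equal. The bound fraction
  `r/(1+r)` is an interpretation layered on the same algebra and is
  labeled as such. Points outside `[A_f, A_b]` by more than 2% of the
  span are flagged, never silently clipped (the 2% is a package choice).
* Ensemble FRET: `E = I_A/(I_A+I_D)` on background-subtracted spectra,
  deliberately without crosstalk terms — ensemble spectra are used for
  relative changes only. Single-molecule traces do get the corrections
  (below).
* Quenching: `|ΔF|/F0`.

## Mass photometry

Calibration is an ordinary least-squares contrast→mass line through ≥2
standards. Mixture deconvolution runs EM on raw event masses:
initialization by deterministic 1-D k-means (Lloyd's algorithm seeded
uniformly across the data range — quantile seeding piles every seed into
the 85% component), convergence at 1e-8 relative log-likelihood change
or 500 iterations, collapse (component sd < 1 kDa on calibrated data, or
a scale-relative floor on raw contrasts) triggering up to 5 jittered
restarts. The literal sum-of-Gaussians histogram fit (5 kDa bins) is
provided as the secondary route; EM is canonical because binning loses
information. Reported fractions are event fractions (mixture weights),
not amplitude ratios — the distinction is ambiguous in most published
legends and is made explicit here.

Stoichiometry calls round `species/monomer` to the nearest integer with
exact halves rounding up. Note the published ring and monomer masses
put the ratio at 9.51, half a subunit from the rounding boundary; calls
on fitted means can therefore dither by one subunit, which is why the
residual fraction is always reported alongside. Events below the
~50 kDa instrument sensitivity floor are flagged, and optionally
excluded, but never dropped silently.

## HDX-MS

Differential uptake is apo minus bound per matched peptide/timepoint
(positive = protected by ligand), SEMs combined in quadrature, summed
over the time course, and classified protected/deprotected when the
delta exceeds 0.5 Da at ≥2 timepoints — a field convention, not a
published threshold; both knobs are exposed. No back-exchange
correction is applied (uptake is compared, not absolute). Exchangeable
amides per peptide are `length − 1 − prolines after the first residue`.
Per-residue maps average the summed deltas of covering peptides and are
invariant to input order.

Bimodal deconvolution fits 1- and 2-Gaussian models to the binned
centroid-intensity distribution by weighted least squares with
Poisson-like weights (per-bin variance proportional to intensity), so
the weighted RSS is a chi-square and model count is selected by
known-variance BIC (`wrss + k·ln n`), with the second component's
searched location charged 2 extra degrees of freedom — the same
optimism correction as the breakpoint search. In simulation the
spurious chi-square gain on unimodal data never exceeded ~13 while true
bimodal structure (30/70 split, 3 Da separation) gained ≥264, so the
margin is wide. `f1` is the area fraction of the low-mean component.
Fits whose modes are closer than half the pooled width are flagged
unidentifiable. An equal-widths constraint is optional.

## smFRET

Per-frame efficiency is `(I_A − α·I_D − δ·I_ref) / ((I_A − α·I_D −
δ·I_ref) + I_D)` with donor-leakage fraction α and direct-acceptor-
excitation fraction δ; δ requires an acceptor-only reference level and
is forced to 0 (and logged) without one. Traces whose corrected
acceptor goes negative on >10% of frames are flagged. Photobleaching
truncation cuts at the last frame before total intensity falls below
25% of its median (package choice; the threshold is exposed).

Segmentation is a Gaussian-emission hidden Markov model fitted by EM
with Viterbi decoding — a deliberate substitution of maximum-likelihood
EM + BIC for variational-Bayes tools, keeping the same output contract
(state means, occupancies, dwell tables). Determinism: emission means
initialize at 1-D k-means centers of the pooled efficiencies, sticky
uniform transitions (0.9 diagonal), fixed random state. The state count
is fixed by the caller or swept 1–4 by BIC. Frame time defaults to
150 ms. Dwell tables are run-length encodings of the Viterbi paths, so
per-trace dwell totals equal trace lengths exactly.

## Synthetic data

Generators use numpy's PCG64 (`default_rng`) seeded explicitly: a fixed
seed is bit-reproducible across runs and platforms, and every generator
returns its latent truth alongside the observations. Conditions they
emulate, and the defaults:

* **Titrations** — latent quenching is piecewise linear through the
  occluded-site corners (the stoichiometric, tight-binding regime;
  biphasic default corners 56 and 158 nt/ring, monophasic 55), or a
  smooth isotherm from a supplied binding model. Plateau amplitudes
  (0.45, 0.75) are typical Trp-quenching magnitudes, not published
  values. The clean curve is contaminated in reverse order of the
  correction algebra: dilution 0.0015/step and photobleaching
  0.002/scan (chosen to keep total dilution <5% over 30 steps), then 2%
  multiplicative Gaussian read noise (per-point noise magnitudes are
  not published for any of these assays; 2% is a package choice
  matching scale-proportional photon noise). Ligand is tracked in
  nucleotides only — poly(dT) (~1.1 knt) is treated as an effectively
  infinite homogeneous lattice. Schedules: linear (default) or
  geometric (dense early points for tight phases).
* **Landing events** — three-component Gaussian mixture at
  72.9/498.4/991.8 kDa (sds 13.9/23.8/75.34) with weights
  0.05/0.85/0.10; labels retained.
* **Bimodal uptake** — two Gaussian populations 3 Da apart (8 and 11 Da,
  widths 0.6 Da — separation is a study condition, absolute centroids
  are package choices), low-uptake fraction 0.30, 1,000 ions binned at
  0.25 Da.
* **FRET traces** — up to four states; default means (0.2, 0.4, 0.6,
  0.8), of which only the dominant 0.2 state is a published value, the
  rest are qualitative; occupancies (0.70, 0.15, 0.10, 0.05). The
  hidden chain is an independence sampler whose stationary distribution
  is exactly the requested occupancies; dwells are geometric
  (discrete-frame memoryless — no dwell model is published), with the
  dominant state's mean dwell set to 20 frames and rarer states
  correspondingly shorter. Emissions add 30-count Gaussian camera noise
  on a 1,000-count total intensity at 150 ms frames; frames whose noisy
  total would be non-positive are redrawn, never emitted.

What the generators do **not** emulate: raw movies or spectra,
instrument drift, baseline wander, correlated noise, photophysics
(blinking, spectral fluctuations), heterogeneous labeling, or peptide
identification errors. Passing recovery tests therefore demonstrates
estimator correctness under the stated statistical structure, not
robustness to every artifact of real instruments.

## Problem sizes

The test suite and the acceptance script use the study-scale designs
throughout: 30-point titrations (20 replicates), 5,000 landing events,
1,000-ion uptake distributions (10 replicates), and 20 traces × 300
frames for smFRET; these match the data volumes the assays actually
produce (a 60 s mass-photometry recording lands ~5,000 particles; a
5-minute movie at 150 ms yields ~2,000 frames per molecule).

## Known limitations

* The isotherm fit cannot pin phase constants in the stoichiometric
  regime (only lower bounds are identified); site sizes are the robust
  output there.
* Segmented regression assumes sharp saturation corners; strongly
  curved transitions bias breakpoints inward.
* The HMM assumes Gaussian emissions and memoryless dwells; real traces
  with blinking or non-exponential dwells will leak between states.
* The bimodal deconvolution assumes exactly one or two Gaussian
  populations per spectrum and a common population structure across
  charge states.
* No global fitting across ssDNA lengths or constructs.
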