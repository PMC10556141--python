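# ringfit

Quantitative analysis of how an oligomeric protein ring binds and wraps
single-stranded DNA, built around the assays used to characterize the
yeast Rad52 homodecamer: tryptophan-quenching and anisotropy titrations,
mass photometry, hydrogen–deuterium exchange mass spectrometry (HDX-MS),
and single-molecule FRET. It is aimed at biophysicists who have tabular
instrument exports (or want realistic synthetic stand-ins) and need the
downstream numbers: occluded site sizes, binding-phase constants,
oligomer stoichiometries, conformational population fractions, and
wrapping-state occupancies.

## What it computes

**Two-site sequential binding with ligand depletion.** Quenching of
intrinsic Trp fluorescence reports ssDNA binding in two sequential
phases:

    TQ(D_f) = (TQ1·K1·D_f + TQ2·K1·K2·D_f²) / (1 + K1·D_f + K1·K2·D_f²)

with free ligand D_f obtained from mass conservation (binding is tight,
so free ≠ total):

    D = D_f + P · (K1·D_f + 2·K1·K2·D_f²) / (1 + K1·D_f + K1·K2·D_f²)

solved by bracketed root-finding per titration point. `TQ1`, `TQ2` are
the phase quenching amplitudes, `K1`, `K2` the macroscopic phase
constants, and `P` the ring (decamer) concentration, held at its nominal
value (50 nM) because dilution stays under 5%.

**Occluded site sizes.** In the stoichiometric regime the titration is
piecewise linear in nucleotides added per ring; the saturation corners
are the occluded site sizes. `estimate_site_sizes` fits continuous
segmented regressions with 0–2 freely placed breakpoints, selects the
count by BIC (with an inflated per-breakpoint penalty — a freely
searched knot buys far more fit than one nominal parameter), and reports
cumulative site sizes with bootstrap standard errors.

**Mass photometry.** Linear contrast→mass calibration from standards,
Gaussian-mixture deconvolution of landing-event masses by EM (plus the
literal sum-of-Gaussians histogram fit), and nearest-integer
stoichiometry calls.

**HDX-MS.** Per-peptide differential uptake between apo and DNA-bound
states, and two-population deconvolution of bimodal centroid-intensity
distributions (EX1-like behavior) quantifying the intensity fraction of
the protected population.

**smFRET.** Crosstalk/cross-excitation-corrected per-frame efficiencies,
Gaussian-emission hidden-Markov segmentation (EM + Viterbi, BIC sweep
over 1–4 states), dwell-time tables and pooled histograms.

Every assay has a synthetic-data generator (`ringfit.synthgen`) that
returns observations **and** the latent truth, so each estimator is
testable end to end without instrument data.

## Worked example

```python
import numpy as np
from ringfit import synthgen
from ringfit.binding import estimate_site_sizes, per_subunit_site_size
from ringfit.stoichiometry import fit_mixture, call_stoichiometry

# biphasic Trp-quenching titration of a 50 nM ring, 2% noise
ds = synthgen.gen_titration(seed=1)
fit = estimate_site_sizes(ds.series, seed=1)
print(fit.n_breakpoints, np.round(fit.breakpoints, 1), np.round(fit.breakpoint_se, 1))
# 2 [ 54.5 157.1] [1.3 2.1]
print(round(per_subunit_site_size(fit.breakpoints[0], 10), 2))
# 5.45

# mass-photometry landing events: monomer / ring / ring-dimer mixture
ev = synthgen.gen_mp_events(seed=1)
mx = fit_mixture(ev, 3, seed=1)
print(np.round(mx.means, 1), np.round(mx.mass_fractions, 3))
# [ 73.4 497.7 997.9] [0.052 0.849 0.099]

call = call_stoichiometry(498.4, 52.4)
print(call.n_subunits, round(call.residual_fraction, 3))
# 10 0.049
```

The titration recovers both saturation corners (truth 56 and 158 nt per
ring) within their bootstrap errors, i.e. a high-affinity site of ~5.5 nt
per subunit for a 10-subunit ring; the mixture fit recovers the
dominant ~498 kDa species at ~85% of events, which over a 52.4 kDa
monomer calls a decamer (4.9% mass residual).

The same analyses are exposed on the command line:

```
ringfit generate --assay titration --seed 1 --out titration.csv
ringfit fit-binding titration.csv --out fit.json
ringfit run --config config.yaml --out results/
```

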