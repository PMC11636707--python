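# Methods

`bioturbflux` quantifies sediment reworking by benthic macrofauna and
the solute fluxes it drives, from two measurement chains: luminophore
tracer depth profiles read off sediment-profile images, and
oxygen/nutrient concentration time series from closed-core incubations.
This note records the models, the numerical choices, the synthetic-data
generator's assumptions, and the known limitations.

## Biodiffusion model and fitting

Tracer mixing is modelled with the classical 1-D biodiffusion
(plane-source) solution for a conservative tracer deposited as a thin
even layer at the sediment–water interface of a half-space with no
sedimentation or erosion:

    C(x, t) = N / sqrt(pi * D_b * t) * exp(-x^2 / (4 * D_b * t))

with depth `x` (cm), time `t` (yr), initial tracer input `N`, and the
biodiffusion coefficient `D_b` (cm² yr⁻¹). This is the image-reflected
solution: mathematically it is a half-normal density with scale
`sqrt(2 D_b t)` scaled by `N`, which is also the closed-form oracle the
simulator is tested against.

Fitting choices:

- **N is held fixed, not co-fitted**, default 0.94 — the thickness of
  the first layer of luminophore pixels estimated across incubation
  cores. It is exposed as configuration (`n_input`). Its depth unit is
  taken to be the same as `x` (cm).
- **`t` is always read from core metadata** (10 days for the standard
  design), never hard-coded.
- **Optimization** is a dense 200-point logarithmic grid scan of the
  single-parameter least-squares objective over `D_b ∈ [10⁻³, 10⁴]`
  cm² yr⁻¹ followed by bounded Brent refinement between the bracketing
  grid neighbours. This supersedes a fixed multistart set: the grid
  scan localizes the global optimum of a possibly flat-tailed 1-D
  objective, and refinement reaches ~10⁻⁹ relative precision. Exact
  Crank profiles are recovered to better than 10⁻⁶ relative error.
- **Log-space fit (`D_b^log`)**: zero-concentration bins are dropped —
  no pseudo-count, since `ln 0` is undefined and a pseudo-count would
  distort exactly the low-concentration tail the non-locality index is
  designed to weight. The model prediction is log-transformed
  analytically (avoiding exp underflow at depth).
- **Non-locality index** `NLI = |D_b^log − D_b| / sqrt(D_b^log · D_b)`:
  zero for purely diffusive profiles; positive when fast, direct
  downward transport adds a deep low-concentration tail. Undefined
  (reported missing) when either rate is non-positive.
- **Burial depths**: the mean weighted depth is the
  concentration-weighted mean `Σ x C / Σ C`; the maximum depth is the
  deepest bin centre with tracer present (0 with an `empty` flag for
  empty profiles).
- **Control correction** subtracts the arithmetic mean of the
  defaunated control cores within each (sediment site × temperature)
  group — pooled over tanks, since a per-tank rule is not identifiable
  with one control pair per tank. Physically non-negative quantities
  (D_b, burial depths) that go negative after correction are floored at
  0 and flagged rather than silently clipped.

## Image analysis

The water column of each core photograph is pre-painted a uniform mask
colour (default RGB 253, 3, 155). The sediment surface in each column
is one row past the last mask pixel; columns without mask pixels are
interpolated from neighbours and the line is smoothed with a running
median (default width 5 px — the original smoothing algorithm/width is
not documented, so both are configuration). Matching is exact by
default because the colour was applied digitally; a per-channel
tolerance exists for recompressed archives.

Luminophores are selected by an inclusive HSB window on the ImageJ
0–255 convention (defaults Hue 1–130, Saturation 1–250, Brightness
60–255), computed from RGB via the standard HSV transform rescaled to
0–255. Depth is assigned per column relative to the smoothed local
surface (not a single horizontal line); pixels above the surface are
tracer resting on the interface and are assigned depth 0 (configurable
by pre-masking). Default bin width is one pixel row; the pixel-to-cm
calibration must be supplied per image set. The two photographed faces
(180°) of a core are pooled bin-wise before normalization.
Normalization scales counts so the depth-integrated concentration
equals `N`, making profiles invariant to uniform count rescaling.

## Flux model

In a closed core the supernatant concentration of an analyte evolves
linearly when the benthic flux is constant; the net flux is

    J = R * V / A    (µmol m⁻² h⁻¹)

with `R` the OLS slope (µmol L⁻¹ h⁻¹, from `scipy.stats.linregress`,
which also supplies the slope standard error), `V` the supernatant
volume (default 1 L) and `A` the core cross-section (default ø 10 cm,
7.854×10⁻³ m²). Positive J is out of the sediment.

Each sample draw (default 20 mL syringe) is replaced by tank water,
mixing `C ← C(V−v)/V + C_tank·v/V`. The correction inverts this
**before** regression, reconstructing the undisturbed sequence sample
by sample: the deficit relative to the undisturbed series is constant
between draws (both evolve at the same rate) and each draw updates it
by the same affine map, so the inversion is exact for any sampling
schedule — closed-loop tests recover the true flux to machine precision
at zero noise. Tank concentrations are taken per time point when
provided, constant otherwise.

Oxygen series are QC-flagged (not dropped) where a sample falls below
80 % of the initial concentration, mirroring the field rule of stopping
incubations before oxygen depletion alters the sediment oxygen
penetration depth.

Species-core fluxes are control-corrected by subtracting the mean
control flux per (site × temperature × analyte), sign preserved, with a
`corrected` flag guarding against double application; they are then
normalized by the ash-free dry mass of the fauna (µmol g⁻¹ h⁻¹ m⁻²; the
unit is read as per-gram, per-hour, per-m²). Total inorganic nitrogen
is NO3 + NO2 + NH4. Stoichiometric classification compares a nutrient
flux against `ratio × |J_O2|` with a band `± uncertainty × |J_O2|`;
only the regional N:P ratio (33.6 ± 1.1) and the O2:C factor (1.5 mol
O2 per mol C) ship as defaults — other reference ratios are
configuration inputs, as they derive from a literature compilation
outside this package's scope.

## Temperature scaling and community upscaling

Q10 = (R2/R1)^(10/(T2−T1)), oriented with T1 = 20 °C and T2 = 15 °C so
a warm rate exceeding the cold rate gives Q10 > 1; rates are first
arithmetically averaged within each (species, temperature) group and
the Q10 taken on the means. Oxygen rates enter as uptake magnitudes
(consumption positive) so the coefficient stays defined for negative
fluxes; groups with non-positive mean rates yield a flagged missing
Q10.

Community fluxes are the additive model `F = Σ_s f̄_s B_s` over species
`s`, weighting each species' mean normalized flux by its population
biomass (g AFDM m⁻²), with first-order uncertainty propagation assuming
independence: `var F = Σ_s (B_s² var f̄_s + f̄_s² var B_s)`. The
carbon-to-AFDM conversion factor is a required input with provenance
recorded by the caller; no default is invented. Temperature contrasts
use the summary-statistics t `(X̄1−X̄2)/sqrt(s1²/N1 + s2²/N2)` with
Welch–Satterthwaite degrees of freedom (no df rule is prescribed with
the statistic, so the standard unequal-variance choice is used) and a
two-sided p.

Median grain size (D50) interpolates the cumulative sieve-mass fraction
linearly on the phi (−log2 mm) scale, the sedimentology convention; an
arithmetic-scale interpolation is available behind a flag. The top
sieve's upper bound and the pan's lower bound are taken one phi unit
beyond the mesh (geometric doubling/halving), since the true extremes
are unobserved.

## Synthetic-data generator

The generator provides ground truth for every stage and encodes the
study design it emulates: 12 mesocosm tanks × 6 cores (one core per
species — a lugworm, a ragworm, a cockle, a tube-building polychaete —
plus two defaunated site controls), six tanks at 15 °C and six at
20 °C, a 10-day tracer incubation, three concentration samples over
~7 h in a 1 L supernatant over a ø 10 cm core with 20 mL draws.

- **Tracer transport** is a seeded random walk: particles start
  uniformly in a thin surface layer (default 0.25 cm), take Gaussian
  steps of variance `2 D_b dt` (dt default 0.01 d, small enough that a
  single step is ≪ bin width for realistic D_b), reflect at the
  interface (tracer cannot leave the sediment, matching the
  plane-source model's image reflection and the no-sedimentation
  assumption), and are absorbed (clamped, counted separately) at the
  domain bottom (default 20 cm, matching the ~17 cm sediment columns).
- **Non-local events are downward only** (direct fast transport, e.g. a
  particle dropping down a burrow). `jump_prob` is interpreted as the
  per-particle probability of experiencing **one** such event over the
  whole run, at a uniformly random time; a per-step hazard at the
  default dt would displace every particle to the domain floor within
  days, which is not a usable transport regime. The jump length is a
  truncated-normal deviate (> 0). The depth distribution of real
  non-local events is uncharacterized for any of these species; the
  truncated normal is a stand-in, not an inference about the animals.
- **Incubations** evolve the supernatant linearly at `R = J A / V`,
  add Gaussian measurement noise at each sample, and apply the
  tank-water mixing step after each draw — the exact process the
  dilution correction inverts.
- **Species presets** define the *faunal contribution* on top of a
  common defaunated background (control preset: D_b 1.5 cm² yr⁻¹, weak
  background fluxes), so the control-correction machinery recovers
  exactly what the presets declare. Cold-temperature contributions and
  per-species Q10 targets (bioturbation 10.58 / 3.97 / 2.52 / 0.84 and
  oxygen uptake 5.2 / 8.3 / 2.3 / 2.5 for lugworm / ragworm / cockle /
  tube worm) set the warm rates via `ratio = Q10^(ΔT/10)`; magnitudes
  follow the observed ranges (lugworm strongest, ~300 cm² yr⁻¹ warm;
  cockle and tube worm weak, single digits). AFDM values are drawn
  per core around species-typical means. Measurement noise defaults
  (oxygen 2 µmol L⁻¹, nutrients 0.03–0.5 µmol L⁻¹) reflect optode and
  autoanalyzer precision.
- Everything is driven by an explicit seed threaded through
  `numpy.random.SeedSequence`; no global random state. A fixed seed
  reproduces the fixture byte-identically.

What passing tests on this generator do **not** show about real data:
the generator has no bioirrigation, no depth-dependent or anisotropic
mixing, no animal behaviour, no tracer loss or resuspension, no
photosynthetic activity beyond what the control subtraction removes,
and measurement noise is Gaussian and homoscedastic. Recovery of the
generator's parameters demonstrates the estimators are correct and
unbiased under the stated model, not that the model captures every
process in a mesocosm core.

Because group-mean Q10 is a ratio of noisy means raised to the power
`10/ΔT = 2`, the oxygen-consumption Q10 recovered from noisy 3-point
incubations scatters substantially around its preset even when the
underlying fluxes are unbiased — visible in the synthetic-experiment
outputs, and a caution that applies equally to 3-sample field designs.

## Problem sizes

Simulator fidelity and recovery checks run at 5×10⁴ particles (the
binomial sampling bound at that size is the tested tolerance), 20 seeds
per grid point for D_b recovery, and 200 seeds for noisy flux recovery.
The synthetic experiment uses 2–2×10⁴ particles per core depending on
context. These sizes give sampling errors well below the scientific
tolerances being checked.

## Known limitations

- No sedimentation/erosion term, depth-dependent D_b(x), Bayesian
  fitting, or colour-resolved two-tracer analysis.
- No porewater/diagenetic modelling behind the fluxes; control
  subtraction is the only correction for non-faunal activity.
- The ANOVA/GLM inference layer of a full study (aligned-rank
  transforms, post-hoc contrasts, model selection) is out of scope;
  off-the-shelf statistics packages cover it.
- `stoich_classify` needs externally supplied reference ratios for
  N:O2, P:O2 and Si:O2; only N:P and O2:C ship as defaults.
- Reproduction of published summary tables requires the deposited raw
  measurement files, which must be supplied by the user as tidy CSVs
  (see `tests/test_acceptance.py::TestDepositedDataReproduction`).
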