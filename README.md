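# bioturbflux

Bioturbation rates and benthic nutrient fluxes from sediment-profile
images and closed-core incubations.

Burrowing macrofauna — lugworms, ragworms, cockles, tube-building
polychaetes — rework coastal sediments and pump solutes across the
sediment–water interface, coupling the seafloor to the water column.
`bioturbflux` is a Python library for quantifying these processes the
way mesocosm and field studies measure them:

- **Tracer profiling**: fluorescent luminophore particles are spread on
  the sediment surface; after an incubation, blacklight photographs of
  the core wall are converted to vertical tracer concentration profiles
  (water-column mask detection, HSB thresholding, per-column depth
  binning).
- **Biodiffusion fitting**: the 1-D plane-source mixing model
  `C(x,t) = N/√(πD_b t) · exp(−x²/4D_b t)` is fitted by least squares
  to give the biodiffusion coefficient `D_b` (cm² yr⁻¹); a second fit
  on log-transformed concentrations gives `D_b^log`, and the
  non-locality index `NLI = |D_b^log − D_b|/√(D_b^log·D_b)` flags fast,
  direct downward transport the diffusive model cannot represent.
  Mean-weighted and maximum burial depths and defaunated-control
  corrections complete the per-core analysis.
- **Benthic fluxes**: net solute fluxes from closed-core concentration
  time series via `J = R·V/A`, with exact sample-by-sample correction
  for tank-water dilution, control-core subtraction, and normalization
  by ash-free dry mass (AFDM), plus TIN sums, N:P ratios and
  classification against regional stoichiometric reference ratios.
- **Scaling**: Q10 temperature coefficients
  `(R2/R1)^(10/(T2−T1))` from group-mean rates, biomass-weighted
  additive community fluxes with first-order uncertainty propagation,
  a summary-statistics Welch t-test, and phi-scale median grain size.
- **Synthetic data**: a seeded random-walk tracer simulator, a
  sediment-profile image renderer, an incubation generator, and a
  full 72-core mesocosm experiment factory with known ground truth, so
  every stage is testable end to end without external data.

## Worked example

```python
import bioturbflux as bt

# simulate a tracer profile with a known mixing rate, then recover it
cfg = bt.SimConfig(db_true=100.0, t_days=10.0, n_particles=50_000, seed=1)
fit = bt.fit_profile(bt.simulate_profile(cfg))
print(fit.db, fit.nli)          # 101.75 cm²/yr, NLI 0.005

# a closed-core incubation with sampling dilution, inverted exactly
series = bt.simulate_incubation(bt.IncubationSimConfig(
    j_true=150.0, c0=2.0, c_tank=8.0, sample_volume_ml=20.0,
    sample_times_h=(0.5, 3.5, 7.0), noise_sd=0.0))
print(bt.compute_flux(series).j_raw)   # 150.00 µmol/m²/h
```

Running `python examples/simulate_and_fit.py` prints both transport
regimes:

```
--- diffusive only (true D_b = 100.0 cm^2/yr) ---
fitted D_b     =   101.75 cm^2/yr
fitted D_b^log =   102.28 cm^2/yr
NLI            =    0.005
--- jump_prob=0.05 (true D_b = 100.0 cm^2/yr) ---
fitted D_b     =   109.37 cm^2/yr
fitted D_b^log =   367.36 cm^2/yr
NLI            =    1.287
```

The diffusive run recovers the true rate with NLI ≈ 0; adding rare 8-cm
downward jump events (5 % of particles) barely moves `D_b` but inflates
the log-space fit, so the NLI cleanly separates the two transport
modes. The other scripts in `examples/` walk through the image
round-trip, the flux chain, and the full 72-core experiment with Q10
and community upscaling.

## Command line

A thin CLI wraps the library:

```sh
bioturbflux simulate --db 100 --seed 1 --out profile.csv
bioturbflux profile img1.png img2.png --px-per-cm 20 --out profiles.csv
bioturbflux fit  --profiles profiles.csv --metadata meta.csv --out run/
bioturbflux flux --incubations inc.csv  --metadata meta.csv --out run/
bioturbflux scale --fits run/fits.csv --flux run/flux.csv \
    --metadata meta.csv --biomass biomass.csv --out run/
bioturbflux run --config run.yml --seed 1
```

Every output CSV carries a header block with the package version,
configuration hash and seed; identical configuration and seed reproduce
outputs byte-identically.

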