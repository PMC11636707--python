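"""Full mesocosm experiment: 72 synthetic cores through every stage.

Generates the 12-tank × 6-core design (four species, two defaunated
site controls per tank, 15 vs 20 °C), runs profile fitting, flux
computation with control and AFDM corrections, Q10 temperature
coefficients, and the biomass-weighted community-flux extrapolation.
"""

import tempfile
from pathlib import Path

import pandas as pd

from bioturbflux.pipeline import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as td:
    biomass = pd.DataFrame([
        dict(species=s, biomass_g_afdm_m2=b, sd=0.1 * b)
        for s, b in [("A. marina", 20.0), ("H. diversicolor", 5.0),
                     ("C. edule", 15.0), ("L. conchilega", 10.0)]
    ])
    biomass_path = Path(td) / "biomass.csv"
    biomass.to_csv(biomass_path, index=False)

    cfg = RunConfig(out_dir=str(Path(td) / "run"), seed=1,
                    sim_n_particles=10_000, biomass_csv=str(biomass_path))
    tables = run_pipeline(cfg)

print("Q10 temperature coefficients (group-mean rates, 20 vs 15 °C):")
print(tables["q10"][["species", "process", "q10"]].to_string(index=False))

print("\nCommunity fluxes (µmol/m²/h, biomass-weighted, ± propagated sd):")
comm = tables["community_flux"]
print(comm[comm.analyte.isin(["O2", "TIN", "SiO4"])].to_string(index=False))

print("\nTemperature contrasts of the community fluxes (Welch t from summaries):")
print(tables["tests"].to_string(index=False))

print("\nQ10 > 1 means the process accelerates with warming; the community")
print("oxygen uptake and nutrient effluxes roughly double from 15 to 20 °C.")
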