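"""Simulate a luminophore depth profile and recover the bioturbation rate.

A known biodiffusion coefficient drives a random-walk tracer simulation;
the Crank plane-source model is then fitted back to the binned profile,
with and without non-local (burrow-drop) transport events, to show how
the non-locality index separates the two transport modes.
"""

import bioturbflux as bt

for jump_prob in (0.0, 0.05):
    cfg = bt.SimConfig(db_true=100.0, t_days=10.0, n_particles=50_000,
                       jump_prob=jump_prob, jump_depth_mean=8.0, seed=1)
    profile = bt.simulate_profile(cfg)
    fit = bt.fit_profile(profile)
    label = "diffusive only" if jump_prob == 0 else f"jump_prob={jump_prob}"
    print(f"--- {label} (true D_b = {cfg.db_true} cm^2/yr) ---")
    print(f"fitted D_b     = {fit.db:8.2f} cm^2/yr")
    print(f"fitted D_b^log = {fit.db_log:8.2f} cm^2/yr")
    print(f"NLI            = {fit.nli:8.3f}")
    print(f"mean burial    = {fit.lum_mean:8.2f} cm")
    print(f"max burial     = {fit.lum_max:8.2f} cm")

print()
print("The diffusive run recovers D_b with NLI near zero; injecting rare")
print("8-cm downward jumps leaves D_b similar but inflates D_b^log, so the")
print("NLI flags the non-local transport the Crank model cannot represent.")
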