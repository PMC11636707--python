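"""Synthetic-data generators with known ground truth.

Three forward models mirror the measurement chain of a mesocosm
bioturbation experiment:

* a stochastic 1-D particle-tracking simulator for luminophore tracer
  redistribution under biodiffusive mixing plus rare non-local downward
  transport events,
* a sediment-profile image renderer (the inverse of the image profiler,
  enabling end-to-end image tests), and
* a closed-core incubation time-series generator for oxygen/nutrient
  flux estimation, including the per-sample tank-water dilution step.

A fixture factory assembles a full 12-tank × 6-core experiment with
species-specific presets so every downstream stage can be tested against
known truth without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .flux import CORE_AREA_M2, IncubationSeries
from .profiles import DEFAULT_N_INPUT, DepthProfile, normalize_profile

DAYS_PER_YEAR = 365.0


@dataclass
class SimConfig:
    """Ground-truth parameters for one tracer-transport simulation.

    ``db_true`` is the biodiffusion coefficient in cm² yr⁻¹ acting over
    ``t_days`` of mixing. ``jump_prob`` is the per-particle probability
    of experiencing one non-local downward transport event during the
    run (e.g. a particle dropping down a burrow); the event time is
    uniform over the run and the jump length is a truncated-normal
    deviate (mean ``jump_depth_mean``, sd ``jump_depth_sd``, > 0 cm).
    """

    db_true: float = 50.0
    t_days: float = 10.0
    n_particles: int = 50_000
    dt_days: float = 0.01
    jump_prob: float = 0.0
    jump_depth_mean: float = 8.0
    jump_depth_sd: float = 2.0
    layer_thickness: float = 0.25
    depth_max: float = 20.0
    bin_width: float = 0.25
    seed: int = 0
    n_input: float = DEFAULT_N_INPUT
    core_id: str = "sim"

    def validate(self) -> None:
        vals = [
            self.db_true, self.t_days, self.dt_days, self.jump_prob,
            self.jump_depth_mean, self.jump_depth_sd, self.layer_thickness,
            self.depth_max, self.bin_width,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("SimConfig parameters must be finite")
        if self.db_true < 0:
            raise ValueError("db_true must be >= 0")
        if self.t_days <= 0:
            raise ValueError("t_days must be > 0")
        if not (0 < self.dt_days <= self.t_days):
            raise ValueError("dt_days must satisfy 0 < dt_days <= t_days")
        if not (0 <= self.jump_prob <= 1):
            raise ValueError("jump_prob must lie in [0, 1]")
        if self.bin_width <= 0 or self.depth_max <= 0:
            raise ValueError("bin_width and depth_max must be > 0")
        if self.layer_thickness < 0:
            raise ValueError("layer_thickness must be >= 0")
        if self.n_particles <= 0:
            raise ValueError("n_particles must be > 0")


@dataclass
class IncubationSimConfig:
    """Ground truth for one closed-core incubation series.

    ``j_true`` is the net flux in µmol m⁻² h⁻¹ (positive out of the
    sediment). The supernatant of volume ``v_liters`` over a core of
    cross-section ``area_m2`` evolves linearly, C(t) = c0 + J·A·t/V;
    each sample draw of ``sample_volume_ml`` is instantly replaced by
    tank water of concentration ``c_tank``.
    """

    j_true: float = 100.0
    v_liters: float = 1.0
    area_m2: float = CORE_AREA_M2
    c0: float = 10.0
    c_tank: float = 10.0
    sample_volume_ml: float = 20.0
    sample_times_h: tuple = (0.5, 3.5, 7.0)
    noise_sd: float = 0.0
    seed: int = 0
    core_id: str = "sim"
    analyte: str = "NH4"

    def validate(self) -> None:
        if self.v_liters <= 0 or self.area_m2 <= 0:
            raise ValueError("v_liters and area_m2 must be > 0")
        if not (0 <= self.sample_volume_ml < 1000 * self.v_liters):
            raise ValueError("sample_volume_ml must be >= 0 and < supernatant volume")
        t = np.asarray(self.sample_times_h, dtype=float)
        if t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("sample_times_h must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not all(math.isfinite(v) for v in
                   [self.j_true, self.c0, self.c_tank, self.noise_sd]):
            raise ValueError("IncubationSimConfig parameters must be finite")


def simulate_profile(cfg: SimConfig) -> DepthProfile:
    """Random-walk forward model of diffusive tracer mixing.

    Particles start uniformly within the initial surface layer
    ``[0, layer_thickness]``. Each time step adds a Gaussian displacement
    of variance ``2 · D_b · dt`` (D_b converted from cm² yr⁻¹ to act over
    dt in years), with a reflecting boundary at the sediment–water
    interface (depth 0) and an absorbing cap at ``depth_max``: particles
    reaching the cap are clamped there, stop moving, and are excluded
    from the binned profile (reported via ``n_capped``). Particles
    selected for a non-local event take their downward jump at their
    event step instead of a diffusive step.

    Returns a normalized :class:`DepthProfile` (per
    :func:`~bioturbflux.profiles.normalize_profile` conventions).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_particles
    n_steps = int(round(cfg.t_days / cfg.dt_days))
    dt_yr = cfg.dt_days / DAYS_PER_YEAR
    sigma = math.sqrt(2.0 * cfg.db_true * dt_yr)

    pos = rng.uniform(0.0, cfg.layer_thickness, size=n)
    absorbed = np.zeros(n, dtype=bool)

    # Assign at most one non-local event per particle, at a uniform step.
    jump_step = np.full(n, -1, dtype=np.int64)
    if cfg.jump_prob > 0 and n_steps > 0:
        jumpers = rng.random(n) < cfg.jump_prob
        jump_step[jumpers] = rng.integers(0, n_steps, size=int(jumpers.sum()))

    a = (0.0 - cfg.jump_depth_mean) / cfg.jump_depth_sd if cfg.jump_depth_sd > 0 else 0.0

    for step in range(n_steps):
        active = ~absorbed
        if not active.any():
            break
        disp = np.zeros(n)
        if sigma > 0:
            disp[active] = rng.normal(0.0, sigma, size=int(active.sum()))
        jump_now = active & (jump_step == step)
        if jump_now.any():
            if cfg.jump_depth_sd > 0:
                jumps = stats.truncnorm.rvs(
                    a, np.inf, loc=cfg.jump_depth_mean, scale=cfg.jump_depth_sd,
                    size=int(jump_now.sum()), random_state=rng,
                )
            else:
                jumps = np.full(int(jump_now.sum()), cfg.jump_depth_mean)
            disp[jump_now] = jumps
        pos[active] = pos[active] + disp[active]
        # reflecting boundary at the interface
        pos[active] = np.abs(pos[active])
        hit = active & (pos >= cfg.depth_max)
        pos[hit] = cfg.depth_max
        absorbed |= hit

    edges = np.arange(0.0, cfg.depth_max + cfg.bin_width / 2, cfg.bin_width)
    counts, _ = np.histogram(pos[~absorbed], bins=edges)
    centres = (edges[:-1] + edges[1:]) / 2
    prof = DepthProfile(
        x=centres,
        counts=counts.astype(float),
        bin_width=cfg.bin_width,
        t_yr=cfg.t_days / DAYS_PER_YEAR,
        n_input=cfg.n_input,
        core_id=cfg.core_id,
        n_capped=int(absorbed.sum()),
    )
    if prof.total_count > 0:
        prof = normalize_profile(prof)
    return prof


def crank_oracle_profile(db: float, t_yr: float, edges: np.ndarray,
                         n_input: float = DEFAULT_N_INPUT) -> np.ndarray:
    """Closed-form bin-averaged Crank concentrations (independent oracle).

    The half-space plane-source solution is a half-normal density with
    scale sqrt(2·D_b·t) scaled by N; bin-averaging uses its CDF.
    """
    scale = math.sqrt(2.0 * db * t_yr)
    mass = np.diff(stats.halfnorm.cdf(edges, scale=scale))
    return n_input * mass / np.diff(edges)


# ---------------------------------------------------------------------------
# Sediment-profile image rendering

MASK_RGB = (253, 3, 155)  # uniform colour painted over the water column
LUM_RGB = (50, 255, 50)   # bright luminophore green, inside the HSB window
SEDIMENT_RGB = (30, 30, 30)


def render_spi_image(
    profile: DepthProfile,
    px_per_cm: float = 20.0,
    image_width_px: int = 200,
    water_height_px: int = 40,
    mask_rgb: tuple = MASK_RGB,
    lum_rgb: tuple = LUM_RGB,
    sediment_rgb: tuple = SEDIMENT_RGB,
    seed: int = 0,
) -> np.ndarray:
    """Render a blacklight core photograph consistent with a profile.

    The top ``water_height_px`` rows are filled with the water-column
    mask colour; the sediment surface is the flat line immediately
    below. Each depth bin's count of luminophore pixels is scattered
    (seeded) within that bin's row band so that extraction recovers the
    profile exactly. Requires ``px_per_cm * bin_width`` to be an
    integer number of rows so bins map onto whole row bands.
    """
    if px_per_cm <= 0 or image_width_px <= 0 or water_height_px < 0:
        raise ValueError("scales and sizes must be positive")
    if np.any(profile.counts < 0):
        raise ValueError("profile counts must be non-negative")
    rows_per_bin_f = px_per_cm * profile.bin_width
    rows_per_bin = int(round(rows_per_bin_f))
    if rows_per_bin < 1 or not math.isclose(rows_per_bin_f, rows_per_bin):
        raise ValueError(
            "px_per_cm * bin_width must be a whole number of pixel rows "
            f"(got {rows_per_bin_f})"
        )
    n_bins = len(profile.x)
    height = water_height_px + n_bins * rows_per_bin
    img = np.empty((height, image_width_px, 3), dtype=np.uint8)
    img[:] = np.asarray(sediment_rgb, dtype=np.uint8)
    img[:water_height_px] = np.asarray(mask_rgb, dtype=np.uint8)

    rng = np.random.default_rng(seed)
    surface = water_height_px
    for i, count in enumerate(profile.counts):
        count = int(round(count))
        if count == 0:
            continue
        r0 = surface + i * rows_per_bin
        capacity = rows_per_bin * image_width_px
        if count > capacity:
            raise ValueError(
                f"bin {i} needs {count} luminophore pixels but the row band "
                f"only holds {capacity}; increase image_width_px or px_per_cm"
            )
        flat = rng.choice(capacity, size=count, replace=False)
        rr = r0 + flat // image_width_px
        cc = flat % image_width_px
        img[rr, cc] = np.asarray(lum_rgb, dtype=np.uint8)
    return img


# ---------------------------------------------------------------------------
# Closed-core incubation series

def simulate_incubation(cfg: IncubationSimConfig) -> IncubationSeries:
    """Forward model of a closed-core incubation with sampling dilution.

    The true supernatant concentration rises at rate R = J·A/V
    (µmol L⁻¹ h⁻¹). At each sample time the reported value is the
    current concentration plus Gaussian noise; immediately afterwards
    the drawn volume is replaced by tank water (instantaneous mixing),
    resetting the supernatant to ``C·(V−v)/V + c_tank·v/V``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    r = cfg.j_true * cfg.area_m2 / cfg.v_liters  # µmol / L / h
    f = cfg.sample_volume_ml / 1000.0 / cfg.v_liters
    times = np.asarray(cfg.sample_times_h, dtype=float)
    conc = np.empty_like(times)
    c = cfg.c0
    t_prev = 0.0
    for i, t in enumerate(times):
        c += r * (t - t_prev)
        obs = c + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
        conc[i] = obs
        c = c * (1.0 - f) + cfg.c_tank * f
        t_prev = t
    return IncubationSeries(
        core_id=cfg.core_id,
        analyte=cfg.analyte,
        times_h=times,
        conc=conc,
        v_liters=cfg.v_liters,
        area_m2=cfg.area_m2,
        sample_volume_ml=cfg.sample_volume_ml,
        tank_conc=np.full_like(times, cfg.c_tank),
    )


# ---------------------------------------------------------------------------
# Experimental-design fixture

SPECIES = ("A. marina", "H. diversicolor", "C. edule", "L. conchilega")
CONTROL = "control"
ANALYTES = ("O2", "NO3", "NO2", "NH4", "SiO4", "PO4")

#: Species presets. Bioturbation: warm (20 °C) D_b set from the cold rate and
#: a target Q10 over the 5 °C gap (ratio = sqrt(Q10)); magnitudes follow the
#: observed ranges (A. marina strongest, up to ~375 cm² yr⁻¹ warm;
#: H. diversicolor intermediate; C. edule / L. conchilega weak). Oxygen-uptake
#: Q10 targets likewise; nutrient effluxes loosely track oxygen uptake.
SPECIES_PRESETS: dict[str, dict] = {
    "A. marina": dict(
        db_cold=90.0, q10_bioturb=10.58, q10_o2=5.2,
        jump_prob=0.01, jump_depth_mean=6.0, site="Uthoern",
        o2_cold=-350.0, afdm_mean=3.0, afdm_sd=0.3,
        nutrients=dict(NO3=8.0, NO2=1.0, NH4=40.0, SiO4=90.0, PO4=10.0),
    ),
    "H. diversicolor": dict(
        db_cold=40.0, q10_bioturb=3.97, q10_o2=8.3,
        jump_prob=0.02, jump_depth_mean=8.0, site="Uthoern",
        o2_cold=-120.0, afdm_mean=0.4, afdm_sd=0.05,
        nutrients=dict(NO3=5.0, NO2=0.8, NH4=25.0, SiO4=50.0, PO4=8.0),
    ),
    "C. edule": dict(
        db_cold=6.0, q10_bioturb=2.52, q10_o2=2.3,
        jump_prob=0.03, jump_depth_mean=1.2, site="Uthoern",
        o2_cold=-200.0, afdm_mean=1.5, afdm_sd=0.15,
        nutrients=dict(NO3=3.0, NO2=0.4, NH4=10.0, SiO4=20.0, PO4=1.5),
    ),
    "L. conchilega": dict(
        db_cold=8.0, q10_bioturb=0.84, q10_o2=2.5,
        jump_prob=0.025, jump_depth_mean=5.0, site="Reef",
        o2_cold=-220.0, afdm_mean=1.0, afdm_sd=0.1,
        nutrients=dict(NO3=4.0, NO2=0.5, NH4=15.0, SiO4=25.0, PO4=2.0),
    ),
}

#: Residual mixing and fluxes in defaunated control sediment.
CONTROL_PRESET = dict(db=1.5, o2=-40.0,
                      nutrients=dict(NO3=1.0, NO2=0.1, NH4=3.0, SiO4=8.0, PO4=0.5))

#: Typical tank-water concentrations (µmol L⁻¹) used as both the initial
#: supernatant and the dilution source.
TANK_CONC = dict(O2=250.0, NO3=5.0, NO2=0.5, NH4=2.0, SiO4=15.0, PO4=0.8)

NOISE_SD = dict(O2=2.0, NO3=0.15, NO2=0.03, NH4=0.2, SiO4=0.5, PO4=0.05)

T_COLD, T_WARM = 15.0, 20.0


def _warm_rate(cold: float, q10: float, dT: float = T_WARM - T_COLD) -> float:
    return cold * q10 ** (dT / 10.0)


@dataclass
class ExperimentFixture:
    """All tables a full pipeline run consumes, plus the ground truth."""

    metadata: pd.DataFrame      # core_id, tank, species, site, temperature_c, afdm_g, geometry
    profiles: pd.DataFrame      # tidy: core_id, depth_cm, count, concentration
    incubations: pd.DataFrame   # tidy: core_id, analyte, time_h, conc_umol_l
    truth: pd.DataFrame         # per-core true db / jump / flux parameters
    seed: int = 0


def make_experiment_fixture(seed: int = 0, *, n_particles: int = 20_000,
                            t_days: float = 10.0) -> ExperimentFixture:
    """Generate the full 12-tank × 6-core mesocosm experiment.

    Six tanks at 15 °C and six at 20 °C; each tank holds one core per
    species plus two defaunated site controls (72 cores in total).
    Species presets give warm > cold responses for bioturbation and
    oxygen uptake according to their target Q10 values, so the
    downstream group-mean Q10 computation recovers the presets exactly
    on the noiseless truth table.
    """
    root = np.random.SeedSequence(seed)
    meta_rows, truth_rows, prof_frames, inc_frames = [], [], [], []
    afdm_rng = np.random.default_rng(root.spawn(1)[0])

    core_no = 0
    for tank in range(1, 13):
        temp = T_COLD if tank <= 6 else T_WARM
        members = list(SPECIES) + [f"{CONTROL}:Uthoern", f"{CONTROL}:Reef"]
        for member in members:
            core_no += 1
            core_id = f"T{tank:02d}C{core_no:02d}"
            is_control = member.startswith(CONTROL)
            if is_control:
                species, site = CONTROL, member.split(":")[1]
                db_faunal, o2_faunal = 0.0, 0.0
                db = CONTROL_PRESET["db"]
                jump_p, jump_mu = 0.0, 0.0
                o2 = CONTROL_PRESET["o2"]
                nutrients = CONTROL_PRESET["nutrients"]
                afdm = np.nan
            else:
                # species cores carry the defaunated background plus the
                # faunal contribution; control correction downstream
                # recovers the contribution, whose presets set the Q10
                species = member
                p = SPECIES_PRESETS[species]
                site = p["site"]
                warm = temp == T_WARM
                db_faunal = (_warm_rate(p["db_cold"], p["q10_bioturb"])
                             if warm else p["db_cold"])
                o2_faunal = (-_warm_rate(-p["o2_cold"], p["q10_o2"])
                             if warm else p["o2_cold"])
                db = CONTROL_PRESET["db"] + db_faunal
                o2 = CONTROL_PRESET["o2"] + o2_faunal
                scale = abs(o2_faunal / p["o2_cold"])
                nutrients = {k: CONTROL_PRESET["nutrients"][k] + v * scale
                             for k, v in p["nutrients"].items()}
                jump_p, jump_mu = p["jump_prob"], p["jump_depth_mean"]
                afdm = float(afdm_rng.normal(p["afdm_mean"], p["afdm_sd"]))
                afdm = max(afdm, 0.05)

            meta_rows.append(dict(
                core_id=core_id, tank=tank, species=species, site=site,
                temperature_c=temp, afdm_g=afdm, v_liters=1.0,
                area_m2=CORE_AREA_M2, t_days=t_days,
            ))

            core_ss = root.spawn(1)[0]
            prof_seed = int(core_ss.generate_state(1)[0] % (2**31))
            prof = simulate_profile(SimConfig(
                db_true=db, t_days=t_days, n_particles=n_particles,
                jump_prob=jump_p, jump_depth_mean=jump_mu,
                jump_depth_sd=max(0.25 * jump_mu, 0.1),
                seed=prof_seed, core_id=core_id,
            ))
            prof_frames.append(prof.to_frame())

            truth = dict(core_id=core_id, species=species, site=site,
                         temperature_c=temp,
                         db_true=db_faunal if not is_control else db,
                         db_core_total=db,
                         jump_prob=jump_p, jump_depth_mean=jump_mu,
                         o2_flux_true=o2_faunal if not is_control else o2,
                         o2_core_total=o2)
            fluxes = dict(nutrients)
            fluxes["O2"] = o2
            for a_idx, analyte in enumerate(ANALYTES):
                j = fluxes[analyte]
                truth[f"j_true_{analyte}"] = j
                inc_seed = (int(core_ss.generate_state(2)[1]) + a_idx) % (2**31)
                series = simulate_incubation(IncubationSimConfig(
                    j_true=j, c0=TANK_CONC[analyte], c_tank=TANK_CONC[analyte],
                    noise_sd=NOISE_SD[analyte], seed=inc_seed,
                    core_id=core_id, analyte=analyte,
                ))
                inc_frames.append(series.to_frame())
            truth_rows.append(truth)

    return ExperimentFixture(
        metadata=pd.DataFrame(meta_rows),
        profiles=pd.concat(prof_frames, ignore_index=True),
        incubations=pd.concat(inc_frames, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        seed=seed,
    )
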