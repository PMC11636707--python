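"""Pipeline orchestration: configuration, validation, staged execution.

Binds the stages (simulate → profile → fit → flux → scale) into one
reproducible run driven by a flat YAML configuration. All physical
constants (V, A, t, N, thresholds) live in the configuration, never in
code, so reanalysis of deposited tables and synthetic runs share one
code path. Every output CSV carries a header block recording the
package version, a hash of the configuration and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffusion import control_correct, fit_profile
from .flux import (IncubationSeries, add_tin, compute_flux, control_subtract,
                   flag_o2_depletion, np_ratio)
from .profiles import DEFAULT_N_INPUT, profile_from_frame
from .scaling import (PopulationBiomass, SpeciesFluxSummary, SummaryStats,
                      extrapolate_community, q10_from_groups, t_from_summary)
from .sim import make_experiment_fixture

log = logging.getLogger("bioturbflux")

ALL_STAGES = ("sim", "fit", "flux", "scale")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending core."""

    def __init__(self, stage: str, message: str, core_id: str = ""):
        self.stage = stage
        self.core_id = core_id
        where = f"stage '{stage}'" + (f", core {core_id}" if core_id else "")
        super().__init__(f"{where}: {message}")


@dataclass
class RunConfig:
    """Flat key/value run configuration (YAML-serializable)."""

    out_dir: str = "run_out"
    stages: tuple = ALL_STAGES
    seed: int = 0
    # sim
    sim_n_particles: int = 20_000
    t_days: float = 10.0
    # fit
    n_input: float = DEFAULT_N_INPUT
    # flux
    tank_conc_col: str = "tank_conc_umol_l"
    # scale
    t_warm_c: float = 20.0
    t_cold_c: float = 15.0
    biomass_csv: str | None = None
    # inputs (when the sim stage is disabled)
    metadata_csv: str | None = None
    profiles_csv: str | None = None
    incubations_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def digest(self) -> str:
        # hash the analysis parameters only; the output location is not
        # part of the scientific configuration
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    """Write a CSV with a provenance header block (read back with comment='#')."""
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# bioturbflux {__version__}\n"
        f"# config_hash {cfg.digest()}\n"
        f"# seed {cfg.seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Input validation

REQUIRED_COLUMNS = {
    "metadata": ["core_id", "species", "site", "temperature_c", "afdm_g",
                 "v_liters", "area_m2", "t_days"],
    "profiles": ["core_id", "depth_cm", "count"],
    "incubations": ["core_id", "analyte", "time_h", "conc_umol_l"],
    "biomass": ["species", "biomass_g_afdm_m2", "sd"],
}


def validate_inputs(tables: dict[str, pd.DataFrame]) -> dict:
    """Schema-check input tables; returns {'errors': [...], 'warnings': [...]}.

    Checks required columns, strictly increasing per-core sample times,
    and non-negative depths. Never mutates its inputs.
    """
    report: dict = {"errors": [], "warnings": []}
    for kind, df in tables.items():
        required = REQUIRED_COLUMNS.get(kind)
        if required is None:
            report["warnings"].append(f"unknown table kind '{kind}' not validated")
            continue
        missing = [c for c in required if c not in df.columns]
        for col in missing:
            report["errors"].append(f"{kind}: missing column '{col}'")
        if missing:
            continue
        if kind == "profiles" and (df["depth_cm"] < 0).any():
            report["errors"].append("profiles: negative depth_cm values")
        if kind == "incubations":
            for (core, analyte), sub in df.groupby(["core_id", "analyte"]):
                t = sub["time_h"].to_numpy()
                if np.any(np.diff(t) <= 0):
                    report["errors"].append(
                        f"incubations: non-monotone times for core {core}, {analyte}"
                    )
    return report


# ---------------------------------------------------------------------------
# Stages

def _stage_sim(cfg: RunConfig, out: Path) -> dict[str, pd.DataFrame]:
    fx = make_experiment_fixture(cfg.seed, n_particles=cfg.sim_n_particles,
                                 t_days=cfg.t_days)
    tables = {"metadata": fx.metadata, "profiles": fx.profiles,
              "incubations": fx.incubations, "truth": fx.truth}
    for name, df in tables.items():
        write_table(df, out / f"{name}.csv", cfg)
    return tables


def _stage_fit(cfg: RunConfig, out: Path, metadata: pd.DataFrame,
               profiles: pd.DataFrame) -> pd.DataFrame:
    rows = []
    meta = metadata.set_index("core_id")
    from .profiles import normalize_profile

    for core_id in profiles["core_id"].unique():
        try:
            t_yr = float(meta.loc[core_id, "t_days"]) / 365.0
            prof = profile_from_frame(profiles, core_id, t_yr=t_yr,
                                      n_input=cfg.n_input)
            prof = normalize_profile(prof)
            fit = fit_profile(prof)
        except Exception as exc:  # noqa: BLE001 - stage contract names the core
            raise PipelineError("fit", str(exc), core_id=core_id) from exc
        rows.append(dict(core_id=core_id, db=fit.db, db_log=fit.db_log,
                         nli=fit.nli, lum_mean=fit.lum_mean,
                         lum_max=fit.lum_max, rss=fit.rss,
                         rss_log=fit.rss_log))
        for key in fit.flags:
            log.warning("fit core %s: flag %s", core_id, key)
    fits = control_correct(pd.DataFrame(rows), metadata)
    write_table(fits, out / "fits.csv", cfg)
    return fits


def _stage_flux(cfg: RunConfig, out: Path, metadata: pd.DataFrame,
                incubations: pd.DataFrame) -> pd.DataFrame:
    meta = metadata.set_index("core_id")
    rows = []
    for (core_id, analyte), sub in incubations.groupby(["core_id", "analyte"]):
        try:
            m = meta.loc[core_id]
            tank = (sub[cfg.tank_conc_col].to_numpy()
                    if cfg.tank_conc_col in sub.columns else None)
            series = IncubationSeries(
                core_id=core_id, analyte=analyte,
                times_h=sub["time_h"].to_numpy(),
                conc=sub["conc_umol_l"].to_numpy(),
                v_liters=float(m["v_liters"]), area_m2=float(m["area_m2"]),
                sample_volume_ml=float(m.get("sample_volume_ml", 20.0)),
                tank_conc=tank,
            )
            if analyte == "O2":
                series = flag_o2_depletion(series)
                if series.qc_flags:
                    log.warning("flux core %s O2: %s", core_id, series.qc_flags)
            res = compute_flux(series, correct_dilution=tank is not None)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("flux", str(exc), core_id=core_id) from exc
        rows.append(dict(core_id=core_id, analyte=analyte, j_raw=res.j_raw,
                         slope=res.slope, slope_se=res.slope_se))
    table = add_tin(pd.DataFrame(rows), value_cols=("j_raw",))
    table = control_subtract(table, metadata)
    afdm = metadata.set_index("core_id")["afdm_g"]
    table["afdm_g"] = table["core_id"].map(afdm)
    table["j_normalized"] = np.where(
        table["afdm_g"] > 0, table["j_corrected"] / table["afdm_g"], np.nan
    )
    write_table(table, out / "flux.csv", cfg)
    return table


def _stage_scale(cfg: RunConfig, out: Path, metadata: pd.DataFrame,
                 fits: pd.DataFrame | None, flux: pd.DataFrame | None) -> dict:
    results: dict = {}
    meta_cols = metadata[["core_id", "species", "temperature_c"]]
    q10_frames = []
    if fits is not None:
        bio = fits.merge(meta_cols, on="core_id", how="left", suffixes=("", "_m"))
        bio = bio[bio["species"] != "control"]
        db_col = "db_corrected" if "db_corrected" in bio.columns else "db"
        q = q10_from_groups(bio.rename(columns={db_col: "rate"}),
                            t_warm=cfg.t_warm_c, t_cold=cfg.t_cold_c)
        q["process"] = "bioturbation"
        q10_frames.append(q)
    if flux is not None:
        o2 = flux[flux["analyte"] == "O2"].merge(meta_cols, on="core_id", how="left")
        o2 = o2[o2["species"] != "control"]
        q = q10_from_groups(o2.rename(columns={"j_corrected": "rate"}),
                            t_warm=cfg.t_warm_c, t_cold=cfg.t_cold_c,
                            magnitude=True)
        q["process"] = "oxygen-consumption"
        q10_frames.append(q)
    if q10_frames:
        q10_table = pd.concat(q10_frames, ignore_index=True)
        write_table(q10_table, out / "q10.csv", cfg)
        results["q10"] = q10_table

    if flux is not None and cfg.biomass_csv:
        biomass_df = read_table(cfg.biomass_csv)
        biomasses = {
            r["species"]: PopulationBiomass(r["species"], r["biomass_g_afdm_m2"],
                                            r.get("sd", 0.0))
            for _, r in biomass_df.iterrows()
        }
        sp_flux = flux.merge(meta_cols, on="core_id", how="left")
        sp_flux = sp_flux[sp_flux["species"].isin(biomasses)]
        comm_rows, test_rows = [], []
        for analyte, asub in sp_flux.groupby("analyte"):
            per_temp: dict[float, tuple] = {}
            for temp, tsub in asub.groupby("temperature_c"):
                stats = tsub.groupby("species")["j_normalized"].agg(["mean", "sem", "count"])
                if not set(biomasses).issubset(stats.index):
                    continue
                summaries = {
                    sp: SpeciesFluxSummary(sp, row["mean"],
                                           0.0 if np.isnan(row["sem"]) else row["sem"],
                                           int(row["count"]))
                    for sp, row in stats.iterrows()
                }
                cf = extrapolate_community(summaries, biomasses)
                n_total = int(stats["count"].sum())
                comm_rows.append(dict(analyte=analyte, temperature_c=temp,
                                      flux=cf.flux, sd=cf.sd, n=n_total))
                per_temp[temp] = (cf, n_total)
            if cfg.t_warm_c in per_temp and cfg.t_cold_c in per_temp:
                (cw, nw), (cc, nc) = per_temp[cfg.t_warm_c], per_temp[cfg.t_cold_c]
                try:
                    t, df_, p = t_from_summary(SummaryStats(cw.flux, cw.sd**2, nw),
                                               SummaryStats(cc.flux, cc.sd**2, nc))
                    test_rows.append(dict(analyte=analyte, t=t, df=df_, p=p))
                except ValueError:
                    pass
        if comm_rows:
            comm = pd.DataFrame(comm_rows)
            write_table(comm, out / "community_flux.csv", cfg)
            results["community_flux"] = comm
        if test_rows:
            tests = pd.DataFrame(test_rows)
            write_table(tests, out / "tests.csv", cfg)
            results["tests"] = tests

    if flux is not None:
        ratio_rows = []
        for core_id, sub in flux.groupby("core_id"):
            by = sub.set_index("analyte")["j_corrected"]
            if {"TIN", "PO4"}.issubset(by.index) and by["PO4"] != 0:
                ratio_rows.append(dict(core_id=core_id,
                                       np_ratio=np_ratio(by["TIN"], by["PO4"])))
        if ratio_rows:
            results["np_ratios"] = pd.DataFrame(ratio_rows)
            write_table(results["np_ratios"], out / "np_ratios.csv", cfg)
    return results


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the result tables.

    Writes a run manifest (seed, config hash, package version, stage
    list) alongside the outputs. Any stage failure aborts with the
    stage name and the offending core id.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict = {}

    if "sim" in cfg.stages:
        tables.update(_stage_sim(cfg, out))
    else:
        if cfg.metadata_csv:
            tables["metadata"] = read_table(cfg.metadata_csv)
        if cfg.profiles_csv:
            tables["profiles"] = read_table(cfg.profiles_csv)
        if cfg.incubations_csv:
            tables["incubations"] = read_table(cfg.incubations_csv)

    if "metadata" in tables:
        report = validate_inputs({k: v for k, v in tables.items()
                                  if k in REQUIRED_COLUMNS})
        if report["errors"]:
            raise PipelineError("validate", "; ".join(report["errors"]))

    fits = flux_table = None
    if "fit" in cfg.stages:
        if not {"metadata", "profiles"} <= tables.keys():
            raise PipelineError("fit", "needs metadata and profiles tables")
        fits = _stage_fit(cfg, out, tables["metadata"], tables["profiles"])
        tables["fits"] = fits
    if "flux" in cfg.stages:
        if not {"metadata", "incubations"} <= tables.keys():
            raise PipelineError("flux", "needs metadata and incubations tables")
        flux_table = _stage_flux(cfg, out, tables["metadata"], tables["incubations"])
        tables["flux"] = flux_table
    if "scale" in cfg.stages:
        tables.update(_stage_scale(cfg, out, tables["metadata"], fits, flux_table))

    manifest = dict(version=__version__, config_hash=cfg.digest(), seed=cfg.seed,
                    stages=list(cfg.stages),
                    outputs=sorted(p.name for p in out.glob("*.csv")))
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return tables
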