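"""Temperature coefficients, community upscaling, and summary statistics.

The Q10 temperature coefficient, Q10 = (R2/R1)^(10/(T2−T1)), expresses
the factor by which a biological rate changes per 10 °C of warming
(Q10 = 2 means a doubling). Community-level fluxes are obtained by
weighting each species' mean AFDM-normalized flux by its population
biomass and combining species additively, with first-order propagation
of uncertainty. A summary-statistics t-test (Welch form) compares
propagated community estimates between temperatures, and a phi-scale
median grain size (D50) characterizes the sediments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def q10(r1_at_t1: float, r2_at_t2: float, t1_c: float, t2_c: float) -> float:
    """Q10 = (R2/R1)^(10/(T2−T1)) for rates R1 at T1 and R2 at T2.

    With the convention T1 = 20 °C, T2 = 15 °C, a warm rate exceeding
    the cold rate yields Q10 > 1. Rates must be positive (apply the
    uptake sign convention first for oxygen).
    """
    if r1_at_t1 <= 0 or r2_at_t2 <= 0:
        raise ValueError("Q10 undefined for non-positive rates")
    if t1_c == t2_c:
        raise ValueError("Q10 undefined for equal temperatures")
    return (r2_at_t2 / r1_at_t1) ** (10.0 / (t2_c - t1_c))


def q10_from_groups(rates: pd.DataFrame, *, rate_col: str = "rate",
                    species_col: str = "species", temp_col: str = "temperature_c",
                    t_warm: float = 20.0, t_cold: float = 15.0,
                    magnitude: bool = False) -> pd.DataFrame:
    """Per-species Q10 from group-mean rates at the two temperatures.

    Rates are first arithmetically averaged within each (species,
    temperature) group, then the Q10 is taken on the two means. Set
    ``magnitude=True`` for processes measured as uptake (negative
    fluxes), e.g. oxygen consumption. Groups with a non-positive mean
    rate get a missing Q10 and a flag instead of an error.
    """
    df = rates.copy()
    if magnitude:
        df[rate_col] = df[rate_col].abs()
    means = df.groupby([species_col, temp_col])[rate_col].mean().unstack(temp_col)
    for t in (t_warm, t_cold):
        if t not in means.columns:
            raise ValueError(f"no rates at temperature {t}")
    out = []
    for species, row in means.iterrows():
        r_warm, r_cold = row[t_warm], row[t_cold]
        rec = dict(species=species, r_warm=r_warm, r_cold=r_cold,
                   q10=np.nan, flag="")
        if r_warm > 0 and r_cold > 0:
            rec["q10"] = q10(r_warm, r_cold, t_warm, t_cold)
        else:
            rec["flag"] = "non-positive group mean rate"
        out.append(rec)
    return pd.DataFrame(out)


def carbon_to_afdm(biomass_gc: float, factor: float) -> float:
    """Convert carbon biomass (g C) to ash-free dry mass via a literature factor.

    The factor is a required input with provenance recorded by the
    caller; no default is assumed.
    """
    if factor <= 0:
        raise ValueError("conversion factor must be > 0")
    return biomass_gc * factor


@dataclass
class PopulationBiomass:
    """Population biomass of one species, g AFDM m⁻², with uncertainty."""

    species: str
    biomass: float
    uncertainty: float = 0.0
    provenance: str = ""
    c_to_afdm_factor: float | None = None

    def __post_init__(self) -> None:
        if self.biomass < 0 or self.uncertainty < 0:
            raise ValueError("biomass and uncertainty must be >= 0")


@dataclass
class SpeciesFluxSummary:
    """Mean AFDM-normalized flux of one species with the sd of that mean."""

    species: str
    mean: float      # µmol g⁻¹ h⁻¹ m⁻²
    sd: float        # uncertainty of the mean
    n: int = 1

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class CommunityFlux:
    """Biomass-weighted, additively combined population flux."""

    flux: float      # µmol m⁻² h⁻¹
    sd: float
    n_species: int


def extrapolate_community(flux_summaries: dict[str, SpeciesFluxSummary],
                          biomasses: dict[str, PopulationBiomass]) -> CommunityFlux:
    """Additive model community: F = Σ_s f̄_s·B_s with propagated variance.

    Assuming independence between species and between flux and biomass
    uncertainties, var(F) = Σ_s (B_s²·var(f̄_s) + f̄_s²·var(B_s)).
    Every species in the flux summaries must have a biomass and vice
    versa.
    """
    if set(flux_summaries) != set(biomasses):
        missing = set(flux_summaries) ^ set(biomasses)
        raise ValueError(f"species without both flux and biomass: {sorted(missing)}")
    total = 0.0
    var = 0.0
    for sp, f in flux_summaries.items():
        b = biomasses[sp]
        total += f.mean * b.biomass
        var += b.biomass**2 * f.sd**2 + f.mean**2 * b.uncertainty**2
    return CommunityFlux(flux=total, sd=math.sqrt(var), n_species=len(flux_summaries))


@dataclass
class SummaryStats:
    """Mean, variance (incl. propagated components) and sample size."""

    mean: float
    var: float
    n: int

    def __post_init__(self) -> None:
        if self.var < 0:
            raise ValueError("variance must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def t_from_summary(a: SummaryStats, b: SummaryStats) -> tuple[float, float, float]:
    """Welch t-test from summary statistics: returns (t, df, p).

    t = (X̄1 − X̄2) / sqrt(s1²/N1 + s2²/N2), with Welch–Satterthwaite
    degrees of freedom and a two-sided p-value.
    """
    va, vb = a.var / a.n, b.var / b.n
    denom = va + vb
    if denom == 0:
        raise ValueError("both variances are zero; t undefined")
    t = (a.mean - b.mean) / math.sqrt(denom)
    df = denom**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, min(p, 1.0)


STANDARD_MESHES_UM = (2000.0, 1000.0, 500.0, 125.0, 63.0)


def median_grain_size(fractions: dict, *, phi_scale: bool = True) -> float:
    """Median grain size D50 (µm) from sieve-fraction masses.

    ``fractions`` maps mesh size in µm (use 0 or 'pan' for the pan) to
    the retained mass. Each sieve retains grains between its own mesh
    and the next-larger one; the top sieve's upper bound and the pan's
    lower bound are taken one phi unit beyond the mesh (geometric
    doubling/halving). D50 interpolates the cumulative mass fraction
    linearly on the phi (log2) scale — the sedimentology convention —
    or on the arithmetic scale with ``phi_scale=False``.
    """
    items = []
    for mesh, mass in fractions.items():
        m = 0.0 if (isinstance(mesh, str) and mesh.lower() == "pan") else float(mesh)
        if mass < 0:
            raise ValueError("fraction masses must be >= 0")
        items.append((m, float(mass)))
    items.sort(reverse=True)  # descending mesh, pan (0) last
    total = sum(m for _, m in items)
    if total <= 0:
        raise ValueError("total sieve mass must be > 0")

    meshes = [m for m, _ in items if m > 0]
    if not meshes:
        raise ValueError("need at least one non-pan sieve")
    top_bound = meshes[0] * 2.0
    pan_lower = meshes[-1] / 2.0

    # interval bounds (upper, lower) per fraction, descending
    bounds = []
    prev_upper = top_bound
    for mesh, mass in items:
        lower = mesh if mesh > 0 else pan_lower
        bounds.append((prev_upper, lower, mass))
        prev_upper = lower

    # cumulative fraction finer than each boundary, from fine to coarse
    sizes = [bounds[-1][1]] + [b[1] for b in reversed(bounds[:-1])] + [bounds[0][0]]
    cum = [0.0]
    for _, _, mass in reversed(bounds):
        cum.append(cum[-1] + mass / total)

    def coord(d_um: float) -> float:
        return -math.log2(d_um / 1000.0) if phi_scale else d_um

    for i in range(len(cum) - 1):
        lo_c, hi_c = cum[i], cum[i + 1]
        if hi_c >= 0.5:
            d_lo, d_hi = sizes[i], sizes[i + 1]
            if hi_c == lo_c:
                continue
            frac = (0.5 - lo_c) / (hi_c - lo_c)
            c = coord(d_lo) + frac * (coord(d_hi) - coord(d_lo))
            return 2.0 ** (-c) * 1000.0 if phi_scale else c
    return sizes[-1]
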