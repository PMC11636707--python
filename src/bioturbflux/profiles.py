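"""Depth-binned luminophore profiles.

A :class:`DepthProfile` is the common currency between the tracer
simulator, the image profiler and the biodiffusion fitting stage: counts
of tracer (pixels or particles) accumulated into depth bins below the
sediment–water interface, optionally normalized to per-cm concentration
units relative to the initial tracer input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default initial tracer input N: the thickness of the first layer of
#: luminophore pixels, estimated across all incubation cores.
DEFAULT_N_INPUT = 0.94


@dataclass
class DepthProfile:
    """Binned tracer concentration versus depth for one core.

    Parameters
    ----------
    x : ndarray
        Bin centres in cm below the (smoothed) sediment surface,
        strictly increasing, non-negative.
    counts : ndarray
        Raw tracer counts per bin (pixels or particles), non-negative.
    bin_width : float
        Bin width in cm.
    t_yr : float or None
        Elapsed mixing time in years (``t_days / 365``); required for
        diffusion fitting, irrelevant for pure image extraction.
    n_input : float
        Initial tracer input N used for normalization.
    concentration : ndarray or None
        Per-cm normalized concentrations; ``None`` until
        :func:`normalize_profile` has been applied.
    n_capped : int
        Particles absorbed at the bottom of the simulated domain and
        therefore excluded from the bins (simulator bookkeeping).
    """

    x: np.ndarray
    counts: np.ndarray
    bin_width: float
    t_yr: float | None = None
    n_input: float = DEFAULT_N_INPUT
    concentration: np.ndarray | None = None
    core_id: str = ""
    view: str = ""
    n_capped: int = 0
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.concentration is not None:
            self.concentration = np.asarray(self.concentration, dtype=float)
        if self.x.shape != self.counts.shape:
            raise ValueError("x and counts must have the same shape")
        if self.x.size and (np.any(np.diff(self.x) <= 0) or self.x[0] < 0):
            raise ValueError("bin centres must be strictly increasing and >= 0")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.total_count == 0

    def same_binning(self, other: "DepthProfile") -> bool:
        return (
            self.x.shape == other.x.shape
            and np.allclose(self.x, other.x)
            and np.isclose(self.bin_width, other.bin_width)
        )

    def to_frame(self) -> pd.DataFrame:
        conc = (
            self.concentration
            if self.concentration is not None
            else np.full_like(self.counts, np.nan)
        )
        return pd.DataFrame(
            {
                "core_id": self.core_id,
                "view": self.view,
                "depth_cm": self.x,
                "count": self.counts,
                "concentration": conc,
            }
        )


def combine_views(a: DepthProfile, b: DepthProfile) -> DepthProfile:
    """Pool the two photographed faces (180°) of one core bin-wise.

    Both profiles must share identical binning; counts are summed before
    any normalization.
    """
    if not a.same_binning(b):
        raise ValueError("profiles have mismatched binning and cannot be combined")
    return replace(
        a,
        counts=a.counts + b.counts,
        concentration=None,
        view="combined",
        n_capped=a.n_capped + b.n_capped,
    )


def normalize_profile(profile: DepthProfile, n_input: float | None = None) -> DepthProfile:
    """Scale counts so that the depth-integrated concentration equals N.

    The normalized concentration satisfies ``sum(C_i) * bin_width ==
    n_input``, making C a per-cm fraction of the initial tracer input —
    the quantity the Crank plane-source model predicts. Normalization is
    invariant to uniformly rescaling the counts.
    """
    if n_input is None:
        n_input = profile.n_input
    total = profile.total_count
    if total <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    conc = profile.counts * (n_input / (total * profile.bin_width))
    return replace(profile, concentration=conc, n_input=n_input)


def profile_from_frame(df: pd.DataFrame, core_id: str, *, t_yr: float | None = None,
                       n_input: float = DEFAULT_N_INPUT, view: str = "") -> DepthProfile:
    """Build a profile from a tidy table (core_id, depth_cm, count/concentration)."""
    sub = df[df["core_id"] == core_id]
    if view and "view" in sub.columns:
        sub = sub[sub["view"] == view]
    sub = sub.sort_values("depth_cm")
    x = sub["depth_cm"].to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError(f"profile for core {core_id!r} has fewer than 2 bins")
    widths = np.diff(x)
    if not np.allclose(widths, widths[0]):
        raise ValueError(f"profile for core {core_id!r} has uneven bins")
    counts = (
        sub["count"].to_numpy(dtype=float)
        if "count" in sub.columns
        else np.zeros_like(x)
    )
    prof = DepthProfile(
        x=x, counts=counts, bin_width=float(widths[0]), t_yr=t_yr,
        n_input=n_input, core_id=core_id, view=view,
    )
    if "concentration" in sub.columns and sub["concentration"].notna().all():
        prof.concentration = sub["concentration"].to_numpy(dtype=float)
    return prof
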