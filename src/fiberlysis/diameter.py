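"""Fiber-diameter analysis: apparent diameters from fluorescence profiles,
diameter scaling, regression, and matching degradation fractions to a fixed
experimental cleavage-time-vs-diameter slope.

Fluorescence microscopy cannot resolve true fiber diameters below the
diffraction limit, so a fiber's "apparent diameter" is defined as four times
the standard deviation of a Gaussian fit to a background-subtracted 1D
intensity profile taken perpendicular to the fiber (4*sigma covers 95.4% of
the intensity). Apparent diameters are relative quantities; cohorts are
compared after dividing by the apparent diameter of the second-smallest
fiber. The model-side counterpart scales simulated diameters by the thinnest
simulated fiber (72.7 nm), which then sits at scaled diameter 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .ensemble import fraction_sweep
from .geometry import FiberSpec
from .ssa import RateSet

__all__ = [
    "IntensityProfile",
    "FiberMeasurement",
    "apparent_diameter",
    "scale_diameters",
    "ols_fit",
    "match_fractions",
    "make_profile_fixture",
    "model_time_table",
    "REFERENCE_MODEL_DIAMETER_NM",
    "MODEL_DIAMETERS_NM",
]

#: Thinnest simulated fiber; model diameters are scaled by this value.
REFERENCE_MODEL_DIAMETER_NM = 72.7

#: The nine simulated fiber diameters (nm).
MODEL_DIAMETERS_NM = (72.7, 93.5, 114.3, 124.6, 145.4, 176.6, 197.3, 218.1, 280.4)


@dataclass(frozen=True)
class IntensityProfile:
    """A 1D fluorescence intensity profile across a fiber."""

    positions_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_nm, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.size != inten.size:
            raise ValueError("positions and intensities must have equal length")
        if pos.size < 5:
            raise ValueError("need at least 5 samples")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "positions_nm", pos)
        object.__setattr__(self, "intensities", inten)


@dataclass(frozen=True)
class FiberMeasurement:
    """One fiber: its apparent diameter, scaled diameter, and cleavage time."""

    apparent_diameter_nm: float
    cleavage_time_s: float
    scaled_diameter: Optional[float] = None
    fiber_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.apparent_diameter_nm > 0:
            raise ValueError("apparent_diameter_nm must be > 0")


def _gaussian_offset(x, amplitude, center, sigma, background):
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2)) + background


def apparent_diameter(profile: IntensityProfile) -> float:
    """Apparent fiber diameter: 4x the sigma of a Gaussian profile fit.

    Fits amplitude * exp(-(x-mu)^2 / 2 sigma^2) + c by least squares with the
    constant background c estimated jointly (equivalent to subtracting a
    constant background first, and robust when it is only approximately
    known). Raises ``RuntimeError`` on non-convergence and ``ValueError``
    on a degenerate fit.
    """
    x = profile.positions_nm
    y = profile.intensities
    bg0 = float(np.min(y))
    amp0 = float(np.max(y) - bg0)
    if amp0 <= 0:
        raise ValueError("no signal above background")
    center0 = float(x[np.argmax(y)])
    # Moment-based sigma start from background-subtracted weights.
    w = np.clip(y - bg0, 0, None)
    sigma0 = float(np.sqrt(np.sum(w * (x - center0) ** 2) / np.sum(w)))
    if not sigma0 > 0:
        sigma0 = (x[-1] - x[0]) / 6.0
    popt, _ = curve_fit(
        _gaussian_offset,
        x,
        y,
        p0=(amp0, center0, sigma0, bg0),
        maxfev=10_000,
    )
    amplitude, _center, sigma, _bg = popt
    sigma = abs(float(sigma))
    if not np.isfinite(sigma) or sigma <= 0 or amplitude <= 0:
        raise ValueError("degenerate Gaussian fit")
    return 4.0 * sigma


def scale_diameters(
    measurements: Sequence[FiberMeasurement],
) -> list[FiberMeasurement]:
    """Scale apparent diameters by the second-smallest fiber's diameter.

    The second-smallest fiber gets scaled diameter 1.0; the smallest may fall
    below 1.0 (an outlier-robust reference, since the very thinnest measured
    fiber can sit far below the rest of the cohort).
    """
    if len(measurements) < 2:
        raise ValueError("need at least 2 fibers to scale")
    ref = sorted(m.apparent_diameter_nm for m in measurements)[1]
    return [
        replace(m, scaled_diameter=m.apparent_diameter_nm / ref)
        for m in measurements
    ]


def ols_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least-squares line y = slope * x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x values are degenerate (all equal)")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def match_fractions(
    median_times: pd.DataFrame,
    slope: float,
    anchor: tuple[float, float],
) -> pd.DataFrame:
    """Degradation fraction per diameter matching a fixed time-vs-diameter line.

    ``median_times`` is a table of median first-crossing times (s), indexed
    by degradation fraction (ascending), one column per scaled diameter; NaN
    marks fractions a diameter never reached. A line of the given ``slope``
    is anchored at ``anchor = (scaled_diameter, fraction)``, i.e. it passes
    through that diameter's median time at that fraction. For each diameter
    the returned frame gives the fraction whose median time equals the line's
    value there (linear interpolation between tabulated fractions), plus
    whether the line's value fell inside the diameter's reachable time range
    (outside, the fraction is clamped to the nearest endpoint and flagged).
    """
    d_anchor, f_anchor = anchor
    if median_times.empty:
        raise ValueError("empty median-time table")
    if d_anchor not in median_times.columns:
        raise ValueError(f"anchor diameter {d_anchor} not in table columns")
    col = median_times[d_anchor].dropna()
    if f_anchor not in col.index:
        raise ValueError(f"anchor fraction {f_anchor} not reached at {d_anchor}")
    t_anchor = float(col.loc[f_anchor])
    rows = []
    for d in median_times.columns:
        target = t_anchor + slope * (float(d) - float(d_anchor))
        series = median_times[d].dropna()
        fracs = series.index.to_numpy(dtype=float)
        times = series.to_numpy(dtype=float)
        # Median first-crossing times are nondecreasing in fraction; enforce
        # monotonicity against ties so interpolation inverts cleanly.
        times = np.maximum.accumulate(times)
        in_range = bool(times[0] <= target <= times[-1])
        matched = float(np.interp(target, times, fracs))
        rows.append(
            {
                "scaled_diameter": float(d),
                "target_time_s": target,
                "matched_fraction": matched,
                "in_range": in_range,
            }
        )
    return pd.DataFrame(rows)


def make_profile_fixture(
    true_sigma_nm: float = 25.0,
    amplitude: float = 1000.0,
    background: float = 100.0,
    noise_sd: float = 0.0,
    n_points: int = 101,
    span_nm: float = 400.0,
    seed: int = 0,
    center_nm: Optional[float] = None,
) -> IntensityProfile:
    """Synthetic fluorescence profile: Gaussian fiber + background + noise.

    A stand-in generator for microscopy line profiles: a Gaussian of the
    given sigma and amplitude over a constant background, with i.i.d.
    Gaussian noise of standard deviation ``noise_sd``. Seeded and
    reproducible.
    """
    if not true_sigma_nm > 0:
        raise ValueError("true_sigma_nm must be > 0")
    rng = np.random.default_rng(seed)
    x = np.linspace(-span_nm / 2.0, span_nm / 2.0, n_points)
    c = 0.0 if center_nm is None else center_nm
    y = _gaussian_offset(x, amplitude, c, true_sigma_nm, background)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_points)
    return IntensityProfile(positions_nm=x, intensities=y)


def model_time_table(
    rates: RateSet = RateSet(),
    diameters_nm: Sequence[float] = MODEL_DIAMETERS_NM,
    n_runs: int = 10_000,
    master_seed: int = 0,
    fractions: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Median first-crossing times for each simulated diameter and fraction.

    Runs a no-early-stop fraction sweep per diameter and pivots to the
    fraction x scaled-diameter table :func:`match_fractions` consumes.
    Scaled diameter is diameter / 72.7 (the thinnest simulated fiber).
    """
    cols = {}
    for i, d in enumerate(diameters_nm):
        df = fraction_sweep(
            FiberSpec(d), rates, n_runs=n_runs, master_seed=master_seed + i
        )
        s = pd.Series(df["median_s"].to_numpy(), index=df["fraction"])
        if fractions is not None:
            s = s.loc[[f for f in fractions if f in s.index]]
        cols[round(d / REFERENCE_MODEL_DIAMETER_NM, 6)] = s
    table = pd.DataFrame(cols)
    table.index.name = "fraction"
    return table
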