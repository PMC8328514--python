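"""Western-blot lane densitometry.

A lane intensity profile (position along the lane vs densitometric
intensity) is background-subtracted, monomer and dimer bands are
integrated over user-supplied windows, and the dimer level is expressed
relative to the monomer band — the same monomer-equivalent convention as
the SEC analysis, so blot- and chromatography-derived dimer levels are
directly comparable (e.g. before/after reduction with TCEP).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .chromatography import _flank_anchor
from .errors import DegenerateInputError, ParseError, UndefinedRatioError, ValidationError

__all__ = [
    "LaneProfile",
    "BandQuant",
    "read_lane_profile",
    "subtract_profile_background",
    "quantify_bands",
    "ladder_to_kda",
]


@dataclass
class LaneProfile:
    """Position (pixels or mm, strictly increasing) vs intensity along one
    gel/blot lane; optional ladder calibration points (position, kDa)."""

    position: np.ndarray
    intensity: np.ndarray
    lane_label: str = ""
    ladder: list[tuple[float, float]] | None = None
    background_subtracted: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position.shape != self.intensity.shape:
            raise ValidationError("position and intensity lengths differ")
        if np.any(np.diff(self.position) <= 0):
            raise ValidationError("position must be strictly increasing")
        if self.background_subtracted and np.any(self.intensity < -1e-9):
            raise ValidationError("negative intensity after background subtraction")


@dataclass(frozen=True)
class BandQuant:
    """Integrated band areas and the monomer-equivalent dimer level."""

    monomer_window: tuple[float, float]
    dimer_window: tuple[float, float]
    monomer_area: float
    dimer_area: float

    @property
    def dimer_level(self) -> float:
        return self.dimer_area / self.monomer_area


def read_lane_profile(path: str | Path, lane_label: str | None = None) -> LaneProfile:
    """Two-column (position, intensity) CSV with optional header."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    try:
        float(str(df.columns[0]))
        df = pd.read_csv(path, header=None, comment="#")
    except ValueError:
        pass
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns")
    sub = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    if sub.isna().any(axis=None):
        line = int(np.flatnonzero(sub.isna().any(axis=1).to_numpy())[0]) + 2
        raise ParseError(f"{path}: malformed row at line {line}")
    return LaneProfile(sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy(),
                       lane_label=lane_label or path.stem)


def subtract_profile_background(
    profile: LaneProfile,
    method: str = "linear",
    window_fraction: float = 0.3,
) -> LaneProfile:
    """Remove the slowly varying lane background.

    ``linear`` (default) interpolates a straight line between noise-robust
    flank anchors, which is exact for offset and drift backgrounds.
    ``rolling_min`` subtracts a morphological opening (rolling minimum then
    rolling maximum; the window, a fraction of the lane length, must be
    wider than any band) and can follow a curved background, at the cost
    of a small bias under the bands when the background also drifts.
    """
    y = profile.intensity
    if float(np.ptp(y)) <= 1e-12 * (1.0 + abs(float(np.mean(y)))):
        raise DegenerateInputError("constant or all-zero lane profile")
    n = len(y)
    if method == "rolling_min":
        w = max(3, int(round(window_fraction * n)))
        base = maximum_filter1d(minimum_filter1d(y, size=w, mode="nearest"),
                                size=w, mode="nearest")
        base = np.minimum(base, y)
    elif method == "linear":
        k = max(3, n // 20)
        x = profile.position
        y_l = _flank_anchor(x[:k], y[:k])
        y_r = _flank_anchor(x[-k:], y[-k:])
        x_l, x_r = float(np.median(x[:k])), float(np.median(x[-k:]))
        base = y_l + (y_r - y_l) / (x_r - x_l) * (x - x_l)
        base = np.minimum(base, y)
    else:
        raise ValidationError(f"unknown background method {method!r}")
    return LaneProfile(profile.position.copy(), y - base,
                       lane_label=profile.lane_label, ladder=profile.ladder,
                       background_subtracted=True)


def quantify_bands(
    profile: LaneProfile,
    monomer_window: tuple[float, float],
    dimer_window: tuple[float, float],
) -> BandQuant:
    """Trapezoidal band areas over the two windows and their ratio.

    Windows are (lo, hi) position ranges; they must lie inside the profile
    and must not overlap.  The dimer level is dimer area / monomer area.
    """
    x = profile.position
    for name, (lo, hi) in (("monomer", monomer_window), ("dimer", dimer_window)):
        if lo >= hi:
            raise ValidationError(f"{name} window is empty")
        if lo < x[0] or hi > x[-1]:
            raise ValidationError(f"{name} window outside profile range")
    m_lo, m_hi = monomer_window
    d_lo, d_hi = dimer_window
    if max(m_lo, d_lo) < min(m_hi, d_hi):
        raise ValidationError("monomer and dimer windows overlap")

    def window_area(lo: float, hi: float) -> float:
        m = (x >= lo) & (x <= hi)
        if m.sum() < 2:
            raise ValidationError("window contains fewer than 2 samples")
        return float(np.trapezoid(profile.intensity[m], x[m]))

    m_area = window_area(m_lo, m_hi)
    d_area = window_area(d_lo, d_hi)
    if m_area <= 0:
        raise UndefinedRatioError("monomer band area is zero; dimer level undefined")
    return BandQuant(monomer_window, dimer_window, m_area, d_area)


def ladder_to_kda(profile: LaneProfile, position: float) -> float:
    """Apparent molecular weight at a lane position by monotone log-linear
    interpolation of the ladder.  Labeling aid only; never enters
    quantification."""
    if not profile.ladder or len(profile.ladder) < 2:
        raise ValidationError("ladder needs at least two calibration points")
    pts = sorted(profile.ladder)
    xs = np.array([p for p, _ in pts])
    logk = np.log([k for _, k in pts])
    return float(np.exp(np.interp(position, xs, logk)))
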