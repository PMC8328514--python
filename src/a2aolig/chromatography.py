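"""SEC trace deconvolution and the monomer-equivalent oligomer level.

A size-exclusion chromatogram of a receptor preparation resolves, in
elution order, high-molecular-weight (HMW) oligomer, dimer, and monomer.
The pipeline is:

1. baseline correction (linear anchor or asymmetric least squares),
2. least-squares fit of a sum of Gaussians (lmfit),
3. mapping of fitted peaks onto species (ordinal elution rule, or
   calibrated elution windows),
4. the oligomer-level statistic: each oligomeric species' integrated area
   divided by the monomer area, with 95% confidence intervals propagated
   from the fit covariance by the delta method.

Levels are dimensionless monomer-equivalent concentration ratios; they are
invariant under rescaling of the absorbance axis and shifting of the
elution axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit.models import GaussianModel
from scipy import signal, sparse
from scipy.sparse.linalg import spsolve

from .errors import (
    DegenerateInputError,
    FitFailureError,
    ParseError,
    UndefinedRatioError,
    ValidationError,
)

__all__ = [
    "Chromatogram",
    "GaussianPeak",
    "PeakFit",
    "Species",
    "SpeciesAssignment",
    "OligomerLevels",
    "read_chromatogram",
    "write_chromatogram",
    "correct_baseline",
    "fit_peaks",
    "assign_species",
    "compute_levels",
    "sec_levels",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)
Z_95 = 1.959963984540054  # two-sided 95% normal quantile


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------

@dataclass
class Chromatogram:
    """An elution trace: strictly increasing elution coordinate (mL or s)
    vs A280 absorbance."""

    elution: np.ndarray
    absorbance: np.ndarray
    label: str = ""
    units: str = "mL"
    baseline_corrected: bool = False

    def __post_init__(self):
        self.elution = np.asarray(self.elution, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.elution.ndim != 1 or self.absorbance.ndim != 1:
            raise ValidationError("elution and absorbance must be 1-D")
        if len(self.elution) != len(self.absorbance):
            raise ValidationError("elution and absorbance lengths differ")
        if len(self.elution) < 10:
            raise ValidationError("chromatogram shorter than 10 points")
        if not np.all(np.isfinite(self.elution)) or not np.all(np.isfinite(self.absorbance)):
            raise ValidationError("non-finite values in chromatogram")
        if np.any(np.diff(self.elution) <= 0):
            raise ValidationError("elution coordinate must be strictly increasing")

    def __len__(self) -> int:
        return len(self.elution)


@dataclass(frozen=True)
class GaussianPeak:
    """One fitted Gaussian component.  ``amplitude`` is the peak height in
    absorbance units; ``area = amplitude * sigma * sqrt(2*pi)``."""

    amplitude: float
    center: float
    sigma: float

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * SQRT_2PI

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((np.asarray(x) - self.center) / self.sigma) ** 2)


@dataclass
class PeakFit:
    """A multi-Gaussian fit: peaks sorted by center, the covariance of the
    area parameters, and goodness of fit."""

    peaks: list[GaussianPeak]
    area_covariance: np.ndarray  # covariance of per-peak areas, peak order
    r_squared: float
    window: tuple[float, float] | None = None
    residual: np.ndarray | None = None
    chromatogram: Chromatogram | None = None

    def __post_init__(self):
        centers = [p.center for p in self.peaks]
        if centers != sorted(centers):
            raise ValidationError("peaks must be sorted by center")
        C = np.asarray(self.area_covariance, dtype=float)
        if C.shape != (len(self.peaks), len(self.peaks)):
            raise ValidationError("area covariance shape mismatch")
        if not np.allclose(C, C.T, atol=1e-10 * (1 + np.abs(C).max())):
            raise ValidationError("covariance not symmetric")
        self.area_covariance = 0.5 * (C + C.T)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks])

    def model(self, x: np.ndarray) -> np.ndarray:
        return np.sum([p(x) for p in self.peaks], axis=0)


class Species(str, Enum):
    HMW = "HMW"
    DIMER = "DIMER"
    MONOMER = "MONOMER"


#: elution order on a size-exclusion column: larger species elute earlier
SPECIES_ORDER = (Species.HMW, Species.DIMER, Species.MONOMER)


@dataclass
class SpeciesAssignment:
    """Fitted peaks mapped onto oligomeric species, with pooled areas and
    the covariance of the three species areas (HMW, DIMER, MONOMER)."""

    mapping: dict[Species, frozenset[int]]
    areas: dict[Species, float]
    area_se: dict[Species, float]
    species_covariance: np.ndarray  # 3x3, order SPECIES_ORDER
    unassigned: frozenset[int] = frozenset()

    def __post_init__(self):
        all_idx: list[int] = []
        for s in SPECIES_ORDER:
            all_idx.extend(self.mapping.get(s, frozenset()))
        if len(all_idx) != len(set(all_idx)):
            raise ValidationError("peak index sets are not disjoint")


@dataclass(frozen=True)
class OligomerLevels:
    """The headline statistic: oligomeric areas relative to the monomer
    area, with half-widths of 95% confidence intervals from the fit
    covariance (fit variance only, not experimental replication)."""

    dimer_level: float
    hmw_level: float
    dimer_ci95: float
    hmw_ci95: float
    total_ci95: float
    label: str = ""

    @property
    def total_level(self) -> float:
        return self.dimer_level + self.hmw_level


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_chromatogram(
    path: str | Path,
    label: str | None = None,
    delimiter: str = ",",
    decimal: str = ".",
    units: str = "mL",
) -> Chromatogram:
    """Read a two-column (elution, absorbance) CSV, with or without a
    one-line header."""
    path = Path(path)
    try:
        df = pd.read_csv(path, delimiter=delimiter, decimal=decimal, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    # headerless files come back with numeric-looking column names
    try:
        float(str(df.columns[0]))
        df = pd.read_csv(path, delimiter=delimiter, decimal=decimal,
                         header=None, comment="#")
    except ValueError:
        pass
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns, found {df.shape[1]}")
    sub = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
        raise ParseError(f"{path}: malformed row at line {line}")
    return Chromatogram(sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy(),
                        label=label or path.stem, units=units)


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    """Write the trace as a two-column CSV with an ``elution,absorbance``
    header (the format ``read_chromatogram`` consumes)."""
    pd.DataFrame({"elution": chrom.elution, "absorbance": chrom.absorbance}).to_csv(
        path, index=False, float_format="%.10g"
    )


# --------------------------------------------------------------------------
# baseline correction
# --------------------------------------------------------------------------

def _flank_anchor(x: np.ndarray, y: np.ndarray) -> float:
    # Anchor on the 5th percentile of the *detrended* flank (robust to a
    # peak tail leaking in), then correct the percentile's noise bias:
    # under pure Gaussian noise p5 sits 1.645 sigma below the baseline.
    # Slope and noise both come from first differences, which a slow drift
    # or a partial peak tail barely perturbs.
    half = len(y) // 2
    x1m, x2m = float(np.median(x[:half])), float(np.median(x[half:]))
    slope = (float(np.median(y[half:])) - float(np.median(y[:half]))) / (x2m - x1m)
    detrended = y - slope * (x - float(np.median(x)))
    sigma = float(np.std(np.diff(y))) / math.sqrt(2.0)
    return float(np.percentile(detrended, 5.0)) + 1.6449 * sigma


def _linear_baseline(x: np.ndarray, y: np.ndarray, flank_fraction: float) -> np.ndarray:
    n = len(x)
    k = max(3, int(round(flank_fraction * n)))
    left, right = slice(0, k), slice(n - k, n)
    y_l, y_r = _flank_anchor(x[left], y[left]), _flank_anchor(x[right], y[right])
    x_l, x_r = float(np.median(x[left])), float(np.median(x[right]))
    slope = (y_r - y_l) / (x_r - x_l)
    return y_l + slope * (x - x_l)


def _als_baseline(y: np.ndarray, lam: float, p: float, n_iter: int = 10) -> np.ndarray:
    """Asymmetric least squares (Eilers & Boelens): iteratively reweighted
    smooth baseline that hugs the signal from below."""
    n = len(y)
    D = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    DDT = lam * (D @ D.T)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        W = sparse.diags(w)
        z = spsolve((W + DDT).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def correct_baseline(
    chrom: Chromatogram,
    method: str = "linear",
    flank_fraction: float = 0.05,
    lam: float = 1e10,
    p: float = 0.001,
) -> Chromatogram:
    """Subtract a slowly varying baseline so that fitting and integration
    are uniform across the peaks.

    ``method='linear'`` anchors a straight line on the 5th-percentile
    signal of the two flanking windows (``flank_fraction`` of the trace
    each); ``method='als'`` uses iterative asymmetric least squares.
    Re-correcting an already corrected trace is permitted and is close to
    a no-op.
    """
    y = chrom.absorbance
    if float(np.ptp(y)) <= 1e-12 * (1.0 + abs(float(np.mean(y)))):
        raise DegenerateInputError("constant or all-zero trace has no peaks to correct")
    if method == "linear":
        base = _linear_baseline(chrom.elution, y, flank_fraction)
    elif method == "als":
        base = _als_baseline(y, lam=lam, p=p)
    else:
        raise ValidationError(f"unknown baseline method {method!r}")
    return Chromatogram(chrom.elution.copy(), y - base, label=chrom.label,
                        units=chrom.units, baseline_corrected=True)


# --------------------------------------------------------------------------
# multi-Gaussian fitting
# --------------------------------------------------------------------------

def _initial_guesses(x: np.ndarray, y: np.ndarray, n_peaks: int):
    """Peak-candidate centers from local maxima of a Savitzky–Golay
    smoothed trace; amplitudes from trace height, sigma from half width at
    half maximum."""
    n = len(x)
    win = max(5, (n // 50) | 1)
    ys = signal.savgol_filter(y, window_length=min(win, n - (n + 1) % 2), polyorder=2)
    span = float(np.ptp(ys))
    idx, props = signal.find_peaks(ys, prominence=0.02 * span)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(ys))])
        props = {"prominences": np.array([span])}
    order = np.argsort(props["prominences"])[::-1]
    idx = idx[order][:n_peaks]
    idx = np.sort(idx)
    guesses = []
    dx = float(np.mean(np.diff(x)))
    for i in idx:
        amp = max(ys[i], 1e-3 * span)
        # half-width at half maximum on the smoothed trace
        half = amp / 2.0
        j = i
        while j + 1 < n and ys[j] > half:
            j += 1
        k = i
        while k - 1 >= 0 and ys[k] > half:
            k -= 1
        hwhm = max(0.5 * (x[j] - x[k]), 2 * dx)
        guesses.append((float(amp), float(x[i]), float(hwhm / 1.1774)))  # HWHM -> sigma
    return guesses


def fit_peaks(
    chrom: Chromatogram,
    n_peaks: int = 3,
    init: list[tuple[float, float, float]] | None = None,
    window: tuple[float, float] | None = None,
    fixed_sigma: list[float] | None = None,
    shared_sigma: bool = False,
    max_restarts: int = 5,
    seed: int = 0,
) -> PeakFit:
    """Least-squares fit of a sum of ``n_peaks`` Gaussians.

    ``init`` optionally supplies (amplitude, center, sigma) triples;
    otherwise centers come from local maxima of a smoothed trace.
    ``window`` restricts the fit to an elution sub-range and ``fixed_sigma``
    pins each component's width — together these mirror the manual
    area/width definition used for low-SNR traces.  ``shared_sigma`` ties
    all widths to a single parameter.  The fit is deterministic for a given
    input, initialization and ``seed`` (the seed only drives the jittered
    restarts taken on non-convergence).
    """
    if not chrom.baseline_corrected:
        raise ValidationError("fit requires a baseline-corrected chromatogram")
    if not 1 <= n_peaks <= 6:
        raise ValidationError("n_peaks must be in 1..6")

    x, y = chrom.elution, chrom.absorbance
    if window is not None:
        lo, hi = window
        m = (x >= lo) & (x <= hi)
        if m.sum() < 10:
            raise ValidationError("fit window contains fewer than 10 points")
        x, y = x[m], y[m]

    if init is None:
        guesses = _initial_guesses(x, y, n_peaks)
        if len(guesses) < n_peaks:
            warnings.warn(
                f"requested {n_peaks} peaks but only {len(guesses)} detected; "
                "falling back to detected count",
                stacklevel=2,
            )
            n_peaks = len(guesses)
    else:
        if len(init) != n_peaks:
            raise ValidationError("init length must equal n_peaks")
        guesses = [tuple(map(float, g)) for g in init]

    if fixed_sigma is not None and len(fixed_sigma) != n_peaks:
        raise ValidationError("fixed_sigma length must equal n_peaks")

    rng = np.random.default_rng(seed)
    x_span = float(x[-1] - x[0])
    best = None

    for attempt in range(max_restarts + 1):
        model = None
        params = None
        for i, (amp, cen, sig) in enumerate(guesses):
            if attempt > 0:
                cen = cen + rng.normal(0.0, 0.02 * x_span)
            g = GaussianModel(prefix=f"g{i}_")
            p = g.make_params()
            p[f"g{i}_amplitude"].set(value=max(amp * sig * SQRT_2PI, 1e-12), min=0.0)
            p[f"g{i}_center"].set(value=cen, min=float(x[0]), max=float(x[-1]))
            if fixed_sigma is not None:
                p[f"g{i}_sigma"].set(value=fixed_sigma[i], vary=False)
            elif shared_sigma and i > 0:
                p[f"g{i}_sigma"].set(expr="g0_sigma")
            else:
                p[f"g{i}_sigma"].set(value=sig, min=1e-6 * x_span, max=x_span)
            model = g if model is None else model + g
            params = p if params is None else params.update(p) or params
        result = model.fit(y, params, x=x)
        ss_res = float(np.sum(result.residual**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if best is None or ss_res < best[1]:
            best = (result, ss_res, r2)
        if result.success and (result.covar is not None or result.nvarys == 0):
            best = (result, ss_res, r2)
            break
    else:
        result, ss_res, r2 = best
        if not result.success:
            raise FitFailureError(
                f"fit did not converge after {max_restarts} restarts",
                best_residual=math.sqrt(ss_res / len(x)),
            )
    result, ss_res, r2 = best

    # collect per-peak parameters, sorted by center
    triples = []
    for i in range(n_peaks):
        area = float(result.params[f"g{i}_amplitude"].value)  # lmfit amplitude == area
        cen = float(result.params[f"g{i}_center"].value)
        sig = float(result.params[f"g{i}_sigma"].value)
        triples.append((i, area / (sig * SQRT_2PI), cen, sig))
    order = sorted(range(n_peaks), key=lambda k: triples[k][2])

    # covariance of the per-peak *areas* (lmfit's amplitude parameters)
    cov_areas = np.zeros((n_peaks, n_peaks))
    if result.covar is not None:
        names = result.var_names
        for a, ia in enumerate(order):
            for b, ib in enumerate(order):
                na, nb = f"g{ia}_amplitude", f"g{ib}_amplitude"
                if na in names and nb in names:
                    cov_areas[a, b] = result.covar[names.index(na), names.index(nb)]

    peaks = [GaussianPeak(triples[i][1], triples[i][2], triples[i][3]) for i in order]
    return PeakFit(
        peaks=peaks,
        area_covariance=cov_areas,
        r_squared=r2,
        window=window,
        residual=np.asarray(result.residual, dtype=float),
        chromatogram=chrom,
    )


# --------------------------------------------------------------------------
# species assignment
# --------------------------------------------------------------------------

def assign_species(
    fit: PeakFit,
    policy: str = "ordinal",
    windows: dict[Species, tuple[float, float]] | None = None,
) -> SpeciesAssignment:
    """Map fitted peaks to {HMW, DIMER, MONOMER}.

    ``policy='ordinal'`` uses the elution-order rule: the last peak is the
    monomer, the one before it the dimer, and any earlier peaks pool into
    the HMW oligomer (an HMW population too broad for one Gaussian is fit
    with two).  Two peaks are read as dimer + monomer.  A single peak is
    ambiguous under this rule and requires the window policy.

    ``policy='window'`` assigns each peak to the calibrated elution window
    containing its center; a peak inside several windows raises with the
    candidate list, a peak in none is flagged unassigned.
    """
    n = len(fit.peaks)
    if n < 1:
        raise ValidationError("fit has no peaks")
    mapping: dict[Species, set[int]] = {s: set() for s in SPECIES_ORDER}
    unassigned: set[int] = set()

    if policy == "ordinal":
        if n == 1:
            raise ValidationError(
                "single-peak trace is ambiguous under the ordinal rule; "
                "use the window policy or label the species explicitly"
            )
        mapping[Species.MONOMER].add(n - 1)
        mapping[Species.DIMER].add(n - 2)
        for i in range(n - 2):
            mapping[Species.HMW].add(i)
    elif policy == "window":
        if not windows:
            raise ValidationError("window policy requires elution windows")
        for i, pk in enumerate(fit.peaks):
            hits = [s for s, (lo, hi) in windows.items() if lo <= pk.center <= hi]
            if len(hits) > 1:
                raise ValidationError(
                    f"peak {i} at {pk.center:g} straddles windows: "
                    + ", ".join(Species(h).value for h in hits)
                )
            if not hits:
                unassigned.add(i)
            else:
                mapping[Species(hits[0])].add(i)
    else:
        raise ValidationError(f"unknown assignment policy {policy!r}")

    areas_vec = fit.areas
    areas: dict[Species, float] = {}
    se: dict[Species, float] = {}
    # species areas are sums of peak areas; propagate the area covariance
    J = np.zeros((3, n))
    for r, s in enumerate(SPECIES_ORDER):
        idx = sorted(mapping[s])
        areas[s] = float(areas_vec[idx].sum()) if idx else 0.0
        J[r, idx] = 1.0
    cov3 = J @ fit.area_covariance @ J.T
    for r, s in enumerate(SPECIES_ORDER):
        se[s] = float(math.sqrt(max(cov3[r, r], 0.0)))
    return SpeciesAssignment(
        mapping={s: frozenset(v) for s, v in mapping.items()},
        areas=areas,
        area_se=se,
        species_covariance=cov3,
        unassigned=frozenset(unassigned),
    )


# --------------------------------------------------------------------------
# oligomer levels
# --------------------------------------------------------------------------

def compute_levels(assignment: SpeciesAssignment, label: str = "") -> OligomerLevels:
    """Monomer-equivalent oligomer levels with delta-method 95% CIs.

    For a ratio r = A_s / A_m the delta-method variance is

        Var(r) = Var(A_s)/A_m^2 + A_s^2 Var(A_m)/A_m^4
                 - 2 A_s Cov(A_s, A_m)/A_m^3

    evaluated from the fitted species-area covariance; the reported
    half-widths are 1.96 standard errors.  Errors reflect fit variance
    only, not experimental replication.
    """
    A = {s: assignment.areas[s] for s in SPECIES_ORDER}
    Am = A[Species.MONOMER]
    if Am <= 0:
        raise UndefinedRatioError("monomer area is zero or absent; levels undefined")
    C = assignment.species_covariance  # order HMW, DIMER, MONOMER

    def ratio_var(i_num: int) -> float:
        As = A[SPECIES_ORDER[i_num]]
        v = (C[i_num, i_num] / Am**2
             + As**2 * C[2, 2] / Am**4
             - 2.0 * As * C[i_num, 2] / Am**3)
        return max(v, 0.0)

    hmw_level = A[Species.HMW] / Am
    dimer_level = A[Species.DIMER] / Am
    # total = (A_h + A_d)/A_m: gradient (1/Am, 1/Am, -(A_h+A_d)/Am^2)
    g = np.array([1.0 / Am, 1.0 / Am, -(A[Species.HMW] + A[Species.DIMER]) / Am**2])
    total_var = max(float(g @ C @ g), 0.0)
    return OligomerLevels(
        dimer_level=dimer_level,
        hmw_level=hmw_level,
        dimer_ci95=Z_95 * math.sqrt(ratio_var(1)),
        hmw_ci95=Z_95 * math.sqrt(ratio_var(0)),
        total_ci95=Z_95 * math.sqrt(total_var),
        label=label,
    )


def sec_levels(
    chrom: Chromatogram,
    n_peaks: int = 3,
    baseline_method: str = "linear",
    policy: str = "ordinal",
    windows: dict[Species, tuple[float, float]] | None = None,
    **fit_kwargs,
) -> tuple[OligomerLevels, PeakFit]:
    """Convenience pipeline: baseline -> fit -> assign -> levels."""
    corrected = chrom if chrom.baseline_corrected else correct_baseline(chrom, baseline_method)
    fit = fit_peaks(corrected, n_peaks=n_peaks, **fit_kwargs)
    assignment = assign_species(fit, policy=policy, windows=windows)
    return compute_levels(assignment, label=chrom.label), fit
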