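"""Solution-biophysics calculators.

Ionic strength of fully dissociated buffers, Debye screening length in
aqueous electrolyte, Kyte–Doolittle hydropathy profiles, differential
scanning fluorimetry (DSF) melt-curve analysis, and turbidity-based
aggregation classification.

The Debye length

    kappa^-1 = sqrt( eps0 * eps_r(T) * kB * T / (2 * NA * e^2 * 1000 * I) )

uses the ionic strength I in mol/L and an empirical pure-water dielectric
model eps_r(T) (Malmberg & Maryott, NBS 1956), so that screening can be
evaluated at chromatography-cold-room temperatures as well as 25 degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.constants import Avogadro, Boltzmann, e as ELEMENTARY_CHARGE, epsilon_0

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "Ion",
    "DissolvedSpecies",
    "BufferComposition",
    "MeltCurve",
    "TurbiditySeries",
    "SALT_REGISTRY",
    "ionic_strength",
    "water_relative_permittivity",
    "debye_length",
    "is_screened",
    "KYTE_DOOLITTLE",
    "hydropathy_profile",
    "melt_derivative",
    "detect_melt_events",
    "classify_aggregation",
]


# --------------------------------------------------------------------------
# buffer composition and ionic strength
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Ion:
    """One ion released on dissolution: stoichiometry per formula unit and
    integer charge."""

    stoichiometry: int
    charge: int


@dataclass(frozen=True)
class DissolvedSpecies:
    name: str
    concentration_mM: float
    ions: tuple[Ion, ...]

    def __post_init__(self):
        if self.concentration_mM < 0:
            raise ValidationError(f"{self.name}: negative concentration")
        net = sum(i.stoichiometry * i.charge for i in self.ions)
        if net != 0:
            raise ValidationError(
                f"{self.name}: species not electroneutral (net charge {net})"
            )


#: Dissociation patterns for the salts used in the study's buffers.
#: Phosphates are taken as fully dissociated into the ion drawn in the
#: buffer table (H2PO4- monovalent, HPO4 2- divalent); no pKa speciation.
SALT_REGISTRY: dict[str, tuple[Ion, ...]] = {
    "NaCl": (Ion(1, +1), Ion(1, -1)),
    "KCl": (Ion(1, +1), Ion(1, -1)),
    "NaH2PO4": (Ion(1, +1), Ion(1, -1)),
    "Na2HPO4": (Ion(2, +1), Ion(1, -2)),
    "MgCl2": (Ion(1, +2), Ion(2, -1)),
    "CaCl2": (Ion(1, +2), Ion(2, -1)),
    "GdnHCl": (Ion(1, +1), Ion(1, -1)),
    "NH4OAc": (Ion(1, +1), Ion(1, -1)),
}


@dataclass
class BufferComposition:
    """A fully dissociating buffer: a list of dissolved species plus the
    working temperature."""

    species: list[DissolvedSpecies]
    temperature_C: float = 4.0
    label: str = ""

    @classmethod
    def from_components(
        cls, components: dict[str, float], temperature_C: float = 4.0, label: str = ""
    ) -> "BufferComposition":
        """Build from a ``{salt name: concentration mM}`` mapping using the
        salt registry."""
        sp = []
        for name, conc in components.items():
            if name not in SALT_REGISTRY:
                raise ValidationError(
                    f"unknown salt {name!r}; supply DissolvedSpecies explicitly"
                )
            sp.append(DissolvedSpecies(name, float(conc), SALT_REGISTRY[name]))
        return cls(sp, temperature_C=temperature_C, label=label)


def ionic_strength(buffer: BufferComposition) -> float:
    """Ionic strength I = 1/2 * sum_i c_i z_i^2 in mM, assuming full
    dissociation of every species."""
    total = 0.0
    for sp in buffer.species:
        for ion in sp.ions:
            c = sp.concentration_mM * ion.stoichiometry
            total += c * ion.charge**2
    return 0.5 * total


# --------------------------------------------------------------------------
# Debye screening
# --------------------------------------------------------------------------

def water_relative_permittivity(T_K: float) -> float:
    """Static relative permittivity of pure water (Malmberg & Maryott),
    valid 0-100 degC."""
    t = T_K - 273.15
    if not -5.0 <= t <= 105.0:
        raise ValidationError(f"water dielectric model out of range: {t:.1f} degC")
    return 87.740 - 0.40008 * t + 9.398e-4 * t**2 - 1.410e-6 * t**3


def debye_length(I_molar: float, T_K: float = 277.15, eps_r: float | None = None) -> float:
    """Debye screening length in angstrom for ionic strength ``I_molar``
    (mol/L) at temperature ``T_K``.

    ``eps_r`` overrides the pure-water dielectric model with a constant.
    """
    if I_molar <= 0:
        raise ValidationError("ionic strength must be positive")
    if not 273.0 <= T_K <= 373.0:
        raise ValidationError("temperature outside 273-373 K")
    er = water_relative_permittivity(T_K) if eps_r is None else eps_r
    I_m3 = I_molar * 1e3  # mol/L -> mol/m^3
    kappa_sq = 2 * Avogadro * ELEMENTARY_CHARGE**2 * I_m3 / (epsilon_0 * er * Boltzmann * T_K)
    return 1e10 / math.sqrt(kappa_sq)


def is_screened(distance_A: float, I_molar: float, T_K: float = 277.15) -> bool:
    """True iff an electrostatic interaction at ``distance_A`` angstrom is
    longer than the Debye length (strict inequality)."""
    return distance_A > debye_length(I_molar, T_K)


# --------------------------------------------------------------------------
# hydropathy
# --------------------------------------------------------------------------

#: Kyte & Doolittle (1982) per-residue hydropathy values.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def hydropathy_profile(sequence: str, window: int = 3) -> np.ndarray:
    """Sliding-window mean Kyte–Doolittle hydropathy.

    Returns one value per full window, i.e. positions ``window//2`` through
    ``len(sequence) - window//2 - 1``; flanking positions without a complete
    window are omitted.
    """
    if window % 2 == 0 or window < 1:
        raise ValidationError("window must be odd and positive")
    if window > len(sequence):
        raise ValidationError("window longer than sequence")
    vals = np.empty(len(sequence))
    for i, aa in enumerate(sequence.upper()):
        try:
            vals[i] = KYTE_DOOLITTLE[aa]
        except KeyError:
            raise ValidationError(f"unknown residue {aa!r} at position {i + 1}") from None
    kernel = np.ones(window) / window
    return np.convolve(vals, kernel, mode="valid")


# --------------------------------------------------------------------------
# DSF melt curves
# --------------------------------------------------------------------------

@dataclass
class MeltCurve:
    """A DSF trace: temperature ramp vs dye fluorescence, with an optional
    first derivative dRFU/dT."""

    temperature_C: np.ndarray
    fluorescence: np.ndarray
    derivative: np.ndarray | None = None
    label: str = ""
    smoothing: int = 1  # moving-average width used to form the derivative

    def __post_init__(self):
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature_C.shape != self.fluorescence.shape:
            raise ValidationError("temperature and fluorescence lengths differ")
        if np.any(np.diff(self.temperature_C) <= 0):
            raise ValidationError("temperature must be strictly increasing")


def melt_derivative(curve: MeltCurve, smooth_points: int = 5) -> MeltCurve:
    """First derivative of the fluorescence curve.

    Fluorescence is smoothed with a centered moving average over
    ``smooth_points`` samples (1 disables smoothing) before differencing;
    central differences interior, one-sided at the endpoints.
    """
    if len(curve.temperature_C) < 5:
        raise ValidationError("need at least 5 points")
    f = curve.fluorescence
    if smooth_points > 1:
        k = np.ones(smooth_points) / smooth_points
        pad = smooth_points // 2
        # odd reflection continues the local trend, so a linear curve stays
        # exactly linear through the smoothing window at the endpoints
        fp = np.pad(f, pad, mode="reflect", reflect_type="odd")
        f = np.convolve(fp, k, mode="valid")
    deriv = np.gradient(f, curve.temperature_C)
    return MeltCurve(curve.temperature_C.copy(), curve.fluorescence.copy(),
                     derivative=deriv, label=curve.label,
                     smoothing=max(smooth_points, 1))


def detect_melt_events(
    curve: MeltCurve,
    min_prominence: float = 0.05,
    quench_fraction: float = 0.2,
    quench_run: int = 3,
) -> tuple[float | None, float | None]:
    """Locate the melting transition and any aggregation quench.

    Tm is the temperature of the global derivative maximum, provided that
    maximum exceeds ``min_prominence`` times the fluorescence dynamic range
    per degC.  The quench onset is the first temperature after Tm where the
    derivative stays below ``-quench_fraction * max derivative`` for at
    least ``quench_run`` consecutive samples.  Either event may be absent
    (returned as None).
    """
    if curve.derivative is None:
        raise ValidationError("curve carries no derivative; run melt_derivative first")
    d = curve.derivative
    T = curve.temperature_C
    span = float(np.ptp(curve.fluorescence))
    if span == 0:
        return None, None
    i_max = int(np.argmax(d))
    scale = span / (T[-1] - T[0])
    if d[i_max] < min_prominence * scale:
        return None, None
    tm = float(T[i_max])

    thresh = -quench_fraction * d[i_max]
    below = d < thresh
    quench_T = None
    # a width-w moving average pulls an onset edge (w-1)/2 samples early;
    # compensate so the reported onset is on the unsmoothed curve's scale
    pad = (curve.smoothing - 1) // 2
    for i in range(i_max + 1, len(T) - quench_run + 1):
        if below[i : i + quench_run].all():
            quench_T = float(T[min(i + pad, len(T) - 1)])
            break
    return tm, quench_T


# --------------------------------------------------------------------------
# turbidity
# --------------------------------------------------------------------------

@dataclass
class TurbiditySeries:
    """A450 turbidity readings across ionic-strength conditions for a
    single salt."""

    ionic_strength_M: np.ndarray
    a450: np.ndarray
    salt: str = "NaCl"
    label: str = ""

    def __post_init__(self):
        self.ionic_strength_M = np.asarray(self.ionic_strength_M, dtype=float)
        self.a450 = np.asarray(self.a450, dtype=float)
        if self.ionic_strength_M.shape != self.a450.shape:
            raise ValidationError("condition and reading lengths differ")
        if np.any(np.diff(self.ionic_strength_M) < 0):
            raise ValidationError("conditions must be sorted ascending")
        if np.any(self.a450 < 0):
            raise ValidationError("negative A450 reading")


def classify_aggregation(
    series: TurbiditySeries,
    slight_threshold: float = 0.05,
    aggregated_threshold: float = 0.3,
) -> list[str]:
    """Map each A450 reading to {'soluble', 'slight', 'aggregated'} by a
    two-level threshold; the state is monotone non-decreasing in A450."""
    if len(series.a450) < 1:
        raise DegenerateInputError("empty turbidity series")
    if not 0 <= slight_threshold <= aggregated_threshold:
        raise ValidationError("thresholds must satisfy 0 <= slight <= aggregated")
    out = []
    for a in series.a450:
        if a >= aggregated_threshold:
            out.append("aggregated")
        elif a >= slight_threshold:
            out.append("slight")
        else:
            out.append("soluble")
    return out
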