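"""Seeded synthetic-data generators.

Every generator is a pure function of (seed, parameters) and returns the
domain object together with a :class:`GroundTruth` manifest recording all
planted quantities — areas and implied oligomer levels, band areas,
contact pairs, tilt angles, cluster membership, melt temperatures — so
each analysis stage can be checked against an analytic oracle.

The defaults emulate the study conditions: a Superdex-200-style trace with
HMW oligomer, dimer, and monomer eluting in that order (the wild-type
receptor preset plants a dimer level of 1.14 and a total oligomer level of
1.34); two-band blot lanes; two-protomer scaffolds with planted contacts;
a rising DSF sigmoid whose melt peak is quenched near 65 degC.  Scaffold
protomers are labeled point clouds (idealized helices plus a disordered
tail), not physical receptors — only the geometric predicates are under
test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chromatography import SQRT_2PI, Chromatogram
from .densitometry import LaneProfile
from .errors import GenerationError, ValidationError
from .interface_analysis import (
    DimerConfiguration,
    ProtomerModel,
    Residue,
    Site,
    SiteClass,
)
from .solution import MeltCurve, TurbiditySeries
from .structure_io import DEFAULT_REGIONS

__all__ = [
    "GroundTruth",
    "SEC_STUDY_PRESETS",
    "gen_chromatogram",
    "gen_lane_profile",
    "PlannedContact",
    "gen_dimer_configuration",
    "gen_dimer_frames",
    "gen_melt_curve",
    "gen_turbidity_series",
]


@dataclass
class GroundTruth:
    """Manifest of every planted parameter of one synthetic dataset."""

    manifest: dict

    def __getitem__(self, key):
        return self.manifest[key]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest, indent=2, sort_keys=True,
                                         default=_jsonable))


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


# --------------------------------------------------------------------------
# chromatograms
# --------------------------------------------------------------------------

#: Printed oligomer levels of the receptor variants whose raw traces the
#: study deposited; used as planted levels when emulating those samples
#: (monomer area normalised to 1).
SEC_STUDY_PRESETS: dict[str, dict[str, float]] = {
    "WT": {"dimer_level": 1.14, "hmw_level": 0.20},
    "N359dC": {"dimer_level": 0.81, "hmw_level": 0.28},
    "P354dC": {"dimer_level": 0.19, "hmw_level": 0.43},
}


def gen_chromatogram(
    seed: int = 0,
    areas: dict[str, float] | None = None,
    centers: dict[str, float] | None = None,
    sigmas: dict[str, float] | None = None,
    elution_range: tuple[float, float] = (6.0, 16.0),
    step: float = 0.01,
    snr: float = 50.0,
    baseline_offset: float = 0.02,
    baseline_slope: float = -0.001,
    label: str = "synthetic",
) -> tuple[Chromatogram, GroundTruth]:
    """A sum-of-Gaussians elution trace over a drifting linear baseline
    with additive i.i.d. Gaussian noise.

    ``areas`` maps species (HMW/DIMER/MONOMER) to peak areas; a species
    may be omitted.  SNR is the tallest peak amplitude over the noise
    standard deviation; ``snr=inf`` gives a noiseless trace.  Elution
    centers must respect the column order HMW < DIMER < MONOMER.
    """
    areas = dict(areas or {"HMW": 0.20, "DIMER": 1.14, "MONOMER": 1.0})
    centers = dict(centers or {"HMW": 9.0, "DIMER": 11.0, "MONOMER": 13.2})
    sigmas = dict(sigmas or {"HMW": 0.45, "DIMER": 0.40, "MONOMER": 0.35})
    species = [s for s in ("HMW", "DIMER", "MONOMER") if areas.get(s, 0.0) > 0]
    if not species:
        raise ValidationError("no species with positive area")
    cen = [centers[s] for s in species]
    if any(b <= a for a, b in zip(cen, cen[1:])):
        raise ValidationError("peak centers must be distinct and in HMW < DIMER < MONOMER order")

    x = np.arange(elution_range[0], elution_range[1] + 0.5 * step, step)
    rng = np.random.default_rng(seed)
    y = baseline_offset + baseline_slope * (x - x[0])
    amps = {}
    for s in species:
        amp = areas[s] / (sigmas[s] * SQRT_2PI)
        amps[s] = amp
        y = y + amp * np.exp(-0.5 * ((x - centers[s]) / sigmas[s]) ** 2)
    noise_sigma = 0.0 if not np.isfinite(snr) else max(amps.values()) / snr
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=len(x))

    monomer = areas.get("MONOMER", 0.0)
    manifest = {
        "kind": "chromatogram",
        "seed": seed,
        "areas": {s: areas[s] for s in species},
        "amplitudes": amps,
        "centers": {s: centers[s] for s in species},
        "sigmas": {s: sigmas[s] for s in species},
        "baseline_offset": baseline_offset,
        "baseline_slope": baseline_slope,
        "noise_sigma": noise_sigma,
        "snr": snr,
        "levels": {
            "dimer_level": areas.get("DIMER", 0.0) / monomer if monomer > 0 else None,
            "hmw_level": areas.get("HMW", 0.0) / monomer if monomer > 0 else None,
            "total_level": (areas.get("DIMER", 0.0) + areas.get("HMW", 0.0)) / monomer
            if monomer > 0 else None,
        },
    }
    return Chromatogram(x, y, label=label), GroundTruth(manifest)


def gen_lane_profile(
    seed: int = 0,
    band_areas: dict[str, float] | None = None,
    band_centers: dict[str, float] | None = None,
    band_sigmas: dict[str, float] | None = None,
    length: float = 100.0,
    step: float = 0.2,
    snr: float = 100.0,
    background_offset: float = 5.0,
    background_slope: float = 0.01,
    label: str = "synthetic-lane",
) -> tuple[LaneProfile, GroundTruth]:
    """A blot lane with Gaussian monomer/dimer bands over a linear
    background; the dimer (larger apparent mass) migrates less, i.e. sits
    at a smaller position."""
    # default lane mirrors the untreated wild-type blot: dimer level 1.14,
    # bands two orders of magnitude above the membrane background
    band_areas = dict(band_areas or {"DIMER": 570.0, "MONOMER": 500.0})
    band_centers = dict(band_centers or {"DIMER": 35.0, "MONOMER": 65.0})
    band_sigmas = dict(band_sigmas or {"DIMER": 4.0, "MONOMER": 4.0})
    x = np.arange(0.0, length + 0.5 * step, step)
    rng = np.random.default_rng(seed)
    y = background_offset + background_slope * x
    amps = {}
    for s, area in band_areas.items():
        if area <= 0:
            continue
        amp = area / (band_sigmas[s] * SQRT_2PI)
        amps[s] = amp
        y = y + amp * np.exp(-0.5 * ((x - band_centers[s]) / band_sigmas[s]) ** 2)
    noise_sigma = 0.0 if not np.isfinite(snr) or not amps else max(amps.values()) / snr
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=len(x))
    y = np.clip(y, 0.0, None)
    monomer = band_areas.get("MONOMER", 0.0)
    manifest = {
        "kind": "lane_profile",
        "seed": seed,
        "band_areas": band_areas,
        "band_centers": band_centers,
        "band_sigmas": band_sigmas,
        "noise_sigma": noise_sigma,
        "dimer_level": band_areas.get("DIMER", 0.0) / monomer if monomer > 0 else None,
    }
    return LaneProfile(x, y, lane_label=label), GroundTruth(manifest)


# --------------------------------------------------------------------------
# dimer scaffolds
# --------------------------------------------------------------------------

_SIDE_CLASS = {
    "LYS": SiteClass.CHARGED_POS, "ARG": SiteClass.CHARGED_POS,
    "ASP": SiteClass.CHARGED_NEG, "GLU": SiteClass.CHARGED_NEG,
    "SER": SiteClass.POLAR_DONOR, "THR": SiteClass.POLAR_DONOR,
    "ASN": SiteClass.POLAR_ACCEPTOR, "GLN": SiteClass.POLAR_ACCEPTOR,
    "LEU": SiteClass.NONPOLAR, "ILE": SiteClass.NONPOLAR,
    "VAL": SiteClass.NONPOLAR, "ALA": SiteClass.NONPOLAR,
    "PHE": SiteClass.NONPOLAR, "MET": SiteClass.NONPOLAR,
}
_NAMES = list(_SIDE_CLASS)

_TM_AXIS_POSITIONS = {f"TM{i}": (14.0 * math.cos(2 * math.pi * i / 7),
                                 14.0 * math.sin(2 * math.pi * i / 7))
                      for i in range(1, 8)}


@dataclass(frozen=True)
class PlannedContact:
    """One planted cross-protomer contact.

    ``angle_dev`` (deg, hydrogen bonds only) is the planted deviation of
    the D-H...A angle from linearity.
    """

    resid_a: int
    resid_b: int
    contact_type: str  # electrostatic | hbond | nonpolar
    distance: float
    angle_dev: float = 0.0


def _build_scaffold(
    rng: np.random.Generator,
    n_residues: int,
    regions: list[tuple[str, int, int]],
    tilt_plan: dict[str, float],
    tilt_noise: float,
    label: str,
) -> ProtomerModel:
    region_of = {}
    for name, lo, hi in regions:
        for r in range(lo, min(hi, n_residues) + 1):
            region_of[r] = name
    # helix axes: per TM region, direction tilted from z by the planned angle
    residues = []
    helix_counter: dict[str, int] = {}
    walk = np.array([0.0, 0.0, -20.0])
    for resid in range(1, n_residues + 1):
        region = region_of.get(resid)
        if region is None:
            continue
        name = _NAMES[int(rng.integers(len(_NAMES)))]
        if region in _TM_AXIS_POSITIONS:
            k = helix_counter.get(region, 0)
            helix_counter[region] = k + 1
            cx, cy = _TM_AXIS_POSITIONS[region]
            theta = math.radians(tilt_plan.get(region, 0.0))
            axis = np.array([math.sin(theta), 0.0, math.cos(theta)])
            # ideal helix: 1.5 A rise per residue, 1.0 A coil radius (a CA
            # trace seen at the resolution of the principal-axis estimate),
            # 100 deg turn per residue
            phase = math.radians(100.0 * k)
            perp1 = np.array([math.cos(theta), 0.0, -math.sin(theta)])
            perp2 = np.array([0.0, 1.0, 0.0])
            base = np.array([cx, cy, -15.0]) + axis * (1.5 * k)
            pos = base + 1.0 * (math.cos(phase) * perp1 + math.sin(phase) * perp2)
            pos = pos + rng.normal(0.0, tilt_noise, 3)
        else:
            # loops and the disordered tail: bounded random walk
            walk = walk + rng.normal(0.0, 1.5, 3)
            walk[2] = min(walk[2], -18.0)  # stay on the intracellular side
            pos = walk.copy()
        side_dir = rng.normal(size=3)
        side_dir /= np.linalg.norm(side_dir)
        side_class = _SIDE_CLASS[name]
        backbone = Site("CA", SiteClass.BACKBONE, pos)
        side = Site("SIDE", side_class, pos + 2.0 * side_dir)
        if side_class is SiteClass.POLAR_DONOR:
            side.hydrogen = side.xyz + 1.0 * side_dir
        residues.append(Residue(resid, name, region, [backbone, side]))
    return ProtomerModel(residues, label=label)


def _site_name_for(contact_type: str, end: str) -> tuple[str, SiteClass]:
    if contact_type == "electrostatic":
        return ("LYS", SiteClass.CHARGED_POS) if end == "a" else ("GLU", SiteClass.CHARGED_NEG)
    if contact_type == "hbond":
        return ("SER", SiteClass.POLAR_DONOR) if end == "a" else ("ASN", SiteClass.POLAR_ACCEPTOR)
    if contact_type == "nonpolar":
        return ("LEU", SiteClass.NONPOLAR)
    raise ValidationError(f"unknown contact type {contact_type!r}")


def _plant_contact(pa: ProtomerModel, pb: ProtomerModel, pc: PlannedContact,
                   slot: np.ndarray) -> None:
    """Rebuild the two residues of a planned contact at a docking slot so
    that exactly the planned site pair sits at the planned distance; all
    other planted and scaffold sites stay tens of angstroms away."""
    res_a = next((r for r in pa.residues if r.resid == pc.resid_a), None)
    res_b = next((r for r in pb.residues if r.resid == pc.resid_b), None)
    if res_a is None or res_b is None:
        raise GenerationError(
            f"planned contact references missing residue {pc.resid_a}/{pc.resid_b}"
        )
    name_a, class_a = _site_name_for(pc.contact_type, "a")
    name_b, class_b = _site_name_for(pc.contact_type, "b")
    u = np.array([1.0, 0.0, 0.0])
    w = np.array([0.0, 0.0, 1.0])
    if pc.contact_type == "hbond":
        # donor D at the slot, H 1 A along u, acceptor placed for an exact
        # D...A distance and planned angle deviation
        d = pc.distance
        if d <= 1.0:
            raise GenerationError("hydrogen-bond distance must exceed the 1 A D-H bond")
        delta = math.radians(pc.angle_dev)
        r = -math.cos(delta) + math.sqrt(math.cos(delta) ** 2 - 1.0 + d * d)
        D = slot.copy()
        H = D + u
        A = H + r * (math.cos(delta) * u + math.sin(delta) * w)
        site_a = Site("SIDE", class_a, D, hydrogen=H)
        site_b = Site("SIDE", class_b, A)
    else:
        site_a = Site("SIDE", class_a, slot - 0.5 * pc.distance * u)
        site_b = Site("SIDE", class_b, slot + 0.5 * pc.distance * u)
    res_a.name = name_a
    res_a.sites = [Site("CA", SiteClass.BACKBONE, site_a.xyz + np.array([0, 0, 5.0])), site_a]
    res_b.name = name_b
    res_b.sites = [Site("CA", SiteClass.BACKBONE, site_b.xyz + np.array([0, 0, 5.0])), site_b]


#: default plans realizing the two interface topologies: the symmetric one
#: is tail-to-tail, the asymmetric one docks the tail of protomer A onto
#: the partner's intracellular loops
_DEFAULT_PLANS = {
    "symmetric": [
        PlannedContact(394, 394, "electrostatic", 4.0),
        PlannedContact(355, 357, "electrostatic", 4.5),
        PlannedContact(380, 382, "hbond", 3.0),
    ],
    "asymmetric": [
        PlannedContact(394, 208, "electrostatic", 4.0),
        PlannedContact(355, 109, "electrostatic", 4.5),
    ],
}


def gen_dimer_configuration(
    seed: int = 0,
    contact_plan: list[PlannedContact] | None = None,
    topology: str = "symmetric",
    tilt_plan: dict[str, float] | None = None,
    tilt_noise: float = 0.2,
    n_residues: int = 412,
    regions: list[tuple[str, int, int]] | None = None,
    separation: float = 150.0,
) -> tuple[DimerConfiguration, GroundTruth]:
    """Two labeled protomer scaffolds with planted cross-protomer contacts
    and planted helix tilts.

    Every planted contact is realized at exactly its target distance at a
    well-separated docking slot; every non-planted cross-protomer site
    pair is far beyond any cutoff.  A residue may appear in only one
    planned contact — conflicting requirements raise
    :class:`GenerationError`.
    """
    regions = regions or DEFAULT_REGIONS
    tilt_plan = dict(tilt_plan or {})
    if contact_plan is None:
        if topology not in _DEFAULT_PLANS:
            raise ValidationError(f"unknown topology {topology!r}")
        contact_plan = _DEFAULT_PLANS[topology]

    used_a, used_b = set(), set()
    for pc in contact_plan:
        if pc.resid_a in used_a or pc.resid_b in used_b:
            raise GenerationError(
                f"infeasible plan: residue {pc.resid_a}/{pc.resid_b} appears in "
                "more than one planned contact with independent distance requirements"
            )
        used_a.add(pc.resid_a)
        used_b.add(pc.resid_b)

    rng = np.random.default_rng(seed)
    pa = _build_scaffold(rng, n_residues, regions, tilt_plan, tilt_noise, "A")
    pb = _build_scaffold(rng, n_residues, regions, tilt_plan, tilt_noise, "B")
    # push protomer B far away so the scaffolds themselves never touch
    for r in pb.residues:
        for s in r.sites:
            s.xyz = s.xyz + np.array([separation, 0.0, 0.0])
            if s.hydrogen is not None:
                s.hydrogen = s.hydrogen + np.array([separation, 0.0, 0.0])
    for k, pc in enumerate(contact_plan):
        slot = np.array([separation / 2.0, 25.0 * k, -40.0])
        _plant_contact(pa, pb, pc, slot)

    config = DimerConfiguration(pa, pb, frame_index=0)
    manifest = {
        "kind": "dimer_configuration",
        "seed": seed,
        "topology": topology,
        "contacts": [pc.__dict__ for pc in contact_plan],
        "counts": {
            t: sum(1 for pc in contact_plan if pc.contact_type == t)
            for t in ("electrostatic", "hbond", "nonpolar")
        },
        "tilt_plan": tilt_plan,
        "tilt_noise": tilt_noise,
    }
    return config, GroundTruth(manifest)


def gen_dimer_frames(
    seed: int = 0,
    cluster_sizes: list[int] | None = None,
    cluster_separation: float = 6.0,
    within_jitter: float = 0.15,
    **config_kwargs,
) -> tuple[list[DimerConfiguration], GroundTruth]:
    """A frame series with planted conformational clusters.

    Each cluster applies one random internal displacement field (scale
    ``cluster_separation`` per coordinate) to a common base configuration;
    members add i.i.d. jitter of ``within_jitter`` per coordinate, so
    within-cluster backbone RMSD is ~ ``sqrt(6)*within_jitter`` and
    between-cluster RMSD is set by ``cluster_separation``.
    """
    cluster_sizes = cluster_sizes or [5, 3, 2]
    base, base_truth = gen_dimer_configuration(seed=seed, **config_kwargs)
    rng = np.random.default_rng(seed + 1)

    def backbone_sites(cfg):
        for prot in (cfg.protomer_a, cfg.protomer_b):
            for r in prot.residues:
                for s in r.sites:
                    if s.site_class is SiteClass.BACKBONE:
                        yield s

    import copy

    # only backbone sites move between frames: clustering sees the planted
    # conformational families while every planted side-site contact stays
    # realized at its exact distance in every frame
    frames = []
    membership = []
    fidx = 0
    n_bb = sum(1 for _ in backbone_sites(base))
    for ci, size in enumerate(cluster_sizes):
        field_disp = rng.normal(0.0, cluster_separation, size=(n_bb, 3))
        for _ in range(size):
            cfg = copy.deepcopy(base)
            cfg.frame_index = fidx
            jit = rng.normal(0.0, within_jitter, size=(n_bb, 3))
            for s, dv, jv in zip(backbone_sites(cfg), field_disp, jit):
                s.xyz = s.xyz + dv + jv
            frames.append(cfg)
            membership.append(ci)
            fidx += 1
    manifest = dict(base_truth.manifest)
    manifest.update({
        "kind": "dimer_frames",
        "cluster_sizes": cluster_sizes,
        "membership": membership,
        "cluster_separation": cluster_separation,
        "within_jitter": within_jitter,
    })
    return frames, GroundTruth(manifest)


# --------------------------------------------------------------------------
# melt curves and turbidity
# --------------------------------------------------------------------------

def gen_melt_curve(
    seed: int = 0,
    tm: float = 55.0,
    quench_T: float | None = 65.0,
    t_range: tuple[float, float] = (20.0, 70.0),
    step: float = 0.5,
    width: float = 2.0,
    amplitude: float = 1000.0,
    baseline: float = 100.0,
    quench_tau: float = 1.0,
    noise_sigma: float = 2.0,
    label: str = "synthetic-melt",
) -> tuple[MeltCurve, GroundTruth]:
    """A DSF trace: rising unfolding sigmoid with midpoint ``tm``, then an
    abrupt exponential collapse of the dye signal from ``quench_T`` on
    (None for no quench), plus additive Gaussian noise.  The temperature
    step of 0.5 degC mirrors a 0.5 degC / 30 s ramp."""
    if quench_T is not None and quench_T <= tm:
        raise ValidationError("quench temperature must exceed the melting midpoint")
    T = np.arange(t_range[0], t_range[1] + 0.5 * step, step)
    rng = np.random.default_rng(seed)
    f = baseline + amplitude / (1.0 + np.exp(-(T - tm) / width))
    if quench_T is not None:
        collapse = np.where(T > quench_T, np.exp(-(T - quench_T) / quench_tau), 1.0)
        f = baseline + (f - baseline) * collapse
    if noise_sigma > 0:
        f = f + rng.normal(0.0, noise_sigma, size=len(T))
    manifest = {
        "kind": "melt_curve", "seed": seed, "tm": tm, "quench_T": quench_T,
        "width": width, "amplitude": amplitude, "noise_sigma": noise_sigma,
    }
    return MeltCurve(T, f, label=label), GroundTruth(manifest)


def gen_turbidity_series(
    seed: int = 0,
    conditions: list[float] | None = None,
    step_at: float = 1.0,
    soluble_a450: float = 0.01,
    slight_a450: float = 0.08,
    aggregated_a450: float = 1.0,
    slight_range: tuple[float, float] = (0.25, 0.5),
    noise_sigma: float = 0.002,
    salt: str = "NaCl",
) -> tuple[TurbiditySeries, GroundTruth]:
    """A450 vs ionic strength with a slight-aggregation band and a hard
    aggregation step at ``step_at`` (the C-terminal peptide precipitates
    above ~1 M NaCl)."""
    conditions = conditions or [0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0]
    rng = np.random.default_rng(seed)
    a450 = []
    states = []
    for c in conditions:
        if c > step_at:
            v, s = aggregated_a450, "aggregated"
        elif slight_range[0] <= c <= slight_range[1]:
            v, s = slight_a450, "slight"
        else:
            v, s = soluble_a450, "soluble"
        a450.append(max(v + rng.normal(0.0, noise_sigma), 0.0))
        states.append(s)
    manifest = {
        "kind": "turbidity", "seed": seed, "conditions": conditions,
        "step_at": step_at, "states": states, "salt": salt,
    }
    return TurbiditySeries(np.array(conditions), np.array(a450), salt=salt), GroundTruth(manifest)
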