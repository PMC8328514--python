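"""Dimer-configuration geometry: contacts, interfaces, tilt, clustering.

A :class:`DimerConfiguration` holds two annotated protomers — ordered
residues carrying labeled coordinate sites (charged +/-, polar donor or
acceptor with an attached hydrogen, nonpolar, backbone) and a region label
(TM1..TM7, loops, H8, CTERM).  On top of it sit the operators used to
characterise receptor dimers sampled from simulation:

* dimer detection by the minimum residue center-of-mass distance (< 5 A),
* electrostatic contacts (opposite charges within 5.0 A),
* hydrogen bonds (donor-acceptor <= 3.5 A, D-H...A within 20 deg of
  linear, C-terminal residues only by default),
* nonpolar contacts,
* interacting-helix screening (TM pairs closer than 7 A),
* helical tilt against the membrane normal,
* symmetric/asymmetric interface classification,
* Daura neighbor-count clustering at an RMSD cutoff (default 1.5 A).

Distance cutoffs for contacts are inclusive (<=); the dimer and
interacting-helix criteria are strict (<).  All geometry is invariant
under global rigid motion, and minimum-image convention is applied to the
center-of-mass search when a periodic box is present.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import UnsupportedInputError, ValidationError

__all__ = [
    "SiteClass",
    "Site",
    "Residue",
    "ProtomerModel",
    "DimerConfiguration",
    "Contact",
    "ContactSet",
    "InterfaceCall",
    "ClusterResult",
    "TM_REGIONS",
    "min_com_distance",
    "detect_dimer",
    "electrostatic_contacts",
    "hydrogen_bonds",
    "nonpolar_contacts",
    "helix_tilt",
    "interacting_helices",
    "classify_interface",
    "daura_cluster",
    "average_contact_counts",
    "kabsch_rmsd",
]

TM_REGIONS = tuple(f"TM{i}" for i in range(1, 8))
REGIONS = TM_REGIONS + ("H8", "ICL1", "ICL2", "ICL3", "ECL1", "ECL2", "ECL3", "CTERM")


class SiteClass(str, Enum):
    CHARGED_POS = "charged+"
    CHARGED_NEG = "charged-"
    POLAR_DONOR = "polar-donor"
    POLAR_ACCEPTOR = "polar-acceptor"
    NONPOLAR = "nonpolar"
    BACKBONE = "backbone"


@dataclass
class Site:
    """One labeled coordinate point; donors may carry the position of the
    attached hydrogen."""

    name: str
    site_class: SiteClass
    xyz: np.ndarray
    hydrogen: np.ndarray | None = None

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValidationError(f"site {self.name}: non-finite coordinates")
        if self.hydrogen is not None:
            self.hydrogen = np.asarray(self.hydrogen, dtype=float).reshape(3)


@dataclass
class Residue:
    resid: int
    name: str
    region: str
    sites: list[Site]

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValidationError(f"residue {self.resid}: unknown region {self.region!r}")
        if not self.sites:
            raise ValidationError(f"residue {self.resid}: no sites")

    @property
    def com(self) -> np.ndarray:
        return np.mean([s.xyz for s in self.sites], axis=0)


@dataclass
class ProtomerModel:
    """Ordered residues of one receptor copy; 1-based receptor numbering."""

    residues: list[Residue]
    label: str = ""
    cterm_start: int = 291

    def __post_init__(self):
        if not self.residues:
            raise ValidationError("empty protomer")
        ids = [r.resid for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValidationError("residue ids must be strictly increasing")
        for r in self.residues:
            if r.region == "CTERM" and r.resid < self.cterm_start:
                raise ValidationError(
                    f"residue {r.resid} labeled CTERM before cterm_start={self.cterm_start}"
                )

    def coms(self) -> np.ndarray:
        return np.array([r.com for r in self.residues])

    def sites_of_class(self, classes: set[SiteClass], regions: set[str] | None = None):
        """Flat list of (residue, site) for sites of the given classes,
        optionally restricted to regions."""
        out = []
        for r in self.residues:
            if regions is not None and r.region not in regions:
                continue
            for s in r.sites:
                if s.site_class in classes:
                    out.append((r, s))
        return out

    def backbone_coords(self, region: str | None = None) -> np.ndarray:
        pts = []
        for r in self.residues:
            if region is not None and r.region != region:
                continue
            for s in r.sites:
                if s.site_class is SiteClass.BACKBONE:
                    pts.append(s.xyz)
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class DimerConfiguration:
    protomer_a: ProtomerModel
    protomer_b: ProtomerModel
    frame_index: int = 0
    box: np.ndarray | None = None  # orthorhombic box lengths (A), or None

    def __post_init__(self):
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValidationError("box lengths must be positive")

    def swapped(self) -> "DimerConfiguration":
        return DimerConfiguration(self.protomer_b, self.protomer_a,
                                  frame_index=self.frame_index, box=self.box)


@dataclass(frozen=True)
class Contact:
    residue_a: int
    residue_b: int
    region_a: str
    region_b: str
    contact_type: str  # electrostatic | hbond | nonpolar
    distance: float
    angle: float | None = None  # deviation from linearity, deg (hbond only)


@dataclass
class ContactSet:
    contacts: list[Contact]
    frame_index: int = 0

    def __len__(self) -> int:
        return len(self.contacts)

    def residues(self, protomer: str = "both") -> set[tuple[str, int]]:
        """Distinct contacting residues, tagged by protomer ('a'/'b')."""
        out: set[tuple[str, int]] = set()
        for c in self.contacts:
            if protomer in ("a", "both"):
                out.add(("a", c.residue_a))
            if protomer in ("b", "both"):
                out.add(("b", c.residue_b))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.contacts])


@dataclass(frozen=True)
class InterfaceCall:
    classification: str  # symmetric | asymmetric | none
    direction: str | None  # 'a->b' / 'b->a' for asymmetric calls
    tallies: tuple[tuple[str, int], ...]  # (category, count)


@dataclass
class ClusterResult:
    clusters: list[list[int]]  # frame indices, ordered by decreasing size
    representatives: list[int]  # medoid frame per cluster
    rmsd_cutoff: float

    def membership(self) -> dict[int, int]:
        return {f: ci for ci, cl in enumerate(self.clusters) for f in cl}


# --------------------------------------------------------------------------
# distances and dimer detection
# --------------------------------------------------------------------------

def _pairwise_min_image(da: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        da = da - box * np.round(da / box)
    return da


def min_com_distance(config: DimerConfiguration) -> float:
    """Minimum over all cross-protomer residue pairs of the distance
    between residue centers of mass (minimum-image under a periodic box)."""
    A = config.protomer_a.coms()
    B = config.protomer_b.coms()
    if len(A) == 0 or len(B) == 0:
        raise ValidationError("empty protomer")
    diff = A[:, None, :] - B[None, :, :]
    diff = _pairwise_min_image(diff, config.box)
    d = np.sqrt(np.sum(diff**2, axis=-1))
    return float(d.min())


def detect_dimer(config: DimerConfiguration, cutoff: float = 5.0) -> bool:
    """True iff the protomers form a dimeric interface: minimum
    residue-COM distance strictly below ``cutoff`` (default 5 A)."""
    return min_com_distance(config) < cutoff


# --------------------------------------------------------------------------
# contacts
# --------------------------------------------------------------------------

def _region_set(scope) -> set[str] | None:
    if scope is None:
        return None
    if isinstance(scope, str):
        return {scope}
    return set(scope)


def electrostatic_contacts(
    config: DimerConfiguration,
    cutoff: float = 5.0,
    scope=None,
) -> ContactSet:
    """Cross-protomer pairs of oppositely charged sites within ``cutoff``
    (inclusive).  ``scope`` optionally restricts both residues to a region
    set."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    regions = _region_set(scope)
    charged = {SiteClass.CHARGED_POS, SiteClass.CHARGED_NEG}
    sa = config.protomer_a.sites_of_class(charged, regions)
    sb = config.protomer_b.sites_of_class(charged, regions)
    if not sa or not sb:
        warnings.warn("no charged sites in scope", stacklevel=2)
        return ContactSet([], frame_index=config.frame_index)
    contacts = []
    for ra, site_a in sa:
        for rb, site_b in sb:
            if site_a.site_class is site_b.site_class:
                continue  # like charges never form an electrostatic contact
            d = float(np.linalg.norm(site_a.xyz - site_b.xyz))
            if d <= cutoff:
                contacts.append(Contact(ra.resid, rb.resid, ra.region, rb.region,
                                        "electrostatic", d))
    return ContactSet(contacts, frame_index=config.frame_index)


def _hbond_pairs(donors, acceptors, d_cut: float, ang_cut: float):
    out = []
    for rd, sd in donors:
        if sd.hydrogen is None:
            raise UnsupportedInputError(
                f"donor site {sd.name} of residue {rd.resid} carries no hydrogen; "
                "hydrogen-bond geometry needs atomistic-style sites"
            )
        for ra, sa in acceptors:
            d = float(np.linalg.norm(sd.xyz - sa.xyz))
            if d > d_cut:
                continue
            v1 = sd.xyz - sd.hydrogen  # H -> D
            v2 = sa.xyz - sd.hydrogen  # H -> A
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                continue
            cosang = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
            dha = math.degrees(math.acos(cosang))
            deviation = 180.0 - dha
            if deviation <= ang_cut:
                out.append((rd, ra, d, deviation))
    return out


def hydrogen_bonds(
    config: DimerConfiguration,
    d_cut: float = 3.5,
    ang_cut: float = 20.0,
    scope="CTERM",
) -> ContactSet:
    """Cross-protomer hydrogen bonds: donor-acceptor distance <= ``d_cut``
    and D-H...A angle within ``ang_cut`` degrees of linear.

    By default only C-terminal residues are considered (``scope='CTERM'``);
    pass ``scope=None`` for all regions.  Donors must carry hydrogen
    positions — coarse-grained sites without hydrogens raise
    :class:`UnsupportedInputError`.
    """
    regions = _region_set(scope)
    don = {SiteClass.POLAR_DONOR}
    acc = {SiteClass.POLAR_ACCEPTOR}
    contacts = []
    for rd, ra, d, dev in _hbond_pairs(
        config.protomer_a.sites_of_class(don, regions),
        config.protomer_b.sites_of_class(acc, regions),
        d_cut, ang_cut,
    ):
        contacts.append(Contact(rd.resid, ra.resid, rd.region, ra.region, "hbond", d, dev))
    for rd, ra, d, dev in _hbond_pairs(
        config.protomer_b.sites_of_class(don, regions),
        config.protomer_a.sites_of_class(acc, regions),
        d_cut, ang_cut,
    ):
        # donor on protomer B: record as (a-residue, b-residue) all the same
        contacts.append(Contact(ra.resid, rd.resid, ra.region, rd.region, "hbond", d, dev))
    return ContactSet(contacts, frame_index=config.frame_index)


def nonpolar_contacts(
    config: DimerConfiguration,
    cutoff: float = 5.0,
    scope=None,
) -> ContactSet:
    """Cross-protomer nonpolar-site pairs within ``cutoff`` (inclusive)."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    regions = _region_set(scope)
    np_class = {SiteClass.NONPOLAR}
    sa = config.protomer_a.sites_of_class(np_class, regions)
    sb = config.protomer_b.sites_of_class(np_class, regions)
    contacts = []
    for ra, site_a in sa:
        for rb, site_b in sb:
            d = float(np.linalg.norm(site_a.xyz - site_b.xyz))
            if d <= cutoff:
                contacts.append(Contact(ra.resid, rb.resid, ra.region, rb.region,
                                        "nonpolar", d))
    return ContactSet(contacts, frame_index=config.frame_index)


# --------------------------------------------------------------------------
# helices
# --------------------------------------------------------------------------

def helix_tilt(
    protomer: ProtomerModel,
    helix: str,
    normal=(0.0, 0.0, 1.0),
) -> float:
    """Angle (deg, folded into [0, 90]) between the helix principal axis —
    leading eigenvector of the backbone-coordinate covariance — and the
    membrane normal (fixed z by default)."""
    coords = protomer.backbone_coords(region=helix)
    if len(coords) < 4:
        raise ValidationError(f"helix {helix}: fewer than 4 backbone sites")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    if w[-1] <= 1e-12:
        raise ValidationError(f"helix {helix}: degenerate coordinates")
    axis = v[:, -1]
    n = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValidationError("zero membrane normal")
    cosang = abs(float(axis @ n) / nn)
    return math.degrees(math.acos(np.clip(cosang, 0.0, 1.0)))


def interacting_helices(
    config: DimerConfiguration,
    cutoff: float = 7.0,
) -> list[tuple[str, str]]:
    """Cross-protomer TM helix pairs whose minimum inter-site distance is
    strictly below ``cutoff``; an empty list certifies a non-TM interface."""
    pairs = []
    site_cache_a = {}
    site_cache_b = {}
    for h in TM_REGIONS:
        pts = [s.xyz for r in config.protomer_a.residues if r.region == h for s in r.sites]
        if pts:
            site_cache_a[h] = np.array(pts)
        pts = [s.xyz for r in config.protomer_b.residues if r.region == h for s in r.sites]
        if pts:
            site_cache_b[h] = np.array(pts)
    for ha, pa in site_cache_a.items():
        for hb, pb in site_cache_b.items():
            if float(cdist(pa, pb).min()) < cutoff:
                pairs.append((ha, hb))
    return pairs


# --------------------------------------------------------------------------
# interface classification
# --------------------------------------------------------------------------

def classify_interface(contacts: ContactSet, regions=None) -> InterfaceCall:
    """Classify the dimer interface topology from region-labeled contacts.

    symmetric: C-terminus-to-C-terminus contacts form the plurality
    (face-to-face association of the two disordered tails);
    asymmetric: the C-terminus of exactly one protomer contacting
    non-C-terminal regions (loops) of the other forms the plurality
    (face-to-back); none: no cross-protomer contacts at all.

    Swapping the protomer labels leaves the class unchanged and reverses
    the direction of an asymmetric call.
    """
    if len(contacts) == 0:
        return InterfaceCall("none", None, ())
    cc = a_only = b_only = other = 0
    for c in contacts.contacts:
        ia, ib = c.region_a == "CTERM", c.region_b == "CTERM"
        if ia and ib:
            cc += 1
        elif ia:
            a_only += 1
        elif ib:
            b_only += 1
        else:
            other += 1
    tallies = (("cterm-cterm", cc), ("cterm_a-other", a_only),
               ("cterm_b-other", b_only), ("other", other))
    if cc > 0 and cc >= a_only and cc >= b_only and cc >= other:
        return InterfaceCall("symmetric", None, tallies)
    if a_only > max(b_only, other):
        return InterfaceCall("asymmetric", "a->b", tallies)
    if b_only > max(a_only, other):
        return InterfaceCall("asymmetric", "b->a", tallies)
    if a_only > 0 and a_only == b_only:
        # both tails engaged with the partner's loops: mutually face-to-back,
        # reported as symmetric since neither direction dominates
        return InterfaceCall("symmetric", None, tallies)
    return InterfaceCall("asymmetric", None, tallies) if (a_only or b_only) \
        else InterfaceCall("none", None, tallies)


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def kabsch_rmsd(P: np.ndarray, Q: np.ndarray, fit: bool = True) -> float:
    """RMSD between matched coordinate sets, after optimal least-squares
    rigid superposition (Kabsch) when ``fit`` is True."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValidationError("coordinate sets must be matching (n, 3) arrays")
    if fit:
        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
        H = Pc.T @ Qc
        U, S, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        D = np.diag([1.0, 1.0, d])
        R = Vt.T @ D @ U.T
        Pc = Pc @ R.T
        diff = Pc - Qc
    else:
        diff = P - Q
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _dimer_backbone(config: DimerConfiguration) -> np.ndarray:
    pts = np.vstack([config.protomer_a.backbone_coords(),
                     config.protomer_b.backbone_coords()])
    if len(pts) == 0:
        raise ValidationError("no backbone sites for superposition")
    return pts


def daura_cluster(
    frames: list[DimerConfiguration],
    rmsd_cutoff: float = 1.5,
    fit: bool = True,
) -> ClusterResult:
    """Daura neighbor-count clustering of dimer conformations.

    Pairwise backbone RMSD (after optimal rigid superposition of the whole
    dimer unless ``fit=False``) defines neighbors at ``rmsd_cutoff``; the
    frame with the most neighbors seeds a cluster of itself plus its
    neighbors, all are removed from the pool, and the step repeats until
    the pool is empty.  Ties on neighbor count go to the lowest frame
    index; clusters are reported by decreasing size (ties by smallest
    member).  The cluster representative is the seed (medoid) frame.
    """
    if not frames:
        raise ValidationError("no frames to cluster")
    coords = []
    shape = None
    for f in frames:
        c = _dimer_backbone(f)
        if shape is None:
            shape = c.shape
        elif c.shape != shape:
            raise ValidationError("frames do not share the site schema")
        coords.append(c)
    n = len(frames)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kabsch_rmsd(coords[i], coords[j], fit=fit)

    pool = list(range(n))
    clusters: list[list[int]] = []
    reps: list[int] = []
    while pool:
        best_seed, best_neigh = None, None
        for i in pool:
            neigh = [j for j in pool if D[i, j] <= rmsd_cutoff]  # includes i
            if best_neigh is None or len(neigh) > len(best_neigh):
                best_seed, best_neigh = i, neigh
        clusters.append(sorted(best_neigh))
        reps.append(best_seed)
        pool = [i for i in pool if i not in set(best_neigh)]

    order = sorted(range(len(clusters)), key=lambda k: (-len(clusters[k]), clusters[k][0]))
    return ClusterResult([clusters[k] for k in order], [reps[k] for k in order],
                         rmsd_cutoff)


# --------------------------------------------------------------------------
# averaging
# --------------------------------------------------------------------------

def average_contact_counts(
    per_frame: list[ContactSet],
    segments: dict[str, tuple[int, int]],
    mode: str = "residues",
) -> pd.DataFrame:
    """Mean (over frames) number of contacting residues per sequence
    segment, with standard deviation.

    ``mode='residues'`` counts distinct residues (either protomer) in the
    segment participating in >= 1 contact per frame; ``mode='events'``
    counts contact events whose a- or b-residue falls in the segment.
    """
    if not per_frame:
        raise ValidationError("no frames")
    if not segments:
        raise ValidationError("empty segment definition")
    for name, (lo, hi) in segments.items():
        if lo > hi:
            raise ValidationError(f"segment {name}: empty range")
    rows = []
    for name, (lo, hi) in segments.items():
        counts = []
        for cs in per_frame:
            if mode == "residues":
                resids = {(p, r) for p, r in cs.residues() if lo <= r <= hi}
                counts.append(len(resids))
            elif mode == "events":
                counts.append(sum(1 for c in cs.contacts
                                  if lo <= c.residue_a <= hi or lo <= c.residue_b <= hi))
            else:
                raise ValidationError(f"unknown mode {mode!r}")
        arr = np.array(counts, dtype=float)
        rows.append({"segment": name, "start": lo, "end": hi,
                     "mean_count": float(arr.mean()),
                     "sd": float(arr.std(ddof=0)),
                     "n_frames": len(arr)})
    return pd.DataFrame(rows)
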