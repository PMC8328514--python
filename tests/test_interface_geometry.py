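"""Contact geometry against exhaustive brute-force oracles and under
rigid-motion invariance."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from a2aolig import interface_analysis as ia
from a2aolig.errors import UnsupportedInputError, ValidationError
from a2aolig.interface_analysis import SiteClass
from conftest import make_residue, random_config


# --------------------------------------------------------------------------
# independent oracles (straight double loops over the raw data model)
# --------------------------------------------------------------------------

def brute_min_com(config):
    best = math.inf
    for ra in config.protomer_a.residues:
        ca = np.mean([s.xyz for s in ra.sites], axis=0)
        for rb in config.protomer_b.residues:
            cb = np.mean([s.xyz for s in rb.sites], axis=0)
            d = cb - ca
            if config.box is not None:
                d = d - config.box * np.round(d / config.box)
            best = min(best, float(np.linalg.norm(d)))
    return best


def brute_pair_count(config, class_a, class_b, cutoff, symmetric_classes=False):
    count = 0
    for ra in config.protomer_a.residues:
        for sa in ra.sites:
            for rb in config.protomer_b.residues:
                for sb in rb.sites:
                    ok = (sa.site_class is class_a and sb.site_class is class_b) or \
                         (symmetric_classes and sa.site_class is class_b
                          and sb.site_class is class_a)
                    if ok and np.linalg.norm(sa.xyz - sb.xyz) <= cutoff:
                        count += 1
    return count


def brute_hbonds(config, d_cut, ang_cut, region):
    count = 0
    for donor_prot, acc_prot in ((config.protomer_a, config.protomer_b),
                                 (config.protomer_b, config.protomer_a)):
        for rd in donor_prot.residues:
            if region and rd.region != region:
                continue
            for sd in rd.sites:
                if sd.site_class is not SiteClass.POLAR_DONOR:
                    continue
                for ra in acc_prot.residues:
                    if region and ra.region != region:
                        continue
                    for sa in ra.sites:
                        if sa.site_class is not SiteClass.POLAR_ACCEPTOR:
                            continue
                        if np.linalg.norm(sd.xyz - sa.xyz) > d_cut:
                            continue
                        v1 = sd.xyz - sd.hydrogen
                        v2 = sa.xyz - sd.hydrogen
                        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
                        if 180.0 - ang <= ang_cut:
                            count += 1
    return count


def transform_config(config, R, t):
    import copy

    cfg = copy.deepcopy(config)
    for prot in (cfg.protomer_a, cfg.protomer_b):
        for r in prot.residues:
            for s in r.sites:
                s.xyz = R @ s.xyz + t
                if s.hydrogen is not None:
                    s.hydrogen = R @ s.hydrogen + t
    return cfg


# --------------------------------------------------------------------------
# minimum COM distance / dimer detection
# --------------------------------------------------------------------------

class TestMinComDistance:
    def test_coincident_residue_com_gives_zero(self):
        a = ia.ProtomerModel([make_residue(300, "CTERM",
                                           [(SiteClass.BACKBONE, [1.0, 2.0, 3.0])])])
        b = ia.ProtomerModel([make_residue(300, "CTERM",
                                           [(SiteClass.BACKBONE, [1.0, 2.0, 3.0])])])
        assert ia.min_com_distance(ia.DimerConfiguration(a, b)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pairwise_minimum(self, seed):
        cfg = random_config(seed)
        assert ia.min_com_distance(cfg) == pytest.approx(brute_min_com(cfg), abs=1e-12)

    def test_minimum_image_under_periodic_box(self):
        a = ia.ProtomerModel([make_residue(300, "CTERM",
                                           [(SiteClass.BACKBONE, [1.0, 0.0, 0.0])])])
        b = ia.ProtomerModel([make_residue(300, "CTERM",
                                           [(SiteClass.BACKBONE, [19.0, 0.0, 0.0])])])
        cfg = ia.DimerConfiguration(a, b, box=np.array([20.0, 20.0, 20.0]))
        assert ia.min_com_distance(cfg) == pytest.approx(2.0)
        assert brute_min_com(cfg) == pytest.approx(2.0)

    def test_invariant_under_rigid_motion(self):
        cfg = random_config(3)
        d0 = ia.min_com_distance(cfg)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = transform_config(cfg, R, np.array([5.0, -2.0, 11.0]))
        assert ia.min_com_distance(moved) == pytest.approx(d0, abs=1e-9)

    def test_dimer_cutoff_is_strict(self):
        def cfg_at(dist):
            a = ia.ProtomerModel([make_residue(300, "CTERM",
                                               [(SiteClass.BACKBONE, [0.0, 0.0, 0.0])])])
            b = ia.ProtomerModel([make_residue(300, "CTERM",
                                               [(SiteClass.BACKBONE, [dist, 0.0, 0.0])])])
            return ia.DimerConfiguration(a, b)

        assert ia.detect_dimer(cfg_at(3.0))
        assert not ia.detect_dimer(cfg_at(6.0))
        assert not ia.detect_dimer(cfg_at(5.0))  # boundary: strict <


# --------------------------------------------------------------------------
# electrostatic contacts
# --------------------------------------------------------------------------

class TestElectrostatic:
    def _pair(self, dist):
        a = ia.ProtomerModel([make_residue(300, "CTERM",
                                           [(SiteClass.CHARGED_POS, [0.0, 0.0, 0.0])],
                                           name="LYS")])
        b = ia.ProtomerModel([make_residue(301, "CTERM",
                                           [(SiteClass.CHARGED_NEG, [dist, 0.0, 0.0])],
                                           name="GLU")])
        return ia.DimerConfiguration(a, b)

    def test_opposite_charges_within_cutoff(self):
        assert len(ia.electrostatic_contacts(self._pair(4.0))) == 1

    def test_beyond_cutoff_excluded(self):
        assert len(ia.electrostatic_contacts(self._pair(5.5))) == 0

    def test_boundary_distance_is_inclusive(self):
        assert len(ia.electrostatic_contacts(self._pair(5.0))) == 1

    def test_like_charges_never_contact(self):
        a = ia.ProtomerModel([make_residue(300, "CTERM",
                                           [(SiteClass.CHARGED_POS, [0, 0, 0])])])
        b = ia.ProtomerModel([make_residue(301, "CTERM",
                                           [(SiteClass.CHARGED_POS, [3.0, 0, 0])])])
        assert len(ia.electrostatic_contacts(ia.DimerConfiguration(a, b))) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        cfg = random_config(seed, n_res=15)
        expected = brute_pair_count(cfg, SiteClass.CHARGED_POS, SiteClass.CHARGED_NEG,
                                    5.0, symmetric_classes=True)
        assert len(ia.electrostatic_contacts(cfg, cutoff=5.0)) == expected


# --------------------------------------------------------------------------
# hydrogen bonds
# --------------------------------------------------------------------------

def _hbond_cfg(d, angle_dev_deg):
    """Donor at origin, hydrogen 1 A along +x, acceptor at D...A distance d
    with the planted deviation of the D-H...A angle from linearity."""
    delta = math.radians(angle_dev_deg)
    r = -math.cos(delta) + math.sqrt(math.cos(delta) ** 2 - 1 + d * d)
    H = np.array([1.0, 0.0, 0.0])
    A = H + r * np.array([math.cos(delta), math.sin(delta), 0.0])
    pa = ia.ProtomerModel([make_residue(300, "CTERM",
                                        [(SiteClass.POLAR_DONOR, [0, 0, 0], H)],
                                        name="SER")])
    pb = ia.ProtomerModel([make_residue(301, "CTERM",
                                        [(SiteClass.POLAR_ACCEPTOR, A)], name="ASN")])
    return ia.DimerConfiguration(pa, pb)


class TestHydrogenBonds:
    def test_collinear_within_distance(self):
        assert len(ia.hydrogen_bonds(_hbond_cfg(3.4, 0.0))) == 1

    def test_collinear_beyond_distance(self):
        assert len(ia.hydrogen_bonds(_hbond_cfg(3.6, 0.0))) == 0

    def test_angle_beyond_cutoff(self):
        assert len(ia.hydrogen_bonds(_hbond_cfg(3.2, 25.0))) == 0

    @pytest.mark.parametrize("d,dev,expect", [
        (3.5, 20.0, 1),   # both at their cutoffs: inclusive
        (3.0, 19.9, 1),
        (3.0, 20.1, 0),
        (3.51, 0.0, 0),
    ])
    def test_boundary_geometry(self, d, dev, expect):
        cs = ia.hydrogen_bonds(_hbond_cfg(d, dev))
        assert len(cs) == expect
        if expect:
            assert cs.contacts[0].distance == pytest.approx(d, abs=1e-9)
            assert cs.contacts[0].angle == pytest.approx(dev, abs=1e-6)

    def test_scope_excludes_non_cterm_residues(self):
        cfg = _hbond_cfg(3.0, 0.0)
        cfg.protomer_a.residues[0].region = "ICL3"
        cfg.protomer_a.residues[0].resid = 208
        assert len(ia.hydrogen_bonds(cfg)) == 0
        assert len(ia.hydrogen_bonds(cfg, scope=None)) == 1

    def test_missing_hydrogen_is_unsupported(self):
        cfg = _hbond_cfg(3.0, 0.0)
        cfg.protomer_a.residues[0].sites[0].hydrogen = None
        with pytest.raises(UnsupportedInputError, match="300"):
            ia.hydrogen_bonds(cfg)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        cfg = random_config(seed, n_res=15)
        expected = brute_hbonds(cfg, 3.5, 20.0, "CTERM")
        assert len(ia.hydrogen_bonds(cfg)) == expected


# --------------------------------------------------------------------------
# nonpolar contacts
# --------------------------------------------------------------------------

class TestNonpolar:
    def test_leucine_pair_within_cutoff(self):
        a = ia.ProtomerModel([make_residue(320, "CTERM",
                                           [(SiteClass.NONPOLAR, [0, 0, 0])], "LEU")])
        b = ia.ProtomerModel([make_residue(321, "CTERM",
                                           [(SiteClass.NONPOLAR, [4.5, 0, 0])], "LEU")])
        assert len(ia.nonpolar_contacts(ia.DimerConfiguration(a, b), cutoff=5.0)) == 1

    def test_no_nonpolar_sites_gives_empty_set(self):
        a = ia.ProtomerModel([make_residue(320, "CTERM",
                                           [(SiteClass.CHARGED_POS, [0, 0, 0])])])
        b = ia.ProtomerModel([make_residue(321, "CTERM",
                                           [(SiteClass.CHARGED_NEG, [3.0, 0, 0])])])
        assert len(ia.nonpolar_contacts(ia.DimerConfiguration(a, b))) == 0

    def test_nonpositive_cutoff_rejected(self):
        cfg = random_config(0)
        with pytest.raises(ValidationError):
            ia.nonpolar_contacts(cfg, cutoff=0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        cfg = random_config(seed, n_res=15)
        expected = brute_pair_count(cfg, SiteClass.NONPOLAR, SiteClass.NONPOLAR, 5.0)
        assert len(ia.nonpolar_contacts(cfg, cutoff=5.0)) == expected


# --------------------------------------------------------------------------
# rigid-motion invariance across all contact operators
# --------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_contact_counts_and_distances_invariant_under_rigid_motion(seed):
    cfg = random_config(seed, n_res=15)
    rng = np.random.default_rng(seed + 100)
    R = Rotation.random(random_state=seed).as_matrix()
    t = rng.uniform(-50, 50, 3)
    moved = transform_config(cfg, R, t)
    for op in (ia.electrostatic_contacts, ia.nonpolar_contacts, ia.hydrogen_bonds):
        c0 = op(cfg)
        c1 = op(moved)
        assert len(c0) == len(c1)
        d0 = sorted(c.distance for c in c0.contacts)
        d1 = sorted(c.distance for c in c1.contacts)
        np.testing.assert_allclose(d1, d0, atol=1e-6)
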