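"""Daura clustering, helix tilt, interface classification, interacting
helices, and contact-count averaging."""

import copy
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from a2aolig import interface_analysis as ia
from a2aolig.errors import ValidationError
from a2aolig.interface_analysis import Contact, ContactSet, SiteClass
from a2aolig.synthetic import gen_dimer_configuration, gen_dimer_frames
from conftest import make_residue, random_config


# --------------------------------------------------------------------------
# Daura clustering
# --------------------------------------------------------------------------

def reference_daura(D, cutoff):
    """Independent simulation of the neighbor-count algorithm over a
    precomputed RMSD matrix."""
    pool = list(range(len(D)))
    clusters = []
    while pool:
        best, best_n = None, None
        for i in pool:
            n = [j for j in pool if D[i][j] <= cutoff]
            if best_n is None or len(n) > len(best_n):
                best, best_n = i, n
        clusters.append(sorted(best_n))
        pool = [i for i in pool if i not in set(best_n)]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


def reference_rmsd(P, Q):
    """Superposition RMSD via scipy's rotation alignment (independent of
    the package's Kabsch)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(Qc, Pc)
    return float(np.sqrt(np.mean(np.sum((rot.apply(Pc) - Qc) ** 2, axis=1))))


class TestDauraCluster:
    def test_identical_frames_form_one_cluster(self):
        base, _ = gen_dimer_configuration(seed=0, contact_plan=[])
        frames = [copy.deepcopy(base) for _ in range(5)]
        for i, f in enumerate(frames):
            f.frame_index = i
        res = ia.daura_cluster(frames)
        assert [len(c) for c in res.clusters] == [5]

    def test_zero_cutoff_gives_singletons(self):
        frames, _ = gen_dimer_frames(seed=2, cluster_sizes=[4])
        res = ia.daura_cluster(frames, rmsd_cutoff=0.0)
        assert [len(c) for c in res.clusters] == [1, 1, 1, 1]

    def test_planted_cluster_sizes_recovered(self):
        frames, truth = gen_dimer_frames(seed=5, cluster_sizes=[5, 3, 2])
        res = ia.daura_cluster(frames, rmsd_cutoff=1.5)
        assert [len(c) for c in res.clusters] == [5, 3, 2]
        membership = res.membership()
        planted = truth["membership"]
        # same partition: frames planted together end up together
        for i in range(len(frames)):
            for j in range(i + 1, len(frames)):
                assert (membership[i] == membership[j]) == (planted[i] == planted[j])

    def test_matches_reference_simulation_on_rmsd_matrix(self):
        frames, _ = gen_dimer_frames(seed=7, cluster_sizes=[3, 2, 1],
                                     within_jitter=0.4)
        coords = [np.vstack([f.protomer_a.backbone_coords(),
                             f.protomer_b.backbone_coords()]) for f in frames]
        n = len(frames)
        D = [[reference_rmsd(coords[i], coords[j]) for j in range(n)] for i in range(n)]
        res = ia.daura_cluster(frames, rmsd_cutoff=1.5)
        assert res.clusters == reference_daura(D, 1.5)

    def test_partition_is_disjoint_and_exhaustive(self):
        frames, _ = gen_dimer_frames(seed=9, cluster_sizes=[4, 4, 2])
        res = ia.daura_cluster(frames)
        flat = [f for c in res.clusters for f in c]
        assert sorted(flat) == list(range(len(frames)))
        assert len(set(flat)) == len(flat)

    def test_idempotent_on_representatives(self):
        frames, _ = gen_dimer_frames(seed=11, cluster_sizes=[4, 3, 2])
        res = ia.daura_cluster(frames)
        reps = [frames[r] for r in res.representatives]
        res2 = ia.daura_cluster(reps)
        assert [len(c) for c in res2.clusters] == [1] * len(reps)

    def test_schema_mismatch_rejected(self):
        frames, _ = gen_dimer_frames(seed=1, cluster_sizes=[2])
        small, _ = gen_dimer_configuration(seed=1, contact_plan=[], n_residues=50)
        with pytest.raises(ValidationError, match="schema"):
            ia.daura_cluster(frames + [small])


# --------------------------------------------------------------------------
# helix tilt
# --------------------------------------------------------------------------

def ideal_helix_protomer(direction, n=20, region="TM7"):
    direction = np.asarray(direction, float)
    direction /= np.linalg.norm(direction)
    residues = []
    for k in range(n):
        pos = direction * 1.5 * k
        residues.append(make_residue(266 + k, region, [(SiteClass.BACKBONE, pos)]))
    return ia.ProtomerModel(residues)


class TestHelixTilt:
    def test_axis_along_normal_is_zero(self):
        assert ia.helix_tilt(ideal_helix_protomer([0, 0, 1]), "TM7") == pytest.approx(0.0, abs=1e-9)

    def test_axis_in_membrane_plane_is_ninety(self):
        assert ia.helix_tilt(ideal_helix_protomer([1, 0, 0]), "TM7") == pytest.approx(90.0, abs=1e-9)

    def test_planted_thirty_degrees_with_noise(self):
        cfg, _ = gen_dimer_configuration(seed=13, tilt_plan={"TM7": 30.0},
                                         contact_plan=[])
        assert ia.helix_tilt(cfg.protomer_a, "TM7") == pytest.approx(30.0, abs=1.0)

    def test_complementary_angles_sum_to_ninety(self):
        p = ideal_helix_protomer([math.sin(0.6), 0.0, math.cos(0.6)])
        a1 = ia.helix_tilt(p, "TM7", normal=(0, 0, 1))
        a2 = ia.helix_tilt(p, "TM7", normal=(1, 0, 0))  # in-plane, in the axis plane
        assert a1 + a2 == pytest.approx(90.0, abs=1e-6)

    def test_too_few_backbone_sites_rejected(self):
        with pytest.raises(ValidationError):
            ia.helix_tilt(ideal_helix_protomer([0, 0, 1], n=3), "TM7")


# --------------------------------------------------------------------------
# interacting helices
# --------------------------------------------------------------------------

class TestInteractingHelices:
    def test_separated_scaffolds_have_no_tm_interface(self):
        cfg, _ = gen_dimer_configuration(seed=1, contact_plan=[])
        assert ia.interacting_helices(cfg, cutoff=7.0) == []

    def test_planted_tm4_approach_detected(self):
        cfg, _ = gen_dimer_configuration(seed=1, contact_plan=[])
        # drag one TM4 residue of B next to a TM4 residue of A
        ra = next(r for r in cfg.protomer_a.residues if r.region == "TM4")
        rb = next(r for r in cfg.protomer_b.residues if r.region == "TM4")
        shift = ra.sites[0].xyz + np.array([6.0, 0.0, 0.0]) - rb.sites[0].xyz
        for s in rb.sites:
            s.xyz = s.xyz + shift
        pairs = ia.interacting_helices(cfg, cutoff=7.0)
        assert ("TM4", "TM4") in pairs

    def test_matches_exhaustive_scan(self):
        cfg, _ = gen_dimer_configuration(seed=3, contact_plan=[], separation=30.0)
        expected = set()
        for ha in ia.TM_REGIONS:
            pa = [s.xyz for r in cfg.protomer_a.residues if r.region == ha
                  for s in r.sites]
            for hb in ia.TM_REGIONS:
                pb = [s.xyz for r in cfg.protomer_b.residues if r.region == hb
                      for s in r.sites]
                dmin = min(np.linalg.norm(a - b) for a in pa for b in pb)
                if dmin < 7.0:
                    expected.add((ha, hb))
        assert set(ia.interacting_helices(cfg, cutoff=7.0)) == expected


# --------------------------------------------------------------------------
# interface classification
# --------------------------------------------------------------------------

def _contacts(pairs):
    return ContactSet([Contact(ra, rb, rega, regb, "electrostatic", 4.0)
                       for ra, rb, rega, regb in pairs])


class TestClassifyInterface:
    def test_pure_cterm_cterm_is_symmetric(self):
        cs = _contacts([(394, 394, "CTERM", "CTERM"), (355, 357, "CTERM", "CTERM")])
        assert ia.classify_interface(cs).classification == "symmetric"

    def test_cterm_to_loop_is_asymmetric(self):
        cs = _contacts([(394, 208, "CTERM", "ICL3"), (390, 108, "CTERM", "ICL2")])
        call = ia.classify_interface(cs)
        assert call.classification == "asymmetric"
        assert call.direction == "a->b"

    def test_empty_contact_set_is_none(self):
        assert ia.classify_interface(ContactSet([])).classification == "none"

    def test_swap_invariance(self):
        sym = _contacts([(394, 394, "CTERM", "CTERM")])
        swapped = _contacts([(394, 394, "CTERM", "CTERM")])
        assert ia.classify_interface(sym).classification == \
            ia.classify_interface(swapped).classification == "symmetric"
        asym = _contacts([(394, 208, "CTERM", "ICL3")])
        asym_sw = _contacts([(208, 394, "ICL3", "CTERM")])
        c1, c2 = ia.classify_interface(asym), ia.classify_interface(asym_sw)
        assert c1.classification == c2.classification == "asymmetric"
        assert {c1.direction, c2.direction} == {"a->b", "b->a"}

    def test_generated_topologies_classify_as_planted(self):
        for topology in ("symmetric", "asymmetric"):
            cfg, truth = gen_dimer_configuration(seed=17, topology=topology)
            union = ContactSet(
                ia.electrostatic_contacts(cfg).contacts
                + ia.hydrogen_bonds(cfg).contacts)
            assert ia.classify_interface(union).classification == topology


# --------------------------------------------------------------------------
# averaging
# --------------------------------------------------------------------------

class TestAverageContactCounts:
    segs = {"291-334": (291, 334), "335-394": (335, 394)}

    def test_constant_series_has_zero_sd(self):
        cs = _contacts([(300, 300, "CTERM", "CTERM"), (340, 350, "CTERM", "CTERM")])
        df = ia.average_contact_counts([cs] * 4, self.segs)
        row = df.set_index("segment").loc["291-334"]
        assert row["mean_count"] == 2.0  # residue 300 on both protomers
        assert row["sd"] == 0.0

    def test_two_frame_arithmetic(self):
        f1 = _contacts([(340 + i, 340 + i, "CTERM", "CTERM") for i in range(2)])  # 4 residues
        f2 = _contacts([(340 + i, 340 + i, "CTERM", "CTERM") for i in range(3)])  # 6 residues
        df = ia.average_contact_counts([f1, f2], {"335-394": (335, 394)})
        assert df.iloc[0]["mean_count"] == 5.0

    def test_planted_series_matches_bookkeeping(self, rng):
        per_frame = []
        expected = []
        for _ in range(10):
            k = int(rng.integers(0, 6))
            pairs = [(340 + i, 391, "CTERM", "CTERM") for i in range(k)]
            per_frame.append(_contacts(pairs))
            # k distinct a-residues + residue 391 on protomer b (when k > 0)
            expected.append(k + (1 if k else 0))
        df = ia.average_contact_counts(per_frame, {"335-394": (335, 394)})
        assert df.iloc[0]["mean_count"] == pytest.approx(np.mean(expected))
        assert df.iloc[0]["sd"] == pytest.approx(np.std(expected))

    def test_event_mode_counts_events(self):
        cs = _contacts([(340, 340, "CTERM", "CTERM")] * 1
                       + [(341, 340, "CTERM", "CTERM")])
        df = ia.average_contact_counts([cs], {"335-394": (335, 394)}, mode="events")
        assert df.iloc[0]["mean_count"] == 2.0

    def test_empty_segments_rejected(self):
        with pytest.raises(ValidationError):
            ia.average_contact_counts([ContactSet([])], {})
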