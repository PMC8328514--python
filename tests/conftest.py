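import numpy as np
import pytest

from a2aolig.interface_analysis import (
    DimerConfiguration,
    ProtomerModel,
    Residue,
    Site,
    SiteClass,
)


def make_residue(resid, region, sites_spec, name="ALA"):
    """sites_spec: list of (site_class, xyz) or (site_class, xyz, hydrogen)."""
    sites = []
    for spec in sites_spec:
        if len(spec) == 2:
            cls, xyz = spec
            sites.append(Site("S", cls, np.asarray(xyz, float)))
        else:
            cls, xyz, hyd = spec
            sites.append(Site("S", cls, np.asarray(xyz, float),
                              hydrogen=np.asarray(hyd, float)))
    return Residue(resid, name, region, sites)


def random_config(seed, n_res=12, spread=8.0):
    """Two compact random protomers with mixed site classes, close enough
    that contacts of every type occur; used against brute-force oracles."""
    rng = np.random.default_rng(seed)
    classes = [SiteClass.CHARGED_POS, SiteClass.CHARGED_NEG,
               SiteClass.POLAR_DONOR, SiteClass.POLAR_ACCEPTOR,
               SiteClass.NONPOLAR, SiteClass.BACKBONE]
    regions = ["CTERM", "ICL3", "TM1", "CTERM"]

    def protomer(offset, label):
        residues = []
        for i in range(n_res):
            resid = 291 + i  # keep CTERM labels legal
            region = regions[i % len(regions)]
            if region == "CTERM" and resid < 291:
                region = "ICL3"
            n_sites = int(rng.integers(1, 4))
            sites = []
            for _ in range(n_sites):
                cls = classes[int(rng.integers(len(classes)))]
                xyz = rng.uniform(-spread, spread, 3) + offset
                if cls is SiteClass.POLAR_DONOR:
                    hdir = rng.normal(size=3)
                    hdir /= np.linalg.norm(hdir)
                    sites.append(Site("S", cls, xyz, hydrogen=xyz + hdir))
                else:
                    sites.append(Site("S", cls, xyz))
            residues.append(Residue(resid, "ALA", region, sites))
        return ProtomerModel(residues, label=label)

    return DimerConfiguration(protomer(np.zeros(3), "A"),
                              protomer(np.array([4.0, 0.0, 0.0]), "B"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
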