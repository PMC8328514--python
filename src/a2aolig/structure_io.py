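"""Reading and writing dimer configurations as multi-model PDB.

A frame series is stored as a multi-model PDB (chain A / chain B, one
model per frame) written and parsed with biotite.  Site classes are
encoded in atom names and region labels live in a sidecar annotation file
(TOML): residue ranges -> region, the C-terminus start, and the atom-name
-> site-class map, all editable.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ParseError, ValidationError
from .interface_analysis import (
    DimerConfiguration,
    ProtomerModel,
    Residue,
    Site,
    SiteClass,
)

__all__ = [
    "DEFAULT_ATOM_CLASSES",
    "DEFAULT_REGIONS",
    "write_annotation",
    "read_annotation",
    "write_dimer_frames",
    "read_dimer_frames",
]

#: atom-name encoding of site classes (PDB atom names are <= 4 chars)
DEFAULT_ATOM_CLASSES: dict[str, str] = {
    "CA": SiteClass.BACKBONE.value,
    "CP": SiteClass.CHARGED_POS.value,
    "CN": SiteClass.CHARGED_NEG.value,
    "ND": SiteClass.POLAR_DONOR.value,
    "OA": SiteClass.POLAR_ACCEPTOR.value,
    "CB": SiteClass.NONPOLAR.value,
}
HYDROGEN_ATOM = "HD"  # hydrogen attached to the donor site of the same residue

#: default A2A-receptor-like region boundaries (1-based residue ranges).
#: Approximate and editable; only the C-terminus start (291) is load-bearing.
DEFAULT_REGIONS: list[tuple[str, int, int]] = [
    ("TM1", 1, 33), ("ICL1", 34, 38), ("TM2", 39, 66), ("ECL1", 67, 72),
    ("TM3", 73, 106), ("ICL2", 107, 110), ("TM4", 111, 137), ("ECL2", 138, 173),
    ("TM5", 174, 204), ("ICL3", 205, 221), ("TM6", 222, 258), ("ECL3", 259, 265),
    ("TM7", 266, 290), ("CTERM", 291, 412),
]


def write_annotation(
    path: str | Path,
    regions: list[tuple[str, int, int]] | None = None,
    cterm_start: int = 291,
    atom_classes: dict[str, str] | None = None,
) -> None:
    regions = regions or DEFAULT_REGIONS
    atom_classes = atom_classes or DEFAULT_ATOM_CLASSES
    lines = [f"cterm_start = {cterm_start}", "", "[atom_classes]"]
    for k, v in atom_classes.items():
        lines.append(f'{k} = "{v}"')
    lines.append("")
    for name, lo, hi in regions:
        lines.extend(["[[regions]]", f'name = "{name}"', f"start = {lo}", f"end = {hi}", ""])
    Path(path).write_text("\n".join(lines))


def read_annotation(path: str | Path):
    try:
        data = tomllib.loads(Path(path).read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    regions = [(r["name"], int(r["start"]), int(r["end"])) for r in data.get("regions", [])]
    if not regions:
        raise ValidationError(f"{path}: no region definitions")
    return {
        "regions": regions,
        "cterm_start": int(data.get("cterm_start", 291)),
        "atom_classes": dict(data.get("atom_classes", DEFAULT_ATOM_CLASSES)),
    }


def _region_of(resid: int, regions: list[tuple[str, int, int]]) -> str:
    for name, lo, hi in regions:
        if lo <= resid <= hi:
            return name
    raise ValidationError(f"residue {resid} not covered by any region range")


def _protomer_atoms(protomer: ProtomerModel, chain: str):
    atoms = []
    class_to_name = {v: k for k, v in DEFAULT_ATOM_CLASSES.items()}
    for r in protomer.residues:
        for s in r.sites:
            name = class_to_name[s.site_class.value]
            atoms.append((chain, r.resid, r.name, name, s.xyz))
            if s.hydrogen is not None:
                atoms.append((chain, r.resid, r.name, HYDROGEN_ATOM, s.hydrogen))
    return atoms


def write_dimer_frames(frames: list[DimerConfiguration], path: str | Path) -> None:
    """Write a frame series as a multi-model PDB (chains A and B)."""
    if not frames:
        raise ValidationError("no frames to write")
    per_model = []
    n_atoms = None
    for f in frames:
        atoms = _protomer_atoms(f.protomer_a, "A") + _protomer_atoms(f.protomer_b, "B")
        if n_atoms is None:
            n_atoms = len(atoms)
        elif len(atoms) != n_atoms:
            raise ValidationError("frames do not share the site schema")
        per_model.append(atoms)

    arr = struc.AtomArrayStack(len(per_model), n_atoms)
    first = per_model[0]
    arr.chain_id = np.array([a[0] for a in first])
    arr.res_id = np.array([a[1] for a in first])
    arr.res_name = np.array([a[2][:3].upper() for a in first])
    arr.atom_name = np.array([a[3] for a in first])
    arr.element = np.array(["H" if a[3] == HYDROGEN_ATOM else a[3][0] for a in first])
    arr.hetero = np.full(n_atoms, False)
    for m, atoms in enumerate(per_model):
        arr.coord[m] = np.array([a[4] for a in atoms])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_dimer_frames(
    path: str | Path,
    annotation: str | Path | dict,
    box: np.ndarray | None = None,
) -> list[DimerConfiguration]:
    """Read a multi-model PDB back into a frame series, using the
    annotation file for region labels and site classes."""
    if not isinstance(annotation, dict):
        annotation = read_annotation(annotation)
    regions = annotation["regions"]
    cterm_start = annotation["cterm_start"]
    name_to_class = {k: SiteClass(v) for k, v in annotation["atom_classes"].items()}

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    frames = []
    for m in range(stack.stack_depth()):
        model = stack[m]
        protomers = {}
        for chain in ("A", "B"):
            mask = model.chain_id == chain
            if not mask.any():
                raise ParseError(f"{path}: chain {chain} missing in model {m}")
            sub = model[mask]
            residues: list[Residue] = []
            for resid in np.unique(sub.res_id):
                rmask = sub.res_id == resid
                ratoms = sub[rmask]
                rname = str(ratoms.res_name[0])
                sites: list[Site] = []
                hyd = None
                for i in range(ratoms.array_length()):
                    aname = str(ratoms.atom_name[i])
                    if aname == HYDROGEN_ATOM:
                        hyd = ratoms.coord[i].copy()
                        continue
                    if aname not in name_to_class:
                        raise ParseError(f"{path}: unknown atom name {aname!r}")
                    sites.append(Site(aname, name_to_class[aname], ratoms.coord[i].copy()))
                if hyd is not None:
                    donors = [s for s in sites if s.site_class is SiteClass.POLAR_DONOR]
                    if donors:
                        donors[0].hydrogen = hyd
                residues.append(Residue(int(resid), rname,
                                        _region_of(int(resid), regions), sites))
            protomers[chain] = ProtomerModel(residues, label=chain,
                                             cterm_start=cterm_start)
        frames.append(DimerConfiguration(protomers["A"], protomers["B"],
                                         frame_index=m, box=box))
    return frames
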