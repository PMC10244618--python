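"""Distance-based residue-residue contact classification on 3D structures.

Heavy-atom, distance-only criteria (no hydrogen placement, no angle
terms): a hydrogen bond is an N/O donor-acceptor heavy-atom pair within
3.4 A, a salt bridge an opposite-charge group N/O pair within 4.0 A, a
hydrophobic contact a sidechain carbon-carbon pair within 5.6 A (wide
enough to include the weak contacts reported for FERM-domain variants),
and a pi-sulfur contact an aromatic ring centroid within 5.5 A of a
sulfur.  All cutoffs are configuration values.

Structures are read with gemmi (PDB and mmCIF)."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Literal

import gemmi
import numpy as np
import pandas as pd

__all__ = ["load_structure", "min_distance", "classify_contacts",
           "ContactRecord", "ContactCutoffs", "contacts_to_tsv"]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

#: charged sidechain group atoms per residue type (heavy atoms carrying the
#: formal charge)
_CHARGED: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2"),
}
_NEGATIVE = {"ASP", "GLU"}
_POSITIVE = {"ARG", "LYS", "HIS"}

_AROMATIC_RING: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

Selector = Literal["all", "sidechain", "charged_group", "carbon"]


@dataclass(frozen=True)
class ContactCutoffs:
    """Distance cutoffs (Angstrom) for contact classification."""

    hydrogen_bond: float = 3.4
    salt_bridge: float = 4.0
    hydrophobic: float = 5.6
    pi_sulfur: float = 5.5


@dataclass(frozen=True)
class ContactRecord:
    chain_a: str
    resnum_a: int
    resname_a: str
    chain_b: str
    resnum_b: int
    resname_b: str
    contact_type: str
    min_distance: float
    atom_a: str
    atom_b: str


def load_structure(path) -> gemmi.Structure:
    """Read a PDB or mmCIF file into a gemmi Structure."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def _find_residue(model: gemmi.Model, chain: str, resnum: int) -> gemmi.Residue:
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            if res.seqid.num == resnum:
                return res
    raise KeyError(f"residue {chain}/{resnum} not found in structure")


def _select_atoms(res: gemmi.Residue, selector: Selector
                  ) -> list[tuple[str, np.ndarray]]:
    out = []
    for atom in res:
        name = atom.name
        el = atom.element.name.upper()
        if selector == "all":
            keep = True
        elif selector == "sidechain":
            keep = name not in _BACKBONE
        elif selector == "charged_group":
            keep = name in _CHARGED.get(res.name, ())
        elif selector == "carbon":
            keep = el == "C" and name not in _BACKBONE
        else:
            raise ValueError(f"unknown selector {selector!r}")
        if keep:
            out.append((name, np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
    return out


def min_distance(
    structure: gemmi.Structure,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    selector: Selector = "all",
    model_index: int = 0,
) -> tuple[float, str, str]:
    """Minimum Euclidean distance between two residues' selected atoms.

    Returns (distance in A, atom name in A-residue, atom name in B).
    The degenerate case ``res_a == res_b`` returns (0.0, "", "").
    """
    model = structure[model_index]
    ra = _find_residue(model, *res_a)
    rb = _find_residue(model, *res_b)
    if res_a == res_b:
        return 0.0, "", ""
    atoms_a = _select_atoms(ra, selector)
    atoms_b = _select_atoms(rb, selector)
    if not atoms_a or not atoms_b:
        raise ValueError(
            f"selector {selector!r} matches no atoms for "
            f"{res_a if not atoms_a else res_b}")
    best = None
    for (na, pa), (nb, pb) in product(atoms_a, atoms_b):
        d = float(np.linalg.norm(pa - pb))
        if best is None or d < best[0]:
            best = (d, na, nb)
    return best


def _pair_min(atoms_a, atoms_b):
    best = None
    for (na, pa), (nb, pb) in product(atoms_a, atoms_b):
        d = float(np.linalg.norm(pa - pb))
        if best is None or d < best[0]:
            best = (d, na, nb)
    return best


def classify_contacts(
    structure: gemmi.Structure,
    residue: tuple[str, int],
    cutoffs: ContactCutoffs = ContactCutoffs(),
    min_separation: int = 2,
    model_index: int = 0,
) -> list[ContactRecord]:
    """All classified contacts of one residue against the rest of the model.

    ``min_separation`` suppresses trivially bonded sequence neighbours on
    the same chain (|delta residue number| <= min_separation).  Unknown
    residue types are skipped for type-specific criteria.  A residue
    pair can yield one record per satisfied contact type.
    """
    model = structure[model_index]
    ra = _find_residue(model, *residue)
    chain_a, num_a = residue
    records: list[ContactRecord] = []
    for ch in model:
        for rb in ch:
            if ch.name == chain_a and abs(rb.seqid.num - num_a) <= min_separation:
                continue
            for rec in _classify_pair(ra, chain_a, num_a, rb, ch.name, cutoffs):
                records.append(rec)
    records.sort(key=lambda r: (r.chain_b, r.resnum_b, r.contact_type))
    return records


def _no_atoms_ok(res, selector):
    try:
        return _select_atoms(res, selector)
    except ValueError:
        return []


def _classify_pair(ra, chain_a, num_a, rb, chain_b, cutoffs
                   ) -> Iterable[ContactRecord]:
    def rec(ctype, d, aa, ab):
        return ContactRecord(chain_a, num_a, ra.name, chain_b, rb.seqid.num,
                             rb.name, ctype, round(d, 3), aa, ab)

    # hydrogen bond: N/O heavy atoms (backbone + sidechain) within cutoff
    no_a = [(n, p) for n, p in _select_atoms(ra, "all")
            if n.startswith(("N", "O"))]
    no_b = [(n, p) for n, p in _select_atoms(rb, "all")
            if n.startswith(("N", "O"))]
    if no_a and no_b:
        best = _pair_min(no_a, no_b)
        if best and best[0] <= cutoffs.hydrogen_bond:
            yield rec("hydrogen_bond", *best)

    # salt bridge: opposite formal charges, charged-group atoms
    pair_signs = {(True, False), (False, True)}
    sign_a = ra.name in _POSITIVE if ra.name in _CHARGED else None
    sign_b = rb.name in _POSITIVE if rb.name in _CHARGED else None
    if sign_a is not None and sign_b is not None and (sign_a, sign_b) in pair_signs:
        ga = _select_atoms(ra, "charged_group")
        gb = _select_atoms(rb, "charged_group")
        if ga and gb:
            best = _pair_min(ga, gb)
            if best and best[0] <= cutoffs.salt_bridge:
                yield rec("salt_bridge", *best)

    # hydrophobic: sidechain carbon-carbon
    ca = _select_atoms(ra, "carbon")
    cb = _select_atoms(rb, "carbon")
    if ca and cb:
        best = _pair_min(ca, cb)
        if best and best[0] <= cutoffs.hydrophobic:
            yield rec("hydrophobic", *best)

    # pi-sulfur: aromatic ring centroid vs S
    for aromatic, sulfur, swap in ((ra, rb, False), (rb, ra, True)):
        ring = _AROMATIC_RING.get(aromatic.name)
        if ring is None:
            continue
        pts = [p for n, p in _select_atoms(aromatic, "all") if n in ring]
        if len(pts) < 3:
            continue
        centroid = np.mean(pts, axis=0)
        s_atoms = [(n, p) for n, p in _select_atoms(sulfur, "all")
                   if n.startswith("S") and n not in _BACKBONE]
        for n, p in s_atoms:
            d = float(np.linalg.norm(centroid - p))
            if d <= cutoffs.pi_sulfur:
                aa, ab = ("ring_centroid", n) if not swap else (n, "ring_centroid")
                yield rec("pi_sulfur", d, aa, ab)
                break


def contacts_to_tsv(records: list[ContactRecord], path,
                    header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame([r.__dict__ for r in records]).to_csv(fh, sep="\t",
                                                           index=False)
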