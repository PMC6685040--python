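"""Intermolecular residue contact mapping for receptor complexes.

Contacts are defined on minimum heavy-atom distance between residues of
two chains.  Chemical classes follow common structural-biology practice
on unrefined models: a salt bridge needs a basic side-chain nitrogen
within 4 Å of an acidic side-chain oxygen, a hydrogen-bond candidate is
any N/O–N/O pair within 3.5 Å (no angle term — the models carry no
hydrogens), and an aromatic contact pairs two aromatic residues.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureModel

ACIDIC = {"ASP", "GLU"}
BASIC = {"ARG", "LYS", "HIS"}
AROMATIC = {"PHE", "TYR", "TRP", "HIS"}

BASIC_SC_N = {"NE", "NH1", "NH2", "NZ", "ND1", "NE2"}
ACIDIC_SC_O = {"OD1", "OD2", "OE1", "OE2"}

DEFAULT_CUTOFF = 4.0
SALT_BRIDGE_CUTOFF = 4.0
HBOND_CUTOFF = 3.5


@dataclass(frozen=True)
class ContactRecord:
    chain_a: str
    residue_a: int
    resname_a: str
    chain_b: str
    residue_b: int
    resname_b: str
    distance: float
    contact_class: str
    atom_a: str
    atom_b: str
    truncated: bool = False  # a partner is a Cβ-truncated threaded residue


def _chain_atoms(model: StructureModel, chain_id: str):
    chain = model.chain(chain_id)
    coords, meta = [], []
    for res in chain.residues:
        truncated = res.is_cb_truncated
        for atom in res.heavy_atoms():
            coords.append(atom.pos)
            meta.append((res, atom, truncated))
    if not coords:
        raise ValueError(f"chain {chain_id} has no heavy atoms")
    return np.array(coords), meta


def _classify(res_a, res_b, pairs: list[tuple[str, str, float]]) -> str:
    na, nb = res_a.name, res_b.name
    salt = ((na in BASIC and nb in ACIDIC) or (na in ACIDIC and nb in BASIC))
    if salt:
        for atom_a, atom_b, d in pairs:
            basic_atom = atom_a if na in BASIC else atom_b
            acidic_atom = atom_b if na in BASIC else atom_a
            if (basic_atom in BASIC_SC_N and acidic_atom in ACIDIC_SC_O
                    and d <= SALT_BRIDGE_CUTOFF):
                return "salt_bridge"
    for atom_a, atom_b, d in pairs:
        if (atom_a.startswith(("N", "O")) and atom_b.startswith(("N", "O"))
                and d <= HBOND_CUTOFF):
            return "hbond_candidate"
    if na in AROMATIC and nb in AROMATIC:
        return "aromatic"
    return "generic"


def compute_contacts(model: StructureModel, ligand_chain: str,
                     receptor_chain: str,
                     cutoff: float = DEFAULT_CUTOFF) -> list[ContactRecord]:
    """All residue pairs across two chains with min heavy-atom distance
    within the cutoff, reported once each and sorted by distance."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_xyz, lig_meta = _chain_atoms(model, ligand_chain)
    rec_xyz, rec_meta = _chain_atoms(model, receptor_chain)
    tree = cKDTree(rec_xyz)
    neighbors = tree.query_ball_point(lig_xyz, r=cutoff)

    per_pair: dict[tuple, dict] = {}
    for i, hits in enumerate(neighbors):
        res_a, atom_a, trunc_a = lig_meta[i]
        for j in hits:
            res_b, atom_b, trunc_b = rec_meta[j]
            d = float(np.linalg.norm(lig_xyz[i] - rec_xyz[j]))
            key = (res_a.number, res_a.icode, res_b.number, res_b.icode)
            entry = per_pair.setdefault(
                key, {"res_a": res_a, "res_b": res_b,
                      "pairs": [], "trunc": trunc_a or trunc_b})
            entry["pairs"].append((atom_a.name, atom_b.name, d))

    records = []
    for entry in per_pair.values():
        pairs = sorted(entry["pairs"], key=lambda p: p[2])
        atom_a, atom_b, dmin = pairs[0]
        res_a, res_b = entry["res_a"], entry["res_b"]
        records.append(ContactRecord(
            chain_a=ligand_chain, residue_a=res_a.number, resname_a=res_a.name,
            chain_b=receptor_chain, residue_b=res_b.number,
            resname_b=res_b.name, distance=round(dmin, 4),
            contact_class=_classify(res_a, res_b, pairs),
            atom_a=atom_a, atom_b=atom_b, truncated=entry["trunc"]))
    records.sort(key=lambda r: (r.distance, r.residue_a, r.residue_b))
    return records


def verify_anchor_contacts(contacts: Sequence[ContactRecord],
                           expected: Iterable[tuple[int, int]]) -> list[dict]:
    """Mark each expected (ligand residue, receptor residue) pair as
    present or absent among the computed contacts."""
    observed = {(c.residue_a, c.residue_b): c for c in contacts}
    report = []
    for lig, rec in expected:
        hit = observed.get((lig, rec))
        report.append({
            "ligand_residue": lig,
            "receptor_residue": rec,
            "present": hit is not None,
            "distance": None if hit is None else hit.distance,
            "contact_class": None if hit is None else hit.contact_class,
        })
    return report


def pocket_residues(contacts: Sequence[ContactRecord]) -> set[int]:
    """Receptor residues participating in at least one contact."""
    return {c.residue_b for c in contacts}


def interface_residues_gprotein(model: StructureModel, receptor_chain: str,
                                subunit_chains: Mapping[str, str],
                                cutoff: float = DEFAULT_CUTOFF
                                ) -> dict[str, set[int]]:
    """Receptor residues within the cutoff of each G-protein subunit.

    ``subunit_chains`` maps a subunit label (e.g. ``alpha``/``beta``/
    ``gamma``) to its chain id; the result maps labels to receptor
    residue sets.
    """
    result: dict[str, set[int]] = {}
    for label, chain_id in subunit_chains.items():
        pairs = compute_contacts(model, receptor_chain, chain_id, cutoff)
        result[label] = {c.residue_a for c in pairs}
    return result


def contacts_to_csv(contacts: Sequence[ContactRecord], path,
                    header_comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(["chain_a", "residue_a", "resname_a", "chain_b",
                         "residue_b", "resname_b", "distance",
                         "contact_class", "atom_a", "atom_b", "truncated"])
        for c in contacts:
            writer.writerow([c.chain_a, c.residue_a, c.resname_a, c.chain_b,
                             c.residue_b, c.resname_b, c.distance,
                             c.contact_class, c.atom_a, c.atom_b,
                             int(c.truncated)])


def contacts_to_json(contacts: Sequence[ContactRecord], path,
                     provenance: dict | None = None) -> None:
    payload = {"provenance": provenance or {},
               "contacts": [asdict(c) for c in contacts]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
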