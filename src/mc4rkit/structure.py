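"""Coordinate models: PDB I/O, rigid superposition, and alignment-based
threading of a target sequence onto a template backbone.

Threading is purely geometric — backbone atoms are copied from the
template, conserved residues keep their side chains, substituted residues
are truncated to an ideally placed Cβ, and unalignable target residues are
reported rather than built.  No refinement of any kind is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

from .geometry import ideal_cb, kabsch
from .sequences import PairwiseAlignment, SequenceRecord

BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}


def _element_of(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[0].upper() if stripped else "X"


@dataclass
class Atom:
    name: str
    pos: np.ndarray  # (3,) Å
    element: str = ""
    b: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: coordinates must be a "
                             "finite 3-vector")
        if not self.element:
            self.element = _element_of(self.name)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    number: int
    name: str  # 3-letter code
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def coords(self, names: Iterable[str] | None = None) -> np.ndarray:
        if names is None:
            return np.array([a.pos for a in self.atoms])
        sel = [self.atom(n) for n in names]
        missing = [n for n, a in zip(names, sel) if a is None]
        if missing:
            raise KeyError(f"residue {self.name}{self.number} lacks atoms "
                           f"{missing}")
        return np.array([a.pos for a in sel])

    @property
    def one_letter(self) -> str:
        return ONE_LETTER.get(self.name, "X")

    @property
    def is_cb_truncated(self) -> bool:
        """True when a non-Gly/Ala residue carries no atoms beyond Cβ."""
        if self.name in ("GLY", "ALA"):
            return False
        return all(a.name in ("N", "CA", "C", "O", "CB") for a in self.atoms)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for r in self.residues:
            key = (r.number, r.icode)
            if key in seen:
                raise ValueError(f"duplicate residue {key} in chain {self.id}")
            seen.add(key)

    def residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class StructureModel:
    """Chains of residues of atoms, with provenance metadata."""

    chains: list[Chain]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.chains:
            raise ValueError("a structure needs at least one chain")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} "
                       f"(have {[c.id for c in self.chains]})")

    def atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    @property
    def atom_count(self) -> int:
        return sum(1 for _ in self.atoms())

    def copy(self) -> "StructureModel":
        chains = [Chain(c.id, [Residue(r.number, r.name,
                                       [Atom(a.name, a.pos.copy(), a.element,
                                             a.b, a.occupancy)
                                        for a in r.atoms], r.icode)
                               for r in c.residues])
                  for c in self.chains]
        return StructureModel(chains, dict(self.metadata))

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "StructureModel":
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for _, _, a in out.atoms():
            a.pos = R @ a.pos + t
        return out


# ---------------------------------------------------------------------------
# PDB I/O (wwPDB v3.3 columns via gemmi)

def _pick_altloc(group: list) -> "gemmi.Atom":
    # highest occupancy wins; ties resolved toward altloc 'A' (then
    # alphabetically) so reads are reproducible
    return sorted(group, key=lambda a: (-a.occ, a.altloc or "A"))[0]


def read_structure(path) -> StructureModel:
    """Parse a PDB file into a StructureModel.

    All ATOM/HETATM records are kept, insertion codes are preserved, and
    alternate locations are resolved to the highest-occupancy conformer.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if not st or not len(st[0]):
        raise ValueError(f"no coordinates found in {path}")
    model = st[0]
    chains = []
    for ch in model:
        residues = []
        for res in ch:
            by_name: dict[str, list] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for name, group in by_name.items():
                atom = _pick_altloc(group)
                atoms.append(Atom(name=name,
                                  pos=np.array([atom.pos.x, atom.pos.y,
                                                atom.pos.z]),
                                  element=atom.element.name,
                                  b=atom.b_iso, occupancy=atom.occ))
            residues.append(Residue(number=res.seqid.num, name=res.name,
                                    atoms=atoms,
                                    icode=(res.seqid.icode or "").strip()))
        chains.append(Chain(id=ch.name, residues=residues))
    return StructureModel(chains, metadata={"source": str(path)})


def write_structure(model: StructureModel, path,
                    remarks: Sequence[str] = ()) -> None:
    st = gemmi.Structure()
    st.name = "mc4rkit"
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.pos = gemmi.Position(*atom.pos)
                ga.element = gemmi.Element(atom.element)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        for remark in remarks:
            fh.write(f"REMARK 300 {remark}\n")
        fh.write(doc)


# ---------------------------------------------------------------------------
# superposition

@dataclass
class Superposition:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, model: StructureModel) -> StructureModel:
        return model.transformed(self.rotation, self.translation)


def paired_coords(mobile: StructureModel, target: StructureModel,
                  atom_names: Sequence[str] = ("CA",),
                  chain_pair: tuple[str, str] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms shared by residue number and atom name."""
    if chain_pair is None:
        mob_chains, tgt_chains = mobile.chains, target.chains
    else:
        mob_chains = [mobile.chain(chain_pair[0])]
        tgt_chains = [target.chain(chain_pair[1])]
    P, Q = [], []
    for mc, tc in zip(mob_chains, tgt_chains):
        tgt_res = {(r.number, r.icode): r for r in tc.residues}
        for r in mc.residues:
            other = tgt_res.get((r.number, r.icode))
            if other is None:
                continue
            for name in atom_names:
                a, b = r.atom(name), other.atom(name)
                if a is not None and b is not None:
                    P.append(a.pos)
                    Q.append(b.pos)
    return np.array(P), np.array(Q)


def superpose(mobile: StructureModel, target: StructureModel,
              atom_names: Sequence[str] = ("CA",),
              chain_pair: tuple[str, str] | None = None) -> Superposition:
    """Optimal rigid-body superposition (Kabsch) of paired atoms."""
    P, Q = paired_coords(mobile, target, atom_names, chain_pair)
    if len(P) < 3:
        raise ValueError(f"need at least 3 paired atoms, found {len(P)}")
    R, t, rmsd = kabsch(P, Q)
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(P))


# ---------------------------------------------------------------------------
# threading

def thread_sequence(template: StructureModel, aln: PairwiseAlignment,
                    target: SequenceRecord,
                    template_chain: str | None = None,
                    output_chain: str = "A") -> StructureModel:
    """Substitute the target sequence onto the template backbone.

    The alignment's A side is the target sequence and its B side the
    template chain.  For every aligned column the backbone (N, CA, C, O)
    is copied unchanged; a conserved residue keeps all template atoms,
    while a substituted one is truncated to Cβ built at ideal tetrahedral
    geometry.  Template-only residues are dropped, target-only residues
    are left unmodeled and listed in the metadata.
    """
    chain = (template.chains[0] if template_chain is None
             else template.chain(template_chain))
    by_number = {r.number: r for r in chain.residues}

    residues: list[Residue] = []
    unmodeled: list[int] = []
    dropped: list[int] = []
    for na, nb in aln.columns:
        if na is None:
            dropped.append(nb)
            continue
        if nb is None:
            unmodeled.append(na)
            continue
        if nb not in by_number:
            raise ValueError(f"alignment references template residue {nb}, "
                             "which has no coordinates")
        tmpl = by_number[nb]
        target_res = target.residue_at(na)
        name = THREE_LETTER.get(target_res, "UNK")
        if tmpl.one_letter == target_res:
            atoms = [Atom(a.name, a.pos.copy(), a.element) for a in tmpl.atoms
                     if a.is_heavy]
        else:
            atoms = [Atom(a.name, a.pos.copy(), a.element)
                     for a in tmpl.atoms if a.name in BACKBONE_ATOMS]
            if name != "GLY":
                have = {a.name for a in atoms}
                if {"N", "CA", "C"} <= have:
                    n, ca, c = (next(a.pos for a in atoms if a.name == x)
                                for x in ("N", "CA", "C"))
                    cb = tmpl.atom("CB")
                    pos = cb.pos.copy() if cb is not None else ideal_cb(n, ca, c)
                    atoms.append(Atom("CB", pos, "C"))
        residues.append(Residue(number=na, name=name, atoms=atoms))

    model = StructureModel(
        [Chain(output_chain, residues)],
        metadata={
            "template": template.metadata.get("source", "template"),
            "template_chain": chain.id,
            "target": target.id,
            "unmodeled_target_residues": unmodeled,
            "dropped_template_residues": dropped,
        })
    return model


# ---------------------------------------------------------------------------
# disulfides

@dataclass(frozen=True)
class DisulfideBond:
    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    distance: float
    atom_pair: str = "SG-SG"


def annotate_disulfides(model: StructureModel,
                        max_ss_distance: float = 2.5,
                        cb_fallback_distance: float = 5.5
                        ) -> list[DisulfideBond]:
    """Cystine pairing by Sγ–Sγ proximity, greedy nearest-first.

    Cysteines truncated to Cβ are paired on Cβ–Cβ distance with a wider
    cutoff, since the sulfur positions are not present in threaded models.
    Each cysteine joins at most one bond.
    """
    cys = []
    for chain in model.chains:
        for res in chain.residues:
            if res.name != "CYS":
                continue
            sg = res.atom("SG")
            cb = res.atom("CB")
            if sg is not None:
                cys.append((chain.id, res.number, sg.pos, "SG"))
            elif cb is not None:
                cys.append((chain.id, res.number, cb.pos, "CB"))
    candidates = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            ca, na, pa, ta = cys[i]
            cb_, nb, pb, tb = cys[j]
            d = float(np.linalg.norm(pa - pb))
            cutoff = (max_ss_distance if ta == tb == "SG"
                      else cb_fallback_distance)
            if d <= cutoff:
                candidates.append((d, i, j))
    bonds = []
    used: set[int] = set()
    for d, i, j in sorted(candidates):
        if i in used or j in used:
            continue
        used.update((i, j))
        ca, na, _, ta = cys[i]
        cb_, nb, _, tb = cys[j]
        bonds.append(DisulfideBond(ca, na, cb_, nb, round(d, 3),
                                   atom_pair=f"{ta}-{tb}"))
    return bonds
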