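"""Receptor dimer assembly and bivalent-ligand span geometry.

Two alternative protomer packings recur in class A GPCR crystal dimers
and frame the analysis here: a compact interface through TMH4/ICL2/TMH5
(CXCR4-like) and an interface through TMH1/TMH2/H8 (KOR-like).  Because
the orthosteric pocket sits toward the TMH3-6 face, the two arrangements
put the pocket pair at very different separations, which decides whether
one bivalent ligand of a given linker length can bridge both protomers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .sequences import TopologyAnnotation
from .structure import Chain, StructureModel, superpose

#: interface helices per arrangement label
ARRANGEMENTS = {
    "cxcr4": {"label": "TM4_ICL2_TM5", "helices": (4, 5)},
    "kor": {"label": "TM1_TM2_H8", "helices": (1, 2)},
}

CLASH_DISTANCE = 2.0  # Å heavy-atom; dimers are reported, never repacked
PER_ATOM_REACH = 1.25  # Å per linker atom, extended sp3 chain projection
INTERFACE_CUTOFF = 5.0  # Å heavy-atom for interface residue listing


@dataclass
class SpanReport:
    arrangement: str
    centroid_a: tuple[float, float, float]
    centroid_b: tuple[float, float, float]
    span: float
    linker_atoms: int
    reach: float
    feasible: bool
    margin: float

    def to_json(self, path, provenance: dict | None = None) -> None:
        payload = asdict(self)
        if provenance:
            payload["provenance"] = provenance
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _clash_count(model: StructureModel, chain_a: str, chain_b: str,
                 threshold: float = CLASH_DISTANCE) -> int:
    xa = np.array([a.pos for r in model.chain(chain_a).residues
                   for a in r.heavy_atoms()])
    xb = np.array([a.pos for r in model.chain(chain_b).residues
                   for a in r.heavy_atoms()])
    tree = cKDTree(xb)
    return int(sum(len(hits) for hits in tree.query_ball_point(xa, threshold)))


def assemble_dimer(protomer: StructureModel,
                   template_dimer: StructureModel,
                   atom_names: Sequence[str] = ("CA",)) -> StructureModel:
    """Superpose one protomer copy onto each chain of a template dimer.

    Atoms are paired by residue number and atom name, so the protomer and
    template chains must share a numbering frame (a threading product on
    the same sequence, or the synthetic fixtures).  The returned model has
    chains A and B and records the inter-protomer clash count (< 2 Å) in
    its metadata.
    """
    if len(template_dimer.chains) != 2:
        raise ValueError("template dimer must have exactly 2 chains")
    if len(protomer.chains) != 1:
        raise ValueError("protomer must be a single chain")

    placed = []
    rmsds = []
    for out_id, tmpl_chain in zip("AB", template_dimer.chains):
        sup = superpose(protomer, template_dimer, atom_names,
                        chain_pair=(protomer.chains[0].id, tmpl_chain.id))
        copy = sup.apply(protomer)
        chain = copy.chains[0]
        placed.append(Chain(out_id, chain.residues))
        rmsds.append(sup.rmsd)

    dimer = StructureModel(placed, metadata={
        "template": template_dimer.metadata.get("source", "template"),
        "superposition_rmsd": [round(r, 4) for r in rmsds],
    })
    dimer.metadata["clash_count"] = _clash_count(dimer, "A", "B")
    return dimer


def interface_residues(dimer: StructureModel,
                       topology: TopologyAnnotation | None = None,
                       cutoff: float = INTERFACE_CUTOFF
                       ) -> dict[str, list[tuple[int, str]]]:
    """Residues of each protomer within the cutoff of the other, joined
    to topology region labels when a topology is supplied."""
    if len(dimer.chains) != 2:
        raise ValueError("expected a two-protomer dimer")
    ca, cb = dimer.chains

    def _atoms(chain):
        xyz, owners = [], []
        for res in chain.residues:
            for atom in res.heavy_atoms():
                xyz.append(atom.pos)
                owners.append(res.number)
        return np.array(xyz), owners

    xa, owner_a = _atoms(ca)
    xb, owner_b = _atoms(cb)
    tree = cKDTree(xb)
    hits_a: set[int] = set()
    hits_b: set[int] = set()
    for i, hits in enumerate(tree.query_ball_point(xa, cutoff)):
        if hits:
            hits_a.add(owner_a[i])
            hits_b.update(owner_b[j] for j in hits)

    def _label(nums: set[int]) -> list[tuple[int, str]]:
        if topology is None:
            return [(n, "") for n in sorted(nums)]
        return [(n, topology.label_of(n)) for n in sorted(nums)]

    return {ca.id: _label(hits_a), cb.id: _label(hits_b)}


def _pocket_centroid(chain: Chain, pocket: Iterable[int]) -> np.ndarray:
    coords = []
    missing = []
    for number in pocket:
        res = chain.residue(number)
        if res is None:
            missing.append(number)
            continue
        coords.extend(a.pos for a in res.heavy_atoms())
    if missing:
        raise ValueError(f"pocket residues {missing} absent from chain "
                         f"{chain.id}")
    return np.array(coords).mean(axis=0)


def linker_feasibility(span: float, n_atoms: int,
                       per_atom_reach: float = PER_ATOM_REACH
                       ) -> tuple[bool, float]:
    """Whether an n-atom spacer can bridge a pocket-to-pocket span.

    Reach is the extended-chain approximation ``n_atoms * per_atom_reach``;
    the margin is ``reach - span`` (non-negative means feasible).
    """
    if span < 0:
        raise ValueError("span must be non-negative")
    if n_atoms < 1 or per_atom_reach <= 0:
        raise ValueError("linker needs at least one atom of positive reach")
    reach = n_atoms * per_atom_reach
    margin = reach - span
    return margin >= 0, margin


def pocket_span(dimer: StructureModel, pocket: Iterable[int],
                arrangement: str = "",
                linker_atoms: int = 20,
                per_atom_reach: float = PER_ATOM_REACH) -> SpanReport:
    """Distance between the pocket heavy-atom centroids of both protomers,
    with the bivalent-linker feasibility verdict for that span."""
    if len(dimer.chains) != 2:
        raise ValueError("expected a two-protomer dimer")
    pocket = list(pocket)
    a = _pocket_centroid(dimer.chains[0], pocket)
    b = _pocket_centroid(dimer.chains[1], pocket)
    span = float(np.linalg.norm(a - b))
    feasible, margin = linker_feasibility(span, linker_atoms, per_atom_reach)
    return SpanReport(arrangement=arrangement,
                      centroid_a=tuple(np.round(a, 4)),
                      centroid_b=tuple(np.round(b, 4)),
                      span=round(span, 4), linker_atoms=linker_atoms,
                      reach=round(linker_atoms * per_atom_reach, 4),
                      feasible=feasible, margin=round(margin, 4))
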