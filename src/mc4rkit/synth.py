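"""Seeded synthetic fixtures for every input class the pipeline consumes.

Nothing here is a physical model: the generators produce idealized
geometry and tables whose ground truth is known by construction, so each
analysis stage can be verified against a manifest.  The fixtures emulate

* a 7-helix transmembrane bundle carrying the real hMC4R sequence and
  topology (ideal α-helices on a ring, antiparallel, loops as bowed
  connectors),
* peptide poses with contacts planted at stated distances (an α-MSH-like
  strict mode where the contact count is exact, and an AgRP-core-like
  anchor mode reproducing the published interaction pairs),
* dimers built by a known rigid transform with a chosen interface face,
* ternary complexes with planted G-protein subunit interfaces,
* variant tables with planted class proportions and region tallies, and
* ortholog/template sequence surrogates with planted identity and
  similarity levels.

Sequence surrogates are synthetic stand-ins: real zebrafish MC4R/MC2R and
S1PR1 sequences are not shipped, so mutated derivatives of hMC4R with the
comparison levels planted by construction take their place.

Every generator draws from its own stream (``default_rng([seed, stream])``)
so adding a generator never shifts the output of another; the same seed
always reproduces byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .geometry import (HELIX_PHI, HELIX_PSI, OMEGA_TRANS, BOND_N_CA,
                       BOND_CA_C, BOND_C_N, BOND_C_O, ANGLE_N_CA_C,
                       ANGLE_CA_C_N, ANGLE_C_N_CA, ANGLE_CA_C_O, ideal_cb,
                       place_atom, rotation_about_z, rotation_between, unit)
from .sequences import (SequenceRecord, TopologyAnnotation, assign_topology,
                        default_topology, hmc4r_sequence, load_anchors,
                        load_matrix, load_pocket)
from .structure import Atom, Chain, Residue, StructureModel, THREE_LETTER

#: fixed sub-stream ids; one documented stream per generator
STREAMS = {"bundle": 1, "complex": 2, "dimer": 3, "variants": 4,
           "sequences": 5, "sm1": 6, "agrp": 7, "ternary": 8}

#: pseudo side-chain tip atom per residue type: a single named atom placed
#: beyond Cβ so charge/H-bond chemistry is classifiable on toy models
SIDE_CHAIN_TIPS = {
    "R": ("NH1", 4.0), "K": ("NZ", 3.4), "H": ("NE2", 2.2),
    "D": ("OD1", 1.4), "E": ("OE1", 2.4), "N": ("ND2", 1.5),
    "Q": ("NE2", 2.5), "Y": ("OH", 3.4), "W": ("NE1", 2.4),
    "S": ("OG", 1.0), "T": ("OG1", 1.0), "C": ("SG", 1.8),
}

ALPHA_MSH = "SYSMEHFRWGKPV"  # α-MSH with the HFRW core at 6-9

#: AgRP active-core surrogate: residue identities at the published hot
#: spots (R111, F112, F113, N114, F116, Y109, Y118, R120); synthetic.
AGRP_CORE = {109: "Y", 110: "A", 111: "R", 112: "F", 113: "F", 114: "N",
             115: "A", 116: "F", 117: "A", 118: "Y", 119: "A", 120: "R"}

AMINO_ACIDS_20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GeneratorConfig:
    """Bundle of sizes and the master seed used by the demo pipeline."""
    seed: int = 0
    ring_radius: float = 10.0
    dimer_separation: float = 27.5
    contact_cutoff: float = 4.0
    n_planted_contacts: int = 5


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), STREAMS[stream]])


# ---------------------------------------------------------------------------
# helix and residue construction

def _helix_backbone(n: int) -> list[dict]:
    """Ideal α-helix backbone (φ=-57°, ψ=-47°) built from internal
    coordinates; returns per-residue N/CA/C/O positions."""
    residues = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    a = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(a), np.sin(a), 0.0])
    prev = {"N": n0, "CA": ca0, "C": c0}
    residues.append(prev)
    for _ in range(1, n):
        nn = place_atom(prev["N"], prev["CA"], prev["C"],
                        BOND_C_N, ANGLE_CA_C_N, HELIX_PSI)
        ca = place_atom(prev["CA"], prev["C"], nn,
                        BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c = place_atom(prev["C"], nn, ca,
                       BOND_CA_C, ANGLE_N_CA_C, HELIX_PHI)
        cur = {"N": nn, "CA": ca, "C": c}
        residues.append(cur)
        prev = cur
    for res in residues:
        res["O"] = place_atom(res["N"], res["CA"], res["C"],
                              BOND_C_O, ANGLE_CA_C_O, HELIX_PSI + 180.0)
    return residues


def _residue_atoms(letter: str, backbone: dict) -> list[Atom]:
    atoms = [Atom("N", backbone["N"], "N"), Atom("CA", backbone["CA"], "C"),
             Atom("C", backbone["C"], "C"), Atom("O", backbone["O"], "O")]
    if letter != "G":
        cb = ideal_cb(backbone["N"], backbone["CA"], backbone["C"])
        atoms.append(Atom("CB", cb, "C"))
        tip = SIDE_CHAIN_TIPS.get(letter)
        if tip is not None:
            name, ext = tip
            pos = cb + ext * unit(cb - backbone["CA"])
            atoms.append(Atom(name, pos, name[0]))
    return atoms


def expected_atoms_per_residue(letter: str) -> int:
    if letter == "G":
        return 4
    return 6 if letter in SIDE_CHAIN_TIPS else 5


_LOOP_TEMPLATE = None


def _loop_template() -> dict:
    """A single ideal residue backbone, CA at the origin (loop placement)."""
    global _LOOP_TEMPLATE
    if _LOOP_TEMPLATE is None:
        bb = _helix_backbone(1)[0]
        ca = bb["CA"]
        _LOOP_TEMPLATE = {k: v - ca for k, v in bb.items()}
    return _LOOP_TEMPLATE


def _place_loop_residue(letter: str, ca_pos: np.ndarray) -> list[Atom]:
    tmpl = _loop_template()
    backbone = {k: v + ca_pos for k, v in tmpl.items()}
    return _residue_atoms(letter, backbone)


def _arc_points(start: np.ndarray, end: np.ndarray, n: int,
                outward: np.ndarray, target_spacing: float = 3.0
                ) -> list[np.ndarray]:
    """n points on a bowed arc from start to end whose polyline spacing is
    close to target_spacing (loops are given slack, not stretched)."""
    ts = np.linspace(0.0, 1.0, n + 2)[1:-1]
    chord = np.linalg.norm(end - start)
    target_len = target_spacing * (n + 1)

    def points(amp: float) -> list[np.ndarray]:
        return [start + t * (end - start)
                + amp * np.sin(np.pi * t) * outward for t in ts]

    def path_len(amp: float) -> float:
        pts = [start] + points(amp) + [end]
        return float(sum(np.linalg.norm(b - a)
                         for a, b in zip(pts, pts[1:])))

    if chord >= target_len or n == 0:
        return points(0.0)
    lo, hi = 0.0, 4.0 * target_len
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if path_len(mid) < target_len:
            lo = mid
        else:
            hi = mid
    return points(0.5 * (lo + hi))


def make_helical_bundle(seq: SequenceRecord | None = None,
                        topology: TopologyAnnotation | None = None,
                        *, n_helices: int = 7,
                        residues_per_helix: int = 22,
                        loop_length: int = 4,
                        ring_radius: float = 10.0,
                        include_loops: bool = True,
                        plant_disulfides: tuple = (),
                        chain_id: str = "R",
                        seed: int = 0
                        ) -> tuple[StructureModel, TopologyAnnotation, dict]:
    """Idealized transmembrane bundle with consistent topology labels.

    Helices stand on a ring with antiparallel alternation (odd helices run
    extracellular→intracellular, matching a GPCR whose N-terminus is
    outside); loops and tails are bowed connectors.  When no sequence is
    given a random one is drawn.  ``plant_disulfides`` pairs of cysteine
    residue numbers are pulled together to an Sγ–Sγ distance of 2.05 Å.

    Returns ``(model, topology, manifest)``; the manifest records the
    expected atom count and helix geometry for closed-loop testing.
    """
    rng = _rng(seed, "bundle")
    if ring_radius < 6.0 and n_helices > 1:
        raise ValueError(f"ring radius {ring_radius} Å would clash the "
                         "helices (inter-axis spacing below ~5 Å)")
    if seq is None:
        boundaries = []
        cursor = 1
        for h in range(1, n_helices + 1):
            boundaries.append((f"TMH{h}", cursor,
                               cursor + residues_per_helix - 1))
            cursor += residues_per_helix
            if h < n_helices and loop_length > 0:
                label = (f"ICL{(h + 1) // 2}" if h % 2 == 1
                         else f"ECL{h // 2}")
                boundaries.append((label, cursor, cursor + loop_length - 1))
                cursor += loop_length
        letters = "".join(rng.choice(list(AMINO_ACIDS_20), cursor - 1))
        seq = SequenceRecord(id=f"bundle{n_helices}", residues=letters)
        topology = assign_topology(seq, boundaries)
    elif topology is None:
        raise ValueError("a topology is required with an explicit sequence")

    helix_labels = [r for r, _, _ in topology.regions if r.startswith("TMH")]
    helix_geo: dict[str, dict] = {}
    residues_by_number: dict[int, Residue] = {}

    n_hel = len(helix_labels)
    for idx, label in enumerate(helix_labels):
        start, end = topology.span(label)
        n_res = end - start + 1
        theta = 2.0 * np.pi * idx / max(n_hel, 1)
        axis_xy = ring_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        descending = idx % 2 == 0  # TMH1 runs top → bottom
        bb = _helix_backbone(n_res)
        cas = np.array([r["CA"] for r in bb])
        centroid = cas.mean(axis=0)
        _, _, vt = np.linalg.svd(cas - centroid)
        axis = vt[0]
        if np.dot(cas[-1] - cas[0], axis) < 0:
            axis = -axis
        target_dir = np.array([0.0, 0.0, -1.0 if descending else 1.0])
        rot = rotation_between(axis, target_dir)
        for res_bb in bb:
            for key in res_bb:
                res_bb[key] = rot @ (res_bb[key] - centroid) + axis_xy
        for offset, res_bb in enumerate(bb):
            number = start + offset
            letter = seq.residue_at(number)
            residues_by_number[number] = Residue(
                number=number, name=THREE_LETTER.get(letter, "UNK"),
                atoms=_residue_atoms(letter, res_bb))
        helix_geo[label] = {
            "axis_xy": axis_xy[:2].tolist(), "theta_deg": np.rad2deg(theta),
            "descending": descending, "n_res": n_res,
        }

    if include_loops:
        region_labels = [r for r, _, _ in topology.regions]
        for i, label in enumerate(region_labels):
            if label.startswith("TMH"):
                continue
            start, end = topology.span(label)
            n_res = end - start + 1
            prev_tm = next((region_labels[j] for j in range(i - 1, -1, -1)
                            if region_labels[j].startswith("TMH")), None)
            next_tm = next((region_labels[j]
                            for j in range(i + 1, len(region_labels))
                            if region_labels[j].startswith("TMH")), None)
            up = label.startswith(("ECL", "Ntt"))
            zdir = 0.5 if up else -0.5
            if prev_tm and next_tm:  # interhelical loop
                p_start = residues_by_number[topology.span(prev_tm)[1]].atom("C").pos
                p_end = residues_by_number[topology.span(next_tm)[0]].atom("N").pos
                mid = 0.5 * (p_start + p_end)
                outward = unit(np.array([mid[0], mid[1], 0.0]) + [0, 0, zdir]) \
                    if np.linalg.norm(mid[:2]) > 1e-6 else np.array([0, 0, 1.0])
                points = _arc_points(p_start, p_end, n_res, outward)
                numbers = range(start, end + 1)
            elif next_tm:  # leading tail (Ntt)
                attach = residues_by_number[topology.span(next_tm)[0]].atom("N").pos
                outward = unit(np.array([attach[0], attach[1], 0.0]) * 0.4
                               + np.array([0.0, 0.0, 1.0]))
                points = [attach + 3.0 * outward * (end - num + 1)
                          for num in range(start, end + 1)]
                numbers = range(start, end + 1)
            else:  # trailing tail (H8, Ctt)
                attach = residues_by_number[topology.span(prev_tm)[1]].atom("C").pos
                outward = unit(np.array([attach[0], attach[1], 0.0]) * 1.0
                               + np.array([0.0, 0.0, -0.4]))
                points = [attach + 3.0 * outward * (num - start + 1)
                          for num in range(start, end + 1)]
                numbers = range(start, end + 1)
            for num, pos in zip(numbers, points):
                letter = seq.residue_at(num)
                residues_by_number[num] = Residue(
                    number=num, name=THREE_LETTER.get(letter, "UNK"),
                    atoms=_place_loop_residue(letter, pos))

    for a_num, b_num in plant_disulfides:
        res_a = residues_by_number.get(a_num)
        res_b = residues_by_number.get(b_num)
        if res_a is None or res_b is None:
            raise ValueError(f"cannot plant disulfide {a_num}-{b_num}: "
                             "residue not built (loops excluded?)")
        sg_a, sg_b = res_a.atom("SG"), res_b.atom("SG")
        if sg_a is None or sg_b is None:
            raise ValueError(f"disulfide {a_num}-{b_num}: not cysteines")
        target = sg_a.pos + 2.05 * unit(sg_b.pos - sg_a.pos)
        delta = target - sg_b.pos
        for atom in res_b.atoms:
            atom.pos = atom.pos + delta

    ordered = [residues_by_number[n] for n in sorted(residues_by_number)]
    model = StructureModel([Chain(chain_id, ordered)],
                           metadata={"source": "synthetic bundle",
                                     "seed": seed})
    built_letters = [seq.residue_at(r.number) for r in ordered]
    manifest = {
        "seed": seed, "chain_id": chain_id, "ring_radius": ring_radius,
        "n_helices": n_hel, "include_loops": include_loops,
        "n_residues": len(ordered),
        "expected_atom_count": int(sum(expected_atoms_per_residue(x)
                                       for x in built_letters)),
        "helices": helix_geo,
        "plant_disulfides": [list(p) for p in plant_disulfides],
        "sequence_id": seq.id,
    }
    return model, topology, manifest


def hmc4r_bundle(seed: int = 0, include_loops: bool = True,
                 ring_radius: float = 10.0
                 ) -> tuple[StructureModel, TopologyAnnotation, dict]:
    """Toy hMC4R model: the real sequence and topology on an ideal bundle,
    with the ECL3 C271–C277 disulfide planted when loops are built."""
    seq = hmc4r_sequence()
    topo = default_topology()
    ss = ((271, 277),) if include_loops else ()
    return make_helical_bundle(seq, topo, ring_radius=ring_radius,
                               include_loops=include_loops,
                               plant_disulfides=ss, seed=seed)


# ---------------------------------------------------------------------------
# ligand poses

def _bundle_axis_xy(model: StructureModel) -> np.ndarray:
    cas = np.array([r.atom("CA").pos for r in model.chains[0].residues
                    if r.atom("CA") is not None])
    return cas[:, :2].mean(axis=0)


def _outermost_atom(res: Residue, axis_xy: np.ndarray) -> Atom:
    return max(res.heavy_atoms(),
               key=lambda a: np.linalg.norm(a.pos[:2] - axis_xy))


def _contact_atom(res: Residue) -> Atom:
    letter = res.one_letter
    tip = SIDE_CHAIN_TIPS.get(letter)
    if tip is not None:
        atom = res.atom(tip[0])
        if atom is not None:
            return atom
    return res.atom("CB") or res.atom("CA")


def _min_distance(res_a: Residue, res_b: Residue) -> float:
    xa = np.array([a.pos for a in res_a.heavy_atoms()])
    xb = np.array([a.pos for a in res_b.heavy_atoms()])
    return float(np.sqrt(
        ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1)).min())


def _translate(res: Residue, delta: np.ndarray) -> None:
    for atom in res.atoms:
        atom.pos = atom.pos + delta


def _plant_residue(lig: Residue, rec: Residue, distance: float,
                   direction: np.ndarray) -> None:
    """Move a ligand residue so its minimum heavy-atom distance to the
    receptor residue equals ``distance``, approaching along ``direction``.

    The residue is first oriented so its body trails away along the
    approach direction (contact atom nearest the receptor), which keeps
    the planted contact local instead of sprawling sideways."""
    anchor = _contact_atom(lig)
    others = np.array([a.pos for a in lig.heavy_atoms()
                       if a.name != anchor.name])
    body = others.mean(axis=0) - anchor.pos
    if np.linalg.norm(body) > 1e-9:
        rot = rotation_between(body, direction)
        pivot = anchor.pos.copy()
        for atom in lig.atoms:
            atom.pos = rot @ (atom.pos - pivot) + pivot
    rec_atom = max(rec.heavy_atoms(), key=lambda a: np.dot(a.pos, direction))
    _translate(lig, rec_atom.pos + distance * direction - anchor.pos)
    for _ in range(80):
        m = _min_distance(lig, rec)
        err = m - distance
        if abs(err) < 1e-9:
            break
        _translate(lig, -err * direction)


def _extended_strand(letters: str, numbers, center: np.ndarray,
                     chain_letters_spacing: float = 3.5) -> list[Residue]:
    residues = []
    n = len(letters)
    for i, (letter, number) in enumerate(zip(letters, numbers)):
        pos = center + np.array([(i - (n - 1) / 2.0)
                                 * chain_letters_spacing, 0.0, 0.0])
        residues.append(Residue(number=number,
                                name=THREE_LETTER.get(letter, "UNK"),
                                atoms=_place_loop_residue(letter, pos)))
    return residues


def _all_pair_contacts(lig_residues, rec_residues, cutoff):
    found = []
    for lr in lig_residues:
        for rr in rec_residues:
            d = _min_distance(lr, rr)
            if d <= cutoff:
                found.append((lr.number, rr.number, d))
    return found


def make_toy_complex(bundle: StructureModel, topology: TopologyAnnotation,
                     *, k: int = 5, distances=None, cutoff: float = 4.0,
                     ligand_chain: str = "P", seed: int = 0
                     ) -> tuple[StructureModel, dict]:
    """An α-MSH-like peptide placed so that exactly ``k`` residue pairs sit
    under the cutoff, at manifest-recorded distances.

    Partner residues are the extracellular tips of distinct helices; when
    the receptor offers an acidic residue near a helix tip and the peptide
    arginine is among the planted residues, an Arg–Asp/Glu salt-bridge pair
    is planted.  The generator verifies by brute force that no spurious
    pair slips under the cutoff and raises if the geometry cannot honor
    the contract — pass a helix-only bundle (``include_loops=False``);
    loop connectors crowd the extracellular mouth and usually make an
    exact contact count unattainable.
    """
    rng = _rng(seed, "complex")
    receptor = bundle.chains[0]
    axis_xy = _bundle_axis_xy(bundle)

    helix_labels = [r for r, _, _ in topology.regions if r.startswith("TMH")]
    by_number = {r.number: r for r in receptor.residues}

    top_residues = []   # extracellular tip residue of each helix
    acidic_near_top = []
    for label in helix_labels:
        span = topology.residues_in(label)
        members = [by_number[n] for n in span if n in by_number]
        members.sort(key=lambda r: r.atom("CA").pos[2], reverse=True)
        if members:
            top_residues.append(members[0])
            acidic_near_top.extend(r for r in members[:4]
                                   if r.name in ("ASP", "GLU"))

    if k > len(top_residues):
        raise ValueError(f"cannot plant {k} contacts on "
                         f"{len(top_residues)} helices")

    tm_atoms_z = [a.pos[2] for label in helix_labels
                  for n in topology.residues_in(label)
                  if n in by_number for a in by_number[n].atoms]
    strand_z = max(tm_atoms_z) + 25.0
    pep = _extended_strand(ALPHA_MSH, range(1, len(ALPHA_MSH) + 1),
                           np.array([axis_xy[0], axis_xy[1], strand_z]))
    pep_by_number = {r.number: r for r in pep}

    if distances is None:
        distances = np.round(rng.uniform(2.8, 3.5, size=k), 2).tolist()
    if len(distances) != k:
        raise ValueError("need one planted distance per contact")

    partner_pool = list(top_residues)
    rng.shuffle(partner_pool)
    pep_order = [8, 6, 9, 7, 4, 2, 11, 5, 10, 3, 12, 1, 13]
    planted: list[dict] = []
    salt_pair = None
    if k >= 1 and acidic_near_top:
        acid = acidic_near_top[0]
        partner_pool = [r for r in partner_pool
                        if topology.label_of(r.number)
                        != topology.label_of(acid.number)]
        salt_pair = {"ligand": 8, "receptor": acid.number}
        pairs = [(8, acid)] + [(p, r) for p, r in
                               zip([x for x in pep_order if x != 8],
                                   partner_pool[:k - 1])]
    else:
        pairs = list(zip(pep_order, partner_pool[:k]))

    rec_residues = list(receptor.residues)
    for (pnum, rres), dist in zip(pairs, distances):
        lig = pep_by_number[pnum]
        radial = unit(np.hstack([
            _outermost_atom(rres, axis_xy).pos[:2] - axis_xy, [0.0]]))
        for azim in (0.0, 20.0, -20.0, 40.0, -40.0, 60.0, -60.0):
            rot = rotation_about_z(azim)
            for elev in (0.6, 1.0, 0.3, 1.6, 0.1):
                direction = unit(rot @ radial + np.array([0, 0, elev]))
                _plant_residue(lig, rres, dist, direction)
                local = _all_pair_contacts([lig], rec_residues, cutoff)
                if {(a, b) for a, b, _ in local} == {(pnum, rres.number)}:
                    break
            else:
                continue
            break
        else:
            raise ValueError(f"could not plant an exact contact on residue "
                             f"{rres.number} without spurious pairs")
    found = _all_pair_contacts(pep, rec_residues, cutoff)
    want = sorted((p, r.number) for (p, r) in pairs)
    if sorted((a, b) for a, b, _ in found) != want:
        raise ValueError("could not plant contacts without spurious pairs; "
                         "adjust distances or cutoff")

    chains = [Chain(c.id, c.residues) for c in bundle.chains]
    chains.append(Chain(ligand_chain, pep))
    model = StructureModel(chains, metadata={"source": "synthetic complex",
                                             "seed": seed})
    dist_map = {(a, b): d for a, b, d in found}
    manifest = {
        "seed": seed, "ligand_chain": ligand_chain,
        "receptor_chain": receptor.id, "cutoff": cutoff, "exact": True,
        "planted": [{"ligand_residue": p, "receptor_residue": r.number,
                     "distance": round(dist_map[(p, r.number)], 4)}
                    for (p, r) in pairs],
        "pocket": sorted(r.number for _, r in pairs),
        "salt_bridge_pair": salt_pair,
    }
    return model, manifest


#: AgRP-core/receptor pairs planted by the anchor-mode pose: the published
#: hot-spot pairs plus backbone-level contacts onto further pocket
#: residues (E100, S191) that pad the pose out to a realistic pocket size
AGRP_ANCHOR_PLAN = (
    (111, 126, 2.9), (112, 184, 3.4), (113, 261, 3.5),
    (116, 284, 3.6), (109, 268, 3.3), (120, 189, 3.0),
    (115, 100, 3.2), (117, 191, 3.3), (110, 103, 3.4),
)


def _two_sphere_point(o1: np.ndarray, r1: float, o2: np.ndarray, r2: float,
                      prefer: np.ndarray) -> tuple[np.ndarray, float, float]:
    """A point at the given distances from two centers (radii inflated
    minimally when the spheres do not intersect), picked toward ``prefer``."""
    d = float(np.linalg.norm(o2 - o1))
    if d > r1 + r2:
        pad = 0.5 * (d - r1 - r2) + 0.05
        r1, r2 = r1 + pad, r2 + pad
    elif d < abs(r1 - r2):
        pad = 0.5 * (abs(r1 - r2) - d) + 0.05
        if r1 > r2:
            r2 += pad
            r1 -= pad
        else:
            r1 += pad
            r2 -= pad
    u = unit(o2 - o1)
    a = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    h = float(np.sqrt(max(r1 * r1 - a * a, 0.0)))
    center = o1 + a * u
    w = prefer - np.dot(prefer, u) * u
    w = unit(w) if np.linalg.norm(w) > 1e-9 else unit(np.cross(u, [0, 0, 1.0]))
    p = center + h * w
    return p, float(np.linalg.norm(p - o1)), float(np.linalg.norm(p - o2))


def make_agrp_complex(bundle: StructureModel, topology: TopologyAnnotation,
                      *, ligand_chain: str = "G", seed: int = 0
                      ) -> tuple[StructureModel, dict]:
    """AgRP-core-like inverse-agonist pose with the published anchor pairs
    planted: R111 between D122/D126, the F112/F113/F116 aromatics against
    F184/F261/F284, Y109 on Y268 and R120 on D189.

    The contact count is NOT exact here — mid-helix plantings spill over
    onto neighboring receptor residues, as a real pose would; the manifest
    records the planted pairs with their measured distances.
    """
    del seed  # deterministic pose; signature kept uniform
    receptor = bundle.chains[0]
    axis_xy = _bundle_axis_xy(bundle)
    by_number = {r.number: r for r in receptor.residues}

    tm_z = [a.pos[2] for r in receptor.residues for a in r.atoms]
    strand_z = max(tm_z) + 25.0
    numbers = sorted(AGRP_CORE)
    letters = "".join(AGRP_CORE[n] for n in numbers)
    pep = _extended_strand(letters, numbers,
                           np.array([axis_xy[0], axis_xy[1], strand_z]))
    pep_by_number = {r.number: r for r in pep}

    planted = []
    # R111 wedged between the acidic D122/D126 pair
    lig = pep_by_number[111]
    d122, d126 = by_number[122], by_number[126]
    o1 = _contact_atom(d126).pos
    o2 = _contact_atom(d122).pos
    radial = unit(np.hstack([0.5 * (o1 + o2)[:2] - axis_xy, [0.0]]))
    p, m126, m122 = _two_sphere_point(o1, 2.9, o2, 3.6, radial)
    _translate(lig, p - _contact_atom(lig).pos)
    planted.append({"ligand_residue": 111, "receptor_residue": 126,
                    "distance": round(_min_distance(lig, d126), 4)})
    planted.append({"ligand_residue": 111, "receptor_residue": 122,
                    "distance": round(_min_distance(lig, d122), 4)})

    for pnum, rnum, dist in AGRP_ANCHOR_PLAN[1:]:
        lig = pep_by_number[pnum]
        rres = by_number[rnum]
        radial = _outermost_atom(rres, axis_xy).pos[:2] - axis_xy
        direction = unit(np.array([radial[0], radial[1],
                                   0.4 * np.linalg.norm(radial)]))
        _plant_residue(lig, rres, dist, direction)
        planted.append({"ligand_residue": pnum, "receptor_residue": rnum,
                        "distance": round(_min_distance(lig, rres), 4)})

    chains = [Chain(c.id, c.residues) for c in bundle.chains]
    chains.append(Chain(ligand_chain, pep))
    model = StructureModel(chains, metadata={"source": "synthetic AgRP pose"})
    manifest = {"ligand_chain": ligand_chain, "receptor_chain": receptor.id,
                "exact": False, "planted": planted,
                "expected_pairs": [(111, 126), (111, 122), (112, 184),
                                   (113, 261), (116, 284), (109, 268),
                                   (120, 189)]}
    return model, manifest


# ---------------------------------------------------------------------------
# dimers and ternary complexes

def make_toy_dimer(protomer: StructureModel, topology: TopologyAnnotation,
                   arrangement: str = "cxcr4", separation: float = 27.5,
                   seed: int = 0) -> tuple[StructureModel, dict]:
    """Two protomer copies related by a known rigid transform.

    The second protomer is the first rotated 180° about the membrane
    normal and shifted along the direction of the arrangement's interface
    helices (TMH4/5 for the CXCR4-like packing, TMH1/2 for the KOR-like
    one), so those helices face each other across the interface.
    """
    del seed  # transform is deterministic; signature kept uniform
    from .oligomer import ARRANGEMENTS
    if arrangement not in ARRANGEMENTS:
        raise ValueError(f"unknown arrangement {arrangement!r}")
    if separation <= 0:
        raise ValueError("separation must be positive")
    helices = ARRANGEMENTS[arrangement]["helices"]
    chain = protomer.chains[0]
    axis_xy = _bundle_axis_xy(protomer)
    by_number = {r.number: r for r in chain.residues}

    cas = []
    for h in helices:
        for n in topology.residues_in(f"TMH{h}"):
            res = by_number.get(n)
            if res is not None and res.atom("CA") is not None:
                cas.append(res.atom("CA").pos[:2])
    direction = unit(np.hstack([np.mean(cas, axis=0) - axis_xy, [0.0]]))

    all_xyz = np.array([a.pos for r in chain.residues for a in r.atoms])
    centroid = all_xyz.mean(axis=0)
    R = rotation_about_z(180.0)
    t = centroid - R @ centroid + separation * direction

    moved = protomer.transformed(R, t)
    dimer = StructureModel(
        [Chain("A", protomer.copy().chains[0].residues),
         Chain("B", moved.chains[0].residues)],
        metadata={"source": f"synthetic {arrangement} dimer"})
    manifest = {
        "arrangement": arrangement, "separation": separation,
        "interface_helices": list(helices),
        "interface_direction": np.round(direction, 6).tolist(),
        "rotation": R.tolist(), "translation": np.round(t, 6).tolist(),
        "centroid_distance": separation,
        "pocket_suggestion": _extracellular_half(topology, by_number,
                                                 (3, 4, 5)),
    }
    return dimer, manifest


def _extracellular_half(topology, by_number, helices) -> list[int]:
    picked = []
    for h in helices:
        members = [by_number[n] for n in topology.residues_in(f"TMH{h}")
                   if n in by_number]
        members.sort(key=lambda r: r.atom("CA").pos[2], reverse=True)
        picked.extend(r.number for r in members[:len(members) // 2])
    return sorted(picked)


def make_toy_ternary(bundle: StructureModel, topology: TopologyAnnotation,
                     *, alpha_contacts=(161, 240), beta_contacts=(76, 73),
                     distance: float = 3.2, seed: int = 0
                     ) -> tuple[StructureModel, dict]:
    """Bundle plus minimal G-protein subunit chains (Gα as chain S, Gβ as
    chain T) planted within interaction distance of chosen intracellular
    receptor residues (defaults: Gα at ICL2/ICL3, Gβ at ICL1 H76/K73)."""
    del seed
    receptor = bundle.chains[0]
    axis_xy = _bundle_axis_xy(bundle)
    by_number = {r.number: r for r in receptor.residues}

    def _subunit(chain_id: str, targets, start_number: int) -> Chain:
        residues = []
        for i, rnum in enumerate(targets):
            rres = by_number[rnum]
            radial = _outermost_atom(rres, axis_xy).pos[:2] - axis_xy
            norm = np.linalg.norm(radial)
            direction = unit(np.array([0.3 * radial[0], 0.3 * radial[1],
                                       -max(norm, 1.0)]))
            res = Residue(number=start_number + i, name="ALA",
                          atoms=_place_loop_residue(
                              "A", np.zeros(3)))
            _plant_residue(res, rres, distance, direction)
            residues.append(res)
        return Chain(chain_id, residues)

    chains = [Chain(c.id, c.residues) for c in bundle.chains]
    alpha = _subunit("S", alpha_contacts, 1)
    beta = _subunit("T", beta_contacts, 1)
    chains.extend([alpha, beta])
    model = StructureModel(chains, metadata={"source": "synthetic ternary"})
    # ground truth by brute force: receptor residues each subunit touches
    rec_res = list(receptor.residues)
    expected = {
        "alpha": sorted({r for _, r, _ in
                         _all_pair_contacts(alpha.residues, rec_res, 4.0)}),
        "beta": sorted({r for _, r, _ in
                        _all_pair_contacts(beta.residues, rec_res, 4.0)}),
    }
    if not set(alpha_contacts) <= set(expected["alpha"]) \
            or not set(beta_contacts) <= set(expected["beta"]):
        raise ValueError("ternary planting failed to reach its targets")
    manifest = {"receptor_chain": receptor.id,
                "subunits": {"alpha": "S", "beta": "T"},
                "planted": {"alpha": sorted(alpha_contacts),
                            "beta": sorted(beta_contacts)},
                "expected": expected,
                "distance": distance, "cutoff": 4.0}
    return model, manifest


# ---------------------------------------------------------------------------
# variant tables

def _mutant_letter(rng: np.random.Generator, wt: str,
                   used: set | None = None) -> str:
    choices = [a for a in AMINO_ACIDS_20
               if a != wt and (used is None or a not in used)]
    if not choices:
        raise ValueError(f"all 19 substitutions at a position already used")
    return str(rng.choice(choices))


def make_variant_table(n_variants: int, n_positions: int,
                       counts: tuple[int, int, int, int],
                       seed: int = 0,
                       sequence: SequenceRecord | None = None
                       ) -> tuple[list[dict], dict]:
    """Random raw variant rows with planted class tallies.

    ``counts`` is in the overlap convention ``(no_data, like_wt,
    decreased, contradictory)`` with contradictory included in both the
    like-WT and decreased tallies, so the entries must satisfy
    ``no_data + like_wt + decreased − contradictory = n_variants``.
    Contradictory variants are emitted as two rows from different sources.
    """
    nd, lw, dec, contr = counts
    if nd + lw + dec - contr != n_variants:
        raise ValueError("counts do not satisfy the overlap identity")
    if not 0 < n_positions <= n_variants:
        raise ValueError("need 0 < n_positions <= n_variants")
    if n_variants > 19 * n_positions:
        raise ValueError("at most 19 substitutions exist per position")
    if sequence is None:
        sequence = hmc4r_sequence()
    rng = _rng(seed, "variants")

    positions = rng.choice(np.arange(1, len(sequence) + 1),
                           size=n_positions, replace=False)
    slots = [int(p) for p in positions]
    capacity = {p: 18 for p in slots}  # 19 substitutions minus the first
    for _ in range(n_variants - n_positions):
        open_positions = [p for p, c in capacity.items() if c > 0]
        p = int(rng.choice(open_positions))
        capacity[p] -= 1
        slots.append(p)

    variants = []
    seen: dict[int, set] = {}
    for pos in slots:
        pos = int(pos)
        wt = sequence.residue_at(pos)
        mut = _mutant_letter(rng, wt, seen.setdefault(pos, set()))
        seen[pos].add(mut)
        variants.append((pos, wt, mut))

    classes = (["no_data"] * nd + ["like_wt"] * (lw - contr)
               + ["decreased"] * (dec - contr) + ["contradictory"] * contr)
    rng.shuffle(classes)
    rows = _emit_rows(variants, classes, rng)
    manifest = {"seed": seed, "n_variants": n_variants,
                "n_positions": n_positions,
                "counts": {"no_data": nd, "like_wt": lw, "decreased": dec,
                           "contradictory": contr},
                "positions": sorted(int(p) for p in positions)}
    return rows, manifest


def _emit_rows(variants, classes, rng) -> list[dict]:
    rows = []
    for (pos, wt, mut), fclass in zip(variants, classes):
        name = f"{wt}{pos}{mut}"
        if fclass == "no_data":
            rows.append({"variant": name, "source": "collection"})
        elif fclass == "like_wt":
            col = str(rng.choice(["camp", "binding"]))
            rows.append({"variant": name, col: "=", "source": "studyA"})
        elif fclass == "decreased":
            col = str(rng.choice(["camp", "binding", "expression"]))
            rows.append({"variant": name, col: "down", "source": "studyA"})
        elif fclass == "contradictory":
            rows.append({"variant": name, "camp": "=", "source": "studyA"})
            rows.append({"variant": name, "camp": "down", "source": "studyB"})
        else:
            raise AssertionError(fclass)
    return rows


#: variants named in the clinical-structural literature, fixed in the
#: SM1-style table with their reported behavior
_NAMED_DECREASED = ("L54P", "E61K", "N62S", "A87D", "D90N", "D126Y",
                    "A154D", "Y157S", "M161T", "H76R", "G238D", "F261S",
                    "P299H", "I301T", "A303T", "R305W", "R305S")
_NAMED_CAM = "H158R"  # constitutively activating: like-WT cAMP, raised basal

#: (positions, variants) planted per region; totals 129 positions and 165
#: variants with the published loop tallies (Ntt 21@14, ICL1 5, ICL2 6,
#: ICL3 7@6)
_SM1_REGION_QUOTAS = {
    "Ntt": (14, 21), "TMH1": (10, 13), "ICL1": (5, 5), "TMH2": (12, 16),
    "ECL1": (3, 4), "TMH3": (14, 18), "ICL2": (6, 6), "TMH4": (9, 11),
    "ECL2": (2, 3), "TMH5": (12, 15), "ICL3": (6, 7), "TMH6": (11, 14),
    "ECL3": (4, 5), "TMH7": (12, 16), "H8": (5, 6), "Ctt": (4, 5),
}

_SM1_COUNTS = {"no_data": 24, "like_wt": 71, "decreased": 92,
               "contradictory": 22}  # overlap convention; 24+71+92-22=165

_SM1_EXCLUDED_ROWS = ({"variant": "Y35X", "source": "collection"},
                      {"variant": "W16X", "source": "collection"},
                      {"variant": "ΔI125", "source": "collection"},
                      {"variant": "L106del", "source": "collection"},
                      {"variant": "D37V/I102T", "source": "collection"})


def make_sm1_like_table(seed: int = 0, include_excluded_rows: bool = True
                        ) -> tuple[list[dict], dict]:
    """Synthetic stand-in for the published supplementary variant table.

    The real supplementary collection is not redistributable, so this
    generator rebuilds a table with the same curation arithmetic planted:
    165 single substitutions at 129 positions; 24 without functional data,
    71 with a like-wild-type report, 92 with a loss report, and 22 with
    both (contradictory); the published region tallies (21 N-terminal
    variants at 14 positions, 5 ICL1 positions of 8, 6 ICL2 positions of
    13, 7 ICL3 variants at 6 positions); the literature-named variants
    above with their reported classes; and, when requested, planted stop/
    deletion/double-substitution rows that curation must discard.
    """
    rng = _rng(seed, "sm1")
    seq = hmc4r_sequence()
    topo = default_topology()

    named: dict[str, list[tuple[int, str, str, str]]] = {}
    for text in _NAMED_DECREASED:
        wt, pos, mut = text[0], int(text[1:-1]), text[-1]
        assert seq.residue_at(pos) == wt, text
        named.setdefault(topo.label_of(pos), []).append(
            (pos, wt, mut, "decreased"))
    wt, pos, mut = _NAMED_CAM[0], int(_NAMED_CAM[1:-1]), _NAMED_CAM[-1]
    named.setdefault(topo.label_of(pos), []).append((pos, wt, mut, "cam"))

    variants: list[tuple[int, str, str]] = []   # fillers needing a class
    fixed: list[tuple[int, str, str, str]] = []  # named, class known
    ntt_filler = 0
    filler_by_region: list[tuple[str, int]] = []
    for region, (q_pos, q_var) in _SM1_REGION_QUOTAS.items():
        here = named.get(region, [])
        fixed.extend(here)
        named_positions = {p for p, *_ in here}
        assert len(named_positions) <= q_pos, region
        start, end = topo.span(region)
        pool = [p for p in range(start, end + 1) if p not in named_positions]
        add_pos = rng.choice(pool, size=q_pos - len(named_positions),
                             replace=False)
        region_positions = sorted(named_positions | {int(p) for p in add_pos})
        n_filler = q_var - len(here)
        filler_positions = [int(p) for p in add_pos]
        doubles = n_filler - len(filler_positions)
        assert doubles >= 0, region
        more = rng.choice(region_positions, size=doubles, replace=True)
        filler_positions.extend(int(p) for p in more)
        used: dict[int, set] = {}
        for p, _, m, _ in here:
            used.setdefault(p, set()).add(m)
        for p in filler_positions:
            wt = seq.residue_at(p)
            mut = _mutant_letter(rng, wt, used.setdefault(p, set()))
            used[p].add(mut)
            variants.append((p, wt, mut))
            filler_by_region.append((region, len(variants) - 1))
            if region == "Ntt":
                ntt_filler += 1

    # class pools: overlap convention resolved to disjoint assignments
    n_named_dec = len(_NAMED_DECREASED)
    pool = {"no_data": _SM1_COUNTS["no_data"],
            "like_wt": (_SM1_COUNTS["like_wt"] - _SM1_COUNTS["contradictory"]
                        - 1),  # the CAM variant carries a like-WT report
            "decreased": (_SM1_COUNTS["decreased"]
                          - _SM1_COUNTS["contradictory"] - n_named_dec),
            "contradictory": _SM1_COUNTS["contradictory"]}
    assert sum(pool.values()) == len(variants)

    # the N-terminal variants predominantly show no functional impact
    ntt_classes = (["like_wt"] * 14 + ["no_data"] * 7)[:ntt_filler]
    rest = []
    for name, count in pool.items():
        rest.extend([name] * count)
    for c in ntt_classes:
        rest.remove(c)
    rng.shuffle(rest)

    classes = [None] * len(variants)
    ntt_indices = [i for region, i in filler_by_region if region == "Ntt"]
    for i, c in zip(ntt_indices, ntt_classes):
        classes[i] = c
    it = iter(rest)
    for i in range(len(classes)):
        if classes[i] is None:
            classes[i] = next(it)

    rows = _emit_rows(variants, classes, rng)
    for pos, wt, mut, fclass in fixed:
        name = f"{wt}{pos}{mut}"
        if fclass == "decreased":
            rows.append({"variant": name, "camp": "down", "source": "studyA"})
        else:  # constitutively activating
            rows.append({"variant": name, "camp": "=", "basal": "up",
                         "source": "studyA"})
    # a duplicate same-class report that curation must merge, not recount
    rows.append({"variant": "D90N", "camp": "down", "source": "studyB"})
    # a handful of biased-signaling flags (orthogonal to the class)
    for row in rows[:: max(len(rows) // 8, 1)][:8]:
        row["biased"] = "*"
    if include_excluded_rows:
        rows.extend(dict(r) for r in _SM1_EXCLUDED_ROWS)
    rng.shuffle(rows)

    manifest = {
        "seed": seed,
        "expected": {"n_variants": 165, "n_positions": 129,
                     "n_no_data": 24, "n_like_wt": 71, "n_decreased": 92,
                     "n_contradictory": 22},
        "expected_regions": {r: {"n_positions": p, "n_variants": v}
                             for r, (p, v) in _SM1_REGION_QUOTAS.items()},
        "n_excluded_rows": len(_SM1_EXCLUDED_ROWS)
        if include_excluded_rows else 0,
        "named_decreased": list(_NAMED_DECREASED),
        "named_cam": _NAMED_CAM,
    }
    return rows, manifest


# ---------------------------------------------------------------------------
# sequence surrogates

def make_sequences(length: int, identity_pct: float = 100.0,
                   motifs=(), seed: int = 0
                   ) -> tuple[SequenceRecord, SequenceRecord, dict]:
    """A random sequence pair with an exact planted column identity
    (gap-free) and optional planted motifs shared by both."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = _rng(seed, "sequences")
    letters = [str(x) for x in rng.choice(list(AMINO_ACIDS_20), length)]
    protected = set()
    for pos, motif in motifs:
        for i, ch in enumerate(motif):
            letters[pos - 1 + i] = ch
            protected.add(pos + i)
    a = "".join(letters)
    n_mut = round(length * (1.0 - identity_pct / 100.0))
    mutable = [i for i in range(length) if i + 1 not in protected]
    if n_mut > len(mutable):
        raise ValueError("cannot reach the requested identity with the "
                         "planted motifs protected")
    sites = rng.choice(mutable, size=n_mut, replace=False)
    b_letters = list(letters)
    for i in sites:
        b_letters[i] = _mutant_letter(rng, b_letters[i])
    rec_a = SequenceRecord(id="synthA", residues=a)
    rec_b = SequenceRecord(id="synthB", residues="".join(b_letters))
    manifest = {"seed": seed, "length": length,
                "identity_pct": 100.0 * (length - n_mut) / length,
                "n_mutated": int(n_mut),
                "mutated_positions": sorted(int(i) + 1 for i in sites),
                "motifs": [list(m) for m in motifs]}
    return rec_a, rec_b, manifest


def _nonpositive_letter(rng, mat, wt: str) -> str:
    choices = [a for a in AMINO_ACIDS_20 if mat[wt, a] <= 0]
    return str(rng.choice(choices))


def make_ortholog_surrogates(seed: int = 0) -> tuple[dict, dict]:
    """Synthetic ortholog/template sequences with planted comparison levels.

    Derived from the real hMC4R sequence: a zfMC4R-like surrogate at 68%
    planted identity, a zfMC2R-like surrogate whose similarity to the
    zfMC4R-like one is ~60%, and an S1PR1-like template surrogate whose
    similarity to hMC4R over the transmembrane columns is ~50% (with a
    leucine at position 5.50, as in the real template).  The conserved
    agonist-pocket residues (E100, D122, D126, F261, H264, F284), the BW
    anchor motifs, and the melanocortin signature motifs are protected in
    the MC4R/MC2R surrogates, mirroring their conservation in fish.
    """
    rng = _rng(seed, "sequences")
    mat = load_matrix("BLOSUM62")
    h = hmc4r_sequence()
    topo = default_topology()
    anchors = load_anchors()
    pocket = set(load_pocket("msh_binding"))

    protected = set(pocket) | set(anchors.values())
    protected |= set(range(14, 20)) | set(range(257, 261))
    protected |= set(range(298, 303)) | set(range(146, 149))

    n = len(h)
    mutable = [p for p in range(1, n + 1) if p not in protected]

    # zfMC4R-like: exact planted identity of 68% against hMC4R
    n_mut4 = round(n * 0.32)
    sites4 = sorted(int(p) for p in rng.choice(mutable, size=n_mut4,
                                               replace=False))
    zf4 = list(h.residues)
    for p in sites4:
        zf4[p - 1] = _mutant_letter(rng, zf4[p - 1])
    zf4_rec = SequenceRecord(id="zfMC4R-like", residues="".join(zf4),
                             species="synthetic")

    # zfMC2R-like: ~60% planted similarity against the zfMC4R-like seq
    n_div2 = round(n * 0.40)
    sites2 = sorted(int(p) for p in rng.choice(mutable, size=n_div2,
                                               replace=False))
    zf2 = list(zf4)
    for p in sites2:
        zf2[p - 1] = _nonpositive_letter(rng, mat, zf2[p - 1])
    zf2_rec = SequenceRecord(id="zfMC2R-like", residues="".join(zf2),
                             species="synthetic")

    # S1PR1-like: ~50% planted similarity to hMC4R over TM columns
    tm_positions = [p for p in range(1, n + 1)
                    if topo.label_of(p).startswith("TMH")]
    s1p = list(h.residues)
    s1p[204 - 1] = "L"  # template 5.50 leucine (M→L scores positive)
    tm_mutable = [p for p in tm_positions if p != 204]
    n_div_tm = round(len(tm_positions) * 0.50)
    tm_sites = sorted(int(p) for p in rng.choice(tm_mutable, size=n_div_tm,
                                                 replace=False))
    for p in tm_sites:
        s1p[p - 1] = _nonpositive_letter(rng, mat, s1p[p - 1])
    loop_positions = [p for p in range(1, n + 1) if p not in tm_positions]
    loop_sites = sorted(int(p) for p in rng.choice(
        loop_positions, size=round(len(loop_positions) * 0.5), replace=False))
    for p in loop_sites:
        s1p[p - 1] = _nonpositive_letter(rng, mat, s1p[p - 1])
    s1p_rec = SequenceRecord(id="S1PR1-like", residues="".join(s1p),
                             species="synthetic")

    manifest = {
        "seed": seed,
        "planted_identity_hmc4r_zfmc4r": 100.0 * (n - n_mut4) / n,
        "planted_similarity_zfmc4r_zfmc2r_min": 100.0 * (n - n_div2) / n,
        "planted_tm_similarity_hmc4r_s1pr1": 100.0
        * (len(tm_positions) - n_div_tm) / len(tm_positions),
        "tm_positions": tm_positions,
        "protected_positions": sorted(protected),
    }
    return ({"hMC4R": h, "zfMC4R": zf4_rec, "zfMC2R": zf2_rec,
             "S1PR1": s1p_rec}, manifest)


def manifest_to_json(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
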