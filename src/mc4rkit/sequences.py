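"""Sequence-level toolkit for melanocortin receptor analysis.

Pairwise global alignment (BLOSUM62, affine gaps), identity/similarity
scoring, Ballesteros–Weinstein (BW) generic numbering, class A GPCR motif
detection, and receptor topology annotation (Ntt, TMH1-7, ICL1-3, ECL1-3,
H8, Ctt).

Residue numbering is 1-based on the mature receptor sequence throughout,
so the familiar hMC4R landmarks keep their literature names (D90, D126,
C271, D298, ...).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

#: canonical region order of a class A GPCR, N- to C-terminus
REGION_ORDER = (
    "Ntt", "TMH1", "ICL1", "TMH2", "ECL1", "TMH3", "ICL2", "TMH4",
    "ECL2", "TMH5", "ICL3", "TMH6", "ECL3", "TMH7", "H8", "Ctt",
)

TM_REGIONS = tuple(r for r in REGION_ORDER if r.startswith("TMH"))


class AnchorNotFoundError(ValueError):
    """A BW anchor motif could not be located; carries the failing helix."""

    def __init__(self, helix: int, message: str):
        self.helix = helix
        super().__init__(message)


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with an explicit residue-numbering origin."""

    id: str
    residues: str
    species: str = ""
    first_residue_number: int = 1

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-amino-acid letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def numbers(self) -> range:
        return range(self.first_residue_number,
                     self.first_residue_number + len(self.residues))

    def residue_at(self, number: int) -> str:
        i = number - self.first_residue_number
        if not 0 <= i < len(self.residues):
            raise KeyError(f"residue {number} outside {self.id} "
                           f"({self.numbers.start}-{self.numbers.stop - 1})")
        return self.residues[i]


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment as an explicit column list.

    ``columns`` holds ``(number_in_a, number_in_b)`` residue numbers, with
    ``None`` marking a gap; no column is a double gap.
    """

    a: SequenceRecord
    b: SequenceRecord
    columns: list[tuple[int | None, int | None]]
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0
    score: float = 0.0

    def __post_init__(self):
        last_a = last_b = None
        for ia, ib in self.columns:
            if ia is None and ib is None:
                raise ValueError("alignment contains a double-gap column")
            if ia is not None:
                if last_a is not None and ia <= last_a:
                    raise ValueError("non-increasing residue numbers in A")
                last_a = ia
            if ib is not None:
                if last_b is not None and ib <= last_b:
                    raise ValueError("non-increasing residue numbers in B")
                last_b = ib

    def a_to_b(self) -> dict[int, int]:
        """Map residue numbers of A onto aligned residue numbers of B."""
        return {ia: ib for ia, ib in self.columns
                if ia is not None and ib is not None}


@lru_cache(maxsize=8)
def load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {name!r}") from exc


def align_pair(a: SequenceRecord, b: SequenceRecord, *,
               matrix: str = "BLOSUM62",
               gap_open: float = -10.0,
               gap_extend: float = -1.0) -> PairwiseAlignment:
    """Global (Needleman–Wunsch) alignment under an affine gap model.

    Ties are broken deterministically by taking the aligner's first
    traceback, which prefers aligned pairs over gaps in A over gaps in B.
    """
    mat = load_matrix(matrix)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    result = aligner.align(a.residues, b.residues)
    best = result[0]
    ia, ib = best.indices  # -1 marks gaps
    columns: list[tuple[int | None, int | None]] = []
    for i, j in zip(ia.tolist(), ib.tolist()):
        na = None if i < 0 else i + a.first_residue_number
        nb = None if j < 0 else j + b.first_residue_number
        columns.append((na, nb))
    return PairwiseAlignment(a=a, b=b, columns=columns,
                             substitution_matrix=matrix,
                             gap_open=gap_open, gap_extend=gap_extend,
                             score=float(result.score))


def _counted_columns(aln: PairwiseAlignment,
                     positions: Iterable[int] | None) -> list[tuple[str, str]]:
    wanted = None if positions is None else set(positions)
    pairs = []
    for na, nb in aln.columns:
        if na is None or nb is None:
            continue
        if wanted is not None and na not in wanted:
            continue
        pairs.append((aln.a.residue_at(na), aln.b.residue_at(nb)))
    return pairs


def percent_identity(aln: PairwiseAlignment, *,
                     positions: Iterable[int] | None = None,
                     include_gaps: bool = False) -> float:
    """Percent identical columns.

    The denominator is the number of aligned (gap-free) columns by default;
    ``include_gaps=True`` switches to full alignment length.
    """
    pairs = _counted_columns(aln, positions)
    denom = len(aln.columns) if include_gaps else len(pairs)
    if denom == 0:
        raise ValueError("alignment has no aligned columns to score")
    return 100.0 * sum(x == y for x, y in pairs) / denom


def percent_similarity(aln: PairwiseAlignment, *,
                       positions: Iterable[int] | None = None,
                       include_gaps: bool = False) -> float:
    """Percent columns with a positive substitution-matrix score."""
    mat = load_matrix(aln.substitution_matrix)
    pairs = _counted_columns(aln, positions)
    denom = len(aln.columns) if include_gaps else len(pairs)
    if denom == 0:
        raise ValueError("alignment has no aligned columns to score")
    return 100.0 * sum(mat[x, y] > 0 for x, y in pairs) / denom


# ---------------------------------------------------------------------------
# topology

@dataclass
class TopologyAnnotation:
    """Contiguous region labels over a receptor sequence."""

    regions: list[tuple[str, int, int]]  # (label, start, end) inclusive

    def __post_init__(self):
        labels = [r[0] for r in self.regions]
        order = [r for r in REGION_ORDER if r in labels]
        if labels != order:
            raise ValueError(f"regions out of canonical order: {labels}")
        prev_end = None
        for label, start, end in self.regions:
            if end < start:
                raise ValueError(f"region {label} has end < start")
            if prev_end is not None and start != prev_end + 1:
                raise ValueError(f"region {label} is not contiguous with its "
                                 f"predecessor (starts {start}, expected {prev_end + 1})")
            prev_end = end

    @property
    def start(self) -> int:
        return self.regions[0][1]

    @property
    def end(self) -> int:
        return self.regions[-1][2]

    def label_of(self, number: int) -> str:
        for label, start, end in self.regions:
            if start <= number <= end:
                return label
        raise KeyError(f"residue {number} outside annotated range")

    def span(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.regions:
            if lab == label:
                return start, end
        raise KeyError(f"no region {label!r}")

    def size(self, label: str) -> int:
        start, end = self.span(label)
        return end - start + 1

    def residues_in(self, label: str) -> range:
        start, end = self.span(label)
        return range(start, end + 1)

    def as_mapping(self) -> dict[int, str]:
        return {n: label for label, start, end in self.regions
                for n in range(start, end + 1)}


def assign_topology(seq: SequenceRecord,
                    boundaries: Sequence[tuple[str, int, int]]) -> TopologyAnnotation:
    """Label every residue with its region; boundaries must tile the sequence."""
    topo = TopologyAnnotation(list(boundaries))
    if topo.start != seq.numbers.start or topo.end != seq.numbers.stop - 1:
        raise ValueError(
            f"boundary table covers {topo.start}-{topo.end} but {seq.id} "
            f"spans {seq.numbers.start}-{seq.numbers.stop - 1}")
    return topo


# ---------------------------------------------------------------------------
# Ballesteros–Weinstein numbering

@dataclass
class BWAnnotation:
    """Generic numbers for transmembrane residues, anchored at h.50."""

    mapping: dict[int, tuple[int, str]]  # residue number -> (helix, "h.nn")

    def bw(self, number: int) -> str:
        return self.mapping[number][1]

    def position_of(self, bw: str) -> int:
        for number, (_, label) in self.mapping.items():
            if label == bw:
                return number
        raise KeyError(f"no residue numbered {bw}")


def assign_bw_numbers(seq: SequenceRecord,
                      anchors: Mapping[int, int],
                      topology: TopologyAnnotation) -> BWAnnotation:
    """Number each TM residue relative to its helix anchor (anchor = h.50).

    ``anchors`` maps helix index (1-7) to the anchor residue number.
    """
    mapping: dict[int, tuple[int, str]] = {}
    for helix in sorted(anchors):
        start, end = topology.span(f"TMH{helix}")
        anchor = anchors[helix]
        if not start <= anchor <= end:
            raise AnchorNotFoundError(
                helix, f"anchor {anchor} for helix {helix} lies outside "
                       f"TMH{helix} ({start}-{end})")
        for n in range(start, end + 1):
            mapping[n] = (helix, f"{helix}.{50 + n - anchor}")
    return BWAnnotation(mapping)


#: regex anchor motifs for the class A consensus positions; the matched
#: group offset gives the x.50 residue.  Helix 5 has no melanocortin motif
#: (no P5.50) and must be supplied explicitly or by template alignment.
ANCHOR_MOTIFS: dict[int, tuple[str, int]] = {
    1: (r"N[IVL][LIV][VIL]", 0),
    2: (r"L[A-Z][A-Z][ASG]D", 4),
    3: (r"[DE]R[YFWH]", 1),
    4: (r"W", 0),
    6: (r"C[WF][A-Z]P", 3),
    7: (r"[DN]P[A-Z][A-Z][YF]", 1),
}


def find_anchors_by_motif(seq: SequenceRecord,
                          topology: TopologyAnnotation,
                          motifs: Mapping[int, tuple[str, int]] = ANCHOR_MOTIFS,
                          ) -> dict[int, int]:
    """Locate x.50 anchors by consensus-motif search inside each TM span."""
    anchors: dict[int, int] = {}
    for helix, (pattern, offset) in motifs.items():
        start, end = topology.span(f"TMH{helix}")
        segment = "".join(seq.residue_at(n) for n in range(start, end + 1))
        m = re.search(pattern, segment)
        if m is None:
            raise AnchorNotFoundError(
                helix, f"anchor motif /{pattern}/ not found in TMH{helix} "
                       f"of {seq.id}")
        anchors[helix] = start + m.start() + offset
    return anchors


# ---------------------------------------------------------------------------
# motif detection

@dataclass(frozen=True)
class MotifHit:
    name: str
    start: int
    end: int
    sequence: str


def detect_motifs(seq: SequenceRecord,
                  topology: TopologyAnnotation | None = None,
                  anchors: Mapping[int, int] | None = None) -> dict:
    """Survey the diagnostic class A / melanocortin sequence motifs.

    Reports the TM7 micro-switch class (NPxxY vs the melanocortin DPxxY),
    the N-terminal HxWNRS-type motif, the TM6 CWxP-like region, and —
    when a helix 5 anchor is known — whether position 5.50 is the class A
    proline (kinked TMH5) or another residue (regular α-helix expected).
    Absent motifs are reported as absent, never as errors.
    """
    s = seq.residues
    off = seq.first_residue_number

    def hit(name: str, m: re.Match) -> MotifHit:
        return MotifHit(name, m.start() + off, m.end() + off - 1, m.group())

    report: dict = {"tm7_motif": None, "tm7_class": "absent",
                    "n_terminal_motif": None, "cwxp_motif": None,
                    "position_5_50": None, "tmh5_geometry": None}

    m = re.search(r"[DN]P[A-Z][A-Z]Y", s)
    if m:
        report["tm7_motif"] = hit("TM7 micro-switch", m)
        report["tm7_class"] = "DPxxY" if m.group()[0] == "D" else "NPxxY"

    m = re.search(r"H[A-Z]WNRS|[YF][A-Z]{2}NHS", s)
    if m:
        report["n_terminal_motif"] = hit("HxWNRS", m)

    m = re.search(r"C[WF][A-Z]P", s)
    if m:
        report["cwxp_motif"] = hit("CWxP", m)

    if anchors is not None and 5 in anchors:
        res = seq.residue_at(anchors[5])
        report["position_5_50"] = res
        report["tmh5_geometry"] = ("kinked (P5.50)" if res == "P"
                                   else "regular α-helix expected")
    return report


# ---------------------------------------------------------------------------
# pocket conservation

def pocket_conservation_check(seqs: Sequence[SequenceRecord],
                              pocket_positions: Iterable[int],
                              *, matrix: str = "BLOSUM62",
                              gap_open: float = -10.0,
                              gap_extend: float = -1.0) -> list[dict]:
    """Conservation of reference pocket positions across a sequence set.

    The first record is the reference; every other sequence is aligned to
    it pairwise and the aligned residue at each pocket position is
    compared.  A position is ``identical`` when all sequences carry the
    reference residue, ``similar`` when every substitution scores
    positively under the matrix, and ``divergent`` otherwise.
    """
    ref = seqs[0]
    mat = load_matrix(matrix)
    maps = []
    for other in seqs[1:]:
        aln = align_pair(ref, other, matrix=matrix,
                         gap_open=gap_open, gap_extend=gap_extend)
        maps.append((other, aln.a_to_b()))

    table = []
    for pos in pocket_positions:
        ref_res = ref.residue_at(pos)  # raises if outside the reference
        residues = {ref.id: ref_res}
        status = "identical"
        for other, a2b in maps:
            if pos not in a2b:
                residues[other.id] = "-"
                status = "divergent"
                continue
            res = other.residue_at(a2b[pos])
            residues[other.id] = res
            if res != ref_res and status != "divergent":
                status = "similar" if mat[ref_res, res] > 0 else "divergent"
        table.append({"position": pos, "reference": ref_res,
                      "residues": residues, "status": status})
    return table


# ---------------------------------------------------------------------------
# shipped reference data and I/O

def read_fasta(path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i:i + 60] + "\n")


def write_aligned_fasta(aln: PairwiseAlignment, path) -> None:
    rows = {aln.a.id: [], aln.b.id: []}
    for na, nb in aln.columns:
        rows[aln.a.id].append("-" if na is None else aln.a.residue_at(na))
        rows[aln.b.id].append("-" if nb is None else aln.b.residue_at(nb))
    with open(path, "w") as fh:
        for name, letters in rows.items():
            fh.write(f">{name}\n{''.join(letters)}\n")


def write_annotation_csv(seq: SequenceRecord, topology: TopologyAnnotation,
                         bw: BWAnnotation, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["residue_number", "aa", "region", "bw"])
        for n in seq.numbers:
            label = topology.label_of(n)
            generic = bw.mapping.get(n, (None, ""))[1]
            writer.writerow([n, seq.residue_at(n), label, generic])


def _data_path(name: str):
    return resources.files("mc4rkit.data").joinpath(name)


def hmc4r_sequence() -> SequenceRecord:
    """The 332-residue human MC4R sequence, mature 1-based numbering."""
    rec = read_fasta(_data_path("hmc4r.fasta"))[0]
    return SequenceRecord(id="hMC4R", residues=rec.residues, species="human")


def load_boundaries(path=None) -> list[tuple[str, int, int]]:
    """Region boundary table; the shipped default reproduces the hMC4R
    topology with an 8-residue ICL1, 13-residue ICL2, and 4-residue ECL2."""
    path = _data_path("boundaries_hmc4r.csv") if path is None else path
    with open(path, newline="") as fh:
        return [(row["region"], int(row["start"]), int(row["end"]))
                for row in csv.DictReader(fh)]


def default_topology() -> TopologyAnnotation:
    return assign_topology(hmc4r_sequence(), load_boundaries())


def load_anchors(path=None) -> dict[int, int]:
    """Default hMC4R BW anchor positions (helix -> x.50 residue number)."""
    path = _data_path("bw_anchors_hmc4r.csv") if path is None else path
    with open(path, newline="") as fh:
        return {int(row["helix"]): int(row["anchor_position"])
                for row in csv.DictReader(fh)}


def load_pocket(name: str = "msh_binding") -> list[int]:
    """Named pocket definitions on hMC4R.

    ``msh_binding``: the conserved agonist-contact residues
    (E100, D122, D126, F261, H264, F284).
    ``variant_sensitive``: ligand-pocket positions carrying reported
    pathogenic substitutions (G32, D37, I125, D126, S191, I194, F261, F280).
    """
    with open(_data_path("pockets_hmc4r.csv"), newline="") as fh:
        positions = [int(row["position"]) for row in csv.DictReader(fh)
                     if row["pocket"] == name]
    if not positions:
        raise KeyError(f"no pocket named {name!r}")
    return positions
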