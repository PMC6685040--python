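"""Curation and structural classification of naturally occurring MC4R
substitutions.

The curated set mirrors how the clinical literature tallies MC4R
variants: single side-chain substitutions only (stop codons, deletions
and double substitutions are excluded), merged across reports, with a
functional class derived from in vitro evidence.  A variant supported by
any like-wild-type report counts toward the like-WT tally and one
supported by any loss report (α-MSH binding, cAMP accumulation, or cell
surface expression) toward the decreased tally; a variant with both
kinds of report is additionally flagged contradictory, so the class
tallies deliberately overlap (no_data + like_wt + decreased −
contradictory = total).
"""

from __future__ import annotations

import csv
import json
import re
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequences import (BWAnnotation, SequenceRecord, TopologyAnnotation,
                        REGION_ORDER)

FUNCTIONAL_CLASSES = ("no_data", "like_wt", "decreased", "increased_basal",
                      "contradictory")

GPROTEIN_REGIONS = {"ICL1", "ICL2", "ICL3", "H8"}

_SUB_RE = re.compile(r"^([A-Y])(\d+)([A-Y*X])$")
_DEL_RE = re.compile(r"^(?:Δ|DEL)?([A-Y])(\d+)(?:DEL)?$")


@dataclass
class VariantRecord:
    position: int
    wt: str
    mut: str
    functional_class: str
    biased: bool = False
    basal_increased: bool = False
    like_wt_support: bool = False
    decreased_support: bool = False
    sources: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.wt == self.mut:
            raise ValueError(f"{self.wt}{self.position}{self.mut}: "
                             "wild-type and mutant residue are identical")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional class "
                             f"{self.functional_class!r}")

    @property
    def name(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


@dataclass
class VariantSummary:
    n_variants: int
    n_positions: int
    n_no_data: int
    n_like_wt: int      # includes contradictory variants
    n_decreased: int    # includes contradictory variants
    n_contradictory: int
    n_increased_basal: int
    n_biased: int
    per_region: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def overlap_identity_holds(self) -> bool:
        """no_data + like_wt + decreased − contradictory == n_variants"""
        return (self.n_no_data + self.n_like_wt + self.n_decreased
                - self.n_contradictory == self.n_variants)


def parse_variant(text: str) -> dict:
    """Classify a variant string.

    Grammar: ``D90N`` single substitution; ``Y35X``/``Y35*`` stop;
    ``ΔI125``/``I125del`` deletion; ``D37V/I102T`` double substitution.
    Raises ValueError for anything else.
    """
    s = text.strip()
    if not s:
        raise ValueError("empty variant string")
    if "/" in s:
        parts = s.split("/")
        for p in parts:
            if not _SUB_RE.match(p.strip().upper()):
                raise ValueError(f"unparseable multi-substitution {text!r}")
        return {"kind": "double", "text": s}
    u = s.upper().replace("Δ", "Δ")
    m = _SUB_RE.match(u)
    if m:
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
        if mut in ("X", "*"):
            return {"kind": "stop", "position": pos, "wt": wt, "text": s}
        return {"kind": "substitution", "position": pos, "wt": wt,
                "mut": mut, "text": s}
    if s.startswith(("Δ", "del")) or u.endswith("DEL") or s.startswith("Δ"):
        m = _DEL_RE.match(u.lstrip("Δ").replace("Δ", ""))
        if m:
            return {"kind": "deletion", "position": int(m.group(2)),
                    "wt": m.group(1), "text": s}
    raise ValueError(f"unparseable variant string {text!r}")


def _row_evidence(row: Mapping[str, str]) -> tuple[bool, bool, bool, bool]:
    """(like_wt, decreased, basal_up, biased) support carried by one row."""
    camp = (row.get("camp") or "").strip().lower()
    binding = (row.get("binding") or "").strip().lower()
    expression = (row.get("expression") or "").strip().lower()
    basal = (row.get("basal") or "").strip().lower()
    biased = (row.get("biased") or "").strip()
    like = camp == "=" or binding == "="
    dec = "down" in (camp, binding, expression)
    return like, dec, basal == "up", biased in ("*", "1", "true", "yes")


def curate(rows: Iterable[Mapping[str, str]],
           sequence: SequenceRecord | None = None
           ) -> tuple[list[VariantRecord], list[tuple[dict, str]]]:
    """Filter and merge raw variant rows into curated records.

    Stop codons, deletions, and double substitutions are excluded (by
    definition of the single-substitution set), duplicates are merged
    with their evidence pooled, and variants with both like-WT and
    decreased reports are labeled contradictory.  Rows that cannot be
    parsed, or whose wild-type residue contradicts the reference
    sequence, are rejected with a reason.
    """
    merged: "OrderedDict[tuple, dict]" = OrderedDict()
    rejected: list[tuple[dict, str]] = []
    for row in rows:
        try:
            parsed = parse_variant(row.get("variant", ""))
        except ValueError as exc:
            rejected.append((dict(row), str(exc)))
            continue
        if parsed["kind"] != "substitution":
            rejected.append((dict(row), f"excluded: {parsed['kind']}"))
            continue
        pos, wt, mut = parsed["position"], parsed["wt"], parsed["mut"]
        if sequence is not None:
            try:
                ref = sequence.residue_at(pos)
            except KeyError:
                rejected.append((dict(row), f"position {pos} outside "
                                 f"{sequence.id}"))
                continue
            if ref != wt:
                rejected.append((dict(row), f"wild-type mismatch: sequence "
                                 f"has {ref} at {pos}, row says {wt}"))
                continue
        like, dec, basal, biased = _row_evidence(row)
        entry = merged.setdefault((pos, wt, mut), {
            "like": False, "dec": False, "basal": False, "biased": False,
            "sources": []})
        entry["like"] |= like
        entry["dec"] |= dec
        entry["basal"] |= basal
        entry["biased"] |= biased
        src = (row.get("source") or "").strip()
        if src and src not in entry["sources"]:
            entry["sources"].append(src)

    records = []
    for (pos, wt, mut), e in merged.items():
        if e["like"] and e["dec"]:
            fclass = "contradictory"
        elif e["dec"]:
            fclass = "decreased"
        elif e["like"]:
            fclass = "like_wt"
        elif e["basal"]:
            fclass = "increased_basal"
        else:
            fclass = "no_data"
        records.append(VariantRecord(
            position=pos, wt=wt, mut=mut, functional_class=fclass,
            biased=e["biased"], basal_increased=e["basal"],
            like_wt_support=e["like"] or fclass == "contradictory",
            decreased_support=e["dec"], sources=e["sources"]))
    return records, rejected


def summarize(records: Sequence[VariantRecord],
              topology: TopologyAnnotation | None = None) -> VariantSummary:
    """Tally curated variants the way the clinical collections do.

    ``n_like_wt`` and ``n_decreased`` each include the contradictory
    variants, so ``n_no_data + n_like_wt + n_decreased − n_contradictory``
    equals ``n_variants``.
    """
    n_contr = sum(r.functional_class == "contradictory" for r in records)
    n_like = sum(r.functional_class == "like_wt" for r in records) + n_contr
    n_dec = sum(r.functional_class == "decreased" for r in records) + n_contr
    counted = {"like_wt", "decreased", "contradictory", "no_data",
               "increased_basal"}
    assert all(r.functional_class in counted for r in records)
    n_no_data = sum(r.functional_class == "no_data" for r in records)

    per_region: dict[str, dict[str, int]] = {}
    if topology is not None:
        for region in REGION_ORDER:
            in_region = [r for r in records
                         if topology.label_of(r.position) == region]
            if not in_region:
                continue
            per_region[region] = {
                "n_variants": len(in_region),
                "n_positions": len({r.position for r in in_region}),
                "region_size": topology.size(region),
            }

    return VariantSummary(
        n_variants=len(records),
        n_positions=len({r.position for r in records}),
        n_no_data=n_no_data,
        n_like_wt=n_like,
        n_decreased=n_dec,
        n_contradictory=n_contr,
        n_increased_basal=sum(r.basal_increased for r in records),
        n_biased=sum(r.biased for r in records),
        per_region=per_region,
    )


def region_report(records: Sequence[VariantRecord],
                  topology: TopologyAnnotation) -> list[dict]:
    """Per-region variant/position counts with functional-class breakdown."""
    rows = []
    for region in REGION_ORDER:
        in_region = [r for r in records
                     if topology.label_of(r.position) == region]
        if not in_region:
            continue
        row = {"region": region,
               "region_size": topology.size(region),
               "n_variants": len(in_region),
               "n_positions": len({r.position for r in in_region})}
        for fclass in FUNCTIONAL_CLASSES:
            row[fclass] = sum(r.functional_class == fclass for r in in_region)
        rows.append(row)
    return rows


@dataclass(frozen=True)
class StructuralContext:
    label: str  # ligand_binding | gprotein_interface | TM_microdomain | other
    region: str
    bw: str | None
    evidence: str


def classify_structural_context(record: VariantRecord,
                                pocket: Iterable[int],
                                gprotein_interface: Iterable[int],
                                topology: TopologyAnnotation,
                                bw: BWAnnotation | None = None
                                ) -> StructuralContext:
    """Assign the structural mechanism category of a substitution.

    Precedence: ligand-pocket membership, then G-protein interface
    (intracellular loops, H8, or an explicit interface residue set), then
    transmembrane micro-domain, else other.
    """
    pos = record.position
    region = topology.label_of(pos)  # raises for unannotated positions
    generic = None
    if bw is not None and pos in bw.mapping:
        generic = bw.mapping[pos][1]
    if pos in set(pocket):
        return StructuralContext("ligand_binding", region, generic,
                                 "within the ligand-binding pocket set")
    if region in GPROTEIN_REGIONS or pos in set(gprotein_interface):
        return StructuralContext("gprotein_interface", region, generic,
                                 f"{region} / G-protein interface")
    if region.startswith("TMH"):
        note = "transmembrane micro-domain"
        if generic in ("2.50", "7.49"):
            note = "sodium-pocket residue (2.50/7.49)"
        return StructuralContext("TM_microdomain", region, generic, note)
    return StructuralContext("other", region, generic, "outside the mapped "
                             "functional surfaces")


# ---------------------------------------------------------------------------
# I/O

CSV_FIELDS = ["variant", "camp", "binding", "expression", "basal", "biased",
              "source"]


def read_variant_csv(path) -> list[dict]:
    """Read a raw variant table; '#'-prefixed header lines are skipped."""
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return [dict(row) for row in csv.DictReader(lines)]


def write_variant_csv(rows: Iterable[Mapping[str, str]], path,
                      header_comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in CSV_FIELDS})


def write_curated_csv(records: Sequence[VariantRecord],
                      contexts: Mapping[str, StructuralContext] | None,
                      path, header_comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(["variant", "position", "wt", "mut",
                         "functional_class", "biased", "basal_increased",
                         "structural_context", "region", "bw", "sources"])
        for r in records:
            ctx = contexts.get(r.name) if contexts else None
            writer.writerow([
                r.name, r.position, r.wt, r.mut, r.functional_class,
                int(r.biased), int(r.basal_increased),
                ctx.label if ctx else "", ctx.region if ctx else "",
                (ctx.bw or "") if ctx else "", ";".join(r.sources)])


def summary_to_json(summary: VariantSummary, path,
                    provenance: dict | None = None) -> None:
    payload = {
        "n_variants": summary.n_variants,
        "n_positions": summary.n_positions,
        "n_no_data": summary.n_no_data,
        "n_like_wt": summary.n_like_wt,
        "n_decreased": summary.n_decreased,
        "n_contradictory": summary.n_contradictory,
        "n_increased_basal": summary.n_increased_basal,
        "n_biased": summary.n_biased,
        "overlap_identity_holds": summary.overlap_identity_holds,
        "per_region": summary.per_region,
    }
    if provenance:
        payload["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


#: B-factor codes for Figure-style structural rendering
CONTEXT_BFACTOR = {"ligand_binding": 10.0, "TM_microdomain": 20.0,
                   "gprotein_interface": 30.0, "other": 40.0}


def annotate_bfactors(model, records: Sequence[VariantRecord],
                      contexts: Mapping[str, StructuralContext],
                      chain_id: str | None = None):
    """Write the structural-context code of each variant position into the
    B-factor column of a model (rendering handoff; returns a copy)."""
    out = model.copy()
    chains = out.chains if chain_id is None else [out.chain(chain_id)]
    codes = {r.position: CONTEXT_BFACTOR.get(
        contexts[r.name].label, 0.0) for r in records if r.name in contexts}
    for chain in chains:
        for res in chain.residues:
            code = codes.get(res.number)
            if code is not None:
                for atom in res.atoms:
                    atom.b = code
    return out
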