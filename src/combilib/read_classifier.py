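"""Read identification: chain alignments per read and call the construct.

Implements the verification algorithm for combinatorial assembly products:
alignments are ordered first by read then by read coordinate, chained, and
each chain is matched against construct templates (multigene, digested
single-gene, undigested single-gene).  Identified reads must be a similar
length (within 15 %, inclusive) to the summed lengths of the regions they
aligned to, and digested single-gene calls must additionally start and finish
within 50 bp of the first/final region's boundaries — this minimises
misidentifying a multigene assembly as a single-gene one.  The promoter at
each gene slot of an identified read is recorded.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alignment_io import AlignmentRecord
from .library_model import CATEGORIES, DesignError, LibraryDesign

VERDICTS = ("multigene", "digested_single", "undigested_single", "unidentified")

#: backbone parts of the single-assembly plasmid; their presence in a chain
#: alongside one promoter+unit cassette marks an undigested single assembly
DEFAULT_BACKBONE_REGIONS = frozenset({
    "AmpRTerm_AmpR_AmpRProm",
    "His3Prom_His3Term_2Micron_KanRTerm_KanR_KanRProm",
    "ColE1",
})


class UnknownRegionError(DesignError):
    pass


@dataclass
class ReadChain:
    """Per-read alignment segments, sorted by forward-strand read start."""

    read_name: str
    read_total_len: int
    segments: list[AlignmentRecord]
    orientation: str  # score-weighted majority strand
    decoy: bool  # best-scoring segment maps to a decoy region

    def __post_init__(self) -> None:
        starts = [s.read_start for s in self.segments]
        if starts != sorted(starts):
            raise ValueError("chain segments must be sorted by read start")
        if any(s.read_name != self.read_name for s in self.segments):
            raise ValueError("chain mixes read names")


@dataclass
class ReadIdentification:
    read_name: str
    verdict: str
    gene: str | None = None  # for single-gene verdicts
    slot_promoters: dict[str, str] = field(default_factory=dict)
    length_ratio: float = 0.0  # read length / summed region lengths
    reasons: list[str] = field(default_factory=list)

    @property
    def identified(self) -> bool:
        return self.verdict in ("multigene", "digested_single", "undigested_single")


def _overlap(a: AlignmentRecord, b: AlignmentRecord) -> bool:
    return a.read_start < b.read_end and b.read_start < a.read_end


def _try_merge(a: AlignmentRecord, b: AlignmentRecord) -> AlignmentRecord | None:
    """Merge split alignments of one region: same strand, collinear on read
    and reference, small read gap.  Genuine part repeats (same region at two
    slots) re-cover the same reference interval and are never merged."""
    if a.ref_name != b.ref_name or a.read_strand != b.read_strand:
        return None
    first, second = (a, b) if a.read_start <= b.read_start else (b, a)
    if first.read_strand == "+":
        ref_first, ref_second = first, second
    else:  # read order reverses reference order on the minus strand
        ref_first, ref_second = second, first
    if ref_second.ref_start < ref_first.ref_end - 5:  # ref overlap ⇒ repeat
        return None
    read_gap = second.read_start - first.read_end
    if read_gap > max(0.5 * a.ref_total_len, 20):
        return None
    ref_start = min(a.ref_start, b.ref_start)
    ref_end = max(a.ref_end, b.ref_end)
    return AlignmentRecord(
        score=a.score + b.score, ref_name=a.ref_name, ref_start=ref_start,
        ref_aln_len=ref_end - ref_start, read_name=a.read_name,
        read_start=first.read_start,
        read_aln_len=second.read_end - first.read_start,
        read_strand=a.read_strand, read_total_len=a.read_total_len,
        ref_total_len=a.ref_total_len,
    )


def chain_reads(
    records: Iterable[AlignmentRecord],
    design: LibraryDesign,
) -> list[ReadChain]:
    """Group alignments by read and order them along the read.

    Overlapping duplicates of one region collapse to the highest-scoring
    record; split alignments of one region are merged when collinear.  Chains
    whose best alignment is to a decoy region (a region not in the design) are
    flagged for removal downstream.
    """
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        by_read[rec.read_name].append(rec)

    chains: list[ReadChain] = []
    for read_name, recs in by_read.items():
        recs.sort(key=lambda r: (r.read_start, -r.score))
        kept: list[AlignmentRecord] = []
        for rec in recs:
            collapsed = False
            for i, other in enumerate(kept):
                if rec.ref_name == other.ref_name and _overlap(rec, other):
                    if rec.score > other.score:
                        kept[i] = rec
                    collapsed = True
                    break
            if not collapsed:
                kept.append(rec)
        kept.sort(key=lambda r: r.read_start)
        # merge collinear split alignments of the same region
        merged: list[AlignmentRecord] = []
        for rec in kept:
            if merged:
                joined = _try_merge(merged[-1], rec)
                if joined is not None:
                    merged[-1] = joined
                    continue
            merged.append(rec)

        best = max(merged, key=lambda r: r.score)
        plus = sum(r.score for r in merged if r.read_strand == "+")
        minus = sum(r.score for r in merged if r.read_strand == "-")
        chains.append(ReadChain(
            read_name=read_name,
            read_total_len=merged[0].read_total_len,
            segments=merged,
            orientation="+" if plus >= minus else "-",
            decoy=design.region_role(best.ref_name) == "decoy",
        ))
    chains.sort(key=lambda c: c.read_name)
    return chains


def _projected_read_interval(seg: AlignmentRecord) -> tuple[int, int]:
    """Full region extent projected onto forward read coordinates."""
    left_ref = seg.ref_start
    right_ref = seg.ref_total_len - seg.ref_end
    if seg.read_strand == "-":
        left_ref, right_ref = right_ref, left_ref
    return seg.read_start - left_ref, seg.read_end + right_ref


def identify_read(
    chain: ReadChain,
    design: LibraryDesign,
    length_tol: float = 0.15,
    end_tol: int = 50,
    backbone_regions: frozenset[str] | set[str] | None = None,
    known_regions: set[str] | None = None,
) -> ReadIdentification:
    """Classify one non-decoy chain against the construct templates.

    Rules applied in order: template match on the canonicalised region
    pattern, global length test (inclusive at exactly ``length_tol``), and —
    for digested single-gene candidates only — end anchoring within
    ``end_tol`` bp.  Failures yield ``unidentified`` with reason tags.
    """
    if chain.decoy:
        raise ValueError(f"chain for {chain.read_name!r} is flagged as decoy")
    if not chain.segments:
        raise ValueError("empty chain")
    backbone = DEFAULT_BACKBONE_REGIONS if backbone_regions is None else frozenset(backbone_regions)

    if known_regions is not None:
        for seg in chain.segments:
            if design.region_role(seg.ref_name) == "decoy" and seg.ref_name not in known_regions:
                raise UnknownRegionError(
                    f"chain for {chain.read_name!r} references unknown region {seg.ref_name!r}"
                )

    region_sum = sum(seg.ref_total_len for seg in chain.segments)
    ratio = chain.read_total_len / region_sum
    reasons: list[str] = []

    # canonicalise: a read sequenced from the other end lists regions in
    # reverse order
    segments = chain.segments if chain.orientation == "+" else chain.segments[::-1]

    core: list[AlignmentRecord] = []
    extras: list[AlignmentRecord] = []
    for seg in segments:
        role = design.region_role(seg.ref_name)
        (core if role in ("promoter", "gene_unit") else extras).append(seg)

    if any(seg.ref_name not in backbone for seg in extras):
        reasons.append("decoy_segment")

    # core must alternate promoter, gene_unit pairs
    pairs: list[tuple[str, str]] = []  # (promoter, gene)
    pending_promoter: str | None = None
    for seg in core:
        role = design.region_role(seg.ref_name)
        if role == "promoter":
            if pending_promoter is not None:
                reasons.append("ambiguous_promoter")
                break
            pending_promoter = seg.ref_name
        else:
            if pending_promoter is None:
                reasons.append("template")
                break
            pairs.append((pending_promoter, seg.ref_name))
            pending_promoter = None
    else:
        if pending_promoter is not None:
            reasons.append("template")

    verdict = "unidentified"
    gene: str | None = None
    slot_promoters: dict[str, str] = {}

    if not reasons:
        genes = tuple(g for _, g in pairs)
        candidate_ok = all(
            g in design.genes and p in design.slot_for(g).candidate_promoters
            for p, g in pairs
        )
        if not pairs or not candidate_ok:
            reasons.append("template")
        elif extras:
            if len(pairs) == 1:
                verdict = "undigested_single"
                gene = genes[0]
            else:
                reasons.append("template")
        elif genes == design.genes:
            verdict = "multigene"
        elif len(pairs) == 1:
            verdict = "digested_single"
            gene = genes[0]
        else:
            reasons.append("template")

    if verdict != "unidentified":
        # length rule: |read − Σ regions| / Σ regions ≤ tol, boundary inclusive
        if abs(chain.read_total_len - region_sum) > length_tol * region_sum:
            reasons.append("length")
        if verdict == "digested_single":
            first_start, _ = _projected_read_interval(chain.segments[0])
            _, last_end = _projected_read_interval(chain.segments[-1])
            if abs(first_start) > end_tol or abs(chain.read_total_len - last_end) > end_tol:
                reasons.append("end_anchor")
        if not reasons:
            slot_promoters = {g: p for p, g in pairs}
        else:
            verdict = "unidentified"
            gene = None

    return ReadIdentification(
        read_name=chain.read_name, verdict=verdict, gene=gene,
        slot_promoters=slot_promoters, length_ratio=ratio, reasons=reasons,
    )


def classify_reads(
    records: Iterable[AlignmentRecord],
    design: LibraryDesign,
    length_tol: float = 0.15,
    end_tol: int = 50,
    backbone_regions: frozenset[str] | None = None,
) -> list[ReadIdentification]:
    """Chain and classify every read; decoy chains get verdict ``decoy``."""
    out: list[ReadIdentification] = []
    for chain in chain_reads(records, design):
        if chain.decoy:
            out.append(ReadIdentification(
                read_name=chain.read_name, verdict="decoy",
                length_ratio=0.0, reasons=["decoy"]))
        else:
            out.append(identify_read(
                chain, design, length_tol=length_tol, end_tol=end_tol,
                backbone_regions=backbone_regions))
    return out


@dataclass
class PromoterCountTable:
    """Promoter (and category) observations per gene slot for one stage."""

    stage: str
    counts: dict[tuple[str, str], int]  # (gene, promoter) -> n
    category_counts: dict[tuple[str, str], int]  # (gene, category) -> n

    def total(self, gene: str) -> int:
        return sum(n for (g, _), n in self.counts.items() if g == gene)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": self.stage, "gene": g, "promoter": p, "count": n}
            for (g, p), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["stage", "gene", "promoter", "count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, design: LibraryDesign) -> "PromoterCountTable":
        df = pd.read_csv(path, sep="\t")
        stage = str(df["stage"].iloc[0]) if len(df) else ""
        counts = {(str(r.gene), str(r.promoter)): int(r.count) for r in df.itertuples()}
        return _with_categories(stage, counts, design)


def _with_categories(
    stage: str, counts: dict[tuple[str, str], int], design: LibraryDesign
) -> PromoterCountTable:
    category_counts: dict[tuple[str, str], int] = {
        (slot.gene, cat): 0 for slot in design.slots for cat in CATEGORIES
    }
    for (gene, prom), n in counts.items():
        if prom not in design.parts:
            raise DesignError(f"promoter {prom!r} not in part registry")
        category_counts[(gene, design.parts[prom].category)] += n
    return PromoterCountTable(stage=stage, counts=counts, category_counts=category_counts)


def tabulate(
    identifications: Iterable[ReadIdentification],
    design: LibraryDesign,
    stage: str,
    include: Sequence[str] = ("multigene", "digested_single", "undigested_single"),
) -> PromoterCountTable:
    """Count the promoter recorded at each slot across identified reads.

    Multigene reads contribute one observation per design slot; single-gene
    reads one observation at their slot; unidentified/decoy reads none.
    """
    counts: dict[tuple[str, str], int] = {
        (slot.gene, p): 0 for slot in design.slots for p in slot.candidate_promoters
    }
    for ident in identifications:
        if ident.verdict not in include or not ident.identified:
            continue
        for gene, prom in ident.slot_promoters.items():
            if (gene, prom) not in counts:
                raise DesignError(f"promoter {prom!r} is not a candidate at {gene!r}")
            counts[(gene, prom)] += 1
    return _with_categories(stage, counts, design)


def verdicts_frame(identifications: Iterable[ReadIdentification]) -> pd.DataFrame:
    rows = []
    for ident in identifications:
        row = {
            "read_id": ident.read_name, "verdict": ident.verdict,
            "gene": ident.gene or "", "length_ratio": round(ident.length_ratio, 4),
            "reasons": ",".join(ident.reasons),
        }
        for gene, prom in ident.slot_promoters.items():
            row[f"prom_{gene}"] = prom
        rows.append(row)
    return pd.DataFrame(rows)
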