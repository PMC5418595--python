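"""Combinatorial promoter-library designs and their reference databases.

A :class:`LibraryDesign` holds an ordered list of gene slots, each with a set
of candidate promoters drawn from a shared part registry.  From it one can
enumerate the design space, derive the null (chance) distribution of promoter
categories at a slot, and assemble the alignment reference database of
promoter regions, combined CDS+terminator units and decoy sequences.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CATEGORIES = ("strong", "medium", "weak", "inducible")
ROLES = ("promoter", "gene_unit", "decoy")

_VALID_DNA = set("ACGTNacgtn")


class DesignError(ValueError):
    """Raised when a design or reference database violates an invariant."""


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise DesignError(f"sequence for {name!r} is empty")
    if not set(seq) <= _VALID_DNA:
        bad = sorted(set(seq) - _VALID_DNA)
        raise DesignError(f"sequence for {name!r} has non-DNA characters: {bad}")


@dataclass(frozen=True)
class PromoterPart:
    """A promoter part: the unit whose incorporation frequency is under test."""

    name: str
    category: str
    sequence: str
    strength: float | None = None  # relative strength, a.u.; metadata only

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise DesignError(
                f"unknown category {self.category!r} for promoter {self.name!r}; "
                f"expected one of {CATEGORIES}"
            )
        _check_sequence(self.sequence, self.name)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneUnit:
    """A combined CDS+terminator region for one pathway gene."""

    gene: str
    sequence: str

    def __post_init__(self) -> None:
        _check_sequence(self.sequence, self.gene)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Slot:
    gene: str
    candidate_promoters: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.candidate_promoters:
            raise DesignError(f"slot {self.gene!r} has no candidate promoters")


@dataclass
class LibraryDesign:
    """Ordered gene slots plus the promoter and gene-unit registries."""

    slots: list[Slot]
    parts: dict[str, PromoterPart]
    units: dict[str, GeneUnit]

    def __post_init__(self) -> None:
        for name, part in self.parts.items():
            if name != part.name:
                raise DesignError(f"part registry key {name!r} != part name {part.name!r}")
        for gene, unit in self.units.items():
            if gene != unit.gene:
                raise DesignError(f"unit registry key {gene!r} != unit gene {unit.gene!r}")
        seen = set()
        for slot in self.slots:
            if slot.gene in seen:
                raise DesignError(f"duplicate slot gene {slot.gene!r}")
            seen.add(slot.gene)
            if slot.gene not in self.units:
                raise DesignError(f"slot gene {slot.gene!r} has no gene unit")
            for pname in slot.candidate_promoters:
                if pname not in self.parts:
                    raise DesignError(
                        f"candidate promoter {pname!r} at slot {slot.gene!r} "
                        "is not in the part registry"
                    )

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(slot.gene for slot in self.slots)

    def slot_for(self, gene: str) -> Slot:
        for slot in self.slots:
            if slot.gene == gene:
                return slot
        raise DesignError(f"gene {gene!r} is not a slot of this design")

    def promoter_category(self, name: str) -> str:
        return self.parts[name].category

    def region_role(self, name: str) -> str:
        """Role of a region name relative to this design (unknown ⇒ decoy)."""
        if name in self.parts:
            return "promoter"
        if name in self.units:
            return "gene_unit"
        return "decoy"


@dataclass(frozen=True)
class ReferenceRegion:
    name: str
    sequence: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DesignError(f"unknown role {self.role!r} for region {self.name!r}")
        _check_sequence(self.sequence, self.name)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceDatabase:
    """Named reference regions (promoter / gene_unit / decoy) for alignment."""

    regions: dict[str, ReferenceRegion] = field(default_factory=dict)

    def add(self, region: ReferenceRegion) -> None:
        if region.name in self.regions:
            raise DesignError(f"duplicate region name {region.name!r}")
        self.regions[region.name] = region

    def __getitem__(self, name: str) -> ReferenceRegion:
        return self.regions[name]

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions.values())

    @property
    def names(self) -> list[str]:
        return list(self.regions)

    def names_with_role(self, role: str) -> list[str]:
        return [r.name for r in self if r.role == role]

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(r.sequence), id=r.name, description=f"role={r.role}")
            for r in self
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, roles: Mapping[str, str] | None = None) -> "ReferenceDatabase":
        """Read a multi-record FASTA; role from ``role=`` description tags,
        overridable via *roles*, defaulting to decoy."""
        db = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            role = "decoy"
            for token in rec.description.split():
                if token.startswith("role="):
                    role = token[5:]
            if roles and rec.id in roles:
                role = roles[rec.id]
            db.add(ReferenceRegion(rec.id, str(rec.seq).upper(), role))
        return db


def design_space_size(design: LibraryDesign) -> int:
    """Number of distinct promoter combinations the design can produce."""
    if not design.slots:
        raise DesignError("design has no slots; design space is degenerate")
    return math.prod(len(slot.candidate_promoters) for slot in design.slots)


def null_category_distribution(design: LibraryDesign, gene: str) -> dict[str, float]:
    """Chance (uniform-draw) probability of each promoter category at a slot."""
    slot = design.slot_for(gene)
    counts = Counter(design.parts[p].category for p in slot.candidate_promoters)
    total = len(slot.candidate_promoters)
    return {cat: counts.get(cat, 0) / total for cat in CATEGORIES}


def build_reference_db(
    design: LibraryDesign, decoys: Mapping[str, str] | None = None
) -> ReferenceDatabase:
    """Assemble the alignment database: promoters, gene units, decoys."""
    db = ReferenceDatabase()
    for part in design.parts.values():
        db.add(ReferenceRegion(part.name, part.sequence, "promoter"))
    for unit in design.units.values():
        db.add(ReferenceRegion(unit.gene, unit.sequence, "gene_unit"))
    if decoys:
        for name, seq in decoys.items():
            db.add(ReferenceRegion(name, seq, "decoy"))
    return db


# ---------------------------------------------------------------------------
# Manifest I/O
#
# A design is stored as a TSV manifest plus a FASTA of sequences.  Manifest
# columns: name, role (promoter|gene_unit), category, strength, slots.
# gene_unit rows define slot order; a promoter's ``slots`` column is a
# comma-separated list of genes, or ``*`` for every slot.

def save_design(design: LibraryDesign, manifest_path: str | Path, fasta_path: str | Path) -> None:
    rows = []
    records = []
    all_genes = design.genes
    for slot in design.slots:
        unit = design.units[slot.gene]
        rows.append({"name": slot.gene, "role": "gene_unit", "category": "",
                     "strength": "", "slots": ""})
        records.append(SeqRecord(Seq(unit.sequence), id=slot.gene, description="role=gene_unit"))
    for part in design.parts.values():
        genes = tuple(s.gene for s in design.slots if part.name in s.candidate_promoters)
        slots = "*" if genes == all_genes else ",".join(genes)
        rows.append({
            "name": part.name, "role": "promoter", "category": part.category,
            "strength": "" if part.strength is None else part.strength, "slots": slots,
        })
        records.append(SeqRecord(Seq(part.sequence), id=part.name, description="role=promoter"))
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    SeqIO.write(records, str(fasta_path), "fasta")


def load_design(manifest_path: str | Path, fasta_path: str | Path) -> LibraryDesign:
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    def seq_for(name: str) -> str:
        if name not in seqs:
            raise DesignError(f"no FASTA sequence for manifest entry {name!r}")
        return seqs[name]

    units: dict[str, GeneUnit] = {}
    gene_order: list[str] = []
    parts: dict[str, PromoterPart] = {}
    promoter_slots: dict[str, str] = {}
    for _, row in manifest.iterrows():
        name, role = row["name"], row["role"]
        if role == "gene_unit":
            units[name] = GeneUnit(name, seq_for(name))
            gene_order.append(name)
        elif role == "promoter":
            strength = float(row["strength"]) if row.get("strength", "") != "" else None
            parts[name] = PromoterPart(name, row["category"], seq_for(name), strength)
            promoter_slots[name] = row.get("slots", "*") or "*"
        else:
            raise DesignError(f"unknown manifest role {role!r} for {name!r}")

    slots = []
    for gene in gene_order:
        candidates = tuple(
            p for p, spec in promoter_slots.items()
            if spec == "*" or gene in spec.split(",")
        )
        slots.append(Slot(gene, candidates))
    return LibraryDesign(slots=slots, parts=parts, units=units)
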