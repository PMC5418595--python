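"""Ground-truthed synthetic inputs for the verification pipeline.

Generates random promoter assemblies from a :class:`LibraryDesign`, applies a
restriction-digest size selection, and emits error-bearing long reads with a
per-read truth table, so every downstream stage is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library_model import GeneUnit, LibraryDesign, PromoterPart, Slot
from .seqs import random_dna, reverse_complement

KINDS = ("multigene", "digested_single", "undigested_single")
CONTAMINANT = "contaminant"

GENES = ("pcbC", "pclA", "penDE")

# Ten promoters: 4 strong, 2 medium, 2 weak, 2 inducible.  Names follow the
# yeast toolkit convention; strengths are rough relative values (a.u.).
DEFAULT_PROMOTERS: tuple[tuple[str, str, float], ...] = (
    ("pTDH3", "strong", 100.0),
    ("pCCW12", "strong", 88.0),
    ("pPGK1", "strong", 49.0),
    ("pTEF1", "strong", 59.0),
    ("pRPL18B", "medium", 17.0),
    ("pSAC6", "medium", 10.0),
    ("pREV1", "weak", 0.9),
    ("pPSP2", "weak", 2.6),
    ("pGAL1", "inducible", 75.0),
    ("pGAL10", "inducible", 70.0),
)

# Full-scale lengths chosen so every digested single-gene fragment
# (promoter+unit) falls exactly inside the printed per-gene digest windows.
_PROMOTER_LENGTHS = (400, 419, 437, 456, 474, 493, 511, 530, 548, 567)
_UNIT_LENGTHS = {"pcbC": 1662, "pclA": 2149, "penDE": 1485}

PAPER_MULTIGENE_WINDOW = (5616, 6117)
PAPER_SINGLE_WINDOWS = {
    "pcbC": (2062, 2229),
    "pclA": (2549, 2716),
    "penDE": (1885, 2052),
}

DEFAULT_DECOY_LENGTHS = {
    "AmpRTerm_AmpR_AmpRProm": 1200,
    "His3Prom_His3Term_2Micron_KanRTerm_KanR_KanRProm": 2600,
    "ColE1": 600,
    "lambda": 4000,  # short random surrogate for the phage genome
}

# Backbone parts of the single-assembly plasmid; appended to undigested
# single-gene assemblies and recognised by the classifier.
SINGLE_BACKBONE_DECOYS = ("AmpRTerm_AmpR_AmpRProm", "ColE1")


def demo_design(seed: int = 7, scale: float = 1.0) -> LibraryDesign:
    """Bundled 3-slot × 10-promoter demo design with random sequences.

    ``scale`` shrinks all region lengths proportionally (the classifier rules
    are scale-free); sequences are deterministic in ``seed``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    parts: dict[str, PromoterPart] = {}
    for (name, category, strength), length in zip(DEFAULT_PROMOTERS, _PROMOTER_LENGTHS):
        n = max(20, round(length * scale))
        parts[name] = PromoterPart(name, category, random_dna(n, rng), strength)
    units = {
        gene: GeneUnit(gene, random_dna(max(40, round(_UNIT_LENGTHS[gene] * scale)), rng))
        for gene in GENES
    }
    slots = [Slot(gene, tuple(parts)) for gene in GENES]
    return LibraryDesign(slots=slots, parts=parts, units=units)


def demo_decoys(seed: int = 11, scale: float = 1.0) -> dict[str, str]:
    """Random surrogate decoy sequences (backbones + lambda stand-in)."""
    rng = np.random.default_rng(seed)
    return {
        name: random_dna(max(30, round(length * scale)), rng)
        for name, length in DEFAULT_DECOY_LENGTHS.items()
    }


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base substitution / insertion / deletion rates."""

    substitution_rate: float = 0.03
    insertion_rate: float = 0.02
    deletion_rate: float = 0.02

    def __post_init__(self) -> None:
        rates = (self.substitution_rate, self.insertion_rate, self.deletion_rate)
        if any(not (0 <= r < 1) for r in rates):
            raise ValueError("error rates must be in [0, 1)")
        if sum(rates) >= 1:
            raise ValueError("error rates must sum to < 1")

    @classmethod
    def perfect(cls) -> "ErrorModel":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class AssemblyInstance:
    """One simulated assembly molecule with its ground truth."""

    kind: str  # multigene | digested_single | undigested_single | contaminant
    gene: str | None
    promoter_choice: Mapping[str, str]  # gene slot -> promoter name
    sequence: str
    truth_id: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS and self.kind != CONTAMINANT:
            raise ValueError(f"unknown assembly kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SizeWindows:
    """Inclusive fragment-length windows per assembly kind (and gene)."""

    windows: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for key, (lo, hi) in self.windows.items():
            if lo <= 0 or hi <= 0 or lo > hi:
                raise ValueError(f"bad size window {key!r}: ({lo}, {hi})")

    @staticmethod
    def key_for(kind: str, gene: str | None = None) -> str:
        return kind if kind == "multigene" else f"{kind}:{gene}"

    def window_for(self, instance: AssemblyInstance) -> tuple[int, int]:
        key = self.key_for(instance.kind, instance.gene)
        if key not in self.windows:
            raise KeyError(f"no size window defined for {key!r}")
        return self.windows[key]

    @classmethod
    def from_design(
        cls,
        design: LibraryDesign,
        backbone_len: int | None = None,
    ) -> "SizeWindows":
        """Exact achievable length windows for each fragment kind."""
        windows: dict[str, tuple[int, int]] = {}
        lo = hi = 0
        for slot in design.slots:
            plens = [len(design.parts[p]) for p in slot.candidate_promoters]
            lo += min(plens) + len(design.units[slot.gene])
            hi += max(plens) + len(design.units[slot.gene])
        windows["multigene"] = (lo, hi)
        for slot in design.slots:
            plens = [len(design.parts[p]) for p in slot.candidate_promoters]
            ulen = len(design.units[slot.gene])
            windows[f"digested_single:{slot.gene}"] = (min(plens) + ulen, max(plens) + ulen)
            if backbone_len is not None:
                windows[f"undigested_single:{slot.gene}"] = (
                    min(plens) + ulen + backbone_len,
                    max(plens) + ulen + backbone_len,
                )
        return cls(windows)


def paper_windows() -> SizeWindows:
    """The digest-product isolation windows printed in the source protocol."""
    windows = {"multigene": PAPER_MULTIGENE_WINDOW}
    for gene, win in PAPER_SINGLE_WINDOWS.items():
        windows[f"digested_single:{gene}"] = win
    return SizeWindows(windows)


def _draw_promoter(
    slot: Slot,
    rng: np.random.Generator,
    weights: Mapping[str, Mapping[str, float]] | None,
    gene: str,
) -> str:
    candidates = slot.candidate_promoters
    if weights and gene in weights:
        w = np.array([weights[gene].get(p, 0.0) for p in candidates], dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"weights for slot {gene!r} sum to zero")
        return candidates[rng.choice(len(candidates), p=w / w.sum())]
    return candidates[rng.integers(len(candidates))]


def simulate_assembly(
    design: LibraryDesign,
    kind: str,
    rng: np.random.Generator | int,
    *,
    gene: str | None = None,
    weights: Mapping[str, Mapping[str, float]] | None = None,
    backbone_seqs: Sequence[str] = (),
    serial: int = 0,
) -> AssemblyInstance:
    """Draw one assembly: promoters i.i.d. uniform per slot (or per *weights*).

    ``undigested_single`` assemblies carry the supplied backbone fragment(s)
    downstream of the promoter+unit cassette.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown assembly kind {kind!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    if kind == "multigene":
        choice = {s.gene: _draw_promoter(s, rng, weights, s.gene) for s in design.slots}
        seq = "".join(
            design.parts[choice[s.gene]].sequence + design.units[s.gene].sequence
            for s in design.slots
        )
        label = "-".join(choice[g] for g in design.genes)
        truth_id = f"multigene|{label}|{serial}"
        return AssemblyInstance(kind, None, choice, seq, truth_id)

    if gene is None:
        gene = design.genes[rng.integers(len(design.genes))]
    slot = design.slot_for(gene)
    prom = _draw_promoter(slot, rng, weights, gene)
    seq = design.parts[prom].sequence + design.units[gene].sequence
    if kind == "undigested_single":
        if not backbone_seqs:
            raise ValueError("undigested_single requires backbone_seqs")
        seq += "".join(backbone_seqs)
    truth_id = f"{kind}|{gene}|{prom}|{serial}"
    return AssemblyInstance(kind, gene, {gene: prom}, seq, truth_id)


def digest_and_select(instance: AssemblyInstance, windows: SizeWindows) -> str | None:
    """Return the fragment iff its length lies inside the (inclusive) window;
    rejection is the value ``None``, not an error."""
    lo, hi = windows.window_for(instance)
    n = len(instance.sequence)
    return instance.sequence if lo <= n <= hi else None


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    truth_id: str
    kind: str
    gene: str | None
    strand: str
    promoter_choice: Mapping[str, str]


def apply_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Apply i.i.d. per-base substitutions, insertions and deletions."""
    if model.substitution_rate == model.insertion_rate == model.deletion_rate == 0:
        return seq
    from .seqs import decode, encode

    arr = encode(seq).astype(np.int64)
    n = arr.size
    u = rng.random(n)
    keep = u >= model.deletion_rate
    sub = (u >= model.deletion_rate) & (u < model.deletion_rate + model.substitution_rate)
    # substitute with a guaranteed different base
    arr = np.where(sub, (arr + rng.integers(1, 4, size=n)) % 4, arr)
    n_ins = rng.binomial(1, model.insertion_rate, size=n + 1)  # before each base + end
    pieces: list[np.ndarray] = []
    ins_total = int(n_ins.sum())
    ins_bases = rng.integers(0, 4, size=ins_total)
    ins_i = 0
    for i in range(n):
        if n_ins[i]:
            pieces.append(ins_bases[ins_i:ins_i + 1])
            ins_i += 1
        if keep[i]:
            pieces.append(arr[i:i + 1])
    if n_ins[n]:
        pieces.append(ins_bases[ins_i:ins_i + 1])
    if not pieces:
        return ""
    return decode(np.concatenate(pieces))


def simulate_reads(
    fragments: Sequence[AssemblyInstance],
    model: ErrorModel,
    n_reads: int,
    seed: int,
    read_prefix: str = "read",
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Sequence full-length reads from *fragments*, uniform source and strand.

    Deterministic in ``seed``; returns the reads plus a truth table with one
    row per read.
    """
    if not fragments:
        raise ValueError("empty fragment list")
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        frag = fragments[int(rng.integers(len(fragments)))]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = frag.sequence if strand == "+" else reverse_complement(frag.sequence)
        seq = apply_errors(seq, model, rng)
        reads.append(SimulatedRead(
            read_id=f"{read_prefix}_{i:05d}", sequence=seq, truth_id=frag.truth_id,
            kind=frag.kind, gene=frag.gene, strand=strand,
            promoter_choice=dict(frag.promoter_choice),
        ))
    return reads, truth_table(reads)


def truth_table(reads: Sequence[SimulatedRead]) -> pd.DataFrame:
    rows = []
    for r in reads:
        row = {"read_id": r.read_id, "truth_id": r.truth_id, "kind": r.kind,
               "gene": r.gene or "", "strand": r.strand}
        for gene, prom in r.promoter_choice.items():
            row[f"prom_{gene}"] = prom
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LibrarySimulation:
    reads: list[SimulatedRead]
    truth: pd.DataFrame
    design: LibraryDesign
    decoys: Mapping[str, str]


DEFAULT_FRACTIONS = {
    "multigene": 0.70,
    "digested_single": 0.15,
    "undigested_single": 0.10,
    "contaminant": 0.05,
}


def simulate_library(
    design: LibraryDesign,
    n_reads: int,
    seed: int,
    *,
    model: ErrorModel | None = None,
    fractions: Mapping[str, float] | None = None,
    decoys: Mapping[str, str] | None = None,
    weights: Mapping[str, Mapping[str, float]] | None = None,
    windows: SizeWindows | None = None,
) -> LibrarySimulation:
    """End-to-end simulation: assemble, size-select, sequence.

    One fresh assembly is drawn per read (independent draws, as in a pooled
    library).  Contaminant reads are taken from decoy sequences.  Fragments of
    selectable kinds are passed through :func:`digest_and_select` against
    *windows* (defaulting to the design's exact windows, under which every
    proper fragment is accepted); undigested singles bypass selection.
    """
    model = model or ErrorModel()
    fractions = dict(fractions or DEFAULT_FRACTIONS)
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    decoys = dict(decoys if decoys is not None else demo_decoys())
    windows = windows or SizeWindows.from_design(design)
    backbone = [decoys[n] for n in SINGLE_BACKBONE_DECOYS if n in decoys]
    decoy_names = list(decoys)

    rng = np.random.default_rng(seed)
    classes = list(fractions)
    probs = np.array([fractions[c] for c in classes])
    fragments: list[AssemblyInstance] = []
    for i in range(n_reads):
        cls_name = classes[int(rng.choice(len(classes), p=probs))]
        if cls_name == CONTAMINANT:
            name = decoy_names[int(rng.integers(len(decoy_names)))]
            fragments.append(AssemblyInstance(
                CONTAMINANT, None, {}, decoys[name], f"contaminant|{name}|{i}"))
            continue
        inst = simulate_assembly(
            design, cls_name, rng, weights=weights,
            backbone_seqs=backbone if cls_name == "undigested_single" else (),
            serial=i,
        )
        if cls_name != "undigested_single":
            frag = digest_and_select(inst, windows)
            if frag is None:  # pragma: no cover - design windows accept all
                continue
        fragments.append(inst)

    reads: list[SimulatedRead] = []
    for i, frag in enumerate(fragments):
        strand = "+" if rng.random() < 0.5 else "-"
        seq = frag.sequence if strand == "+" else reverse_complement(frag.sequence)
        seq = apply_errors(seq, model, rng)
        reads.append(SimulatedRead(
            read_id=f"read_{i:05d}", sequence=seq, truth_id=frag.truth_id,
            kind=frag.kind, gene=frag.gene, strand=strand,
            promoter_choice=dict(frag.promoter_choice),
        ))
    return LibrarySimulation(reads=reads, truth=truth_table(reads),
                             design=design, decoys=decoys)


def write_fasta(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def write_fastq(reads: Sequence[SimulatedRead], path: str | Path, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality * len(r.sequence)}\n")
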