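"""Local-alignment records: LAST ``-fTAB`` parsing plus a test-scale aligner.

Production users pipe in tabular output from an external aligner run with
``-fTAB``; :func:`naive_align` provides a slow exact-scoring local aligner so
the classifier can be exercised without the external binary.  Coordinates are
0-based half-open throughout; minus-strand query starts are converted to
forward-strand coordinates on parse.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .library_model import ReferenceDatabase
from .seqs import encode, reverse_complement

#: scoring used by the oracle aligner: unit match/mismatch, gap existence 2
#: (open 1 + extend 1), gap extension 1
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, 2, 1


class TabFormatError(ValueError):
    """Malformed LAST TAB input; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment of a read segment to a reference region.

    ``read_start`` is always on the forward strand of the read, regardless of
    ``read_strand``.
    """

    score: int
    ref_name: str
    ref_start: int
    ref_aln_len: int
    read_name: str
    read_start: int
    read_aln_len: int
    read_strand: str
    read_total_len: int
    ref_total_len: int
    blocks: str | None = None

    def __post_init__(self) -> None:
        if self.read_strand not in "+-":
            raise ValueError(f"bad strand {self.read_strand!r}")
        if self.ref_start < 0 or self.read_start < 0:
            raise ValueError("negative alignment start")
        if self.ref_aln_len <= 0 or self.read_aln_len <= 0:
            raise ValueError("non-positive alignment length")
        if self.ref_start + self.ref_aln_len > self.ref_total_len:
            raise ValueError(f"reference overrun for {self.ref_name!r}")
        if self.read_start + self.read_aln_len > self.read_total_len:
            raise ValueError(f"read overrun for {self.read_name!r}")

    @property
    def read_end(self) -> int:
        return self.read_start + self.read_aln_len

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_aln_len


def _open_text(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_alignment_table(source) -> list[AlignmentRecord]:
    """Parse LAST ``-fTAB`` output (path, ``.gz`` path, or open text stream).

    Column order: score, ref name/start/alnlen/strand/seqlen, query
    name/start/alnlen/strand/seqlen, blocks [, extra fields].  ``#`` lines are
    skipped.  Minus-strand query starts (given in reverse-complement
    coordinates) are converted to forward-strand: ``seqlen - start - alnlen``.
    """
    records: list[AlignmentRecord] = []
    fh = _open_text(source)
    try:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 12:
                raise TabFormatError(
                    line_no, f"expected >= 12 whitespace-delimited fields, got {len(fields)}"
                )
            try:
                score = int(fields[0])
                ref_name = fields[1]
                ref_start, ref_len = int(fields[2]), int(fields[3])
                ref_strand = fields[4]
                ref_total = int(fields[5])
                read_name = fields[6]
                read_start, read_len = int(fields[7]), int(fields[8])
                read_strand = fields[9]
                read_total = int(fields[10])
            except ValueError as exc:
                raise TabFormatError(line_no, f"non-numeric coordinate field: {exc}") from None
            if ref_strand not in "+-" or read_strand not in "+-":
                raise TabFormatError(line_no, "strand fields must be '+' or '-'")
            if read_strand == "-":
                read_start = read_total - read_start - read_len
            try:
                records.append(AlignmentRecord(
                    score=score, ref_name=ref_name, ref_start=ref_start,
                    ref_aln_len=ref_len, read_name=read_name, read_start=read_start,
                    read_aln_len=read_len, read_strand=read_strand,
                    read_total_len=read_total, ref_total_len=ref_total,
                    blocks=fields[11],
                ))
            except ValueError as exc:
                raise TabFormatError(line_no, str(exc)) from None
    finally:
        if fh is not source:
            fh.close()
    return records


def serialize_alignment_table(records: Iterable[AlignmentRecord], path=None) -> str:
    """Write records back to the TAB dialect (inverse of the parser)."""
    lines = ["# score name1 start1 alnSize1 strand1 seqSize1 "
             "name2 start2 alnSize2 strand2 seqSize2 blocks"]
    for r in records:
        start2 = r.read_start
        if r.read_strand == "-":
            start2 = r.read_total_len - r.read_start - r.read_aln_len
        lines.append("\t".join(str(x) for x in (
            r.score, r.ref_name, r.ref_start, r.ref_aln_len, "+", r.ref_total_len,
            r.read_name, start2, r.read_aln_len, r.read_strand, r.read_total_len,
            r.blocks if r.blocks is not None else f"{r.read_aln_len}",
        )))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


@njit(cache=True)
def _sw_best_end(a, b):  # pragma: no cover - numba-compiled
    """Best local-alignment score and (exclusive) end coordinates."""
    n, m = a.shape[0], b.shape[0]
    NEG = -(1 << 40)
    h_prev = np.zeros(m + 1, np.int64)
    h_cur = np.zeros(m + 1, np.int64)
    f = np.full(m + 1, NEG, np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        e = NEG
        h_cur[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = 1 if (ai == b[j - 1] and ai < 4) else -1
            fj = h_prev[j] - 2
            if f[j] - 1 > fj:
                fj = f[j] - 1
            f[j] = fj
            ej = h_cur[j - 1] - 2
            if e - 1 > ej:
                ej = e - 1
            e = ej
            h = h_prev[j - 1] + s
            if ej > h:
                h = ej
            if fj > h:
                h = fj
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return best, bi, bj


def _best_local(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int, int, int]:
    """(score, a_start, a_end, b_start, b_end) of the best local alignment."""
    score, ae, be = _sw_best_end(a, b)
    if score <= 0:
        return 0, 0, 0, 0, 0
    score2, ri, rj = _sw_best_end(a[:ae][::-1].copy(), b[:be][::-1].copy())
    return score, ae - ri, ae, be - rj, be


def naive_align(
    read_seq: str,
    db: ReferenceDatabase,
    min_score: int = 50,
    read_name: str = "read",
    max_hits_per_region: int = 4,
) -> list[AlignmentRecord]:
    """Exhaustive local alignment of a read against every region, both strands.

    O(n·m) dynamic programming per region — test-scale only.  Up to
    ``max_hits_per_region`` non-overlapping hits per (region, strand) are
    reported by iterative masking, so repeated parts in one read are all
    found.  Output is sorted by read name then forward-strand read coordinate.
    """
    if not read_seq:
        raise ValueError("empty read")
    total = len(read_seq)
    encoded = {
        "+": encode(read_seq).astype(np.uint8),
        "-": encode(reverse_complement(read_seq)).astype(np.uint8),
    }
    records: list[AlignmentRecord] = []
    for region in db:
        b = encode(region.sequence).astype(np.uint8)
        for strand in "+-":
            a = encoded[strand].copy()
            for _ in range(max_hits_per_region):
                score, a0, a1, b0, b1 = _best_local(a, b)
                if score < min_score:
                    break
                read_start = a0 if strand == "+" else total - a1
                records.append(AlignmentRecord(
                    score=score, ref_name=region.name, ref_start=b0,
                    ref_aln_len=b1 - b0, read_name=read_name, read_start=read_start,
                    read_aln_len=a1 - a0, read_strand=strand,
                    read_total_len=total, ref_total_len=len(region),
                ))
                a[a0:a1] = 4  # mask and re-search
    records.sort(key=lambda r: (r.read_name, r.read_start, -r.score))
    return records


def align_reads(
    reads: Sequence,
    db: ReferenceDatabase,
    min_score: int = 50,
) -> list[AlignmentRecord]:
    """Run :func:`naive_align` over (read_id, sequence) pairs or SimulatedReads."""
    out: list[AlignmentRecord] = []
    for read in reads:
        if hasattr(read, "read_id"):
            name, seq = read.read_id, read.sequence
        else:
            name, seq = read
        out.extend(naive_align(seq, db, min_score=min_score, read_name=name))
    return out
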