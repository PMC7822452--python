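"""Seed-driven progressive assembly.

A deliberately small seed-and-extend assembler: starting from a seed
contig (e.g. a conserved RdRp fragment), each round recruits reads that
overlap a contig end by at least ``min_overlap`` bases with at most
``max_mm`` substitutions (either strand, ungapped), then extends each end
one column at a time by majority vote of the overhanging bases, requiring
``min_depth`` support.  Iteration stops when neither end grows or
``max_rounds`` is reached.  Ties in the vote break toward the
lexicographically smallest base, so the whole procedure is deterministic.

This captures the seed-driven targeted-assembly concept at desk scale;
it is not a production assembler (no indels, no paired ends, no de Bruijn
graph).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .seqcore import NucSequence, reverse_complement
from .srna import ReadRecord

__all__ = ["ReadPlacement", "AssemblyResult", "recruit_reads", "progressive_assemble"]

_K = 10  # seed k-mer length for overlap candidate discovery


@dataclass(frozen=True)
class ReadPlacement:
    """An ungapped placement of a read against the contig.

    ``offset`` is the contig coordinate of the read's first oriented base
    and may be negative (read overhangs the left end) or extend past the
    contig (right overhang).  ``overlap`` is the number of bases shared
    with the contig; ``mismatches`` are counted inside the overlap only.
    """

    read_id: str
    oriented: str
    offset: int
    strand: str
    overlap: int
    mismatches: int


@dataclass
class AssemblyResult:
    contig: NucSequence
    rounds: int
    extensions: list = field(default_factory=list)  # (left_nt, right_nt) per round
    reads_used: int = 0
    seed_id: str = ""

    @property
    def total_extension(self) -> tuple:
        return (sum(l for l, _ in self.extensions), sum(r for _, r in self.extensions))


def _placements_for(contig: str, index: dict, oriented: str, min_overlap: int, max_mm: int):
    """Candidate placements of one oriented read via exact k-mer seeding.

    Any valid placement (overlap >= min_overlap, mismatches <= max_mm)
    contains an exact stretch of length >= ceil((min_overlap - max_mm) /
    (max_mm + 1)) inside the overlap; with the defaults that is >= 9, so
    scanning every read k-mer (k=10 <= that bound only when mismatches are
    spread out; we scan all offsets, which is exhaustive for k <= the
    longest guaranteed exact run) finds it.
    """
    n, L = len(oriented), len(contig)
    seen = set()
    for off in range(0, n - _K + 1):
        for pos in index.get(oriented[off : off + _K], ()):
            start = pos - off
            if start in seen:
                continue
            seen.add(start)
            lo = max(0, start)
            hi = min(L, start + n)
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            mm = 0
            ok = True
            for i in range(lo, hi):
                if contig[i] != oriented[i - start]:
                    mm += 1
                    if mm > max_mm:
                        ok = False
                        break
            if ok:
                yield start, overlap, mm


def recruit_reads(
    contig: NucSequence,
    reads: Sequence[ReadRecord],
    min_overlap: int = 20,
    max_mm: int = 1,
) -> list:
    """Reads with an ungapped overlap of >= min_overlap and <= max_mm
    substitutions against the contig, either strand.

    Fully interior reads are recruited too (they support the consensus
    without extending it).  Each read is reported once with its best
    placement (fewest mismatches, then longest overlap, then lowest
    offset, '+' before '-').
    """
    if min_overlap < 15:
        raise ValueError("min_overlap must be >= 15")
    c = contig.residues
    index: dict = {}
    for i in range(len(c) - _K + 1):
        index.setdefault(c[i : i + _K], []).append(i)
    out = []
    for r in reads:
        best = None
        for strand in ("+", "-"):
            oriented = r.sequence if strand == "+" else reverse_complement(r.sequence)
            for start, overlap, mm in _placements_for(c, index, oriented, min_overlap, max_mm):
                key = (mm, -overlap, start, strand)
                if best is None or key < best[0]:
                    best = (key, ReadPlacement(r.id, oriented, start, strand, overlap, mm))
        if best is not None:
            out.append(best[1])
    return out


def _extend_right(contig: str, placements: list, min_depth: int) -> str:
    L = len(contig)
    votes: dict = {}
    for p in placements:
        end = p.offset + len(p.oriented)
        for col in range(max(L, p.offset), end):
            votes.setdefault(col - L, Counter())[p.oriented[col - p.offset]] += 1
    ext = []
    col = 0
    while col in votes and sum(votes[col].values()) >= min_depth:
        # majority base; ties break lexicographically
        best = min(votes[col].items(), key=lambda kv: (-kv[1], kv[0]))
        ext.append(best[0])
        col += 1
    return "".join(ext)


def progressive_assemble(
    seed: NucSequence,
    reads: Sequence[ReadRecord],
    min_overlap: int = 20,
    max_mm: int = 1,
    min_depth: int = 2,
    max_rounds: int = 100,
) -> AssemblyResult:
    """Iterative seed extension until neither end grows.

    A round with no recruiting reads (including round 1) simply stops with
    the contig as-is; that is a valid outcome, not an error.
    """
    if len(seed) < min_overlap:
        raise ValueError("seed shorter than min_overlap")
    contig = seed.residues
    result = AssemblyResult(seed, 0, seed_id=seed.id)
    used: set = set()
    for _ in range(max_rounds):
        cur = NucSequence(seed.id, contig)
        placements = recruit_reads(cur, reads, min_overlap, max_mm)
        if not placements:
            break
        used.update(p.read_id for p in placements)
        right = _extend_right(contig, [p for p in placements
                                       if p.offset + len(p.oriented) > len(contig)], min_depth)
        # left extension = right extension of the reverse complement
        rc = reverse_complement(contig)
        rc_pl = [
            ReadPlacement(p.read_id, reverse_complement(p.oriented),
                          len(contig) - (p.offset + len(p.oriented)),
                          p.strand, p.overlap, p.mismatches)
            for p in placements
            if p.offset < 0
        ]
        left = reverse_complement(_extend_right(rc, rc_pl, min_depth))
        if not left and not right:
            break
        contig = left + contig + right
        result.rounds += 1
        result.extensions.append((len(left), len(right)))
    result.contig = NucSequence(f"{seed.id}_assembled", contig)
    result.reads_used = len(used)
    return result
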