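"""Nucleotide sequences, genetic codes, translation, ORF discovery.

The central objects are :class:`NucSequence` (a linear DNA/RNA sequence,
U normalized to T on ingest) and :class:`GeneticCode` (an NCBI translation
table restricted to the ones relevant for mitochondria and their viruses:
1 standard, 4 mold/protozoan mitochondrial, 5 invertebrate mitochondrial,
16 chlorophycean mitochondrial).  Tables 4, 5 and 16 read TGA as
tryptophan, which is what lets a mitovirus hide a long RdRp gene that the
standard code shatters into short ORFs.

Coordinates are 0-based half-open on the plus strand throughout; GenBank
1-based inclusive coordinates are converted at the I/O boundary by
Biopython.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError

__all__ = [
    "NucSequence",
    "GeneticCode",
    "OrfRecord",
    "CdsRecord",
    "CdsSet",
    "translate",
    "find_orfs",
    "extract_cds",
    "base_composition",
    "ambigram_scan",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_genbank",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Strand = Literal["+", "-"]


def reverse_complement(residues: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucSequence:
    """A linear nucleotide sequence.

    ``residues`` is uppercased and U is normalized to T on construction, so
    RNA virus genomes and DNA records share one representation.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("U", "T")
        bad = set(norm) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid residues in {self.id!r}: {sorted(bad)}")
        if not norm:
            raise EmptyInputError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self, new_id: str | None = None) -> "NucSequence":
        return NucSequence(new_id or f"{self.id}_rc", reverse_complement(self.residues))

    def __getitem__(self, sl) -> str:
        return self.residues[sl]


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table over DNA codons.

    ``codon_to_aa`` maps all 64 codons to one-letter amino acids with stops
    rendered as '*'.
    """

    table_id: int
    codon_to_aa: dict
    stop_codons: frozenset

    SUPPORTED = (1, 4, 5, 16)

    @classmethod
    def from_table_id(cls, table_id: int) -> "GeneticCode":
        if table_id not in cls.SUPPORTED:
            raise ValueError(
                f"genetic code table {table_id} unsupported (use one of {cls.SUPPORTED})"
            )
        tbl = unambiguous_dna_by_id[table_id]
        mapping = dict(tbl.forward_table)
        for stop in tbl.stop_codons:
            mapping[stop] = "*"
        assert len(mapping) == 64
        return cls(table_id, mapping, frozenset(tbl.stop_codons))

    def translate_codon(self, codon: str) -> str:
        aa = self.codon_to_aa.get(codon)
        return aa if aa is not None else "X"

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def synonymous_codons(self, aa: str) -> list:
        return sorted(c for c, a in self.codon_to_aa.items() if a == aa)


@dataclass(frozen=True)
class OrfRecord:
    """A maximal open reading frame.

    ``start``/``end`` are 0-based half-open on the plus strand and include
    the closing stop codon when one is present (``closed`` is True).
    ``frame`` is the reading frame on the ORF's own strand.  ``aa_length``
    counts coding codons only, so a closed ORF of span L has
    aa_length = L/3 - 1.
    """

    start: int
    end: int
    strand: Strand
    frame: int
    aa_length: int
    protein: str
    closed: bool = True

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF span must be divisible by 3")


@dataclass(frozen=True)
class CdsRecord:
    """One in-frame coding sequence with its genetic-code context."""

    source_id: str
    cds: str
    code_id: int = 1

    def __post_init__(self) -> None:
        if len(self.cds) % 3:
            raise ValueError(f"CDS {self.source_id!r} length not divisible by 3")

    def codons(self) -> list:
        return [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]


@dataclass
class CdsSet:
    """A collection of coding sequences (possibly from several records)."""

    records: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def require_nonempty(self) -> None:
        if not self.records:
            raise EmptyInputError("empty CdsSet")


def translate(
    seq: NucSequence | str,
    code: GeneticCode,
    frame: int = 0,
    strand: Strand = "+",
) -> str:
    """Translate one reading frame into protein, stops as '*'.

    Codons containing a base outside {A,C,G,T} translate to 'X'; a trailing
    partial codon is ignored.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    residues = seq.residues if isinstance(seq, NucSequence) else seq
    if strand == "-":
        residues = reverse_complement(residues)
    residues = residues[frame:]
    if len(residues) < 3:
        raise ValueError("sequence shorter than one codon in this frame")
    return "".join(
        code.translate_codon(residues[i : i + 3])
        for i in range(0, len(residues) - len(residues) % 3, 3)
    )


def _frame_orfs(
    working: str,
    frame: int,
    code: GeneticCode,
    start_policy: str,
) -> Iterable[tuple[int, int, bool]]:
    """Maximal ORFs as (w_start, w_end, closed) on the working strand.

    A maximal ORF runs from the first permissible start codon after the
    previous stop to the next stop (inclusive).  ``any_sense_codon`` treats
    the whole stop-to-stop segment as the ORF.
    """
    n = len(working)
    seg_start = frame  # first codon index of the current stop-free segment
    first_atg: int | None = None
    i = frame
    while i + 3 <= n:
        codon = working[i : i + 3]
        if code.is_stop(codon):
            begin = seg_start if start_policy == "any_sense_codon" else first_atg
            if begin is not None and i > begin:
                yield begin, i + 3, True
            seg_start = i + 3
            first_atg = None
        elif codon == "ATG" and first_atg is None:
            first_atg = i
        i += 3
    begin = seg_start if start_policy == "any_sense_codon" else first_atg
    if begin is not None and i > begin:
        yield begin, i, False  # runs off the end, no closing stop


def find_orfs(
    seq: NucSequence,
    code: GeneticCode,
    min_codons: int = 1,
    start_policy: str = "ATG_only",
) -> list:
    """All maximal ORFs on both strands and all six frames.

    Returns :class:`OrfRecord` objects sorted by decreasing amino-acid
    length, then by plus-strand coordinate, then strand.  With the default
    ``ATG_only`` policy an ORF starts at the first ATG of its stop-free
    segment; ``any_sense_codon`` returns full stop-to-stop segments (useful
    for ambigram scans where the reverse gene need not start with ATG).
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    if start_policy not in ("ATG_only", "any_sense_codon"):
        raise ValueError(f"unknown start_policy {start_policy!r}")
    n = len(seq)
    out: list[OrfRecord] = []
    for strand in ("+", "-"):
        working = seq.residues if strand == "+" else reverse_complement(seq.residues)
        for frame in range(3):
            for w_start, w_end, closed in _frame_orfs(working, frame, code, start_policy):
                n_codons = (w_end - w_start) // 3 - (1 if closed else 0)
                if n_codons < min_codons:
                    continue
                prot = "".join(
                    code.translate_codon(working[i : i + 3])
                    for i in range(w_start, w_start + 3 * n_codons, 3)
                )
                if strand == "+":
                    start, end = w_start, w_end
                else:
                    start, end = n - w_end, n - w_start
                out.append(
                    OrfRecord(start, end, strand, frame, n_codons, prot, closed)
                )
    out.sort(key=lambda o: (-o.aa_length, o.start, o.strand, o.frame))
    return out


def extract_cds(record: SeqRecord) -> CdsSet:
    """Extract spliced, strand-corrected coding sequences from a GenBank record.

    Honors the ``transl_table`` qualifier when present (default table 1).
    A CDS whose length is not divisible by 3 triggers a warning and is
    truncated to the last complete codon.
    """
    cds_feats = [f for f in record.features if f.type == "CDS"]
    if not cds_feats:
        raise EmptyInputError(f"record {record.id!r} has no CDS features")
    out = CdsSet()
    for idx, feat in enumerate(cds_feats):
        nt = str(feat.extract(record.seq)).upper().replace("U", "T")
        code_id = int(feat.qualifiers.get("transl_table", [1])[0])
        if len(nt) % 3:
            warnings.warn(
                f"CDS {idx} of {record.id!r} length {len(nt)} not divisible by 3; "
                "truncating trailing bases",
                stacklevel=2,
            )
            nt = nt[: len(nt) - len(nt) % 3]
        label = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", [f"{record.id}_cds{idx}"]))[0]
        out.records.append(CdsRecord(label, nt, code_id))
    return out


def base_composition(seq: NucSequence | str) -> dict:
    """AT%, GC% and per-base fractions; N excluded from the denominator."""
    residues = seq.residues if isinstance(seq, NucSequence) else seq
    counts = {b: residues.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise EmptyInputError("sequence contains no unambiguous bases")
    frac = {b: counts[b] / total for b in "ACGT"}
    return {
        "AT_percent": 100.0 * (frac["A"] + frac["T"]),
        "GC_percent": 100.0 * (frac["G"] + frac["C"]),
        "fractions": frac,
        "length_effective": total,
    }


def ambigram_scan(seq: NucSequence, fwd_orf: OrfRecord, code: GeneticCode) -> dict:
    """Scan for an ambisense (reverse-frame) ORF and stop-shadow avoidance.

    Some capsidless RNA viruses keep a second long ORF on the reverse
    complement of the RdRp gene; doing so requires avoiding CTA, TTA and TCA
    in the forward CDS because these are the reverse complements of the
    stop codons.  Returns the longest reverse-strand ORF overlapping the
    forward one (``None`` if there is none) plus the observed/expected
    ratio of the three avoided codons, with the expectation from the CDS
    mononucleotide composition.
    """
    if not (0 <= fwd_orf.start < fwd_orf.end <= len(seq)):
        raise ValueError("fwd_orf lies outside the sequence")
    rev = [
        o
        for o in find_orfs(seq, code, min_codons=1, start_policy="any_sense_codon")
        if o.strand == "-" and o.start < fwd_orf.end and o.end > fwd_orf.start
    ]
    reverse_orf = max(rev, key=lambda o: o.aa_length) if rev else None

    cds = seq.residues[fwd_orf.start : fwd_orf.end]
    if fwd_orf.closed:
        cds = cds[:-3]
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    comp = base_composition(cds)["fractions"]
    avoided = ("CTA", "TTA", "TCA")
    observed = sum(codons.count(c) for c in avoided)
    expected = len(codons) * sum(comp[c[0]] * comp[c[1]] * comp[c[2]] for c in avoided)
    ratio = observed / expected if expected > 0 else float("nan")
    return {
        "reverse_orf": reverse_orf,
        "avoided_codon_observed": observed,
        "avoided_codon_expected": expected,
        "avoided_codon_stat": ratio,
    }


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> list:
    return [NucSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[NucSequence], path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_genbank(path) -> list:
    return list(SeqIO.parse(str(path), "genbank"))
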