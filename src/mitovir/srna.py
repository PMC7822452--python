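"""Virus-derived small-RNA analysis.

Strand-resolved size profiling of small RNAs mapped to a candidate viral
genome, with Z-score normalization, 5' base enrichment statistics,
coverage tracks, ECDF/Kolmogorov–Smirnov comparison of size
distributions, correlation clustering of profiles, and a rule-based
classifier for the canonical antiviral small-RNA signatures:

* insect siRNA: symmetric ~21-nt peak on both strands, no 5' base bias —
  the footprint of Dicer-2 dicing viral dsRNA replication intermediates;
* fungal siRNA: 20–22-nt symmetric peak with a 5' uracil preference;
* piRNA: 24–30-nt reads with 5'-U bias and strand asymmetry.

Reads are mapped ungapped and end-to-end with at most ``max_mm``
substitutions (Bowtie-v1-like semantics); multi-mapping reads are placed
once, deterministically, at the lowest coordinate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import composition
from .errors import EmptyInputError
from .seqcore import NucSequence, reverse_complement

__all__ = [
    "SIZE_MIN",
    "SIZE_MAX",
    "ReadRecord",
    "Alignment",
    "AlignmentSet",
    "SizeProfile",
    "FivePrimeEnrichment",
    "CoverageTrack",
    "EcdfComparison",
    "ClassifyConfig",
    "read_fastq",
    "write_fastq",
    "filter_reads",
    "map_reads",
    "size_profile",
    "five_prime_enrichment",
    "coverage_track",
    "ecdf_ks_compare",
    "classify_signature",
    "profile_cluster",
]

SIZE_MIN = 15
SIZE_MAX = 35
SIZES = tuple(range(SIZE_MIN, SIZE_MAX + 1))
STRANDS = ("+", "-")


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    qualities: tuple  # integer Phred scores, one per base

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Alignment:
    read_id: str
    start: int  # 0-based on the reference plus strand
    length: int
    strand: str
    mismatches: int


@dataclass
class AlignmentSet:
    reference_id: str
    reference_length: int
    alignments: list = field(default_factory=list)
    n_reads_input: int = 0

    def __len__(self) -> int:
        return len(self.alignments)

    def __iter__(self):
        return iter(self.alignments)


def read_fastq(path) -> list:
    """Parse a Phred+33 FASTQ file into ReadRecords.

    Malformed records raise with the 0-based record index for diagnosis.
    """
    reads = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 and any(lines[len(lines) - len(lines) % 4 :]):
        raise ValueError(f"truncated FASTQ record at index {len(lines) // 4}")
    for idx in range(len(lines) // 4):
        head, seq, plus, qual = lines[4 * idx : 4 * idx + 4]
        if not head.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record at index {idx}")
        reads.append(ReadRecord(head[1:].split()[0], seq.upper().replace("U", "T"),
                                tuple(ord(c) - 33 for c in qual)))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.qualities) + "\n")


def filter_reads(
    reads: Iterable[ReadRecord],
    min_len: int = 20,
    q_thresh: int = 20,
    min_good_frac: float = 0.80,
) -> list:
    """Quality filter: keep reads of length >= min_len whose fraction of
    bases at Phred >= q_thresh is at least min_good_frac."""
    kept = []
    for r in reads:
        if len(r) < min_len:
            continue
        good = sum(1 for q in r.qualities if q >= q_thresh)
        if good / len(r) >= min_good_frac:
            kept.append(r)
    return kept


class _RefIndex:
    """Pigeonhole k-mer index over the reference plus strand.

    For ungapped end-to-end alignment with at most ``max_mm``
    substitutions, a read split into ``max_mm + 1`` contiguous blocks has
    at least one block mismatch-free, so seeding with the first k bases of
    each block finds every valid placement.
    """

    K = 7

    def __init__(self, ref: NucSequence):
        self.residues = ref.residues
        self.index: dict = {}
        for i in range(len(self.residues) - self.K + 1):
            self.index.setdefault(self.residues[i : i + self.K], []).append(i)

    def placements(self, oriented: str, max_mm: int) -> list:
        """All (start, mismatches) end-to-end placements of ``oriented``."""
        n, L = len(oriented), len(self.residues)
        if n < self.K or n > L:
            return []
        parts = max_mm + 1
        block = n // parts
        if block < self.K:
            parts, block = 1, n  # short read: fall back to exact seeding only
        seen: set = set()
        out = []
        for b in range(parts):
            off = b * block
            for pos in self.index.get(oriented[off : off + self.K], ()):
                start = pos - off
                if start < 0 or start + n > L or start in seen:
                    continue
                seen.add(start)
                mm = 0
                window = self.residues[start : start + n]
                for x, y in zip(oriented, window):
                    if x != y:
                        mm += 1
                        if mm > max_mm:
                            break
                if mm <= max_mm:
                    out.append((start, mm))
        return out


def map_reads(
    reads: Sequence[ReadRecord],
    ref: NucSequence,
    max_mm: int = 1,
) -> AlignmentSet:
    """Ungapped end-to-end mapping of reads to both strands of ``ref``.

    Each read gets at most one placement: among placements with the fewest
    mismatches, the one with the lowest (start, strand) wins, '+' ordered
    before '-'.  Deterministic; identical read sequences share one cached
    placement.
    """
    idx = _RefIndex(ref)
    cache: dict = {}
    aln = AlignmentSet(ref.id, len(ref), n_reads_input=len(reads))
    for r in reads:
        key = r.sequence
        if key not in cache:
            cands = [(mm, start, "+") for start, mm in idx.placements(key, max_mm)]
            cands += [
                (mm, start, "-")
                for start, mm in idx.placements(reverse_complement(key), max_mm)
            ]
            cache[key] = min(cands, default=None)
        best = cache[key]
        if best is not None:
            mm, start, strand = best
            aln.alignments.append(Alignment(r.id, start, len(key), strand, mm))
    return aln


@dataclass
class SizeProfile:
    """Per-strand read-size frequency spectrum over 15–35 nt.

    ``freq`` has shape (21 sizes, 2 strands) and sums to 1 over all 42
    cells for non-empty input.  ``zscores`` standardizes the 42 cells
    jointly; a zero-variance spectrum is all-zero by convention.
    """

    reference_id: str
    counts: np.ndarray  # (n_sizes, 2) ints
    freq: np.ndarray
    zscores: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def strand_counts(self) -> dict:
        return {"+": int(self.counts[:, 0].sum()), "-": int(self.counts[:, 1].sum())}

    def zscore_vector(self) -> np.ndarray:
        return self.zscores.ravel()

    def size_counts(self) -> np.ndarray:
        """Counts per size summed over strands (for ECDF comparison)."""
        return self.counts.sum(axis=1)

    def modal_size(self, strand: str | None = None) -> int | None:
        col = self.counts.sum(axis=1) if strand is None else self.counts[:, STRANDS.index(strand)]
        if col.sum() == 0:
            return None
        return SIZE_MIN + int(np.argmax(col))  # ties -> smallest size


def size_profile(aln: AlignmentSet) -> SizeProfile:
    counts = np.zeros((len(SIZES), 2), dtype=int)
    for a in aln:
        if SIZE_MIN <= a.length <= SIZE_MAX:
            counts[a.length - SIZE_MIN, STRANDS.index(a.strand)] += 1
    total = counts.sum()
    freq = counts / total if total else counts.astype(float)
    sd = freq.std()
    z = (freq - freq.mean()) / sd if sd > 0 else np.zeros_like(freq)
    return SizeProfile(aln.reference_id, counts, freq, z)


@dataclass(frozen=True)
class EnrichmentCell:
    size: int
    strand: str
    n: int
    base_counts: dict
    expected_frac: dict
    p_adjusted: dict  # Bonferroni within the cell (x4)
    enriched: dict  # base -> bool (adjusted p < alpha AND observed > expected)
    tested: bool


@dataclass
class FivePrimeEnrichment:
    cells: list
    alpha: float
    min_reads: int

    def cell(self, size: int, strand: str) -> EnrichmentCell | None:
        for c in self.cells:
            if c.size == size and c.strand == strand:
                return c
        return None

    def enriched_bases(self, size: int, strand: str) -> list:
        c = self.cell(size, strand)
        if c is None or not c.tested:
            return []
        return [b for b, flag in c.enriched.items() if flag]


def five_prime_enrichment(
    aln: AlignmentSet,
    ref: NucSequence,
    min_reads: int = 20,
    alpha: float = 0.05,
) -> FivePrimeEnrichment:
    """Per-(size, strand) 5' base enrichment against reference composition.

    For every cell with at least ``min_reads`` reads, each of the four
    bases gets a two-sided exact binomial test of its 5' count against the
    expected fraction — the base composition of the read-bearing strand of
    the reference — Bonferroni-corrected by 4 within the cell.  A base is
    flagged enriched when the adjusted p is below ``alpha`` and the
    observed fraction exceeds the expectation.  Cells below ``min_reads``
    are reported untested.
    """
    if len(aln) == 0:
        raise EmptyInputError("no alignments")
    comp_plus = Counter(ref.residues.replace("N", ""))
    tot = sum(comp_plus.values())
    exp = {
        "+": {b: comp_plus[b] / tot for b in "ACGT"},
        "-": {b: comp_plus[{"A": "T", "C": "G", "G": "C", "T": "A"}[b]] / tot for b in "ACGT"},
    }
    five_prime: dict = {}
    for a in aln:
        if not (SIZE_MIN <= a.length <= SIZE_MAX):
            continue
        base = (
            ref.residues[a.start]
            if a.strand == "+"
            else reverse_complement(ref.residues[a.start + a.length - 1])
        )
        five_prime.setdefault((a.length, a.strand), []).append(base)
    cells = []
    for (size, strand), bases in sorted(five_prime.items()):
        counts = Counter(b for b in bases if b in "ACGT")
        n = sum(counts.values())
        tested = n >= min_reads
        p_adj: dict = {}
        flags: dict = {}
        for b in "ACGT":
            if tested:
                p = stats.binomtest(counts[b], n, exp[strand][b]).pvalue
                p_adj[b] = min(1.0, 4 * p)
                flags[b] = p_adj[b] < alpha and counts[b] / n > exp[strand][b]
            else:
                p_adj[b] = float("nan")
                flags[b] = False
        cells.append(
            EnrichmentCell(size, strand, n, {b: counts[b] for b in "ACGT"},
                           exp[strand], p_adj, flags, tested)
        )
    return FivePrimeEnrichment(cells, alpha, min_reads)


@dataclass
class CoverageTrack:
    reference_id: str
    depth_plus: np.ndarray
    depth_minus: np.ndarray

    def covered_fraction(self) -> float:
        return float(np.mean((self.depth_plus + self.depth_minus) > 0))

    def strand_depth_ratio(self) -> float:
        minus = self.depth_minus.sum()
        return float(self.depth_plus.sum() / minus) if minus else float("inf")

    def to_bedgraph(self, path, strand: str = "+") -> None:
        depth = self.depth_plus if strand == "+" else self.depth_minus
        with open(path, "w") as fh:
            start = 0
            for i in range(1, len(depth) + 1):
                if i == len(depth) or depth[i] != depth[start]:
                    if depth[start]:
                        fh.write(f"{self.reference_id}\t{start}\t{i}\t{int(depth[start])}\n")
                    start = i


def coverage_track(aln: AlignmentSet, ref: NucSequence) -> CoverageTrack:
    """Full read-footprint depth per reference position and strand."""
    plus = np.zeros(len(ref), dtype=np.int64)
    minus = np.zeros(len(ref), dtype=np.int64)
    for a in aln:
        tgt = plus if a.strand == "+" else minus
        tgt[a.start : a.start + a.length] += 1
    return CoverageTrack(ref.id, plus, minus)


@dataclass(frozen=True)
class EcdfComparison:
    d: float
    pvalue: float
    n_a: int
    n_b: int
    method: str


def _size_counts(sample) -> np.ndarray:
    """Coerce a SizeProfile or an array of raw read sizes to a
    counts-per-size vector over 15..35 (out-of-range sizes clipped)."""
    if isinstance(sample, SizeProfile):
        return sample.size_counts().astype(np.int64)
    arr = np.asarray(sample, dtype=int)
    if arr.ndim != 1:
        raise ValueError("size sample must be 1-D")
    if arr.size == 0:
        return np.zeros(len(SIZES), dtype=np.int64)
    sizes = np.clip(arr, SIZE_MIN, SIZE_MAX)
    return np.bincount(sizes - SIZE_MIN, minlength=len(SIZES)).astype(np.int64)


def ecdf_ks_compare(
    profile_a,
    profile_b,
    method: str = "permutation",
    n_permutations: int = 999,
    seed: int | None = None,
) -> EcdfComparison:
    """Two-sample Kolmogorov–Smirnov comparison of read-size distributions.

    Inputs are SizeProfiles or arrays of read sizes.  The KS statistic D
    is the maximum ECDF gap.  Because read sizes are small integers the
    classical asymptotic null (which assumes continuity) is conservative,
    so the default p-value is a permutation test: sample-A counts are
    redrawn per size bin from the pooled counts (multivariate
    hypergeometric), which is exact up to Monte-Carlo error under the null
    of identical size distributions.  ``method="asymp"`` gives the
    classical asymptotic p for comparison with continuous-theory tools.
    """
    ca, cb = _size_counts(profile_a), _size_counts(profile_b)
    na, nb = int(ca.sum()), int(cb.sum())
    if na == 0 or nb == 0:
        raise EmptyInputError("both size samples must be non-empty")
    d = float(np.abs(np.cumsum(ca) / na - np.cumsum(cb) / nb).max())
    if method == "asymp":
        en = na * nb / (na + nb)
        p = float(np.clip(stats.distributions.kstwobign.sf(np.sqrt(en) * d), 0.0, 1.0))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_hypergeometric(ca + cb, na, size=n_permutations)
        cdf_a = np.cumsum(draws, axis=1) / na
        cdf_b = np.cumsum((ca + cb) - draws, axis=1) / nb
        d_perm = np.abs(cdf_a - cdf_b).max(axis=1)
        p = float((1 + np.sum(d_perm >= d - 1e-12)) / (1 + n_permutations))
    else:
        raise ValueError(f"unknown method {method!r}")
    return EcdfComparison(d, p, na, nb, method)


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds for the rule-based signature classifier.

    ``u_frac_min`` demands that a 5'-U call reflect a strong preference
    (a majority of reads), not a marginally significant tilt; both the
    binomial flag and this fraction must hold.
    """

    insect_band: tuple = (19, 23)
    fungal_band: tuple = (20, 22)
    pi_band: tuple = (24, 30)
    symmetric_ratio: tuple = (1 / 3, 3.0)
    min_peak_frac: float = 0.10
    u_frac_min: float = 0.50


def _u_preference(enr: FivePrimeEnrichment, size: int, strand: str, cfg: ClassifyConfig) -> bool:
    cell = enr.cell(size, strand)
    if cell is None or not cell.tested:
        return False
    frac = cell.base_counts["T"] / cell.n if cell.n else 0.0
    return cell.enriched["T"] and frac >= cfg.u_frac_min


def classify_signature(
    profile: SizeProfile,
    enr: FivePrimeEnrichment,
    config: ClassifyConfig | None = None,
) -> str:
    """Call the small-RNA signature class of one reference.

    Returns one of ``siRNA_insect_like``, ``fungal_siRNA_like``,
    ``piRNA_like`` or ``none``.  Rules (defaults in ClassifyConfig):

    * piRNA_like — pooled modal size 24–30 with a clear peak, 5'-U
      preference on the dominant strand, and strand asymmetry (+/− read
      ratio outside [1/3, 3]).
    * fungal_siRNA_like — modal size 20–22 on both strands, near-symmetric
      strands, 5'-U preference in a modal cell.
    * siRNA_insect_like — modal size 19–23 on both strands, near-symmetric
      strands, and no 5' base preference.
    """
    cfg = config or ClassifyConfig()
    if profile.total == 0:
        raise EmptyInputError("empty size profile")
    sc = profile.strand_counts()
    n_plus, n_minus = sc["+"], sc["-"]
    ratio = n_plus / n_minus if n_minus else float("inf")
    symmetric = n_plus > 0 and n_minus > 0 and cfg.symmetric_ratio[0] <= ratio <= cfg.symmetric_ratio[1]

    pooled_mode = profile.modal_size()
    pooled_peak = profile.size_counts().max() / profile.total

    def strand_peak_ok(strand: str, band: tuple) -> bool:
        mode = profile.modal_size(strand)
        if mode is None or not band[0] <= mode <= band[1]:
            return False
        col = profile.counts[:, STRANDS.index(strand)]
        return col.max() / col.sum() >= cfg.min_peak_frac

    dominant = "+" if n_plus >= n_minus else "-"
    u_modal = any(
        _u_preference(enr, profile.modal_size(s), s, cfg)
        for s in STRANDS
        if profile.modal_size(s) is not None
    )

    if (
        pooled_mode is not None
        and cfg.pi_band[0] <= pooled_mode <= cfg.pi_band[1]
        and pooled_peak >= cfg.min_peak_frac
        and not symmetric
        and _u_preference(enr, profile.modal_size(dominant), dominant, cfg)
    ):
        return "piRNA_like"
    if (
        symmetric
        and strand_peak_ok("+", cfg.fungal_band)
        and strand_peak_ok("-", cfg.fungal_band)
        and u_modal
    ):
        return "fungal_siRNA_like"
    if (
        symmetric
        and strand_peak_ok("+", cfg.insect_band)
        and strand_peak_ok("-", cfg.insect_band)
        and not u_modal
    ):
        return "siRNA_insect_like"
    return "none"


def profile_cluster(profiles: Sequence[SizeProfile], threshold: float = 0.8):
    """Cluster size profiles by Pearson correlation of their Z-score
    vectors (delegates to composition.cluster_by_correlation)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    corr = composition.profile_correlation(
        [(p.reference_id, p.zscore_vector()) for p in profiles]
    )
    return composition.cluster_by_correlation(corr, threshold)
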