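"""Synthetic inputs with known ground truth.

Every downstream stage of the pipeline is exercised against data from
this module: mitovirus-like genomes (one long RdRp-style ORF under a
chosen genetic code, tunable AT content and UGA(Trp) fraction), coding
sequences drawn from explicit codon-probability tables, small-RNA read
sets with controlled size/strand/5'-base structure, long reads tiling a
genome for assembly, and DNA libraries with or without an integrated
viral copy.

Generators are pure functions of (parameters, seed) and re-measure what
they emit: the returned :class:`SyntheticTruth` is recounted from the
actual sequence, never assumed.  Infeasible constraint combinations
raise :class:`~mitovir.errors.InfeasibleParameterError` rather than
drifting silently.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np

from .composition import CODONS
from .errors import EmptyInputError, InfeasibleParameterError
from .seqcore import (
    CdsRecord,
    CdsSet,
    GeneticCode,
    NucSequence,
    base_composition,
    find_orfs,
    reverse_complement,
)
from .srna import ReadRecord

__all__ = [
    "SyntheticTruth",
    "SRNA_PRESETS",
    "MITOVIRUS_PRESET",
    "gen_viral_genome",
    "gen_cds_set",
    "gen_codon_table_family",
    "gen_srna_reads",
    "gen_long_reads",
    "gen_dna_library",
    "write_truth_tsv",
]

# Average globular-protein amino-acid composition; Trp ~1.3% so an
# 800-codon ORF carries enough Trp codons to realize a UGA fraction with
# a few percentage points of granularity.
DEFAULT_AA_FREQS = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.053, "C": 0.014,
    "Q": 0.040, "E": 0.063, "G": 0.072, "H": 0.022, "I": 0.055,
    "L": 0.091, "K": 0.059, "M": 0.022, "F": 0.040, "P": 0.050,
    "S": 0.068, "T": 0.059, "W": 0.013, "Y": 0.032, "V": 0.067,
}

# Small-RNA signature presets. Strand ratio 0.5 for siRNA-like classes
# reflects symmetric dicing of dsRNA replication intermediates; the piRNA
# preset is strand-asymmetric with a strong 5'-U preference.
SRNA_PRESETS = {
    "siRNA_insect": dict(peak_size=21, size_sd=1.6, strand_ratio=0.5, five_prime_bias=None),
    "fungal_siRNA": dict(peak_size=21, size_sd=1.2, strand_ratio=0.5, five_prime_bias=("T", 0.85)),
    "piRNA": dict(peak_size=27, size_sd=1.8, strand_ratio=0.85, five_prime_bias=("T", 0.9)),
}

# An insect-mitovirus-like genome: 804-codon ORF read with the
# invertebrate mitochondrial code, 69.74% AT, 73.3% UGA(Trp), 2697 nt.
MITOVIRUS_PRESET = dict(
    orf_codons=804, code_id=5, at_target=69.74, trp_uga_frac=73.3, genome_length=2697
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recounted from an emitted synthetic genome."""

    genome_length: int
    at_content: float  # percent, measured on the emitted sequence
    code_id: int
    orf_span: tuple  # 0-based half-open, + strand, includes the stop codon
    trp_uga_fraction: float | None  # percent of Trp codons that are TGA
    signature_class: str
    rng_seed: int

    def __post_init__(self) -> None:
        if (self.orf_span[1] - self.orf_span[0]) % 3:
            raise ValueError("orf_span length must be divisible by 3")
        if not 0 <= self.at_content <= 100:
            raise ValueError("at_content must be a percentage")


def _attempt_genome(
    rng: np.random.Generator,
    orf_codons: int,
    code: GeneticCode,
    at_target: float,
    trp_uga_frac: float,
    genome_length: int,
) -> tuple | None:
    orf_nt = 3 * (orf_codons + 1)
    left = max(3, (genome_length - orf_nt) // 2)
    right = genome_length - orf_nt - left

    aa_list = sorted(DEFAULT_AA_FREQS)
    probs = np.array([DEFAULT_AA_FREQS[a] for a in aa_list])
    probs /= probs.sum()
    aas = ["M"] + list(rng.choice(aa_list, size=orf_codons - 1, p=probs))

    trp_idx = [i for i, a in enumerate(aas) if a == "W"]
    if not trp_idx and trp_uga_frac > 0:
        return None  # redraw: no Trp codon to carry the requested fraction
    n_uga = round(trp_uga_frac / 100.0 * len(trp_idx)) if trp_idx else 0
    shuffled = list(trp_idx)
    rng.shuffle(shuffled)
    uga_positions = set(shuffled[:n_uga])

    codons = []
    for i, aa in enumerate(aas):
        if i == 0:
            codons.append("ATG")
        elif aa == "W":
            codons.append("TGA" if i in uga_positions else "TGG")
        else:
            syn = code.synonymous_codons(aa)
            codons.append(syn[rng.integers(len(syn))])
    codons.append("TAA")  # closing stop; present in every supported table

    flank_bases = np.array(list("ACGT"))
    left_flank = list(rng.choice(flank_bases, size=left))
    right_flank = list(rng.choice(flank_bases, size=right))
    left_flank[-3:] = ["T", "A", "A"]  # in-frame stop so the planted ATG is maximal

    genome = list("".join(left_flank) + "".join(codons) + "".join(right_flank))

    # Tunable sites: free flank bases and third codon positions where the
    # amino acid admits synonymous codons of both AT and GC third base
    # (same first two bases, so only the wobble position moves).
    tunable = []  # (genome index, at_options, gc_options)
    for j in range(len(left_flank) - 3):
        tunable.append((j, ("A", "T"), ("G", "C")))
    off = left + orf_nt
    for j in range(off, off + len(right_flank)):
        tunable.append((j, ("A", "T"), ("G", "C")))
    for i, aa in enumerate(aas):
        if i == 0 or aa == "W":
            continue
        codon = codons[i]
        thirds = [c[2] for c in code.synonymous_codons(aa) if c[:2] == codon[:2]]
        at_opts = tuple(b for b in thirds if b in "AT")
        gc_opts = tuple(b for b in thirds if b in "GC")
        if at_opts and gc_opts:
            tunable.append((left + 3 * i + 2, at_opts, gc_opts))

    at_now = sum(1 for b in genome if b in "AT")
    target_at = round(at_target / 100.0 * genome_length)
    order = rng.permutation(len(tunable))
    for k in order:
        if at_now == target_at:
            break
        j, at_opts, gc_opts = tunable[k]
        is_at = genome[j] in "AT"
        if at_now < target_at and not is_at:
            genome[j] = at_opts[rng.integers(len(at_opts))]
            at_now += 1
        elif at_now > target_at and is_at:
            genome[j] = gc_opts[rng.integers(len(gc_opts))]
            at_now -= 1

    sequence = "".join(genome)
    realized_at = 100.0 * at_now / genome_length
    if abs(realized_at - at_target) > 2.0:
        return None

    seq = NucSequence("synthetic_viral_genome", sequence)
    orfs = find_orfs(seq, code, min_codons=min(50, orf_codons))
    if not orfs:
        return None
    top = orfs[0]
    if (top.start, top.end, top.strand, top.aa_length) != (left, left + orf_nt, "+", orf_codons):
        return None
    if len(orfs) > 1 and orfs[1].aa_length >= orf_codons:
        return None

    achieved = 100.0 * n_uga / len(trp_idx) if trp_idx else None
    return seq, (left, left + orf_nt), realized_at, achieved


def gen_viral_genome(
    orf_codons: int,
    code_id: int,
    at_target: float,
    trp_uga_frac: float,
    seed: int,
    genome_length: int | None = None,
    max_attempts: int = 50,
) -> tuple:
    """A mitovirus-like genome: one long ORF under ``code_id``.

    The emitted plus strand carries exactly one maximal ORF of
    ``orf_codons`` coding codons (ATG start, TAA stop, flanked by
    untranslated ends) whose Trp codons are TGA at the nearest achievable
    fraction to ``trp_uga_frac``; overall AT content lands within ±2
    percentage points of ``at_target``, tuned only at wobble positions and
    flanks so the protein and Trp constraints are never touched.

    Returns ``(NucSequence, SyntheticTruth)``; deterministic given
    ``seed``.
    """
    if orf_codons < 50:
        raise ValueError("orf_codons must be >= 50")
    if not 0 <= trp_uga_frac <= 100:
        raise ValueError("trp_uga_frac must be in [0, 100]")
    if not 0 <= at_target <= 100:
        raise ValueError("at_target must be in [0, 100]")
    code = GeneticCode.from_table_id(code_id)
    if trp_uga_frac > 0 and "TGA" in code.stop_codons:
        raise InfeasibleParameterError(
            f"table {code_id} reads TGA as stop; a nonzero UGA(Trp) fraction is impossible"
        )
    orf_nt = 3 * (orf_codons + 1)
    if genome_length is None:
        genome_length = orf_nt + max(60, round(0.1 * orf_nt))
    if genome_length < orf_nt + 6:
        raise ValueError("genome_length leaves no room for flanks")

    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        got = _attempt_genome(rng, orf_codons, code, at_target, trp_uga_frac, genome_length)
        if got is not None:
            seq, span, _, achieved = got
            measured_at = base_composition(seq)["AT_percent"]
            truth = SyntheticTruth(
                genome_length=len(seq),
                at_content=measured_at,
                code_id=code_id,
                orf_span=span,
                trp_uga_fraction=achieved,
                signature_class="none",
                rng_seed=seed,
            )
            return seq, truth
    raise InfeasibleParameterError(
        f"could not realize AT={at_target}% with orf_codons={orf_codons}, "
        f"code {code_id}, UGA(Trp)={trp_uga_frac}% in {genome_length} nt"
    )


def gen_cds_set(
    codon_probs,
    n_codons: int,
    seed: int,
    code_id: int = 5,
    source_id: str = "synthetic_cds",
    include_stop: bool = False,
) -> CdsSet:
    """Draw an in-frame CDS of ``n_codons`` codons i.i.d. from a 64-entry
    probability table (dict codon->p, or an array in
    :data:`mitovir.composition.CODONS` order).

    Probabilities must sum to 1 and put zero mass on the stop codons of
    ``code_id`` (a terminal stop is appended only when ``include_stop``).
    ``n_codons=0`` yields an empty set.
    """
    if isinstance(codon_probs, dict):
        p = np.array([codon_probs.get(c, 0.0) for c in CODONS], dtype=float)
    else:
        p = np.asarray(codon_probs, dtype=float)
    if p.shape != (64,):
        raise ValueError("codon_probs must cover all 64 codons")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"codon probabilities sum to {p.sum()!r}, not 1")
    code = GeneticCode.from_table_id(code_id)
    for stop in code.stop_codons:
        if p[CODONS.index(stop)] > 0:
            raise ValueError(f"nonzero internal stop probability for {stop}")
    if n_codons == 0:
        return CdsSet()
    rng = np.random.default_rng(seed)
    draws = rng.choice(64, size=n_codons, p=p)
    cds = "".join(CODONS[i] for i in draws)
    if include_stop:
        cds += sorted(code.stop_codons)[0]
    return CdsSet([CdsRecord(source_id, cds, code_id)])


def gen_codon_table_family(
    at3_bias: float,
    n_members: int,
    seed: int,
    concentration: float = 3000.0,
    skew: float = 1.2,
    code_id: int = 5,
    trp_uga_frac: float | None = None,
) -> list:
    """A family of related codon-probability tables.

    The family shares one skewed base table whose wobble positions are
    AT-rich with probability ``at3_bias`` (mitochondrial genomes are
    heavily AT3-biased; nuclear/fungal comparators less so); members are
    Dirichlet draws around that base with high ``concentration`` (small
    jitter), so within-family codon-usage vectors stay strongly
    correlated while families with different ``at3_bias`` decorrelate.
    ``trp_uga_frac`` (percent) optionally fixes the TGA share of the
    combined Trp mass in every member — handy for building hosts and
    viruses with prescribed UGA(Trp) usage.

    Returns ``n_members`` arrays of 64 probabilities in CODONS order.
    """
    if not 0 < at3_bias < 1:
        raise ValueError("at3_bias must be in (0, 1)")
    rng = np.random.default_rng(seed)
    code = GeneticCode.from_table_id(code_id)
    stop_idx = [CODONS.index(s) for s in code.stop_codons]
    w = np.zeros(64)
    for i, c in enumerate(CODONS):
        if c in code.stop_codons:
            continue
        w[i] = at3_bias / 2 if c[2] in "AT" else (1 - at3_bias) / 2
    w /= w.sum()
    base = rng.dirichlet(w * 64 * skew)
    base[stop_idx] = 0
    base /= base.sum()
    members = []
    for _ in range(n_members):
        p = rng.dirichlet(base * concentration + 1e-9)
        p[stop_idx] = 0
        if trp_uga_frac is not None:
            i_tga, i_tgg = CODONS.index("TGA"), CODONS.index("TGG")
            if "TGA" in code.stop_codons:
                raise InfeasibleParameterError("TGA is a stop under this code")
            trp_mass = p[i_tga] + p[i_tgg]
            p[i_tga] = trp_mass * trp_uga_frac / 100.0
            p[i_tgg] = trp_mass * (1 - trp_uga_frac / 100.0)
        p /= p.sum()
        members.append(p)
    return members


def _biased_start_positions(ref: str, bias_base: str):
    """Sorted position lists for 5'-base-targeted start sampling.

    For a plus-strand read starting at i the 5' base is ref[i]; for a
    minus-strand read whose rightmost reference position is j, the 5'
    base is the complement of ref[j].
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    plus_match = [i for i, b in enumerate(ref) if b == bias_base]
    plus_other = [i for i, b in enumerate(ref) if b != bias_base]
    minus_match = [j for j, b in enumerate(ref) if comp.get(b) == bias_base]
    minus_other = [j for j, b in enumerate(ref) if comp.get(b, "N") != bias_base]
    return plus_match, plus_other, minus_match, minus_other


def gen_srna_reads(
    ref: NucSequence,
    n_reads: int,
    seed: int,
    preset: str | None = None,
    peak_size: int | None = None,
    size_sd: float = 1.6,
    strand_ratio: float = 0.5,
    five_prime_bias: tuple | None = None,
    max_size: int = 35,
    min_size: int = 15,
) -> list:
    """Small-RNA reads that are exact substrings of ``ref`` (or its
    reverse complement).

    Sizes follow a discretized Gaussian truncated to [min_size, max_size];
    strands are Bernoulli(``strand_ratio``) for plus.  With
    ``five_prime_bias=(base, p)`` the start position is drawn so the 5'
    base equals ``base`` with probability exactly ``p`` (rejection-free:
    positions are pre-partitioned by their 5' base), keeping every read an
    exact substring.  Use ``preset`` for the canonical signature classes
    in :data:`SRNA_PRESETS`.
    """
    if preset is not None:
        cfg = SRNA_PRESETS[preset]
        peak_size = cfg["peak_size"]
        size_sd = cfg["size_sd"]
        strand_ratio = cfg["strand_ratio"]
        five_prime_bias = cfg["five_prime_bias"]
    if peak_size is None:
        raise ValueError("peak_size required when no preset is given")
    if not min_size <= peak_size <= max_size:
        raise ValueError(f"peak_size must be in [{min_size}, {max_size}]")
    if not 0 <= strand_ratio <= 1:
        raise ValueError("strand_ratio must be in [0, 1]")
    if len(ref) < max_size:
        raise ValueError("reference shorter than the maximum read size")

    rng = np.random.default_rng(seed)
    sizes = np.clip(np.rint(rng.normal(peak_size, size_sd, n_reads)), min_size, max_size).astype(int)
    plus = rng.random(n_reads) < strand_ratio
    L = len(ref)
    residues = ref.residues

    if five_prime_bias is not None:
        bias_base, bias_p = five_prime_bias
        pm, po, mm, mo = _biased_start_positions(residues, bias_base)
        want_match = rng.random(n_reads) < bias_p

    reads = []
    for i in range(n_reads):
        size = int(sizes[i])
        if five_prime_bias is None:
            start = int(rng.integers(0, L - size + 1))
        elif plus[i]:
            # valid plus starts are positions <= L - size
            pool, alt = (pm, po) if want_match[i] else (po, pm)
            hi = bisect_right(pool, L - size)
            if hi == 0:
                pool, hi = alt, bisect_right(alt, L - size)
            start = pool[int(rng.integers(hi))]
        else:
            # minus-strand 5' base sits at reference position j >= size-1
            pool, alt = (mm, mo) if want_match[i] else (mo, mm)
            lo = bisect_left(pool, size - 1)
            if lo == len(pool):
                pool, lo = alt, bisect_left(alt, size - 1)
            j = pool[int(rng.integers(lo, len(pool)))]
            start = j - size + 1
        window = residues[start : start + size]
        seq = window if plus[i] else reverse_complement(window)
        reads.append(ReadRecord(f"sr{i:06d}", seq, (40,) * size))
    return reads


def gen_long_reads(
    ref: NucSequence,
    coverage: float,
    read_len: int,
    err_rate: float,
    seed: int,
) -> list:
    """Uniformly tiling long reads at ~``coverage`` expected depth with
    i.i.d. substitution errors at ``err_rate`` (no indels)."""
    if read_len >= len(ref):
        raise ValueError("read_len must be shorter than the reference")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 0 <= err_rate < 1:
        raise ValueError("err_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = max(1, round(coverage * len(ref) / read_len))
    starts = rng.integers(0, len(ref) - read_len + 1, size=n)
    strands = rng.random(n) < 0.5
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    reads = []
    for i in range(n):
        window = ref.residues[starts[i] : starts[i] + read_len]
        seq = window if strands[i] else reverse_complement(window)
        if err_rate > 0:
            k = rng.binomial(read_len, err_rate)
            if k:
                chars = list(seq)
                for pos in rng.choice(read_len, size=k, replace=False):
                    chars[pos] = others[chars[pos]][rng.integers(3)]
                seq = "".join(chars)
        reads.append(ReadRecord(f"lr{i:05d}", seq, (40,) * read_len))
    return reads


def gen_dna_library(
    host_ref: NucSequence,
    virus_ref: NucSequence,
    integrated: bool,
    n_reads: int,
    seed: int,
    viral_fraction: float = 0.01,
    read_len: int = 75,
) -> tuple:
    """A DNA-seq library from the host genome, optionally carrying reads
    from an integrated viral copy.

    With ``integrated=False`` zero reads originate from the virus (an
    exogenous RNA virus has no DNA form); with ``integrated=True`` a
    Binomial(n_reads, viral_fraction) share does.  Returns
    ``(reads, truth)`` where truth records the exact origin counts (viral
    read ids are prefixed ``dnaV``, host reads ``dnaH``).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    rng = np.random.default_rng(seed)
    n_virus = int(rng.binomial(n_reads, viral_fraction)) if integrated else 0
    reads = []

    def sample(ref: NucSequence, n: int, prefix: str):
        if n == 0:
            return
        rl = min(read_len, len(ref) - 1)
        starts = rng.integers(0, len(ref) - rl + 1, size=n)
        strands = rng.random(n) < 0.5
        for i in range(n):
            window = ref.residues[starts[i] : starts[i] + rl]
            seq = window if strands[i] else reverse_complement(window)
            reads.append(ReadRecord(f"{prefix}{i:06d}", seq, (40,) * rl))

    sample(host_ref, n_reads - n_virus, "dnaH")
    sample(virus_ref, n_virus, "dnaV")
    truth = {"n_reads": n_reads, "n_virus": n_virus, "n_host": n_reads - n_virus,
             "integrated": integrated}
    return reads, truth


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    """Tab-separated sidecar with the recounted ground truth."""
    rows = [
        ("genome_length", truth.genome_length),
        ("at_content", f"{truth.at_content:.4f}"),
        ("code_id", truth.code_id),
        ("orf_start", truth.orf_span[0]),
        ("orf_end", truth.orf_span[1]),
        ("trp_uga_fraction", "" if truth.trp_uga_fraction is None else f"{truth.trp_uga_fraction:.4f}"),
        ("signature_class", truth.signature_class),
        ("rng_seed", truth.rng_seed),
    ]
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")
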