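"""Compositional genomic signatures: dinucleotide odds ratios, codon usage,
UGA/UGG tryptophan statistics, and correlation-based clustering.

The working hypothesis behind these signatures is that a virus replicating
inside a host compartment for a long time converges on that compartment's
mutational and translational biases.  A mitochondrially-replicating RNA
virus therefore tends to share the high AT content, dinucleotide odds
profile, codon usage and UGA(Trp) preference of its host's mitochondrial
genome, and clustering the signature vectors groups the virus with its
host compartment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .errors import EmptyInputError
from .seqcore import CdsSet, GeneticCode, NucSequence, base_composition

__all__ = [
    "CODONS",
    "DINUCLEOTIDES",
    "DinucleotideProfile",
    "CodonUsageTable",
    "TrpCodonStats",
    "CorrelationClustering",
    "dinucleotide_odds",
    "classify_dinucleotide_bias",
    "codon_usage",
    "trp_codon_stats",
    "profile_correlation",
    "cluster_by_correlation",
]

CODONS = tuple("".join(c) for c in product("TCAG", repeat=3))
DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")


@dataclass(frozen=True)
class DinucleotideProfile:
    """16 observed/expected dinucleotide odds ratios for one sequence."""

    source_id: str
    odds: dict  # dinucleotide -> ratio

    def vector(self) -> np.ndarray:
        return np.array([self.odds[d] for d in DINUCLEOTIDES])


@dataclass(frozen=True)
class CodonUsageTable:
    """Pooled codon usage: raw counts, per-1000-codon frequency, and the
    fraction each codon takes within its synonymous family."""

    source_id: str
    counts: dict
    per_1000: dict
    synonymous_fraction: dict
    code_id: int

    def vector(self) -> np.ndarray:
        return np.array([self.per_1000[c] for c in CODONS])


@dataclass(frozen=True)
class TrpCodonStats:
    """UGA/UGG tryptophan-codon usage for one source.

    A TGA that closes a CDS is a stop, not a tryptophan, and is excluded
    from ``uga_count``.  ``uga_trp_percent`` is None when no Trp codon is
    observed.
    """

    source_id: str
    uga_count: int
    ugg_count: int
    uga_trp_percent: float | None
    at_percent: float


@dataclass
class CorrelationClustering:
    """Pearson r matrix + UPGMA tree + threshold cluster assignment.

    ``assignment`` maps each label to a positive integer cluster id, or
    None for unclustered singletons (including zero-variance profiles whose
    correlations are undefined).
    """

    labels: list
    r: np.ndarray
    linkage_matrix: np.ndarray | None
    assignment: dict

    def r_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.labels, columns=self.labels)

    def clusters(self) -> dict:
        out: dict = {}
        for label, cid in self.assignment.items():
            if cid is not None:
                out.setdefault(cid, []).append(label)
        return out


def dinucleotide_odds(
    seq: NucSequence | str,
    source_id: str | None = None,
    expected: str = "mononucleotide",
) -> DinucleotideProfile:
    """Overlapping dinucleotide odds ratios on a single strand.

    odds(xy) = f(xy) / (f(x)·f(y)) with all frequencies measured on the
    given strand; windows containing N are skipped and N is excluded from
    mononucleotide frequencies.  ``expected="uniform"`` divides by 1/16
    instead (the EMBOSS compseq default) for cross-checking against that
    convention.
    """
    if expected not in ("mononucleotide", "uniform"):
        raise ValueError(f"unknown expectation {expected!r}")
    if isinstance(seq, NucSequence):
        residues, sid = seq.residues, seq.id
    else:
        residues, sid = seq.upper().replace("U", "T"), source_id or "seq"
    if not residues or set(residues) <= {"N"}:
        raise EmptyInputError("empty or all-N sequence")
    if len(residues) < 100:
        warnings.warn(
            f"sequence {sid!r} shorter than 100 nt; odds ratios will be noisy",
            stacklevel=2,
        )
    mono = base_composition(residues)["fractions"]
    di_counts = dict.fromkeys(DINUCLEOTIDES, 0)
    n_windows = 0
    for i in range(len(residues) - 1):
        d = residues[i : i + 2]
        if "N" in d:
            continue
        di_counts[d] += 1
        n_windows += 1
    if n_windows == 0:
        raise EmptyInputError("no N-free dinucleotide windows")
    odds = {}
    for d in DINUCLEOTIDES:
        f_obs = di_counts[d] / n_windows
        f_exp = mono[d[0]] * mono[d[1]] if expected == "mononucleotide" else 1 / 16
        odds[d] = f_obs / f_exp if f_exp > 0 else float("nan")
    return DinucleotideProfile(sid, odds)


def classify_dinucleotide_bias(
    profile: DinucleotideProfile, lo: float = 0.78, hi: float = 1.25
) -> dict:
    """Flag each dinucleotide as biased when its odds ratio falls outside
    the closed interval [lo, hi] (ratios exactly on a cutoff count as
    unbiased)."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    return {d: ("biased" if (r < lo or r > hi) else "unbiased") for d, r in profile.odds.items()}


def codon_usage(cds: CdsSet, code: GeneticCode | None = None) -> CodonUsageTable:
    """Pooled codon-usage table over all CDS in the set.

    All 64 codons are reported, zeros included; per-1000 values are per
    1000 codons and sum to 1000 up to rounding.  Synonymous fractions are
    computed under ``code`` (default: the code of the first CDS record),
    grouping stop codons as their own family.
    """
    cds.require_nonempty()
    if code is None:
        code = GeneticCode.from_table_id(cds.records[0].code_id)
    counts = dict.fromkeys(CODONS, 0)
    for rec in cds:
        for codon in rec.codons():
            if codon in counts:
                counts[codon] += 1
    total = sum(counts.values())
    if total == 0:
        raise EmptyInputError("no unambiguous codons in CdsSet")
    per_1000 = {c: 1000.0 * n / total for c, n in counts.items()}
    syn_frac = {}
    for c in CODONS:
        family = code.synonymous_codons(code.codon_to_aa[c])
        fam_total = sum(counts[x] for x in family)
        syn_frac[c] = counts[c] / fam_total if fam_total else float("nan")
    return CodonUsageTable(cds.records[0].source_id, counts, per_1000, syn_frac, code.table_id)


def trp_codon_stats(
    cds: CdsSet,
    code: GeneticCode,
    allow_standard_code: bool = False,
) -> TrpCodonStats:
    """UGA(Trp) vs UGG usage pooled over a CDS set.

    Requires a code reading TGA as Trp unless ``allow_standard_code`` is
    set (then internal TGA are still tallied, for survey tables of
    standard-code genomes where any internal TGA is suspect).  The final
    codon of each CDS is excluded from the UGA tally when it is TGA —
    there it acts as the stop codon, whatever the table says.
    """
    cds.require_nonempty()
    if code.codon_to_aa.get("TGA") != "W" and not allow_standard_code:
        raise ValueError(
            "code does not read TGA as Trp; pass allow_standard_code=True to count anyway"
        )
    uga = ugg = 0
    concat = []
    for rec in cds:
        codons = rec.codons()
        concat.append(rec.cds)
        for i, codon in enumerate(codons):
            if codon == "TGG":
                ugg += 1
            elif codon == "TGA" and i < len(codons) - 1:
                uga += 1
    at = base_composition("".join(concat))["AT_percent"]
    pct = 100.0 * uga / (uga + ugg) if (uga + ugg) else None
    return TrpCodonStats(cds.records[0].source_id, uga, ugg, pct, at)


def profile_correlation(profiles: dict | list) -> CorrelationClustering:
    """Full pairwise Pearson r matrix over equal-length signature vectors.

    ``profiles`` is either {label: vector} or [(label, vector), ...].
    Zero-variance vectors yield undefined correlations: their rows/columns
    are NaN (diagonal excepted) and they are excluded from any subsequent
    clustering.  Only the matrix part of the result is filled in here; use
    :func:`cluster_by_correlation` for the tree and assignment.
    """
    items = list(profiles.items()) if isinstance(profiles, dict) else list(profiles)
    if len(items) < 2:
        raise ValueError("need at least 2 profiles")
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("profile labels must be unique")
    mat = np.array([np.asarray(v, dtype=float) for _, v in items])
    if mat.ndim != 2:
        raise ValueError("profiles must have equal dimension")
    sd = mat.std(axis=1)
    n = len(labels)
    r = np.full((n, n), np.nan)
    ok = sd > 0
    if ok.sum() >= 2:
        sub = np.corrcoef(mat[ok])
        idx = np.flatnonzero(ok)
        r[np.ix_(idx, idx)] = sub
    np.fill_diagonal(r, 1.0)
    return CorrelationClustering(labels, r, None, {lab: None for lab in labels})


def _tree_clusters(node, r: np.ndarray, threshold: float) -> list:
    """Cut an UPGMA tree into maximal all-pairs-correlated groups."""
    leaves = node.pre_order(lambda x: x.id)
    if len(leaves) >= 2:
        sub = r[np.ix_(leaves, leaves)]
        if np.all(sub >= threshold):
            return [leaves]
    if node.is_leaf():
        return []
    return _tree_clusters(node.left, r, threshold) + _tree_clusters(node.right, r, threshold)


def cluster_by_correlation(
    corr: CorrelationClustering, threshold: float = 0.8
) -> CorrelationClustering:
    """UPGMA clustering of signature profiles at a Pearson-r threshold.

    Average-linkage (UPGMA) hierarchical clustering on distance 1 − r,
    then the tree is cut into maximal groups whose members are *all
    mutually* correlated at r ≥ threshold.  Groups need ≥ 2 members;
    everything else stays an unassigned singleton.  The result is
    invariant to input order (labels are sorted before linkage) and
    cluster ids are numbered by first sorted member.
    """
    order = sorted(range(len(corr.labels)), key=lambda i: str(corr.labels[i]))
    labels = [corr.labels[i] for i in order]
    r = corr.r[np.ix_(order, order)]
    valid = [i for i in range(len(labels)) if not np.isnan(np.delete(r[i], i)).all()]
    assignment: dict = {lab: None for lab in labels}
    link = None
    if len(valid) >= 2:
        rv = r[np.ix_(valid, valid)]
        dist = np.clip(1.0 - rv, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        link = linkage(squareform(dist, checks=False), method="average")
        root = to_tree(link)
        for cid, group in enumerate(
            sorted(_tree_clusters(root, rv, threshold), key=min), start=1
        ):
            for leaf in group:
                assignment[labels[valid[leaf]]] = cid
    return CorrelationClustering(labels, r, link, assignment)
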