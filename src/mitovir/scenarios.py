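"""End-to-end synthetic host-assignment scenarios.

Builds a complete, internally consistent world — a virus adapted to one
host compartment, two candidate host mitochondria, small-RNA libraries,
RNA abundance and a DNA library — runs the whole pipeline on it, and
returns the evidence report together with every intermediate, so tests
and worked examples can check each stage against the scenario's ground
truth.
"""

from __future__ import annotations

import numpy as np

from . import composition, hostcall, srna
from .seqcore import NucSequence, base_composition, GeneticCode
from .synthetic_data import gen_cds_set, gen_codon_table_family, gen_dna_library, gen_srna_reads

__all__ = ["build_host_scenario"]

# Family-level study conditions: insect mitochondria are extremely
# AT3-rich and use UGA for nearly all Trp; the fungal comparator is less
# AT-biased and UGG-leaning (several fungal/oomycete mitochondria use
# little or no UGA(Trp)).
_FAMILIES = {
    "insect_mito": dict(at3=0.90, host_uga=95.0, virus_uga=73.3),
    "fungal": dict(at3=0.60, host_uga=10.0, virus_uga=25.0),
}


def _signature_from_cds(label: str, group: str, cds_set) -> hostcall.HostSignature:
    concat = "".join(rec.cds for rec in cds_set)
    code = GeneticCode.from_table_id(cds_set.records[0].code_id)
    return hostcall.HostSignature(
        label=label,
        group=group,
        at_percent=base_composition(concat)["AT_percent"],
        codon_usage=composition.codon_usage(cds_set),
        dinucleotide=composition.dinucleotide_odds(concat, source_id=label),
        trp=composition.trp_codon_stats(cds_set, code),
    )


def build_host_scenario(
    true_host: str = "insect_mito",
    seed: int = 0,
    n_codons: int = 3000,
    n_srna: int = 6000,
    n_dna_reads: int = 10000,
    integrated: bool = False,
) -> dict:
    """Simulate one virus with two candidate hosts and run the pipeline.

    ``true_host`` selects which host family the virus's composition and
    small-RNA signature are drawn from.  Returns a dict with the
    evidence report under ``"report"`` plus all intermediates.
    """
    if true_host not in _FAMILIES:
        raise ValueError(f"true_host must be one of {sorted(_FAMILIES)}")
    sub = [int(s) for s in np.random.SeedSequence(seed).generate_state(10) % (2**31)]

    cds = {}
    for i, (group, fam) in enumerate(sorted(_FAMILIES.items())):
        host_probs = gen_codon_table_family(
            fam["at3"], 1, seed=sub[i], trp_uga_frac=fam["host_uga"]
        )[0]
        cds[group] = gen_cds_set(host_probs, n_codons, seed=sub[2 + i],
                                 source_id=f"{group}_host")
    fam = _FAMILIES[true_host]
    virus_probs = gen_codon_table_family(
        fam["at3"], 2, seed=sub[sorted(_FAMILIES).index(true_host)],
        trp_uga_frac=fam["virus_uga"],
    )[1]  # second member of the true host's family: related but not identical
    virus_cds = gen_cds_set(virus_probs, n_codons, seed=sub[4], source_id="virus")
    virus_genome = NucSequence("virus", "".join(rec.cds for rec in virus_cds))

    hosts = [_signature_from_cds(f"{g}_host", g, cds[g]) for g in sorted(_FAMILIES)]
    code = GeneticCode.from_table_id(5)
    virus_usage = composition.codon_usage(virus_cds)
    virus_dinuc = composition.dinucleotide_odds(virus_genome)
    virus_trp = composition.trp_codon_stats(virus_cds, code)
    virus_at = base_composition(virus_genome)["AT_percent"]

    # Small-RNA libraries mapped back to the viral genome
    preset = "siRNA_insect" if true_host == "insect_mito" else "fungal_siRNA"
    rna_abundance = []
    profiles = []
    srna_class = None
    for k, n in enumerate([n_srna, n_srna // 3, n_srna // 3]):
        reads = gen_srna_reads(virus_genome, n, seed=sub[5 + k], preset=preset)
        aln = srna.map_reads(reads, virus_genome, max_mm=1)
        rna_abundance.append(
            hostcall.rpm_abundance(len(aln), 1_000_000, f"rna_lib{k + 1}", "virus")
        )
        if k == 0:
            profile = srna.size_profile(aln)
            enrichment = srna.five_prime_enrichment(aln, virus_genome)
            srna_class = srna.classify_signature(profile, enrichment)
            profiles.append(profile)

    # DNA library: host mitochondrial genome as the positive control
    host_genome = NucSequence(
        f"{true_host}_host_mt", "".join(rec.cds for rec in cds[true_host])
    )
    dna_reads, dna_truth = gen_dna_library(
        host_genome, virus_genome, integrated=integrated, n_reads=n_dna_reads, seed=sub[8]
    )
    dna_virus = srna.map_reads(dna_reads, virus_genome, max_mm=1)
    dna_host = srna.map_reads(dna_reads, host_genome, max_mm=1)
    dna_virus_rpm = hostcall.rpm_abundance(len(dna_virus), n_dna_reads).rpm
    dna_control_rpm = hostcall.rpm_abundance(len(dna_host), n_dna_reads).rpm

    cfg = hostcall.EvidenceConfig(sampled_group=true_host)
    report = hostcall.integrate_evidence(
        virus_id="virus",
        virus_at=virus_at,
        virus_codon_usage=virus_usage,
        virus_dinucleotide=virus_dinuc,
        virus_trp=virus_trp,
        srna_class=srna_class,
        candidate_hosts=hosts,
        rna_abundance=rna_abundance,
        dna_virus_rpm=dna_virus_rpm,
        dna_control_rpm=dna_control_rpm,
        config=cfg,
    )
    return {
        "report": report,
        "true_host": true_host,
        "virus_genome": virus_genome,
        "virus_cds": virus_cds,
        "virus_at": virus_at,
        "virus_trp": virus_trp,
        "hosts": hosts,
        "srna_class": srna_class,
        "size_profile": profiles[0] if profiles else None,
        "rna_abundance": rna_abundance,
        "dna_virus_rpm": dna_virus_rpm,
        "dna_control_rpm": dna_control_rpm,
        "dna_truth": dna_truth,
    }
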