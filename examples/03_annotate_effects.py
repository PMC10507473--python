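"""Classify SNP effects against gene models, SnpEff-style.

A synthetic reference genome with embedded UTR-less protein-coding genes is
generated, SNPs are placed on it, and each SNP is classified into one of 14
effect categories (intergenic, up/downstream within 5 kb, intron, splice
donor/acceptor/region, synonymous, missense, stop gained/lost/retained,
start lost, initiator codon) with one call per overlapping gene context.
"""

from chlorisnp.effects import classify_callset_sites, summarize_effects
from chlorisnp.filtering import intersect_callsets
from chlorisnp.synthetic import (
    SimulationConfig,
    emit_callsets,
    simulate_reference,
    simulate_truth,
)

reference, genes = simulate_reference(seed=11, n_chrom=2,
                                      chrom_length=200_000, n_genes=20)
print(f"reference: {len(reference)} chromosomes, {len(genes)} genes")

config = SimulationConfig(seed=11)
caller_a, caller_b, _ = emit_callsets(
    simulate_truth(config), config, reference=reference
)
merged = intersect_callsets(caller_a, caller_b)

calls = classify_callset_sites(merged.sites, genes, reference, flank_bp=5000)
summary = summarize_effects(calls)
print(f"\n{len(calls)} effect calls over {merged.n_sites} SNPs")
print(summary.to_string(index=False))
print(f"\npercent column sums to {summary['percent'].sum():.3f}")
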