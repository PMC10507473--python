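"""Simulate a mixed-ploidy cohort and run the SNP filtering cascade.

The synthetic study mirrors a resequencing design with five cultivars (three
diploid, two tetraploid, 94 samples), shallow ~2.3x coverage and two SNP
callers that disagree on ~30% of sites.  Filtering intersects the callers,
splits by ploidy, applies MAF / missingness / depth thresholds and then the
two heterozygosity-excess rules that target collapsed paralogs and repeats.
"""

from chlorisnp.filtering import (
    FilterReport,
    FilterThresholds,
    apply_het_excess_filters,
    apply_threshold_filters,
    intersect_callsets,
    intersect_ploidy_sets,
    split_by_ploidy,
)
from chlorisnp.synthetic import SimulationConfig, emit_callsets, simulate_truth

config = SimulationConfig(seed=11)
truth = simulate_truth(config)
caller_a, caller_b, metadata = emit_callsets(truth, config)
print(f"caller A: {caller_a.n_sites} sites, caller B: {caller_b.n_sites} sites")

merged = intersect_callsets(caller_a, caller_b)
print(f"intersection of the two callers: {merged.n_sites} sites")

diploid, tetraploid = split_by_ploidy(merged, metadata)
thresholds = FilterThresholds()  # MAF 0.1, missing 0.5, depth 4, het 0.75/0.60

filtered = {}
for name, callset in (("diploid", diploid), ("tetraploid", tetraploid)):
    report = FilterReport()
    report.add("input", callset.n_sites, callset.n_sites)
    step1, rep1 = apply_threshold_filters(callset, thresholds)
    report.extend(rep1)
    step2, rep2 = apply_het_excess_filters(step1, thresholds)
    report.extend(rep2)
    filtered[name] = step2
    print(f"\n{name} attrition:")
    print(report.to_frame().to_string(index=False))

common = intersect_ploidy_sets(filtered["diploid"], filtered["tetraploid"])
print(f"\nhigh-confidence sites common to both ploidy sets: {len(common)}")
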