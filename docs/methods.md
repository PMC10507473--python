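# Methods note

This note records the statistical models, conventions and design decisions
behind `chlorisnp`, in the order the pipeline applies them.

## Collapsed-diploid genotype model

All genotype handling uses a four-state collapsed coding — hom-ref, het,
hom-alt, missing — for every sample regardless of ploidy. At ~2.3x coverage,
tetraploid allelic dosage (0–4 alternate copies) cannot be estimated from read
counts, so a tetraploid with any mixed dosage (1–3 copies) is scored "het",
exactly as a diploid heterozygote would be. This loses information by design
and makes diploid and tetraploid samples directly comparable in one matrix.
Consequences are tracked explicitly: the tetrasomic expectation for the
collapsed het rate at alternate-allele frequency `p` is `1 − p⁴ − (1−p)⁴`
(0.875 at p = 0.5), against the disomic `2p(1−p)` (0.5), and that gap is both
a nuisance (it inflates heterozygosity-based filters on tetraploids) and the
signal the origin classifier consumes.

## Caller intersection and filtering cascade

Two call sets representing independent SNP-discovery pipelines are intersected
on `(chrom, pos, ref, alt)`; genotypes at shared sites are taken from the
first call set, and allele-mismatched positions are excluded. The merged set
is split by ploidy and each half runs the same ordered cascade:

1. **Depth masking** — genotypes with depth < 4 are set to missing (the site
   survives; only the genotype is masked).
2. **Missingness** — sites with a missing fraction strictly greater than 0.5
   are removed (after depth masking, so the two interact).
3. **MAF** — sites with minor-allele frequency strictly below 0.1 among
   called genotypes (het counts one alternate copy, hom-alt two) are removed.
4. **Heterozygosity excess, rule 1** — sites where the het fraction `h`
   exceeds 0.75 are removed.
5. **Heterozygosity excess, rule 2** — sites missing an entire homozygote
   class (no hom-ref or no hom-alt among called genotypes) with `h > 0.60`
   are removed.

All inequalities are strict; boundary sites (`h = 0.75`, MAF = 0.1,
missing = 0.5) are retained by rule 1 but may still fall to rule 2. The het
denominator is the number of *called* genotypes by default (configurable to
all genotypes). Rules 4–5 target collapsed paralogs and repeat-derived
pile-ups, which at low coverage present as implausibly universal
heterozygosity; rule 2 catches the same artifact at lower `h` when the site
also lacks the homozygote class a real segregating site would show. Sites
left with zero called genotypes are removed under their own reason code so
attrition reports telescope exactly (`sites_in − removed = sites_out` at every
step, verified by `FilterReport.validate_chain`). The high-confidence common
set is the allele-matched intersection of the filtered diploid and tetraploid
site lists.

## Distance and tree

Collapsed calls are encoded as the within-individual reference-allele
frequency: hom-ref → 1.0, het → 0.5, hom-alt → 0.0, missing → NaN. Nei's
(1972) standard genetic distance is applied at the individual level:

```
D(x, y) = −ln( J_xy / √(J_x · J_y) )
```

with `J_xy = Σ (x_ref·y_ref + x_alt·y_alt)` over loci genotyped in both
individuals (pairwise deletion), and `J_x`, `J_y` the corresponding
homozygosity sums over the same shared loci. A pair with no shared genotyped
loci is an error; a pair with zero joint identity (`J_xy = 0`, infinite `D`)
is capped at 10x the largest finite distance with a warning, so one degenerate
pair cannot destroy the tree while remaining clearly an outlier.

Neighbour joining follows Saitou & Nei (1987): the Q-criterion selects the
pair to agglomerate, ties resolve deterministically to the lowest index pair
in the current agglomeration order, negative branch lengths are clamped to
zero with the deficit absorbed by the sibling edge, and the final three nodes
join at a basal trifurcation (unrooted tree). On exactly additive matrices
this recovers topology and branch lengths to 1e-9, which the test suite
checks against random trees whose patristic distances are computed
independently by dendropy.

Cultivar/ploidy structure is summarized without rooting assumptions: a
"cluster" is one side of some tree edge, and the cohort is flagged
ploidy-separated iff one edge splits the tetraploid leaves exactly from the
diploid leaves.

## Effect classification

Gene models are UTR-less (CDS = exonic sequence); an exonic, non-coding
position is rejected as outside the supported model class rather than
misclassified. Geometry conventions, all 1-based closed and
transcription-direction aware: splice acceptor = last 2 intronic bases before
an exon; splice donor = first 2 after; splice region = intronic bases 3–8
from a junction; upstream/downstream = within 5 kb (configurable) of the gene
span on the 5'/3' side. A SNP receives one call per gene whose flanked span
contains it (one intergenic call if none), and within a gene a priority
ladder selects a single category (splice acceptor/donor > start lost > stop
gained/lost > initiator codon > stop retained > missense > synonymous >
splice region > intron > up/downstream). Coding consequences are computed on
the codon containing the SNP, strand-aware, under the standard genetic code;
`ATG → {TTG, CTG}` at the start codon counts as an initiator-codon variant
rather than start loss (configurable set). Summary percentages are taken over
total effect *calls* (not SNPs), rounded to 3 decimals, so they sum to 100
within rounding. The implementation is validated against a brute-force oracle
that mutates the chromosome, re-splices and re-translates the entire CDS, and
diffs the proteins.

## Polyploid-origin diagnosis

Two cohort-level statistics are computed from the merged call set:

* `fixed_het_fraction` — fraction of loci whose heterozygote frequency among
  called tetraploid genotypes is ≥ 0.9 (the cutoff below 1.0 tolerates call
  error and missingness at shallow depth);
* `private_variant_fraction` — among loci where the alternate allele is
  observed in the tetraploids, the fraction at which no diploid call carries
  it.

Verdict: **allo** if `fixed_het_fraction > t_fix` *or*
`private_variant_fraction > t_priv`; **auto** if both fall below half their
thresholds; **ambiguous** otherwise. The defaults (`t_fix = 0.3`,
`t_priv = 0.12`) are calibrated on the in-package simulator at the full study
design (94 samples, 30 tetraploid; 5,000 loci; mean depth 2.3) to sit in the
middle of the empirical gap between the auto regime (fixed-het ≤ ~0.12,
private ≤ ~0.03 across seeds) and the allo regime at subgenome divergence 0.3
(fixed-het ≥ ~0.35, private ≥ ~0.14). They are configurable and always
reported alongside the verdict. Mapping-rate concordance between cohorts
(delta of percent-mapped below 1 percentage point) is reported as a
complementary sanity check: an allotetraploid whose second subgenome were
truly absent from the reference would also tend to map worse.

**Operating envelope.** `fixed_het_fraction` is sample-size dependent: with
few tetraploids (≈10 or fewer called genotypes per locus), binomial sampling
alone pushes many genuinely tetrasomic loci past the 0.9 cutoff (at
per-sample het 0.875, all-10-het has probability ~0.26). The default
thresholds assume a cohort of roughly the calibrated size; for much smaller
cohorts, recalibrate or raise `fixed_het_cutoff` toward requiring more called
genotypes.

## Synthetic cohort generator

The generator is the package's test bed and calibration instrument.

* **Allele frequencies** — per-locus ancestral alternate frequency
  `q ~ Beta(2, 2)` (or a point mass for closed-form checks).
* **Hierarchical drift** — the diploid cultivars share one lineage
  perturbation and the tetraploid cultivars another
  (`U(−0.35, 0.35)` per locus), with a smaller per-cultivar perturbation
  (`U(−0.1, 0.1)`) on top. The lineage level exists because two cultivar
  groups drawn from one undifferentiated pool do *not* separate on a tree:
  with only cultivar-level noise, collapsed-diploid Nei distances are
  structurally smaller between het-rich tetraploid profiles and anything else
  than among diploids, and no ploidy edge forms. A shared lineage shift is
  the minimal ancestry model that produces the diploid/tetraploid split such
  cohorts actually show.
* **Dosage models** — diploid `Bin(2, q)`; autotetraploid `Bin(4, q)`
  (tetrasomic); allotetraploid two independent `Bin(2, q)` subgenomes, where
  with probability `d` (subgenome divergence) a locus is a fixed
  inter-subgenome difference: one subgenome fixed reference, the other fixed
  alternate, and the diploid pool carries no alternate copy. At `d = 0` the
  allo model is distributionally identical to the auto model, which the test
  suite uses as a negative control.
* **Depth** — per-genotype depth is Poisson with a per-locus rate
  `mean_depth × Gamma(shape=1, mean=1)`. The Gamma mixing (i.e. negative
  binomial marginal) models the strong across-locus overdispersion of real
  shallow short-read coverage (mappability, GC, library effects). This
  matters: under a pure Poisson at mean 2.3, essentially no genotype reaches
  the depth-4 filter and the cascade empties; overdispersion is what lets a
  2.3x experiment retain a usable minority of well-covered sites. Set
  `depth_shape=None` for plain Poisson.
* **Observation noise** — genotypes with zero covering reads are missing,
  plus 5% extra dropout; 2% of genotypes are flipped to one of the other two
  states; each locus is dropped from exactly one of the two emitted call sets
  with probability 0.3, mimicking caller disagreement.
* **Reference + genes** — random chromosomes with embedded UTR-less genes
  (ATG start, stop end, no internal in-frame stop, CDS = exons, alternating
  strands), used both for placing SNPs and for effect-annotation tests.

All randomness flows from `numpy.random.default_rng([seed, k])` with a fixed
stream index `k` per component (truth, observation, reference), so any part
can be regenerated independently and byte-identically.

## Pseudomolecule anchoring

Hits (BLAST outfmt-6 dialect, strand inferred from subject coordinate order;
or PAF, converted from 0-based half-open) below identity/score thresholds are
dropped at load. Strict mode discards any contig with threshold-passing hits
on two or more reference chromosomes; an optional dominance mode keeps a
contig on its dominant chromosome when that chromosome holds ≥ 90% of its
aligned bases. Anchor position is the median of hit reference midpoints
(robust to a stray hit); orientation is the majority strand weighted by
aligned bases, ties defaulting to `+`; ordering ties break on contig id.
Pseudomolecules concatenate oriented contigs with 100-N spacers (configurable)
and are described by AGP v2.1 (W component rows; U gap rows,
`scaffold yes align_genus`), chosen such that AGP + contigs reconstruct the
pseudomolecule sequence byte-for-byte. Invariants: every input contig ends up
in exactly one of anchored / multi-chromosome / unaligned, and total non-N
pseudomolecule length equals the sum of anchored contig lengths.

## Pipeline and reproducibility

`run_all` executes intersect → ploidy split → filter cascades → common set →
distance/tree → effect annotation → origin assessment, writing per-stage
artifacts and a JSON manifest (package version, seed, thresholds, input
checksums, per-stage counts — no timestamps). One seed governs all stochastic
steps; re-running an identical config reproduces byte-identical outputs. Any
stage failure is wrapped in an error naming the stage.

## Numerical and testing choices

* Distances are computed in float64 with vectorized joint-identity sums; the
  implementation is checked against a straight-line loop re-implementation.
* The filtering cascade is checked site-for-site against a brute-force
  re-implementation over randomized fixtures, including threshold strictness
  and both het-rule denominators.
* Closed forms used as oracles: collapsed het rates (`2p(1−p)`,
  `1 − p⁴ − (1−p)⁴`), the collapsed genotype distribution of `Bin(4, ½)`
  (1/16, 14/16, 1/16), and the single-locus Nei distance between a
  homozygote and a heterozygote (`½·ln 2`).

## Limitations

* Dosage is never estimated; analyses inherit the information loss of the
  collapsed encoding.
* Gene models with UTRs are rejected, not approximated.
* The origin thresholds are calibrated for study-scale cohorts (see operating
  envelope above); the drift model behind the simulator is a deliberately
  minimal stand-in for real population history, adequate for method
  validation but not for inference about real cultivars.
* Anchoring trusts the supplied hits; it neither runs an aligner nor
  estimates gap sizes from alignment geometry.
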