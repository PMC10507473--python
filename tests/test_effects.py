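"""SNP effect classification: hand-built gene geometry plus a brute-force oracle.

The oracle classifies coding SNPs by mutating the chromosome, re-splicing and
re-translating the whole CDS, and diffing the two proteins — no codon index
arithmetic shared with the implementation under test.
"""

import random
from collections import Counter

import pytest
from Bio.Seq import Seq

from chlorisnp.effects import (
    DEFAULT_ALT_STARTS,
    EffectClassifier,
    classify_variant,
    summarize_effects,
)
from chlorisnp.genes import GeneModel
from chlorisnp.synthetic import simulate_reference

# -- a hand-built plus-strand gene on a 75 bp chromosome ---------------------
#
# positions:  1-20 prefix(A) | 21-29 exon1 ATG GCT TGG | 30-49 intron |
#             50-55 exon2 AAA TAA | 56-75 suffix(C)
PREFIX = "A" * 20
EXON1 = "ATGGCTTGG"
INTRON = "GTAAGTCCCCCCCCCCATAG"
EXON2 = "AAATAA"
SUFFIX = "C" * 20
CHROM_T = PREFIX + EXON1 + INTRON + EXON2 + SUFFIX

G1 = GeneModel(
    gene_id="g1",
    chrom="chrT",
    strand="+",
    exons=[(21, 29), (50, 55)],
    cds=[(21, 29), (50, 55)],
)

# its exact mirror image on the reverse-complemented chromosome
CHROM_R = str(Seq(CHROM_T).reverse_complement())
N = len(CHROM_T)
G2 = GeneModel(
    gene_id="g2",
    chrom="chrR",
    strand="-",
    exons=[(N - 55 + 1, N - 50 + 1), (N - 29 + 1, N - 21 + 1)],
    cds=[(N - 55 + 1, N - 50 + 1), (N - 29 + 1, N - 21 + 1)],
)

REF = {"chrT": CHROM_T, "chrR": CHROM_R}


@pytest.fixture
def clf():
    return EffectClassifier([G1, G2], REF, flank_bp=10)


def category(clf, chrom, pos, alt, ref=None):
    ref = ref or REF[chrom][pos - 1]
    calls = clf.classify(chrom, pos, ref, alt)
    assert len(calls) == 1
    return calls[0].category


class TestCodingCategories:
    def test_synonymous_third_position(self, clf):
        # GCT -> GCC, both alanine
        assert category(clf, "chrT", 26, "C") == "synonymous_variant"

    def test_missense(self, clf):
        # GCT -> GAT, Ala -> Asp
        assert category(clf, "chrT", 25, "A") == "missense_variant"

    def test_stop_gained(self, clf):
        # TGG -> TAG
        assert category(clf, "chrT", 28, "A") == "stop_gained"

    def test_stop_lost_and_retained(self, clf):
        # terminal TAA -> TCA (Ser) vs TAG (still stop)
        assert category(clf, "chrT", 54, "C") == "stop_lost"
        assert category(clf, "chrT", 55, "G") == "stop_retained_variant"

    def test_start_codon_fate_depends_on_alternative_start_set(self, clf):
        # ATG -> TTG / CTG are recognised alternative initiators
        assert category(clf, "chrT", 21, "T") == "initiator_codon_variant"
        assert category(clf, "chrT", 21, "C") == "initiator_codon_variant"
        # ATG -> ACG is not
        assert category(clf, "chrT", 22, "C") == "start_lost"
        assert {"TTG", "CTG"} == set(DEFAULT_ALT_STARTS)

    def test_empty_alt_start_set_makes_all_start_changes_lost(self):
        strict = EffectClassifier([G1], {"chrT": CHROM_T}, flank_bp=10,
                                  alt_starts=frozenset())
        assert category(strict, "chrT", 21, "T") == "start_lost"


class TestGeometry:
    def test_splice_donor_first_two_intronic_bases(self, clf):
        assert category(clf, "chrT", 30, "A") == "splice_donor_variant"
        assert category(clf, "chrT", 31, "A") == "splice_donor_variant"

    def test_splice_acceptor_last_two_intronic_bases(self, clf):
        assert category(clf, "chrT", 48, "C") == "splice_acceptor_variant"
        assert category(clf, "chrT", 49, "C") == "splice_acceptor_variant"

    def test_splice_region_intronic_window(self, clf):
        # 3..8 bases from either junction
        assert category(clf, "chrT", 32, "G") == "splice_region_variant"
        assert category(clf, "chrT", 37, "G") == "splice_region_variant"
        assert category(clf, "chrT", 42, "G") == "splice_region_variant"

    def test_deep_intron(self, clf):
        # 11 from the donor, 10 from the acceptor
        assert category(clf, "chrT", 40, "G") == "intron_variant"

    def test_flank_boundary_exact(self, clf):
        # flank 10: span starts at 21, so 11 is the outermost upstream base
        assert category(clf, "chrT", 11, "G") == "upstream_gene_variant"
        assert category(clf, "chrT", 10, "G") == "intergenic_region"
        # span ends at 55: 65 is the outermost downstream base
        assert category(clf, "chrT", 65, "G") == "downstream_gene_variant"
        assert category(clf, "chrT", 66, "G") == "intergenic_region"

    def test_default_flank_is_5kb(self):
        chrom = "A" * 6000 + EXON1 + "C" * 6000
        gene = GeneModel("g", "c", "+", exons=[(6001, 6009)], cds=[(6001, 6009)])
        clf = EffectClassifier([gene], {"c": chrom})
        assert category(clf, "c", 1001, "G", ref="A") == "upstream_gene_variant"
        assert category(clf, "c", 1000, "G", ref="A") == "intergenic_region"
        assert category(clf, "c", 11009, "G", ref="C") == "downstream_gene_variant"
        assert category(clf, "c", 11010, "G", ref="C") == "intergenic_region"

    def test_upstream_downstream_follow_strand(self, clf):
        # before g1 (+) is upstream; the mirrored position before g2 (-)
        # lies after its span, which is also its 5' side
        assert category(clf, "chrT", 15, "G") == "upstream_gene_variant"
        assert category(clf, "chrR", N - 15 + 1, "C") == "upstream_gene_variant"
        assert category(clf, "chrT", 60, "G") == "downstream_gene_variant"
        assert category(clf, "chrR", N - 60 + 1, "G") == "downstream_gene_variant"


class TestStrandSymmetry:
    @pytest.mark.parametrize(
        "pos,alt",
        [(21, "T"), (22, "C"), (25, "A"), (26, "C"), (28, "A"), (54, "C"),
         (55, "G"), (30, "A"), (49, "C"), (35, "G"), (40, "G")],
    )
    def test_mirror_variant_same_category(self, clf, pos, alt):
        mirror_pos = N - pos + 1
        mirror_alt = str(Seq(alt).complement())
        assert category(clf, "chrT", pos, alt) == category(
            clf, "chrR", mirror_pos, mirror_alt
        )


class TestInputValidation:
    def test_reference_base_mismatch(self, clf):
        with pytest.raises(ValueError, match="reference base"):
            clf.classify("chrT", 21, "G", "T")

    def test_unknown_chromosome(self, clf):
        with pytest.raises(KeyError, match="not in reference"):
            clf.classify("chrX", 5, "A", "G")

    def test_position_out_of_range(self, clf):
        with pytest.raises(ValueError, match="outside"):
            clf.classify("chrT", 99, "A", "G")

    def test_utr_gene_models_rejected(self):
        # exon wider than CDS -> exonic non-coding position
        gene = GeneModel("u", "chrT", "+", exons=[(21, 29)], cds=[(21, 26)])
        clf = EffectClassifier([gene], {"chrT": CHROM_T}, flank_bp=10)
        with pytest.raises(ValueError, match="UTR"):
            clf.classify("chrT", 28, "G", "A")


class TestMultiGeneContexts:
    def test_one_call_per_overlapping_gene(self):
        chrom = "A" * 10 + EXON1 + "A" * 30 + EXON1 + "A" * 10
        g_a = GeneModel("a", "c", "+", exons=[(11, 19)], cds=[(11, 19)])
        g_b = GeneModel("b", "c", "+", exons=[(50, 58)], cds=[(50, 58)])
        clf = EffectClassifier([g_a, g_b], {"c": chrom}, flank_bp=40)
        calls = clf.classify("c", 30, "A", "G")
        assert [c.gene_id for c in calls] == ["a", "b"]
        assert [c.category for c in calls] == [
            "downstream_gene_variant",
            "upstream_gene_variant",
        ]

    def test_convenience_wrapper(self):
        calls = classify_variant(("chrT", 26, "T", "C"), [G1], {"chrT": CHROM_T})
        assert calls[0].category == "synonymous_variant"


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def effect_oracle(chrom, pos, ref, alt, genes, reference, flank_bp=5000):
    """(gene_id, category) pairs by whole-protein re-translation and plain loops."""
    out = []
    for gene in genes:
        if gene.chrom != chrom:
            continue
        s, e = gene.span
        if not (s - flank_bp <= pos <= e + flank_bp):
            continue
        if pos < s or pos > e:
            before = pos < s
            five_prime = before if gene.strand == "+" else not before
            out.append(
                (gene.gene_id,
                 "upstream_gene_variant" if five_prime else "downstream_gene_variant")
            )
            continue
        in_exon = any(a <= pos <= b for a, b in gene.exons)
        if not in_exon:
            out.append((gene.gene_id, _intron_oracle(gene, pos)))
            continue
        out.append((gene.gene_id, _coding_oracle(gene, pos, alt, reference)))
    if not out:
        out.append(("", "intergenic_region"))
    return sorted(out)


def _intron_oracle(gene, pos):
    lo, hi = next(i for i in gene.introns() if i[0] <= pos <= i[1])
    from_start, from_end = pos - lo + 1, hi - pos + 1
    donor, acceptor = (
        (from_start, from_end) if gene.strand == "+" else (from_end, from_start)
    )
    if acceptor <= 2:
        return "splice_acceptor_variant"
    if donor <= 2:
        return "splice_donor_variant"
    if donor <= 8 or acceptor <= 8:
        return "splice_region_variant"
    return "intron_variant"


def _coding_oracle(gene, pos, alt, reference):
    seq = reference[gene.chrom]
    mut = seq[: pos - 1] + alt + seq[pos:]
    ref_cds = gene.cds_sequence(seq)
    alt_cds = gene.cds_sequence(mut)
    diff = [i for i in range(len(ref_cds)) if ref_cds[i] != alt_cds[i]]
    assert len(diff) == 1
    codon_no = diff[0] // 3
    ref_codon = ref_cds[codon_no * 3 : codon_no * 3 + 3]
    alt_codon = alt_cds[codon_no * 3 : codon_no * 3 + 3]
    if codon_no == 0:
        return (
            "initiator_codon_variant"
            if alt_codon in DEFAULT_ALT_STARTS
            else "start_lost"
        )
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_no == len(ref_cds) // 3 - 1 and ref_aa == "*":
        return "stop_retained_variant" if alt_aa == "*" else "stop_lost"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == alt_aa:
        return "synonymous_variant"
    return "missense_variant"


def run_oracle_comparison(seed, n_random, n_genic, n_genes=10, chrom_length=30_000):
    """Classifier vs oracle over random and gene-targeted SNPs; returns tally."""
    seqs, genes = simulate_reference(
        seed=seed, n_chrom=2, chrom_length=chrom_length, n_genes=n_genes
    )
    clf = EffectClassifier(genes, seqs)
    rnd = random.Random(seed)
    cases = []
    chroms = sorted(seqs)
    for _ in range(n_random):
        chrom = rnd.choice(chroms)
        cases.append((chrom, rnd.randint(1, len(seqs[chrom]))))
    for _ in range(n_genic):
        gene = rnd.choice(genes)
        s, e = gene.span
        cases.append((gene.chrom, rnd.randint(s, e)))
    tally = Counter()
    strands = set()
    for chrom, pos in cases:
        ref = seqs[chrom][pos - 1]
        alt = rnd.choice([b for b in "ACGT" if b != ref])
        got = sorted((c.gene_id, c.category) for c in clf.classify(chrom, pos, ref, alt))
        want = effect_oracle(chrom, pos, ref, alt, genes, seqs)
        assert got == want, (chrom, pos, ref, alt, got, want)
        for gene_id, cat in got:
            tally[cat] += 1
            if gene_id:
                strands.add(clf.genes[gene_id].strand)
    return tally, strands


class TestAgainstOracle:
    def test_full_agreement_on_simulated_genome(self):
        tally, strands = run_oracle_comparison(seed=23, n_random=400, n_genic=400)
        assert strands == {"+", "-"}
        for must_see in ("missense_variant", "synonymous_variant",
                         "intron_variant", "upstream_gene_variant",
                         "downstream_gene_variant"):
            assert tally[must_see] > 0, must_see


class TestSummaries:
    def test_exact_percent_arithmetic(self):
        summary = summarize_effects(
            {"synonymous_variant": 1, "missense_variant": 3}
        )
        by = summary.set_index("category")["percent"]
        assert by["synonymous_variant"] == 25.0
        assert by["missense_variant"] == 75.0

    def test_rounding_to_three_decimals(self):
        summary = summarize_effects(
            {"synonymous_variant": 1, "missense_variant": 1, "intron_variant": 1}
        )
        assert set(summary["percent"]) == {33.333}

    def test_percents_sum_to_100_within_rounding(self):
        counts = Counter(
            {
                "intergenic_region": 56451,
                "intron_variant": 9067,
                "missense_variant": 7706,
                "synonymous_variant": 7241,
                "upstream_gene_variant": 24930,
                "downstream_gene_variant": 24114,
                "splice_region_variant": 153,
                "stop_gained": 31,
            }
        )
        summary = summarize_effects(counts)
        assert summary["count"].sum() == sum(counts.values())
        assert summary["percent"].sum() == pytest.approx(100.0, abs=0.005)

    def test_single_call_is_100_percent(self, clf):
        calls = clf.classify("chrT", 40, "C", "G")
        summary = summarize_effects(calls)
        assert list(summary["percent"]) == [100.0]

    def test_empty_input_warns(self):
        with pytest.warns(RuntimeWarning, match="no effect calls"):
            summary = summarize_effects([])
        assert summary.empty

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown categories"):
            summarize_effects({"frameshift_variant": 1})
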