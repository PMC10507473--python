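"""Synthetic cohort generator: reference, gene models, truth dosages, call sets.

Emulates a resequencing study of a mixed-ploidy forage-grass cohort: five
cultivars (three diploid, two tetraploid), ~94 samples, shallow coverage
(~2.3x), two SNP callers that disagree on a fraction of sites, and tetraploid
genotypes generated under either a tetrasomic (autotetraploid) model or a
two-subgenome (allotetraploid) model, then collapsed onto diploid-style calls
against a single diploid reference.

Dosage models
-------------
Diploid sample at a locus with alternate-allele frequency q: dosage ~ Bin(2, q).
Autotetraploid: dosage ~ Bin(4, q) (tetrasomic inheritance, one ancestral
genome doubled).  Allotetraploid: two independent disomic subgenomes, each
Bin(2, q); with probability ``subgenome_divergence`` a locus is a fixed
inter-subgenome difference — one subgenome fixed for the reference allele,
the other for the alternate, and the diploid reference population carries no
copy of the alternate.  At subgenome_divergence = 0 the allo model is
distributionally identical to the auto model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .callset import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    Callset,
    SampleMetadata,
)
from .genes import GeneModel

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

DEFAULT_CULTIVARS: tuple[tuple[str, int, int], ...] = (
    ("Finecut", 2, 21),
    ("Tolgar", 2, 22),
    ("Endura", 2, 21),
    ("Mariner", 4, 15),
    ("Toro", 4, 15),
)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults emulate the study conditions: 94 samples over five cultivars
    (64 diploid, 30 tetraploid), ~2.3x mean depth, ~30% caller disagreement.
    """

    seed: int = 0
    n_loci: int = 5000
    cultivars: tuple[tuple[str, int, int], ...] = DEFAULT_CULTIVARS
    origin_model: str = "auto"  # 'auto' | 'allo'
    subgenome_divergence: float = 0.3
    # Beta(a, b) for per-locus alternate-allele frequency, or a float for a
    # point mass (useful in closed-form checks).
    ancestral_freq_dist: tuple[float, float] | float = (2.0, 2.0)
    # hierarchical ancestry: the diploid cultivars share one lineage (common
    # ancestor), the tetraploid cultivars another; each lineage perturbs the
    # ancestral frequency by U(-lineage_drift, lineage_drift) before
    # cultivar-level perturbation.
    lineage_drift: float = 0.35
    cultivar_drift: float = 0.1
    mean_depth: float = 2.3
    # site-level coverage overdispersion: per-locus depth rate multiplier
    # ~ Gamma(depth_shape, 1/depth_shape) (mean 1).  Real shallow short-read
    # coverage is strongly overdispersed across loci (mappability, GC);
    # without it, a depth>=4 genotype filter at 2.3x mean leaves no sites.
    # None = plain Poisson.
    depth_shape: float | None = 1.0
    missing_rate: float = 0.05
    call_error_rate: float = 0.02
    caller_jitter: float = 0.3

    def __post_init__(self) -> None:
        if self.origin_model not in ("auto", "allo"):
            raise ValueError("origin_model must be 'auto' or 'allo'")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        for name, p, n in self.cultivars:
            if p not in (2, 4):
                raise ValueError(f"cultivar {name}: ploidy must be 2 or 4")
            if n < 1:
                raise ValueError(f"cultivar {name}: n_samples must be >= 1")
        for attr in (
            "subgenome_divergence",
            "lineage_drift",
            "cultivar_drift",
            "missing_rate",
            "call_error_rate",
            "caller_jitter",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.depth_shape is not None and self.depth_shape <= 0:
            raise ValueError("depth_shape must be positive or None")


@dataclass
class TruthSet:
    """True allele dosages and the latent quantities behind them."""

    metadata: SampleMetadata
    dosages: np.ndarray  # (n_loci, n_samples) int8: alt-allele copies
    ploidy: np.ndarray  # (n_samples,) int
    alt_freq: np.ndarray  # (n_loci,) ancestral alternate-allele frequency
    fixed_diff: np.ndarray  # (n_loci,) bool: allo fixed inter-subgenome difference

    def collapsed_calls(self) -> np.ndarray:
        """Collapsed-diploid call codes (dosage not estimated for tetraploids)."""
        calls = np.full(self.dosages.shape, HET, dtype=np.int8)
        calls[self.dosages == 0] = HOM_REF
        calls[self.dosages == self.ploidy[None, :]] = HOM_ALT
        return calls


def _make_metadata(cultivars) -> SampleMetadata:
    rows = []
    for name, ploidy, n in cultivars:
        for i in range(1, n + 1):
            rows.append((f"{name}_{i:02d}", name, ploidy))
    return SampleMetadata(
        pd.DataFrame(rows, columns=["sample_id", "cultivar", "ploidy"])
    )


def simulate_truth(config: SimulationConfig) -> TruthSet:
    """Draw per-sample true dosages under the configured origin model."""
    rng = np.random.default_rng([config.seed, 0])
    L = config.n_loci
    if isinstance(config.ancestral_freq_dist, (int, float)):
        alt_freq = np.full(L, float(config.ancestral_freq_dist))
    else:
        a, b = config.ancestral_freq_dist
        alt_freq = rng.beta(a, b, size=L)
    fixed_diff = np.zeros(L, dtype=bool)
    if config.origin_model == "allo":
        fixed_diff = rng.random(L) < config.subgenome_divergence

    meta = _make_metadata(config.cultivars)
    n_samples = len(meta.table)
    ploidy = meta.table["ploidy"].to_numpy()
    dosages = np.zeros((L, n_samples), dtype=np.int8)

    lineage_shift = {
        2: rng.uniform(-config.lineage_drift, config.lineage_drift, size=L),
        4: rng.uniform(-config.lineage_drift, config.lineage_drift, size=L),
    }
    col = 0
    for name, pld, n in config.cultivars:
        drift = rng.uniform(-config.cultivar_drift, config.cultivar_drift, size=L)
        q = np.clip(alt_freq + lineage_shift[pld] + drift, 0.0, 1.0)
        # fixed inter-subgenome differences: the alternate allele belongs to
        # the second (unrepresented) subgenome only
        q = np.where(fixed_diff, 0.0, q)
        for _ in range(n):
            if pld == 2:
                d = rng.binomial(2, q)
            elif config.origin_model == "auto":
                d = rng.binomial(4, q)
            else:
                sub_a = rng.binomial(2, q)
                sub_b = np.where(fixed_diff, 2, rng.binomial(2, q))
                d = sub_a + sub_b
            dosages[:, col] = d
            col += 1
    return TruthSet(
        metadata=meta,
        dosages=dosages,
        ploidy=ploidy,
        alt_freq=alt_freq,
        fixed_diff=fixed_diff,
    )


def _site_table(
    rng: np.random.Generator, n_loci: int, reference: dict[str, str] | None
) -> pd.DataFrame:
    if reference is None:
        pos = (np.arange(n_loci) + 1) * 10
        refs = _BASES[rng.integers(0, 4, n_loci)]
        alt_off = rng.integers(1, 4, n_loci)
        alts = _BASES[(np.searchsorted(_BASES, refs) + alt_off) % 4]
        return pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "ref": refs, "alt": alts}
        )
    # place loci on the provided reference, proportional to chromosome length
    names = sorted(reference)
    lengths = np.array([len(reference[c]) for c in names])
    total = lengths.sum()
    if total < n_loci:
        raise ValueError("reference too short for requested n_loci")
    flat = np.sort(rng.choice(total, size=n_loci, replace=False))
    bounds = np.cumsum(lengths)
    rows = []
    for f in flat:
        ci = int(np.searchsorted(bounds, f, side="right"))
        pos = int(f - (bounds[ci] - lengths[ci])) + 1
        ref = reference[names[ci]][pos - 1].upper()
        if ref not in "ACGT":
            ref = "A"
        choices = [b for b in "ACGT" if b != ref]
        alt = choices[int(rng.integers(0, 3))]
        rows.append((names[ci], pos, ref, alt))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def emit_callsets(
    truth: TruthSet,
    config: SimulationConfig,
    reference: dict[str, str] | None = None,
) -> tuple[Callset, Callset, SampleMetadata]:
    """Observe the truth through depth, missingness, call error and caller jitter.

    Returns two call sets sharing one truth: genotypes are identical at shared
    sites, but each site is dropped from exactly one of the two call sets with
    probability ``caller_jitter`` (split evenly), mimicking two SNP-discovery
    pipelines that disagree on site lists.
    """
    rng = np.random.default_rng([config.seed, 1])
    L, n_samples = truth.dosages.shape
    sites = _site_table(rng, L, reference)

    calls = truth.collapsed_calls()
    if config.depth_shape is None:
        rates = np.full(L, config.mean_depth)
    else:
        k = config.depth_shape
        rates = config.mean_depth * rng.gamma(k, 1.0 / k, size=L)
    depths = rng.poisson(rates[:, None], size=(L, n_samples)).astype(np.int32)

    # symmetric call error: swap to one of the other two states
    err = rng.random((L, n_samples)) < config.call_error_rate
    offset = rng.integers(1, 3, size=(L, n_samples)).astype(np.int8)
    calls = np.where(err, (calls + offset) % 3, calls).astype(np.int8)

    # genotypes with no covering read are missing, plus extra dropout
    miss = (depths < 1) | (rng.random((L, n_samples)) < config.missing_rate)
    calls[miss] = MISSING

    drop = rng.random(L) < config.caller_jitter
    drop_from_a = rng.random(L) < 0.5
    keep_a = ~(drop & drop_from_a)
    keep_b = ~(drop & ~drop_from_a)

    def subset(keep: np.ndarray) -> Callset:
        idx = np.flatnonzero(keep)
        return Callset(
            samples=truth.metadata.table["sample_id"].tolist(),
            sites=sites.iloc[idx].reset_index(drop=True),
            calls=calls[idx].copy(),
            depths=depths[idx].copy(),
        )

    return subset(keep_a), subset(keep_b), truth.metadata


# ---------------------------------------------------------------------------
# reference + gene-model simulation
# ---------------------------------------------------------------------------


def simulate_reference(
    seed: int,
    n_chrom: int = 2,
    chrom_length: int = 50_000,
    n_genes: int = 20,
    min_exons: int = 1,
    max_exons: int = 3,
    codon_range: tuple[int, int] = (30, 120),
    intron_range: tuple[int, int] = (40, 200),
    min_gap: int = 50,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random chromosomes with embedded UTR-less protein-coding genes.

    Every gene starts with ATG, ends with a stop codon, has no internal
    in-frame stop, and CDS == exons.  Strands alternate so both are
    represented.  Raises ValueError when the genes cannot be packed into the
    requested chromosome length.
    """
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    rng = np.random.default_rng([seed, 2])
    sequences: dict[str, str] = {}
    chrom_seqs: dict[str, np.ndarray] = {}
    for i in range(n_chrom):
        chrom_seqs[f"chr{i + 1}"] = _BASES[rng.integers(0, 4, chrom_length)].copy()

    codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    ]
    genes: list[GeneModel] = []
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    gene_no = 0
    for ci, count in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = min_gap + 1  # 1-based
        for _ in range(count):
            n_codons = int(rng.integers(codon_range[0], codon_range[1] + 1))
            cds = (
                "ATG"
                + "".join(
                    codons[int(k)]
                    for k in rng.integers(0, len(codons), n_codons - 2)
                )
                + _STOPS[int(rng.integers(0, 3))]
            )
            n_exons = int(rng.integers(min_exons, max_exons + 1))
            n_exons = min(n_exons, n_codons)  # each exon needs >= 1 base
            # split the CDS into n_exons pieces of random positive length
            if n_exons > 1:
                cuts = np.sort(
                    rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False)
                )
            else:
                cuts = np.array([], dtype=int)
            pieces = np.split(np.arange(len(cds)), cuts)
            intron_lens = rng.integers(
                intron_range[0], intron_range[1] + 1, size=max(n_exons - 1, 0)
            )
            strand = "+" if gene_no % 2 == 0 else "-"
            genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
            # genomic-order exon lengths: for '-' the transcription-order
            # pieces appear reversed along the genome
            piece_lens = [len(p) for p in pieces]
            if strand == "-":
                piece_lens = piece_lens[::-1]
            span_len = sum(piece_lens) + int(intron_lens.sum())
            if cursor + span_len - 1 + min_gap > chrom_length:
                raise ValueError(
                    f"cannot pack {n_genes} genes into {n_chrom} x "
                    f"{chrom_length} bp chromosomes"
                )
            exons: list[tuple[int, int]] = []
            p = cursor
            gpos = 0
            for k, ln in enumerate(piece_lens):
                exons.append((p, p + ln - 1))
                chrom_seqs[chrom][p - 1 : p + ln - 1] = np.array(
                    list(genomic[gpos : gpos + ln])
                )
                gpos += ln
                p += ln
                if k < len(piece_lens) - 1:
                    p += int(intron_lens[k])
            gene_no += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gene_no:04d}",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds=list(exons),
                )
            )
            cursor = exons[-1][1] + 1 + min_gap + int(rng.integers(0, min_gap + 1))
    sequences = {c: "".join(arr) for c, arr in chrom_seqs.items()}
    return sequences, genes
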