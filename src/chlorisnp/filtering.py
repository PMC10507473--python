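"""The SNP filtering cascade.

Order of operations, mirroring the study design:

1. intersect the two callers' site lists (genotypes from the primary caller);
2. split samples into diploid-only and tetraploid-only call sets;
3. per ploidy set: depth-mask genotypes (< min_depth -> missing), drop sites
   exceeding the missingness ceiling, drop sites below the MAF floor;
4. per ploidy set: the two heterozygosity-excess rules (guards against
   collapsed paralogs / mapping artifacts);
5. intersect the filtered diploid and tetraploid site lists into the
   high-confidence common set.

Every step appends to a :class:`FilterReport` whose counts telescope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .callset import HET, HOM_ALT, HOM_REF, MISSING, Callset, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class FilterThresholds:
    """Cascade thresholds; defaults are the study's published settings."""

    min_maf: float = 0.1
    max_missing_fraction: float = 0.5
    min_depth: int = 4
    het_all_threshold: float = 0.75
    het_absent_hom_threshold: float = 0.60
    # denominator for the two het rules: 'called' (non-missing genotypes)
    # or 'all' (every sample column)
    het_denominator: str = "called"

    def __post_init__(self) -> None:
        for attr in (
            "min_maf",
            "max_missing_fraction",
            "het_all_threshold",
            "het_absent_hom_threshold",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if self.het_denominator not in ("called", "all"):
            raise ValueError("het_denominator must be 'called' or 'all'")


@dataclass
class FilterReport:
    """Ordered per-step attrition: (step, sites_in, removed, sites_out)."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, sites_in: int, sites_out: int) -> None:
        removed = sites_in - sites_out
        if removed < 0:
            raise ValueError(f"step {name!r}: negative removal count")
        self.steps.append((name, sites_in, removed, sites_out))

    def extend(self, other: "FilterReport") -> None:
        self.steps.extend(other.steps)

    def validate_chain(self) -> None:
        for (n1, _, _, out1), (n2, in2, _, _) in zip(self.steps, self.steps[1:]):
            if out1 != in2:
                raise ValueError(
                    f"attrition chain broken between {n1!r} (out={out1}) "
                    f"and {n2!r} (in={in2})"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "sites_in", "removed", "sites_out"]
        )


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    """Write the attrition table as TSV after enforcing chain consistency."""
    report.validate_chain()
    report.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def intersect_callsets(a: Callset, b: Callset) -> Callset:
    """Sites present in both call sets with identical (chrom, pos, ref, alt).

    Genotypes and depths come from call set ``a`` (the primary caller); the
    second caller contributes only its site list.  Sites at a shared position
    whose ref allele disagrees are excluded and logged.
    """
    for name, cs in (("A", a), ("B", b)):
        if not cs.is_sorted():
            raise ValueError(f"call set {name} is not sorted by (chrom, pos)")
    keys_a = a.site_keys()
    keys_b = set(b.site_keys())
    keep = np.fromiter((k in keys_b for k in keys_a), dtype=bool, count=len(keys_a))

    pos_b = set(zip(b.sites["chrom"], b.sites["pos"]))
    for i in np.flatnonzero(~keep):
        cp = (a.sites["chrom"].iloc[i], a.sites["pos"].iloc[i])
        if cp in pos_b:
            logger.warning(
                "site %s:%s shared by position but allele-mismatched; excluded",
                *cp,
            )
    return a.take_sites(np.flatnonzero(keep))


def split_by_ploidy(
    callset: Callset, metadata: SampleMetadata
) -> tuple[Callset, Callset]:
    """Partition sample columns into a diploid and a tetraploid call set."""
    known = set(metadata.table["sample_id"])
    unknown = [s for s in callset.samples if s not in known]
    if unknown:
        raise KeyError(f"samples absent from metadata: {unknown}")
    ploidy = {r.sample_id: r.ploidy for r in metadata.table.itertuples()}
    dips = [s for s in callset.samples if ploidy[s] == 2]
    tets = [s for s in callset.samples if ploidy[s] == 4]
    dip_cs = callset.take_samples(dips) if dips else _empty_samples(callset)
    tet_cs = callset.take_samples(tets) if tets else _empty_samples(callset)
    if not dips:
        logger.warning("diploid set has 0 samples")
    if not tets:
        logger.warning("tetraploid set has 0 samples")
    return dip_cs, tet_cs


def _empty_samples(callset: Callset) -> Callset:
    return Callset(
        samples=[],
        sites=callset.sites.copy(),
        calls=np.zeros((callset.n_sites, 0), dtype=np.int8),
        depths=np.zeros((callset.n_sites, 0), dtype=np.int32),
    )


def apply_threshold_filters(
    callset: Callset, thresholds: FilterThresholds
) -> tuple[Callset, FilterReport]:
    """Depth-mask genotypes, then drop high-missingness sites, then low-MAF sites.

    The order matters: depth masking creates missingness that the missingness
    filter must see, and MAF is computed over post-mask non-missing calls.
    """
    report = FilterReport()
    if callset.n_sites == 0 or callset.n_samples == 0:
        report.add("depth_mask", callset.n_sites, callset.n_sites)
        report.add("max_missing", callset.n_sites, callset.n_sites)
        report.add("min_maf", callset.n_sites, callset.n_sites)
        return callset.copy(), report

    cs = callset.copy()
    low_dp = cs.depths < thresholds.min_depth
    cs.calls = np.where(low_dp, MISSING, cs.calls).astype(np.int8)
    report.add("depth_mask", cs.n_sites, cs.n_sites)

    missing_frac = (cs.calls == MISSING).mean(axis=1)
    keep = missing_frac <= thresholds.max_missing_fraction
    n_in = cs.n_sites
    cs = cs.take_sites(np.flatnonzero(keep))
    report.add("max_missing", n_in, cs.n_sites)

    n_called = (cs.calls != MISSING).sum(axis=1)
    n_alt = (cs.calls == HET).sum(axis=1) + 2 * (cs.calls == HOM_ALT).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = np.where(n_called > 0, n_alt / (2 * n_called), 0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = ~(maf < thresholds.min_maf)
    n_in = cs.n_sites
    cs = cs.take_sites(np.flatnonzero(keep))
    report.add("min_maf", n_in, cs.n_sites)
    return cs, report


def apply_het_excess_filters(
    callset: Callset, thresholds: FilterThresholds
) -> tuple[Callset, FilterReport]:
    """The two heterozygosity-excess rules, applied in order.

    Rule 1: remove a site if the heterozygote proportion h exceeds
    ``het_all_threshold`` (strictly).  Rule 2: remove a site if one homozygote
    class is absent AND h strictly exceeds ``het_absent_hom_threshold``.
    h is computed over non-missing calls by default (``het_denominator``).
    Sites with zero non-missing calls are removed with their own reason code.
    """
    report = FilterReport()
    cs = callset.copy()

    n_called = (cs.calls != MISSING).sum(axis=1)
    n_in = cs.n_sites
    keep = n_called > 0
    cs = cs.take_sites(np.flatnonzero(keep))
    report.add("all_missing", n_in, cs.n_sites)

    def het_prop(c: Callset) -> np.ndarray:
        n_het = (c.calls == HET).sum(axis=1)
        if thresholds.het_denominator == "called":
            denom = (c.calls != MISSING).sum(axis=1)
        else:
            denom = np.full(c.n_sites, c.n_samples)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom > 0, n_het / denom, 0.0)

    h = het_prop(cs)
    keep = ~(h > thresholds.het_all_threshold)
    n_in = cs.n_sites
    cs = cs.take_sites(np.flatnonzero(keep))
    report.add("het_excess", n_in, cs.n_sites)

    h = het_prop(cs)
    has_hom_ref = (cs.calls == HOM_REF).any(axis=1)
    has_hom_alt = (cs.calls == HOM_ALT).any(axis=1)
    absent_hom = ~(has_hom_ref & has_hom_alt)
    keep = ~(absent_hom & (h > thresholds.het_absent_hom_threshold))
    n_in = cs.n_sites
    cs = cs.take_sites(np.flatnonzero(keep))
    report.add("het_absent_hom", n_in, cs.n_sites)
    return cs, report


def intersect_ploidy_sets(dip: Callset, tet: Callset) -> pd.DataFrame:
    """High-confidence common site list: (chrom, pos, ref, alt) in both sets.

    ``require_alleles`` behaviour: alleles must match, the stricter reading;
    see :func:`intersect_ploidy_sets_by_position` for the position-only one.
    """
    keys_tet = set(tet.site_keys())
    keep = np.fromiter(
        (k in keys_tet for k in dip.site_keys()), dtype=bool, count=dip.n_sites
    )
    return dip.sites.iloc[np.flatnonzero(keep)].reset_index(drop=True)


def intersect_ploidy_sets_by_position(dip: Callset, tet: Callset) -> pd.DataFrame:
    """Common site list matched on (chrom, pos) only."""
    keys_tet = set(zip(tet.sites["chrom"], tet.sites["pos"]))
    keep = np.fromiter(
        (k in keys_tet for k in zip(dip.sites["chrom"], dip.sites["pos"])),
        dtype=bool,
        count=dip.n_sites,
    )
    return dip.sites.iloc[np.flatnonzero(keep)].reset_index(drop=True)


def restrict_to_sites(callset: Callset, sites: pd.DataFrame) -> Callset:
    """Subset a callset to a (chrom, pos, ref, alt) site list."""
    wanted = set(pd.MultiIndex.from_frame(sites[["chrom", "pos", "ref", "alt"]]))
    keep = np.fromiter(
        (k in wanted for k in callset.site_keys()),
        dtype=bool,
        count=callset.n_sites,
    )
    return callset.take_sites(np.flatnonzero(keep))
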