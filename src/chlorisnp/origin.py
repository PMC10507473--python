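"""Auto- vs allotetraploid diagnosis from collapsed genotype calls.

An allotetraploid mapped to a single diploid reference shows (i) loci at which
(nearly) every tetraploid individual is heterozygous — fixed inter-subgenome
differences — and (ii) alternate alleles private to the tetraploids, absent
from the diploid cohort.  An autotetraploid, sharing one ancestral allele pool
with the diploids, shows neither beyond sampling noise, only a higher mean
heterozygosity (tetrasomic: 1 - p^4 - (1-p)^4 versus disomic 2p(1-p)).  The
classifier turns this qualitative argument into thresholds on the fixed-
heterozygosity and private-variant fractions, calibrated on the in-package
simulator and always reported in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .callset import HET, HOM_ALT, HOM_REF, MISSING, Callset, SampleMetadata


@dataclass
class HetProfile:
    """Heterozygosity summary for one cohort."""

    cohort: str  # 'diploid' | 'tetraploid'
    sample_het: pd.Series  # per-sample het rate over non-missing calls
    locus_het: np.ndarray  # per-locus het frequency over non-missing calls
    fixed_het_fraction: float  # loci with het frequency >= fixed_het_cutoff
    private_variant_fraction: float  # tetraploid-only: see het_profile
    locus_key: tuple  # fingerprint of the locus set (for comparability checks)

    def __post_init__(self) -> None:
        for name in ("fixed_het_fraction", "private_variant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")


@dataclass
class OriginThresholds:
    """Decision thresholds (artifact-defined, simulator-calibrated)."""

    t_fix: float = 0.3
    t_priv: float = 0.12
    fixed_het_cutoff: float = 0.9  # tolerates call error at ~2.3x depth


@dataclass
class OriginAssessment:
    diploid: HetProfile
    tetraploid: HetProfile
    delta_het: float
    verdict: str  # 'auto' | 'allo' | 'ambiguous'
    thresholds: OriginThresholds

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "delta_het": self.delta_het,
            "diploid_mean_het": float(self.diploid.sample_het.mean()),
            "tetraploid_mean_het": float(self.tetraploid.sample_het.mean()),
            "fixed_het_fraction": self.tetraploid.fixed_het_fraction,
            "private_variant_fraction": self.tetraploid.private_variant_fraction,
            "t_fix": self.thresholds.t_fix,
            "t_priv": self.thresholds.t_priv,
            "fixed_het_cutoff": self.thresholds.fixed_het_cutoff,
        }


def _cohort_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    called = calls != MISSING
    het = calls == HET
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_het = np.where(
            called.sum(axis=0) > 0, het.sum(axis=0) / called.sum(axis=0), 0.0
        )
        locus_het = np.where(
            called.sum(axis=1) > 0, het.sum(axis=1) / called.sum(axis=1), 0.0
        )
    return sample_het, locus_het


def het_profile(
    callset: Callset,
    metadata: SampleMetadata,
    fixed_het_cutoff: float = 0.9,
) -> dict[str, HetProfile]:
    """Heterozygosity profiles for the diploid and tetraploid cohorts.

    ``private_variant_fraction`` (tetraploid profile): among loci at which the
    alternate allele is observed in the tetraploids, the fraction where no
    diploid call carries it.  ``fixed_het_fraction`` is reported per cohort.
    """
    profiles: dict[str, HetProfile] = {}
    key = (
        callset.n_sites,
        tuple(callset.sites["chrom"].iloc[:: max(1, callset.n_sites // 8 or 1)]),
        tuple(callset.sites["pos"].iloc[:: max(1, callset.n_sites // 8 or 1)]),
    )
    cohorts = {
        "diploid": metadata.samples_with_ploidy(2),
        "tetraploid": metadata.samples_with_ploidy(4),
    }
    subsets = {}
    for name, samples in cohorts.items():
        samples = [s for s in samples if s in callset.samples]
        if not samples:
            raise ValueError(f"cohort {name!r} has zero samples in the callset")
        subsets[name] = callset.take_samples(samples)

    tet_calls = subsets["tetraploid"].calls
    dip_calls = subsets["diploid"].calls
    tet_has_alt = ((tet_calls == HET) | (tet_calls == HOM_ALT)).any(axis=1)
    dip_has_alt = ((dip_calls == HET) | (dip_calls == HOM_ALT)).any(axis=1)
    n_tet_snp = int(tet_has_alt.sum())
    private_fraction = (
        float((tet_has_alt & ~dip_has_alt).sum() / n_tet_snp) if n_tet_snp else 0.0
    )

    for name, cs in subsets.items():
        sample_het, locus_het = _cohort_stats(cs.calls)
        profiles[name] = HetProfile(
            cohort=name,
            sample_het=pd.Series(sample_het, index=cs.samples),
            locus_het=locus_het,
            fixed_het_fraction=float((locus_het >= fixed_het_cutoff).mean()),
            private_variant_fraction=(
                private_fraction if name == "tetraploid" else 0.0
            ),
            locus_key=key,
        )
    return profiles


def classify_origin(
    diploid_profile: HetProfile,
    tetraploid_profile: HetProfile,
    thresholds: OriginThresholds | None = None,
) -> OriginAssessment:
    """Deterministic verdict from the two cohort profiles.

    allo  if fixed_het_fraction > t_fix OR private_variant_fraction > t_priv;
    auto  if both fall below half their thresholds;
    ambiguous otherwise.
    """
    thresholds = thresholds or OriginThresholds()
    if diploid_profile.locus_key != tetraploid_profile.locus_key:
        raise ValueError("profiles computed on different locus sets")
    fix = tetraploid_profile.fixed_het_fraction
    priv = tetraploid_profile.private_variant_fraction
    if fix > thresholds.t_fix or priv > thresholds.t_priv:
        verdict = "allo"
    elif fix < thresholds.t_fix / 2 and priv < thresholds.t_priv / 2:
        verdict = "auto"
    else:
        verdict = "ambiguous"
    delta = float(
        tetraploid_profile.sample_het.mean() - diploid_profile.sample_het.mean()
    )
    return OriginAssessment(
        diploid=diploid_profile,
        tetraploid=tetraploid_profile,
        delta_het=delta,
        verdict=verdict,
        thresholds=thresholds,
    )


def mapping_concordance_summary(
    stats: pd.DataFrame, max_delta: float = 1.0
) -> dict:
    """Difference in mapped-read percentage between cohorts.

    ``stats`` columns: cohort, pct_mapped[, pct_properly_paired].  Flags
    "concordant" when the absolute mapped-percentage difference is below
    ``max_delta`` percentage points.
    """
    required = {"diploid", "tetraploid"}
    present = set(stats["cohort"])
    missing = required - present
    if missing:
        raise ValueError(f"mapping stats missing cohort(s): {sorted(missing)}")
    by = stats.set_index("cohort")
    delta = abs(
        float(by.loc["diploid", "pct_mapped"])
        - float(by.loc["tetraploid", "pct_mapped"])
    )
    out = {"delta_pct_mapped": round(delta, 10), "concordant": delta < max_delta}
    if "pct_properly_paired" in stats.columns:
        out["delta_pct_properly_paired"] = abs(
            float(by.loc["diploid", "pct_properly_paired"])
            - float(by.loc["tetraploid", "pct_properly_paired"])
        )
    return out
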