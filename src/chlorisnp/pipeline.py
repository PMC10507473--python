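"""End-to-end orchestration: simulate/load -> intersect -> split -> filter ->
het rules -> common set -> tree -> annotate -> origin, with a run manifest.

Stage order mirrors the study's analysis.  A single seed governs every
stochastic step, and re-running with an identical config reproduces identical
outputs (the manifest contains no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .callset import (
    Callset,
    SampleMetadata,
    read_metadata,
    read_vcf,
    write_metadata,
    write_vcf,
)
from .effects import classify_callset_sites, summarize_effects, write_effects_tsv
from .filtering import (
    FilterReport,
    FilterThresholds,
    apply_het_excess_filters,
    apply_threshold_filters,
    intersect_callsets,
    intersect_ploidy_sets,
    restrict_to_sites,
    split_by_ploidy,
    write_filter_report,
)
from .genes import read_fasta, read_gff3, write_fasta, write_gff3
from .origin import (
    OriginThresholds,
    classify_origin,
    het_profile,
    mapping_concordance_summary,
)
from .phylogeny import (
    encode_collapsed,
    group_summary,
    nei_distance,
    nj_tree,
    write_distance_tsv,
    write_newick,
)
from .synthetic import SimulationConfig, emit_callsets, simulate_reference, simulate_truth

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and options for a full run.

    Either the three input paths (vcf_a, vcf_b, metadata) are given, or
    ``simulate`` holds a SimulationConfig and the inputs are generated.
    """

    seed: int = 0
    simulate: SimulationConfig | None = None
    vcf_a: str | None = None
    vcf_b: str | None = None
    metadata: str | None = None
    reference: str | None = None  # FASTA, for annotation
    gff3: str | None = None
    mapping_stats: str | None = None  # TSV: cohort, pct_mapped[, pct_properly_paired]
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    origin_thresholds: OriginThresholds = field(default_factory=OriginThresholds)
    annotate: bool = True
    flank_bp: int = 5000
    # simulated reference geometry (used when simulating and annotate=True)
    sim_n_chrom: int = 2
    sim_chrom_length: int = 200_000
    sim_n_genes: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        if "thresholds" in raw:
            raw["thresholds"] = FilterThresholds(**raw["thresholds"])
        if "origin_thresholds" in raw:
            raw["origin_thresholds"] = OriginThresholds(**raw["origin_thresholds"])
        return cls(**raw)

    def validate_paths(self) -> None:
        if self.simulate is None:
            for name in ("vcf_a", "vcf_b", "metadata"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(
                        f"config requires {name} (or a simulate block)"
                    )
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.annotate and self.simulate is None:
            for name in ("reference", "gff3"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"annotation enabled but {name} missing: {p}"
                    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.validate_paths()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "origin_thresholds": dataclasses.asdict(config.origin_thresholds),
        "inputs": {},
        "stages": {},
    }

    # --- stage: inputs -----------------------------------------------------
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            reference, genes = (
                simulate_reference(
                    sim.seed,
                    n_chrom=config.sim_n_chrom,
                    chrom_length=config.sim_chrom_length,
                    n_genes=config.sim_n_genes,
                )
                if config.annotate
                else (None, None)
            )
            truth = simulate_truth(sim)
            cs_a, cs_b, metadata = emit_callsets(truth, sim, reference=reference)
            write_vcf(cs_a, out / "caller_A.vcf")
            write_vcf(cs_b, out / "caller_B.vcf")
            write_metadata(metadata, out / "metadata.tsv")
            if reference is not None:
                write_fasta(reference, out / "reference.fasta")
                write_gff3(genes, out / "genes.gff3")
            manifest["inputs"]["simulated"] = dataclasses.asdict(sim)
        else:
            cs_a = read_vcf(config.vcf_a)
            cs_b = read_vcf(config.vcf_b)
            metadata = read_metadata(config.metadata)
            reference = read_fasta(config.reference) if config.reference else None
            genes = read_gff3(config.gff3) if config.gff3 else None
            for name in ("vcf_a", "vcf_b", "metadata", "reference", "gff3"):
                p = getattr(config, name)
                if p:
                    manifest["inputs"][name] = _sha256(Path(p))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("inputs", exc) from exc

    # --- stage: caller intersection ---------------------------------------
    try:
        merged = intersect_callsets(cs_a, cs_b)
        manifest["stages"]["intersect_callers"] = {
            "sites_a": cs_a.n_sites,
            "sites_b": cs_b.n_sites,
            "sites_common": merged.n_sites,
        }
    except Exception as exc:
        raise StageError("intersect_callers", exc) from exc

    # --- stage: ploidy split + filtering -----------------------------------
    try:
        dip, tet = split_by_ploidy(merged, metadata)
        filtered = {}
        for name, cs in (("diploid", dip), ("tetraploid", tet)):
            report = FilterReport()
            report.add("input", cs.n_sites, cs.n_sites)
            cs1, rep1 = apply_threshold_filters(cs, config.thresholds)
            report.extend(rep1)
            cs2, rep2 = apply_het_excess_filters(cs1, config.thresholds)
            report.extend(rep2)
            report.validate_chain()
            write_filter_report(report, out / f"attrition_{name}.tsv")
            filtered[name] = cs2
            manifest["stages"][f"filter_{name}"] = {
                "steps": report.steps,
                "sites_out": cs2.n_sites,
            }
    except Exception as exc:
        raise StageError("filtering", exc) from exc

    # --- stage: high-confidence common set ---------------------------------
    try:
        common = intersect_ploidy_sets(filtered["diploid"], filtered["tetraploid"])
        common.to_csv(out / "common_sites.tsv", sep="\t", index=False)
        manifest["stages"]["common_set"] = {"sites": len(common)}
    except Exception as exc:
        raise StageError("common_set", exc) from exc

    # --- stage: distance + tree --------------------------------------------
    try:
        tree_cs = restrict_to_sites(merged, common)
        gm = encode_collapsed(tree_cs)
        dist = nei_distance(gm)
        write_distance_tsv(dist, out / "nei_distances.tsv")
        tree = nj_tree(dist)
        write_newick(tree, out / "nj_tree.nwk")
        summary = group_summary(tree, metadata)
        summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False)
        manifest["stages"]["tree"] = {
            "n_leaves": len(gm.samples),
            "n_loci": len(gm.loci),
            "ploidy_separation": bool(summary.attrs["ploidy_separation"]),
        }
    except Exception as exc:
        raise StageError("tree", exc) from exc

    # --- stage: effect annotation -------------------------------------------
    if config.annotate and reference is not None and genes is not None:
        try:
            calls = classify_callset_sites(
                tree_cs.sites, genes, reference, flank_bp=config.flank_bp
            )
            eff = summarize_effects(calls)
            write_effects_tsv(eff, out / "effects_summary.tsv")
            manifest["stages"]["annotate"] = {
                "n_effect_calls": int(eff["count"].sum()) if len(eff) else 0,
            }
        except Exception as exc:
            raise StageError("annotate", exc) from exc

    # --- stage: ploidy origin ------------------------------------------------
    try:
        profiles = het_profile(
            merged, metadata,
            fixed_het_cutoff=config.origin_thresholds.fixed_het_cutoff,
        )
        assessment = classify_origin(
            profiles["diploid"], profiles["tetraploid"], config.origin_thresholds
        )
        result = assessment.to_dict()
        if config.mapping_stats:
            stats = pd.read_csv(config.mapping_stats, sep="\t")
            result["mapping_concordance"] = mapping_concordance_summary(stats)
        with open(out / "origin_assessment.json", "w") as fh:
            json.dump(result, fh, indent=2)
        manifest["stages"]["origin"] = {"verdict": assessment.verdict}
    except Exception as exc:
        raise StageError("origin", exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
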