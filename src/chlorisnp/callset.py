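"""Genotype call-set container and VCF / metadata I/O.

A :class:`Callset` holds biallelic SNP records as a site table plus dense
per-sample call and depth matrices.  Calls use the collapsed-diploid coding
used throughout the package: every sample, whatever its ploidy, is scored
hom_ref / het / hom_alt / missing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# call codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class Callset:
    """Biallelic SNP calls for a cohort.

    Parameters
    ----------
    samples
        Ordered sample identifiers (column order of ``calls``/``depths``).
    sites
        DataFrame with columns ``chrom, pos, ref, alt`` (1-based positions),
        one row per SNP, sorted by (chrom, pos).
    calls
        int8 array of shape (n_sites, n_samples); values in
        {HOM_REF, HET, HOM_ALT, MISSING}.
    depths
        int32 array of the same shape; per-genotype read depth.
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        n_sites, n_samples = len(self.sites), len(self.samples)
        if self.calls.shape != (n_sites, n_samples):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n_sites}, {n_samples})"
            )
        if self.depths.shape != (n_sites, n_samples):
            raise ValueError(
                f"depths shape {self.depths.shape} != ({n_sites}, {n_samples})"
            )
        bad = (self.sites["ref"] == self.sites["alt"]).to_numpy()
        if bad.any():
            raise ValueError("ref == alt at some sites; biallelic SNPs required")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_keys(self) -> pd.Index:
        """(chrom, pos, ref, alt) MultiIndex identifying each site."""
        return pd.MultiIndex.from_frame(self.sites[SITE_COLUMNS])

    def is_sorted(self) -> bool:
        key = self.sites[["chrom", "pos"]]
        return bool(
            key.equals(key.sort_values(["chrom", "pos"], kind="stable"))
        )

    def take_sites(self, idx: np.ndarray) -> "Callset":
        """New Callset restricted to site rows ``idx`` (positional)."""
        return Callset(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[idx],
            depths=self.depths[idx],
        )

    def take_samples(self, names: list[str]) -> "Callset":
        """New Callset restricted to the given sample columns (in order)."""
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in pos]
        if missing:
            raise KeyError(f"samples not in callset: {missing}")
        cols = [pos[s] for s in names]
        return Callset(
            samples=list(names),
            sites=self.sites.copy(),
            calls=self.calls[:, cols],
            depths=self.depths[:, cols],
        )

    def copy(self) -> "Callset":
        return Callset(
            samples=list(self.samples),
            sites=self.sites.copy(),
            calls=self.calls.copy(),
            depths=self.depths.copy(),
        )


def write_vcf(callset: Callset, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT and DP FORMAT fields."""
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            for chrom in pd.unique(callset.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(callset.samples)
                + "\n"
            )
            chroms = callset.sites["chrom"].to_numpy()
            poss = callset.sites["pos"].to_numpy()
            refs = callset.sites["ref"].to_numpy()
            alts = callset.sites["alt"].to_numpy()
            for i in range(callset.n_sites):
                cells = [
                    f"{_GT_STRINGS[int(c)]}:{int(d)}"
                    for c, d in zip(callset.calls[i], callset.depths[i])
                ]
                fh.write(
                    f"{chroms[i]}\t{poss[i]}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\tGT:DP\t"
                    + "\t".join(cells)
                    + "\n"
                )
    except OSError as exc:
        raise OSError(f"failed writing VCF to {path}: {exc}") from exc


def read_vcf(path: str | Path) -> Callset:
    """Read a VCF into a Callset, keeping biallelic SNP records only.

    Uses cyvcf2; genotypes are collapsed to hom_ref/het/hom_alt/missing and
    DP defaults to 0 where absent.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows: list[tuple] = []
    call_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = np.asarray(v.gt_types)
        calls = np.full(len(samples), MISSING, dtype=np.int8)
        calls[gt == 0] = HOM_REF
        calls[gt == 1] = HET
        calls[gt == 3] = HOM_ALT
        try:
            dp = v.format("DP")
        except KeyError:  # DP absent from the FORMAT header entirely
            dp = None
        if dp is None:
            depths = np.zeros(len(samples), dtype=np.int32)
        else:
            depths = np.asarray(dp).reshape(-1).astype(np.int32)
            depths[depths < 0] = 0
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        call_rows.append(calls)
        depth_rows.append(depths)
    vcf.close()
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if rows:
        calls = np.vstack(call_rows)
        depths = np.vstack(depth_rows)
    else:
        calls = np.zeros((0, len(samples)), dtype=np.int8)
        depths = np.zeros((0, len(samples)), dtype=np.int32)
    return Callset(samples=samples, sites=sites, calls=calls, depths=depths)


@dataclass
class SampleMetadata:
    """sample -> (cultivar, ploidy) table."""

    table: pd.DataFrame  # columns: sample_id, cultivar, ploidy

    def __post_init__(self) -> None:
        required = {"sample_id", "cultivar", "ploidy"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"metadata requires columns {sorted(required)}")
        bad = ~self.table["ploidy"].isin([2, 4])
        if bad.any():
            raise ValueError(
                f"ploidy must be 2 or 4; offending samples: "
                f"{self.table.loc[bad, 'sample_id'].tolist()}"
            )
        self.table = self.table.reset_index(drop=True)

    def ploidy_of(self, sample: str) -> int:
        row = self.table[self.table["sample_id"] == sample]
        if row.empty:
            raise KeyError(f"sample {sample!r} absent from metadata")
        return int(row["ploidy"].iloc[0])

    def cultivar_of(self, sample: str) -> str:
        row = self.table[self.table["sample_id"] == sample]
        if row.empty:
            raise KeyError(f"sample {sample!r} absent from metadata")
        return str(row["cultivar"].iloc[0])

    def samples_with_ploidy(self, ploidy: int) -> list[str]:
        return self.table.loc[
            self.table["ploidy"] == ploidy, "sample_id"
        ].tolist()


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t"))
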