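"""Reference-guided pseudomolecule construction.

Contigs are anchored to a chromosome-level reference via tabular alignment
hits (BLAST outfmt-6 or PAF).  A contig with threshold-passing hits on more
than one reference chromosome is discarded entirely (strict mode; a dominance
mode relaxes this); survivors are ordered by the median reference midpoint of
their hits, oriented by length-weighted majority strand, and concatenated with
runs of N into pseudomolecules described by an AGP v2.1 file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

BLAST6_COLUMNS = [
    "query", "subject", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


@dataclass(frozen=True)
class AlignmentHit:
    contig: str
    contig_start: int  # 1-based closed
    contig_end: int
    chrom: str
    ref_start: int
    ref_end: int
    pct_identity: float
    score: float
    strand: str  # '+' | '-'

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"identity {self.pct_identity} outside [0, 100]")

    @property
    def ref_midpoint(self) -> float:
        return (self.ref_start + self.ref_end) / 2.0

    @property
    def aligned_bases(self) -> int:
        return abs(self.contig_end - self.contig_start) + 1


@dataclass(frozen=True)
class ContigAnchor:
    contig: str
    chrom: str
    position: float  # median of hit reference midpoints
    orientation: str  # '+' | '-'


def load_hits(
    path: str | Path,
    min_identity: float = 0.0,
    min_score: float = 0.0,
    fmt: str = "blast6",
) -> list[AlignmentHit]:
    """Parse BLAST outfmt-6 or PAF hits, dropping rows below thresholds.

    For PAF, percent identity is taken as 100 * matches / alignment block
    length and score as the number of matching bases.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "blast6":
                    if len(fields) < 12:
                        raise ValueError("expected 12 columns")
                    (q, s, ident, _aln, _mm, _go,
                     qs, qe, ss, se, _ev, score) = fields[:12]
                    s_start, s_end = int(ss), int(se)
                    strand = "+" if s_start <= s_end else "-"
                    hit = AlignmentHit(
                        contig=q,
                        contig_start=min(int(qs), int(qe)),
                        contig_end=max(int(qs), int(qe)),
                        chrom=s,
                        ref_start=min(s_start, s_end),
                        ref_end=max(s_start, s_end),
                        pct_identity=float(ident),
                        score=float(score),
                        strand=strand,
                    )
                elif fmt == "paf":
                    if len(fields) < 12:
                        raise ValueError("expected >= 12 columns")
                    q, _qlen, qs, qe, strand, t, _tlen, ts, te, match, block = fields[:11]
                    ident = 100.0 * int(match) / max(int(block), 1)
                    hit = AlignmentHit(
                        contig=q,
                        contig_start=int(qs) + 1,  # PAF is 0-based half-open
                        contig_end=int(qe),
                        chrom=t,
                        ref_start=int(ts) + 1,
                        ref_end=int(te),
                        pct_identity=ident,
                        score=float(match),
                        strand=strand,
                    )
                else:
                    raise ValueError(f"unknown format {fmt!r}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if hit.pct_identity >= min_identity and hit.score >= min_score:
                hits.append(hit)
    return hits


def filter_multi_chrom(
    hits: list[AlignmentHit],
    all_contigs: list[str] | None = None,
    mode: str = "strict",
    dominance: float = 0.9,
) -> tuple[list[ContigAnchor], pd.DataFrame]:
    """Anchor single-chromosome contigs; discard the rest.

    strict mode: any contig with hits on >= 2 distinct chromosomes is
    discarded.  dominant mode: keep the contig on its dominant chromosome if
    that chromosome holds >= ``dominance`` of its aligned bases.  Contigs in
    ``all_contigs`` with zero hits are reported as 'unaligned'.  Returns
    (anchors, discard report with columns contig, reason).
    """
    if mode not in ("strict", "dominant"):
        raise ValueError("mode must be 'strict' or 'dominant'")
    by_contig: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig, []).append(h)

    anchors: list[ContigAnchor] = []
    discarded: list[tuple[str, str]] = []
    for contig in sorted(by_contig):
        chits = by_contig[contig]
        chroms = {h.chrom for h in chits}
        use_hits = chits
        if len(chroms) > 1:
            if mode == "strict":
                discarded.append((contig, "multi_chromosome"))
                continue
            bases = pd.Series(
                [h.aligned_bases for h in chits], index=[h.chrom for h in chits]
            ).groupby(level=0).sum()
            top = bases.idxmax()
            if bases[top] / bases.sum() < dominance:
                discarded.append((contig, "multi_chromosome"))
                continue
            use_hits = [h for h in chits if h.chrom == top]
        chrom = use_hits[0].chrom
        position = float(np.median([h.ref_midpoint for h in use_hits]))
        plus = sum(h.aligned_bases for h in use_hits if h.strand == "+")
        minus = sum(h.aligned_bases for h in use_hits if h.strand == "-")
        orientation = "+" if plus >= minus else "-"
        anchors.append(
            ContigAnchor(
                contig=contig, chrom=chrom, position=position, orientation=orientation
            )
        )
    if all_contigs is not None:
        for contig in sorted(set(all_contigs) - set(by_contig)):
            discarded.append((contig, "unaligned"))
    report = pd.DataFrame(discarded, columns=["contig", "reason"])
    return anchors, report


def order_and_orient(anchors: list[ContigAnchor]) -> dict[str, list[ContigAnchor]]:
    """Per-chromosome contig lists ordered by anchor position (ties: contig id)."""
    out: dict[str, list[ContigAnchor]] = {}
    for a in anchors:
        out.setdefault(a.chrom, []).append(a)
    for chrom in out:
        out[chrom].sort(key=lambda a: (a.position, a.contig))
    return dict(sorted(out.items()))


def build_pseudomolecules(
    ordered: dict[str, list[ContigAnchor]],
    contig_fasta: dict[str, str],
    spacer_n: int = 100,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Concatenate ordered (and oriented) contigs with N spacers.

    Returns (pseudomolecule sequences keyed by 'pm_<chrom>', AGP v2.1 table).
    Minus-orientation contigs are reverse-complemented.  AGP gap rows use
    component type U (gap of unknown size but written with spacer_n length,
    per the scaffold convention 'scaffold, yes, align_genus').
    """
    agp_rows: list[list] = []
    sequences: dict[str, str] = {}
    for chrom, anchors in ordered.items():
        name = f"pm_{chrom}"
        parts: list[str] = []
        cursor = 1
        part_no = 1
        for k, a in enumerate(anchors):
            if a.contig not in contig_fasta:
                raise KeyError(f"contig {a.contig!r} missing from FASTA")
            seq = contig_fasta[a.contig]
            if a.orientation == "-":
                seq = str(Seq(seq).reverse_complement())
            if k > 0 and spacer_n > 0:
                agp_rows.append(
                    [name, cursor, cursor + spacer_n - 1, part_no, "U",
                     spacer_n, "scaffold", "yes", "align_genus"]
                )
                parts.append("N" * spacer_n)
                cursor += spacer_n
                part_no += 1
            agp_rows.append(
                [name, cursor, cursor + len(seq) - 1, part_no, "W",
                 a.contig, 1, len(contig_fasta[a.contig]), a.orientation]
            )
            parts.append(seq)
            cursor += len(seq)
            part_no += 1
        sequences[name] = "".join(parts)
    agp = pd.DataFrame(
        agp_rows,
        columns=["object", "object_beg", "object_end", "part_number",
                 "component_type", "c6", "c7", "c8", "c9"],
    )
    return sequences, agp


def write_agp(agp: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        agp.to_csv(fh, sep="\t", header=False, index=False)


def read_agp(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["object", "object_beg", "object_end", "part_number",
               "component_type", "c6", "c7", "c8", "c9"],
    )


def fasta_from_agp(
    agp: pd.DataFrame, contig_fasta: dict[str, str]
) -> dict[str, str]:
    """Rebuild pseudomolecule sequences from an AGP table plus contigs."""
    out: dict[str, list[str]] = {}
    for row in agp.itertuples():
        parts = out.setdefault(row.object, [])
        if row.component_type in ("N", "U"):
            parts.append("N" * int(row.c6))
        elif row.component_type == "W":
            seq = contig_fasta[row.c6][int(row.c7) - 1 : int(row.c8)]
            if row.c9 == "-":
                seq = str(Seq(seq).reverse_complement())
            parts.append(seq)
        else:
            raise ValueError(f"unsupported AGP component type {row.component_type!r}")
    return {name: "".join(parts) for name, parts in out.items()}


def anchoring_table(anchors: list[ContigAnchor]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.contig, a.chrom, a.position, a.orientation) for a in anchors],
        columns=["contig", "chrom", "position", "orientation"],
    )
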