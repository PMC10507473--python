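"""Collapsed-diploid genotype encoding, Nei's (1972) distance, neighbour joining.

Every sample, diploid or tetraploid, is encoded by its within-individual
reference-allele frequency in {0, 0.5, 1} ("treated as diploid": tetraploid
allelic dosage is not estimated).  Pairwise Nei's standard genetic distance is
computed at the individual level with pairwise deletion of missing loci, and
the distance matrix is resolved into an unrooted tree by the Saitou–Nei
neighbour-joining algorithm with a deterministic tie-break.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .callset import HET, HOM_ALT, HOM_REF, MISSING, Callset, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """samples x loci matrix of within-individual reference-allele frequency."""

    samples: list[str]
    loci: list[str]
    values: np.ndarray  # float (n_samples, n_loci); NaN = missing

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.samples), len(self.loci)):
            raise ValueError("GenotypeMatrix dimensions inconsistent")
        finite = self.values[np.isfinite(self.values)]
        if not np.isin(finite, [0.0, 0.5, 1.0]).all():
            raise ValueError("values must be in {0, 0.5, 1} or NaN")


@dataclass
class DistanceMatrix:
    samples: list[str]
    values: np.ndarray  # (n, n) symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


def encode_collapsed(callset: Callset) -> GenotypeMatrix:
    """hom_ref -> 1.0, het -> 0.5, hom_alt -> 0.0, missing -> NaN, all ploidies."""
    mapping = np.full(3, np.nan)
    mapping[HOM_REF] = 1.0
    mapping[HET] = 0.5
    mapping[HOM_ALT] = 0.0
    vals = np.full(callset.calls.shape, np.nan)
    ok = callset.calls != MISSING
    vals[ok] = mapping[callset.calls[ok]]
    loci = [
        f"{c}:{p}" for c, p in zip(callset.sites["chrom"], callset.sites["pos"])
    ]
    return GenotypeMatrix(
        samples=list(callset.samples), loci=loci, values=vals.T
    )


def nei_distance(
    matrix: GenotypeMatrix, cap_factor: float = 10.0
) -> DistanceMatrix:
    """Nei's 1972 standard genetic distance between individuals.

    D(x, y) = -ln( J_xy / sqrt(J_x * J_y) ), with J_xy = sum over shared loci
    of x_ref*y_ref + x_alt*y_alt, and J_x, J_y the corresponding homozygosity
    sums, restricted for each pair to loci genotyped in both (pairwise
    deletion).  Pairs with J_xy = 0 are infinite under the formula and are
    capped at ``cap_factor`` times the largest finite distance, with a warning.
    """
    n = len(matrix.samples)
    if n < 2:
        raise ValueError("need at least 2 samples")
    A = matrix.values  # ref-allele freq
    M = np.isfinite(A)
    A1 = np.where(M, A, 0.0)
    B1 = np.where(M, 1.0 - A, 0.0)
    Mf = M.astype(float)

    shared = Mf @ Mf.T
    pairs_no_shared = np.argwhere(np.triu(shared == 0, k=1))
    if len(pairs_no_shared):
        names = [
            (matrix.samples[i], matrix.samples[j])
            for i, j in pairs_no_shared[:10]
        ]
        raise ValueError(
            f"{len(pairs_no_shared)} sample pair(s) share no genotyped loci; "
            f"first: {names}"
        )

    jxy = A1 @ A1.T + B1 @ B1.T
    S = A1**2 + B1**2  # per-locus homozygosity, zero where missing
    jx = S @ Mf.T  # J_x over loci shared with each partner

    with np.errstate(divide="ignore", invalid="ignore"):
        D = -np.log(jxy / np.sqrt(jx * jx.T))
    np.fill_diagonal(D, 0.0)
    D[np.isclose(D, 0.0) & (D < 0)] = 0.0  # numeric noise on identical pairs

    inf_mask = ~np.isfinite(D)
    if inf_mask.any():
        finite_max = np.nanmax(np.where(inf_mask, np.nan, D))
        if not np.isfinite(finite_max) or finite_max <= 0:
            finite_max = 1.0
        cap = finite_max * cap_factor
        warnings.warn(
            f"{int(inf_mask.sum() // 2)} sample pair(s) have zero shared gene "
            f"identity; distance capped at {cap:.4g}",
            RuntimeWarning,
            stacklevel=2,
        )
        D = np.where(inf_mask, cap, D)
    D = (D + D.T) / 2.0
    return DistanceMatrix(samples=list(matrix.samples), values=D)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbour joining with deterministic tie-breaking.

    Ties in the Q-criterion resolve to the lowest (i, j) index pair in the
    current agglomeration order.  Negative branch lengths are clamped to zero
    with the deficit absorbed by the sibling edge.  The returned tree is
    unrooted (basal trifurcation).
    """
    n = len(dist.samples)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 samples")
    taxa = dendropy.TaxonNamespace(dist.samples)
    nodes: list[dendropy.Node] = []
    for name in dist.samples:
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(name)
        nodes.append(nd)

    D = dist.values.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
            logger.debug("negative branch clamped; deficit moved to sibling")
        if lj < 0:
            li += lj
            lj = 0.0
            logger.debug("negative branch clamped; deficit moved to sibling")
        return li, lj

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        Q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) among ties, in current agglomeration order
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=1e-12))
        ii, jj = min((min(i, j), max(i, j)) for i, j in ties)
        a, b = active[ii], active[jj]
        d_ab = D[a, b]
        li = 0.5 * d_ab + (row_sums[ii] - row_sums[jj]) / (2 * (r - 2))
        lj = d_ab - li
        li, lj = clamp(li, lj)

        new = dendropy.Node()
        ca, cb = nodes[a], nodes[b]
        new.add_child(ca)
        new.add_child(cb)
        ca.edge.length = float(li)
        cb.edge.length = float(lj)
        # distances to the new node
        d_new = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (a, b):
                continue
            d_new[k] = 0.5 * (D[a, k] + D[b, k] - d_ab)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = d_new[:-1]
        D[:-1, -1] = d_new[:-1]
        nodes.append(new)
        u = D.shape[0] - 1
        active = [k for k in active if k not in (a, b)] + [u]

    # join the last three nodes at a single internal (unrooted, degree 3)
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node_idx, ln in ((a, la), (b, lb), (c, lc)):
        child = nodes[node_idx]
        root.add_child(child)
        child.edge.length = float(max(ln, 0.0))
        if ln < 0:
            logger.debug("negative terminal branch clamped to 0")

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = [lf.taxon for lf in tree.leaf_node_iter()]
    names = [t.label for t in leaves]
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(leaves[i], leaves[j])
    return DistanceMatrix(samples=names, values=out)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_distance_tsv(dist: DistanceMatrix, path: str | Path) -> None:
    dist.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# cultivar / ploidy clustering summary
# ---------------------------------------------------------------------------


def _bipartition_sides(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf sets under each edge of the (arbitrarily rooted) tree."""
    sides = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        sides.append(leaves)
    return sides


def group_summary(
    tree: dendropy.Tree, metadata: SampleMetadata
) -> pd.DataFrame:
    """Per-cultivar largest pure cluster plus the ploidy-separation flag.

    A "cluster" is one side of some tree edge (monophyly in the unrooted
    sense).  The ploidy separation flag is true iff all tetraploid samples
    fall on one side of a single edge, with every diploid on the other.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    sides = _bipartition_sides(tree)
    sides_both = set(sides) | {frozenset(all_leaves - s) for s in sides}

    rows = []
    for cultivar, grp in metadata.table.groupby("cultivar", sort=True):
        members = frozenset(grp["sample_id"]) & all_leaves
        best = max(
            (len(s) for s in sides_both if s and s <= members), default=0
        )
        if len(members) == 1 or members == all_leaves:
            # single samples and a cultivar spanning the whole tree are
            # trivially pure even though no edge isolates them
            best = max(best, len(members))
        rows.append((cultivar, len(members), best))
    out = pd.DataFrame(rows, columns=["cultivar", "n_samples", "largest_pure_cluster"])

    tets = frozenset(
        metadata.table.loc[metadata.table["ploidy"] == 4, "sample_id"]
    ) & all_leaves
    separated = bool(tets) and tets in sides_both
    out.attrs["ploidy_separation"] = separated
    return out


def ploidy_separated(tree: dendropy.Tree, metadata: SampleMetadata) -> bool:
    """True iff one tree edge splits tetraploids from diploids exactly."""
    return bool(group_summary(tree, metadata).attrs["ploidy_separation"])
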