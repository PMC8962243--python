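"""Linkage-disequilibrium block structure, random pruning, and clumping.

LD is supplied externally as a pairwise table (PLINK ``.ld``-style
columns SNP_A, SNP_B, R2); genotype processing is out of scope.  An "LD
block" is a connected component of the graph whose edges join variant
pairs with r^2 strictly above a threshold (single linkage / transitive
closure), matching the behaviour of standard clumping tools.  Random
pruning draws one variant uniformly per block and is the de-correlation
device used when estimating conditional empirical CDFs; clumping reduces
each significant component to its lead variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = ["LdBlockSet", "SharedLocus", "read_ld_table", "ld_blocks", "random_prune", "clump_loci"]


@dataclass
class LdBlockSet:
    """Partition of a variant set into LD blocks.

    ``variant_block`` maps variant id -> block id; ``blocks`` maps block
    id -> list of member ids.  Block ids are consecutive integers from 0,
    numbered by first appearance in the (sorted) variant list, so the
    labelling is deterministic for a given variant set and edge set.
    """

    variant_block: dict = field(repr=False)
    blocks: dict = field(repr=False)
    r2_threshold: float = 0.1

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def __len__(self) -> int:
        return len(self.variant_block)

    def member_arrays(self):
        """Flat member array grouped by block id, with offsets and counts.

        Returns ``(flat, offsets, counts)`` where block ``b`` occupies
        ``flat[offsets[b]:offsets[b]+counts[b]]``.  Cached; used to draw
        one-per-block subsets without a Python loop.
        """
        if not hasattr(self, "_flat"):
            counts = np.array([len(self.blocks[b]) for b in range(self.n_blocks)])
            offsets = np.concatenate([[0], np.cumsum(counts)[:-1]]) if len(counts) else np.array([], int)
            flat = np.concatenate([np.asarray(self.blocks[b], dtype=object)
                                   for b in range(self.n_blocks)]) if self.n_blocks else np.array([], object)
            self._flat, self._offsets, self._counts = flat, offsets.astype(int), counts
        return self._flat, self._offsets, self._counts


def read_ld_table(path):
    """Read a PLINK ``.ld``-style whitespace table; extra columns ignored."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = {"SNP_A", "SNP_B", "R2"} - set(df.columns)
    if missing:
        raise ValueError(f"LD table lacks columns: {sorted(missing)}")
    return df[["SNP_A", "SNP_B", "R2"]]


def ld_blocks(pairs, variants, r2_threshold=0.1):
    """Partition ``variants`` into LD blocks from pairwise r^2 records.

    Parameters
    ----------
    pairs : DataFrame with columns SNP_A, SNP_B, R2 (or iterable of
        (snp_a, snp_b, r2) tuples).  Pairs involving variants outside
        ``variants`` are ignored.
    variants : iterable of variant ids; ids absent from every retained
        pair become singleton blocks.
    r2_threshold : float
        Edges require r^2 strictly greater than this.

    Components are computed on the undirected graph via sparse
    connected-components (union-find equivalent).
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame(list(pairs), columns=["SNP_A", "SNP_B", "R2"])
    r2 = pairs["R2"].to_numpy(dtype=float)
    if len(r2) and (np.nanmin(r2) < 0 or np.nanmax(r2) > 1):
        raise ValueError("r^2 values must lie in [0, 1]")

    ids = pd.Index(pd.unique(pd.Series(list(variants))))
    n = len(ids)
    lookup = pd.Series(np.arange(n), index=ids)

    strong = pairs.loc[r2 > r2_threshold]
    ia = lookup.reindex(strong["SNP_A"]).to_numpy()
    ib = lookup.reindex(strong["SNP_B"]).to_numpy()
    ok = ~(np.isnan(ia) | np.isnan(ib))
    ia, ib = ia[ok].astype(int), ib[ok].astype(int)

    graph = coo_matrix((np.ones(len(ia)), (ia, ib)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)

    # renumber components by first appearance for determinism
    order = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in labels])

    variant_block = dict(zip(ids, labels.tolist()))
    blocks: dict = {}
    for vid, lab in variant_block.items():
        blocks.setdefault(lab, []).append(vid)
    return LdBlockSet(variant_block=variant_block, blocks=blocks, r2_threshold=r2_threshold)


def random_prune(blocks: LdBlockSet, seed=0, iteration=0):
    """Draw one variant uniformly at random from every block.

    Reproducible: the generator is seeded from ``(seed, iteration)``, so
    the same pair always yields the same subset.  Returns a list of
    variant ids (one per block, in block-id order).
    """
    if blocks.n_blocks == 0:
        raise ValueError("empty block set")
    rng = np.random.default_rng([int(seed), int(iteration)])
    flat, offsets, counts = blocks.member_arrays()
    picks = flat[offsets + rng.integers(0, counts)]
    return picks.tolist()


@dataclass
class SharedLocus:
    """One independent shared locus: an LD component of significant variants."""

    locus_no: int
    lead_snp: str
    chrom: str
    pos: int
    a1: str
    a2: str
    z1: float
    z2: float
    p1: float
    p2: float
    conj_fdr: float
    members: list = field(default_factory=list)
    genes: list = field(default_factory=list)


def _chrom_key(c):
    c = str(c)
    special = {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}
    if c.isdigit():
        return int(c)
    return special.get(c.upper(), 99)


def clump_loci(significant, pairs=None, blocks=None, r2_threshold=0.1):
    """Clump significant variants into independent shared loci.

    Components are computed among the significant variants only (an LD
    pair only links two variants if both are significant).  The lead of
    each component is the member with minimal conjFDR; ties break toward
    larger |z1|, then smaller position.  Loci are numbered 1.. by the
    genomic order (chrom, pos) of their leads.

    Parameters
    ----------
    significant : DataFrame with columns snp, chrom, pos, a1, a2, z1,
        z2, p1, p2, conj_fdr.
    pairs : pairwise LD table (used if ``blocks`` not given).
    blocks : LdBlockSet; significant variants sharing a block are linked.
    """
    sig = significant.reset_index(drop=True)
    if len(sig) == 0:
        return []
    snps = sig["snp"].tolist()
    if blocks is not None:
        grp = pd.Series([blocks.variant_block.get(s) for s in snps])
        missing = grp.isna()
        if missing.any():
            logger.warning("%d significant variants lack LD info; treated as singletons",
                           int(missing.sum()))
            grp = grp.astype(object)
            grp[missing] = [f"_singleton{i}" for i in np.flatnonzero(missing)]
        labels = pd.factorize(grp)[0]
    else:
        sub = ld_blocks(pairs if pairs is not None else [], snps, r2_threshold)
        labels = np.array([sub.variant_block[s] for s in snps])

    loci = []
    for lab in np.unique(labels):
        comp = sig.loc[labels == lab]
        lead = comp.sort_values(
            by=["conj_fdr", "z1", "pos"],
            key=lambda s: -s.abs() if s.name == "z1" else s,
        ).iloc[0]
        loci.append(
            SharedLocus(
                locus_no=0,
                lead_snp=str(lead["snp"]),
                chrom=str(lead["chrom"]),
                pos=int(lead["pos"]),
                a1=str(lead["a1"]),
                a2=str(lead["a2"]),
                z1=float(lead["z1"]),
                z2=float(lead["z2"]),
                p1=float(lead["p1"]),
                p2=float(lead["p2"]),
                conj_fdr=float(lead["conj_fdr"]),
                members=comp["snp"].tolist(),
            )
        )
    loci.sort(key=lambda L: (_chrom_key(L.chrom), L.pos, L.lead_snp))
    for i, L in enumerate(loci, start=1):
        L.locus_no = i
    return loci
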