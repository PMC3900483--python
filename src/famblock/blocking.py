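"""Partitioning a gene's SNVs into blocks.

Blocks are assumed mutually independent by the region test; within-block
dependence is absorbed empirically.  Four deterministic schemes are offered
(bp windows, bp intervals with a fixed block count, SNV-count windows, and a
fixed number of SNV-count blocks) plus a data-adaptive scheme that clusters
SNVs by founder-genotype correlation with contiguity-constrained
average-linkage hierarchical clustering.

Conventions: bp windows are half-open ``[start, start + w)`` anchored at the
smallest SNV position (a SNV exactly on a boundary belongs to the right-hand
window); empty bp windows/intervals are dropped; when a fixed block count
does not divide evenly the earlier blocks take the extra SNV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pedigree_data import GeneRegion

__all__ = [
    "BlockPartition",
    "partition_bp_window",
    "partition_bp_nblocks",
    "partition_snv_window",
    "partition_snv_nblocks",
    "one_block",
    "adaptive_partition",
    "make_partition",
    "SCHEMES",
]


@dataclass
class BlockPartition:
    gene_name: str
    blocks: list[np.ndarray]  # ordered groups of positions into region order
    scheme: str
    parameter: float | int | None = None

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(b, dtype=np.intp) for b in self.blocks]
        self.validate()

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError(f"{self.gene_name}: partition has no blocks")
        if any(b.size == 0 for b in self.blocks):
            raise ValueError(f"{self.gene_name}: empty block")
        flat = np.concatenate(self.blocks)
        if np.unique(flat).size != flat.size:
            raise ValueError(f"{self.gene_name}: blocks overlap")
        if not np.array_equal(np.sort(flat), np.arange(flat.size)):
            raise ValueError(f"{self.gene_name}: blocks do not cover all SNVs")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_sizes(self) -> list[int]:
        return [int(b.size) for b in self.blocks]

    def to_table(self, region: GeneRegion, snv_ids: list[str] | None = None) -> str:
        """BED-like TSV: ``gene  block_id  snv_id  position``."""
        lines = []
        for b, block in enumerate(self.blocks):
            for local in block:
                gidx = int(region.snv_indices[local])
                sid = snv_ids[gidx] if snv_ids is not None else str(gidx)
                lines.append(
                    f"{self.gene_name}\t{b}\t{sid}\t{int(region.snv_positions[local])}"
                )
        return "\n".join(lines) + "\n"


def _group_by_edges(region: GeneRegion, edges: np.ndarray, scheme: str, parameter) -> BlockPartition:
    """Assign SNVs to half-open intervals defined by ``edges``; drop empties."""
    pos = region.snv_positions
    assignment = np.searchsorted(edges, pos, side="right") - 1
    blocks = [
        np.flatnonzero(assignment == k)
        for k in range(len(edges))
        if np.any(assignment == k)
    ]
    return BlockPartition(region.gene_name, blocks, scheme, parameter)


def partition_bp_window(region: GeneRegion, window_bp: int) -> BlockPartition:
    """Option 1: consecutive fixed-width bp windows from the smallest position."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    pos = region.snv_positions
    start, stop = int(pos.min()), int(pos.max())
    if stop - start <= window_bp:
        return BlockPartition(
            region.gene_name, [np.arange(pos.size)], "opt1_bp_window", window_bp
        )
    edges = np.arange(start, stop + 1, window_bp)
    return _group_by_edges(region, edges, "opt1_bp_window", window_bp)


def partition_bp_nblocks(region: GeneRegion, n_blocks: int) -> BlockPartition:
    """Option 2: gene span split into ``n_blocks`` equal bp intervals."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    pos = region.snv_positions
    start, stop = float(pos.min()), float(pos.max())
    if n_blocks == 1 or start == stop:
        return BlockPartition(
            region.gene_name, [np.arange(pos.size)], "opt2_bp_nblocks", n_blocks
        )
    edges = start + (stop - start) * np.arange(n_blocks) / n_blocks
    part = _group_by_edges(region, edges, "opt2_bp_nblocks", n_blocks)
    return part


def partition_snv_window(region: GeneRegion, snvs_per_block: int) -> BlockPartition:
    """Option 3: consecutive groups of ``snvs_per_block`` position-ordered SNVs."""
    if snvs_per_block < 1:
        raise ValueError("snvs_per_block must be >= 1")
    m = region.n_snvs
    blocks = [
        np.arange(lo, min(lo + snvs_per_block, m))
        for lo in range(0, m, snvs_per_block)
    ]
    return BlockPartition(region.gene_name, blocks, "opt3_snv_window", snvs_per_block)


def partition_snv_nblocks(region: GeneRegion, n_blocks: int) -> BlockPartition:
    """Option 4: ``min(n_blocks, m)`` consecutive groups, sizes as equal as possible."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    m = region.n_snvs
    b = min(n_blocks, m)  # fewer SNVs than blocks -> singletons
    sizes = np.full(b, m // b, dtype=int)
    sizes[: m % b] += 1  # earlier blocks take the remainder
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    blocks = [np.arange(bounds[k], bounds[k + 1]) for k in range(b)]
    return BlockPartition(region.gene_name, blocks, "opt4_snv_nblocks", n_blocks)


def one_block(region: GeneRegion) -> BlockPartition:
    """No blocking: all SNVs in a single block."""
    return BlockPartition(region.gene_name, [np.arange(region.n_snvs)], "one_block")


def adaptive_partition(
    genotypes: np.ndarray,
    region: GeneRegion,
    founder_rows: np.ndarray,
    linkage: str = "average",
    zero_tol: float = 1e-12,
    cut_gap: float = 0.1,
) -> BlockPartition:
    """Data-adaptive blocks from founder-genotype LD.

    Pairwise SNV distance is ``1 - |r|`` with ``r`` the founder genotype
    correlation.  Contiguous clusters are merged agglomeratively (average
    linkage restricted to adjacent cluster pairs, preserving positional
    contiguity).  Perfect-LD merges (height ~ 0) are always applied; the
    tree is then cut before the largest jump between consecutive merge
    heights provided it reaches ``cut_gap`` (an elbow on the ``1 - |r|``
    scale); without such a jump there is no detectable block structure and
    SNVs stay singletons.  A zero-variance SNV is attached to its nearest
    positional neighbour with a warning.
    """
    if linkage != "average":
        raise ValueError("only average linkage is supported")
    m = region.n_snvs
    if m < 2:
        raise ValueError("adaptive partitioning needs >= 2 SNVs")
    cols = region.snv_indices
    founder = genotypes[np.asarray(founder_rows, dtype=np.intp)][:, cols].astype(float)

    sd = founder.std(axis=0)
    degenerate = sd <= zero_tol
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(founder, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    if degenerate.any():
        warnings.warn(
            f"{region.gene_name}: zero-variance SNV(s) at local indices "
            f"{np.flatnonzero(degenerate).tolist()} attached to nearest neighbour"
        )
        for j in np.flatnonzero(degenerate):
            nb = j + 1 if j + 1 < m else j - 1
            dist[j, nb] = dist[nb, j] = 0.0

    # contiguity-constrained average-linkage agglomeration
    clusters: list[list[int]] = [[j] for j in range(m)]
    heights: list[float] = []
    sizes_hist: list[list[int]] = []

    def avg_dist(a: list[int], b: list[int]) -> float:
        return float(dist[np.ix_(a, b)].mean())

    merge_trace: list[list[list[int]]] = [list(map(list, clusters))]
    while len(clusters) > 1:
        pair_d = [
            avg_dist(clusters[k], clusters[k + 1]) for k in range(len(clusters) - 1)
        ]
        k = int(np.argmin(pair_d))
        heights.append(pair_d[k])
        clusters = (
            clusters[:k] + [clusters[k] + clusters[k + 1]] + clusters[k + 2 :]
        )
        merge_trace.append(list(map(list, clusters)))

    # cumulative max protects the gap rule against (rare) non-monotone merges
    h = np.maximum.accumulate(np.asarray(heights))
    # mandatory merges: perfect LD collapses regardless of the cut
    n_forced = int(np.sum(h <= zero_tol))
    # cut before the largest jump between consecutive merge heights (the
    # dendrogram gap); candidate cuts after t merges give B = m - t >= 2.
    # Distances of thresholded rare-allele data are bounded away from zero,
    # so only a jump of at least ``cut_gap`` counts as an elbow; a gapless
    # sequence means no detectable cluster structure and every (non-forced)
    # SNV stays a singleton.
    if n_forced >= m - 1:
        chosen_t = m - 1  # everything in perfect LD -> one block
    else:
        t_lo, t_hi = max(n_forced, 1), m - 2
        chosen_t = n_forced
        if t_lo <= t_hi:
            gaps = h[t_lo : t_hi + 1] - h[t_lo - 1 : t_hi]
            best = int(np.argmax(gaps))
            if gaps[best] >= cut_gap:
                chosen_t = t_lo + best
    blocks = [np.asarray(sorted(c)) for c in merge_trace[chosen_t]]
    return BlockPartition(region.gene_name, blocks, "adaptive", None)


SCHEMES = {
    "opt1": partition_bp_window,
    "opt2": partition_bp_nblocks,
    "opt3": partition_snv_window,
    "opt4": partition_snv_nblocks,
}


def make_partition(
    region: GeneRegion,
    scheme: str,
    parameter: int | None = None,
    genotypes: np.ndarray | None = None,
    founder_rows: np.ndarray | None = None,
) -> BlockPartition:
    """Dispatch a partition specification (``opt1..opt4``, ``one_block``, ``adaptive``)."""
    if scheme in ("one_block", "one-block"):
        return one_block(region)
    if scheme == "adaptive":
        if genotypes is None or founder_rows is None:
            raise ValueError("adaptive scheme needs genotypes and founder rows")
        return adaptive_partition(genotypes, region, founder_rows)
    if scheme not in SCHEMES:
        raise ValueError(f"unknown blocking scheme {scheme!r}")
    if parameter is None:
        raise ValueError(f"scheme {scheme!r} requires a parameter")
    return SCHEMES[scheme](region, parameter)
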