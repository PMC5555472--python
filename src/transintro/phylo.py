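"""Per-locus neighbor-joining trees and trans-specific polymorphism calls.

A locus is called trans-specific when neither species' sequences form a
monophyletic group on the locus tree — the pattern produced both by balanced
ancestral polymorphism and by introgression. Trees are built by neighbor
joining on Jukes–Cantor distances with pairwise deletion of missing data,
bootstrap supports come from site resampling, and monophyly is judged on the
topology rooted with the outgroup (midpoint rooting when no outgroup is in
the alignment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .io import LocusAlignment, SpeciesPartition
from .popgen import SaturationError, jukes_cantor

__all__ = [
    "TransSpecificCall",
    "jc_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "classify_trans_specific",
    "has_identical_interspecific_pair",
]

# JC distance assigned to saturated pairs during bootstrap resampling only;
# the primary matrix refuses saturation outright.
_SATURATED_D = 5.0


@dataclass(frozen=True)
class TransSpecificCall:
    locus: str
    is_trans_specific: bool
    lyrata_monophyletic: bool
    halleri_monophyletic: bool
    rooting_used: str


def _diff_counts(matrix: np.ndarray, called: np.ndarray):
    """Pairwise mismatch and overlap counts under pairwise deletion."""
    n = matrix.shape[0]
    diffs = np.zeros((n, n), dtype=np.int64)
    ncomp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = called[i] & called[i + 1 :]
        mism = (matrix[i] != matrix[i + 1 :]) & both
        diffs[i, i + 1 :] = mism.sum(axis=1)
        ncomp[i, i + 1 :] = both.sum(axis=1)
    diffs += diffs.T
    ncomp += ncomp.T
    np.fill_diagonal(ncomp, matrix.shape[1])
    return diffs, ncomp


def jc_distance_matrix(
    aln: LocusAlignment, rows: list[int] | None = None
) -> DistanceMatrix:
    """JC-corrected distance matrix with pairwise deletion.

    Raises SaturationError naming the offending pair if any raw proportion
    reaches 3/4, and ValueError if a pair shares no called sites.
    """
    rows = list(range(len(aln.sequences))) if rows is None else list(rows)
    if len(rows) < 3:
        raise ValueError("need >=3 sequences for a distance matrix")
    M = aln.matrix()[rows]
    called = (M != b"-") & (M != b"N")
    diffs, ncomp = _diff_counts(M, called)
    labels = [aln.sequences[i][0] for i in rows]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if ncomp[i, j] == 0:
                raise ValueError(f"no overlapping sites for pair ({labels[i]}, {labels[j]})")
            p = diffs[i, j] / ncomp[i, j]
            try:
                d[i, j] = d[j, i] = jukes_cantor(p)
            except SaturationError:
                raise SaturationError(
                    f"saturated pair ({labels[i]}, {labels[j]}): p={p:.3f}"
                ) from None
    return DistanceMatrix(d, labels)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; negative branch lengths clamped to zero."""
    if not np.all(np.isfinite(dm.data)):
        raise ValueError("non-finite distance matrix entries")
    return nj(dm, neg_as_zero=True)


def _bipartitions(tree: TreeNode) -> list[frozenset]:
    """Tip-name sets under each internal edge of the (arbitrarily rooted) tree."""
    all_tips = frozenset(t.name for t in tree.tips())
    out = []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            out.append(side)
    return out


def bootstrap_support(
    aln: LocusAlignment,
    rows: list[int] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> TreeNode:
    """NJ tree with bootstrap supports (% of site-resampled replicates).

    Supports are attached as ``node.support`` on internal nodes, in [0, 100].
    Saturated pairs arising in a resample are given a large fixed distance
    rather than aborting the replicate.
    """
    rows = list(range(len(aln.sequences))) if rows is None else list(rows)
    dm = jc_distance_matrix(aln, rows)
    tree = neighbor_joining(dm)
    labels = list(dm.ids)
    M = aln.matrix()[rows]
    called = (M != b"-") & (M != b"N")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    target = {bp for bp in _bipartitions(tree)}
    # store both orientations so rooting of replicates cannot hide a match
    all_tips = frozenset(labels)
    oriented = {bp: bp for bp in target} | {all_tips - bp: bp for bp in target}
    tally = {bp: 0 for bp in target}
    L = M.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        Mb, cb = M[:, cols], called[:, cols]
        diffs, ncomp = _diff_counts(Mb, cb)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(ncomp > 0, diffs / np.maximum(ncomp, 1), 0.0)
        d = np.where(p < 0.75, -0.75 * np.log1p(-4.0 * np.minimum(p, 0.7499) / 3.0),
                     _SATURATED_D)
        np.fill_diagonal(d, 0.0)
        rep = nj(DistanceMatrix(d, labels), neg_as_zero=True)
        for bp in _bipartitions(rep):
            hit = oriented.get(bp)
            if hit is not None:
                tally[hit] += 1
    for node in tree.postorder(include_self=False):
        if not node.is_tip():
            side = frozenset(t.name for t in node.tips())
            if side in tally:
                node.support = 100.0 * tally[side] / n_boot
    return tree


def _species_names(partition: SpeciesPartition) -> tuple[set, set, set]:
    aln = partition.locus
    name = lambda i: aln.sequences[i][0]
    return (
        {name(i) for i in partition.lyrata_idx},
        {name(i) for i in partition.halleri_idx},
        {name(i) for i in partition.outgroup_idx},
    )


def classify_trans_specific(
    tree: TreeNode, partition: SpeciesPartition
) -> TransSpecificCall:
    """Monophyly-based trans-specificity call for one locus tree.

    Rooted on the outgroup leaf when present, else by midpoint. A species is
    monophyletic iff its leaves form a clade of the rooted tree (singletons
    count as monophyletic); the locus is trans-specific iff both species are
    non-monophyletic.
    """
    lyr, hal, out = _species_names(partition)
    if not lyr or not hal:
        raise ValueError("both species need >=1 leaf for the trans-specific call")
    tips = {t.name for t in tree.tips()}
    if not (lyr | hal) <= tips:
        raise ValueError("tree does not cover all species leaves")
    if out & tips:
        root_leaf = sorted(out & tips)[0]
        rooted = tree.root_at(
            next(t for t in tree.tips() if t.name == root_leaf), above=True,
            branch_attrs=[],
        )
        rooting = root_leaf
    else:
        rooted = tree.root_at_midpoint(branch_attrs=[])
        rooting = "midpoint"
    clades = {frozenset(t.name for t in node.tips())
              for node in rooted.postorder(include_self=True)
              if not node.is_tip()}
    mono = lambda X: len(X) == 1 or frozenset(X) in clades
    mono_l, mono_h = mono(lyr), mono(hal)
    return TransSpecificCall(
        locus=partition.locus.locus_name,
        is_trans_specific=not mono_l and not mono_h,
        lyrata_monophyletic=mono_l,
        halleri_monophyletic=mono_h,
        rooting_used=rooting,
    )


def has_identical_interspecific_pair(
    partition: SpeciesPartition, min_overlap: float = 0.9
) -> bool:
    """True iff some lyrata/halleri pair matches at every co-called site.

    The pair must share at least ``min_overlap`` of the locus length so that
    identity driven by missing data does not count.
    """
    if not partition.lyrata_idx or not partition.halleri_idx:
        raise ValueError("both species must be non-empty")
    aln = partition.locus
    M = aln.matrix()
    called = (M != b"-") & (M != b"N")
    need = min_overlap * aln.length
    for i in partition.lyrata_idx:
        for j in partition.halleri_idx:
            both = called[i] & called[j]
            if both.sum() >= need and not ((M[i] != M[j]) & both).any():
                return True
    return False
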