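"""Per-locus diversity and divergence statistics.

Implements the classical summary statistics for a two-species panel of
aligned haplotypes: segregating sites, haplotype counts, Jukes–Cantor
corrected nucleotide diversity at all / synonymous / nonsynonymous sites
(Nei–Gojobori site counting with equal-weight pathway averaging), the
Hudson–Kaplan four-gamete lower bound on recombination events (Rm), the
fixed/shared/private partition of polymorphic sites between species, and the
extreme synonymous/nonsynonymous interspecific divergences Ks(L)/Ks(H),
Kn(L)/Kn(H).

Missing data (``-`` and ``N``) are handled by pairwise deletion throughout:
each pair of sequences is compared over the sites where both are called.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .io import MISSING, LocusAlignment, SpeciesPartition

__all__ = [
    "SaturationError",
    "PairwiseDistance",
    "DiversitySummary",
    "PolymorphismPartition",
    "DivergenceExtremes",
    "jukes_cantor",
    "segregating_sites",
    "count_haplotypes",
    "pairwise_diversity",
    "nei_gojobori_pair",
    "min_recombination_events",
    "analyzed_sites",
    "classify_polymorphisms",
    "divergence_extremes",
    "diversity_summary",
    "summarize_gene_class",
]

logger = logging.getLogger(__name__)

# Standard genetic code, DNA alphabet. '*' marks stops.
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


class SaturationError(ValueError):
    """Raised when a raw mismatch proportion is >= 3/4 (JC distance undefined)."""


@dataclass(frozen=True)
class PairwiseDistance:
    p_raw: float
    d_jc: float
    n_compared: int


@dataclass(frozen=True)
class DiversitySummary:
    S: int
    n_haplotypes: int
    pi_s: float
    pi_a: float
    pi_total: float
    Rm: int
    Rm_per_site: float
    n_analyzed_sites: int


@dataclass(frozen=True)
class PolymorphismPartition:
    n_fixed: int
    n_shared: int
    n_private_A: int
    n_private_B: int
    n_analyzed: int

    @property
    def prop_fixed(self) -> float:
        return self.n_fixed / self.n_analyzed if self.n_analyzed else float("nan")

    @property
    def prop_shared(self) -> float:
        return self.n_shared / self.n_analyzed if self.n_analyzed else float("nan")


@dataclass(frozen=True)
class DivergenceExtremes:
    Ks_L: float
    Ks_H: float
    Kn_L: float
    Kn_H: float
    Ks_L_pair: tuple[str, str]
    Ks_H_pair: tuple[str, str]
    Kn_L_pair: tuple[str, str]
    Kn_H_pair: tuple[str, str]


def jukes_cantor(p_raw: float) -> float:
    """Jukes–Cantor corrected distance d = -(3/4) ln(1 - (4/3) p)."""
    if not 0.0 <= p_raw < 0.75:
        raise SaturationError(f"raw proportion {p_raw} outside [0, 0.75)")
    if p_raw == 0.0:
        return 0.0
    return -0.75 * np.log1p(-4.0 * p_raw / 3.0)


def _byte_matrix(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(residue matrix, non-missing mask) for equal-length sequence strings."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"unequal sequence lengths {sorted(lengths)}")
    m = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    called = (m != b"-") & (m != b"N")
    return m, called


def segregating_sites(seqs: Sequence[str]) -> int:
    """Count sites with >=2 distinct non-missing residues (missing ignored)."""
    if len(seqs) < 2:
        raise ValueError("need >=2 sequences")
    m, called = _byte_matrix(seqs)
    count = 0
    for j in range(m.shape[1]):
        alleles = set(m[called[:, j], j].tobytes())
        if len(alleles) >= 2:
            count += 1
    return count


def count_haplotypes(seqs: Sequence[str]) -> int:
    """Number of distinct residue strings (missing compared verbatim)."""
    if not seqs:
        raise ValueError("empty input")
    return len(set(seqs))


@lru_cache(maxsize=None)
def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """Nei–Gojobori synonymous/nonsynonymous site counts for one codon.

    Each position contributes f = (# synonymous single-base changes)/3
    synonymous sites; changes producing a stop codon count as nonsynonymous
    (total sites per codon is conserved at 3).
    """
    aa = CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TABLE[alt] == aa and alt not in STOP_CODONS:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences between two codons.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are excluded. If every pathway is blocked (possible
    only for pathological codon pairs) all pathways are used.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    blocked_results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked_results if blocked else results).append((syn, nonsyn))
    use = results or blocked_results
    s = sum(r[0] for r in use) / len(use)
    n = sum(r[1] for r in use) / len(use)
    return s, n


def _clean_codon(c: str) -> bool:
    return not (set(c) & MISSING)


def nei_gojobori_pair(
    codons_1: Sequence[str], codons_2: Sequence[str]
) -> tuple[float, float, float, float]:
    """(syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs) for two codon lists.

    Codons containing missing residues are skipped pairwise; site counts are
    averaged over the two sequences. An internal stop codon in either input
    is an error (these are coding fragments, stops indicate a frame problem).
    """
    if len(codons_1) != len(codons_2):
        raise ValueError("codon lists differ in length")
    ss = ns = sd = nd = 0.0
    for k, (c1, c2) in enumerate(zip(codons_1, codons_2)):
        if not (_clean_codon(c1) and _clean_codon(c2)):
            continue
        for c in (c1, c2):
            if c in STOP_CODONS:
                raise ValueError(f"internal stop codon at codon index {k}: {c}")
        s1, n1 = _codon_site_fractions(c1)
        s2, n2 = _codon_site_fractions(c2)
        ss += 0.5 * (s1 + s2)
        ns += 0.5 * (n1 + n2)
        if c1 != c2:
            ds, dn = _codon_pair_diffs(c1, c2)
            sd += ds
            nd += dn
    return ss, ns, sd, nd


def pairwise_raw_distance(s1: str, s2: str) -> PairwiseDistance:
    """Raw and JC-corrected distance over sites called in both sequences."""
    (m, called) = _byte_matrix([s1, s2])
    both = called[0] & called[1]
    n = int(both.sum())
    if n == 0:
        raise ValueError("no overlapping called sites")
    p = float((m[0, both] != m[1, both]).sum()) / n
    return PairwiseDistance(p_raw=p, d_jc=jukes_cantor(p), n_compared=n)


class _CodonProfiles:
    """Precomputed per-row codon data for fast pairwise Nei–Gojobori sums.

    Per-pair results are identical to ``nei_gojobori_pair``; the speedup
    comes from vectorising the site-count sums and enumerating only the
    codons at which a pair actually differs.
    """

    def __init__(self, aln: LocusAlignment, rows: Sequence[int]):
        self.rows = list(rows)
        self.codons: dict[int, np.ndarray] = {}
        self.clean: dict[int, np.ndarray] = {}
        self.syn: dict[int, np.ndarray] = {}
        for r in self.rows:
            cods = aln.codon_strings(r)
            arr = np.array(cods, dtype="U3")
            ok = np.array([_clean_codon(c) for c in cods])
            for k in np.flatnonzero(ok):
                if cods[k] in STOP_CODONS:
                    raise ValueError(
                        f"{aln.locus_name}: internal stop codon at codon index {k}"
                        f" in {aln.sequences[r][0]}"
                    )
            syn = np.array([_codon_site_fractions(c)[0] if o else 0.0
                            for c, o in zip(cods, ok)])
            self.codons[r] = arr
            self.clean[r] = ok
            self.syn[r] = syn

    def pair(self, i: int, j: int) -> tuple[float, float, float, float]:
        both = self.clean[i] & self.clean[j]
        n_codons = int(both.sum())
        ss = 0.5 * float(self.syn[i][both].sum() + self.syn[j][both].sum())
        ns = 3.0 * n_codons - ss
        sd = nd = 0.0
        differ = both & (self.codons[i] != self.codons[j])
        for k in np.flatnonzero(differ):
            ds, dn = _codon_pair_diffs(str(self.codons[i][k]), str(self.codons[j][k]))
            sd += ds
            nd += dn
        return ss, ns, sd, nd


def _pair_sites_distance(
    aln: LocusAlignment, i: int, j: int, selector: str,
    profiles: "_CodonProfiles | None" = None,
) -> float | None:
    """JC distance for one pair under a site selector; None if uninformative."""
    if selector == "all":
        d = pairwise_raw_distance(aln.sequences[i][1], aln.sequences[j][1])
        return d.d_jc
    if profiles is not None:
        ss, ns, sd, nd = profiles.pair(i, j)
    else:
        ss, ns, sd, nd = nei_gojobori_pair(aln.codon_strings(i), aln.codon_strings(j))
    if selector == "synonymous":
        if ss <= 0:
            return None
        return jukes_cantor(sd / ss)
    if selector == "nonsynonymous":
        if ns <= 0:
            return None
        return jukes_cantor(nd / ns)
    raise ValueError(f"unknown selector {selector!r}")


def pairwise_diversity(
    aln: LocusAlignment, rows: Sequence[int], selector: str = "all"
) -> float:
    """Mean JC-corrected per-site diversity over all unordered pairs.

    ``selector`` restricts to 'all', 'synonymous' or 'nonsynonymous' sites
    (the latter two via per-pair Nei–Gojobori site counting). Saturated pairs
    are excluded with a warning.
    """
    if len(rows) < 2:
        raise ValueError("need >=2 sequences")
    profiles = _CodonProfiles(aln, rows) if selector != "all" else None
    vals = []
    n_sat = 0
    for i, j in itertools.combinations(rows, 2):
        try:
            d = _pair_sites_distance(aln, i, j, selector, profiles)
        except SaturationError:
            n_sat += 1
            continue
        if d is not None:
            vals.append(d)
    if n_sat:
        warnings.warn(
            f"{aln.locus_name}: {n_sat} saturated pair(s) excluded from pi_{selector}"
        )
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def _biallelic_01(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """0/1 matrix of biallelic, fully-called sites and their column indices."""
    m, called = _byte_matrix(seqs)
    cols = []
    rowsets = []
    for j in range(m.shape[1]):
        if not called[:, j].all():
            continue
        col = m[:, j]
        alleles = sorted(set(col.tobytes()))
        if len(alleles) != 2:
            continue
        cols.append(j)
        rowsets.append((col == bytes([alleles[1]])).astype(np.int64))
    if not cols:
        return np.empty((0, len(seqs)), dtype=np.int64), np.array([], dtype=int)
    return np.array(rowsets), np.asarray(cols)


def incompatible_intervals(seqs: Sequence[str]) -> list[tuple[int, int]]:
    """Site-index intervals bounded by four-gamete-incompatible pairs.

    Only biallelic sites with no missing data enter the test.
    """
    X, cols = _biallelic_01(seqs)
    S, n = X.shape
    if S < 2:
        return []
    ones = X.sum(axis=1)
    n11 = X @ X.T
    n10 = ones[:, None] - n11
    n01 = ones[None, :] - n11
    n00 = n - ones[:, None] - ones[None, :] + n11
    bad = (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)
    out = []
    for a in range(S):
        for b in range(a + 1, S):
            if bad[a, b]:
                out.append((int(cols[a]), int(cols[b])))
    return out


def min_recombination_events(seqs: Sequence[str]) -> int:
    """Hudson–Kaplan lower bound Rm on recombination events.

    Incompatible intervals are reduced (drop any interval containing another)
    and a maximal set of pairwise-disjoint open intervals is taken by the
    standard greedy left-to-right scan.
    """
    if len(seqs) < 2:
        raise ValueError("need >=2 sequences")
    intervals = incompatible_intervals(seqs)
    if not intervals:
        return 0
    # reduction: keep only intervals not strictly containing another
    intervals = sorted(set(intervals), key=lambda iv: (iv[1], -iv[0]))
    reduced = []
    for left, right in intervals:
        if not any(l >= left and r <= right and (l, r) != (left, right)
                   for l, r in intervals):
            reduced.append((left, right))
    reduced.sort(key=lambda iv: iv[1])
    rm = 0
    last_right = -1
    for left, right in reduced:
        if left >= last_right:
            rm += 1
            last_right = right
    return rm


def analyzed_sites(seqs: Sequence[str]) -> int:
    """Sites with >=2 non-missing residues among the sample."""
    _, called = _byte_matrix(seqs)
    return int((called.sum(axis=0) >= 2).sum())


def classify_polymorphisms(partition: SpeciesPartition) -> PolymorphismPartition:
    """Fixed / shared / private partition of sites between the two species.

    Per site (over residues called in each species): *fixed* iff both species
    are monomorphic for different alleles; *shared* iff both are polymorphic
    and share >=2 alleles; *private* iff exactly one is polymorphic. Sites
    with no called residue in either species are excluded from n_analyzed.
    """
    aln = partition.locus
    if not partition.lyrata_idx or not partition.halleri_idx:
        raise ValueError("both species must be non-empty")
    m, called = _byte_matrix([aln.sequences[i][1] for i in
                              list(partition.lyrata_idx) + list(partition.halleri_idx)])
    nA = len(partition.lyrata_idx)
    fixed = shared = privA = privB = analyzed = 0
    for j in range(m.shape[1]):
        a = set(m[:nA, j][called[:nA, j]].tobytes())
        b = set(m[nA:, j][called[nA:, j]].tobytes())
        if not a or not b:
            continue
        analyzed += 1
        if len(a) == 1 and len(b) == 1:
            if a != b:
                fixed += 1
        elif len(a) >= 2 and len(b) >= 2:
            if len(a & b) >= 2:
                shared += 1
        elif len(a) >= 2:
            privA += 1
        else:
            privB += 1
    return PolymorphismPartition(fixed, shared, privA, privB, analyzed)


def divergence_extremes(partition: SpeciesPartition) -> DivergenceExtremes:
    """Lowest/highest JC-corrected Ks and Kn over all interspecific pairs."""
    aln = partition.locus
    if not partition.lyrata_idx or not partition.halleri_idx:
        raise ValueError("both species must be non-empty")
    ks: list[tuple[float, tuple[str, str]]] = []
    kn: list[tuple[float, tuple[str, str]]] = []
    n_sat = 0
    profiles = _CodonProfiles(
        aln, list(partition.lyrata_idx) + list(partition.halleri_idx))
    for i in partition.lyrata_idx:
        for j in partition.halleri_idx:
            ss, ns, sd, nd = profiles.pair(i, j)
            pair = (aln.sequences[i][0], aln.sequences[j][0])
            try:
                if ss > 0:
                    ks.append((jukes_cantor(sd / ss), pair))
                if ns > 0:
                    kn.append((jukes_cantor(nd / ns), pair))
            except SaturationError:
                n_sat += 1
    if not ks and not kn:
        raise SaturationError(f"{aln.locus_name}: all interspecific pairs saturated")
    if n_sat:
        warnings.warn(f"{aln.locus_name}: {n_sat} saturated pair(s) excluded from Ks/Kn")
    nan = (float("nan"), ("", ""))
    ks_lo = min(ks, key=lambda t: t[0]) if ks else nan
    ks_hi = max(ks, key=lambda t: t[0]) if ks else nan
    kn_lo = min(kn, key=lambda t: t[0]) if kn else nan
    kn_hi = max(kn, key=lambda t: t[0]) if kn else nan
    return DivergenceExtremes(
        Ks_L=ks_lo[0], Ks_H=ks_hi[0], Kn_L=kn_lo[0], Kn_H=kn_hi[0],
        Ks_L_pair=ks_lo[1], Ks_H_pair=ks_hi[1], Kn_L_pair=kn_lo[1], Kn_H_pair=kn_hi[1],
    )


def diversity_summary(aln: LocusAlignment, rows: Sequence[int]) -> DiversitySummary:
    """Per-species summary: S, haplotypes, pi_s/pi_a/pi_total, Rm, Rm per site."""
    seqs = [aln.sequences[i][1] for i in rows]
    S = segregating_sites(seqs)
    n_hap = count_haplotypes(seqs)
    rm = min_recombination_events(seqs)
    n_sites = analyzed_sites(seqs)
    return DiversitySummary(
        S=S,
        n_haplotypes=n_hap,
        pi_s=pairwise_diversity(aln, rows, "synonymous"),
        pi_a=pairwise_diversity(aln, rows, "nonsynonymous"),
        pi_total=pairwise_diversity(aln, rows, "all"),
        Rm=rm,
        Rm_per_site=rm / n_sites if n_sites else float("nan"),
        n_analyzed_sites=n_sites,
    )


def summarize_gene_class(
    values: Sequence[float], n_boot: int = 10_000, seed: int | None = None
) -> dict:
    """Unweighted mean across loci with a percentile bootstrap 95% CI.

    With a single locus the mean is returned and the CI flagged undefined.
    """
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        return {"mean": float("nan"), "ci_low": float("nan"), "ci_high": float("nan"),
                "n_loci": 0, "ci_defined": False}
    mean = float(vals.mean())
    if vals.size < 2:
        return {"mean": mean, "ci_low": float("nan"), "ci_high": float("nan"),
                "n_loci": 1, "ci_defined": False}
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    boots = vals[idx].mean(axis=1)
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return {"mean": mean, "ci_low": float(lo), "ci_high": float(hi),
            "n_loci": int(vals.size), "ci_defined": True}
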