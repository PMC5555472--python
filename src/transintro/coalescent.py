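"""Two-species isolation-with-migration coalescent simulator.

Simulates per-locus samples from two populations (haploid sizes 2N) that
diverged T years ago from a common ancestral population, exchanging migrants
symmetrically at a per-sequence rate m per generation. Time runs backwards in
continuous (exact Gillespie) time: within-deme coalescence at rate
k(k-1)/2 / 2N per generation, migration at rate m per lineage, recombination
at rate r per site per generation over each lineage's ancestral span, and
infinite-sites mutation at rate mu per site per generation over ancestral
material. At the split time the demes merge into a single ancestral deme of
haploid size 2N_ancestral.

With r = 0 the history is a single genealogy and a faster tree-based engine
is used; with r > 0 a segment-tracking ancestral-recombination-graph engine
runs the same event algebra. Mutations are recorded as (position, carrier
set) pairs: under infinite sites two haplotypes are identical iff no mutation
separates them, which is what the headline statistic — the number of loci in
which some pair of sequences from the two species is identical — consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IMParams",
    "SimulatedLocus",
    "simulate_locus",
    "identical_interspecific_indicator",
    "simulate_gene_class",
    "run_grid",
    "cross_validate_simulator",
    "GRID_INTROGRESSION_RATES",
    "GRID_T_SPLIT_YEARS",
    "GRID_N",
    "GRID_REC",
]

# The default simulation grid: six distinct introgression rates (alleles
# moved between species per generation), split times per branch in years,
# diploid population sizes, and per-site recombination rates.
GRID_INTROGRESSION_RATES = (0.0, 2e-8, 4e-8, 8e-8, 1e-7, 1.5e-7)
GRID_T_SPLIT_YEARS = (560_000.0, 750_000.0)
GRID_N = (150_000.0, 600_000.0)
GRID_REC = (0.0, 4.3e-9)

_MAX_EVENTS = 2_000_000


@dataclass(frozen=True)
class IMParams:
    """Full parameterization of the two-population IM model.

    Sizes are diploid individuals per species; ``T_split_years`` is the time
    on each branch from the present to the split; ``mu`` is per site per
    year, ``rec`` and ``m_intro`` per generation.
    """

    N_current: float
    T_split_years: float
    N_ancestral: float | None = None
    generation_time_years: float = 1.0
    mu: float = 4e-9
    rec: float = 0.0
    m_intro: float = 0.0
    L: int = 730
    n_sample_A: int = 48
    n_sample_B: int = 23
    n_loci: int = 10

    def __post_init__(self):
        if self.N_current <= 0 or (self.N_ancestral is not None and self.N_ancestral <= 0):
            raise ValueError("population sizes must be positive")
        if self.T_split_years < 0:
            raise ValueError("T_split_years must be >= 0")
        for name in ("mu", "rec"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.m_intro <= 1.0:
            raise ValueError("m_intro must be in [0, 1]")
        if self.L < 1 or self.n_loci < 1:
            raise ValueError("L and n_loci must be >= 1")
        if self.n_sample_A < 1 or self.n_sample_B < 0:
            raise ValueError("need >=1 sample in A and >=0 in B")

    @property
    def N_anc(self) -> float:
        return self.N_current if self.N_ancestral is None else self.N_ancestral

    @property
    def T_gen(self) -> float:
        return self.T_split_years / self.generation_time_years

    @property
    def mu_gen(self) -> float:
        return self.mu * self.generation_time_years


@dataclass
class SimulatedLocus:
    """Infinite-sites output of one locus simulation.

    ``masks[k]`` is the integer bitmask of samples carrying mutation k
    (species A occupies bits 0..n_A-1, species B bits n_A..n_A+n_B-1);
    ``positions[k]`` its continuous position in [0, L).
    """

    n_A: int
    n_B: int
    L: int
    positions: np.ndarray
    masks: list[int]
    genealogy_monophyletic_A: bool | None = None
    genealogy_monophyletic_B: bool | None = None

    @property
    def n(self) -> int:
        return self.n_A + self.n_B

    def sample_keys(self) -> list[int]:
        """Per-sample haplotype key: bit k set iff the sample carries mutation k."""
        keys = [0] * self.n
        for k, m in enumerate(self.masks):
            bit = 1 << k
            while m:
                low = m & -m
                keys[low.bit_length() - 1] |= bit
                m ^= low
        return keys

    def genotype_matrix(self) -> np.ndarray:
        """(n, S) 0/1 matrix in position order."""
        order = np.argsort(self.positions, kind="stable")
        G = np.zeros((self.n, len(self.masks)), dtype=np.uint8)
        for out_col, k in enumerate(order):
            m = self.masks[k]
            while m:
                low = m & -m
                G[low.bit_length() - 1, out_col] = 1
                m ^= low
        return G

    def segregating_sites(self, subset: Sequence[int] | None = None) -> int:
        mask = self._subset_mask(subset)
        nsub = bin(mask).count("1")
        return sum(1 for m in self.masks if 0 < bin(m & mask).count("1") < nsub)

    def mean_pairwise_diversity(self, subset: Sequence[int] | None = None) -> float:
        """Mean pairwise differences per site within a sample subset."""
        mask = self._subset_mask(subset)
        nsub = bin(mask).count("1")
        if nsub < 2:
            raise ValueError("need >=2 samples")
        tot = 0
        for m in self.masks:
            c = bin(m & mask).count("1")
            tot += c * (nsub - c)
        return tot / (nsub * (nsub - 1) / 2) / self.L

    def _subset_mask(self, subset: Sequence[int] | None) -> int:
        if subset is None:
            return (1 << self.n) - 1
        out = 0
        for i in subset:
            out |= 1 << i
        return out


def _sim_tree(nA: int, nB: int, twoN: float, twoN_anc: float, T_gen: float,
              m: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Structured-coalescent genealogy without recombination.

    Returns (parent, time) arrays over 2n-1 nodes; leaves 0..n-1 (A first),
    internal nodes appended in coalescence order; root parent is -1.
    """
    n = nA + nB
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    times = np.zeros(2 * n - 1, dtype=float)
    demes = [list(range(nA)), list(range(nA, n))]
    next_node = n
    t = 0.0
    merged = T_gen <= 0.0
    if merged:
        demes = [demes[0] + demes[1], []]
    events = 0
    while len(demes[0]) + len(demes[1]) > 1:
        events += 1
        if events > _MAX_EVENTS:
            raise RuntimeError("coalescent event cap exceeded (tree engine)")
        k0, k1 = len(demes[0]), len(demes[1])
        size = twoN_anc if merged else twoN
        c0 = k0 * (k0 - 1) / 2.0 / size
        c1 = k1 * (k1 - 1) / 2.0 / size
        mig = 0.0 if merged else m * (k0 + k1)
        total = c0 + c1 + mig
        if total <= 0.0:
            # lone lineages in separate demes waiting for the merge
            t = T_gen
            demes = [demes[0] + demes[1], []]
            merged = True
            continue
        dt = rng.exponential(1.0 / total)
        if not merged and t + dt >= T_gen:
            t = T_gen
            demes = [demes[0] + demes[1], []]
            merged = True
            continue
        t += dt
        u = rng.random() * total
        if u < c0 + c1:
            d = 0 if u < c0 else 1
            pool = demes[d]
            k = len(pool)
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            a, b = pool[i], pool[j]
            node = next_node
            next_node += 1
            parent[a] = parent[b] = node
            times[node] = t
            # swap-pop both, then append the new node
            for victim in sorted((i, j), reverse=True):
                pool[victim] = pool[-1]
                pool.pop()
            pool.append(node)
        else:
            src = 0 if demes[0] and (not demes[1] or rng.random() < k0 / (k0 + k1)) else 1
            pool = demes[src]
            i = int(rng.integers(len(pool)))
            lin = pool[i]
            pool[i] = pool[-1]
            pool.pop()
            demes[1 - src].append(lin)
    return parent, times


def _tree_masks(parent: np.ndarray, n: int) -> list[int]:
    masks = [0] * len(parent)
    for i in range(n):
        masks[i] = 1 << i
    for node in range(len(parent) - 1):
        masks[parent[node]] |= masks[node]
    return masks


def _genealogy_monophyly(masks: list[int], nA: int, n: int) -> tuple[bool, bool]:
    maskA = (1 << nA) - 1
    maskB = ((1 << n) - 1) ^ maskA
    monoA = nA == 1 or any(m == maskA for m in masks)
    monoB = (n - nA) == 1 or any(m == maskB for m in masks)
    return monoA, monoB


def _mutate_tree(parent: np.ndarray, times: np.ndarray, n: int, mu_site_gen: float,
                 L: int, rng: np.random.Generator) -> tuple[np.ndarray, list[int]]:
    masks = _tree_masks(parent, n)
    bl = times[parent[:-1]] - times[:-1]
    counts = rng.poisson(mu_site_gen * L * bl)
    out_masks: list[int] = []
    for v in np.flatnonzero(counts):
        out_masks.extend([masks[v]] * counts[v])
    positions = rng.uniform(0.0, L, size=len(out_masks))
    return positions, out_masks, masks


class _Lineage:
    __slots__ = ("segs", "deme", "anc_len", "span")

    def __init__(self, segs, deme):
        self.segs = segs  # list of (left, right, mask), sorted, non-overlapping
        self.deme = deme
        self.anc_len = sum(r - l for l, r, _ in segs)
        self.span = segs[-1][1] - segs[0][0]


def _merge_segments(a, b, full_mask):
    """Union two segment lists, OR-ing masks on overlaps; drop fully coalesced."""
    points = sorted({p for l, r, _ in a + b for p in (l, r)})
    out = []
    ia = ib = 0
    for lo, hi in zip(points[:-1], points[1:]):
        mask = 0
        for segs in (a, b):
            for l, r, m in segs:
                if l < hi and r > lo:
                    mask |= m
        if mask and mask != full_mask:
            if out and out[-1][1] == lo and out[-1][2] == mask:
                out[-1] = (out[-1][0], hi, mask)
            else:
                out.append((lo, hi, mask))
    return out


def _sim_arg(nA: int, nB: int, twoN: float, twoN_anc: float, T_gen: float, m: float,
             rec: float, mu_site_gen: float, L: int,
             rng: np.random.Generator) -> tuple[list[float], list[int]]:
    """Structured coalescent with recombination; returns mutation (pos, mask) lists."""
    n = nA + nB
    full = (1 << n) - 1
    lineages = [_Lineage([(0.0, float(L), 1 << i)], 0 if i < nA else 1) for i in range(n)]
    mut_pos: list[float] = []
    mut_masks: list[int] = []
    t = 0.0
    merged = T_gen <= 0.0
    if merged:
        for lin in lineages:
            lin.deme = 0
    k0 = sum(1 for lin in lineages if lin.deme == 0)
    tot_span = sum(lin.span for lin in lineages)
    tot_anc = sum(lin.anc_len for lin in lineages)
    events = 0
    exponential = rng.exponential
    random = rng.random
    while lineages:
        events += 1
        if events > _MAX_EVENTS:
            raise RuntimeError("coalescent event cap exceeded (ARG engine)")
        k1 = len(lineages) - k0
        size = twoN_anc if merged else twoN
        c0 = k0 * (k0 - 1) / 2.0 / size
        c1 = k1 * (k1 - 1) / 2.0 / size
        mig = 0.0 if merged else m * len(lineages)
        r_rate = rec * tot_span
        m_rate = mu_site_gen * tot_anc
        total = c0 + c1 + mig + r_rate + m_rate
        if total <= 0.0:
            if merged:
                raise RuntimeError("zero total rate in merged phase")
            t = T_gen
            merged = True
            k0 = len(lineages)
            for lin in lineages:
                lin.deme = 0
            continue
        dt = exponential(1.0 / total)
        if not merged and t + dt >= T_gen:
            t = T_gen
            merged = True
            k0 = len(lineages)
            for lin in lineages:
                lin.deme = 0
            continue
        t += dt
        u = random() * total
        if u < c0 + c1:
            d = 0 if u < c0 else 1
            pool = [i for i, lin in enumerate(lineages) if lin.deme == d]
            k = len(pool)
            i = int(random() * k)
            j = int(random() * (k - 1))
            if j >= i:
                j += 1
            ia, ib = pool[i], pool[j]
            a, b = lineages[ia], lineages[ib]
            segs = _merge_segments(a.segs, b.segs, full)
            tot_span -= a.span + b.span
            tot_anc -= a.anc_len + b.anc_len
            for idx in sorted((ia, ib), reverse=True):
                lineages[idx] = lineages[-1]
                lineages.pop()
            if d == 0:
                k0 -= 1
            if segs:
                child = _Lineage(segs, d)
                lineages.append(child)
                tot_span += child.span
                tot_anc += child.anc_len
            elif d == 0:
                k0 -= 1
        elif u < c0 + c1 + mig:
            lin = lineages[int(random() * len(lineages))]
            k0 += 1 if lin.deme == 1 else -1
            lin.deme = 1 - lin.deme
        elif u < c0 + c1 + mig + r_rate:
            x = (u - c0 - c1 - mig) / rec  # position along cumulative spans
            idx = 0
            while x > lineages[idx].span:
                x -= lineages[idx].span
                idx += 1
            lin = lineages[idx]
            bp = lin.segs[0][0] + x
            left = [s for s in lin.segs if s[1] <= bp]
            right = [s for s in lin.segs if s[0] >= bp]
            for l, r, msk in lin.segs:
                if l < bp < r:
                    left.append((l, bp, msk))
                    right.append((bp, r, msk))
            if left and right:
                left.sort()
                right.sort()
                tot_span -= lin.span
                tot_anc -= lin.anc_len
                lin.segs = left
                lin.anc_len = sum(r - l for l, r, _ in left)
                lin.span = left[-1][1] - left[0][0]
                sib = _Lineage(right, lin.deme)
                lineages.append(sib)
                if lin.deme == 0:
                    k0 += 1
                tot_span += lin.span + sib.span
                tot_anc += lin.anc_len + sib.anc_len
            # breakpoint outside ancestral material on one side: no-op split
        else:
            x = (u - c0 - c1 - mig - r_rate) / mu_site_gen
            idx = 0
            while x > lineages[idx].anc_len:
                x -= lineages[idx].anc_len
                idx += 1
            lin = lineages[idx]
            for l, r, msk in lin.segs:
                if x <= r - l:
                    mut_pos.append(l + x)
                    mut_masks.append(msk)
                    break
                x -= r - l
    return mut_pos, mut_masks


def simulate_locus(params: IMParams, rng: np.random.Generator | int | None = None,
                   record_genealogy: bool = True) -> SimulatedLocus:
    """Simulate one locus under the IM model.

    ``rng`` may be a Generator, an integer seed, or None. With ``rec == 0``
    the single genealogy is recorded and its reciprocal species monophyly
    stored on the result (used as ground truth by the synthetic-data module).
    """
    rng = np.random.default_rng(rng)
    nA, nB = params.n_sample_A, params.n_sample_B
    twoN = 2.0 * params.N_current
    twoN_anc = 2.0 * params.N_anc
    if params.rec == 0.0:
        parent, times = _sim_tree(nA, nB, twoN, twoN_anc, params.T_gen,
                                  params.m_intro, rng)
        positions, masks, node_masks = _mutate_tree(
            parent, times, nA + nB, params.mu_gen, params.L, rng)
        monoA = monoB = None
        if record_genealogy and nB > 0:
            monoA, monoB = _genealogy_monophyly(node_masks, nA, nA + nB)
        return SimulatedLocus(nA, nB, params.L, positions, masks, monoA, monoB)
    pos, masks = _sim_arg(nA, nB, twoN, twoN_anc, params.T_gen, params.m_intro,
                          params.rec, params.mu_gen, params.L, rng)
    return SimulatedLocus(nA, nB, params.L, np.asarray(pos), masks)


def identical_interspecific_indicator(locus: SimulatedLocus) -> bool:
    """True iff some A/B pair of haplotypes carries zero differentiating mutations."""
    if locus.n_A < 1 or locus.n_B < 1:
        raise ValueError("both samples must be non-empty")
    keys = locus.sample_keys()
    return bool(set(keys[: locus.n_A]) & set(keys[locus.n_A :]))


def simulate_gene_class(params: IMParams, n_replicates: int = 100,
                        rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Replicate distribution of the identical-locus count for one gene class.

    Each replicate simulates ``params.n_loci`` independent loci and counts
    those containing an identical interspecific pair.
    """
    rng = np.random.default_rng(rng)
    counts = np.empty(n_replicates, dtype=np.int64)
    for r in range(n_replicates):
        c = 0
        for _ in range(params.n_loci):
            locus = simulate_locus(params, rng, record_genealogy=False)
            if identical_interspecific_indicator(locus):
                c += 1
        counts[r] = c
    return counts


def run_grid(
    class_specs: dict[str, dict],
    m_intro_rates: Sequence[float] = GRID_INTROGRESSION_RATES,
    T_split_years: Sequence[float] = GRID_T_SPLIT_YEARS,
    N_values: Sequence[float] = GRID_N,
    rec_rates: Sequence[float] = GRID_REC,
    mu: float = 4e-9,
    generation_time_years: float = 1.0,
    n_replicates: int = 100,
    seed: int | None = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Full-factorial simulation grid over both gene classes.

    ``class_specs`` maps class name -> {n_loci, L, n_A, n_B}. Returns a long
    DataFrame with one row per (class, m, T, N, r) combination carrying the
    replicate counts and their 2.5/50/97.5% quantiles. Reproducible under
    ``seed``; rows get independent child seeds so the result is independent
    of execution order and of ``n_jobs``.
    """
    rows = []
    for cls in sorted(class_specs):
        spec = class_specs[cls]
        for m in m_intro_rates:
            for T in T_split_years:
                for N in N_values:
                    for r in rec_rates:
                        rows.append((cls, spec, m, T, N, r))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(rows))

    def one(row, child):
        cls, spec, m, T, N, r = row
        params = IMParams(
            N_current=N, T_split_years=T, mu=mu, rec=r, m_intro=m,
            generation_time_years=generation_time_years,
            L=spec["L"], n_sample_A=spec["n_A"], n_sample_B=spec["n_B"],
            n_loci=spec["n_loci"],
        )
        counts = simulate_gene_class(params, n_replicates, np.random.default_rng(child))
        q = np.quantile(counts, [0.025, 0.5, 0.975])
        return {
            "gene_class": cls, "m_intro": m, "T_split_years": T, "N": N, "rec": r,
            "n_loci": spec["n_loci"], "L": spec["L"],
            "n_A": spec["n_A"], "n_B": spec["n_B"],
            "counts": counts.tolist(), "q2.5": q[0], "q50": q[1], "q97.5": q[2],
            "mean": counts.mean(),
        }

    if n_jobs != 1:
        try:
            from joblib import Parallel, delayed

            results = Parallel(n_jobs=n_jobs)(
                delayed(one)(row, child) for row, child in zip(rows, children)
            )
        except ImportError:
            results = [one(row, child) for row, child in zip(rows, children)]
    else:
        results = [one(row, child) for row, child in zip(rows, children)]
    return pd.DataFrame(results)


def cross_validate_simulator(params: IMParams, n_replicates: int = 2000,
                             seed: int | None = None) -> dict:
    """Compare this simulator with msprime under matched parameters.

    Reports z-scores for mean segregating sites, mean within-A pairwise
    diversity, and the probability that an identical interspecific pair
    exists. Returns {"status": "skipped"} if msprime is unavailable.
    """
    try:
        import msprime
    except ImportError:
        return {"status": "skipped", "reason": "msprime unavailable"}

    rng = np.random.default_rng(seed)
    mine_S, mine_pi, mine_id = [], [], []
    for _ in range(n_replicates):
        loc = simulate_locus(params, rng, record_genealogy=False)
        mine_S.append(loc.segregating_sites())
        if params.n_sample_A >= 2:
            mine_pi.append(loc.mean_pairwise_diversity(range(params.n_sample_A)))
        if params.n_sample_B >= 1:
            mine_id.append(identical_interspecific_indicator(loc))

    demography = msprime.Demography()
    if params.T_gen > 0:
        demography.add_population(name="A", initial_size=params.N_current)
        demography.add_population(name="B", initial_size=params.N_current)
        demography.add_population(name="ANC", initial_size=params.N_anc)
        if params.m_intro > 0:
            demography.set_symmetric_migration_rate(["A", "B"], params.m_intro)
        demography.add_population_split(time=params.T_gen, derived=["A", "B"],
                                        ancestral="ANC")
        samples = [msprime.SampleSet(params.n_sample_A, population="A", ploidy=1)]
        if params.n_sample_B:
            samples.append(msprime.SampleSet(params.n_sample_B, population="B",
                                             ploidy=1))
    else:
        # split at time zero: a single panmictic ancestral population
        demography.add_population(name="ANC", initial_size=params.N_anc)
        samples = [msprime.SampleSet(params.n_sample_A + params.n_sample_B,
                                     population="ANC", ploidy=1)]
    orac_S, orac_pi, orac_id = [], [], []
    reps = msprime.sim_ancestry(
        samples=samples, demography=demography, sequence_length=params.L,
        recombination_rate=params.rec, num_replicates=n_replicates,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    mut_seed = int(rng.integers(1, 2**31 - 1))
    for i, ts in enumerate(reps):
        mts = msprime.sim_mutations(ts, rate=params.mu_gen, discrete_genome=False,
                                    random_seed=mut_seed + i)
        orac_S.append(mts.num_sites)
        if params.n_sample_A >= 2:
            orac_pi.append(float(mts.diversity(
                sample_sets=list(range(params.n_sample_A)))))
        if params.n_sample_B >= 1:
            G = mts.genotype_matrix().T
            a = {row.tobytes() for row in G[: params.n_sample_A]}
            b = {row.tobytes() for row in G[params.n_sample_A :]}
            orac_id.append(bool(a & b))

    def z(x, y):
        x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        se = math.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
        return float((x.mean() - y.mean()) / se) if se > 0 else 0.0

    report = {
        "status": "ok",
        "n_replicates": n_replicates,
        "mean_S": float(np.mean(mine_S)),
        "oracle_mean_S": float(np.mean(orac_S)),
        "z_S": z(mine_S, orac_S),
    }
    if mine_pi:
        report.update(mean_pi=float(np.mean(mine_pi)),
                      oracle_mean_pi=float(np.mean(orac_pi)),
                      z_pi=z(mine_pi, orac_pi))
    if mine_id:
        report.update(p_identical=float(np.mean(mine_id)),
                      oracle_p_identical=float(np.mean(orac_id)),
                      z_identical=z(mine_id, orac_id))
    return report
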