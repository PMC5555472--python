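"""Statistical decision rules for the gene-class contrasts.

Three families of tests:

* an *envelope test* comparing an observed count with the central 95% of a
  simulated null distribution (2.5% in each tail, type-7 empirical
  quantiles; an observation exactly on a quantile counts as consistent);
* two-sided Fisher exact tests on 2x2 gene-class contingency tables
  (point-probability rule, via scipy);
* permutation tests on the absolute difference of unweighted class means of
  per-locus proportions, with add-one p-value correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestVerdict",
    "envelope_test",
    "fisher_exact_2x2",
    "permutation_mean_diff_test",
    "compare_observed_to_grid",
]


@dataclass(frozen=True)
class TestVerdict:
    test_name: str
    observed: float
    decision: str  # consistent | excess | deficit | significant | not_significant
    p_value: float | None = None
    null_summary: dict = field(default_factory=dict)
    n_resamples: int | None = None
    seed: int | None = None


def envelope_test(observed: float, replicate_counts, tail: float = 0.025,
                  name: str = "envelope") -> TestVerdict:
    """Position an observed count against a simulated null distribution.

    Decision is *excess* if the observation exceeds the upper 1-tail
    quantile, *deficit* if below the lower, else *consistent*; ties at a
    quantile are consistent (conservative reading of a tail rule).
    """
    counts = np.asarray(replicate_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty replicate vector")
    if counts.size < 20:
        raise ValueError("need >=20 replicates for a 2.5% tail rule")
    q_lo, q_med, q_hi = np.quantile(counts, [tail, 0.5, 1.0 - tail])  # type-7
    if observed > q_hi:
        decision = "excess"
    elif observed < q_lo:
        decision = "deficit"
    else:
        decision = "consistent"
    return TestVerdict(
        test_name=name,
        observed=float(observed),
        decision=decision,
        null_summary={"q2.5": float(q_lo), "q50": float(q_med), "q97.5": float(q_hi),
                      "n": int(counts.size)},
        n_resamples=int(counts.size),
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def permutation_mean_diff_test(
    values_class1,
    values_class2,
    n_perm: int = 10_000,
    seed: int | None = None,
    name: str = "permutation_mean_diff",
) -> TestVerdict:
    """Permutation test on |mean(class1) - mean(class2)|.

    The null is built by shuffling class labels over the pooled loci;
    p = (1 + #{perm >= obs}) / (1 + n_perm), two-sided by construction.
    """
    x1 = np.asarray(values_class1, dtype=float)
    x2 = np.asarray(values_class2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both classes must be non-empty")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-value resolution is poor")
    pooled = np.concatenate([x1, x2])
    n1 = x1.size
    observed = abs(x1.mean() - x2.mean())
    rng = np.random.default_rng(seed)
    # vectorised label shuffles: each row of `order` is one permutation
    order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    perm = pooled[order]
    stat = np.abs(perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1))
    p = (1.0 + np.count_nonzero(stat >= observed)) / (1.0 + n_perm)
    return TestVerdict(
        test_name=name,
        observed=float(observed),
        decision="significant" if p < 0.05 else "not_significant",
        p_value=float(p),
        null_summary={"mean": float(stat.mean()), "q97.5": float(np.quantile(stat, 0.975))},
        n_resamples=n_perm,
        seed=seed,
    )


def compare_observed_to_grid(
    observed: dict[str, int], grid: pd.DataFrame, tail: float = 0.025
) -> pd.DataFrame:
    """Envelope verdicts for every grid row, plus per-combination summaries.

    ``observed`` maps gene-class name -> observed identical-locus count.
    Adds per row the verdict and, per (class, T, N, rec) combination, the
    minimal introgression rate whose envelope contains the observation
    (NaN if none does) and whether introgression is required (the m=0
    envelope excludes the observation from above).
    """
    rows = []
    for _, row in grid.iterrows():
        obs = observed[row["gene_class"]]
        verdict = envelope_test(obs, row["counts"], tail=tail)
        rows.append({
            **{k: row[k] for k in ("gene_class", "m_intro", "T_split_years", "N", "rec",
                                   "q2.5", "q50", "q97.5")},
            "observed": obs,
            "decision": verdict.decision,
        })
    report = pd.DataFrame(rows)
    summaries = []
    for (cls, T, N, r), sub in report.groupby(["gene_class", "T_split_years", "N", "rec"]):
        sub = sub.sort_values("m_intro")
        ok = sub.loc[sub["decision"] == "consistent", "m_intro"]
        zero = sub[sub["m_intro"] == 0.0]
        # introgression is "required" only when the observation exceeds the
        # no-migration envelope (an excess, not a deficit)
        required = bool(len(zero)) and (zero["decision"] == "excess").all()
        summaries.append({
            "gene_class": cls, "T_split_years": T, "N": N, "rec": r,
            "min_consistent_m": float(ok.iloc[0]) if len(ok) else float("nan"),
            "introgression_required": required,
        })
    report.attrs["summary"] = pd.DataFrame(summaries)
    return report
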