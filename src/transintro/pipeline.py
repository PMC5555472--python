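"""End-to-end orchestration: stats -> phylo -> simulation -> tests.

A RunConfig points at per-locus FASTA alignments, a sample sheet and a
gene-class assignment, and carries the simulation-grid settings and a master
seed. Each stage writes plain TSV/Newick/JSON artifacts into the output
directory and returns its tables; ``run_all`` chains the stages and writes a
consolidated JSON report embedding the config hash and seed. The master seed
is expanded into independent per-stage child seeds, so stages are
reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coalescent, inference, phylo, popgen
from .io import (
    LocusAlignment,
    SampleSheet,
    duplicate_singleton_haplotypes,
    partition_by_species,
    read_locus_alignment,
    read_sample_sheet,
)

__all__ = ["RunConfig", "load_dataset", "run_stats", "run_phylo",
           "run_simulation", "run_tests", "run_all"]

logger = logging.getLogger(__name__)

_STAGES = ("stats", "phylo", "simulation", "tests")


@dataclass
class RunConfig:
    """Inputs, gene-class assignment and options for one pipeline run."""

    loci: list[dict]              # {locus, fasta, gene_class, frame_offset?, coding_ranges?}
    sample_sheet: str
    out_dir: str = "transintro_out"
    seed: int = 0
    assume_homozygous: bool = True
    homozygous_exempt_loci: list[str] = field(default_factory=list)
    n_bootstrap_trees: int = 0    # per-locus tree bootstrap replicates (0 = skip)
    n_boot_ci: int = 10_000
    n_permutations: int = 10_000
    grid: dict = field(default_factory=dict)   # overrides for coalescent.run_grid
    observed_counts: dict = field(default_factory=dict)  # optional per-class override

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in {".yml", ".yaml"} else json.load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed, spawn_key=(_STAGES.index(stage),))


def _out(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _stamp(cfg: RunConfig, df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = cfg.config_hash()
    df["seed"] = cfg.seed
    return df


def load_dataset(cfg: RunConfig):
    """Read sheet and loci; returns (list[(LocusAlignment, gene_class)], sheet)."""
    sheet = read_sample_sheet(cfg.sample_sheet)
    loci = []
    for entry in cfg.loci:
        aln = read_locus_alignment(
            entry["fasta"], sheet,
            coding_ranges=entry.get("coding_ranges"),
            frame_offset=entry.get("frame_offset", 0),
            locus_name=entry.get("locus"),
        )
        aln = duplicate_singleton_haplotypes(
            aln, sheet, cfg.assume_homozygous, cfg.homozygous_exempt_loci
        )
        loci.append((aln, entry["gene_class"]))
    return loci, sheet


def run_stats(cfg: RunConfig, dataset=None) -> dict[str, pd.DataFrame]:
    """Per-locus and per-class summary statistics (diversity, Rm, partitions)."""
    loci, sheet = dataset or load_dataset(cfg)
    rows = []
    failures = []
    for aln, cls in loci:
        try:
            part = partition_by_species(aln, sheet)
            row = {"locus": aln.locus_name, "gene_class": cls}
            for species, idx in (("lyrata", part.lyrata_idx), ("halleri", part.halleri_idx)):
                if len(idx) >= 2:
                    s = popgen.diversity_summary(aln, idx)
                    row.update({f"{species}_{k}": v for k, v in asdict(s).items()})
            pp = popgen.classify_polymorphisms(part)
            row.update(n_fixed=pp.n_fixed, n_shared=pp.n_shared,
                       n_private_lyrata=pp.n_private_A, n_private_halleri=pp.n_private_B,
                       n_analyzed=pp.n_analyzed,
                       prop_fixed=pp.prop_fixed, prop_shared=pp.prop_shared)
            ext = popgen.divergence_extremes(part)
            row.update(Ks_L=ext.Ks_L, Ks_H=ext.Ks_H, Kn_L=ext.Kn_L, Kn_H=ext.Kn_H)
            row["identical_interspecific_pair"] = phylo.has_identical_interspecific_pair(part)
            rows.append(row)
        except Exception as exc:  # record and continue; fail only if all fail
            logger.error("stats failed for %s: %s", aln.locus_name, exc)
            failures.append((aln.locus_name, str(exc)))
    if not rows:
        raise RuntimeError(f"all loci failed in stats stage: {failures}")
    per_locus = pd.DataFrame(rows)

    seed = int(cfg.stage_seed("stats").generate_state(1)[0] % (2**31))
    summary_rows = []
    for cls, sub in per_locus.groupby("gene_class"):
        for species in ("lyrata", "halleri"):
            for stat in ("pi_s", "pi_a", "pi_total", "Rm_per_site"):
                col = f"{species}_{stat}"
                if col not in sub:
                    continue
                s = popgen.summarize_gene_class(sub[col].dropna(), cfg.n_boot_ci, seed)
                summary_rows.append({"gene_class": cls, "species": species,
                                     "statistic": stat, **s})
    class_summary = pd.DataFrame(summary_rows)
    out = _out(cfg)
    _stamp(cfg, per_locus).to_csv(out / "per_locus_stats.tsv", sep="\t", index=False)
    _stamp(cfg, class_summary).to_csv(out / "class_summary.tsv", sep="\t", index=False)
    return {"per_locus": per_locus, "class_summary": class_summary,
            "failures": failures}


def run_phylo(cfg: RunConfig, dataset=None) -> dict:
    """NJ trees, trans-specific calls and the gene-class Fisher contrasts."""
    loci, sheet = dataset or load_dataset(cfg)
    out = _out(cfg)
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)
    seed = int(cfg.stage_seed("phylo").generate_state(1)[0] % (2**31))
    calls = []
    for aln, cls in loci:
        if len(aln.sequences) < 3:
            logger.warning("%s: <3 sequences, skipped", aln.locus_name)
            continue
        part = partition_by_species(aln, sheet)
        if cfg.n_bootstrap_trees > 0:
            tree = phylo.bootstrap_support(aln, n_boot=cfg.n_bootstrap_trees, seed=seed)
        else:
            tree = phylo.neighbor_joining(phylo.jc_distance_matrix(aln))
        tree.write(str(tree_dir / f"{aln.locus_name}.nwk"))
        call = phylo.classify_trans_specific(tree, part)
        calls.append({"gene_class": cls, **asdict(call),
                      "identical_interspecific_pair":
                          phylo.has_identical_interspecific_pair(part)})
    calls_df = pd.DataFrame(calls)
    _stamp(cfg, calls_df).to_csv(out / "trans_specific_calls.tsv", sep="\t", index=False)

    def contrast(col):
        classes = sorted(calls_df["gene_class"].unique())
        if len(classes) != 2:
            return None
        a, b = classes
        tab = [[int(calls_df[(calls_df.gene_class == c)][col].sum()),
                int((~calls_df[calls_df.gene_class == c][col]).sum())] for c in (a, b)]
        return {"classes": [a, b], "table": tab,
                "p_two_sided": inference.fisher_exact_2x2(tab)}

    fishers = {"trans_specific": contrast("is_trans_specific"),
               "identical_pair": contrast("identical_interspecific_pair")}
    with open(out / "fisher_contrasts.json", "w") as fh:
        json.dump({**fishers, "config_hash": cfg.config_hash(), "seed": cfg.seed},
                  fh, indent=1)
    return {"calls": calls_df, "fisher": fishers}


def observed_identical_counts(calls_or_stats: pd.DataFrame) -> dict[str, int]:
    return {
        cls: int(sub["identical_interspecific_pair"].sum())
        for cls, sub in calls_or_stats.groupby("gene_class")
    }


def run_simulation(cfg: RunConfig, observed: dict[str, int] | None = None,
                   n_jobs: int = 1) -> dict:
    """IM-grid null for the identical-locus count, plus envelope verdicts."""
    grid_opts = dict(cfg.grid)
    class_specs = grid_opts.pop("class_specs", {
        "resistance": {"n_loci": 10, "L": 730, "n_A": 48, "n_B": 23},
        "reference": {"n_loci": 37, "L": 513, "n_A": 24, "n_B": 16},
    })
    seed = int(cfg.stage_seed("simulation").generate_state(1)[0] % (2**31))
    t0 = time.time()
    grid = coalescent.run_grid(class_specs, seed=seed, n_jobs=n_jobs, **grid_opts)
    logger.info("grid finished in %.1f s", time.time() - t0)
    out = _out(cfg)
    flat = grid.drop(columns=["counts"]).copy()
    _stamp(cfg, flat).to_csv(out / "sim_grid.tsv", sep="\t", index=False)
    long = grid.explode("counts").rename(columns={"counts": "count"})
    _stamp(cfg, long).to_csv(out / "sim_grid_replicates.tsv", sep="\t", index=False)
    result = {"grid": grid}
    observed = observed or cfg.observed_counts
    if observed:
        report = inference.compare_observed_to_grid(
            {k: v for k, v in observed.items() if k in set(grid["gene_class"])}, grid
        )
        _stamp(cfg, report).to_csv(out / "envelope_verdicts.tsv", sep="\t", index=False)
        _stamp(cfg, report.attrs["summary"]).to_csv(
            out / "envelope_summary.tsv", sep="\t", index=False)
        result.update(report=report, summary=report.attrs["summary"])
    return result


def run_tests(cfg: RunConfig, stats: dict | None = None, dataset=None) -> dict:
    """Permutation contrasts of fixed/shared site proportions between classes."""
    stats = stats or run_stats(cfg, dataset)
    per_locus = stats["per_locus"]
    seed = int(cfg.stage_seed("tests").generate_state(1)[0] % (2**31))
    classes = sorted(per_locus["gene_class"].unique())
    verdicts = {}
    if len(classes) == 2:
        a, b = classes
        for col in ("prop_fixed", "prop_shared"):
            v = inference.permutation_mean_diff_test(
                per_locus.loc[per_locus.gene_class == a, col].dropna(),
                per_locus.loc[per_locus.gene_class == b, col].dropna(),
                n_perm=cfg.n_permutations, seed=seed,
                name=f"{col}_{a}_vs_{b}",
            )
            verdicts[col] = asdict(v)
    out = _out(cfg)
    with open(out / "permutation_tests.json", "w") as fh:
        json.dump({**verdicts, "config_hash": cfg.config_hash(), "seed": cfg.seed},
                  fh, indent=1, default=float)
    return verdicts


def run_all(cfg: RunConfig, n_jobs: int = 1) -> dict:
    """Run every stage and write a consolidated JSON report."""
    t0 = time.time()
    dataset = load_dataset(cfg)
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                    "n_loci": len(dataset[0])}
    stats = run_stats(cfg, dataset)
    ph = run_phylo(cfg, dataset)
    observed = cfg.observed_counts or observed_identical_counts(ph["calls"])
    sim = run_simulation(cfg, observed=observed, n_jobs=n_jobs)
    tests = run_tests(cfg, stats=stats)
    report["observed_identical_counts"] = observed
    report["fisher"] = ph["fisher"]
    report["permutation"] = tests
    if "summary" in sim:
        report["envelope_summary"] = sim["summary"].to_dict(orient="records")
    report["runtime_s"] = round(time.time() - t0, 1)
    out = _out(cfg)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
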