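"""Study-shaped synthetic datasets with known ground truth.

Generates per-locus FASTA alignments, a sample sheet and a truth table for a
two-species panel shaped like the real study: a resistance-like class
(10 loci x 730 bp, 48 lyrata / 23 halleri haplotypes) and a reference-like
class (37 loci x 513 bp, smaller panels), coding-frame sequences with no
internal stop codons, an optional outgroup sequence per locus, and optional
planted events — recently introgressed haplotypes (which create identical
interspecific pairs) and deep balanced allelic classes (which create
trans-specific polymorphism).

Infinite-sites mutations from the coalescent engine are mapped onto distinct
integer sites with random non-identical target bases, so the
identity/difference structure of the simulated genealogy is preserved
exactly while producing valid codon sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coalescent import IMParams, SimulatedLocus, identical_interspecific_indicator, simulate_locus
from .io import (
    LocusAlignment,
    SampleRecord,
    SampleSheet,
    coding_mask_from_ranges,
    write_locus_alignment,
)
from .popgen import STOP_CODONS

__all__ = [
    "GeneClassConfig",
    "PlantedEvent",
    "SynthSpec",
    "SyntheticDataset",
    "study_shape_spec",
    "generate_dataset",
    "plant_introgressed_haplotype",
    "make_worked_fixtures",
]

_NONSTOP = [c for c in
            ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
            if c not in STOP_CODONS]

_LYRATA_POPS = ["Iceland", "Plech", "Spiterstulen", "Stubbsand", "Karhumaki", "Indiana"]
_HALLERI_POPS = ["Auby", "FranceB", "FranceC", "I9"]


@dataclass(frozen=True)
class GeneClassConfig:
    """Shape and demography of one gene class."""

    name: str
    n_loci: int
    L: int
    n_A: int
    n_B: int
    N: float = 150_000.0
    T_split_years: float = 750_000.0
    rec: float = 0.0
    m_intro: float = 0.0
    mu: float = 4e-9


@dataclass(frozen=True)
class PlantedEvent:
    locus: str  # locus name, e.g. "R03"
    type: str   # introgressed_haplotype | balanced_trans_specific
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SynthSpec:
    classes: tuple[GeneClassConfig, ...]
    planted: tuple[PlantedEvent, ...] = ()
    seed: int | None = None
    include_outgroup: bool = True
    T_outgroup_years: float = 5_500_000.0
    generation_time_years: float = 1.0


@dataclass
class SyntheticDataset:
    loci: list[LocusAlignment]
    sheet: SampleSheet
    truth: pd.DataFrame
    gene_class: dict[str, str]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for aln in self.loci:
            write_locus_alignment(aln, out / f"{aln.locus_name}.fasta")
        self.sheet.to_frame().to_csv(out / "samples.csv", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "classes.json", "w") as fh:
            json.dump(self.gene_class, fh, indent=1)


def study_shape_spec(
    seed: int | None = None,
    n_introgressed: int = 0,
    n_balanced: int = 0,
    N: float = 150_000.0,
    T_split_years: float = 2_500_000.0,
    rec: float = 0.0,
    m_intro: float = 0.0,
) -> SynthSpec:
    """The study-shaped preset: 10 R-like loci (730 bp, 48/23 samples) and
    37 reference-like loci (513 bp, 24/16 samples).

    The default background split time is calibrated so that interspecific
    divergence (2*mu*T + ancestral diversity, about 0.02 per site) matches
    the total divergence observed between the real species at reference
    loci, giving species trees whose stems are resolvable from sequence
    data. The shallower, deliberately conservative split times used for the
    identical-locus-count null live in the simulation grid, not here.

    Planted events go into the R-like class first (introgressed haplotypes,
    then balanced loci), overflowing into the reference class if requested.
    """
    classes = (
        GeneClassConfig("resistance", 10, 730, 48, 23, N, T_split_years, rec, m_intro),
        GeneClassConfig("reference", 37, 513, 24, 16, N, T_split_years, rec, m_intro),
    )
    names = [f"R{i + 1:02d}" for i in range(10)] + [f"REF{i + 1:02d}" for i in range(37)]
    planted = []
    for k in range(n_introgressed):
        planted.append(PlantedEvent(names[k], "introgressed_haplotype", {"recency": 0.0}))
    for k in range(n_balanced):
        planted.append(PlantedEvent(names[n_introgressed + k], "balanced_trans_specific"))
    return SynthSpec(classes=classes, planted=tuple(planted), seed=seed)


def _make_sheet(classes, include_outgroup: bool) -> SampleSheet:
    nA = max(c.n_A for c in classes)
    nB = max(c.n_B for c in classes)
    records = []
    for i in range(nA):
        records.append(SampleRecord(
            f"L{i + 1:03d}", "lyrata", _LYRATA_POPS[(i // 2) % len(_LYRATA_POPS)],
            f"lyr_ind{i // 2 + 1:02d}"))
    for i in range(nB):
        records.append(SampleRecord(
            f"H{i + 1:03d}", "halleri", _HALLERI_POPS[(i // 2) % len(_HALLERI_POPS)],
            f"hal_ind{i // 2 + 1:02d}"))
    if include_outgroup:
        records.append(SampleRecord("THA1", "thaliana", "outgroup", "tha_ind01"))
    return SampleSheet(tuple(records))


def _assign_sites(n_mut: int, positions: np.ndarray, L: int,
                  rng: np.random.Generator, taken: set[int]) -> list[int]:
    """Map continuous positions to distinct integer sites (redraw collisions)."""
    sites = []
    for p in positions:
        s = int(p) % L
        while s in taken:
            s = int(rng.integers(L))
        taken.add(s)
        sites.append(s)
    return sites


def _fix_stops(mat: np.ndarray, coding_cols: np.ndarray, mut_sites: dict[int, int],
               rng: np.random.Generator, anc: np.ndarray) -> int:
    """Redraw mutant bases that create internal stop codons; returns redraw count."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    col_to_codon = {int(c): k // 3 for k, c in enumerate(coding_cols)}
    n_redraw = 0
    for _ in range(50):
        c0 = mat[:, coding_cols[0::3]]
        c1 = mat[:, coding_cols[1::3]]
        c2 = mat[:, coding_cols[2::3]]
        is_stop = (c0 == b"T") & (
            ((c1 == b"A") & ((c2 == b"A") | (c2 == b"G")))
            | ((c1 == b"G") & (c2 == b"A"))
        )
        bad_codons = set(np.unique(np.nonzero(is_stop)[1]).tolist())
        if not bad_codons:
            return n_redraw
        for site in list(mut_sites):
            if col_to_codon.get(site) in bad_codons:
                old = mat[:, site].copy()
                anc_b = anc[site]
                alt = rng.choice([b for b in bases if b != anc_b])
                mat[:, site] = np.where(old == anc_b, anc_b, alt)
                n_redraw += 1
    raise RuntimeError("could not purge stop codons after 50 redraw rounds")


def _realize(locus: SimulatedLocus, cfg_L: int, coding_mask: np.ndarray,
             rng: np.random.Generator, outgroup_mut: int | None,
             gen_time: float = 1.0) -> list[str]:
    """Realize nucleotide haplotypes (plus optional outgroup) from a locus."""
    L = cfg_L
    coding_cols = np.flatnonzero(coding_mask)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    anc = np.empty(L, dtype="S1")
    noncoding = np.setdiff1d(np.arange(L), coding_cols)
    anc[noncoding] = rng.choice(bases, size=noncoding.size)
    for k in range(0, len(coding_cols), 3):
        codon = _NONSTOP[int(rng.integers(len(_NONSTOP)))]
        for off, c in enumerate(coding_cols[k : k + 3]):
            anc[c] = codon[off].encode()

    n_out = 1 if outgroup_mut is not None else 0
    n = locus.n + n_out
    mat = np.tile(anc, (n, 1))
    taken: set[int] = set()
    sites = _assign_sites(len(locus.masks), locus.positions, L, rng, taken)
    mut_sites: dict[int, int] = {}
    for s, mask in zip(sites, locus.masks):
        alt = bases[int(rng.integers(4))]
        while alt == anc[s]:
            alt = bases[int(rng.integers(4))]
        rows = [i for i in range(locus.n) if (mask >> i) & 1]
        mat[rows, s] = alt
        mut_sites[s] = 1
    if n_out:
        k_out = int(rng.poisson(outgroup_mut))
        out_sites = _assign_sites(k_out, rng.uniform(0, L, size=k_out), L, rng, taken)
        for s in out_sites:
            alt = bases[int(rng.integers(4))]
            while alt == anc[s]:
                alt = bases[int(rng.integers(4))]
            mat[n - 1, s] = alt
            mut_sites[s] = 1
    _fix_stops(mat, coding_cols, mut_sites, rng, anc)
    return [mat[i].tobytes().decode() for i in range(n)]


def plant_introgressed_haplotype(
    seqs: list[str], n_A: int, n_B: int, L: int, mu_gen: float,
    rng: np.random.Generator, donor_species: str = "lyrata",
    recency_generations: float = 0.0, mode: str = "replace",
) -> tuple[list[str], int]:
    """Copy one donor haplotype into the recipient sample.

    ``recency_generations`` adds Poisson(2 * mu * L * recency) private
    mutations to the copy (time since the introgression event, both
    branches). Returns (sequences, recipient row index). ``mode='replace'``
    overwrites a random recipient row; ``'add'`` appends a row.
    """
    if recency_generations < 0:
        raise ValueError("recency must be >= 0")
    donor_rows = range(n_A) if donor_species == "lyrata" else range(n_A, n_A + n_B)
    recip_rows = range(n_A, n_A + n_B) if donor_species == "lyrata" else range(n_A)
    donor = seqs[int(rng.choice(list(donor_rows)))]
    copy = list(donor)
    k = int(rng.poisson(2.0 * mu_gen * L * recency_generations))
    for _ in range(k):
        s = int(rng.integers(L))
        alt = "ACGT"[int(rng.integers(4))]
        while alt == copy[s]:
            alt = "ACGT"[int(rng.integers(4))]
        copy[s] = alt
    copied = "".join(copy)
    if mode == "replace":
        row = int(rng.choice(list(recip_rows)))
        seqs = list(seqs)
        seqs[row] = copied
        return seqs, row
    seqs = list(seqs) + [copied]
    return seqs, len(seqs) - 1


def _balanced_locus(cfg: GeneClassConfig, gen_time: float,
                    rng: np.random.Generator) -> SimulatedLocus:
    """A locus with two deep balanced allelic classes present in both species.

    Members of each class coalesce in a shallow panmictic genealogy spanning
    both species; the two class ancestors are separated by mutations
    accumulated over 4x the species split time. Both species carry both
    classes, so neither is monophyletic — trans-specific by construction.
    """
    n = cfg.n_A + cfg.n_B
    # interleave class membership within each species
    class1 = [i for i in range(cfg.n_A) if i % 2 == 0] + \
             [cfg.n_A + i for i in range(cfg.n_B) if i % 2 == 0]
    class2 = sorted(set(range(n)) - set(class1))
    masks: list[int] = []
    positions: list[float] = []
    for members in (class1, class2):
        sub = IMParams(
            N_current=cfg.N / 5.0, T_split_years=0.0, mu=cfg.mu,
            generation_time_years=gen_time, L=cfg.L,
            n_sample_A=len(members), n_sample_B=0, n_loci=1,
        )
        loc = simulate_locus(sub, rng, record_genealogy=False)
        for pos, m in zip(loc.positions, loc.masks):
            full = 0
            for bit, sample in enumerate(members):
                if (m >> bit) & 1:
                    full |= 1 << sample
            positions.append(float(pos))
            masks.append(full)
    # deep divergence of class 2 from class 1
    deep = int(rng.poisson(2.0 * cfg.mu * gen_time * cfg.L * 4.0
                           * cfg.T_split_years / gen_time))
    mask2 = 0
    for s in class2:
        mask2 |= 1 << s
    for _ in range(max(deep, 8)):  # guarantee a clearly split genealogy
        positions.append(float(rng.uniform(0, cfg.L)))
        masks.append(mask2)
    return SimulatedLocus(cfg.n_A, cfg.n_B, cfg.L,
                          np.asarray(positions), masks,
                          genealogy_monophyletic_A=False,
                          genealogy_monophyletic_B=False)


def generate_dataset(spec: SynthSpec) -> SyntheticDataset:
    """Generate the full synthetic study: alignments, sample sheet, truth table."""
    rng = np.random.default_rng(spec.seed)
    sheet = _make_sheet(spec.classes, spec.include_outgroup)
    planted = {e.locus: e for e in spec.planted}
    loci: list[LocusAlignment] = []
    truth_rows = []
    class_of: dict[str, str] = {}
    counter = 0
    for cfg in spec.classes:
        prefix = "R" if cfg.name == "resistance" else "REF"
        mu_gen = cfg.mu * spec.generation_time_years
        for k in range(cfg.n_loci):
            name = f"{prefix}{k + 1:02d}"
            class_of[name] = cfg.name
            event = planted.get(name)
            if event is not None and event.type == "balanced_trans_specific":
                locus = _balanced_locus(cfg, spec.generation_time_years, rng)
            else:
                params = IMParams(
                    N_current=cfg.N, T_split_years=cfg.T_split_years,
                    generation_time_years=spec.generation_time_years,
                    mu=cfg.mu, rec=cfg.rec, m_intro=cfg.m_intro,
                    L=cfg.L, n_sample_A=cfg.n_A, n_sample_B=cfg.n_B, n_loci=1,
                )
                locus = simulate_locus(params, rng, record_genealogy=True)
            out_mut = None
            if spec.include_outgroup:
                out_mut = 2.0 * cfg.mu * spec.generation_time_years * cfg.L \
                    * spec.T_outgroup_years / spec.generation_time_years
            seqs = _realize(locus, cfg.L, coding_mask_from_ranges(cfg.L, None),
                            rng, out_mut)
            planted_identical = False
            if event is not None and event.type == "introgressed_haplotype":
                ingroup = seqs[: locus.n]
                ingroup, _ = plant_introgressed_haplotype(
                    ingroup, cfg.n_A, cfg.n_B, cfg.L, mu_gen, rng,
                    donor_species=event.params.get("donor", "lyrata"),
                    recency_generations=event.params.get("recency", 0.0),
                )
                seqs = ingroup + seqs[locus.n :]
                planted_identical = event.params.get("recency", 0.0) == 0.0
            realized_identical = identical_interspecific_indicator(locus)
            ids = ([f"L{i + 1:03d}" for i in range(cfg.n_A)]
                   + [f"H{i + 1:03d}" for i in range(cfg.n_B)]
                   + (["THA1"] if spec.include_outgroup else []))
            aln = LocusAlignment(
                locus_name=name,
                sequences=tuple(zip(ids, seqs)),
                coding_mask=coding_mask_from_ranges(cfg.L, None),
            )
            loci.append(aln)
            monoA = locus.genealogy_monophyletic_A
            monoB = locus.genealogy_monophyletic_B
            truth_rows.append({
                "locus": name,
                "gene_class": cfg.name,
                "planted": event.type if event else "none",
                "planted_identical": planted_identical,
                "realized_identical": bool(realized_identical) or planted_identical,
                "genealogy_trans_specific": (
                    None if monoA is None else (not monoA and not monoB)
                ),
                "genealogy_monophyletic_lyrata": monoA,
                "genealogy_monophyletic_halleri": monoB,
            })
            counter += 1
    return SyntheticDataset(
        loci=loci, sheet=sheet, truth=pd.DataFrame(truth_rows), gene_class=class_of
    )


def make_worked_fixtures(out_dir: str | Path) -> dict:
    """Write the small worked examples used across the test-suite and docs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    def fasta(name, pairs):
        p = out / name
        with open(p, "w") as fh:
            for sid, s in pairs:
                fh.write(f">{sid}\n{s}\n")
        files[name] = str(p)

    fasta("seg_sites_toy.fasta", [("s1", "AAT"), ("s2", "AAA"), ("s3", "ACA")])
    fasta("four_gamete_toy.fasta", [("h1", "AA"), ("h2", "AT"), ("h3", "TA"), ("h4", "TT")])
    fasta("ng_codon_pairs.fasta", [("a", "ATGTTT"), ("b", "ATGTTC")])
    fasta("identical_pair_toy.fasta", [("L1", "ACGTAC"), ("H1", "ACGTAC"), ("H2", "ACGTAA")])
    with open(out / "nj_additive_toy.tsv", "w") as fh:
        fh.write("\tA\tB\tC\tD\nA\t0\t3\t4\t5\nB\t3\t0\t5\t6\nC\t4\t5\t0\t3\nD\t5\t6\t3\t0\n")
    files["nj_additive_toy.tsv"] = str(out / "nj_additive_toy.tsv")
    with open(out / "fisher_tables.json", "w") as fh:
        json.dump({"trans_specific": [[7, 3], [8, 29]],
                   "identical": [[4, 6], [3, 34]]}, fh, indent=1)
    files["fisher_tables.json"] = str(out / "fisher_tables.json")
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(sorted(files), fh, indent=1)
    files["MANIFEST.json"] = str(out / "MANIFEST.json")
    return files
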