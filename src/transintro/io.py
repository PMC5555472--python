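"""Alignment and sample-sheet I/O.

Per-locus data arrive as pre-aligned FASTA (one file per locus, coding-frame
aligned Sanger haplotypes) plus a sample sheet mapping each sequence id to a
species (*A. lyrata*, *A. halleri*, or the *A. thaliana* outgroup), a source
population and an individual. This module validates those inputs and
normalises them into the containers every downstream stage consumes.

Conventions
-----------
* residues are upper-case ``A C G T - N``; ``U`` is mapped to ``T``;
  ``-`` and ``N`` are both treated as missing downstream (pairwise deletion);
* coordinates are 0-based half-open internally; human-facing coding ranges in
  configs are 1-based inclusive and converted at parse time;
* individuals represented by a single haplotype may be duplicated to two
  identical haplotypes (``assume_homozygous``), mirroring exhaustively cloned
  allele panels; loci known not to be exhaustively sampled opt out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SPECIES",
    "SampleRecord",
    "SampleSheet",
    "LocusAlignment",
    "SpeciesPartition",
    "read_sample_sheet",
    "read_locus_alignment",
    "partition_by_species",
    "write_locus_alignment",
    "duplicate_singleton_haplotypes",
    "coding_mask_from_ranges",
]

logger = logging.getLogger(__name__)

SPECIES = ("lyrata", "halleri", "thaliana")
_VALID = set("ACGT-N")
MISSING = {"-", "N"}


@dataclass(frozen=True)
class SampleRecord:
    sequence_id: str
    species: str
    population: str
    individual_id: str


@dataclass(frozen=True)
class SampleSheet:
    """Mapping from sequence ids to species/population/individual."""

    records: tuple[SampleRecord, ...]

    def __post_init__(self):
        ids = [r.sequence_id for r in self.records]
        seen = set()
        for i in ids:
            if i in seen:
                raise ValueError(f"duplicate id {i}")
            seen.add(i)
        for r in self.records:
            if r.species not in SPECIES:
                raise ValueError(
                    f"unknown species {r.species!r} for id {r.sequence_id}"
                    f" (expected one of {SPECIES})"
                )
            if not r.individual_id:
                raise ValueError(f"empty individual_id for id {r.sequence_id}")
        if not self.records:
            raise ValueError("sample sheet has no records")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.sequence_id for r in self.records)

    def species_of(self, sequence_id: str) -> str:
        try:
            return self._index()[sequence_id]
        except KeyError:
            raise KeyError(f"unassigned sequence {sequence_id}") from None

    def _index(self) -> dict[str, str]:
        # cached lazily on the instance (frozen dataclass -> object.__setattr__)
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {r.sequence_id: r.species for r in self.records}
            object.__setattr__(self, "_idx", idx)
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sequence_id, r.species, r.population, r.individual_id) for r in self.records],
            columns=["id", "species", "population", "individual"],
        )


@dataclass(frozen=True)
class LocusAlignment:
    """One locus's aligned haplotypes with coding-frame metadata.

    ``coding_mask`` flags codon-bearing sites (introns and dangling bases are
    False); the number of True sites must be divisible by 3 after
    ``frame_offset`` coding positions are discarded from its start.
    """

    locus_name: str
    sequences: tuple[tuple[str, str], ...]
    coding_mask: np.ndarray  # bool, len == alignment length
    frame_offset: int = 0

    def __post_init__(self):
        if not self.sequences:
            raise ValueError(f"{self.locus_name}: empty sequence list")
        L = len(self.sequences[0][1])
        if L < 1:
            raise ValueError(f"{self.locus_name}: zero-length alignment")
        for sid, seq in self.sequences:
            if len(seq) != L:
                raise ValueError(
                    f"{self.locus_name}: ragged lengths ({sid} has {len(seq)}, expected {L})"
                )
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"{self.locus_name}: invalid residues {sorted(bad)} in {sid}")
        mask = np.asarray(self.coding_mask, dtype=bool)
        object.__setattr__(self, "coding_mask", mask)
        if mask.shape != (L,):
            raise ValueError(f"{self.locus_name}: coding_mask length {mask.size} != {L}")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be in {0,1,2}")
        n_coding = int(mask.sum()) - self.frame_offset
        if n_coding > 0 and n_coding % 3 != 0:
            raise ValueError(
                f"{self.locus_name}: {n_coding} coding sites after frame offset "
                "not divisible by 3"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.sequences)

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) byte matrix (b'A' etc.)."""
        return np.frombuffer(
            "".join(s for _, s in self.sequences).encode(), dtype="S1"
        ).reshape(len(self.sequences), self.length)

    def codon_columns(self) -> np.ndarray:
        """Indices of coding sites, frame-trimmed to whole codons."""
        idx = np.flatnonzero(self.coding_mask)[self.frame_offset :]
        return idx[: 3 * (len(idx) // 3)]

    def codon_strings(self, row: int) -> list[str]:
        seq = self.sequences[row][1]
        cols = self.codon_columns()
        return ["".join(seq[c] for c in cols[i : i + 3]) for i in range(0, len(cols), 3)]


@dataclass(frozen=True)
class SpeciesPartition:
    """Row indices of each species within one locus alignment."""

    locus: LocusAlignment
    lyrata_idx: tuple[int, ...]
    halleri_idx: tuple[int, ...]
    outgroup_idx: tuple[int, ...] = ()

    def __post_init__(self):
        groups = (set(self.lyrata_idx), set(self.halleri_idx), set(self.outgroup_idx))
        n = sum(len(g) for g in groups)
        union = set().union(*groups)
        if len(union) != n:
            raise ValueError("species index lists overlap")
        if union and max(union) >= len(self.locus.sequences):
            raise ValueError("species index out of range")


def _fold_species(token: str) -> str:
    t = token.strip().lower()
    # accept binomial-style tokens ("A. lyrata", "arabidopsis_halleri")
    for sp in SPECIES:
        if t == sp or t.endswith(sp):
            return sp
    raise ValueError(f"unknown species token {token!r}")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a CSV/TSV sample sheet with header columns id,species,population,individual."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"id", "species", "population", "individual"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet missing columns {sorted(required - set(df.columns))}")
    records = tuple(
        SampleRecord(
            sequence_id=row["id"].strip(),
            species=_fold_species(row["species"]),
            population=row["population"].strip(),
            individual_id=row["individual"].strip(),
        )
        for _, row in df.iterrows()
    )
    return SampleSheet(records)


def coding_mask_from_ranges(length: int, ranges: Sequence[Sequence[int]] | None) -> np.ndarray:
    """Build a boolean coding mask from 1-based inclusive [start, end] ranges.

    ``None`` means all-coding, trimmed so the coding span is a whole number
    of codons (any dangling 1-2 terminal bases are marked non-coding).
    """
    mask = np.zeros(length, dtype=bool)
    if ranges is None:
        mask[: 3 * (length // 3)] = True
        return mask
    for start, end in ranges:
        if not (1 <= start <= end <= length):
            raise ValueError(f"coding range [{start}, {end}] outside 1..{length}")
        mask[start - 1 : end] = True
    return mask


def read_locus_alignment(
    path: str | Path,
    sheet: SampleSheet | None = None,
    coding_ranges: Sequence[Sequence[int]] | None = None,
    frame_offset: int = 0,
    locus_name: str | None = None,
) -> LocusAlignment:
    """Read one locus from FASTA into the shared data model.

    Residues are upper-cased, U mapped to T; anything outside {A,C,G,T,-,N}
    is rejected. ``coding_ranges`` are 1-based inclusive; default all-coding.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    seqs = []
    for rec in records:
        s = str(rec.seq).upper().replace("U", "T")
        if sheet is not None:
            base = rec.id[: -len("__hom")] if rec.id.endswith("__hom") else rec.id
            if base not in sheet._index():
                raise ValueError(f"{path}: id {rec.id} absent from sample sheet")
        seqs.append((rec.id, s))
    lengths = {len(s) for _, s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"{path}: ragged lengths {sorted(lengths)}")
    L = lengths.pop()
    return LocusAlignment(
        locus_name=locus_name or path.stem,
        sequences=tuple(seqs),
        coding_mask=coding_mask_from_ranges(L, coding_ranges),
        frame_offset=frame_offset,
    )


def partition_by_species(aln: LocusAlignment, sheet: SampleSheet) -> SpeciesPartition:
    """Group alignment rows by species according to the sample sheet."""
    groups: dict[str, list[int]] = {sp: [] for sp in SPECIES}
    for i, sid in enumerate(aln.ids):
        base = sid[: -len("__hom")] if sid.endswith("__hom") else sid
        try:
            sp = sheet.species_of(base)
        except KeyError:
            raise ValueError(f"unassigned sequence {sid}") from None
        groups[sp].append(i)
    part = SpeciesPartition(
        locus=aln,
        lyrata_idx=tuple(groups["lyrata"]),
        halleri_idx=tuple(groups["halleri"]),
        outgroup_idx=tuple(groups["thaliana"]),
    )
    logger.info(
        "%s: %d lyrata, %d halleri, %d outgroup",
        aln.locus_name, len(part.lyrata_idx), len(part.halleri_idx), len(part.outgroup_idx),
    )
    return part


def write_locus_alignment(aln: LocusAlignment, path: str | Path) -> None:
    """Write a locus back to FASTA; read∘write round-trips the data model."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.sequences
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def duplicate_singleton_haplotypes(
    aln: LocusAlignment,
    sheet: SampleSheet,
    assume_homozygous: bool = True,
    exempt_loci: Iterable[str] = (),
) -> LocusAlignment:
    """Duplicate single-haplotype individuals to two identical haplotypes.

    Exhaustively cloned allele panels imply that an individual contributing a
    single sequence is homozygous; its haplotype is doubled so diversity
    statistics see both chromosomes. Loci listed in ``exempt_loci`` (known to
    be incompletely sampled) are returned unchanged, as is everything when
    ``assume_homozygous`` is off.
    """
    if not assume_homozygous or aln.locus_name in set(exempt_loci):
        return aln
    by_ind: dict[tuple[str, str], list[int]] = {}
    for i, sid in enumerate(aln.ids):
        rec = next(r for r in sheet.records if r.sequence_id == sid)
        if rec.species == "thaliana":
            continue
        by_ind.setdefault((rec.species, rec.individual_id), []).append(i)
    extra = []
    for (sp, ind), rows in sorted(by_ind.items()):
        if len(rows) == 1:
            sid, seq = aln.sequences[rows[0]]
            extra.append((f"{sid}__hom", seq))
    if not extra:
        return aln
    return replace(aln, sequences=aln.sequences + tuple(extra))
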