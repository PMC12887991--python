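"""Pan-proteome target/decoy database and peptide indexing.

The search space is built by concatenating all strain proteomes plus phage
and contaminant collections, collapsing exactly identical sequences into one
*sequence group* whose strain provenance is the union of its members.  One
decoy is generated per target by shuffling the sequence while keeping every
K and R at its original position, so that tryptic cleavage-site structure
(and hence the peptide length/mass distribution) is preserved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pt_mass
from pyteomics import parser as _pt_parser

from .config import PipelineConfig
from .records import DECOY_PREFIX, ProteoformRecord, Source

TRYPSIN_RULE = r"[KR](?!P)"
TRYPSIN_LYSC_RULE = r"K|R(?!P)"  # LysC cleaves after K even before P


def _rule(enzyme: str) -> str:
    return TRYPSIN_LYSC_RULE if enzyme == "trypsin/lysc" else TRYPSIN_RULE


@dataclass
class PanDatabase:
    """Deduplicated pan-proteome: targets first, then decoys.

    ``sequence_groups`` maps each distinct target sequence to its group id;
    group ids are assigned in first-occurrence order, so the database is
    deterministic given the input record order.
    """

    records: list[ProteoformRecord]
    sequence_groups: dict[str, int]
    n_targets: int
    n_decoys: int = 0

    @property
    def targets(self) -> list[ProteoformRecord]:
        return self.records[: self.n_targets]

    @property
    def decoys(self) -> list[ProteoformRecord]:
        return self.records[self.n_targets:]

    def group_record(self, group_id: int) -> ProteoformRecord:
        return self.records[group_id]

    def group_of_accession(self, accession: str) -> int | None:
        for gid, rec in enumerate(self.targets):
            if rec.accession == accession or accession in rec.merged_accessions:
                return gid
        return None

    def strains(self) -> frozenset[str]:
        return frozenset(
            s for rec in self.targets for s in rec.strain_ids
        )


_SOURCE_PRIORITY = {Source.STRAIN: 0, Source.PHAGE: 1, Source.CONTAMINANT: 2}


def build_pan_database(proteomes: list[ProteoformRecord]) -> PanDatabase:
    """Concatenate proteomes and collapse exact duplicate sequences.

    The surviving record of a duplicate set keeps the accession of the first
    occurrence; strain ids are unioned and the other accessions retained in
    ``merged_accessions``.  When sources differ, strain provenance wins over
    phage over contaminant, so a contaminant identical to a strain protein
    stays a strain record with the contaminant accession noted.
    """
    if not proteomes:
        raise ValueError("cannot build a database from zero records")
    by_sequence: dict[str, ProteoformRecord] = {}
    order: list[str] = []
    for rec in proteomes:
        if rec.is_decoy:
            raise ValueError("input proteomes must not contain decoys")
        existing = by_sequence.get(rec.sequence)
        if existing is None:
            by_sequence[rec.sequence] = rec
            order.append(rec.sequence)
            continue
        keep, other = existing, rec
        if _SOURCE_PRIORITY[rec.source] < _SOURCE_PRIORITY[existing.source]:
            keep, other = rec, existing
        merged = ProteoformRecord(
            accession=keep.accession,
            sequence=keep.sequence,
            source=keep.source,
            strain_ids=keep.strain_ids | other.strain_ids,
            merged_accessions=tuple(
                dict.fromkeys(
                    keep.merged_accessions + (other.accession,) + other.merged_accessions
                )
            ),
        )
        by_sequence[rec.sequence] = merged
    records = [by_sequence[s] for s in order]
    groups = {seq: gid for gid, seq in enumerate(order)}
    return PanDatabase(records=records, sequence_groups=groups, n_targets=len(records))


def shuffle_preserving_kr(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence keeping every K and R at its original position."""
    chars = np.array(list(sequence))
    movable = np.flatnonzero((chars != "K") & (chars != "R"))
    permuted = chars.copy()
    permuted[movable] = chars[movable[rng.permutation(len(movable))]]
    return "".join(permuted)


def generate_decoys(db: PanDatabase, seed: int) -> PanDatabase:
    """Append one K/R-preserving shuffled decoy per target (in place).

    Decoy accessions get the ``DECOY_`` prefix.  Reproducible given the seed.
    """
    if db.n_decoys:
        raise ValueError("decoys already generated for this database")
    rng = np.random.default_rng(seed)
    decoys = [
        ProteoformRecord(
            accession=DECOY_PREFIX + rec.accession,
            sequence=shuffle_preserving_kr(rec.sequence, rng),
            source=rec.source,
            strain_ids=rec.strain_ids,
            is_decoy=True,
        )
        for rec in db.targets
    ]
    db.records = db.targets + decoys
    db.n_decoys = len(decoys)
    return db


def digest(sequence: str, missed_cleavages: int, min_length: int,
           enzyme: str = "trypsin") -> list[tuple[str, int]]:
    """Fully tryptic digestion with 1-based start coordinates.

    Cleaves after K/R except before P (classical trypsin specificity);
    ``enzyme="trypsin/lysc"`` additionally cleaves after K before P.
    Products are ordered by start, then length.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    # icleave re-emits a terminal peptide when a missed cleavage window runs
    # past the end of the sequence; collapse to distinct (peptide, start)
    out = {
        (pep, start + 1)
        for start, pep in _pt_parser.icleave(
            sequence, _rule(enzyme), missed_cleavages=missed_cleavages,
            min_length=min_length, regex=True,
        )
    }
    return sorted(out, key=lambda t: (t[1], len(t[0])))


@dataclass
class PeptideIndex:
    """Fully tryptic peptide → set of target sequence-group ids."""

    peptide_to_groups: dict[str, set[int]]
    missed_cleavages: int
    min_length: int
    enzyme: str = "trypsin"

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptide_to_groups


def build_peptide_index(db: PanDatabase, config: PipelineConfig) -> PeptideIndex:
    index: dict[str, set[int]] = {}
    for gid, rec in enumerate(db.targets):
        for pep, _ in digest(rec.sequence, config.max_missed_cleavages,
                             config.min_peptide_length, config.enzyme):
            index.setdefault(pep, set()).add(gid)
    return PeptideIndex(
        peptide_to_groups=index,
        missed_cleavages=config.max_missed_cleavages,
        min_length=config.min_peptide_length,
        enzyme=config.enzyme,
    )


def map_peptide(db: PanDatabase, peptide: str,
                index: PeptideIndex | None = None) -> set[int]:
    """All target sequence groups containing ``peptide`` as exact substring.

    Substring matching covers semi-tryptic and non-tryptic termini without
    enumerating those products.  The fully tryptic index, when supplied, is a
    shortcut only: results are identical with or without it.
    """
    if not peptide:
        raise ValueError("empty peptide")
    if index is not None and peptide in index:
        return set(index.peptide_to_groups[peptide])
    return {gid for gid, rec in enumerate(db.targets) if peptide in rec.sequence}


def map_peptide_decoys(db: PanDatabase, peptide: str) -> set[int]:
    """Decoy-side analogue of :func:`map_peptide` (decoy record offsets)."""
    if not peptide:
        raise ValueError("empty peptide")
    return {
        db.n_targets + i
        for i, rec in enumerate(db.decoys)
        if peptide in rec.sequence
    }


def peptide_monoisotopic_mass(peptide: str) -> float:
    """Monoisotopic neutral mass of an unmodified peptide."""
    return _pt_mass.fast_mass(peptide)


def count_detectable_peptides(sequence: str, config: PipelineConfig) -> int:
    """Number of MS-detectable fully tryptic peptides of a protein.

    Zero missed cleavages, length >= min_peptide_length, monoisotopic mass
    inside the configured detectability window.  Peptides containing X have
    no defined mass and are excluded.
    """
    lo, hi = config.detectability_mass_window
    n = 0
    for pep, _ in digest(sequence, 0, config.min_peptide_length, config.enzyme):
        if "X" in pep:
            continue
        if lo <= peptide_monoisotopic_mass(pep) <= hi:
            n += 1
    return n
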