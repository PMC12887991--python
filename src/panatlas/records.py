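"""Core domain records shared across pipeline stages.

A *proteoform* here is one FASTA entry of the multi-strain search space;
identical sequences from different strains are later collapsed into one
sequence group.  A *peptidoform* is a peptide together with its localized
modifications, written in the bracket dialect ``AS[Phospho]K`` (modification
name in square brackets immediately after the modified residue;
N-terminal modifications as a ``[Name]-`` prefix).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

DECOY_PREFIX = "DECOY_"


class Source(str, Enum):
    STRAIN = "strain"
    PHAGE = "phage"
    CONTAMINANT = "contaminant"


class Engine(str, Enum):
    CLOSED = "closed"
    OPEN = "open"


class Tier(str, Enum):
    CANONICAL = "canonical"
    INDISTINGUISHABLE = "indistinguishable"
    MARGINAL = "marginal"
    UNCERTAIN = "uncertain"
    NOT_OBSERVED = "not_observed"


class Provenance(str, Enum):
    CLOSED_ONLY = "closed_only"
    OPEN_ONLY = "open_only"
    BOTH_AGREE = "both_agree"
    CONFLICT_CLOSED_KEPT = "conflict_closed_kept"


class ClusterClass(str, Enum):
    CORE = "core"
    ACCESSORY = "accessory"
    ORPHAN = "orphan"
    NON_STRAIN = "non_strain"


@dataclass
class ProteoformRecord:
    """One search-space FASTA entry with provenance and decoy status."""

    accession: str
    sequence: str
    source: Source
    strain_ids: frozenset[str] = frozenset()
    is_decoy: bool = False
    # accessions of duplicate entries merged into this record during dedup
    merged_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"{self.accession}: sequence must be uppercase")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residues {sorted(bad)} "
                "(allowed: 20 amino acids plus X)"
            )
        if self.source is Source.STRAIN and not self.strain_ids:
            raise ValueError(f"{self.accession}: strain record without strain_ids")
        if self.is_decoy and not self.accession.startswith(DECOY_PREFIX):
            raise ValueError(f"{self.accession}: decoy without {DECOY_PREFIX} prefix")

    def __len__(self) -> int:
        return len(self.sequence)


_MOD_RE = re.compile(r"\[([^\[\]]+)\]")
_NTERM_RE = re.compile(r"^\[([^\[\]]+)\]-")


def strip_peptidoform(peptidoform: str) -> str:
    """Return the bare peptide sequence of a bracketed peptidoform."""
    return _MOD_RE.sub("", _NTERM_RE.sub("", peptidoform))


def parse_peptidoform(peptidoform: str) -> tuple[str, list[tuple[int, str]]]:
    """Parse a peptidoform into (bare peptide, [(position, mod name), ...]).

    Positions are 1-based residue indices within the peptide; an N-terminal
    modification is reported at position 1.
    """
    mods: list[tuple[int, str]] = []
    rest = peptidoform
    m = _NTERM_RE.match(rest)
    if m:
        mods.append((1, m.group(1)))
        rest = rest[m.end():]
    peptide_chars: list[str] = []
    i = 0
    while i < len(rest):
        c = rest[i]
        if c == "[":
            j = rest.index("]", i)
            if not peptide_chars:
                raise ValueError(f"misplaced modification in {peptidoform!r}")
            mods.append((len(peptide_chars), rest[i + 1:j]))
            i = j + 1
        else:
            peptide_chars.append(c)
            i += 1
    return "".join(peptide_chars), mods


@dataclass
class PsmRecord:
    """One peptide-spectrum match from one engine.

    Scores and q-values are produced upstream (search engine + rescoring);
    this package consumes them as given.
    """

    run_id: str
    spectrum_id: str
    engine: Engine
    peptidoform: str
    charge: int
    score: float
    q_value: float
    loc_score: float | None = None
    peptide: str = field(default="")

    def __post_init__(self) -> None:
        derived = strip_peptidoform(self.peptidoform)
        if not self.peptide:
            self.peptide = derived
        elif self.peptide != derived:
            raise ValueError(
                f"{self.spectrum_id}: peptide {self.peptide!r} does not match "
                f"peptidoform {self.peptidoform!r}"
            )
        if len(self.peptide) < 1:
            raise ValueError(f"{self.spectrum_id}: empty peptide")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"{self.spectrum_id}: q_value {self.q_value} outside [0,1]")
        if self.charge < 1:
            raise ValueError(f"{self.spectrum_id}: non-positive charge")

    @property
    def is_modified(self) -> bool:
        return self.peptidoform != self.peptide

    def modifications(self) -> list[tuple[int, str]]:
        return parse_peptidoform(self.peptidoform)[1]


@dataclass
class MergedPsm:
    """A PSM surviving the closed/open merge, with merge provenance."""

    psm: PsmRecord
    provenance: Provenance

    def __post_init__(self) -> None:
        if (
            self.provenance is Provenance.CONFLICT_CLOSED_KEPT
            and self.psm.engine is not Engine.CLOSED
        ):
            raise ValueError("conflict_closed_kept requires the closed-engine record")

    # convenience passthroughs used throughout downstream stages
    @property
    def run_id(self) -> str:
        return self.psm.run_id

    @property
    def spectrum_id(self) -> str:
        return self.psm.spectrum_id

    @property
    def peptide(self) -> str:
        return self.psm.peptide

    @property
    def peptidoform(self) -> str:
        return self.psm.peptidoform

    @property
    def is_modified(self) -> bool:
        return self.psm.is_modified


@dataclass
class PeptideEvidence:
    peptide: str
    group_ids: frozenset[int]
    psm_count: int
    best_score: float

    @property
    def is_unique(self) -> bool:
        return len(self.group_ids) == 1


@dataclass
class TierAssignment:
    group_id: int
    representative_accession: str
    tier: Tier
    n_unique_peptides: int
    n_shared_peptides: int
    in_core_proteome: bool
    is_decoy: bool = False


@dataclass
class HomologyCluster:
    cluster_id: int
    representative_group: int
    member_groups: list[int]
    strains_present: frozenset[str] = frozenset()
    cluster_class: ClusterClass | None = None
    best_tier: Tier | None = None


@dataclass
class ModificationEvent:
    group_id: int
    position: int  # 1-based residue index in the protein
    residue: str
    mod_name: str
    psm_support: int
    runs_observed: frozenset[str]
    unimod_class: str | None = None


@dataclass
class NsafRecord:
    group_id: int
    run_id: str
    unique_psm_count: int
    protein_length: int
    nsaf: float
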