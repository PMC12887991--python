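"""Synthetic strain proteomes and dual-engine PSM tables with ground truth.

The generator emulates the statistical structure of a multi-strain
reprocessing effort at desk scale: protein families planted as core (in all
strains), accessory (in >=2 but not all) or orphan (in exactly one), with
orthologs derived from a family ancestor by i.i.d. substitutions; spectra
sampled from proteins with log-normal abundance; two search engines with
overlapping spectrum sets and a controlled peptidoform conflict rate;
modifications planted at recorded sites with a controlled mislocalization
rate (mislocalized phosphorylations land on a uniformly random peptide
residue, which is what makes the decoy-alanine FLR device work); and false
PSMs drawn from decoy sequences at controlled rates.

Every random draw flows from a single seed, so a fixed seed reproduces the
whole fixture set byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .database import PanDatabase, build_pan_database, digest, generate_decoys
from .records import AMINO_ACIDS, Engine, ProteoformRecord, PsmRecord, Source

# residues a modification can legitimately sit on
ELIGIBLE_RESIDUES = {
    "Phospho": "STY",
    "Oxidation": "M",
    "Acetyl": "K",
    "Methyl": "KR",
    "Deamidated": "NQ",
    "Carbamidomethyl": "C",
    "Glutathione": "C",
}

KR_FLOOR = 0.08  # minimum K+R fraction so tryptic digestion yields peptides


@dataclass
class SynthParams:
    n_strains: int = 5
    n_core: int = 30
    n_accessory: int = 15
    accessory_inclusion_p: float = 0.5
    n_orphan_per_strain: int = 5
    length_range: tuple[int, int] = (80, 400)
    divergence: float = 0.05
    n_runs: int = 4
    psms_per_run: int = 2000
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    modification_rates: dict[str, float] = field(
        default_factory=lambda: {"Phospho": 0.05, "Oxidation": 0.10, "Acetyl": 0.02}
    )
    engine_overlap: float = 0.5
    conflict_rate: float = 0.10
    decoy_psm_rate: float = 0.01
    false_protein_rate: float = 0.01
    mislocalization_rate: float = 0.05
    target_id_rate: float = 0.428
    min_peptide_length: int = 7
    # when > 0, every target protein additionally receives this many PSMs of
    # distinct peptides, emulating deep fractionated coverage where
    # essentially every protein reaches the canonical tier
    min_coverage_psms: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("accessory_inclusion_p", "divergence", "engine_overlap",
                     "conflict_rate", "decoy_psm_rate", "false_protein_rate",
                     "mislocalization_rate", "target_id_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        for name in ("n_strains", "n_core", "n_accessory", "n_orphan_per_strain",
                     "n_runs", "psms_per_run"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_strains < 1:
            raise ValueError("need at least one strain")


@dataclass
class PlantedSite:
    run_id: str
    spectrum_id: str
    accession: str
    position: int  # 1-based in the protein
    residue: str
    mod_name: str
    mislocalized: bool


@dataclass
class GroundTruth:
    family_of_accession: dict[str, int] = field(default_factory=dict)
    class_of_family: dict[int, str] = field(default_factory=dict)
    strains_of_family: dict[int, frozenset[str]] = field(default_factory=dict)
    divergence_warning: bool = False
    abundance: dict[str, float] = field(default_factory=dict)
    # per (run_id, spectrum_id): source accession, or None for false PSMs
    psm_source: dict[tuple[str, str], str | None] = field(default_factory=dict)
    false_psm: set[tuple[str, str]] = field(default_factory=set)
    conflict_spectra: set[tuple[str, str]] = field(default_factory=set)
    both_engine_spectra: set[tuple[str, str]] = field(default_factory=set)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    activated_decoys: list[str] = field(default_factory=list)

    def realized_sty_flr(self) -> float:
        """Fraction of planted phospho observations reported on S/T/Y that
        are mislocalized — the quantity the decoy-alanine estimator targets."""
        sty = [s for s in self.planted_sites
               if s.mod_name == "Phospho" and s.residue in "STY"]
        if not sty:
            return 0.0
        return sum(s.mislocalized for s in sty) / len(sty)

    def realized_sty_site_flr(self) -> float:
        """Site-level variant of :meth:`realized_sty_flr`: fraction of
        distinct (protein, position) phospho-S/T/Y sites whose observations
        are all mislocalized.  Comparable to the estimator, which counts
        distinct sites rather than observations."""
        correct: set[tuple[str, int]] = set()
        wrong: set[tuple[str, int]] = set()
        for s in self.planted_sites:
            if s.mod_name != "Phospho" or s.residue not in "STY":
                continue
            (wrong if s.mislocalized else correct).add((s.accession, s.position))
        wrong -= correct
        total = len(correct) + len(wrong)
        return len(wrong) / total if total else 0.0


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aa = np.array(list(AMINO_ACIDS))
    seq = rng.choice(aa, size=length)
    # enforce a K/R floor so every protein digests into usable peptides
    while np.isin(seq, ("K", "R")).mean() < KR_FLOOR:
        pos = rng.integers(length)
        seq[pos] = "K" if rng.random() < 0.5 else "R"
    return "".join(seq)


def _diverge(rng: np.random.Generator, ancestor: str, rate: float) -> str:
    if rate == 0.0:
        return ancestor
    chars = np.array(list(ancestor))
    hit = rng.random(len(chars)) < rate
    # substitution targets drawn uniformly from all 20 residues
    chars[hit] = rng.choice(np.array(list(AMINO_ACIDS)), size=int(hit.sum()))
    return "".join(chars)


def generate_pan_proteome(
    params: SynthParams,
) -> tuple[dict[str, list[ProteoformRecord]], GroundTruth]:
    """Generate per-strain proteomes with planted core/accessory/orphan
    families and controlled ortholog divergence."""
    rng = np.random.default_rng(params.seed)
    strains = [f"S{i+1:02d}" for i in range(params.n_strains)]
    truth = GroundTruth()
    proteomes: dict[str, list[ProteoformRecord]] = {s: [] for s in strains}

    families: list[tuple[int, str, list[str]]] = []  # (fid, class, members)
    fid = 0
    for _ in range(params.n_core):
        families.append((fid, "core", list(strains)))
        fid += 1
    for _ in range(params.n_accessory):
        if params.n_strains < 3:
            members = list(strains)  # degenerate: cannot be strictly partial
        else:
            while True:
                mask = rng.random(params.n_strains) < params.accessory_inclusion_p
                if 2 <= mask.sum() < params.n_strains:
                    break
            members = [s for s, m in zip(strains, mask) if m]
        families.append((fid, "accessory", members))
        fid += 1
    for s in strains:
        for _ in range(params.n_orphan_per_strain):
            families.append((fid, "orphan", [s]))
            fid += 1

    lo, hi = params.length_range
    for fam_id, fam_class, members in families:
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_protein(rng, length)
        truth.class_of_family[fam_id] = fam_class
        truth.strains_of_family[fam_id] = frozenset(members)
        for strain in members:
            seq = _diverge(rng, ancestor, params.divergence)
            acc = f"{strain}_F{fam_id:04d}"
            proteomes[strain].append(
                ProteoformRecord(
                    accession=acc,
                    sequence=seq,
                    source=Source.STRAIN,
                    strain_ids=frozenset([strain]),
                )
            )
            truth.family_of_accession[acc] = fam_id

    # expected ortholog identity under i.i.d. substitution with uniform targets
    expected_identity = 1.0 - params.divergence * 19.0 / 20.0
    if expected_identity < 0.7:
        truth.divergence_warning = True
    return proteomes, truth


def _peptide_pool(sequence: str, min_length: int) -> list[tuple[str, int]]:
    return digest(sequence, missed_cleavages=1, min_length=min_length)


def _conflicting_form(peptide: str) -> str:
    """A peptidoform over the same bare peptide that differs from the
    unmodified (closed) call — models an engine disagreement."""
    for residue, mod in (("N", "Deamidated"), ("Q", "Deamidated"),
                         ("M", "Oxidation"), ("K", "Methyl"), ("R", "Methyl")):
        idx = peptide.find(residue)
        if idx >= 0:
            return peptide[: idx + 1] + f"[{mod}]" + peptide[idx + 1:]
    return f"[Formyl]-{peptide}"


def simulate_psm_tables(
    proteomes: dict[str, list[ProteoformRecord]],
    truth: GroundTruth,
    params: SynthParams,
) -> tuple[list[PsmRecord], list[PsmRecord], dict[str, int], GroundTruth, PanDatabase]:
    """Simulate closed- and open-engine PSM tables over the proteomes.

    Returns (closed PSMs, open PSMs, spectra-per-run totals, extended ground
    truth, the target+decoy database used).  The decoy sequences are the
    ones the pipeline regenerates from the same seed, so planted false PSMs
    land on real decoy entries.
    """
    rng = np.random.default_rng(params.seed + 1)
    all_records = [rec for recs in proteomes.values() for rec in recs]
    db = build_pan_database(all_records)
    generate_decoys(db, params.seed)

    pools = {
        gid: _peptide_pool(db.records[gid].sequence, params.min_peptide_length)
        for gid in range(db.n_targets)
    }
    usable = [gid for gid, pool in pools.items() if pool]
    if not usable:
        raise ValueError("no target protein yields peptides at this minimum length")
    decoy_pools = {
        i: _peptide_pool(rec.sequence, params.min_peptide_length)
        for i, rec in enumerate(db.decoys)
    }

    abundance = rng.lognormal(params.abundance_mu, params.abundance_sigma, len(usable))
    probs = abundance / abundance.sum()
    for gid, a in zip(usable, abundance):
        truth.abundance[db.records[gid].accession] = float(a)

    mods = list(params.modification_rates.items())
    closed: list[PsmRecord] = []
    open_: list[PsmRecord] = []
    spectra_per_run: dict[str, int] = {}
    spectrum_counter = 0

    def _emit(run_id: str, spectrum_id: str, peptidoform: str, peptide: str,
              engines: tuple[Engine, ...],
              open_form: str | None = None) -> None:
        q = float(rng.uniform(0.0, 0.0004))
        score = float(rng.uniform(20.0, 100.0))
        for engine in engines:
            form = peptidoform
            if engine is Engine.OPEN and open_form is not None:
                form = open_form
            # every modified call carries a confident localization score, so
            # planted modifications survive the ambiguity filter downstream
            loc = float(rng.uniform(25.0, 60.0)) if form != peptide else None
            rec = PsmRecord(
                run_id=run_id, spectrum_id=spectrum_id, engine=engine,
                peptidoform=form, charge=int(rng.integers(2, 5)),
                score=score, q_value=q, loc_score=loc,
            )
            (closed if engine is Engine.CLOSED else open_).append(rec)

    for run_index in range(params.n_runs):
        run_id = f"run{run_index+1:02d}"
        n_identified = 0
        for _ in range(params.psms_per_run):
            spectrum_counter += 1
            spectrum_id = f"sp{spectrum_counter:07d}"
            is_false = rng.random() < params.decoy_psm_rate
            if is_false and decoy_pools:
                didx = int(rng.integers(db.n_decoys))
                pool = decoy_pools[didx]
                if not pool:
                    continue
                peptide, start = pool[int(rng.integers(len(pool)))]
                accession: str | None = None
            else:
                gid = usable[int(rng.choice(len(usable), p=probs))]
                pool = pools[gid]
                peptide, start = pool[int(rng.integers(len(pool)))]
                accession = db.records[gid].accession

            # plant modifications
            peptidoform = peptide
            mod_positions: list[tuple[int, str, bool]] = []
            for mod_name, rate in mods:
                if rng.random() >= rate:
                    continue
                eligible = ELIGIBLE_RESIDUES.get(mod_name, "")
                positions = [i for i, r in enumerate(peptide) if r in eligible]
                if not positions:
                    continue
                mis = (mod_name == "Phospho"
                       and rng.random() < params.mislocalization_rate)
                if mis:
                    pos0 = int(rng.integers(len(peptide)))
                else:
                    pos0 = positions[int(rng.integers(len(positions)))]
                mod_positions.append((pos0, mod_name, mis))
            if mod_positions:
                mod_positions.sort()
                built = []
                prev = 0
                for pos0, mod_name, _mis in mod_positions:
                    built.append(peptide[prev:pos0 + 1] + f"[{mod_name}]")
                    prev = pos0 + 1
                built.append(peptide[prev:])
                peptidoform = "".join(built)

            # engine assignment
            u = rng.random()
            if u < params.engine_overlap:
                engines: tuple[Engine, ...] = (Engine.CLOSED, Engine.OPEN)
            elif u < params.engine_overlap + (1 - params.engine_overlap) / 2:
                engines = (Engine.CLOSED,)
            else:
                engines = (Engine.OPEN,)

            open_form = None
            if len(engines) == 2:
                truth.both_engine_spectra.add((run_id, spectrum_id))
                if rng.random() < params.conflict_rate:
                    open_form = _conflicting_form(peptide)
                    if open_form == peptidoform:  # ensure a real conflict
                        open_form = f"[Formyl]-{peptide}"
                    truth.conflict_spectra.add((run_id, spectrum_id))

            _emit(run_id, spectrum_id, peptidoform, peptide, engines, open_form)
            n_identified += 1
            truth.psm_source[(run_id, spectrum_id)] = accession
            if accession is None:
                truth.false_psm.add((run_id, spectrum_id))
            else:
                for pos0, mod_name, mis in mod_positions:
                    truth.planted_sites.append(
                        PlantedSite(
                            run_id=run_id,
                            spectrum_id=spectrum_id,
                            accession=accession,
                            position=start + pos0,
                            residue=peptide[pos0],
                            mod_name=mod_name,
                            mislocalized=mis,
                        )
                    )
        spectra_per_run[run_id] = max(
            n_identified, int(round(n_identified / params.target_id_rate))
        ) if params.target_id_rate > 0 else n_identified

    # guaranteed baseline coverage: distinct peptides per target, unmodified
    if params.min_coverage_psms > 0:
        run1 = "run01"
        spectra_extra = 0
        for gid in range(db.n_targets):
            distinct = list(dict.fromkeys(pep for pep, _start in pools[gid]))
            picks = distinct[: params.min_coverage_psms]
            for peptide in picks:
                spectrum_counter += 1
                spectrum_id = f"sp{spectrum_counter:07d}"
                _emit(run1, spectrum_id, peptide, peptide, (Engine.CLOSED,))
                truth.psm_source[(run1, spectrum_id)] = db.records[gid].accession
                spectra_extra += 1
        spectra_per_run[run1] = spectra_per_run.get(run1, 0) + spectra_extra

    # plant false proteins: each decoy activated independently, emitting
    # enough distinct peptides to reach the canonical tier in the decoy pass
    run1 = "run01"
    for didx in range(db.n_decoys):
        if rng.random() >= params.false_protein_rate:
            continue
        distinct = list(dict.fromkeys(pep for pep, _start in decoy_pools[didx]))
        if len(distinct) < 2:
            continue
        picks = [distinct[i] for i in rng.choice(len(distinct), size=2, replace=False)]
        truth.activated_decoys.append(db.decoys[didx].accession)
        for peptide in picks:
            spectrum_counter += 1
            spectrum_id = f"sp{spectrum_counter:07d}"
            _emit(run1, spectrum_id, peptide, peptide, (Engine.CLOSED,))
            truth.psm_source[(run1, spectrum_id)] = None
            truth.false_psm.add((run1, spectrum_id))

    return closed, open_, spectra_per_run, truth, db
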