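"""Protein inference: peptide evidence, confidence tiers, protein-level FDR.

Observed peptides are mapped to deduplicated sequence groups and each target
group receives exactly one confidence tier:

* **canonical** — at least two uniquely mapping peptides;
* **marginal** — exactly one unique peptide plus at least one peptide shared
  with a canonical group;
* **indistinguishable** — observed, no unique peptide, and every observed
  peptide is also claimed by at least one canonical group;
* **uncertain** — observed but none of the above (e.g. all peptides shared
  only among non-canonical groups, or one unique peptide with no canonical
  overlap);
* **not_observed** — no peptide evidence.

When several groups carry *identical* observed peptide sets, none of them can
have a unique peptide, yet jointly the set may be unambiguous: if at least
two of their peptides map only within the tie group, one member is promoted
to canonical — preferring a member of the designated core (reference)
proteome, then lexicographically smallest accession — and the rest become
indistinguishable.

Protein-level FDR uses the plain decoy estimator: decoy groups are tiered in
a parallel pass (decoy peptides mapped among decoys only) and the FDR is the
ratio of decoy to target groups at tier canonical or marginal.  This is a
simple decoy-count estimator, not a hypergeometric model.
"""

from __future__ import annotations

from collections import defaultdict

from .database import PanDatabase, PeptideIndex, map_peptide, map_peptide_decoys
from .records import MergedPsm, PeptideEvidence, Tier, TierAssignment

__all__ = [
    "compute_evidence",
    "compute_decoy_evidence",
    "assign_tiers",
    "estimate_protein_fdr",
]


def compute_evidence(
    merged: list[MergedPsm],
    db: PanDatabase,
    index: PeptideIndex | None = None,
) -> tuple[list[PeptideEvidence], list[MergedPsm]]:
    """Aggregate merged PSMs into per-peptide evidence records.

    Returns (evidence, unmatched) where ``unmatched`` collects PSMs whose
    bare peptide maps to no target group (decoy or contaminant-removal
    diagnostics).  Evidence records are ordered by first occurrence of the
    peptide in the PSM stream.
    """
    psms_by_peptide: dict[str, list[MergedPsm]] = {}
    for m in merged:
        psms_by_peptide.setdefault(m.peptide, []).append(m)

    evidence: list[PeptideEvidence] = []
    unmatched: list[MergedPsm] = []
    for peptide, psms in psms_by_peptide.items():
        groups = map_peptide(db, peptide, index)
        if not groups:
            unmatched.extend(psms)
            continue
        evidence.append(
            PeptideEvidence(
                peptide=peptide,
                group_ids=frozenset(groups),
                psm_count=len(psms),
                best_score=max(p.psm.score for p in psms),
            )
        )
    return evidence, unmatched


def compute_decoy_evidence(unmatched: list[MergedPsm], db: PanDatabase) -> list[PeptideEvidence]:
    """Map target-unmatched PSM peptides onto the decoy sequences.

    Used for the parallel decoy tiering pass behind the protein-FDR
    estimate.  Group ids are decoy record offsets (n_targets ..).
    """
    psms_by_peptide: dict[str, list[MergedPsm]] = {}
    for m in unmatched:
        psms_by_peptide.setdefault(m.peptide, []).append(m)
    out: list[PeptideEvidence] = []
    for peptide, psms in psms_by_peptide.items():
        groups = map_peptide_decoys(db, peptide)
        if groups:
            out.append(
                PeptideEvidence(
                    peptide=peptide,
                    group_ids=frozenset(groups),
                    psm_count=len(psms),
                    best_score=max(p.psm.score for p in psms),
                )
            )
    return out


def _tier_groups(
    observed: dict[int, set[str]],
    unique_count: dict[int, int],
    all_group_ids: list[int],
    core_groups: set[int],
    peptide_claimants: dict[str, set[int]],
    accession_of: dict[int, str],
) -> dict[int, Tier]:
    """Shared tier logic over a peptide↔group incidence structure."""
    tiers: dict[int, Tier] = {}
    canonical: set[int] = {
        g for g in all_group_ids if unique_count.get(g, 0) >= 2
    }

    # Promotion of identical observed peptide sets: within a tie class no
    # peptide is unique to a member, but peptides confined to the class
    # ("class-unique") can jointly make one member canonical.
    by_peptide_set: dict[frozenset[str], list[int]] = defaultdict(list)
    for g, peps in observed.items():
        if peps and g not in canonical:
            by_peptide_set[frozenset(peps)].append(g)
    for pepset, members in by_peptide_set.items():
        if len(members) < 2:
            continue
        member_set = set(members)
        class_unique = sum(
            1 for p in pepset if peptide_claimants[p] <= member_set
        )
        if class_unique < 2:
            continue
        in_core = [g for g in members if g in core_groups]
        pool = in_core if in_core else members
        promoted = min(pool, key=lambda g: (accession_of[g], g))
        canonical.add(promoted)

    for g in all_group_ids:
        peps = observed.get(g, set())
        if not peps:
            tiers[g] = Tier.NOT_OBSERVED
        elif g in canonical:
            tiers[g] = Tier.CANONICAL
        elif unique_count.get(g, 0) == 1 and any(
            peptide_claimants[p] & canonical for p in peps
        ):
            tiers[g] = Tier.MARGINAL
        elif unique_count.get(g, 0) == 0 and all(
            peptide_claimants[p] & canonical for p in peps
        ):
            tiers[g] = Tier.INDISTINGUISHABLE
        else:
            tiers[g] = Tier.UNCERTAIN
    return tiers


def assign_tiers(
    evidence: list[PeptideEvidence],
    db: PanDatabase,
    core_proteome_id: str,
    decoy_evidence: list[PeptideEvidence] | None = None,
) -> list[TierAssignment]:
    """Assign every target group (and, in a parallel pass, every decoy group)
    exactly one confidence tier.  See the module docstring for the rules."""
    if core_proteome_id not in db.strains():
        raise ValueError(f"unknown core proteome {core_proteome_id!r}")

    observed: dict[int, set[str]] = defaultdict(set)
    claimants: dict[str, set[int]] = {}
    for ev in evidence:
        claimants[ev.peptide] = set(ev.group_ids)
        for g in ev.group_ids:
            observed[g].add(ev.peptide)
    unique_count: dict[int, int] = defaultdict(int)
    for ev in evidence:
        if ev.is_unique:
            unique_count[next(iter(ev.group_ids))] += 1

    core_groups = {
        gid for gid, rec in enumerate(db.targets)
        if core_proteome_id in rec.strain_ids
    }
    target_ids = list(range(db.n_targets))
    accession_of = {gid: db.records[gid].accession for gid in target_ids}
    tiers = _tier_groups(observed, unique_count, target_ids, core_groups,
                         claimants, accession_of)

    out: list[TierAssignment] = []
    for gid in target_ids:
        peps = observed.get(gid, set())
        n_unique = unique_count.get(gid, 0)
        out.append(
            TierAssignment(
                group_id=gid,
                representative_accession=db.records[gid].accession,
                tier=tiers[gid],
                n_unique_peptides=n_unique,
                n_shared_peptides=len(peps) - n_unique,
                in_core_proteome=gid in core_groups,
            )
        )

    if decoy_evidence:
        d_observed: dict[int, set[str]] = defaultdict(set)
        d_claimants: dict[str, set[int]] = {}
        for ev in decoy_evidence:
            d_claimants[ev.peptide] = set(ev.group_ids)
            for g in ev.group_ids:
                d_observed[g].add(ev.peptide)
        d_unique: dict[int, int] = defaultdict(int)
        for ev in decoy_evidence:
            if ev.is_unique:
                d_unique[next(iter(ev.group_ids))] += 1
        decoy_ids = sorted(d_observed)
        d_accessions = {gid: db.records[gid].accession for gid in decoy_ids}
        d_tiers = _tier_groups(d_observed, d_unique, decoy_ids, set(),
                               d_claimants, d_accessions)
        for gid in decoy_ids:
            peps = d_observed[gid]
            out.append(
                TierAssignment(
                    group_id=gid,
                    representative_accession=db.records[gid].accession,
                    tier=d_tiers[gid],
                    n_unique_peptides=d_unique.get(gid, 0),
                    n_shared_peptides=len(peps) - d_unique.get(gid, 0),
                    in_core_proteome=False,
                    is_decoy=True,
                )
            )
    return out


_PASSING = (Tier.CANONICAL, Tier.MARGINAL)


def estimate_protein_fdr(assignments: list[TierAssignment]) -> float:
    """Decoy-count protein FDR: passing decoys / passing targets.

    "Passing" means tier canonical or marginal.  Simple ratio estimator;
    no finite-size (hypergeometric) correction is applied.
    """
    n_target = sum(1 for a in assignments if not a.is_decoy and a.tier in _PASSING)
    n_decoy = sum(1 for a in assignments if a.is_decoy and a.tier in _PASSING)
    if n_target == 0:
        raise ValueError("no passing target groups; FDR undefined")
    return n_decoy / n_target
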