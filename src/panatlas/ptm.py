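"""Modification-site remapping, classification, FLR, and abundance analysis.

Modified peptides are remapped to canonical proteins: a PSM contributes
sites only when its bare peptide maps to exactly one canonical-tier group.
A *site* is a distinct (protein, position, modification) triple; an *event
observation* is one modified PSM supporting it — both tallies are reported.

Phosphorylation false localization is estimated with the decoy-amino-acid
device: alanine cannot chemically carry a phosphate, so phospho-Ala calls
measure the mislocalization background.  With f_A and f_STY the residue
frequencies of A and S+T+Y in canonical proteins,

    FLR = (N_phosphoA / f_A) / (N_phosphoSTY / f_STY)

is the estimated fraction of reported S/T/Y phospho-sites that are wrongly
localized.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import pandas as pd
from scipy.stats import spearmanr

from .database import PanDatabase, PeptideIndex, map_peptide
from .records import (
    MergedPsm,
    ModificationEvent,
    NsafRecord,
    PeptideEvidence,
    Tier,
    TierAssignment,
)

PHOSPHO = "Phospho"


def remap_modification_sites(
    merged: list[MergedPsm],
    tiers: list[TierAssignment],
    db: PanDatabase,
    index: PeptideIndex | None = None,
) -> list[ModificationEvent]:
    """Remap modified PSMs to unique canonical proteins and aggregate sites.

    A PSM whose bare peptide maps to zero or to two or more canonical groups
    contributes nothing.  The site position is peptide start + offset - 1 in
    protein coordinates (first occurrence of the peptide in the protein);
    N-terminal modifications are assigned to the first peptide residue.
    """
    canonical = {t.group_id for t in tiers if not t.is_decoy and t.tier is Tier.CANONICAL}
    support: dict[tuple[int, int, str], int] = defaultdict(int)
    runs: dict[tuple[int, int, str], set[str]] = defaultdict(set)
    residues: dict[tuple[int, int, str], str] = {}

    for m in merged:
        if not m.is_modified:
            continue
        groups = map_peptide(db, m.peptide, index) & canonical
        if len(groups) != 1:
            continue
        gid = next(iter(groups))
        protein = db.records[gid].sequence
        start = protein.find(m.peptide)  # first occurrence
        for offset, mod_name in m.psm.modifications():
            position = start + offset  # start is 0-based, offset 1-based
            residue = m.peptide[offset - 1]
            if protein[position - 1] != residue:
                raise ValueError(
                    f"PSM {m.run_id}/{m.spectrum_id}: residue mismatch at "
                    f"{db.records[gid].accession} position {position}"
                )
            key = (gid, position, mod_name)
            support[key] += 1
            runs[key].add(m.run_id)
            residues[key] = residue

    events = [
        ModificationEvent(
            group_id=gid,
            position=pos,
            residue=residues[(gid, pos, name)],
            mod_name=name,
            psm_support=support[(gid, pos, name)],
            runs_observed=frozenset(runs[(gid, pos, name)]),
        )
        for (gid, pos, name) in sorted(support)
    ]
    return events


def classify_events(
    events: list[ModificationEvent],
    unimod_map: dict[str, list[str]],
) -> tuple[list[ModificationEvent], Counter]:
    """Attach a Unimod class to every event and tally sites per class.

    Names mapping to more than one class are grouped as "Other"; names
    absent from the map become "Unclassified".
    """
    if not unimod_map:
        raise ValueError("empty Unimod class map")
    counts: Counter = Counter()
    for ev in events:
        classes = unimod_map.get(ev.mod_name)
        if classes is None:
            ev.unimod_class = "Unclassified"
        elif len(set(classes)) > 1:
            ev.unimod_class = "Other"
        else:
            ev.unimod_class = classes[0]
        counts[ev.unimod_class] += 1
    return events, counts


def per_residue_breakdown(events: list[ModificationEvent], mod_name: str) -> dict[str, int]:
    """Distinct (protein, position) site counts per residue for one modification."""
    sites: dict[str, set[tuple[int, int]]] = defaultdict(set)
    for ev in events:
        if ev.mod_name == mod_name:
            sites[ev.residue].add((ev.group_id, ev.position))
    return {res: len(s) for res, s in sorted(sites.items())}


def residue_frequencies(db: PanDatabase, group_ids: set[int]) -> Counter:
    """Residue composition over the given target groups."""
    comp: Counter = Counter()
    for gid in group_ids:
        comp.update(db.records[gid].sequence)
    return comp


def estimate_phospho_flr(
    events: list[ModificationEvent],
    db: PanDatabase,
    tiers: list[TierAssignment],
    mod_name: str = PHOSPHO,
    weight_by_support: bool = True,
) -> float:
    """Decoy-alanine phospho false-localization rate (see module docstring).

    By default counts are PSM-support-weighted (observation counts): distinct
    -site counting is biased upward at high sampling depth, because repeated
    mislocalized placements onto S/T/Y are absorbed into already-reported
    correct sites while every alanine placement opens a new site.
    ``weight_by_support=False`` gives the distinct-site variant.
    """
    if weight_by_support:
        tallies: Counter = Counter()
        for ev in events:
            if ev.mod_name == mod_name:
                tallies[ev.residue] += ev.psm_support
        breakdown = dict(tallies)
    else:
        breakdown = per_residue_breakdown(events, mod_name)
    n_ala = breakdown.get("A", 0)
    n_sty = sum(breakdown.get(r, 0) for r in "STY")
    if n_ala == 0:
        return 0.0
    if n_sty == 0:
        raise ValueError("phospho-Ala sites present but no S/T/Y sites; FLR undefined")
    canonical = {t.group_id for t in tiers if not t.is_decoy and t.tier is Tier.CANONICAL}
    comp = residue_frequencies(db, canonical)
    total = sum(comp.values())
    f_ala = comp.get("A", 0) / total
    f_sty = sum(comp.get(r, 0) for r in "STY") / total
    if f_ala == 0 or f_sty == 0:
        raise ValueError("canonical proteins lack A or S/T/Y residues; FLR undefined")
    return (n_ala / f_ala) / (n_sty / f_sty)


def compute_nsaf(
    merged: list[MergedPsm],
    evidence: list[PeptideEvidence],
    db: PanDatabase,
) -> list[NsafRecord]:
    """Normalized spectral abundance factor per (protein group, run).

    NSAF = (uniquely mapping PSM count / protein length) / total PSMs in the
    run; all merged PSMs in the run form the denominator.  Proteins with no
    unique PSMs in a run are omitted.
    """
    unique_group = {
        ev.peptide: next(iter(ev.group_ids)) for ev in evidence if ev.is_unique
    }
    run_totals: Counter = Counter(m.run_id for m in merged)
    counts: dict[tuple[int, str], int] = defaultdict(int)
    for m in merged:
        gid = unique_group.get(m.peptide)
        if gid is not None:
            counts[(gid, m.run_id)] += 1
    records = []
    for (gid, run_id), n in sorted(counts.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        total = run_totals[run_id]
        if total == 0:
            continue
        length = len(db.records[gid].sequence)
        records.append(
            NsafRecord(
                group_id=gid,
                run_id=run_id,
                unique_psm_count=n,
                protein_length=length,
                nsaf=(n / length) / total,
            )
        )
    return records


def abundance_vs_modification(
    nsaf: list[NsafRecord],
    events: list[ModificationEvent],
) -> tuple[pd.DataFrame, float | None]:
    """Per-protein mean NSAF vs distinct modification-site count.

    Returns the table and the Spearman rank correlation (None with fewer
    than three proteins).
    """
    if not nsaf or not events:
        raise ValueError("both NSAF records and modification events are required")
    mean_nsaf: dict[int, float] = {}
    by_group: dict[int, list[float]] = defaultdict(list)
    for rec in nsaf:
        by_group[rec.group_id].append(rec.nsaf)
    for gid, values in by_group.items():
        mean_nsaf[gid] = sum(values) / len(values)
    site_counts: Counter = Counter()
    for ev in events:
        site_counts[ev.group_id] += 1
    rows = [
        {
            "group_id": gid,
            "mean_nsaf": mean_nsaf[gid],
            "n_mod_sites": site_counts.get(gid, 0),
        }
        for gid in sorted(mean_nsaf)
    ]
    table = pd.DataFrame(rows, columns=["group_id", "mean_nsaf", "n_mod_sites"])
    if len(table) < 3:
        return table, None
    if table["n_mod_sites"].nunique() == 1 or table["mean_nsaf"].nunique() == 1:
        return table, 0.0  # no rank variation: no association
    rho = spearmanr(table["mean_nsaf"], table["n_mod_sites"]).statistic
    return table, float(rho)


def per_run_ptm_vector(
    events: list[ModificationEvent],
    psms: list[MergedPsm],
) -> pd.DataFrame:
    """Run x modification matrix of modified-PSM observation counts.

    Rows follow run order of first appearance in the PSM stream; missing
    combinations are zero.
    """
    run_order = list(dict.fromkeys(m.run_id for m in psms))
    mod_names = sorted({ev.mod_name for ev in events})
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for m in psms:
        if not m.is_modified:
            continue
        for _pos, name in m.psm.modifications():
            counts[(m.run_id, name)] += 1
    all_mods = sorted(set(mod_names) | {k[1] for k in counts})
    data = [
        [counts.get((run, mod), 0) for mod in all_mods]
        for run in run_order
    ]
    return pd.DataFrame(data, index=run_order, columns=all_mods)
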