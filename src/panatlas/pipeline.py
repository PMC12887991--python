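"""End-to-end build orchestration and the build report.

``run_build`` executes every stage in order — database construction →
PSM filtering and merge → protein inference → homology clustering →
PTM analysis → physicochemical characterization — writing every
intermediate table to the output directory and returning a BuildReport whose
every count is reproducible from the stage outputs it summarizes.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import clustering, inference, io, merge, physchem, ptm
from .config import PipelineConfig, write_config
from .database import PanDatabase, build_pan_database, build_peptide_index, generate_decoys
from .records import (
    Engine,
    MergedPsm,
    ProteoformRecord,
    Source,
    Tier,
    TierAssignment,
)

logger = logging.getLogger(__name__)

_TIER_ORDER = [Tier.CANONICAL, Tier.INDISTINGUISHABLE, Tier.MARGINAL,
               Tier.UNCERTAIN, Tier.NOT_OBSERVED]


@dataclass
class BuildReport:
    n_psms: int
    n_distinct_peptides: int
    n_distinct_peptidoforms: int
    tier_counts: dict[str, int]
    coverage_by_strain: dict[str, dict[str, float]]
    cluster_class_counts: dict[str, int]
    mean_cluster_size: float
    protein_fdr: float
    ptm_class_counts: dict[str, int]
    phospho_per_residue: dict[str, int]
    id_rate_median: float | None
    id_rate_per_run: dict[str, float]
    flr_estimate: float | None
    nsaf_mod_spearman: float | None
    config: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["# Pan-proteome build report", ""]
        lines.append(f"PSMs merged into build: {self.n_psms}")
        lines.append(f"Distinct peptides: {self.n_distinct_peptides}")
        lines.append(f"Distinct peptidoforms: {self.n_distinct_peptidoforms}")
        lines.append(f"Protein FDR (decoy-count estimator): {self.protein_fdr:.4f}")
        lines.append("")
        lines.append("Proteins per tier:")
        for tier in _TIER_ORDER:
            lines.append(f"  {tier.value}: {self.tier_counts.get(tier.value, 0)}")
        lines.append("")
        lines.append("Homology cluster classes:")
        for cls, n in sorted(self.cluster_class_counts.items()):
            lines.append(f"  {cls}: {n}")
        lines.append(f"  mean cluster size: {self.mean_cluster_size:.2f}")
        lines.append("")
        if self.id_rate_median is not None:
            lines.append(f"Median identification rate: {self.id_rate_median:.3f}")
        if self.flr_estimate is not None:
            lines.append(f"Phospho FLR estimate (decoy-alanine): {self.flr_estimate:.4f}")
        if self.nsaf_mod_spearman is not None:
            lines.append(
                f"Abundance vs modification sites (Spearman): {self.nsaf_mod_spearman:.3f}")
        lines.append("")
        lines.append("PTM site counts per Unimod class:")
        for cls, n in sorted(self.ptm_class_counts.items()):
            lines.append(f"  {cls}: {n}")
        if self.phospho_per_residue:
            lines.append("Phospho sites per residue: " + ", ".join(
                f"{r}:{n}" for r, n in sorted(self.phospho_per_residue.items())))
        return "\n".join(lines) + "\n"


def coverage_by_strain(
    tiers: list[TierAssignment], db: PanDatabase
) -> dict[str, dict[str, float]]:
    """Per-strain fraction of its proteoforms at each tier (fractions sum to 1)."""
    tier_by_group = {t.group_id: t.tier for t in tiers if not t.is_decoy}
    counts: dict[str, Counter] = defaultdict(Counter)
    for gid, rec in enumerate(db.targets):
        if rec.source is not Source.STRAIN:
            continue
        tier = tier_by_group.get(gid, Tier.NOT_OBSERVED)
        for strain in rec.strain_ids:
            counts[strain][tier] += 1
    out: dict[str, dict[str, float]] = {}
    for strain, tc in sorted(counts.items()):
        total = sum(tc.values())
        out[strain] = {t.value: tc.get(t, 0) / total for t in _TIER_ORDER}
    return out


def run_build(
    config: PipelineConfig,
    proteomes: dict[str, list[ProteoformRecord]],
    closed_psms: list,
    open_psms: list,
    out_dir: str | Path,
    spectra_per_run: dict[str, int] | None = None,
    extra_records: list[ProteoformRecord] | None = None,
    unimod_map: dict[str, list[str]] | None = None,
) -> tuple[BuildReport, dict]:
    """Run every stage end-to-end; returns (report, stage outputs dict)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("pan_db")
        records = [r for recs in proteomes.values() for r in recs]
        records += extra_records or []
        db = build_pan_database(records)
        generate_decoys(db, config.random_seed)
        index = build_peptide_index(db, config)
        io.write_fasta(db.records, out_dir / "pan_database.fasta")
        stages["db"] = db
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage pan_db failed: {exc}") from exc

    try:
        _stage("psm_integration")
        closed_f = merge.filter_closed_psms(closed_psms, config.closed_psm_fdr)
        open_f = merge.filter_open_psms(
            [p for p in open_psms if p.engine is Engine.OPEN], config.open_psm_fdr)
        closed_f = merge.filter_localization(closed_f, config.min_loc_score)
        open_f = merge.filter_localization(open_f, config.min_loc_score)
        merged = merge.merge_searches(closed_f, open_f)
        io.write_merged_table(merged, out_dir / "merged_psms.tsv")
        stages["merged"] = merged
        id_rates: dict[str, float] = {}
        id_median = None
        if spectra_per_run:
            id_rates, id_median = merge.summarize_id_rate(merged, spectra_per_run)
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage psm_integration failed: {exc}") from exc

    try:
        _stage("inference")
        evidence, unmatched = inference.compute_evidence(merged, db, index)
        decoy_evidence = inference.compute_decoy_evidence(unmatched, db)
        tiers = inference.assign_tiers(evidence, db, config.core_proteome_id,
                                       decoy_evidence)
        fdr = inference.estimate_protein_fdr(tiers)
        tier_df = pd.DataFrame(
            [
                {
                    "group_id": t.group_id,
                    "representative": t.representative_accession,
                    "tier": t.tier.value,
                    "n_unique": t.n_unique_peptides,
                    "n_shared": t.n_shared_peptides,
                    "in_core_proteome": t.in_core_proteome,
                    "is_decoy": t.is_decoy,
                }
                for t in tiers
            ]
        )
        io.write_tsv(tier_df, out_dir / "tiers.tsv")
        stages.update(evidence=evidence, unmatched=unmatched, tiers=tiers, fdr=fdr)
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage inference failed: {exc}") from exc

    try:
        _stage("pan_structure")
        clusters = clustering.cluster_proteoforms(db, config.cluster_identity)
        all_strains = {s for rec in db.targets if rec.source is Source.STRAIN
                       for s in rec.strain_ids}
        clustering.classify_clusters(clusters, all_strains, db, tiers)
        cluster_df = pd.DataFrame(
            [
                {
                    "cluster_id": c.cluster_id,
                    "representative": db.records[c.representative_group].accession,
                    "n_members": len(c.member_groups),
                    "strains": ";".join(sorted(c.strains_present)),
                    "class": c.cluster_class.value,
                    "best_tier": c.best_tier.value if c.best_tier else "",
                }
                for c in clusters
            ]
        )
        io.write_tsv(cluster_df, out_dir / "clusters.tsv")
        io.write_tsv(clustering.upset_membership(clusters), out_dir / "upset.tsv")
        seq_by_strain = {
            s: [r.sequence for r in recs] for s, recs in proteomes.items()
        }
        if len(seq_by_strain) >= 2:
            dm = clustering.jaccard_digest_matrix(seq_by_strain, config)
            tree = clustering.build_upgma_tree(dm)
            io.write_newick(tree, out_dir / "proteome_tree.nwk")
            pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
                out_dir / "jaccard_distances.tsv", sep="\t")
            stages.update(distance_matrix=dm, tree=tree)
        stages["clusters"] = clusters
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage pan_structure failed: {exc}") from exc

    try:
        _stage("ptm_analysis")
        if unimod_map is None:
            unimod_map = io.read_unimod_map(
                Path(__file__).parent / "data" / "unimod_classes.tsv")
        events = ptm.remap_modification_sites(merged, tiers, db, index)
        events, class_counts = ptm.classify_events(events, unimod_map)
        phospho_breakdown = ptm.per_residue_breakdown(events, ptm.PHOSPHO)
        flr = None
        try:
            flr = ptm.estimate_phospho_flr(events, db, tiers)
        except ValueError:
            pass
        nsaf = ptm.compute_nsaf(merged, evidence, db)
        spearman = None
        if nsaf and events:
            _table, spearman = ptm.abundance_vs_modification(nsaf, events)
        events_df = pd.DataFrame(
            [
                {
                    "protein": db.records[e.group_id].accession,
                    "position": e.position,
                    "residue": e.residue,
                    "mod_name": e.mod_name,
                    "unimod_class": e.unimod_class,
                    "psm_support": e.psm_support,
                    "runs": ";".join(sorted(e.runs_observed)),
                }
                for e in events
            ]
        )
        io.write_tsv(events_df, out_dir / "modification_events.tsv")
        ptm.per_run_ptm_vector(events, merged).to_csv(
            out_dir / "ptm_vectors.tsv", sep="\t")
        nsaf_df = pd.DataFrame(
            [
                {
                    "protein": db.records[r.group_id].accession,
                    "run_id": r.run_id,
                    "unique_psms": r.unique_psm_count,
                    "length": r.protein_length,
                    "nsaf": r.nsaf,
                }
                for r in nsaf
            ]
        )
        io.write_tsv(nsaf_df, out_dir / "nsaf.tsv")
        stages.update(events=events, nsaf=nsaf, flr=flr, spearman=spearman)
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage ptm_analysis failed: {exc}") from exc

    try:
        _stage("physchem")
        phys_table, phys_summary = physchem.characterize_sets(db, tiers, config)
        io.write_tsv(phys_table, out_dir / "physchem.tsv")
        stages.update(physchem_table=phys_table, physchem_summary=phys_summary)
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage physchem failed: {exc}") from exc

    target_tiers = [t for t in tiers if not t.is_decoy]
    tier_counts = Counter(t.tier.value for t in target_tiers)
    strain_clusters = [c for c in clusters
                       if c.cluster_class is not None and c.strains_present]
    cluster_counts = Counter(c.cluster_class.value for c in clusters)
    mean_size = (
        sum(len(c.member_groups) for c in strain_clusters) / len(strain_clusters)
        if strain_clusters else 0.0
    )
    report = BuildReport(
        n_psms=len(merged),
        n_distinct_peptides=len({m.peptide for m in merged}),
        n_distinct_peptidoforms=len({m.peptidoform for m in merged}),
        tier_counts=dict(tier_counts),
        coverage_by_strain=coverage_by_strain(tiers, db),
        cluster_class_counts=dict(cluster_counts),
        mean_cluster_size=mean_size,
        protein_fdr=fdr,
        ptm_class_counts=dict(class_counts),
        phospho_per_residue=phospho_breakdown,
        id_rate_median=id_median,
        id_rate_per_run=id_rates,
        flr_estimate=flr,
        nsaf_mod_spearman=spearman,
        config=asdict(config),
    )
    (out_dir / "report.txt").write_text(report.to_text())
    (out_dir / "report.json").write_text(json.dumps(asdict(report), indent=2))
    write_config(config, out_dir / "config.echo.txt")
    return report, stages
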