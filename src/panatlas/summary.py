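"""Arithmetic-consistency checks over published build summary counts.

The public *E. coli* PeptideAtlas build (2024-11, https://peptideatlas.org/builds/ecoli/)
reports headline counts — spectra, PSMs, clusters, per-residue modification
sites.  Reproducing them requires the full 73-million-spectrum reprocessing;
what *is* computable at the desk is their internal arithmetic: derived
percentages, means, and totals.  This module ships those published counts as
input data and derives the summary quantities from them with the same
formulas the pipeline applies to its own outputs.
"""

from __future__ import annotations

# Headline counts of the published E. coli PeptideAtlas build (2024-11).
PUBLISHED = {
    "total_spectra": 73_008_556,
    "identified_psms": 23_823_673,
    "distinct_peptidoforms": 537_885,
    "distinct_peptides": 151_590,
    "canonical_proteins": 4_755,
    "proteoforms": 27_806,
    "clusters_70pct": 8_310,
    "orphan_clusters": 2_871,
    "accessory_clusters": 2_649,
    "core_clusters": 2_790,
    "unobserved_proteoforms": 6_445,
}

# Distinct phosphorylation sites per residue in the published build.
PHOSPHO_SITES_PER_RESIDUE = {
    "S": 1753, "T": 996, "Y": 553, "H": 371,
    "C": 58, "E": 38, "D": 30, "K": 4, "R": 3,
}

# Distinct phosphoribosylation sites per residue in the published build.
PHOSPHORIBOSYL_SITES_PER_RESIDUE = {"E": 125, "D": 94, "R": 7}


def mean_cluster_size(n_proteoforms: int | None = None,
                      n_clusters: int | None = None) -> float:
    """Average proteoforms per homology cluster."""
    n_proteoforms = PUBLISHED["proteoforms"] if n_proteoforms is None else n_proteoforms
    n_clusters = PUBLISHED["clusters_70pct"] if n_clusters is None else n_clusters
    return n_proteoforms / n_clusters


def identified_spectra_percent(identified: int | None = None,
                               total: int | None = None) -> float:
    """Identified PSMs as a percentage of acquired spectra."""
    identified = PUBLISHED["identified_psms"] if identified is None else identified
    total = PUBLISHED["total_spectra"] if total is None else total
    return 100.0 * identified / total


def cluster_class_percent(cluster_class: str) -> float:
    """Percentage of clusters in one pan-proteome class (core/accessory/orphan)."""
    key = f"{cluster_class}_clusters"
    if key not in PUBLISHED:
        raise ValueError(f"unknown cluster class {cluster_class!r}")
    return 100.0 * PUBLISHED[key] / PUBLISHED["clusters_70pct"]


def total_sites(per_residue: dict[str, int]) -> int:
    """Total distinct sites as the sum of a per-residue breakdown."""
    return sum(per_residue.values())


def phospho_total_sites() -> int:
    return total_sites(PHOSPHO_SITES_PER_RESIDUE)


def phosphoribosyl_total_sites() -> int:
    return total_sites(PHOSPHORIBOSYL_SITES_PER_RESIDUE)


def unobserved_percent() -> float:
    """Percentage of proteoforms without any peptide evidence."""
    return 100.0 * PUBLISHED["unobserved_proteoforms"] / PUBLISHED["proteoforms"]
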