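"""Pan-proteome structure: homology clustering, proteome distances, trees.

Clustering follows the greedy incremental strategy of standard sequence
clustering tools: sequences are sorted longest-first and each either joins
the first existing cluster whose representative it matches at or above the
identity threshold, or founds a new cluster.  Identity is computed from a
global alignment (match +1, mismatch 0, gap open -5, gap extend -1) and
normalized by the length of the shorter sequence.

Clusters are classified against the full strain list: *core* families have a
member in every strain, *accessory* in at least two but not all, *orphan* in
exactly one.  Clusters containing only phage/contaminant members fall
outside the strain logic and are labelled non_strain.

Proteome-level distances are 1 minus the Jaccard similarity of fully tryptic
peptide sets, and the proteome tree is the UPGMA agglomeration of that
distance matrix (average linkage, ultrametric output).
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import average as _scipy_average_linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from .config import PipelineConfig
from .database import PanDatabase, digest
from .records import ClusterClass, HomologyCluster, Source, Tier, TierAssignment

_TIER_RANK = {
    Tier.CANONICAL: 0,
    Tier.MARGINAL: 1,
    Tier.INDISTINGUISHABLE: 2,
    Tier.UNCERTAIN: 3,
    Tier.NOT_OBSERVED: 4,
}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


_MAX_COOPTIMAL = 64


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity normalized by the shorter sequence length.

    When several alignments share the optimal score, the one with the most
    identical aligned residues defines the identity (deterministic over
    co-optimal tie-breaking).
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    alignments = _ALIGNER.align(a, b)
    try:
        n_alns = min(len(alignments), _MAX_COOPTIMAL)
    except OverflowError:
        n_alns = _MAX_COOPTIMAL
    identities = 0
    for k, alignment in enumerate(alignments):
        if k >= n_alns:
            break
        identities = max(identities, alignment.counts().identities)
    return identities / min(len(a), len(b))


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def cluster_proteoforms(
    db: PanDatabase,
    threshold: float,
    kmer_prefilter: bool = False,
    kmer_size: int = 5,
) -> list[HomologyCluster]:
    """Greedy incremental clustering of target groups at an identity threshold.

    Order: decreasing length, then lexicographic accession — deterministic.
    ``kmer_prefilter`` skips alignments against representatives sharing no
    k-mer with the query; it is an optimization only and cannot change the
    result (a pair with zero shared k-mers of the chosen size cannot reach
    any useful identity threshold, and the flag is asserted equivalent in
    the test suite).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0,1]")
    order = sorted(
        range(db.n_targets),
        key=lambda g: (-len(db.records[g].sequence), db.records[g].accession),
    )
    clusters: list[HomologyCluster] = []
    rep_kmers: list[set[str]] = []
    for gid in order:
        seq = db.records[gid].sequence
        kmers = _kmer_set(seq, kmer_size) if kmer_prefilter else set()
        joined = False
        for ci, cluster in enumerate(clusters):
            if threshold >= 1.0:
                if seq != db.records[cluster.representative_group].sequence:
                    continue
            if kmer_prefilter and not (kmers & rep_kmers[ci]):
                continue
            rep_seq = db.records[cluster.representative_group].sequence
            if pairwise_identity(seq, rep_seq) >= threshold:
                cluster.member_groups.append(gid)
                joined = True
                break
        if not joined:
            clusters.append(
                HomologyCluster(
                    cluster_id=len(clusters),
                    representative_group=gid,
                    member_groups=[gid],
                )
            )
            if kmer_prefilter:
                rep_kmers.append(kmers if kmers else _kmer_set(seq, kmer_size))
            else:
                rep_kmers.append(set())
    return clusters


def classify_clusters(
    clusters: list[HomologyCluster],
    all_strains: set[str],
    db: PanDatabase,
    tiers: list[TierAssignment] | None = None,
) -> list[HomologyCluster]:
    """Set strains_present, cluster_class and best_tier on each cluster.

    Phage/contaminant members contribute no strains; clusters without any
    strain member are classified non_strain.
    """
    tier_by_group = {t.group_id: t.tier for t in tiers or [] if not t.is_decoy}
    for cluster in clusters:
        strains: set[str] = set()
        for gid in cluster.member_groups:
            rec = db.records[gid]
            if rec.source is Source.STRAIN:
                strains |= rec.strain_ids
        cluster.strains_present = frozenset(strains)
        if not strains:
            cluster.cluster_class = ClusterClass.NON_STRAIN
        elif strains == set(all_strains):
            cluster.cluster_class = ClusterClass.CORE
        elif len(strains) == 1:
            cluster.cluster_class = ClusterClass.ORPHAN
        else:
            cluster.cluster_class = ClusterClass.ACCESSORY
        if tier_by_group:
            cluster.best_tier = min(
                (tier_by_group.get(g, Tier.NOT_OBSERVED) for g in cluster.member_groups),
                key=_TIER_RANK.__getitem__,
            )
    return clusters


def class_counts(clusters: list[HomologyCluster]) -> Counter:
    return Counter(c.cluster_class for c in clusters)


def jaccard_digest_matrix(
    proteomes: dict[str, list[str]],
    config: PipelineConfig,
    observed_peptides: set[str] | None = None,
) -> DistanceMatrix:
    """Jaccard distances between strain proteomes over tryptic peptide sets.

    Digestion uses zero missed cleavages and the configured minimum peptide
    length.  ``observed_peptides``, when given, restricts every strain's set
    to peptides actually observed in the build (the observed-pan-proteome
    variant of the comparison).
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two strains for a distance matrix")
    labels = list(proteomes)
    peptide_sets: dict[str, set[str]] = {}
    for strain, seqs in proteomes.items():
        peps = {
            pep
            for seq in seqs
            for pep, _ in digest(seq, 0, config.min_peptide_length, config.enzyme)
        }
        if observed_peptides is not None:
            peps &= observed_peptides
        if not peps:
            raise ValueError(f"strain {strain!r} yields an empty peptide set")
        peptide_sets[strain] = peps
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = peptide_sets[labels[i]], peptide_sets[labels[j]]
            jac = len(a & b) / len(a | b)
            dist[i, j] = dist[j, i] = 1.0 - jac
    return DistanceMatrix(dist, ids=labels)


def build_upgma_tree(matrix: DistanceMatrix) -> TreeNode:
    """UPGMA agglomeration of a distance matrix into an ultrametric tree.

    Average linkage on cluster sizes via scipy; node heights are half the
    merge distances, so every root-to-tip path has the same length.
    """
    labels = list(matrix.ids)
    if len(labels) < 2:
        raise ValueError("UPGMA requires at least two leaves")
    linkage = _scipy_average_linkage(squareform(matrix.data, checks=False))
    nodes: list[TreeNode] = [TreeNode(name=label) for label in labels]
    heights: list[float] = [0.0] * len(labels)
    for left, right, dist, _size in linkage:
        li, ri = int(left), int(right)
        height = dist / 2.0
        a, b = nodes[li], nodes[ri]
        a.length = height - heights[li]
        b.length = height - heights[ri]
        parent = TreeNode(children=[a, b])
        nodes.append(parent)
        heights.append(height)
    root = nodes[-1]
    root.length = None
    # collapse zero-length internal edges: co-clustering at equal heights is
    # a multifurcation, not an arbitrary binary resolution (a zero matrix
    # therefore yields a star tree)
    for node in list(root.postorder()):
        if node.is_tip() or node is root:
            continue
        if node.length == 0.0:
            parent = node.parent
            parent.remove(node)
            parent.extend(node.children)
    return root


def compare_to_known(
    canonical_sequences: list[str],
    known_sequences: list[str],
    threshold: float,
) -> tuple[list[str], list[str]]:
    """Partition canonical sequences into (new, previously_observed).

    A sequence is *new* iff its best identity against every known sequence
    is below the threshold.
    """
    if not canonical_sequences or not known_sequences:
        raise ValueError("both sequence lists must be non-empty")
    new: list[str] = []
    seen: list[str] = []
    for seq in canonical_sequences:
        if any(pairwise_identity(seq, known) >= threshold for known in known_sequences):
            seen.append(seq)
        else:
            new.append(seq)
    return new, seen


def upset_membership(clusters: list[HomologyCluster]) -> pd.DataFrame:
    """Strain-combination membership table (UpSet-plot input).

    One row per distinct strains_present combination, with the cluster count
    and the distribution of best evidence tiers, ordered by descending count.
    Non-strain clusters (no strain member) are excluded.
    """
    combos: dict[frozenset[str], list[HomologyCluster]] = defaultdict(list)
    for c in clusters:
        if c.strains_present:
            combos[c.strains_present].append(c)
    rows = []
    for strains, members in combos.items():
        tier_counts = Counter(c.best_tier for c in members if c.best_tier is not None)
        rows.append(
            {
                "strains": ";".join(sorted(strains)),
                "n_strains": len(strains),
                "n_clusters": len(members),
                "tier_counts": ";".join(
                    f"{t.value}:{n}" for t, n in sorted(
                        tier_counts.items(), key=lambda kv: _TIER_RANK[kv[0]])
                ),
            }
        )
    rows.sort(key=lambda r: (-r["n_clusters"], r["strains"]))
    return pd.DataFrame(rows, columns=["strains", "n_strains", "n_clusters", "tier_counts"])
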