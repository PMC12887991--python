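# Methods

This note documents the models and procedures implemented in `panatlas`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that affect results.

## Search space construction

All strain proteomes (plus optional phage and contaminant collections) are
concatenated and **deduplicated by exact sequence**: identical sequences
collapse into one *sequence group* whose strain set is the union of its
members and whose surviving accession is the first occurrence (when sources
differ, strain provenance outranks phage outranks contaminant; merged
accessions are retained). All downstream peptide mapping is at the level of
these groups, so a peptide shared only between identical cross-strain copies
still counts as uniquely mapping.

**Decoys** are generated one per target by shuffling the sequence while
keeping every K and R at its original position; the non-K/R residues are a
uniform random permutation of themselves (NumPy PCG64, seeded). Fixing K/R
preserves tryptic cleavage sites, hence the decoy peptide length and mass
distributions. The shuffle operates per protein (not per peptide) — the
literal reading of position-preserving shuffling; a peptide-level variant
would preserve peptide compositions exactly but is not implemented.

**Digestion** is classical trypsin: cleavage after K or R except before P,
up to a configurable number of missed cleavages (default 2), minimum
peptide length 7. An optional trypsin/LysC mode also cleaves K before P.
Digestion is delegated to `pyteomics.parser.icleave` with an explicit rule
regex; products carry 1-based start coordinates and are ordered by start,
then length. Semi-tryptic and non-tryptic peptides are handled by **exact
substring mapping** against the target sequences rather than enumeration —
identical results with bounded memory; the fully tryptic index is used as a
shortcut when it contains the query.

**Detectable peptides** (used to characterize unobserved proteins) are fully
tryptic, zero-missed-cleavage products of length ≥ 7 whose monoisotopic mass
falls in a configurable window, default **500–5000 Da** — a conventional
Orbitrap precursor range; the window is recorded in outputs. Peptides
containing X have no defined mass and are excluded.

## PSM filtering and merge

Open-search PSMs are filtered at **q ≤ 0.0005 per run** (inclusive
threshold). Closed-search PSMs are assumed pre-filtered upstream; an
optional q-value cut applies when configured. Site localization: a modified
PSM whose modification targets a residue occurring more than once in the
peptide is *positionally ambiguous* and is kept only when its localization
score is **strictly greater than 20**; unambiguous sites and unmodified PSMs
pass unconditionally, and ambiguous PSMs lacking a score are dropped with a
warning. Localization scores are consumed as an input column, never
computed.

The merge is keyed by (run, spectrum): both engines agreeing on the
peptidoform yields one record (`both_agree`); disagreement keeps the closed
record (`conflict_closed_kept`); single-engine spectra pass through. A
duplicate spectrum within one engine is an error — upstream must deliver
best-PSM-per-spectrum. The merge is idempotent and never exceeds the summed
input sizes.

## Protein inference

Tiers over target sequence groups, from aggregated peptide evidence:

| tier | rule |
|---|---|
| canonical | ≥ 2 uniquely mapping peptides |
| marginal | exactly 1 unique peptide, plus ≥ 1 peptide shared with a canonical |
| indistinguishable | observed, 0 unique, every peptide claimed by ≥ 1 canonical |
| uncertain | observed, none of the above |
| not_observed | no peptide evidence |

Groups with **identical observed peptide sets** can have no unique peptides
individually even when the set is jointly unambiguous. When at least two
peptides are confined to such a tie class, one member is promoted to
canonical — preferring a member of the designated core (reference) proteome,
then the lexicographically smallest accession — and the rest become
indistinguishable. A group with one unique peptide and no overlap with any
canonical is classified *uncertain*, not marginal (the narrower reading of
"distinguished from a canonical"); this case is visible in the tier table
via the unique/shared counts.

Decoy groups are tiered in a parallel pass in which decoy peptides are
mapped among decoy sequences only, so decoys never influence target tiers.
The **protein FDR** is the plain ratio of decoy to target groups at tier
canonical or marginal — a simple decoy-count estimator without
finite-database (hypergeometric) correction, and labelled as such in the
report.

## Pan-proteome structure

**Pairwise identity** is computed from a global alignment (match +1,
mismatch 0, gap open −5, gap extend −1; Biopython `PairwiseAligner`) as
identical aligned residues divided by the length of the shorter sequence —
the convention of common greedy clustering tools, which makes a contained
fragment 100% identical to its parent. Among co-optimal alignments the
maximal identity count is used (deterministic tie-breaking; verified against
an independent Gotoh DP in the test suite).

**Clustering** is greedy incremental: sequences sorted longest-first (ties
by accession) either join the first cluster whose representative they match
at ≥ the threshold (default 0.70) or found a new cluster. A k-mer
containment prefilter is available as a pure optimization and is asserted in
tests not to change results. Clusters are classed by their strain sets:
**core** (every strain), **accessory** (≥ 2 but not all), **orphan** (exactly
one); phage/contaminant members carry no strain and pure non-strain clusters
are reported separately.

**Proteome distances** are 1 − Jaccard over fully tryptic peptide sets
(0 missed cleavages, length ≥ 7 — recorded in output metadata); an optional
restriction to the observed peptide set reproduces the observed-pan-proteome
variant. The proteome tree is **UPGMA** (scipy average linkage; node height
= half the merge distance, hence ultrametric to 1e-9). Zero-length internal
edges are collapsed into multifurcations, so an all-zero matrix yields a
star tree. Whether the original resource used UPGMA or another agglomeration
is not documented; UPGMA is this package's default and only method.

## PTM analysis

Modified PSMs are remapped to **canonical proteins only**: a PSM
contributes sites only when its bare peptide maps to exactly one canonical
group; position = peptide start + offset − 1 (first occurrence of the
peptide in the protein; N-terminal modifications are assigned to residue 1
of the peptide). Events are aggregated by (protein, position, modification)
with PSM support summed and runs unioned. A **site** is a distinct triple;
an **event observation** is one modified PSM — both tallies are reported
since summaries commonly mix the two vocabularies.

Unimod classes come from a small editable TSV shipped with the package;
names listed under more than one class are grouped as "Other", unmapped
names as "Unclassified".

The **phospho FLR** uses the decoy-amino-acid device: with alanine unable
to carry phosphate, `FLR = (N_pA / f_A) / (N_pSTY / f_STY)` where the f's
are residue frequencies over canonical proteins. Counts default to
PSM-support weighting (observation counts): distinct-site counting is
biased upward at high sampling depth because repeated mislocalized
placements on S/T/Y merge into already-reported correct sites while every
alanine placement opens a new site. The estimator targets the fraction of
*reported S/T/Y phospho observations* that are mislocalized — not the raw
per-event mislocalization probability; for mislocalization landing
uniformly on peptide residues at rate r, the two are related by
`FLR = r·f_STY / ((1−r) + r·f_STY)`.

**NSAF** per (protein, run) is (uniquely mapping PSM count / protein
length) / total PSMs in the run, with all merged PSMs of the run in the
denominator (uniqueness is not required of denominator PSMs). Shared-peptide
PSMs count for no protein. The abundance/modification relation is the
Spearman correlation between per-protein mean NSAF and distinct site count
(reported as 0 when either variable is constant, omitted below 3 proteins).

## Physicochemical characterization

Residue masses ship in `data/aa_masses.tsv` — monoisotopic values for
peptide-level work (cross-checked in tests against pyteomics), standard
average residue masses for conventional protein molecular weight. The
isoelectric point solves net charge = 0 under the Henderson–Hasselbalch
model over the termini and D, E, C, Y, H, K, R side chains with the EMBOSS
pKa set (`data/pka.tsv`), by bisection on [0, 14] to 1e-4 (net charge is
strictly decreasing in pH, so the root is unique). pI values are
pKa-table-dependent; a different table shifts absolute values, which is why
only structural properties (monotonicity, grid-scan agreement) are asserted.
Sequences containing X get masses over X-free positions and are flagged;
strict `molecular_weight` raises on X unless the permissive flag is set.

## Synthetic data

The generator plants protein families — core in all strains, accessory in a
sampled subset of ≥ 2, orphan in one — with orthologs derived from a family
ancestor by i.i.d. substitutions (targets uniform over the 20 residues, so
5% divergence gives ≈ 95.25% expected identity); sequences are uniform over
the residue alphabet with a K/R floor of 8% so digestion always yields
peptides. PSMs are sampled per run from proteins with log-normal abundance
(default μ = 0, σ = 1) and uniform peptides from a one-missed-cleavage
digest; both engines observe overlapping spectrum sets with configurable
overlap and conflict rates; per-run acquired-spectrum totals are set so the
identification rate matches a configurable target (default 42.8%, the
median of the published build). Modifications are planted per PSM at
per-name rates on their eligible residues; phosphorylations mislocalize at
a configurable rate onto a uniformly random peptide residue, which is what
gives the alanine decoy channel its signal. False PSMs draw peptides from
decoy sequences at a spectrum-level rate, and false *proteins* are planted
by independently activating each decoy with a configurable probability
(activated decoys emit two distinct peptides, enough for the canonical
tier) — making the decoy/target ratio a binomial estimator of that planted
rate. A guaranteed-coverage mode emits a fixed number of distinct peptides
per target, emulating deep fractionated coverage.

What the generator does **not** emulate: real spectra and search-engine
score distributions (q-values are drawn uniformly below threshold, not
derived from spectra), retention time, fragmentation, shared-peptide
homology between unrelated families, heteroscedastic abundance across runs,
or batch effects. Passing tests therefore demonstrate the correctness of
the bookkeeping, estimators and rules under controlled conditions — not
end-to-end performance on real reprocessing output.

## Verification design

Each estimator or rule with a closed-form or enumerable reference is tested
against an independent implementation: tier assignment against a direct
rule transcription over peptide–protein incidence maps (exhaustive up to
3 groups × 5 peptides and 4 groups × 4 peptides, plus 2000 seeded random
structures at 5 × 6 — full exhaustion at 5 × 6 would be ≈ 9·10⁸ graphs);
pairwise identity against a Gotoh affine-gap DP; greedy clustering against
an all-pairs re-derivation; pI bisection against a 1e-4 grid scan;
detectable-peptide counts against a naive cut-site digest-and-filter;
decoy validity against brute-force enumeration of K/R-preserving
permutations on short sequences. Parameter-recovery checks run the full
pipeline on synthetic data and compare estimates to planted rates within
three binomial standard errors. Problem sizes (n = 1000 proteins for FDR
recovery, 10,000 spectra for the merge conflict rate, 100 proteins for the
NSAF correlation) were chosen to make three standard errors a tight band
while keeping the default suite fast.

## Known limitations

* Protein FDR has no finite-database correction; at very small database
  sizes the plain ratio is noisy and conservative bounds are not computed.
* Greedy clustering is order-dependent in principle; longest-first ordering
  makes it deterministic, and the all-pairs oracle bounds the discrepancy
  on well-separated instances, but adversarial borderline-identity inputs
  can split or merge clusters relative to exhaustive methods.
* Modification positions use the first occurrence of a peptide within a
  protein; repeated exact peptide occurrences within one protein are rare
  but would be assigned to the first copy.
* The peptidoform bracket dialect is a repository convention; upstream
  engine outputs must be converted to it.
* pI and molecular weight depend on the shipped constant tables; outputs
  record which tables were used.
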