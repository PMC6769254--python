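# Methods

## The classification model

`cuproscan` treats a proteome as a set of proteins, each carrying an ordered
string of profile-HMM domain matches (N- to C-terminus by alignment start),
plus an ordinal locus index along the replicon. Classification maps each
protein — or small group of adjacent proteins — to at most one of 31
copper-related types defined in a declarative signature catalog. The model
assumes that (i) domain content plus domain order is sufficient to identify
the cuproprotein families concerned, (ii) subunits of a multi-subunit complex
are encoded close together (operon-like), and (iii) substrate specificity of
P-type ATPases and RND transporters is not decidable from domains alone and
requires similarity to a labeled transporter reference.

### Matching rules and their precedence

Stages run in a fixed order; a protein consumed by an earlier stage is
invisible to later ones (single assignment):

1. **Complexes.** cbb3-type cytochrome C oxidases first, because their FixO
   subunit is diagnostic; then COX1+COX2 pairs, resolved to cytochrome bo
   (CyoB flag) or aa3-type oxidase (QoxB flag), with an optional per-protein
   override that excludes QoxB-flagged nitric oxide reductases; then
   split-subunit architecture patterns (two-chain nitrite reductases before
   two-chain multicopper oxidases, catalog order). Subunits pair greedily
   left-to-right along the replicon, each anchor with its nearest free
   partner within the locus window (default 5 ORFs, strand-agnostic,
   `--complex-window`). Complexes count once per occurrence; per-subunit
   counting is available in `build_profile`.
2. **Per-protein architectures.** A pattern matches when its elements occur
   as an ordered, not necessarily contiguous, subsequence of the protein's
   domain string; the longest matching pattern across all architecture types
   wins, ties broken by catalog order. Subsequence (rather than exact
   contiguous) matching tolerates accessory domains such as extra
   cupredoxin repeats.
3. **Transporter disambiguation.** E1-E2_ATPases or ACR_tran carriers are
   compared against a labeled reference; only hits with effectively zero
   E-value qualify (`evalue <= 1e-180`, since similarity tools print
   underflow as 0.0; configurable). Copper-resistance ATPases require a
   qualifying `3.A.3.5` hit not outscored by a `3.A.3.27`
   (cuproenzyme-biogenesis) hit; RND transporters require `2.A.6.1`.
   Candidates are consumed whatever the verdict, so the N-terminal HMA
   domain of an excluded ATPase is not re-counted as a free chaperone.
4. **Copper-storage proteins.** DUF326/CSP carriers split by compartment:
   a twin-arginine (Tat) export signal in the first 35 residues marks the
   extracytoplasmic group. Detection uses the consensus motif
   `[ST]RR.[FGAVML][LITMVF]`, a transparent surrogate for signal-peptide
   predictors; motif, window and every decision are configurable and
   audited. Missing sequences fall back to cytoplasmic with an audit
   warning.
5. **Single-domain types**, in catalog order.

Two deliberate guards go beyond the rule list. First, a protein that matches
a same-protein architecture pattern on its own is not available as a
split-complex subunit; otherwise two adjacent single-chain multicopper
oxidases would be mis-joined into one two-chain complex. Second, overlapping
hits of the same domain collapse to a greedy best-scoring non-overlapping
set before any matching, so fragmented reporting of one domain cannot
double-count.

### Things the classifier does not do

It never runs hmmsearch/BLAST or signal-peptide predictors; it consumes
their tabular outputs. Metal-sensing regulators (two-component sensors, MerR
family) are outside the catalog. Unresolved COX1+COX2 pairs and excluded
transporters go to an audit channel, not to the 31-type profile.

## Profiles and statistics

`curp_percent = 100 · curp_count / proteome_size`, where `curp_count` counts
classified proteins and complexes (complexes once). Category shares divide
by `curp_count` and are all defined as 0 for species with none. Two
accounting modes exist because dual-membership types make the convention
material: **dual** (default) counts multicopper oxidases in both the
cuproprotein and homeostasis shares and cytoplasmic storage proteins in both
homeostasis and chaperone shares, so shares may sum above 100; **exclusive**
assigns each type only to its catalog section, so shares sum to exactly 100.
Group medians use the standard convention (mean of the two middle values for
even group sizes). Ingestion applies a per-domain inclusion filter
(independent E-value ≤ 1e-5 by default, logged) as an explicit, reproducible
surrogate for unstated upstream curation.

## Clustering

Species (or protein types) are clustered agglomeratively under the
uncentered-correlation distance `1 − Σx_i y_i/(‖x‖‖y‖)`; an all-zero vector
yields r = 0 with a warning. For species clustering, each type column is
median-centered and scaled by its median absolute deviation (columns with
MAD = 0 are centered but not scaled); type co-occurrence clustering skips
centering, since shared presence/absence structure is the signal there.
Linkage defaults to average (UPGMA) and is configurable (complete, single,
centroid via Lance–Williams). Exact distance ties break on the
lexicographically smallest pair of cluster indices — required for
cross-platform determinism. The agglomeration is written directly (O(n³),
small n) and is cross-checked in the test suite against both a
from-definition reference and scipy's implementation on tie-free inputs.
Newick export places each internal node at half its merge height (midpoint
convention), so leaf-to-leaf path length between the two children of a node
equals that node's merge height.

The homeostasis clustering subset comprises the 10 types whose categories
include homeostasis (the 9 homeostasis-section types plus multicopper
oxidases); the full subset uses all 31.

## Synthetic data

The generator emulates a multi-species domain-annotation study: one
archetype per lifestyle code (E, OE, AP, PP, OC, C, S, EnP, EnS), each with
a Gaussian proteome-size distribution and a Poisson rate per type. Planted
proteins instantiate a uniformly chosen pattern of their type; split-complex
subunits sit at adjacent loci and planted instances are separated by at
least 12 loci so that they cannot invade each other's complex windows. Decoy
proteins carry domains disjoint from the catalog (so zero-noise recovery is
exact by construction), and one decoy biogenesis ATPase per species
exercises the transporter exclusion path. Copper-storage proteins get real
amino-acid sequences: Tat-positive ones embed the motif within the search
window; negatives contain no arginine in their first 35 residues.

Default rates are fixed a priori to the study conditions the pipeline
targets: environmental archetypes have a total copper-related expectation
near 0.7% of their proteome with roughly a third of it in each functional
category, host-associated archetypes progressively shed homeostasis systems
(E ≥ AP ≥ EnS in summed homeostasis rates), and endosymbionts retain little
beyond respiratory cuproproteins on proteomes an order of magnitude smaller.
Counts are Poisson (no overdispersion); lifestyles within an archetype are
exchangeable; there is no phylogenetic autocorrelation, horizontal transfer,
pseudogenization or annotation bias. Passing recovery tests on these data
therefore demonstrates the correctness of the classification logic, not the
accuracy of any upstream annotation on real proteomes.

Noise: each planted domain hit is dropped with probability `p_drop`, using
one latent uniform per hit drawn from a noise-only stream, so dropout sets
are nested across noise levels (raising `p_drop` can only remove hits —
this makes the "dropout never gains complexes" property testable per seed
rather than only in expectation). Spurious hits are added at a per-species
Poisson rate with domains drawn from the full vocabulary. Identical seed
and configuration reproduce the dataset byte for byte.

## Numerical and degenerate-input conventions

* Coordinates are 1-based inclusive throughout (profile-HMM convention).
* Correlation values are clipped to [−1, 1] against floating-point drift.
* `proteome_size = 0` is an error for statistics; zero copper proteins is
  not (all shares 0).
* Empty domain tables parse to empty lists; malformed rows are fatal with
  their line numbers (nothing is silently dropped).
* Locus indices default to file order when the input table has none.

## Known limitations

* The Tat motif is a heuristic; borderline signal peptides on real
  sequences will be misassigned compared to dedicated predictors.
* The locus-window complex assembler is strand-agnostic and cannot
  distinguish two interleaved operons closer than the window.
* Transporter verdicts are only as good as the reference label map; absent
  similarity data, all transporter candidates are audited as unclassified
  and excluded from profiles.
* Centroid linkage via Lance–Williams assumes squared-Euclidean geometry
  and is heuristic under correlation distances; it is provided for parity
  with common clustering tools, not as the default.
* The catalog ships one accession per domain name; genuinely new copper
  domain families require a user catalog file, which the loader validates
  with the same invariants.
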