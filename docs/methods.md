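# Methods

## The reconciliation model

`hgtrecon` infers candidate HGT events as the transfer labels of a
minimum-cost embedding of each gene tree into a rooted binary species
tree under the *undated* DTL parsimony model. Each internal gene node is
assigned one event:

- **speciation** (cost 0): its two child lineages separate into the two
  child subtrees of the species node it maps to;
- **duplication** (cost *D*, default 2): both child lineages stay in the
  subtree of the mapped node;
- **transfer** (cost *T*, default 3): one child stays, the other jumps to
  any species node *incomparable* to the donor (neither ancestor nor
  descendant). No global time consistency is imposed across transfers —
  the undated model; enforcing consistency is NP-hard and the undated
  relaxation is the standard large-scale choice.

Losses (cost *L*, default 1) are charged implicitly, one per species edge
a gene lineage skips; they are counted during backtracking but never
materialized as nodes. The defaults D=2, T=3, L=1 are the common
parsimony setting for prokaryotic datasets; all three are exposed on
`DTLCosts`.

The dynamic program fills, for each gene node *g* in postorder, three
arrays over species nodes *s*:
`C(g,s)` (cost with *g* mapped exactly to *s*), `IN(g,s)` (minimum of
`C(g,s')` over *s'* at or below *s*, plus one loss per skipped edge), and
`OUT(g,s)` (minimum of `C(g,s')` over *s'* incomparable to *s*). The
recurrence in the module docstring of `reconcile.py` follows. Complexity
is O(|G|·|S|) per rooting with numpy-vectorized species dimensions; the
incomparability mask is precomputed once per species tree.

**Unrooted gene trees.** Single-gene trees carry no reliable root, so the
DP is run for a rooting on every edge (2n−3 for n leaves) and one rooting
is drawn uniformly among the cost-minimal set under a caller-supplied
seed. The minimum cost itself is seed-invariant; only tie-breaking among
co-optimal rootings is randomized, mirroring how large-scale
reconciliation pipelines resolve rooting ambiguity.

**Determinism among co-optimal labelings.** For a fixed rooting the
backtrack prefers speciation over duplication over transfer at equal
cost, resolves `IN` chains top-down preferring the shallower stop, and
takes the lowest-index species node among tied transfer recipients.
Event counts are known to be largely conserved across co-optimal DTL
reconciliations, so a deterministic representative is adequate and makes
runs reproducible.

**Validation.** The DP is checked against an independent brute-force
oracle (exhaustive enumeration of every internal-node mapping with
explicit event admissibility and loss counting, `tests/dtl_oracle.py`)
for random gene/species pairs up to 6 leaves, rooted and over all
rootings, for default and non-default costs, plus invariants: cost 0 iff
the gene tree is the homeomorphic restriction of the (pruned) species
tree; transfer-cost monotonicity with a duplication-loss-only limit; and
donor/recipient incomparability of every reported transfer.

## Pipeline semantics

Families ("gene sets", single-copy putative orthologs) pass four filters
before reconciliation: at least 4 genomes (a tree needs four taxa);
more than one species (single-species families produce no species-tree
signal); optionally, removal of families spanning >50% of all genomes
(`keep_large=False`; kept by default); and removal of families whose
alignment has all pairwise p-distances below `eps` (default 1e-6 — the
filter's purpose is to drop zero-divergence families, so any tiny
threshold serves; there is no natural data-derived value).

The species tree is pruned to each family's taxa before reconciliation,
so each gene tree is compared against exactly the evidence it carries.
Consequently internal-node body-site sets (for niche classification) are
unions over the family's extant genomes, not the full species tree.

Classification: a transfer is *one-to-one* / *one-to-many* /
*many-to-many* by whether donor and recipient are species-tree leaves
(many-to-one is folded into one-to-many); *intra-niche* iff all extant
genomes descending from donor or recipient occupy a single body site.
Per-site tallies book intra events once (split by family scope,
unique/mixed) and inter events once per involved site — so the inter
column sums to more than the unduplicated inter total, which is reported
separately. Two-site tables are restricted to families whose genomes span
exactly two sites and satisfy total = intra + inter per pair by
construction.

Statistics: the gene HGT-index is events/taxa (unbounded above in
principle, small in practice); the genome HGT-index counts a gene as
participating when the genome descends from a donor or recipient endpoint
of at least one event in that family — the stricter of the two plausible
participation rules (mere membership in an HGT-positive family would
inflate indices; both are available, event involvement is the default).
FTG selection takes the top decile by gene HGT-index using the
nearest-rank rule (k = ⌊n/10⌋ values, minimum one, boundary ties
included — with 10 distinct values exactly the maximum is selected). RTG
selection first drops families with <5 events, <5 genera or <10 genomes,
then ranks by one-to-one ratio and keeps the top decile. Widespread
(presence strictly >70% of a site's or site-combination's genomes), core
(widespread over all genomes pooled), and marker rules (presence >90% of
all genomes, gene HGT-index <0.2) use strict inequalities throughout.
Group comparisons delegate to scipy (Mann–Whitney U, Welch's t);
representative-protein selection uses the lower median length with
lexicographic tie-breaks so it is order-invariant.

Residence screening consumes FastANI-style output: directions are
collapsed to unordered pairs by taking the maximum identity,
self-comparisons are dropped (positive controls only), same-site and
(by default) cross-genus pairs are excluded, and pairs above 95% / 99.9%
identity are binned as species- / strain-level multi-residents; the
species-level pair graph's connected components are the species networks
(GraphML/edge-list export via networkx).

Enrichment is the upper-tail hypergeometric test per term against a
background universe, zero-overlap terms reported at p = 1 so FDR ranks
are stable, with Benjamini–Hochberg adjustment
(`scipy.stats.false_discovery_control`). Annotations are not propagated
up any term hierarchy.

## The simulator

`simulate_species_tree` draws a birth–death time tree conditioned on the
requested number of extant genomes (dendropy's sampler; defaults birth
1.0, death 0.2 per lineage per unit time — a mild-extinction regime that
produces realistic branch-length heterogeneity). Body sites evolve along
branches by Poisson switching (default rate 0.3 per unit time over up to
six HMP-style site names), giving phylogenetically clustered niches at
low rates and scrambled niches at high rates. Synthetic taxonomy
(phylum/genus/species) is defined by clade membership at fixed depth
fractions (0.15/0.5/0.85 of the root age), which suffices for the
genus-based statistics and the cross-genus ANI exclusion.

`simulate_gene_family` runs a birth–death-transfer process down the
species tree: per gene lineage, duplication (δ), loss (λ) and transfer
(τ) compete as exponential clocks per unit branch length; a transfer
copies the lineage onto a uniformly chosen branch alive at that instant
(contemporaneity is enforced in simulation even though the undated
reconciler does not require it). Transfers are additive — the recipient
keeps its resident copy — and families are afterwards reduced to
single-copy form by keeping one uniformly chosen copy per genome,
recorded in the truth log, to match the pipeline's single-copy ortholog
assumption. Default per-family rates (δ=0.1, τ=0.3, λ=0.1 per unit
branch length) yield a mix of clean families and families with a handful
of events on a 20-leaf tree, comparable to small real ortholog sets.
Families with fewer than 4 surviving genomes are flagged (they fail the
pipeline's minimum-taxa filter). Sequence evolution is out of scope;
distance-based tests use path-length (patristic) matrices.

**What the simulator does not emulate:** alignment and gene-tree
estimation error (gene trees are the true simulated topologies),
rate heterogeneity across sites and lineages, replacing transfers,
within-species recombination, and incomplete taxon sampling. Passing
recovery tests therefore demonstrate correctness of the reconciliation
and classification machinery under the model's own assumptions, not
robustness to tree-estimation noise in real data.

**Recovery benchmarking convention.** Because down-sampling can remove
every descendant of a transferred lineage, each planted transfer is
marked *observable* or not after sampling, and recovery is scored against
observable transfers. A second identifiability limit is direction: with
no losses, the recipient's displaced resident copy leaves no sampled
descendant, and an unrooted undated reconciliation then has two
cost-equal orientations for a transfer adjacent to the gene root. The
benchmark (`transfer_recovery_benchmark`) therefore requires every
recovered event to match a planted transfer's endpoints up to that
direction swap, and reports the strictly direction-faithful rate
separately (~97% under the default conditions: 200 families, 20 genomes,
expected 0.5 transfers per family).

## Numerical choices and degenerate inputs

- Cost comparisons in the backtrack use an absolute tolerance of 1e-9;
  with the default integer costs all optima are exact.
- NJ Q-matrix ties break at the lowest (row, column) pair after
  lexicographic taxon ordering; negative branch-length estimates are
  clamped to zero with a warning.
- Polytomies are resolved deterministically into caterpillars of
  zero-length edges, children ordered by sorted leaf-label sets; an
  unrooted tree keeps its basal trifurcation.
- p-distance pairs with no comparable columns get distance 1 and are
  flagged in `attrs["undefined_pairs"]`.
- Ratios are kept at full precision internally and rounded only in
  reports (two decimals, matching the usual presentation).
- Per-family reconciliation seeds are spawned from the pipeline seed via
  `numpy.random.SeedSequence`, so runs are reproducible end to end and
  independent of family iteration order.

## Problem sizes

Test and benchmark sizes were chosen as the smallest that exercise each
property with comfortable statistical margin: exhaustive DP-vs-oracle
checks up to 6 leaves (the oracle enumerates |S|^|G| mappings), recovery
on 200 families over 20-genome trees at an expected 0.5 transfers per
family, Monte-Carlo rate calibration on 400 families, and null
enrichment calibration with a 2,000-family universe, 400-family terms and
200-family foregrounds over 1,000 replicates (sizes picked so the
discrete p-value lattice is fine relative to its ~0.19-sd spacing).

## Known limitations

- The undated model can produce time-inconsistent multi-transfer
  scenarios; the simulator is time-consistent but the reconciler does not
  check this.
- Only one co-optimal reconciliation is reported per family (a
  deterministic representative; rooting ties are seed-randomized).
- Transfers between strains of one species are invisible by construction
  (single-species families are filtered; no species-tree conflict).
- The genome HGT-index depends on annotation completeness of the family
  table; genomes absent from all families get index 0.
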