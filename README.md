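# hgtrecon

Phylogeny-based detection and characterization of horizontal gene transfer
(HGT) in collections of microbial genomes, built for host-associated
datasets where each genome carries a habitat label (a human body site such
as the GI tract, oral cavity, skin, airways, blood, or urogenital tract).

Sequence-similarity screens only see recent transfers; topological
conflict between a gene tree and the species tree persists over much
longer timescales. `hgtrecon` detects that conflict by **undated
duplication–transfer–loss (DTL) parsimony reconciliation**: every internal
node of a gene tree *G* is embedded into the rooted species tree *S* and
labeled speciation, duplication (cost *D* = 2), or transfer (cost *T* = 3,
allowed between any two species-tree nodes that are not
ancestor–descendant), with a loss cost (*L* = 1) per skipped species edge.
The minimum-cost embedding

&nbsp;&nbsp;&nbsp;&nbsp;cost(G, S) = min over embeddings of ( 2·#dup + 3·#transfer + 1·#loss )

is found by dynamic programming over (gene node, species node) pairs.
Unrooted gene trees are reconciled under every possible rooting (one per
edge); a root is drawn uniformly, under a caller seed, among rootings of
minimal cost. Each transfer-labeled node yields a donor and recipient
species node, which are then classified by

- **cardinality** — *one-to-one* (both endpoints extant genomes),
  *one-to-many* (one endpoint ancestral), *many-to-many* (both ancestral);
- **niche** — *intra-niche* (all endpoint descendant genomes share one
  body site) vs *inter-niche*.

On top of the event table the package computes the field's standard
summary statistics: the **gene HGT-index** (events on a gene tree / taxa
in that tree), the **genome HGT-index** (fraction of a genome's genes
participating in transfers), per-family **HGT-ratios** by cardinality
class, PS/PD × SH/DH strata (same/different genus × same/different
habitat), transfer-pair protein identity, frequently/recently transferred
gene selection (FTG/RTG), widespread/core genes and low-HGT phylogenetic
marker candidates, ANI-based multi-residence screening with species
networks, and hypergeometric term enrichment with BH-FDR control.

A built-in simulator generates complete ground-truthed inputs — a
birth–death species tree with body sites evolving along branches, and gene
families evolved under explicit duplication/transfer/loss rates with a
planted-event truth log — so the whole pipeline is testable without any
external data.

## Worked example

```python
from hgtrecon import HGTAnalysis, SimulationConfig, simulate_dataset

cfg = SimulationConfig(n_leaves=20, n_families=50, seed=42)
ds = simulate_dataset(cfg)                  # species tree + families + truth
res = HGTAnalysis.from_dataset(ds).fit(seed=0)
print(res.summary())
```

```
HGT detection summary
======================================================
genomes                        20
phyla / genera / species     2 / 6 / 14
gene sets (input/analyzed)    49 / 49
HGT-genes                      47
HGT events                    317
HGT-genes per genome            2.35
events per HGT-gene             6.74
intra-niche events            105 (33%)
inter-niche events            212
median genome HGT-index        0.81

Per-site tally (a: intra/unique, b: intra/mixed, c=a+b,
                d: inter involving site, e=d/c):
           a   b   c    d     e
body_site
GI_tract   0  84  84  185  2.20
airways    0   0   0   33   NaN
oral       0  21  21  173  8.24
skin       0   0   0   68   NaN
```

Reading the output: of 50 simulated families one went extinct; 47 of the
49 surviving families show reconciliation conflict attributable to
transfer ("HGT-genes"), carrying 317 transfer events in total. A third of
the events are intra-niche (both endpoints' descendant genomes share a
body site). The per-site table books intra events once for their site
(split by whether the family is unique to that site or mixed) and inter
events once for *every* site they involve, so column *d* sums to more than
the inter total. `res.ftg()`, `res.rtg()`, `res.markers()`,
`res.pair_tally()` and `res.strata_summary()` expose the gene selections
and the remaining tables; `res.save(outdir)` writes everything as TSV plus
a run manifest.

The same pipeline runs from the shell:

```bash
hgtrecon simulate --out data --seed 42 --n-leaves 20 --n-families 50
hgtrecon run --data data --out results --seed 0
hgtrecon reconcile --species st.nwk --gene gt.nwk --dup 2 --transfer 3 --loss 1
```

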