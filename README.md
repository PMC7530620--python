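# ohnoscope

Whole-genome duplications (WGDs) leave a characteristic footprint: sets
of chromosomes — *paralogons* — linked by many small paralog families,
even where the gene you care about has been lost (a *ghost locus*).
`ohnoscope` is a toolkit for reading that footprint in a duplicated gene
family's neighborhood, built around the chordate myogenic regulatory
factor (MRF) case: an independent five-gene tandem cluster in amphioxus,
a two-gene pre-2R vertebrate ancestor whose 2R ohnologs were pared back
to four genes in three loci plus a ghost locus in human, and further
3R/4R expansions in teleosts and salmonids (nine genes in salmon).

It is aimed at comparative genomicists who want the full inference chain
— orthology, synteny statistics, paralogon detection, gene trees,
reconciliation — as tested, scriptable pieces, with a genome-evolution
simulator supplying ground truth so every step can be validated without
downloading a single genome.

## What's inside

* **Simulator** (`ohnoscope.simulate`, `ohnoscope.presets`): scripted or
  stochastic histories of tandem duplication, WGD with per-copy
  retention, loss, rearrangement, and exon-restricted gene conversion;
  emits gene tables, proteomes, true gene trees, and the
  ortholog/ohnolog/tandem-paralog relation set.
* **Orthology** (`ohnoscope.orthology`): reciprocal best hits (RBH) with
  a built-in symmetric scorer or external blast-tabular files; rank
  depth 2 for post-WGD co-orthologs.
* **Enrichment** (`ohnoscope.enrichment`): per-chromosome ortholog
  enrichment. For a chromosome with `c` of `d` genes carrying `a` of `b`
  orthologs it reports the binomial tails P(X > a) and P(X ≥ a) for
  X ~ Bin(b, c/d), Barnard's one-sided unconditional exact test on the
  2×2 table [[a, b−a], [c−a, (d−c)−(b−a)]] (pooled-variance Wald z,
  nuisance maximized over a 0.001 grid), and the Fisher/hypergeometric
  tail as the conditional benchmark.
* **Paralogons** (`ohnoscope.paralogon`): the ≤ 4-member shared-family
  filter, binomial ghost-locus ranking, and greedy k-fold paralogon
  detection (k = 2, 4, 8).
* **Phylogenetics** (`ohnoscope.phylo`): p / Poisson / gamma-corrected
  protein distances (shape α = 0.77 default, pairwise deletion),
  Saitou–Nei neighbor joining with deterministic tie-breaks, bootstrap
  supports, per-exon partition trees, Robinson–Foulds split distance.
* **Reconciliation** (`ohnoscope.reconcile`): LCA gene-tree/species-tree
  mapping with duplication/loss counts, a classifier for the timing of
  the early/late tandem duplication (vertebrate stem, Olfactores stem,
  chordate stem, or undetermined), and a lineage-expansion independence
  test.

## Worked example

Run the demo pipeline on the two-species 2R preset (an amphioxus-like
genome versus a vertebrate-like genome whose focal gene was deleted from
one of the four 2R chromosomes):

```sh
ohnoscope demo --preset ghost_2R --seed 1 --out demo_out
```

prints (abridged):

```
## Focal gene counts
- Amphioxus: 5
- Vertebrate: 3

## Ortholog enrichment (top chromosomes)
- chrM_a_a: a=9/25, Barnard p=5.58e-04
- chrM_b_a: a=7/25, Barnard p=1.81e-03
- chrM_b_b: a=5/25, Barnard p=4.78e-02
- chrM_a_b: a=4/25, Barnard p=1.25e-01

## Ghost locus: top candidate chrM_b_b
```

Reading it: the amphioxus lineage expanded its focal gene to a five-gene
tandem cluster while the vertebrate lineage kept three of four 2R
copies. All 25 mapped orthologs of the amphioxus focal-scaffold genes
land on the four chromosomes descended from the ancestral focal
chromosome (`chrM_*`), the strongest two with Barnard p < 2 × 10⁻³,
while unrelated chromosomes sit at p = 1. The ghost scorer then ranks
`chrM_b_b` — the chromosome that *lost* the focal gene but kept its
neighbors — as the top ghost-locus candidate, which matches the
simulation's scripted truth. `demo_out/` holds the per-stage TSV/FASTA/
newick files plus `report.md`.

The same stages are available piecewise (`ohnoscope simulate | rbh |
enrich | ghost | nj | reconcile`) and as library calls; see
`docs/methods.md` for the models and defaults.

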