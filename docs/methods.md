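# Methods

`ohnoscope` studies the genomic footprint that gene duplication — tandem
duplication (TD) and whole-genome duplication (WGD) — leaves in gene
neighborhoods, with the chordate myogenic-regulatory-factor (MRF) story
as its built-in case study: a five-gene tandem cluster in amphioxus, a
two-gene pre-2R vertebrate ancestor, post-2R losses leaving three
occupied loci and one ghost locus, and further 3R/4R expansions in
teleosts and salmonids. This note records the models, the defaults, and
the reasoning behind the genuinely open design choices.

## The genome-evolution simulator

The simulator replays an explicit event script down a labeled species
tree. A genome is an ordered list of chromosomes, each an ordered list
of gene slots (gene id, family, strand, protein sequence). Events fire
on a branch at a fractional position `at` in [0, 1]:

* `tandem_duplication` inserts the copy immediately downstream of the
  template on the same strand — tandem copies therefore form contiguous
  clusters, as observed in real MRF loci.
* `wgd(name, retention_prob, protect, retain_at_least_one)` doubles
  every chromosome (suffixing `_a`/`_b`) and every gene (the `_b` copy
  is suffixed `-name`, giving traceable ohnolog bookkeeping). Each
  unprotected copy survives with probability `retention_prob`; a family
  is never driven extinct when `retain_at_least_one` is on. Focal genes
  are placed on the `protect` list and lost only through scripted
  `loss` events, so preset gene counts are deterministic while the
  background is stochastic.
* `loss` removes a named gene, or every member of a family (optionally
  on one chromosome).
* `inversion`, `translocation`, `fission`, `fusion` rearrange slots and
  preserve the gene multiset (a tested invariant).
* `gene_conversion(donor, acceptor, start, end)` overwrites the
  acceptor's segment with the donor's current residues. Its default
  position is the branch **end** (`at = 1.0`), after that branch's
  substitutions, so a converted segment is exactly identical at the
  tip — the strongest version of the homogenization signature.

**Sequences.** Proteins are fixed-length (default L = 200), gap-free,
and evolve by Poisson substitution: a branch segment of length *t*
draws Poisson(rate × t × L) events, each replacing a uniformly chosen
site by one of the 19 alternative residues. There are no indels, so
families stay trivially aligned and no alignment step is needed; there
is no empirical exchangeability matrix, because distance/topology
recovery only requires additivity in expectation. The default rate is
0.3 substitutions/site per unit branch length — with the preset branch
lengths this keeps ortholog p-distances in the 0.2–0.6 range, far from
the 0.95 saturation guard but diverged enough that cross-family scores
are background noise.

**Randomness.** Every stochastic draw comes from a stream keyed by
`(seed, crc32(branch label))`, so a replay is bit-identical and adding
a lineage never changes another lineage's history. The event log, the
per-family true gene tree (duplication nodes tagged), and the pairwise
relation set (ortholog = coalescence at a speciation, ohnolog = at a
WGD node, tandem-paralog = at a TD node) are recorded as ground truth.

**Presets.** `fig2_chordate` encodes the full chordate scenario:
four successive TDs spread along the cephalochordate stem (`at` = 0.1,
0.3, 0.5, 0.7 — spreading them gives the cluster internal phylogenetic
structure; firing them all at the branch base would leave the paralogs
star-like, which is also why the analogous deep clade is weakly
supported in real data); an early/late TD on the Olfactores stem (the
timing the data leave open — `td_branch="vertebrate"` switches it); 2R
on the vertebrate stem with the loss pattern that leaves early+late,
early+late, late-only, and empty (ghost) loci; Myf7-analog losses in
tetrapods and teleosts; 3R retaining only the early gene in duplicate;
a zebrafish-specific early-copy loss; and 4R in the salmonid followed
by one late-class loss. The resulting focal counts are amphioxus 5
(contiguous), tunicate 1, human 4 in 3 loci, gar 5, teleost 5,
zebrafish 4, salmon 9. `ghost_2R` is the two-species workhorse for
orthology/enrichment/ghost tests: 24 single-copy neighbor families
around the focal gene (so every family has ≤ 4 members after 2R),
two further 20-gene chromosomes, background retention 0.7–0.8 per copy
per round (default 0.8), and a scripted focal loss from `chrM_b_b`, the
ghost. The tunicate retains the late-class gene (the NJ evidence leant
weakly that way; the choice only affects labels, not counts).

The timing-scenario scripts place the early/late TD midway (`at = 0.5`)
along the vertebrate stem, Olfactores stem, or chordate stem: a
duplication coincident with a speciation is statistically
unidentifiable, so the half-branch offset is what makes the scenarios
distinguishable at all (with 0.25-substitution branches and rate 0.4
that offset is ~10 expected substitutions of signal).

`sample_random_history` draws TD/loss/inversion/translocation counts
per branch from Poisson(rate × branch length) and resolves WGD
retention immediately into explicit loss events, so the returned script
is a pure record and replays without further structural randomness.

## Orthology

The built-in scorer stands in for a local aligner: identical-length
proteins score their count of identical positions; mixed lengths score
shared distinct k-mers (k = 4 by default). It is symmetric, so
reciprocal best hits need one scoring pass. Hits are ranked by
(−score, subject id); the lexicographic tie-break is a determinism
device, nothing more. Rank depth 2 ("top two hits") is the standard
concession to a lineage that doubled again after the comparison point:
each query then has two legitimate co-orthologs. No e-value model is
attached to the built-in scores; externally supplied blast-tabular
files default to a bit-score cutoff of 200. With no cutoff, rank-2
lists for families with a single surviving subject admit junk second
hits — the mode is meant for post-WGD searches, as in its source
workflow.

## Enrichment statistics

For b orthologs mapped into a genome of d genes, a chromosome with c
genes and a ortholog hits is tested three ways:

* **Binomial.** The conventional inclusive tail P(X ≥ a) for
  X ~ Bin(b, c/d), plus the "exclusive" spreadsheet variant
  P(X > a) = 1 − CDF(a), reproduced because published values computed
  that way; exclusive ≤ inclusive always, and the scan reports both.
* **Barnard's unconditional exact test.** The 2×2 table fixes group
  sizes n₁ = c (on the chromosome) and n₂ = d − c, success = being an
  ortholog. The test statistic is the pooled-variance Wald z, one-sided
  (greater); the statistic is defined as 0 when the pooled proportion is
  degenerate. The p-value maximizes, over a closed nuisance grid
  {0, step, …, 1} (default step 0.001), the total probability of all
  outcome pairs scoring ≥ the observed z minus a 1e-12 tie tolerance.
  Which statistic/grid the circulated R implementation used is not
  recoverable; the Wald/grid variant matches the commonly distributed
  one and agrees with an independent continuous-optimization
  implementation to ~1e-3 on spot checks. Pmfs are computed in log
  space and the outcome grid is vectorized; cost is
  O(grid × n₁ × n₂), so genome-scale tables (n₂ ≈ 2×10⁴) take minutes
  unless the grid is coarsened (`--grid-step`). The grid is chunked to
  bound memory.
* **Fisher.** The one-sided hypergeometric tail with all margins fixed,
  kept as the conditional benchmark; on the [[1,0],[0,1]] table Barnard
  (0.25) beats Fisher (0.5), the classic power gap.

No multiple-testing adjustment is applied (the scan mirrors its source
procedure); a Bonferroni column is attached for information only.

## Paralogons and ghost loci

Families with ≤ 4 members genome-wide that hit ≥ 2 anchor chromosomes
are the candidate 2R relics; the size cap is what keeps large,
promiscuous families from washing out the signal. Ghost scoring counts
candidate-family members on each non-anchor chromosome and ranks by the
inclusive binomial tail against that chromosome's share of non-anchor
genes (ties: raw count, then name). The k-fold detector greedily grows
the seed chromosome set by the chromosome sharing the most ≤ k-member
families with the current set, stopping at k or when the addition's
binomial p exceeds 0.05. Greedy (not exhaustive) search is deliberate:
on a clean 2R simulation every ≤ 4 family spans exactly the ohnologous
quartet, so the greedy path is already exact (a tested invariant), and
real genomes are far from the regime where exhaustive quartet search
would change the answer. There is no quantitative published criterion
for declaring a ghost locus; the binomial ranking is this package's
formalization.

## Phylogenetics

Distances: p-distance over ungapped shared sites (pairwise deletion;
an optional ≥ 95% column-coverage filter is provided because the source
description is ambiguous between the two), with Poisson
(−ln(1−p)) or gamma rate-heterogeneity correction
α[(1−p)^(−1/α) − 1], default shape α = 0.77. Saturation (p ≥ 0.95)
is an error rather than a clamped large distance. Neighbor joining is
the standard Saitou–Nei O(n³) algorithm; Q-ties resolve to the smallest
(row, column) pair, negative branch lengths clamp to zero, and
exact-zero-distance pairs are joined preferentially — a zero pair is
always a valid cherry on additive input, and without that rule the
placement of duplicate taxa (e.g. freshly gene-converted copies) is
arbitrary. One further numerical point: the Q matrix is computed as
(n−2)d − (rᵢ + rⱼ) with the row sums added first, because the naive
two-subtraction form is asymmetric at one ulp and breaks exact-tie
detection.

Bootstrap supports resample alignment columns with replacement
(default 1,000 replicates; tests and the demo use 100–200 since NJ
supports stabilize quickly at these sizes) and report the percentage of
replicates containing each internal bipartition. Taxa are sorted
internally so supports are invariant to input order. Partition trees
run the same machinery per disjoint column range — the exon-tree
workflow; the Robinson–Foulds split distance quantifies between-
partition discordance. Trees are unrooted; rooting at a designated
outgroup is available for reconciliation.

## Reconciliation and duplication timing

LCA reconciliation maps each rooted gene-tree node to the LCA of its
leaves' species. Duplications are called by lineage overlap: a node is
a duplication iff two of its children's lineages pass through the same
child subtree of the mapped species node (at a binary node this is the
textbook rule; at a polytomy it makes the polytomy "soft", so
descending into different children of an unresolved node never forces a
duplication — chosen because deep chordate backbones are weakly
resolved). Losses accumulate per edge as the mapped depth difference,
minus one across speciation nodes. On gene trees small enough for
exhaustive search, the LCA labeling attains the minimal
duplication + loss cost (a tested invariant).

The TD-timing classifier finds the smallest gene-tree clade containing
both the early-class and late-class genes; a call is made only when
that node is a duplication whose children separate the classes, and the
call is the species-tree branch it maps to (vertebrate stem /
Olfactores stem / chordate stem). Everything else — including the
configuration where the tunicate gene's placement is unresolved — is
`undetermined`, which is a first-class outcome, not an error. An
optional pre-pass collapses gene-tree edges below a support threshold
(default 50) to make the classifier more conservative. The
independence test for a lineage-specific expansion requires the gene
subset to be monophyletic with every internal duplication mapping to
the named species clade or its stem.

## What the simulator does and does not establish

Passing tests show the inference stack is correct and powerful **under
the generator's assumptions**: gap-free fixed-length proteins, a
uniform substitution process, clock-like branches, clean one-protein-
per-gene tables, and chromosome-scale assemblies. Real data add
alignment error, rate heterogeneity across lineages, assembly
fragmentation, annotation noise (isoforms must be pre-collapsed;
multi-gene-model loci are out of scope), and ancient divergences near
saturation — which is why published support values for the deepest
clades are low, and why this package's acceptance checks deliberately
target scripted counts, exact statistics, and recovery rates rather
than any real-sequence quantity. ML/Bayesian tree inference, alignment
construction, empirical substitution matrices, e-value statistics,
Ks dating, and ancestral-linkage-group reconstruction are out of scope.

## Problem sizes

The shipped experiments use an 85-gene, 3-chromosome ancestral genome
(2-species 2R runs), a 65-gene three-chromosome chordate ancestor for
the 7-species scenario, 50-seed recovery batches, 100–200 bootstrap
replicates, and the full 18,225-table Barnard enumeration at n₁, n₂
≤ 15 — sizes chosen so the whole suite exercises every claim in a few
minutes on one core while keeping binomial counts (50 trials, ≥ 45
thresholds) large enough to be meaningful.
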