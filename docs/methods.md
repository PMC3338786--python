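# Methods

`lsubench` benchmarks taxonomic classification of large-subunit (LSU,
25–28S) rDNA amplicon reads. It simulates the whole observation chain —
reference database, primer-anchored read clipping, per-base sequencing
error — and pushes the resulting reads through three classifiers that
represent the three families of assignment methods used for fungal
amplicon surveys: sequence similarity with lowest-common-ancestor (LCA)
consensus, naive Bayesian k-mer composition, and phylogenetic
(neighbor-joining) placement. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The synthetic reference model

Real curated LSU reference sets have three structural properties the
benchmark depends on: a rank-structured taxonomy whose sequence
divergence grows toward the root, a mosaic gene architecture of
alignable conserved cores interleaved with fast-evolving divergent
(expansion) domains, and near-universal primer binding sites inside the
conserved cores. The generator reproduces exactly these three
properties and nothing else.

A root sequence of 3,400 bp is drawn uniformly over A/C/G/T and evolved
down a balanced seven-rank taxonomy (kingdom → species). On the branch
into each taxon, every position mutates independently with probability

    p(site) = segment_rate(site) × rank_multiplier(child_rank)

with defaults:

| parameter | default | meaning |
|---|---|---|
| conserved segment rate | 0.003 /site/branch | background divergence of alignable cores |
| divergent segment rate | 0.025 /site/branch | expansion-domain divergence |
| primer-footprint rate | 0.0002 /site/branch | near-invariant binding sites |
| rank multipliers | phylum 3.0, class 2.0, order 1.5, family 1.2, genus 1.0, species 0.7, record 0.3 | divergence budget per level |
| counts | 2 × 2 × 2 × 2 × 2 × 2 species, 1 record each | 64-species balanced taxonomy |

The default architecture has twelve divergent domains (the classical
description of the eukaryote LSU expansion segments), with conserved
cores at the coordinates where the standard LSU primer panel (LR0R,
LR3, LR5, LR7) is published; the primer footprints are written into the
root exactly there (reverse primers as reverse complements, degenerate
symbols concretized). These rates are stand-ins chosen so that the
structural properties hold — all four primers findable at ≤1 mismatch in
≥95% of records, within-genus identity above between-phylum identity,
family-level neighbors within 90% identity of 100–400 bp reads — not
estimates of real LSU substitution rates.

Evolution is substitution-only. Without indels, primer coordinates,
fragment arithmetic and error accounting stay exact, which is what the
clipping and error analyses measure; the price is that length variation
of real expansion segments (and alignment ambiguity it causes) is not
modelled. Consequences: alignment-based steps here see an easier problem
than on real data, and passing trends demonstrate internal consistency
of the methods, not field performance.

`degrade_annotations` optionally truncates a random fraction of
lineages at or above genus, emulating partially annotated public
records; the benchmark protocols run with fully annotated references.

A separate synthetic "coordinate scaffold" (3,396 bp, seeded) carries
all twelve published primer footprints at their published coordinates.
It is a stand-in constructed from the primer table itself — random
background, real footprints — used to verify coordinate/strand/IUPAC
semantics of the primer finder; it contains no real 25S sequence.

## Read simulation

Primer sites are located by IUPAC-aware sliding-window scan of both
strands with ≤1 mismatch (the conventional mapping allowance); among
equally good sites the expected-orientation strand and then the 5′-most
start wins, and the tie is flagged. Fragments of exactly 50/100/200/400
bp are clipped in sequencing direction starting at the primer's 5′ end
(the primer span is included; both this and reverse-complement emission
are parameters, since published pipelines differ). Reads from reverse
primers are emitted 5′→3′ of the sequencing strand, i.e.
reverse-complemented relative to the reference — classifiers therefore
auto-orient each query by comparing infix edit distances of the query
and its reverse complement against three sampled references, as real
pipelines do implicitly (similarity search scans both strands; the RDP
classifier orients reads).

Sequencing error is independent per-base substitution at rate r, the
substituted base uniform over the three alternatives, so counts are
exactly Binomial(L, r); no indels, no quality profile, no chimeras.

Mock communities restrict to parents on which *all four* primers yield
a valid clip, so the per-primer datasets are equally sized with
identical parent sets; the error/community protocols additionally cap
communities at 33 parents, the study size this design emulates. The
read-length protocols use all passing parents (~60 of 64) for tighter
estimates.

## Classifiers

**Similarity + LCA.** Queries are aligned locally (Smith–Waterman via
Biopython's C aligner: match +2, mismatch −3, gap cost 5 + 2·g — the
convention that the first gap base pays open+extend) against every
reference; an 11-mer shared-word prefilter can skip hopeless subjects,
and every reported hit is rescored by full dynamic programming. Hits
with score ≥ min_score (50 for ≤50 bp queries, else 100 — the stock
thresholds, with the caveat that raw SW scores stand in for bit scores)
and within top_percent = 1% of the best score are collapsed onto the
lowest common ancestor of their lineages; winscore (default 0 =
disabled) acts as a hard floor when positive, and min_support (default
1) pushes under-supported taxa up to the nearest supported ancestor.
NBC output can be re-parsed the same way with confidence×100 as the
score: ranks failing min_score are dropped, and disagreements with the
reference taxonomy collapse to the deepest shared ancestor.

**Naive Bayesian k-mer classifier.** Genus g scores a query's distinct
8-mers by Σ log[(m(w)+P_w)/(M_g+1)], with m(w) the number of genus-g
training sequences containing w, M_g the genus size, and
P_w=(n(w)+0.5)/(N+1) the corpus prior — the classical formulation;
words are counted once per sequence and words containing non-ACGT
symbols are skipped. Confidence at each rank is the fraction of 100
bootstrap replicates (⌈W/8⌉ words redrawn with replacement) agreeing
with the full-set winner; the recommended cutoffs (50% below 250 bp,
80% otherwise) are applied when thresholds are enabled. Leave-one-out
search is implemented exactly, by subtracting the excluded record's
word contributions from the fitted counts.

**NJ placement.** Homologs are compiled greedily by descending identity
(infix edit-distance identity ≥ 90%) under diversity quotas (≥1 phylum,
2 classes, 3 orders, 5 families, 10 genera; ≤1 record per species),
then projected onto query coordinates via semi-global alignment — the
package's simplification of profile alignment, which gives all pairs a
shared column space. Pairwise p-distances feed standard neighbor
joining; the tree is rooted at the most distant non-query leaf (ties by
id) and the query inherits the lineage LCA of its smallest enclosing
non-trivial clade. Support is the fraction of 100 column-resampling
bootstrap replicates agreeing at each rank; the 95% cutoff clears
unsupported ranks when enforced. This deterministic clade rule replaces
the full Bayesian machinery of phylogenetic assignment tools — a stated
simplification that keeps the method's character (placement improves
with query length and homolog diversity).

## Metrics and protocols

Per rank, over queries whose truth names that rank: recovery = fraction
correct, erroneous recovery = fraction incorrect, coverage = fraction
classified (= recovery + erroneous). Truth-side annotation gaps are
excluded from the denominator. Error tracking follows the reads correct
at 0% error and reports delta(r) = surviving fraction − 1, so deltas
are non-positive by construction. Means ± SEM across the four primers
mirror how such benchmarks draw error bars.

Community profiles summarize assignments at the order rank (reads
assigned above the rank are "unplaced" and excluded from distances but
reported). Sizes are normalized to the smallest placed total by
largest-remainder rounding. Distances: Bray–Curtis Σ|x−y|/Σ(x+y), and a
simplified taxonomy-UniFrac — the fraction of unit-length taxonomy
edges on paths of taxa private to one community among all edges present
in either (presence/absence; read-count weighting is a documented
unknown of the tool being emulated, so unweighted is the default).
NMDS is non-metric SMACOF with isotonic regression (scikit-learn),
best of 10 seeded restarts, reporting Kruskal stress-1; "iterations" in
the emulated default is read as restarts, each run to convergence.

## Numerical and degenerate-input choices

* Ties for the NBC winning genus: uniform from the seeded stream.
  Primer-site ties: deterministic (orientation, then 5′-most), flagged.
  NJ rooting ties: lexicographic id.
* Queries shorter than k, with no valid words, with <3 homologs, or
  with all-identical distance matrices return explicit unclassified
  assignments with a diagnostic note, and count against coverage.
* One root seed fans out to per-stage child seeds by hashing stage
  labels (SHA-256, 31-bit), so grids are reproducible and adding a
  stage never perturbs another stage's stream.
* Largest-remainder rounding preserves integer totals exactly;
  remainder ties break lexicographically.

## Problem sizes

Default protocols run on the 64-species database: read-length grids on
all passing parents, error and community grids on 33-parent
communities at 200 bp, bootstrap B=100 where confidence is evaluated,
and the binomial check on 150 seeds × 10 kb. These sizes give stable
trend estimates on a single CPU in minutes.

## Known limitations

* The leave-one-out scenario removes one sequence from the query's
  genus while sister genera stay intact; with small per-genus training
  counts this gives sister genera a systematic per-shared-word
  advantage in the Bayes score. One observable consequence: injected
  error, which converts shared words into out-of-vocabulary words,
  can *help* the composition classifier under leave-one-out, so its
  error-degradation onset on this balanced synthetic system is no
  earlier than the aligner's — unlike on large, unevenly represented
  real training sets, where composition methods are the more
  error-sensitive. The error protocols report both methods' deltas so
  this behaviour is visible rather than hidden.
* Substitution-only evolution and equal-length records understate
  alignment difficulty; absolute recovery levels are optimistic and
  only the trends are meaningful.
* Raw Smith–Waterman scores are not bit scores; the stock min-score
  thresholds are applied to them by convention.
* The taxonomy-UniFrac uses the reference taxonomy, not a phylogeny;
  branch lengths are unit.
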