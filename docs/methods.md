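# Methods

## Scope and model

The package treats a *complex dataset* as a named collection of complexes,
each a set of typed members. All comparative statements are made over unique
protein identifiers: stoichiometry is parsed and retained but never enters a
membership computation, and non-protein members (small molecules, RNAs) are
excluded from protein membership. Two normalisation steps precede any
comparison:

* **Subcomplex expansion.** A member typed `complex` is replaced,
  recursively, by the referenced record's protein members. The recursion
  caches flattened records, rejects dangling references, and reports cycles
  by name. The operation is idempotent, which the tests verify.
* **Paralog expansion.** Any member belonging to a declared paralog set is
  replaced by the whole set. This deliberately over-inflates subunit counts
  for paralog-rich assemblies (e.g. ribosomal subunits); it is the only way
  to make datasets with different paralog-handling conventions comparable,
  so the inflation is accepted and documented rather than corrected.
* **Identifier mapping.** One-to-many mappings expand membership to every
  target (ambiguous locus→accession mappings keep all candidates). Unmapped
  identifiers are *retained* by default and reported, since silently
  dropping them would shrink pair universes invisibly; a flag drops them
  instead. The same expansion is available at the pair level
  (`map_pairs`) for carrying protein-space pairs into ORF space before
  genetic-interaction comparison; coverage fractions are counted after the
  expansion.

## Pairs

Co-complex pairs are the matrix expansion of each complex (all n(n−1)/2
unordered member pairs) unioned over the dataset; a pair occurring in
several complexes counts once, and self-pairs are impossible by
construction. Background pairs are the complement within the dataset's own
protein universe: pairs of proteins that each occur somewhere but never
together. The background is intra-dataset, not proteome-wide, so the two
sets partition the dataset's pair universe — a property test asserts both
disjointness and completeness.

## Dataset comparison

Complex matching reports *all* cross-dataset pairs with Jaccard index at or
above the threshold; no one-to-one assignment is attempted, so at
stringencies below 1.0 one complex may be "broken into" several partial
matches and match totals can exceed dataset sizes. Matched fractions are
computed per dataset over complexes with at least `min_size` (default 3)
unique proteins, dropped from numerator and denominator alike — predicted
datasets contain no dimers, and including dimers on one side only would
bias the fractions. Mean and median complex sizes are likewise reported
over complexes of size ≥ 3, with a secondary maximum that excludes named
outlier complexes (paralog-inflated ribosomal subunits in real data).

## Functional standards

* **Genetic interaction.** Per-screen outcomes (negative / positive / none)
  are pooled per gene pair across query alleles; a sign is called when at
  least half the screens report it, implemented as `2·count ≥ total` so a
  1-of-2 split still qualifies. DAmP (hypomorphic) rows are removed before
  calling by default; a pair screened only by DAmP then leaves the tested
  universe. If negative and positive each reach half (possible only in
  small even splits), the pair is called `none` and the conflict logged —
  the calling rule is otherwise silent on conflicts and a directionless
  "interaction" would be meaningless downstream.
* **Co-expression.** Pairs whose integrated score is *strictly* greater
  than the cutoff (default 1.0, the conventional threshold for MEFIT-style
  log-likelihood scores). The tested universe is the set of scored pairs.
* **Co-localization.** Pairs sharing at least one annotated compartment;
  the universe is pairs with both proteins annotated.
* **Co-annotation.** Protein annotations are up-propagated through the
  is_a/part_of DAG (only these relations are traversed); terms annotated to
  more than a cutoff number of proteins are then discarded, and a pair is
  co-annotated if it shares a surviving biological-process term. The
  frequent-term cutoff defaults to 5% of annotated proteins: the exact
  threshold used with published co-annotation standards is not printed in
  the sources this design follows, so a round, conventional value was
  chosen and made configurable.

GO SLIM classification is descendant closure: a complex counts under a SLIM
root if its complex-level annotations intersect the root's closure. A
complex under two roots counts once in the overall total and once per root.
The 12 default roots (nuclear and nucleic-acid-related processes, functions
and the nucleus component) ship as package data.

## Enrichment statistics

Enrichment restricts co-complex and background pairs to a standard's tested
universe, computes the fraction of each group inside the standard, their
ratio (fold enrichment), and a two-sided Fisher exact p-value on the induced
2×2 table. The two-sided p follows the probability-mass convention (sum of
hypergeometric probabilities no larger than the observed table's); the test
itself is delegated to `scipy.stats.fisher_exact`, and the test suite checks
it against an independent exact-rational enumeration for every table with
margins ≤ 20 (34 810 tables, agreement to 1e−10). A table whose standard
column margin is empty or full carries no information and returns p = 1.

Feature profiling z-scores each numeric feature against the **background
median and ordinary sample standard deviation** — the median centre gives
robustness to skewed feature distributions while the plain SD keeps the
scale interpretable; the median z over members is reported with a two-sided
Mann–Whitney U p-value. Binary features report member/background fold
enrichment with Fisher tests. Features with zero background spread are
skipped with a warning. Z-scores are affine-invariant, which a property
test asserts.

Rank tests use mid-rank tie handling; the exact null distribution is used
for tie-free samples of ≤ 25 per group (configurable), the tie-corrected
normal approximation with continuity correction otherwise. Fully tied
inputs return p = 1 with a warning rather than dividing by a zero variance.

The relative difference of a non-negative paired measure is
(MAX−MIN)/MAX ∈ [0, 1]; pairs with a missing value are excluded, pairs with
both values zero are excluded with a warning (0/0 undefined). The score is
scale-invariant.

The contact analysis selects complexes of size ≥ 3 that carry both direct
contacts and non-contact co-member pairs, classifies pairs as direct
(annotated contact in any selected complex), indirect (co-complex, never in
contact) or background (across different selected complexes), and compares
allele-averaged genetic-interaction profile similarities between the three
classes with pairwise two-sided Mann–Whitney tests. Allele-level rows
(`GENE-allele` tags) are collapsed to gene pairs by unweighted mean;
self-pairs are dropped.

Reported significance uses 0.05 two-sided throughout and no
multiple-testing correction is applied; the analyses make a handful of
planned comparisons, not a genome-wide scan.

## Synthetic data

The generator's defaults encode the study conditions the analyses target:

* **Size law** — body `1 + Geometric(p=0.3)` (median of sizes ≥ 3 equal
  to 4), a 5% uniform tail on [20, 60] emulating paralog-expanded large
  assemblies (pushing the size-≥3 mean toward ~7), and 2% homomers. An
  empirical histogram can be injected instead.
* **Protein reuse** — members are drawn with preferential-attachment
  weights (each use adds weight 1), producing the observed pattern that
  >70% of proteins occur in one complex with a short multi-complex tail.
  Complex protein sets are kept distinct.
* **Derived overlap** — exact counts, not coin flips: 50% identical copies,
  30% one-member-swapped copies (the swapped-in protein is fresh, so the
  Jaccard index against the source is exactly (s−1)/(s+1)), 20% novel
  complexes over a disjoint pool (Jaccard 0 against everything). This makes
  matched-fraction recovery exact at stringency 1.0.
* **Planted standards** — each co-complex pair enters the standard with
  probability `p_co` (default 0.30) and each background pair with `p_bg`
  (default 0.068, a 4.4-fold enrichment); a coverage fraction (default
  0.52) of pairs is marked tested, independently of membership. The
  defaults mirror the genetic-interaction overlap reported for curated
  yeast complexomes. Emitters encode the planted sets exactly in each
  reader dialect: GI screens with majority-sign calls plus adversarial DAmP
  rows, co-expression scores straddling the strict cutoff, pair-private
  shared compartments (plus a per-protein home compartment so every protein
  is annotated), and pair-private GO leaves under a toy DAG with diamond
  motifs plus near-universal mid/root terms that the frequency filter must
  remove. For the two protein-level dialects the tested universe is all
  pairs over annotated proteins; per-pair coverage can only be encoded in
  the pair-level dialects.
* **Contacts** — each complex of size ≥ 3 gets a random spanning tree plus
  extra edges with probability `density` (0.3), guaranteeing connectivity;
  similarities are drawn per class from normals at offsets 0.30 / 0.15 /
  0.00 with SD 0.05, and allele-level replicates are emitted with
  zero-mean jitter so gene-pair means are preserved exactly. Contact truth
  classes are defined over contact-bearing complexes only, matching the
  downstream selection.

Everything is driven by `numpy.random.default_rng(seed)` and is
deterministic given the seed. What the generator does **not** emulate:
real identifier namespaces and gene names, correlated screen errors,
biased coverage (coverage is independent of biology), compositional
correlations between complexes, or realistic GO topology. Passing recovery
tests therefore demonstrate correctness of the computations under the
planted model, not robustness to real-data pathologies such as systematic
screen bias or incomplete curation.

## Problem sizes

The acceptance computations use a 700-protein / 260-complex dataset
(≥ 10 000 co-complex, ≥ 50 000 background pairs; the two groups are
subsampled to exactly those counts), a 100-complex derived-overlap run with
all complexes of size ≥ 4, the full margins-≤ 20 Fisher sweep, and a
200-complex contact run. These sizes give binomial CIs tight enough to
separate the planted effects by a wide margin while completing in well
under a minute each (the Fisher sweep in ~15 s).

## Known limitations

* Complex matching is all-pairs (O(n·m) Jaccard evaluations); adequate for
  complexome-scale inputs (hundreds of complexes), not for millions of
  predicted clusters.
* Background pair sets are materialised explicitly (O(P²) pairs); fine up
  to a few thousand proteins.
* The consensus caller treats screens as exchangeable; it does not model
  per-allele reliability.
* The co-annotation universe is defined by surviving (post-filter) terms,
  so proteins annotated only to frequent terms drop out of the universe
  rather than counting as tested-but-unshared.
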