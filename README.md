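# complexome

Comparative and functional analysis of protein-complex datasets.

Curated complexomes (e.g. the manually curated yeast complex compendia) and
complex sets predicted from protein–protein interaction networks describe the
same biology in different ways. This package provides the analysis toolkit a
systems biologist needs to compare such datasets and to assess their
functional coherence:

* **Normalisation and expansion** — parse ComplexTab-style or simple TSV
  complex tables; recursively expand subcomplex references; expand
  interchangeable paralog sets; translate identifiers through one-to-many
  mappings. Comparisons are always over unique protein identifiers
  (stoichiometry and non-protein members are parsed but excluded).
* **Pair expansion** — matrix-expand every n-member complex into its
  n(n−1)/2 unordered *co-complex pairs*; derive the disjoint *background
  pairs* (proteins present only in different complexes).
* **Dataset comparison** — shared proteins, complex matching by Jaccard index
  J(A,B) = |A∩B|/|A∪B| at chosen stringencies, co-complex pair containment,
  size statistics and multifunctionality (complexes per protein).
* **Functional standards** — consensus-called genetic interactions ("at
  least half of the screens", DAmP alleles dropped), co-expression (score
  strictly above a cutoff), co-localization (shared compartment) and
  co-annotation (shared infrequent GO biological-process term after
  up-propagation); plus bespoke GO SLIMs built by descendant closure.
* **Enrichment statistics** — fold enrichment of co-complex over background
  pairs within each standard with two-sided Fisher exact tests; member
  vs non-member feature profiling (median z-scores against the background
  median/SD, Mann–Whitney U); relative difference (MAX−MIN)/MAX of paired
  measures; direct vs indirect intra-complex contact analysis of
  genetic-interaction profile similarities.
* **Synthetic data** — seeded generators for complexomes, derived
  overlapping datasets, planted functional standards and contact graphs, so
  every stage is testable against known ground truth without downloads.

## Worked example

```python
from complexome import (
    SyntheticConfig, StandardSpec, generate_complexome, generate_standard,
    cocomplex_pairs, background_pairs, standard_enrichment,
)

cfg = SyntheticConfig(n_proteins=300, n_complexes=80, seed=1)
ds, _ = generate_complexome(cfg)
co, bg = cocomplex_pairs(ds), background_pairs(ds)
print(len(co), len(bg))                  # 3592 16911

std, tested, _ = generate_standard(ds, StandardSpec(), seed=2)
res = standard_enrichment(co, bg, std, tested)
print(f"{res.fraction_cocomplex:.3f} {res.fraction_background:.3f} "
      f"{res.fold:.2f} {res.p_value:.2e}")
# 0.301 0.068 4.42 1.93e-149
```

The generated dataset yields 3592 co-complex and 16 911 background pairs.
The default `StandardSpec` plants a genetic-interaction-like standard in
which 30% of co-complex pairs and 6.8% of background pairs interact, with
52% of pairs covered by screens; the enrichment analysis recovers fractions
0.301 and 0.068 — a 4.42-fold enrichment of co-complex pairs, Fisher
p ≈ 2e−149.

The same analyses run on real files from the shell:

```bash
complexome simulate --outdir bundle --seed 5
complexome compare --a bundle/complexes.tsv --b bundle/complexes_derived.tsv \
    --threshold 0.5 --out cmp.json
complexome run-all --config run.yaml
```

`run-all` produces a JSON report (with TSV mirrors) containing size
statistics, overlap matrices, threshold matching, per-standard enrichment,
relative-difference, contact and SLIM sections.

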