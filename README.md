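# metevol

Timing and mode of metastatic divergence from multi-region tumour
phylogenies, with a deme-based spatial model of tumour growth and
metastatic seeding.

`metevol` is aimed at cancer-genomics analysts working with multi-region
whole-exome cohorts in which each patient's somatic mutations have been
clustered into a clone tree with per-sample cancer cell fractions
(phyloCCF). From those inputs it answers, per metastasis and per case:

* **When did the metastatic lineage diverge?** Let *C* be the set of
  mutation clusters clonal in every primary region, and *f* the fraction
  of their mutations also clonal in the metastasis. *f* < 1 means a
  clonal sweep completed in the primary after the metastatic lineage
  branched — **early** divergence; *f* = 1 is **late**. Orthogonal
  read-outs use arm-level LOH (>= 75% of an arm, same allele lost in all
  primary regions) and whole-genome-doubling identity as irreversible
  timing ratchets, and a region-based mutation presence method with
  LOH-locus filtering.
* **How many clones seeded it?** **Monoclonal** if every cluster shared
  between primary and metastasis is clonal in the metastasis,
  **polyclonal** otherwise (or when several monoclonal metastases carry
  different shared sets); **monophyletic** versus **polyphyletic** by
  whether the shared clusters lie on one tree branch.
* **Which clones seeded it?** A leaf-up walk from the most recent
  shared cluster, ascending while met-subclonal and adding ancestors
  whose metastasis CCF exceeds their path child's (branch CCFs summed at
  shared parents).
* **How expanded are the seeding clones?** Clone proportions per region
  (leaf proportion = phyloCCF; internal = phyloCCF minus direct
  children's, clamped and renormalised) and the clonal dispersion index
  `D = 1 - (max(p_i) - 1/n) / (1 - 1/n)` with `p_i = x_i / sum(x)`
  (1 = evenly spread across regions, 0 = region-private).
* **Is seeding under selection?** Paired primary-metastasis favouring
  of mutation clusters and of gene-level copy-number events, tested per
  gene against a non-driver background with an exact/Monte-Carlo
  multinomial test plus Benjamini-Hochberg correction; G-score
  differences from GISTIC-style tables; dN/dS odds-ratio gene
  classification from supplied estimates (> 2 seeding favoured, < 0.5
  primary favoured).

It also quantifies the *illusion of clonality* — how often a late case
is misclassified early when the primary is undersampled — and includes
a deme-based agent model (demes of 5,000 cells on a 3D lattice,
fitness-ratio division rule, asymmetric-Laplace fitness effects, rare
drivers, genomic events, emulated 400x WES) that relates divergence
timing to primary tumour size. A synthetic-data generator produces
cohorts with known ground truth so every stage is testable without
access-controlled patient data.

## Worked example

```python
import numpy as np
from metevol import synth, timing, dissemination
from metevol.core import classify_clonality

cohort = synth.generate_cohort(synth.SynthConfig(
    n_cases=4, fraction_early=0.5, fraction_polyclonal=0.5, seed=11))

for tree, truth in cohort:
    matrix = classify_clonality(tree)
    t = timing.time_divergence_case(tree, matrix)
    d = dissemination.classify_dissemination_case(tree, matrix)
    seeds = {m: dissemination.find_seeding_clusters(tree, matrix, m).seeding_cluster_ids
             for m in tree.metastasis_ids()}
    print(tree.case_id, t.label, round(t.shared_clonal_fraction, 3),
          d.clonality, d.origin, seeds)
```

prints

```
SYN0001 late 1.0 polyclonal monophyletic {'SYN0001_M1': ('C6', 'C8')}
SYN0002 early 0.541 polyclonal monophyletic {'SYN0002_M1': ('C1',), 'SYN0002_M2': ('C3',)}
SYN0003 early 0.231 polyclonal monophyletic {'SYN0003_M1': ('C1', 'C4')}
SYN0004 late 1.0 monoclonal monophyletic {'SYN0004_M1': ('C3',), 'SYN0004_M2': ('C3',)}
```

— case SYN0003 diverged early (only 23% of the mutations clonal across
all primary regions are clonal in its metastasis, so a clonal sweep
completed in the primary after divergence) and was seeded polyclonally
by cluster C4 together with its ancestor C1; SYN0004's two metastases
were founded by the same clone C3, hence monoclonal at the case level.

The same analyses run from the shell on the TSV dialects documented in
`metevol.io`:

```bash
metevol synth --seed 11 --out cohort/
metevol timing --clusters cohort/clusters.tsv --samples cohort/samples.tsv --out timing.tsv
metevol disseminate --clusters cohort/clusters.tsv --samples cohort/samples.tsv --out dis.tsv
metevol sim-experiment --sizes 100,10000,1000000 --final-size 1000000 --out curve.tsv
```

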