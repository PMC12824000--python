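# pegl — phylogenetically effective gene length via sparse learning

`pegl` quantifies the phylogenetic information content of a nucleotide
alignment at single-site resolution, without committing to any reference
topology.  It is aimed at systematists choosing markers — for example
weighing mitochondrial genes such as *CYTB* or *COX1* against nuclear
coding sequences for within-species (population) or among-species
(congeneric) questions.

## The statistic

For a gene *g* with *n* aligned sites, an ensemble of *T* random trees
(random topology **and** branch lengths) is generated and the
log-likelihood ℓ_{t,i} of every site *i* on every tree *t* is computed
under a substitution model.  Because sites are independent, the tree
log-likelihood is exactly the row sum L_t = Σ_i ℓ_{t,i}.  An
L1-penalized (Lasso) regression of L_t on the site log-likelihoods,

  min_{β₀, β}  Σ_t (L_t − β₀ − Σ_i β_i ℓ_{t,i})² / 2T  +  λ Σ_i |β_i|,

with λ\* chosen by k-fold cross-validation, zeroes out sites whose
contribution to the likelihood is redundant across topologies and
branch lengths.  The **phylogenetically effective gene length** is

  PEGL(g) = Σ_{i=1}^{n} 1{ β̂_i(λ\*) ≠ 0 },

and PEGL(g)/n is the proportion of phylogenetically informative sites.
Companion metrics: the parametric aLRT branch support (½χ²₀ + ½χ²₁
mixture over the best NNI alternative) averaged over internal branches
of an ML tree, gapless-length vs PEGL regression across a gene panel,
codon-position breakdowns, positional profiles, and a
percentile-bootstrap test for mean differences between gene panels.

## Worked example

```python
from pegl import (SubstModel, simulate_yule_tree, simulate_alignment,
                  informativeness_run, codon_position_counts)

model = SubstModel("HKY85", pi=(0.33, 0.29, 0.13, 0.25), kappa=8.0)
tree = simulate_yule_tree(6, depth_scale=0.05, seed=2)          # congeners
aln, truth = simulate_alignment(tree, model, n=900, p_invariant=0.25,
                                codon_rates=(1.0, 0.5, 5.0), seed=3)
result = informativeness_run(aln, n_trees=400, seed=7, model=model)
print(f"PEGL = {result.pegl} of n = {result.n_sites} "
      f"({100 * result.proportion:.1f}% informative)")
print("codon positions (c1, c2, c3):",
      codon_position_counts(result.mask, aln.frame))
```

prints

```
PEGL = 132 of n = 900 (14.7% informative)
codon positions (c1, c2, c3): (41, 32, 59)
```

Third codon positions evolve fastest here (rate multiplier 5), so they
carry the most informative sites — 59, versus 41 and 32 at the
purifying-selection-dominated first and second positions (about 1.6×
the first/second-position average), the enrichment expected for
protein-coding markers among congeneric species.  The same analysis is available from the shell:

```sh
pegl informativeness --fasta gene.fasta --trees 10000 --model auto \
     --seed 1 --out-dir out/
pegl support --fasta gene.fasta --model HKY --out-dir out/
pegl reproduce-synthetic --trees 500 --genes 8 --out-dir report/
```

Defaults follow the reference workflow: 10,000 random trees, 10-fold
cross-validation with the CV-minimum rule, and 10,000 percentile-
bootstrap replicates for panel comparisons.

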