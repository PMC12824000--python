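# Methods

## Model and procedure

`pegl` treats phylogenetic informativeness as a feature-selection
problem.  For an alignment of n sites, T random unrooted binary trees
are generated — topology by Yule–Harding growth (each new taxon
attached to a uniformly chosen pendant edge of a shuffled-order star),
branch lengths i.i.d. Exponential with mean `bl_mean` (default 0.1
substitutions/site) — and the site log-likelihood matrix ℓ_{t,i} is
computed by the pruning algorithm under a reversible nucleotide model.
The per-tree totals L_t = Σ_i ℓ_{t,i} (an exact identity, enforced to
1e-8 by the `SiteLogLikMatrix` container) are regressed on the site
columns with an L1 penalty.  Sites keeping non-zero coefficients at the
cross-validated penalty λ\* are "informative"; their count is PEGL.

The regression asks which sites are *individually necessary* to
reconstruct the likelihood across random topologies and branch
lengths.  Sites whose likelihood varies only with overall tree length
(invariant or near-invariant columns) are mutually redundant and are
represented by a handful of columns; sites whose likelihood responds
idiosyncratically to topology are retained.

### Assumptions

- Sites are independent given the tree (no codon or RNA pairing
  structure).
- The substitution model is reversible and homogeneous across the tree;
  rate variation across sites is i.i.d. (discrete gamma and/or an
  invariant-sites class).
- The random-tree ensemble is the reference measure over "phylogenetic
  hypotheses"; informativeness is relative to that measure, not to any
  particular true tree.

## Tunable parameters

| parameter | default | units / notes |
|---|---|---|
| `n_trees` (T) | 10,000 | reference workflow default; tests and the acceptance script use 150–1,000 (see problem sizes) |
| `bl_mean` | 0.1 | substitutions/site; mean of the Exponential branch-length law of the ensemble |
| `n_lambda`, `lambda_min_ratio` | 100, 1e-4 | geometric penalty grid from λ_max |
| `folds` | 10 | k-fold CV, seeded shuffled folds |
| `lambda_rule` | `"min"` | CV-minimum; `"1se"` available |
| gamma categories | 4 | mean-of-quantiles discretization |
| branch-length bounds | [1e-8, 10] | clamps for the bounded Brent search |
| branch-length tolerance | 1e-6 | total-lnL improvement per sweep |
| aLRT mode | focal-branch | only the focal branch re-optimized per rearrangement; `full=True` re-optimizes the five local branches |
| bootstrap replicates | 10,000 | percentile method, 95% CI |
| indel-rich threshold | 0.5 | column flagged when the within-group gap fraction exceeds it |

## Numerical choices

- **Scaling.**  Partial likelihoods are rescaled per internal node with
  accumulated log scalers, so 2,000-site alignments with near-zero
  branch lengths stay in range.
- **Penalty path.**  Features are standardized once on the full data
  (zero-variance columns are forced to zero coefficients); the response
  is centered and the intercept unpenalized.  The path descends
  geometrically from λ_max and stops early once the explained deviance
  exceeds 0.999 or its gain stalls below 1e-5 per step (judged over two
  steps to be robust to solver granularity).  Without the stop, the
  response — being an exact linear function of the features — drives
  cross-validation error onto a machine-precision plateau and the
  selected penalty into a non-converged, essentially arbitrary dense
  region of the path.
- **Solver tolerance.**  Coordinate descent runs at tol 1e-5 (max
  10,000 iterations).  On these strongly collinear designs the
  active-set size at λ\* retains a mild dependence on solver tolerance;
  1e-5 is the loosest setting whose masks are invariant under common
  rescaling of all likelihoods, which is the package's stability
  criterion.  Coefficients below 1e-8 of the largest (standardized)
  coefficient are snapped to exact zero before the mask is formed.
- **Duplicate columns.**  Identical columns (e.g. invariant sites of
  the same base, repeated site patterns at small taxon counts) produce
  identical features; any split of a duplicate block's total
  coefficient has the same L1 norm, so membership of the mask within a
  block is arbitrary.  Cyclic coordinate descent in fixed column order
  makes it deterministic and reproducible.
- **Branch-length optimization.**  Iterated bounded 1-D searches per
  branch on the inside/outside edge decomposition (the likelihood as a
  function of one branch length needs only two 4-vectors per site);
  only improving updates are accepted, so total lnL is monotone.
- **Ties in model selection.**  BIC over {JC69, HKY85, GTR} × {+Γ4, —}
  with empirical (ambiguity-weighted) base frequencies; ties go to
  fewer parameters.
- **Degenerate inputs.**  All-gap alignments yield PEGL = 0 rather than
  an error; a saturated sequence pair clamps its distance at 10 with a
  warning; an aLRT statistic within optimizer tolerance below zero is
  clamped silently, a genuinely negative one (non-optimal input tree)
  with a warning; 1-based coordinates everywhere.

## Synthetic data: what it does and does not emulate

The generator produces the statistical structure the analysis assumes:
shallow within-species samples (star-like trees, terminal branch means
0.005 vs internal 0.0005 substitutions/site, autapomorphy-dominated),
deeper among-species samples (Yule trees rescaled to mean root-to-tip
depth 0.05), codon-position rate multipliers (default (1.0, 0.5, 5.0) —
fast third positions, conserved second positions), a planted
invariant-site fraction (default 0.25 in panels), multi-gene panels of
700–2,000 bp, and optional indel-rich regions gapped out for a taxon
subset.  The default panel model for mammalian-style markers is HKY85
with π = (0.33, 0.29, 0.13, 0.25) and κ = 8, a typical mitochondrial
protein-coding composition and transition bias.

"Expected informative" ground truth is defined operationally as the
non-invariant site classes.  In recovery experiments the variable
classes are resimulated until each realizes at least one substitution
(`ensure_variable=True`), since a planted-variable column that happens
to be constant is indistinguishable from an invariant one.  The
generator does **not** emulate alignment error, realistic indel
evolution, selection heterogeneity along the gene, base-composition
drift among lineages, or gene-tree discordance (ILS, introgression).
Passing tests therefore demonstrate internal correctness and the
method's behaviour under its own assumptions — not performance on real
mammalian data.

### A structural limit of per-column recovery

At small taxon counts (5–6), variable columns repeat a limited set of
site patterns, and identical columns are interchangeable in any L1
solution.  The mask consequently keeps *representatives* of pattern
clusters rather than every member: per-column sensitivity is bounded by
the unique-pattern fraction (≈0.5–0.7 at 5 taxa) times the selection
rate within represented clusters, at any penalty sparse enough to keep
the invariant duplicates out.  The package therefore reports, and its
green tests assert, the robust directional result — variable sites are
selected at several times the rate of invariant duplicates — rather
than near-complete per-column recall, which no penalty on the path
attains in this regime.

## Problem sizes used by the shipped experiments

Chosen as desk-scale versions of the full design: unit tests use
ensembles of 150–1,000 trees on 100–400-site alignments; the planted
recovery experiment uses 5 taxa, 400 sites (half invariant), T = 1,000,
20 seeds; the acceptance script runs two independent 8-gene
among-species panels (700–2,000 bp, 6 taxa) at T = 300, planted
recovery at 5 seeds, and 500 bootstrap-coverage runs at R = 1,000.

## Design choices where the design was open

- Random-tree law: Yule–Harding topology + i.i.d. Exponential lengths,
  exposed in config; verified to reach all 3 (m=4) and 15 (m=5)
  unrooted topologies.
- Site likelihoods for the ensemble are computed under the selected
  (or user-fixed) model; model selection is BIC over a six-model sweep
  rather than a full model-space search.
- CV rule `"min"` and full-data standardization, with `"1se"` as a
  flag; fold count 10.
- All n columns (including gapped ones) count in PEGL/n; "gapless
  length" is the count of completely gap-free columns (a per-reference
  alternative is available via `indel_rich_columns` flags).
- Percentile CI (not BCa) for the bootstrap; no multiple-testing
  correction across branches for aLRT supports.
- Seed policy: one master seed per entry point; child seeds derived via
  `numpy.random.SeedSequence` spawning, so every stage is independently
  reproducible.

## Known limitations

Trees beyond ~25 taxa make the NNI search and aLRT loop slow (the
search is exhaustive best-improvement, not stochastic); the Lasso stage
holds the full T × n matrix in memory; amino-acid and codon models,
partitioned models, and nonparametric SH-aLRT are out of scope; PEGL
values retain a mild dependence on the coordinate-descent tolerance on
near-degenerate designs (see Numerical choices).
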