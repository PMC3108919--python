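# Methods

## Data model and preprocessing

The pipeline operates on a binary matrix **H** derived from a continuous
cohort of per-patient gene-expression log fold-changes plus survival
follow-up. Binarization keeps only the sign of expression: an entry is 1
iff the log ratio is strictly positive. A ratio of exactly zero maps to 0
— zero is not positive — and missing measurements also map to 0, which
deliberately conflates "not over-expressed" with "not measured"; this is a
property of the binarization scheme itself, not of this implementation.

The outcome is survival status at a fixed horizon `t_end` (years): label 1
if the patient died of disease strictly before `t_end`, label 0 if
followed up alive to at least `t_end`. A patient censored before `t_end`
has unknown status and is excluded. Death from causes other than the
disease is excluded by default, since such a patient is neither "dead of
disease" nor known alive at `t_end`; a flag converts these to censoring at
the time of death instead. `select_balanced_endpoint` scans a candidate
grid (by default every observed disease-death time) and returns the cutoff
minimizing the dead/alive imbalance among eligible patients, ties going to
the smallest cutoff; a one-element grid acts as a fixed cutoff for
deliberately unbalanced designs.

Resampling draws `n_runs` independent train/test partitions, test size
`round(n * (1 - train_fraction))` (44 patients for n = 148 at 70/30). Each
run's permutation comes from its own RNG stream seeded by (master seed,
run index), so extending a study with more runs never alters earlier
splits, and one `SplitPlan` object is shared by every method so per-run
errors are paired.

## The GP engine

Individuals are boolean syntax trees: internal nodes from {AND, OR, NOT}
(arities 2, 2, 1), leaves indexing the p binary features. A lone terminal
has depth 0. Fitness is `w_FN * FN + w_FP * FP` on the training set,
minimized; (1, 1) counts total errors, the (0.9, 0.1) preset trades
specificity for sensitivity. Tree output 1 is the positive class (death
before `t_end`), so FN is the clinically costly error.

The evolutionary loop is generational with no elitism:

- **Initialization** — ramped half-and-half: depths cycle uniformly over
  `init_depth_range` (default (2, 6)); at each depth half the trees are
  built by the *full* method (functions down to the target depth, then
  terminals) and half by *grow* (uniform over the combined primitive set
  below the root, so shapes vary). Terminal choice is uniform over the p
  features with no input-dependent bias.
- **Selection** — tournament of size 10, sampled with replacement; ties
  among the sampled competitors are broken uniformly at random.
- **Variation** — each offspring is produced by exactly one operator:
  subtree crossover with probability 0.9 (a uniformly chosen subtree of
  parent A replaced by a uniformly chosen subtree of parent B) or subtree
  mutation with probability 0.1 (a uniformly chosen subtree replaced by a
  fresh grown tree of depth <= 4). The rates are interpreted as mutually
  exclusive per-offspring probabilities and must sum to 1.
- **Depth cap** — offspring may not exceed `max_tree_depth` (default 17).
  Crossover retries point selection up to 5 times and then returns the
  first parent unchanged; mutation caps the regrown subtree's depth by the
  room remaining under the chosen point.
- **Best-of-run** — with no elitism the final population need not contain
  the best individual ever evaluated, so the reported solution is the
  lowest-fitness tree seen in any generation, ties broken by fewer nodes
  and then earlier discovery.

Defaults are population 500 and 5 generations — a deliberately small
budget of 2500 tree inspections per run, which is also why the random
forest comparator uses 2500 trees. Both knobs are exposed. Per-run
determinism is exact: one `numpy` Generator seeded per run drives
initialization, selection and variation.

The per-generation full-population evaluation means the inspection counter
equals `population_size * generations` exactly; trees are not cached or
deduplicated.

## Comparators

The SVMs, MLP and random forest are adapters over scikit-learn; the
underlying learners are standard and reimplementing them would add nothing
but risk. Mapped settings: SVM complexity C = 0.1, tolerance 0.001,
homogeneous polynomial kernel (x·y)^d with d in {1, 2, 3} (gamma = 1,
coef0 = 0; d = 1 uses the linear kernel); MLP with one hidden layer of
(attributes + classes)/2 logistic units, SGD back-propagation at constant
learning rate 0.03 and momentum 0.2, 500 epochs with per-instance
(batch-size-1) updates; random forest of 2500 trees with 1 candidate
attribute per split. Options with no scikit-learn counterpart — kernel
cache size, SMO round-off epsilon, a momentum schedule decaying to 1e-4 —
are ignored; the momentum is held constant at 0.2. All methods consume the
same binarized features.

## Scoring baseline

The signature's original classifier scores each patient by the Pearson
correlation *s* between their 70-gene profile and a good-prognosis
centroid profile, calling s > 0.4 good prognosis and s <= 0.4 bad (the
boundary is bad). The centroid is an input: deriving it belongs to the
signature's original training cohort and is out of scope, and precomputed
scores can be supplied directly. A false prediction is a good call on a
patient who died (the baseline's false negative) or a bad call on a
survivor. Evaluation draws random patient lists of the same size as the
machine-learning test sets and reports per-list false-prediction counts
with mean and SEM.

## Statistics

Run summaries report best (minimum), mean, and SEM = sample sd / sqrt(runs).
Across methods: one-way fixed-effects ANOVA over all supplied per-run
error groups (the groups used are recorded in the machine-readable
summary), and pairwise two-sided Student t-tests of GP against each
comparator. The equal-variance form is used throughout; when an F-test of
the two variances rejects at 0.05 a warning is logged rather than
switching tests. No multiple-testing correction is applied — raw pairwise
p-values are reported by design. Degenerate inputs (all groups constant
and equal) return p = 1 by convention. External validation applies frozen
trees to an independent cohort with no retraining: a tree is applicable
iff every terminal gene exists on the external platform, and each
applicable tree's 2x2 prediction-vs-outcome table gets a two-sided Fisher
exact p-value; tables with an all-zero margin return p = 1.

## Synthetic cohorts

The generators produce data with exactly the dependence structure the
analysis assumes, so every stage is testable without restricted clinical
data. `generate_binary_cohort` draws i.i.d. Bernoulli(background)
features and sets `label = rule(features) XOR Bernoulli(noise)` — a
planted boolean rule with label-flip noise, the ground truth for
parameter-recovery and Bayes-floor checks. Defaults are n = 148, p = 70,
background 0.5, matching the balanced 148 x 70 geometry of the cohort
design the pipeline reproduces. `generate_continuous_cohort` wraps the
same binary structure for the preprocessing stage: log ratios with
magnitude |N(0.5, 0.25)| and sign given by the binary feature (so
binarization recovers the planted features exactly when nothing is
missing), missingness at a configurable rate, and exponential survival
times — high-risk (rule-positive) patients at hazard 0.2/y, low-risk at
0.02/y, independently censored at 0.05/y. Exponential waiting times were
chosen for their closed-form medians (ln 2 / hazard), which make ordering
checks exact. `make_external_cohort` emulates a second microarray
platform: the same rule generates labels but each signature gene is
dropped with probability `gene_dropout`, and the returned gene map
determines which frozen trees remain applicable.

What the generators do **not** emulate: gene–gene correlation, batch
effects, realistic intensity distributions, or any coupling between
expression and censoring. Passing tests therefore demonstrate that the
machinery is correct under the stated model, not that any method will
attain a particular accuracy on real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at reduced
replication (typically 20 runs rather than 50, and the default 2500-tree
GP budget) on the 148 x 70 synthetic geometry; the package's defaults keep
the full 50-run design. Probabilistic checks use 3-sigma binomial bands or
directional comparisons over paired runs. All stochastic stages consume
named substreams of a single master seed (`SeedSequence` over a method
tag and run index), so adding methods or runs perturbs nothing else and
repeat executions are byte-identical.

## Known limitations

- No bloat control beyond the depth cap, and no strongly-typed GP.
- The Weka-equivalent settings are approximations; numerical
  bit-compatibility with other toolkits is explicitly not a goal.
- The scoring baseline's correlation flavour (Pearson vs uncentered
  cosine) is ambiguous in the original description; Pearson is the
  default and precomputed scores sidestep the choice.
- Signature-to-platform gene matching for real external cohorts is
  reduced to an explicit user-supplied gene map; no identifier translation
  is attempted.
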