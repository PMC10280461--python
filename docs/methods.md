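# Methods

## Problem and model

`hawkselect` performs wrapper feature selection on clinical tabular data:
the search object is a binary mask over the table's columns, and the quality
of a mask is the cross-validated accuracy of a K-nearest-neighbour classifier
restricted to the selected columns. Two objectives are pursued — maximise
that accuracy, minimise the number of selected columns — and the final
deliverable is a Pareto archive over the two, not a single mask.

The search metaheuristic is a binary adaptation of Harris Hawks Optimization.
Hawks (candidate masks) converge on the best-so-far mask (the rabbit). A
per-hawk escaping energy

    E = 2·E0·(1 − t/T),  E0 ~ U(−1, 1)

decays linearly over the T generations. `|E| ≥ 1` selects exploration,
`|E| < 1` exploitation, with the exploitation regime split at `|E| = 0.5`
(soft vs hard besiege) and a second uniform draw `r` selecting the plain or
the "dive" variant. In this binary setting the canonical vector arithmetic
is re-expressed as bit-copy operators:

| regime | condition | move |
|---|---|---|
| exploration (random) | `\|E\| ≥ 1`, `q < 0.5` | copy a uniform block (size 1..⌈d/2⌉) of a random partner's bits |
| exploration (best-guided) | `\|E\| ≥ 1`, `q ≥ 0.5` | switch on a random subset of the rabbit's selected features |
| soft besiege | `0.5 ≤ \|E\| < 1`, `r ≥ 0.5` | copy `m = max(1, round(\|E\|·J·d/4))` differing rabbit bits, `J = 2(1−u)` |
| hard besiege | `\|E\| < 0.5`, `r ≥ 0.5` | copy exactly one differing rabbit bit |
| soft besiege + dive | `0.5 ≤ \|E\| < 1`, `r < 0.5` | copy `m = max(1, round(\|E\|·d/4))` differing bits, then flip one random bit |
| hard besiege + dive | `\|E\| < 0.5`, `r < 0.5` | identical to hard besiege (minimal perturbation near convergence) |

Copy-count formulas scale the step with the prey's energy; the `d/4` scaling
keeps early soft-besiege steps near d/2 bits (with `J` up to 2) and lets
them shrink smoothly to single-bit moves. When a besiege is asked to move a
hawk that already equals the rabbit, one random bit is flipped instead —
duplicates are useless in a population that forbids them. If any operator
produces an empty mask, one feature is switched back on (for besiege moves,
one of the rabbit's own features, so a besiege never increases the Hamming
distance to the prey).

### Insertion and ranking

Each hawk proposes exactly one candidate per generation; each candidate is
scored, counted against the evaluation budget (`eval_counter = N·T`
invariantly, 15,000 at the default N = 30, T = 500), rejected if its mask
duplicates a population member, and otherwise replaces the worst hawk only
when strictly better. "Better" is lexicographic: higher accuracy, then fewer
selected features, remaining ties rejected. The feature-count tie-break is
the in-island acknowledgment of the second objective; the full
multi-objective treatment happens at the master. Duplicate candidates still
consume their evaluation — the budget counts proposals scored, not
insertions — which is what makes the `N·T` arithmetic exact.

### Island model and the archive

Islands are completely independent runs seeded `base_seed + island_id`; there
is no migration. Parallelism is a contract, not a technology: the sequential
emulation and the process-pool mode produce bit-identical gathered results,
so the 64-island accounting (960,000 evaluations) is testable on one CPU.
The master deduplicates gathered masks (exact-mask identity), extracts the
non-dominated front under (accuracy ↑, feature count ↓), and selects up to
30 solutions: the whole front first (highest-accuracy members if the front
itself exceeds 30), then the best remaining solutions by accuracy, then
fewer features. The fill rule beyond the front is a design choice of this
package; it is deterministic and configurable through the `limit` argument.

All islands of one run score masks against the *same* cross-validation fold
assignment (drawn from the run's base seed). This makes fitness a pure
function of the mask — without it, "strictly better" comparisons and
cross-island accuracy comparisons at the master would be ill-defined.

## KNN fitness

K = 5 neighbours under Manhattan (L1) distance, 5-fold cross-validation:
folds are a random near-equal partition; each fold is predicted by the model
trained on the other four; fitness is the mean over folds of the fraction
correct. Features enter on their raw numeric/integer-coded scale — no
standardisation — which is the natural reading of L1 distance on
integer-coded clinical columns.

Determinism requires explicit tie rules, so the classifier is implemented
directly (scipy `cdist` + stable argsort) rather than through a library
whose tie behaviour is unspecified: distance ties at the k-th neighbour keep
the lower training-row index; vote ties go to the class with the smaller
summed distance among its voting neighbours, then the lower label. `k`
larger than the training split truncates. Reported confusion counts are
CV-pooled: every row is predicted exactly once (when its fold is held out)
and the TP/TN/FP/FN counts are accumulated over all rows.

Metric formulas: accuracy = (TP+TN)/total, precision = TP/(TP+FP),
recall = TP/(TP+FN), MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
A zero MCC denominator reports 0; zero-denominator precision/recall are
reported as undefined (`None`) rather than silently coerced to 0.

## Data handling and augmentation

Loading refuses missing cells (error names the row and column) — there is no
principled imputation rule to apply, and inventing one would change the
problem. Text columns are integer-encoded in first-appearance order with the
mapping retained. Labels must be binary after encoding.

Augmentation appends `round(fraction × n)` copies of uniformly chosen rows.
Per appended row a fair coin chooses between two perturbations: the age cell
multiplied by exactly 0.95, or every non-binary numeric cell jittered by a
relative amount uniform in ±1%. Binary indicators and integer-coded
categoricals are never altered (a 1% change is meaningless for them), labels
are copied unchanged, and original rows are preserved bit-exactly. The fair
coin, the uniform-in-magnitude jitter, and the exclusion of categoricals are
design choices where the recipe's prose gives a bound but no distribution.
Note that growing 1,085 rows to 1,192 corresponds to an appended fraction of
107/1085 ≈ 9.86%, not a literal 10% (which would give 1,194 rows); `fraction`
is therefore a free parameter rather than a hard-coded 0.10.

## Synthetic data

The generator emulates the shape of a mortality table: `d − 2` binary
symptom columns (per-column prevalence uniform in [0.02, 0.4]), one integer
age column (1–90), one small integer region column, and a rare positive
outcome (6% by default). A planted subset of symptom columns (prevalence
boosted to [0.15, 0.4], weights uniform in [0.8, 1.2]) carries all the
signal: the `round(rate·n)` rows with the highest weighted symptom score are
labelled positive, ties broken at random, optionally followed by independent
label flips (`flip_noise`). Consequences: the marginal positive rate is
exact before noise; labels never depend on noise columns; and the outcome is
approximately "enough informative symptoms present", which a KNN restricted
to the planted columns can learn while their complement cannot.

What passing tests on this generator do and do not show: they demonstrate
that the search machinery finds and prefers genuinely informative columns
under class imbalance and that every piece of bookkeeping (budgets,
determinism, archive logic) is exact; they do not demonstrate clinical
validity on real records, where feature correlations, measurement noise and
label ambiguity are richer than this linear-threshold model.

## Problem sizes and numerical choices

Default search parameters mirror the published configuration: N = 30,
T = 500, K = 5, 5 folds. The default island count is 4 — a desk-scale
choice; `--islands 64` reproduces the full 960,000-evaluation accounting
(the 64 came from a specific cluster, not from the method). Verification
runs use deliberately scaled problems chosen to exercise every code path
while keeping the whole suite fast: a 100×10 table for the single-island
budget, a cheap separable stand-in fitness (`LinearMaskFitness`, a fixed
weighted fraction of selected bits) for the 64-island accounting — the
budget arithmetic is independent of what the fitness costs — and 500×30
tables with 5 planted features, N = 20, T = 100, ten seeds for feature
recovery.

Other numerical details: energy uses generation index t ∈ {0, …, T−1}, so
the final generation still has a small nonzero |E|; `round()` is Python's
banker's rounding (only visible exactly at .5 copy counts); initial
populations draw fair-coin masks, rejecting duplicates, and fail loudly if
the feature space cannot hold N distinct non-empty masks; the N initial
evaluations are not charged to the operator-candidate budget.

## Known limitations

- KNN fitness is O(n²·d_selected) per evaluation; very large tables need
  subsampling or a different classifier, which is out of scope here.
- The archive's "top 30" fill rule beyond the Pareto front is a convention;
  different fill rules yield the same front but different tails.
- The process-pool mode pickles the dataset per worker; for desk-scale data
  this is negligible, but the sequential mode is the default since islands
  are CPU-bound and reproducibility, not wall-clock speed-up, is the goal
  of this implementation.
- Euclidean or other distance metrics are not offered; the fitness is
  Manhattan-only by design.
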