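# Methods

This note documents the models and procedures implemented in `qreuse`, the
choices made where the design was genuinely open, and what results on
synthetic data do and do not establish.

## Task domain and hypothesis spaces

A world assigns each of three monsters (blue, red, purple) a head shape
(square/circle) and a leg count (1–3): 18 distinct monsters, 6 feature
combinations per color, 216 complete worlds. A trial array reveals some
features and hides others; hidden-feature counts (h heads, l legs) range
over the 14 canonical patterns (0–3 of each, excluding nothing-hidden and
everything-hidden). Hidden features are represented explicitly (`None` in
observations), so h and l are always derived, never stored — they cannot
fall out of sync. The hypothesis space of an array is constructed as a
cross product of per-color feature options (size 2^h·3^l by construction)
and is verified in tests against brute-force filtering of all 216 worlds.
Trial arrays optionally carry their true world for answer simulation; no
scoring operation reads it.

## The question language

Programs are parenthesized typed s-expressions. The function inventory —
feature queries `shape`/`legs`; `==` over matching Number/Shape pairs;
variadic `+` over numbers (with booleans coerced to 0/1 *only* inside `+`,
so counting questions like "How many monsters have a square head?" are
expressible while `==` stays strict); comparisons `>`/`<`; logic
`and`/`or`/`not`; `set` of distinct color literals; higher-order
`map`/`lambda`; reducers `any`/`all`, summing `+`, and
`all_same`/`all_different` — is the minimal closure over the question
forms the task elicits. It lives in a grammar table rather than being
hard-coded, and is intended to be extended rather than edited. Number
literals span 0–9 because combined-legs answers reach 9. The root of every
well-formed program must be answerable in one word (Boolean, Number,
Shape, or Color); the typeset variant `= =` is read as the single operator
`==`.

Complexity is measured as unique and total function-node counts, excluding
`lambda` (which always co-occurs with `map`). `set` and `map` count as
functions — they are functions under the notation's own rule that the
first element of a parenthetical is a function; whether to count them was
an open choice and is documented here rather than configurable.

## Templates and reuse

A template abstracts a program's typed terminal parameters to slots
(colors used as monster references, shape literals, number literals) and
alpha-normalizes lambda variables (x0, x1, … by first use). Function
symbols are never slots. One deliberate refinement: **color literals
inside `set` are configuration, not slots.** The set names *which*
monsters a question quantifies over — "do the blue and red monsters…" asks
a different question than "do the red and purple monsters…" at the
template level — and it makes the all-monster aggregate questions
(`(+ (map (lambda x0 (legs x0)) (set Blue Red Purple)))`, the combined-legs
target) parameter-free, matching only themselves.

Reuse of a question = template equality with any earlier question by the
same participant; each participant's first valid question is excluded from
denominators. Reuse classification provably coincides with tree edit
distance zero (tested over sampled program pairs).

## Tree edit distance

Grammar-based similarity uses the Zhang–Shasha ordered-tree edit distance
with unit insertion/deletion/relabel costs, except that relabeling a
terminal argument to another argument of the same type is free. Trees are
ordered: argument order matters (`(== x y)` and `(== y x)` are distinct
programs in this notation). Function relabels always cost 1 — asking about
head shape is a different thing than asking about legs. Alpha-normalized
lambda variables are *not* free-relabel terminals; a bound variable is
part of the question's configuration. These two choices together are what
make distance 0 equivalent to template equality.

The implementation is the standard keyroot dynamic program; its
correctness oracle in the test suite is an independent exhaustive search
over all valid edit mappings (one-to-one, postorder- and
ancestor-preserving) on small random trees. Similarity is `1 − d/d_max`,
clipped to [0, 1], where `d_max` defaults to the maximum pairwise distance
in the analyzed dataset (a fixed constant can be supplied for
cross-dataset comparability; if all distances are 0 similarity is defined
as 1). The normalization is computed per analyzed dataset — whether the
original analyses normalized per study or globally is unknowable from the
outside, so the constant is always reported alongside scores.

## Text-based similarity

Computed as cosine similarity between embeddings of *standardized*
English renderings (one deterministic rendering per program; parameter
words vary within a template), never raw wording. The embedding backend is
pluggable. The bundled default is a deterministic term-frequency
bag-of-words embedder, which makes the measure reproducible and offline;
it approximates, and does not reproduce, results obtained with a
pretrained sentence-embedding model, so text-based numbers from this
package should be compared in direction and ordering, not in magnitude,
with analyses that used a neural embedder.

## Expected Information Gain

EIG is computed in bits under a uniform prior over the hypothesis space,
primarily via the posterior formula H(prior) − Σ_a p(a)·H(posterior|a);
the identity with the answer-distribution entropy (exact under
deterministic answers and a uniform prior) is carried as a second route
and asserted to 1e-9 in tests. The ceiling h + l·log2 3 is used for the
"maximally informative question" benchmark. Conditioning on an answer
filters the space and re-uniformizes; conditioning on an answer no world
produces raises a distinct error rather than returning an empty space.

Context sensitivity is tested by permuting the array assigned to each
question record (globally, ignoring participant structure) and recomputing
the mean EIG; the one-tailed p counts permuted means ≥ observed with
add-one smoothing (k+1)/(n+1). Add-one smoothing is used for every
one-tailed p in the package: it avoids exact zeros at finite simulation
counts, at the cost of a conservative floor of 1/(n+1).

## Simulated null distributions

The null for across-trial reuse/recombination replaces each
previously-asked question with a uniform draw from all questions asked for
that same trial array by any participant (the current question stays
fixed). Draws are independent per (record, prior-trial) pair; the
recombination variant additionally excludes pool questions matching the
current record's template (those would be reuse), and raises an error if
that empties a pool — a sign the dataset is too small to support the
recombination null. Observed recombination is the mean over non-reused
eligible records of the maximum similarity to any earlier own question;
null datasets contain no reuse by construction, so all eligible records
contribute there.

A calibration property worth knowing: because the reuse-rate statistic is
discrete and ties at the observed value count as "at least as extreme",
the one-tailed test is conservative — under a memoryless generator the
measured type-I rate sits at the low edge of the nominal 5% (2–3% in the
test suite's replicates). Power is high: agents reusing half the time are
flagged (p ≤ .05, usually p ≤ .002) in essentially every replicate at 20
participants × 4 trials with 500 simulations.

## Exposure analysis (two-condition design)

The two target questions are "How many monsters have a square head?"
(shape is a free slot, so the circle variant also matches) and "How many
legs do all the monsters have combined together?" (parameter-free). Trial
types are derived, not hard-coded: candidate arrays are ranked by the
target's EIG; *best* is the highest-EIG array, *worst* the lowest
(EIG 0 when the queried features are fully revealed), *medium* the
remaining array closest to their midpoint, and *too-complex* flags arrays
where the target reaches the ceiling but a strictly simpler program (fewer
total functions, from a systematic battery of all small grammar forms)
reaches it too.

The reuse effect is the difference in proportion of target-matching
questions (exposure − no-exposure) over the best/medium/too-complex trial
types (on the worst trial the target is worthless and matching it is not
expected); the recombination effect is the difference in mean
target-question similarity among non-matching questions over all trial
types. Uncertainty comes from percentile bootstrap over participants
(respecting clustering); mixed-effects regression is deliberately out of
scope — datasets export cleanly to external stats tools for that.

## The synthetic question-asker

The generator is a test harness, not a cognitive-model claim. Each agent
keeps a memory of its prior questions (exposure-condition agents start
with the target question in memory, as if a confederate had just asked
it). On each trial: with probability `rho_reuse` (given any memory) it
reuses — candidate templates are its prior templates, instantiated with
uniform parameters (number slots from the leg range 1–3, keeping reused
questions task-sensible) and chosen by a softmax over each candidate's
current EIG with weight `beta_eig` per bit. Otherwise it innovates: with
probability `kappa_recombine` it applies `n_edits` random type-respecting
tree edits to a random prior question (the edit kernel is local — mean
edit distance under 1 versus ≈5 between independent samples), else it
samples fresh from the probabilistic grammar.

Defaults, chosen once as the realistic regime: `rho_reuse = 0.35`
(between the child and adult reuse tendencies the task elicits),
`kappa_recombine = 0.30`, `n_edits = 1`, `beta_eig = 1.0`/bit (reuse is
context-sensitive; `beta_eig = 0` is the context-blind special case used
for null calibration), grammar weights placing roughly half the mass on
simple one-feature questions. The previous-quality manipulation is a
label only by default (`informative_rho_multiplier = 1.0`), mirroring a
null effect; a multiplier is available for power studies. A `drop_rate`
models invalid/untranscribable trials as deletions and nothing more.

What the generator does *not* emulate: natural-language production and
transcription noise, systematic age differences, idiosyncratic question
preferences beyond memory effects, EIG-directed *innovation* (only reuse
is informativeness-sensitive), and answer-interpretability costs. Passing
tests on this synthetic data therefore validate the estimators —
detection, calibration, parameter recovery — not any claim about human
behavior.

## Problem sizes and numerics

The test suite validates at: 500 sampled (program, array) pairs for the
EIG identity; 200 random tree pairs (≤ 5 nodes) for the edit-distance
oracle; 500 program pairs for the reuse/distance link; 100 replicate
datasets (20 participants × 4 trials, 500 null simulations) for
calibration and power; 20 replicates per reuse-probability level for
parameter recovery; and 50 replicate two-condition experiments (60
participants per condition, 400 bootstrap draws) for exposure-effect
recovery. The acceptance script uses 40 participants (Study-1 style), 60
per cell (Study-2 style), and 1000 simulations/permutations/bootstrap
draws. Probabilities are validated to 1e-9; EIG comparisons use 1e-9;
float ties in array ranking are broken by stable sort order. All
randomness flows through `numpy.random.Generator` seeds; equal seeds give
byte-identical datasets and reports.

## Known limitations

- The function inventory is a reconstruction sufficient for every question
  form the package handles; a richer task language (e.g. dedicated
  counting primitives) would change complexity counts and some templates.
- The fallback text embedder shares no representation with neural sentence
  embeddings; text-similarity magnitudes are not comparable across
  backends.
- The English renderer guarantees determinism and template-consistency,
  not fluency, for rare compositional forms.
- The simulated-null p-values are conservative for discrete statistics
  (see above); with very small datasets the recombination null can be
  unsatisfiable and errors out rather than silently degrading.
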