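# qreuse

Tools for studying **how people find good questions**: do they search the
vast space of possible questions from scratch, or do they *reuse* and
*recombine* questions they have asked before?

`qreuse` implements the computational machinery for a child-friendly
question-asking task: three cartoon monsters (one blue, one red, one
purple) vary in head shape (square/circle) and number of legs (1–3); on
each trial some features are hidden, and the learner asks one question
whose answer must be a single word. The package represents questions as
typed programs, scores their informativeness, detects reuse, quantifies
recombination, and tests both against trial-matched simulated null
distributions — end to end on synthetic question-asker data.

## The core quantities

**Questions as programs.** A question is a typed s-expression, e.g.
`(legs Red)` ("How many legs does the red monster have?") or
`(all (map (lambda x0 (== (shape x0) Square)) (set Blue Red Purple)))`
("Do all the monsters have a square head?"). Programs execute against a
complete world to yield a one-word answer.

**Expected Information Gain.** A trial array with *h* hidden heads and *l*
hidden legs induces a uniform hypothesis space of 2^h·3^l worlds. A
question *q* partitions that space by answer *a*, and its informativeness
is the expected entropy reduction in bits,

    EIG(q) = H(prior) − Σ_a p(a) · H(posterior | a),

which under the uniform prior equals the Shannon entropy of the answer
distribution. The ceiling is log2(2^h·3^l) = h + l·log2 3.

**Reuse.** Two questions share a *template* when their programs use the
same functions in the same configuration, with typed parameters free
(`(== (legs Blue) 2)` and `(== (legs Red) 3)` share a template;
`(== (shape Red) Square)` does not). Reuse = repeating an earlier template.

**Recombination.** For innovated (non-reused) questions, similarity to
earlier questions: either *grammar-based* — `1 − d/d_max` where *d* is the
Zhang–Shasha tree edit distance with same-type argument substitutions free
— or *text-based* — cosine similarity between embeddings of standardized
English renderings (pluggable backend; a deterministic term-frequency
embedder ships by default).

**Simulated nulls.** Observed reuse/recombination is compared against
datasets in which every previously-asked question is replaced by a random
question asked *for the same trial array* by any participant: the amount of
reuse expected if each trial were answered independently of one's own
history, while respecting each trial's informational demands.

## Worked example

```python
import numpy as np
import qreuse as q

array = q.TrialArray("demo", {
    "Blue":   {"head": "Square", "legs": 3},
    "Red":    {"head": "Circle", "legs": None},   # legs hidden
    "Purple": {"head": None,     "legs": None},   # fully hidden
})
for text in ["(shape Purple)", "(legs Red)",
             "(+ (map (lambda x0 (== (shape x0) Square)) (set Blue Red Purple)))"]:
    p = q.parse(text)
    print(f"{q.render_english(p):<42s} EIG = {q.expected_information_gain(p, array):.3f} bits")
```

```
What shape is the purple monster's head?   EIG = 1.000 bits
How many legs does the red monster have?   EIG = 1.585 bits
How many monsters have a square head?      EIG = 1.000 bits
```

One hidden head splits 2 ways (1 bit), hidden legs split 3 ways (1.585
bits), and the counting question collapses the two hidden heads into a
count. The ceiling for this array (h=1 head, l=2 legs hidden) is
1 + 2·log2 3 ≈ 4.17 bits — no one-word question can be more informative.

Fitting the across-trial analysis to a simulated cohort (30 participants,
4 trials each, reuse probability 0.5):

```python
from qreuse.simulate import AgentParams, StudyDesign, generate_dataset
ds = generate_dataset(AgentParams(rho_reuse=0.5, seed=0), StudyDesign.study1(n_participants=30))
res = q.AcrossTrialModel(ds).fit(n_sims=1000, rng=np.random.default_rng(0))
print(res.summary())
```

```
Across-trial reuse and recombination
  eligible records            : 90
  reuse rate (observed)       : 0.722
    null mean (1000 sims)      : 0.372
    one-tailed p              : 0.000999
  mean recombination (grammar) : 0.717
    null mean                 : 0.752
    one-tailed p              : 0.991
```

The observed reuse rate (0.722) exceeds every one of 1000 simulated
trial-matched nulls (p ≈ .001): these agents repeat their own templates far
more than task structure alone predicts. Recombination, by contrast, sits
inside its null here — the generator's editing tendency (its default 0.3)
is too weak to detect at this sample size.

There is also a command-line surface:

```bash
qreuse simulate --design study2 --n-participants 60 --seed 1 --out data.jsonl
qreuse score   --data data.jsonl --arrays data.arrays.json --out scores.csv
qreuse effects --data data.jsonl --arrays data.arrays.json --out effects.json
qreuse demo    --outdir demo_out --seed 0
```

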