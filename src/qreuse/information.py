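"""Expected Information Gain of questions given a trial array.

A question partitions the hypothesis space by answer.  With a uniform prior
and deterministic answers, the expected reduction in entropy (base 2) from
hearing the answer,

    EIG = H(prior) - sum_a p(a) * H(posterior | a),

equals the Shannon entropy of the answer distribution.  Both routes are
implemented; the posterior formula is the primary one, and the entropy
identity serves as an internal cross-check.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .domain import HypothesisSpace, TrialArray, hypothesis_space
from .interpreter import compile_program
from .language import QuestionProgram

LOG2_3 = math.log2(3)


class InconsistentAnswerError(ValueError):
    """Conditioning on an answer no world in the space produces."""


# caches keyed on (program identity, observation pattern)
_ANSWER_COUNT_CACHE: dict[tuple[str, str], tuple[tuple[object, int], ...]] = {}


def clear_caches() -> None:
    _ANSWER_COUNT_CACHE.clear()


def _answer_counts(program: QuestionProgram, array: TrialArray) -> tuple[tuple[object, int], ...]:
    cache_key = (program.key, array.key())
    hit = _ANSWER_COUNT_CACHE.get(cache_key)
    if hit is not None:
        return hit
    fn = compile_program(program)
    counts = Counter(fn(w.as_tuple(), {}) for w in hypothesis_space(array).worlds)
    out = tuple(sorted(counts.items(), key=lambda kv: repr(kv[0])))
    _ANSWER_COUNT_CACHE[cache_key] = out
    return out


def answer_distribution(program: QuestionProgram, array: TrialArray) -> dict:
    """p(answer) induced by executing the program across the hypothesis space."""
    counts = _answer_counts(program, array)
    total = sum(n for _, n in counts)
    return {a: n / total for a, n in counts}


def expected_information_gain(
    program: QuestionProgram, array: TrialArray, method: str = "posterior"
) -> float:
    """EIG of a question given a trial array, in bits.

    ``method="posterior"`` computes H(prior) - E_a[H(posterior | a)];
    ``method="entropy"`` computes the entropy of the answer distribution.
    The two agree to numerical precision under the uniform prior.
    """
    counts = _answer_counts(program, array)
    total = sum(n for _, n in counts)
    if method == "posterior":
        h_prior = math.log2(total)
        h_post = sum((n / total) * math.log2(n) for _, n in counts)
        return h_prior - h_post
    if method == "entropy":
        p = np.array([n for _, n in counts], dtype=float) / total
        return float(_scipy_entropy(p, base=2))
    raise ValueError(f"unknown method {method!r}")


def condition_on_answer(
    array: TrialArray, program: QuestionProgram, answer
) -> HypothesisSpace:
    """The subset of worlds whose answer matches, re-uniformized."""
    fn = compile_program(program)
    worlds = tuple(
        w for w in hypothesis_space(array).worlds if fn(w.as_tuple(), {}) == answer
    )
    if not worlds:
        raise InconsistentAnswerError(
            f"no world in the hypothesis space answers {answer!r} to {program}"
        )
    return HypothesisSpace(worlds)


def max_eig(array: TrialArray) -> float:
    """EIG of the most informative possible question: log2(2^h * 3^l) bits."""
    h, l = array.pattern
    return h + l * LOG2_3


@dataclass(frozen=True)
class ContextSensitivityResult:
    """Permutation test of whether questions are tailored to their trial arrays."""

    observed_mean_eig: float
    null_means: np.ndarray
    one_tailed_p: float
    n_perm: int

    def summary(self) -> str:
        lo, hi = np.quantile(self.null_means, [0.025, 0.975])
        return (
            "Context-sensitivity permutation test\n"
            f"  observed mean EIG : {self.observed_mean_eig:.4f} bits\n"
            f"  null mean (95% of {self.n_perm} permutations): [{lo:.4f}, {hi:.4f}]\n"
            f"  one-tailed p      : {self.one_tailed_p:.4g}"
        )


def context_sensitivity_test(
    records,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> ContextSensitivityResult:
    """Permute array assignments across question records and recompute mean EIG.

    ``records`` is an iterable of objects (or pairs) carrying a program and a
    trial array.  The one-tailed p uses add-one smoothing,
    (#{null >= observed} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pairs = []
    for rec in records:
        if isinstance(rec, tuple):
            program, array = rec
        else:
            program, array = rec.program, rec.array
        pairs.append((program, array))
    if not pairs:
        raise ValueError("no records supplied")
    programs = [p for p, _ in pairs]
    arrays = [a for _, a in pairs]
    n = len(pairs)
    # EIG matrix over distinct (program, array) combinations, via the caches
    eig = np.empty((n, n))
    uniq_arrays = {a.key(): a for a in arrays}
    for i, prog in enumerate(programs):
        by_key = {k: expected_information_gain(prog, a) for k, a in uniq_arrays.items()}
        for j, arr in enumerate(arrays):
            eig[i, j] = by_key[arr.key()]
    observed = float(np.mean(np.diag(eig)))
    null_means = np.empty(n_perm)
    for s in range(n_perm):
        perm = rng.permutation(n)
        null_means[s] = eig[np.arange(n), perm].mean()
    k = int(np.sum(null_means >= observed - 1e-12))
    p = (k + 1) / (n_perm + 1)
    return ContextSensitivityResult(observed, null_means, p, n_perm)
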