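"""Sampling and enumerating question programs.

The sampler is a probabilistic grammar over the question language:
productions are chosen by weight, subject to a depth bound, and every
sampled program is type-correct by construction with a one-word-answerable
root.  It drives the synthetic question-asker generator and the property
tests; weights are a plain dict so callers can reshape the distribution.
"""

from __future__ import annotations

import itertools

import numpy as np

from .domain import COLORS, SHAPES
from .language import QuestionProgram, func, lit, program_from_node, var

#: Default production weights.  Roughly: half the mass on simple one-feature
#: questions, the rest spread over comparisons, counts, and quantified forms,
#: echoing the mix of forms the task elicits.
DEFAULT_WEIGHTS: dict[str, float] = {
    # root type
    "root_boolean": 0.45,
    "root_number": 0.35,
    "root_shape": 0.20,
    # Number productions
    "num_legs": 0.45,
    "num_sum2": 0.12,
    "num_sum3": 0.06,
    "num_count_shape": 0.19,
    "num_count_legs": 0.18,
    # Boolean productions
    "bool_eq_shape": 0.20,
    "bool_eq_legs": 0.20,
    "bool_eq_shape2": 0.09,
    "bool_eq_legs2": 0.09,
    "bool_all_shape": 0.07,
    "bool_any_shape": 0.07,
    "bool_all_legs": 0.05,
    "bool_any_legs": 0.05,
    "bool_all_same_shape": 0.04,
    "bool_all_same_legs": 0.03,
    "bool_all_diff_shape": 0.02,
    "bool_all_diff_legs": 0.04,
    "bool_gt": 0.02,
    "bool_not": 0.01,
    "bool_and": 0.01,
    "bool_or": 0.01,
    # set choice inside quantified/counting forms
    "set_full": 0.85,
    "set_pair": 0.15,
}

# minimum tree depth each production needs (root node = depth 1)
_MIN_DEPTH = {
    "num_legs": 2, "num_sum2": 3, "num_sum3": 3,
    "num_count_shape": 5, "num_count_legs": 5,
    "bool_eq_shape": 3, "bool_eq_legs": 3,
    "bool_eq_shape2": 3, "bool_eq_legs2": 3,
    "bool_all_shape": 5, "bool_any_shape": 5,
    "bool_all_legs": 5, "bool_any_legs": 5,
    "bool_all_same_shape": 4, "bool_all_same_legs": 4,
    "bool_all_diff_shape": 4, "bool_all_diff_legs": 4,
    "bool_gt": 3, "bool_not": 3, "bool_and": 4, "bool_or": 4,
}


class UnsatisfiableDepthError(ValueError):
    pass


def _pick(rng: np.random.Generator, weights: dict[str, float], names: list[str]) -> str:
    w = np.array([weights[n] for n in names], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("production weights must be positive")
    return names[rng.choice(len(names), p=w / w.sum())]


def _color(rng) -> str:
    return COLORS[rng.integers(3)]


def _two_colors(rng) -> tuple[str, str]:
    i, j = rng.choice(3, size=2, replace=False)
    return COLORS[min(i, j)], COLORS[max(i, j)]


def _shape_lit(rng) -> str:
    return SHAPES[rng.integers(2)]


def _legs_lit(rng) -> int:
    return int(rng.integers(1, 4))


def _set_node(rng, weights):
    names = [n for n in ("set_full", "set_pair") if weights.get(n, 0) > 0]
    if _pick(rng, weights, names) == "set_full":
        return func("set", lit("Blue"), lit("Red"), lit("Purple"))
    a, b = _two_colors(rng)
    return func("set", lit(a), lit(b))


def _sample_number(rng, weights, depth):
    names = [n for n in ("num_legs", "num_sum2", "num_sum3", "num_count_shape", "num_count_legs")
             if weights.get(n, 0) > 0 and _MIN_DEPTH[n] <= depth]
    if not names:
        raise UnsatisfiableDepthError(f"no Number production fits depth {depth}")
    p = _pick(rng, weights, names)
    if p == "num_legs":
        return func("legs", lit(_color(rng)))
    if p == "num_sum2":
        a, b = _two_colors(rng)
        return func("+", func("legs", lit(a)), func("legs", lit(b)))
    if p == "num_sum3":
        return func("+", *(func("legs", lit(c)) for c in COLORS))
    body = (
        func("==", func("shape", var("x0")), lit(_shape_lit(rng)))
        if p == "num_count_shape"
        else func("==", func("legs", var("x0")), lit(_legs_lit(rng)))
    )
    return func("+", func("map", func("lambda", var("x0"), body), _set_node(rng, weights)))


def _sample_boolean(rng, weights, depth):
    names = [n for n in _MIN_DEPTH if n.startswith("bool_")
             and weights.get(n, 0) > 0 and _MIN_DEPTH[n] <= depth]
    if not names:
        raise UnsatisfiableDepthError(f"no Boolean production fits depth {depth}")
    p = _pick(rng, weights, sorted(names))
    if p == "bool_eq_shape":
        return func("==", func("shape", lit(_color(rng))), lit(_shape_lit(rng)))
    if p == "bool_eq_legs":
        return func("==", func("legs", lit(_color(rng))), lit(_legs_lit(rng)))
    if p == "bool_eq_shape2":
        a, b = _two_colors(rng)
        return func("==", func("shape", lit(a)), func("shape", lit(b)))
    if p == "bool_eq_legs2":
        a, b = _two_colors(rng)
        return func("==", func("legs", lit(a)), func("legs", lit(b)))
    if p in ("bool_all_shape", "bool_any_shape", "bool_all_legs", "bool_any_legs"):
        quant = "all" if "all" in p else "any"
        body = (
            func("==", func("shape", var("x0")), lit(_shape_lit(rng)))
            if p.endswith("shape")
            else func("==", func("legs", var("x0")), lit(_legs_lit(rng)))
        )
        return func(quant, func("map", func("lambda", var("x0"), body), _set_node(rng, weights)))
    if p in ("bool_all_same_shape", "bool_all_same_legs", "bool_all_diff_shape", "bool_all_diff_legs"):
        fn = "all_same" if "same" in p else "all_different"
        feat = "shape" if p.endswith("shape") else "legs"
        return func(fn, func("map", func("lambda", var("x0"), func(feat, var("x0"))), _set_node(rng, weights)))
    if p == "bool_gt":
        a, b = _two_colors(rng)
        return func(">", func("legs", lit(a)), func("legs", lit(b)))
    if p == "bool_not":
        return func("not", _sample_boolean(rng, weights, depth - 1))
    if p in ("bool_and", "bool_or"):
        # conjuncts drawn from non-recursive boolean forms to keep depth bounded
        flat = {**weights, "bool_not": 0, "bool_and": 0, "bool_or": 0}
        return func(p[5:], _sample_boolean(rng, flat, depth - 1), _sample_boolean(rng, flat, depth - 1))
    raise AssertionError(p)


def sample_program(
    weights: dict[str, float] | None = None,
    max_depth: int = 6,
    rng: np.random.Generator | int | None = None,
) -> QuestionProgram:
    """Sample a type-correct question program from the probabilistic grammar.

    Same seed, same program.  Raises :class:`UnsatisfiableDepthError` if the
    depth bound cannot accommodate any production.
    """
    weights = {**DEFAULT_WEIGHTS, **(weights or {})}
    if any(w < 0 for w in weights.values()):
        raise ValueError("production weights must be nonnegative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if max_depth < 2:
        raise UnsatisfiableDepthError("max_depth must be at least 2")
    roots = [n for n in ("root_boolean", "root_number", "root_shape") if weights.get(n, 0) > 0]
    root = _pick(rng, weights, roots)
    if root == "root_shape" or max_depth < 3:
        return program_from_node(func("shape", lit(_color(rng))))
    if root == "root_number":
        return program_from_node(_sample_number(rng, weights, max_depth))
    return program_from_node(_sample_boolean(rng, weights, max_depth))


def enumerate_simple_programs(max_functions: int | None = None):
    """A systematic battery of small question programs.

    Covers every form the grammar types at up to five function nodes:
    single-feature queries, literal and cross-monster comparisons, pairwise
    sums, aggregate same/different questions, quantified predicates, and
    counting questions.  Returns ``[(program, total_functions), ...]``;
    used to decide whether a target question is more complex than needed
    for a trial array.
    """
    full_set = func("set", lit("Blue"), lit("Red"), lit("Purple"))
    out = []
    for c in COLORS:
        out.append(func("shape", lit(c)))
        out.append(func("legs", lit(c)))
    for c in COLORS:
        for s in SHAPES:
            out.append(func("==", func("shape", lit(c)), lit(s)))
        for n in (1, 2, 3):
            out.append(func("==", func("legs", lit(c)), lit(n)))
    for a, b in itertools.combinations(COLORS, 2):
        out.append(func("==", func("shape", lit(a)), func("shape", lit(b))))
        out.append(func("==", func("legs", lit(a)), func("legs", lit(b))))
        out.append(func("+", func("legs", lit(a)), func("legs", lit(b))))
    out.append(func("+", *(func("legs", lit(c)) for c in COLORS)))
    for fn in ("all_same", "all_different"):
        for feat in ("shape", "legs"):
            out.append(func(fn, func("map", func("lambda", var("x0"), func(feat, var("x0"))), full_set)))
    out.append(func("+", func("map", func("lambda", var("x0"), func("legs", var("x0"))), full_set)))
    for quant in ("any", "all", "+"):
        for s in SHAPES:
            body = func("==", func("shape", var("x0")), lit(s))
            out.append(func(quant, func("map", func("lambda", var("x0"), body), full_set)))
        for n in (1, 2, 3):
            body = func("==", func("legs", var("x0")), lit(n))
            out.append(func(quant, func("map", func("lambda", var("x0"), body), full_set)))
    programs = []
    for node in out:
        prog = program_from_node(node)
        from .language import complexity_metrics

        _, total = complexity_metrics(prog)
        if max_functions is None or total <= max_functions:
            programs.append((prog, total))
    return programs
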