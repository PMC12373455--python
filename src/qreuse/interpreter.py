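"""Executing question programs against complete worlds.

A type-checked program is compiled once into a closure over the compact
world tuple ``((head, legs), ...)`` (Blue, Red, Purple order), so scoring a
question across a whole hypothesis space is cheap.  Evaluation is pure and
total on type-checked input: the dynamic answer type always equals the
static root type.  Booleans coerce to 0/1 inside ``+`` only.
"""

from __future__ import annotations

from functools import lru_cache

from .domain import COLORS, World
from .language import ProgramNode, QuestionProgram

_COLOR_INDEX = {c: i for i, c in enumerate(COLORS)}

_ANSWER_WORDS = {True: "yes", False: "no"}


def answer_word(value) -> str:
    """Serialize an answer to its lowercase one-word form."""
    if isinstance(value, bool):
        return _ANSWER_WORDS[value]
    return str(value).lower()


def _compile(node: ProgramNode):
    """Compile a node to ``f(world_tuple, env) -> value``."""
    if node.kind == "literal":
        if node.label in _COLOR_INDEX:
            idx = _COLOR_INDEX[node.label]
            return lambda w, env: idx
        value = int(node.label) if node.label.isdigit() else node.label
        return lambda w, env: value
    if node.kind == "variable":
        name = node.label
        return lambda w, env: env[name]

    name = node.label
    if name == "lambda":
        v, body = node.children
        body_fn = _compile(body)
        vname = v.label
        def fn(w, env):
            return lambda m: body_fn(w, {**env, vname: m})
        return fn

    args = [_compile(c) for c in node.children]

    if name == "shape":
        (a,) = args
        return lambda w, env: w[a(w, env)][0]
    if name == "legs":
        (a,) = args
        return lambda w, env: w[a(w, env)][1]
    if name == "==":
        a, b = args
        return lambda w, env: a(w, env) == b(w, env)
    if name == "+":
        if len(args) == 1:
            (a,) = args
            return lambda w, env: int(sum(a(w, env)))
        return lambda w, env: int(sum(f(w, env) for f in args))
    if name == ">":
        a, b = args
        return lambda w, env: a(w, env) > b(w, env)
    if name == "<":
        a, b = args
        return lambda w, env: a(w, env) < b(w, env)
    if name == "and":
        return lambda w, env: all(f(w, env) for f in args)
    if name == "or":
        return lambda w, env: any(f(w, env) for f in args)
    if name == "not":
        (a,) = args
        return lambda w, env: not a(w, env)
    if name == "set":
        # members are color literals; compiled to monster indices
        return lambda w, env: tuple(f(w, env) for f in args)
    if name == "map":
        fn, members = args
        return lambda w, env: tuple(fn(w, env)(m) for m in members(w, env))
    if name == "any":
        (a,) = args
        return lambda w, env: any(a(w, env))
    if name == "all":
        (a,) = args
        return lambda w, env: all(a(w, env))
    if name == "all_same":
        (a,) = args
        return lambda w, env: len(set(a(w, env))) == 1
    if name == "all_different":
        (a,) = args
        values = a
        return lambda w, env: len(set(values(w, env))) == len(values(w, env))
    raise ValueError(f"cannot compile unknown function {name!r}")


@lru_cache(maxsize=65536)
def _compiled_by_key(key: str):
    from .language import parse

    return _compile(parse(key).root)


def compile_program(program: QuestionProgram):
    """A callable evaluating the program on a world tuple; cached by identity key."""
    return _compiled_by_key(program.key)


def evaluate(program: QuestionProgram, world: World):
    """One-word answer of ``program`` on the complete ``world``.

    Returns a Python bool, int, or feature string; use :func:`answer_word`
    for the serialized lowercase form.
    """
    fn = compile_program(program)
    return fn(world.as_tuple(), {})
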