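"""Deterministic standardized English renderings of question programs.

Every distinct program gets exactly one canonical English question; two
programs sharing a template render to sentences differing only in the
parameter words.  Text-based similarity is always computed over these
standardized renderings, never over participants' raw wording, so
differences in expression cannot masquerade as differences in content.

Common question forms get idiomatic phrasings; anything else falls back to
a compositional rendering that is stilted but deterministic.
"""

from __future__ import annotations

from .domain import COLORS
from .language import ProgramNode, QuestionProgram

_NUMBER_WORDS = ("zero", "one", "two", "three", "four", "five", "six", "seven", "eight", "nine")


def _color(node: ProgramNode) -> str:
    return node.label.lower()


def _shape(node: ProgramNode) -> str:
    return node.label.lower()


def _numword(node: ProgramNode) -> str:
    return _NUMBER_WORDS[int(node.label)]


def _legs_phrase(node: ProgramNode) -> str:
    n = int(node.label)
    return f"{_NUMBER_WORDS[n]} leg" + ("" if n == 1 else "s")


def _is(node: ProgramNode, label: str, nargs: int | None = None) -> bool:
    return (
        node.kind == "function"
        and node.label == label
        and (nargs is None or len(node.children) == nargs)
    )


def _is_color(node: ProgramNode) -> bool:
    return node.kind == "literal" and node.label in COLORS


def _set_phrase(node: ProgramNode) -> str:
    members = [c.label for c in node.children]
    if set(members) == set(COLORS):
        return "all the monsters"
    names = [m.lower() for m in members]
    return "the " + " and ".join(names) + " monsters"


def _set_of_phrase(node: ProgramNode) -> str:
    """Subject form for counting questions ('monsters' / 'the blue and red monsters')."""
    members = [c.label for c in node.children]
    if set(members) == set(COLORS):
        return "monsters"
    return "of " + _set_phrase(node)


def _mapped(node: ProgramNode):
    """Decompose (f (map (lambda v body) set)) -> (f, v, body, set) or None."""
    if node.kind != "function" or len(node.children) != 1:
        return None
    inner = node.children[0]
    if not _is(inner, "map", 2):
        return None
    lam, members = inner.children
    if not _is(lam, "lambda", 2) or not _is(members, "set"):
        return None
    v, body = lam.children
    return node.label, v, body, members


def _predicate_phrase(body: ProgramNode, v: ProgramNode) -> str | None:
    """'have a square head' / 'have two legs' for simple lambda bodies."""
    if _is(body, "==", 2):
        a, b = body.children
        if _is(a, "shape", 1) and a.children[0].label == v.label and b.kind == "literal":
            return f"have a {_shape(b)} head"
        if _is(a, "legs", 1) and a.children[0].label == v.label and b.kind == "literal":
            return f"have {_legs_phrase(b)}"
    return None


def _render_special(node: ProgramNode) -> str | None:
    if _is(node, "shape", 1) and _is_color(node.children[0]):
        return f"What shape is the {_color(node.children[0])} monster's head?"
    if _is(node, "legs", 1) and _is_color(node.children[0]):
        return f"How many legs does the {_color(node.children[0])} monster have?"

    if _is(node, "==", 2):
        a, b = node.children
        if _is(a, "shape", 1) and _is_color(a.children[0]) and b.kind == "literal":
            return f"Does the {_color(a.children[0])} monster have a {_shape(b)} head?"
        if _is(a, "legs", 1) and _is_color(a.children[0]) and b.kind == "literal":
            return f"Does the {_color(a.children[0])} monster have {_legs_phrase(b)}?"
        if _is(a, "shape", 1) and _is(b, "shape", 1) and _is_color(a.children[0]) and _is_color(b.children[0]):
            return (
                f"Is the {_color(a.children[0])} monster's head the same shape as "
                f"the {_color(b.children[0])} monster's head?"
            )
        if _is(a, "legs", 1) and _is(b, "legs", 1) and _is_color(a.children[0]) and _is_color(b.children[0]):
            return (
                f"Does the {_color(a.children[0])} monster have the same number of legs as "
                f"the {_color(b.children[0])} monster?"
            )

    if _is(node, "+") and len(node.children) >= 2 and all(
        _is(c, "legs", 1) and _is_color(c.children[0]) for c in node.children
    ):
        colors = [c.children[0].label for c in node.children]
        if set(colors) == set(COLORS) and len(colors) == 3:
            return "How many legs do all the monsters have combined together?"
        names = " and ".join(c.lower() for c in colors)
        return f"How many legs do the {names} monsters have combined?"

    m = _mapped(node)
    if m is not None:
        fname, v, body, members = m
        pred = _predicate_phrase(body, v)
        if fname == "+" and pred is not None:
            return f"How many {_set_of_phrase(members)} {pred}?"
        if fname == "+" and _is(body, "legs", 1) and body.children[0].label == v.label:
            if set(c.label for c in members.children) == set(COLORS):
                return "How many legs do all the monsters have combined together?"
            names = " and ".join(c.label.lower() for c in members.children)
            return f"How many legs do the {names} monsters have combined?"
        if fname == "all" and pred is not None:
            return f"Do {_set_phrase(members)} {pred}?"
        if fname == "any" and pred is not None:
            group = _set_phrase(members)
            group = "the monsters" if group == "all the monsters" else group
            return f"Do any of {group} {pred}?"
        if fname in ("all_same", "all_different"):
            same = "the same" if fname == "all_same" else "a different"
            if _is(body, "shape", 1) and body.children[0].label == v.label:
                return f"Do {_set_phrase(members)} have {same} shape head?"
            if _is(body, "legs", 1) and body.children[0].label == v.label:
                return f"Do {_set_phrase(members)} have {same} number of legs?"
    return None


# --- compositional fallback -------------------------------------------------

def _noun(node: ProgramNode) -> str:
    """Noun phrase for a value-typed expression."""
    if node.kind == "literal":
        if node.label.isdigit():
            return _NUMBER_WORDS[int(node.label)]
        return node.label.lower()
    if node.kind == "variable":
        return "that monster"
    if _is(node, "shape", 1):
        return f"the shape of {_noun_ref(node.children[0])}'s head"
    if _is(node, "legs", 1):
        return f"the number of legs {_noun_ref(node.children[0])} has"
    if _is(node, "+"):
        m = _mapped(node)
        if m is not None:
            _, v, body, members = m
            return f"the number of {_set_of_phrase(members)} that {_clause(body)}"
        return "the sum of " + " and ".join(_noun(c) for c in node.children)
    return _clause(node)


def _noun_ref(node: ProgramNode) -> str:
    if _is_color(node):
        return f"the {node.label.lower()} monster"
    return "that monster"


def _clause(node: ProgramNode) -> str:
    """Declarative clause for a boolean-typed expression."""
    if _is(node, "==", 2):
        a, b = node.children
        return f"{_noun(a)} equals {_noun(b)}"
    if _is(node, ">", 2):
        a, b = node.children
        return f"{_noun(a)} is greater than {_noun(b)}"
    if _is(node, "<", 2):
        a, b = node.children
        return f"{_noun(a)} is less than {_noun(b)}"
    if _is(node, "not", 1):
        return f"it is not the case that {_clause(node.children[0])}"
    if _is(node, "and") or _is(node, "or"):
        joiner = f" {node.label} "
        return joiner.join(_clause(c) for c in node.children)
    m = _mapped(node)
    if m is not None:
        fname, v, body, members = m
        quant = {"any": "at least one of", "all": "each of"}.get(fname)
        if quant is not None:
            return f"for {quant} {_set_phrase(members)}, {_clause(body)}"
        if fname == "all_same":
            return f"{_set_phrase(members)} all share the same value of {_noun(body)}"
        if fname == "all_different":
            return f"{_set_phrase(members)} all have different values of {_noun(body)}"
    return to_fallback_string(node)


def to_fallback_string(node: ProgramNode) -> str:
    from .language import to_string

    return to_string(node)


def render_english(program: QuestionProgram) -> str:
    """The canonical standardized English question for a program."""
    special = _render_special(program.root)
    if special is not None:
        return special
    if program.root_type == "Boolean":
        return f"Is it true that {_clause(program.root)}?"
    return f"What is {_noun(program.root)}?"
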