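"""The task-specific question language.

Questions are typed s-expressions over a small grammar: feature queries
(``shape``, ``legs``), logical and arithmetic primitives, set construction
and higher-order ``map``/``lambda``, and reducers (``any``, ``all``,
``all_same``, ``all_different``, and summing ``+``).  Every well-formed
question has a root type answerable in one word (Boolean, Number, Shape, or
Color).

The function inventory is a minimal closure over the questions the task
elicits; it lives in a grammar table (:func:`grammar_table`) so it can be
extended without touching the checker.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .domain import COLORS, SHAPES

# ---------------------------------------------------------------------------
# Types

BOOLEAN = "Boolean"
NUMBER = "Number"
SHAPE = "Shape"
COLOR = "Color"
MONSTER_REF = "MonsterRef"

#: Root types answerable with a single word.
ANSWERABLE_TYPES = frozenset({BOOLEAN, NUMBER, SHAPE, COLOR})

NUMBER_LITERALS = tuple(range(10))  # sums of legs reach 9

_VARIABLE_RE = re.compile(r"^x\d+$")


def set_of(elem: str) -> tuple[str, str]:
    return ("Set", elem)


class QuestionLanguageError(ValueError):
    """Base class for parse and type errors."""


class ParseError(QuestionLanguageError):
    pass


class TypeCheckError(QuestionLanguageError):
    pass


class UnboundVariableError(TypeCheckError):
    pass


# ---------------------------------------------------------------------------
# Grammar table

# name -> (min_arity, max_arity or None); typing rules live in _check.
FUNCTION_ARITY: dict[str, tuple[int, int | None]] = {
    "shape": (1, 1),
    "legs": (1, 1),
    "==": (2, 2),
    "+": (1, None),
    ">": (2, 2),
    "<": (2, 2),
    "and": (2, None),
    "or": (2, None),
    "not": (1, 1),
    "set": (2, 3),
    "map": (2, 2),
    "lambda": (2, 2),
    "any": (1, 1),
    "all": (1, 1),
    "all_same": (1, 1),
    "all_different": (1, 1),
}


def grammar_table() -> list[dict]:
    """The grammar as a JSON-serializable table (symbol, arity, types)."""
    rows = [
        {"symbol": "shape", "arity": [1, 1], "args": [MONSTER_REF], "returns": SHAPE},
        {"symbol": "legs", "arity": [1, 1], "args": [MONSTER_REF], "returns": NUMBER},
        {"symbol": "==", "arity": [2, 2], "args": ["T", "T (T in {Number, Shape})"], "returns": BOOLEAN},
        {"symbol": "+", "arity": [1, None],
         "args": ["Number|Boolean... (>=2) or one Set of Number|Boolean"], "returns": NUMBER},
        {"symbol": ">", "arity": [2, 2], "args": [NUMBER, NUMBER], "returns": BOOLEAN},
        {"symbol": "<", "arity": [2, 2], "args": [NUMBER, NUMBER], "returns": BOOLEAN},
        {"symbol": "and", "arity": [2, None], "args": ["Boolean..."], "returns": BOOLEAN},
        {"symbol": "or", "arity": [2, None], "args": ["Boolean..."], "returns": BOOLEAN},
        {"symbol": "not", "arity": [1, 1], "args": [BOOLEAN], "returns": BOOLEAN},
        {"symbol": "set", "arity": [2, 3], "args": ["distinct color literals"], "returns": "Set[MonsterRef]"},
        {"symbol": "map", "arity": [2, 2], "args": ["lambda MonsterRef->T", "Set[MonsterRef]"], "returns": "Set[T]"},
        {"symbol": "lambda", "arity": [2, 2], "args": ["variable", "body"], "returns": "MonsterRef->T"},
        {"symbol": "any", "arity": [1, 1], "args": ["Set[Boolean]"], "returns": BOOLEAN},
        {"symbol": "all", "arity": [1, 1], "args": ["Set[Boolean]"], "returns": BOOLEAN},
        {"symbol": "all_same", "arity": [1, 1], "args": ["Set[T] (T in {Number, Shape})"], "returns": BOOLEAN},
        {"symbol": "all_different", "arity": [1, 1], "args": ["Set[T] (T in {Number, Shape})"], "returns": BOOLEAN},
    ]
    return rows


def dump_grammar_table(path) -> None:
    with open(path, "w") as fh:
        json.dump(grammar_table(), fh, indent=2)


# ---------------------------------------------------------------------------
# AST

@dataclass(frozen=True)
class ProgramNode:
    """A node of a question program: a function, literal, or variable."""

    label: str
    kind: str  # "function" | "literal" | "variable"
    children: tuple["ProgramNode", ...] = ()

    def __post_init__(self) -> None:
        if self.kind in ("literal", "variable") and self.children:
            raise ValueError(f"{self.kind} node {self.label!r} cannot have children")

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


def func(label: str, *children: ProgramNode) -> ProgramNode:
    return ProgramNode(label, "function", tuple(children))


def lit(value) -> ProgramNode:
    return ProgramNode(str(value), "literal")


def var(name: str) -> ProgramNode:
    return ProgramNode(name, "variable")


@dataclass(frozen=True)
class QuestionProgram:
    """A type-checked question: an AST plus its (answerable) root type."""

    root: ProgramNode
    root_type: str

    def __str__(self) -> str:
        return to_string(self.root)

    @property
    def key(self) -> str:
        """Canonical identity string (alpha-normalized, whitespace-normal)."""
        return to_string(alpha_normalize(self.root))


# ---------------------------------------------------------------------------
# Parser / printer

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[str]:
    # the typeset "= =" is a single equality operator
    text = re.sub(r"=\s+=", "==", text)
    return _TOKEN_RE.findall(text)


def _classify_atom(token: str) -> ProgramNode:
    if token in COLORS or token in SHAPES:
        return lit(token)
    if token.isdigit():
        n = int(token)
        if n not in NUMBER_LITERALS:
            raise ParseError(f"number literal {n} outside 0-9")
        return lit(n)
    if _VARIABLE_RE.match(token):
        return var(token)
    raise ParseError(f"unknown symbol {token!r}")


def _parse_tokens(tokens: list[str], pos: int) -> tuple[ProgramNode, int]:
    if pos >= len(tokens):
        raise ParseError("unexpected end of input")
    tok = tokens[pos]
    if tok == ")":
        raise ParseError("unexpected ')'")
    if tok != "(":
        return _classify_atom(tok), pos + 1
    pos += 1
    if pos >= len(tokens):
        raise ParseError("unbalanced parentheses")
    head = tokens[pos]
    if head in ("(", ")"):
        raise ParseError("expected a function symbol after '('")
    if head not in FUNCTION_ARITY:
        raise ParseError(f"unknown function {head!r}")
    pos += 1
    children: list[ProgramNode] = []
    while pos < len(tokens) and tokens[pos] != ")":
        child, pos = _parse_tokens(tokens, pos)
        children.append(child)
    if pos >= len(tokens):
        raise ParseError("unbalanced parentheses")
    lo, hi = FUNCTION_ARITY[head]
    if len(children) < lo or (hi is not None and len(children) > hi):
        raise ParseError(f"{head} takes {lo}..{hi if hi is not None else 'n'} arguments, got {len(children)}")
    return ProgramNode(head, "function", tuple(children)), pos + 1


def parse(text: str) -> QuestionProgram:
    """Parse a parenthesized s-expression into a type-checked program."""
    tokens = _tokenize(text)
    if not tokens:
        raise ParseError("empty input")
    node, pos = _parse_tokens(tokens, 0)
    if pos != len(tokens):
        raise ParseError("trailing input after program")
    return program_from_node(node)


def to_string(node: ProgramNode) -> str:
    if node.kind != "function":
        return node.label
    inner = " ".join(to_string(c) for c in node.children)
    return f"({node.label} {inner})"


# ---------------------------------------------------------------------------
# Type checking

def _check(node: ProgramNode, env: dict[str, str]):
    if node.kind == "literal":
        if node.label in COLORS:
            return MONSTER_REF
        if node.label in SHAPES:
            return SHAPE
        return NUMBER
    if node.kind == "variable":
        if node.label not in env:
            raise UnboundVariableError(f"unbound variable {node.label}")
        return env[node.label]

    name, args = node.label, node.children
    if name == "lambda":
        v, body = args
        if v.kind != "variable":
            raise TypeCheckError("lambda binder must be a variable")
        body_type = _check(body, {**env, v.label: MONSTER_REF})
        return ("Function", MONSTER_REF, body_type)

    arg_types = [_check(a, env) for a in args]

    if name in ("shape", "legs"):
        if arg_types != [MONSTER_REF]:
            raise TypeCheckError(f"{name} expects a monster reference, got {arg_types}")
        return SHAPE if name == "shape" else NUMBER
    if name == "==":
        t1, t2 = arg_types
        if t1 != t2 or t1 not in (NUMBER, SHAPE):
            raise TypeCheckError(f"cannot compare {t1} with {t2}")
        return BOOLEAN
    if name == "+":
        if len(arg_types) == 1:
            t = arg_types[0]
            if not (isinstance(t, tuple) and t[0] == "Set" and t[1] in (NUMBER, BOOLEAN)):
                raise TypeCheckError("unary + sums a set of numbers or booleans")
            return NUMBER
        for t in arg_types:
            if t not in (NUMBER, BOOLEAN):  # booleans coerce to 0/1 inside + only
                raise TypeCheckError(f"+ cannot add a {t}")
        return NUMBER
    if name in (">", "<"):
        if arg_types != [NUMBER, NUMBER]:
            raise TypeCheckError(f"{name} compares numbers, got {arg_types}")
        return BOOLEAN
    if name in ("and", "or"):
        if any(t != BOOLEAN for t in arg_types):
            raise TypeCheckError(f"{name} expects booleans, got {arg_types}")
        return BOOLEAN
    if name == "not":
        if arg_types != [BOOLEAN]:
            raise TypeCheckError(f"not expects a boolean, got {arg_types}")
        return BOOLEAN
    if name == "set":
        labels = [a.label for a in args]
        if any(a.kind != "literal" or a.label not in COLORS for a in args):
            raise TypeCheckError("set takes color literals")
        if len(set(labels)) != len(labels):
            raise TypeCheckError("set members must be distinct")
        return set_of(MONSTER_REF)
    if name == "map":
        fn_t, set_t = arg_types
        if not (isinstance(fn_t, tuple) and fn_t[0] == "Function"):
            raise TypeCheckError("map expects a lambda as first argument")
        if set_t != set_of(MONSTER_REF):
            raise TypeCheckError("map expects a set of monsters as second argument")
        return set_of(fn_t[2])
    if name in ("any", "all"):
        t = arg_types[0]
        if t != set_of(BOOLEAN):
            raise TypeCheckError(f"{name} expects a set of booleans, got {t}")
        return BOOLEAN
    if name in ("all_same", "all_different"):
        t = arg_types[0]
        if not (isinstance(t, tuple) and t[0] == "Set" and t[1] in (NUMBER, SHAPE)):
            raise TypeCheckError(f"{name} expects a set of feature values, got {t}")
        return BOOLEAN
    raise TypeCheckError(f"unknown function {name!r}")


def type_check(node: ProgramNode) -> str:
    """Type a program rooted at ``node``; enforce the one-word-answer rule."""
    root_type = _check(node, {})
    if root_type not in ANSWERABLE_TYPES:
        raise TypeCheckError(f"root type {root_type} is not answerable in one word")
    return root_type


def program_from_node(node: ProgramNode) -> QuestionProgram:
    return QuestionProgram(root=node, root_type=type_check(node))


# ---------------------------------------------------------------------------
# Alpha normalization and templates

def alpha_normalize(node: ProgramNode) -> ProgramNode:
    """Rename lambda-bound variables to x0, x1, ... by first binding occurrence."""
    counter = [0]

    def rec(n: ProgramNode, ren: dict[str, str]) -> ProgramNode:
        if n.kind == "variable":
            return var(ren.get(n.label, n.label))
        if n.kind == "literal":
            return n
        if n.label == "lambda":
            v, body = n.children
            new_name = f"x{counter[0]}"
            counter[0] += 1
            return func("lambda", var(new_name), rec(body, {**ren, v.label: new_name}))
        return ProgramNode(n.label, "function", tuple(rec(c, ren) for c in n.children))

    return rec(node, {})


_SLOT_LABELS = {MONSTER_REF: "<MonsterRef>", SHAPE: "<Shape>", NUMBER: "<Number>"}


@dataclass(frozen=True)
class Template:
    """A question program with typed terminal parameters abstracted to slots.

    Two programs share a template iff their function identity and
    configuration agree and corresponding parameters share a type.  Color
    literals inside ``set`` are part of the configuration (they name *which*
    monsters the question quantifies over), not free slots.
    """

    root: ProgramNode = field(compare=False)
    key: str

    def __str__(self) -> str:
        return self.key


def _slotted(node: ProgramNode, in_set: bool) -> ProgramNode:
    if node.kind == "literal":
        if in_set or node.label in _SLOT_LABELS.values():
            return node
        if node.label in COLORS:
            return ProgramNode(_SLOT_LABELS[MONSTER_REF], "literal")
        if node.label in SHAPES:
            return ProgramNode(_SLOT_LABELS[SHAPE], "literal")
        return ProgramNode(_SLOT_LABELS[NUMBER], "literal")
    if node.kind == "variable":
        return node
    return ProgramNode(
        node.label, "function",
        tuple(_slotted(c, node.label == "set") for c in node.children),
    )


def extract_template(program: QuestionProgram) -> Template:
    """Abstract a program's typed terminal parameters to slots."""
    root = _slotted(alpha_normalize(program.root), in_set=False)
    return Template(root=root, key=to_string(root) if root.kind == "function" else root.label)


def complexity_metrics(program: QuestionProgram) -> tuple[int, int]:
    """(unique function count, total function count), excluding ``lambda``."""
    names = [n.label for n in program.root.walk() if n.kind == "function" and n.label != "lambda"]
    return len(set(names)), len(names)
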