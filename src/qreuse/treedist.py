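"""Ordered tree edit distance with typed free relabels (Zhang-Shasha).

Grammar-based similarity between question programs is the minimum number of
node insertions, deletions, and relabelings turning one program tree into
the other, computed with the Zhang-Shasha dynamic program over keyroots.
The one nonstandard cost: relabeling a terminal argument to another
argument of the *same type* is free (changing "which color" or "which
number" a question asks about does not make it a different question).

Trees here are generic labeled ordered trees (:class:`LabeledTree`); the
conversion from question programs attaches the type tags that drive the
free-relabel rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .domain import COLORS, SHAPES
from .language import MONSTER_REF, NUMBER, SHAPE, QuestionProgram, alpha_normalize


@dataclass(frozen=True)
class LabeledTree:
    """A finite rooted ordered tree with labeled nodes.

    ``arg_type`` tags terminal *arguments*: two terminals with equal,
    non-None tags relabel at zero cost.  Function (internal) nodes carry no
    tag and always cost 1 to relabel.
    """

    label: str
    children: tuple["LabeledTree", ...] = ()
    arg_type: str | None = None

    @property
    def size(self) -> int:
        return 1 + sum(c.size for c in self.children)


def tree(label: str, *children: LabeledTree, arg_type: str | None = None) -> LabeledTree:
    return LabeledTree(label, tuple(children), arg_type)


def program_tree(program: QuestionProgram) -> LabeledTree:
    """Convert a program to a labeled tree with typed terminal arguments.

    Lambda variables are alpha-normalized first and deliberately *not*
    tagged: a bound variable is part of the question's configuration, not a
    free parameter, so swapping a variable for a color costs an edit.  This
    makes distance 0 coincide exactly with template equality.
    """
    root = alpha_normalize(program.root)

    def rec(node, in_set: bool) -> LabeledTree:
        if node.kind == "function":
            return LabeledTree(
                node.label, tuple(rec(c, node.label == "set") for c in node.children)
            )
        if node.kind == "variable" or in_set:
            # variables and set members are configuration, not free parameters
            return LabeledTree(node.label)
        if node.label in COLORS:
            return LabeledTree(node.label, arg_type=MONSTER_REF)
        if node.label in SHAPES:
            return LabeledTree(node.label, arg_type=SHAPE)
        return LabeledTree(node.label, arg_type=NUMBER)

    return rec(root, False)


def relabel_cost(a: LabeledTree, b: LabeledTree) -> int:
    if a.label == b.label:
        return 0
    if a.arg_type is not None and a.arg_type == b.arg_type:
        return 0  # same-type argument substitution is free
    return 1


def _postorder(root: LabeledTree) -> tuple[list[LabeledTree], list[int]]:
    """Postorder nodes and leftmost-leaf-descendant indices (Zhang-Shasha)."""
    nodes: list[LabeledTree] = []
    lld: list[int] = []

    def rec(node: LabeledTree) -> int:
        if not node.children:
            nodes.append(node)
            lld.append(len(nodes) - 1)
            return len(nodes) - 1
        first = None
        for c in node.children:
            idx = rec(c)
            if first is None:
                first = lld[idx]
        nodes.append(node)
        lld.append(first)
        return len(nodes) - 1

    rec(root)
    return nodes, lld


def _keyroots(lld: list[int]) -> list[int]:
    seen: dict[int, int] = {}
    for i, l in enumerate(lld):
        seen[l] = i  # last (highest) node with each lld is a keyroot
    return sorted(seen.values())


def tree_edit_distance(a: LabeledTree, b: LabeledTree) -> int:
    """Zhang-Shasha optimal edit-mapping cost between two ordered trees.

    Unit insert/delete/relabel, except same-type terminal-argument
    relabels, which are free.
    """
    an, alld = _postorder(a)
    bn, blld = _postorder(b)
    na, nb = len(an), len(bn)
    td = [[0] * nb for _ in range(na)]

    for i in _keyroots(alld):
        for j in _keyroots(blld):
            # forest distance between a[lld(i)..i] and b[lld(j)..j]
            ioff, joff = alld[i], blld[j]
            m, n = i - ioff + 2, j - joff + 2
            fd = [[0] * n for _ in range(m)]
            for x in range(1, m):
                fd[x][0] = fd[x - 1][0] + 1  # delete
            for y in range(1, n):
                fd[0][y] = fd[0][y - 1] + 1  # insert
            for x in range(1, m):
                for y in range(1, n):
                    ai, bj = x + ioff - 1, y + joff - 1
                    if alld[ai] == alld[i] and blld[bj] == blld[j]:
                        cost = relabel_cost(an[ai], bn[bj])
                        fd[x][y] = min(
                            fd[x - 1][y] + 1,
                            fd[x][y - 1] + 1,
                            fd[x - 1][y - 1] + cost,
                        )
                        td[ai][bj] = fd[x][y]
                    else:
                        p = alld[ai] - ioff
                        q = blld[bj] - joff
                        fd[x][y] = min(
                            fd[x - 1][y] + 1,
                            fd[x][y - 1] + 1,
                            fd[p][q] + td[ai][bj],
                        )
    return td[na - 1][nb - 1]


def program_distance(a: QuestionProgram, b: QuestionProgram) -> int:
    return tree_edit_distance(program_tree(a), program_tree(b))
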