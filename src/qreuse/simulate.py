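"""Generative model of question-asking participants.

Each simulated participant completes a sequence of trials.  On each trial
they either *reuse* an earlier question template (probability
``rho_reuse``, given at least one prior question), optionally preferring
templates that are informative right now (softmax with weight
``beta_eig`` per bit of EIG), or *innovate* — by editing a prior question
(probability ``kappa_recombine``; local, type-respecting tree edits) or by
sampling a fresh question from the probabilistic grammar.  Exposure-design
participants start with the target question in memory, as if a confederate
had just asked it.

The generator is a test harness for the analysis pipeline, not a cognitive
model: it produces datasets with the statistical structure the analyses
assume (known reuse probability, recombination tendency, and
informativeness-sensitivity), so that the estimators can be validated by
parameter recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .dataset import QuestionDataset, QuestionRecord
from .domain import COLORS, SHAPES, TrialArray, canonical_arrays
from .information import expected_information_gain
from .language import (
    ProgramNode,
    QuestionProgram,
    Template,
    TypeCheckError,
    extract_template,
    func,
    lit,
    program_from_node,
    type_check,
)
from .reuse import TARGET_PROGRAMS, rank_arrays_for_target
from .sampling import sample_program


@dataclass(frozen=True)
class AgentParams:
    """Tunable parameters of the simulated question asker.

    rho_reuse : probability of attempting template reuse when at least one
        prior question exists.
    kappa_recombine : probability that an innovated question is produced by
        editing a prior question rather than fresh grammar sampling.
    n_edits : number of random tree edits applied when recombining.
    beta_eig : softmax sensitivity (per bit) toward reusing templates with
        higher EIG on the current trial; 0 = context-blind reuse.
    informative_rho_multiplier : optional multiplier on rho_reuse for
        previously-informative exposure participants (1.0 = the
        previous-quality manipulation is a label only).
    drop_rate : probability a trial yields no analyzable question.
    """

    rho_reuse: float = 0.35
    kappa_recombine: float = 0.30
    n_edits: int = 1
    beta_eig: float = 1.0
    grammar_weights: dict | None = None
    max_depth: int = 6
    informative_rho_multiplier: float = 1.0
    drop_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho_reuse <= 1 and 0 <= self.kappa_recombine <= 1):
            raise ValueError("rho_reuse and kappa_recombine must lie in [0, 1]")
        if self.beta_eig < 0 or self.n_edits < 1:
            raise ValueError("beta_eig must be >= 0 and n_edits >= 1")
        if not (0 <= self.drop_rate < 1):
            raise ValueError("drop_rate must lie in [0, 1)")


@dataclass(frozen=True)
class StudyDesign:
    """Which trials which participants complete.

    ``participant_specs`` is a list of dicts with keys ``participant_id``,
    ``array_ids`` (trial order), and optional condition labels
    (``exposure``, ``previous_quality``, ``target_id``, ``trial_types``).
    Use :meth:`study1` / :meth:`study2` for the two canonical layouts.
    """

    arrays: dict[str, TrialArray]
    participant_specs: tuple = ()

    def __post_init__(self) -> None:
        for spec in self.participant_specs:
            if len(spec["array_ids"]) < 1:
                raise ValueError("each participant needs at least one trial")
            if spec.get("exposure") == "exposure" and spec.get("target_id") not in TARGET_PROGRAMS:
                raise ValueError("exposure design requires a valid target question")

    @classmethod
    def study1(
        cls,
        n_participants: int = 40,
        trials_per_participant: int = 4,
        array_seed: int = 0,
        assignment_seed: int = 0,
        n_arrays: int | None = None,
    ) -> "StudyDesign":
        """Participants each complete ``trials_per_participant`` trials drawn
        without replacement from the 14 canonical trial arrays (or the first
        ``n_arrays`` of them, for small designs needing denser per-array
        question pools)."""
        arrays = canonical_arrays(array_seed)
        if n_arrays is not None:
            arrays = dict(list(arrays.items())[:n_arrays])
        ids = list(arrays)
        rng = np.random.default_rng(assignment_seed)
        specs = []
        for p in range(n_participants):
            chosen = rng.choice(len(ids), size=trials_per_participant, replace=False)
            specs.append(
                {"participant_id": f"P{p:03d}", "array_ids": [ids[i] for i in chosen]}
            )
        return cls(arrays=arrays, participant_specs=tuple(specs))

    @classmethod
    def study2(
        cls,
        n_per_cell: int = 60,
        array_seed: int = 0,
        assignment_seed: int = 0,
        target_ids: tuple[str, ...] = ("square_head_count", "combined_legs"),
    ) -> "StudyDesign":
        """Exposure x previous-quality x target design over the four trial types.

        For each target question the best / medium / worst / too-complex
        arrays are selected from the canonical 14 by the target's EIG; every
        participant completes the four trial types in random order.
        """
        arrays = canonical_arrays(array_seed)
        assignments = {}
        for t in target_ids:
            ranking = rank_arrays_for_target(TARGET_PROGRAMS[t], arrays.values())
            by_type = ranking.dropna(subset=["trial_type"]).set_index("trial_type")["array_id"]
            missing = [tt for tt in ("best", "medium", "worst", "too_complex") if tt not in by_type]
            if missing:
                raise ValueError(f"target {t!r}: no candidate array for trial type(s) {missing}")
            assignments[t] = by_type.to_dict()
        rng = np.random.default_rng(assignment_seed)
        specs = []
        p = 0
        for exposure, quality, target in itertools.product(
            ("exposure", "no_exposure"), ("informative", "uninformative"), target_ids
        ):
            for _ in range(n_per_cell):
                order = [
                    ("best", "medium", "worst", "too_complex")[i] for i in rng.permutation(4)
                ]
                specs.append(
                    {
                        "participant_id": f"P{p:03d}",
                        "array_ids": [assignments[target][tt] for tt in order],
                        "trial_types": order,
                        "exposure": exposure,
                        "previous_quality": quality,
                        "target_id": target,
                    }
                )
                p += 1
        return cls(arrays=arrays, participant_specs=tuple(specs))


# ---------------------------------------------------------------------------
# Template instantiation and random edits

_SLOT_FILLERS = {
    "<MonsterRef>": lambda rng: lit(COLORS[rng.integers(3)]),
    "<Shape>": lambda rng: lit(SHAPES[rng.integers(2)]),
    # Number slots refilled from the leg range, keeping reused questions sensible
    "<Number>": lambda rng: lit(int(rng.integers(1, 4))),
}


def instantiate_template(template: Template, rng: np.random.Generator) -> QuestionProgram:
    """Fill a template's typed slots with uniformly sampled parameters."""

    def rec(node: ProgramNode) -> ProgramNode:
        if node.kind == "literal" and node.label in _SLOT_FILLERS:
            return _SLOT_FILLERS[node.label](rng)
        if node.kind == "function":
            return ProgramNode(node.label, "function", tuple(rec(c) for c in node.children))
        return node

    return program_from_node(rec(template.root))


_FUNCTION_SWAPS = {
    "any": ["all"], "all": ["any"],
    "all_same": ["all_different"], "all_different": ["all_same"],
    ">": ["<", "=="], "<": [">", "=="], "==": [">", "<"],
    "and": ["or"], "or": ["and"],
}


def _replace_at(root: ProgramNode, path: tuple[int, ...], new: ProgramNode) -> ProgramNode:
    if not path:
        return new
    head, rest = path[0], path[1:]
    children = list(root.children)
    children[head] = _replace_at(children[head], rest, new)
    return ProgramNode(root.label, root.kind, tuple(children))


def _candidate_edits(root: ProgramNode):
    """All single-edit variants of a program tree (before type filtering)."""
    positions: list[tuple[tuple[int, ...], ProgramNode, ProgramNode | None]] = []

    def walk(node: ProgramNode, path: tuple[int, ...], parent: ProgramNode | None):
        positions.append((path, node, parent))
        for i, c in enumerate(node.children):
            walk(c, path + (i,), node)

    walk(root, (), None)
    out = []
    for path, node, parent in positions:
        in_set = parent is not None and parent.label == "set"
        if node.kind == "literal":
            if node.label in COLORS:
                taken = {c.label for c in parent.children} if in_set else set()
                for c in COLORS:
                    if c != node.label and c not in taken:
                        out.append(_replace_at(root, path, lit(c)))
            elif node.label in SHAPES:
                for s in SHAPES:
                    if s != node.label:
                        out.append(_replace_at(root, path, lit(s)))
            else:
                for n in (1, 2, 3):
                    if str(n) != node.label:
                        out.append(_replace_at(root, path, lit(n)))
        elif node.kind == "function":
            for alt in _FUNCTION_SWAPS.get(node.label, ()):
                out.append(_replace_at(root, path, ProgramNode(alt, "function", node.children)))
            # insertions: negate a boolean, add a constant to a number
            out.append(_replace_at(root, path, func("not", node)))
            if node.label in ("legs", "+"):
                out.append(_replace_at(root, path, func("+", node, lit(1))))
            # deletions: splice a child in place of its parent
            for child in node.children:
                if child.kind == "function":
                    out.append(_replace_at(root, path, child))
    return out


def random_tree_edit(
    program: QuestionProgram, rng: np.random.Generator
) -> QuestionProgram:
    """Apply one random type-respecting edit (relabel, insert, or delete).

    The result always type-checks with an answerable root and differs from
    the input program.  Raises ``ValueError`` if no valid edit exists.
    """
    candidates = _candidate_edits(program.root)
    valid = []
    seen = set()
    for node in candidates:
        try:
            edited = program_from_node(node)
        except TypeCheckError:
            continue
        if edited.key != program.key and edited.key not in seen:
            seen.add(edited.key)
            valid.append(edited)
    if not valid:
        raise ValueError(f"no valid edit available for {program}")
    valid.sort(key=lambda p: p.key)
    return valid[rng.integers(len(valid))]


# ---------------------------------------------------------------------------
# Dataset generation

def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


def generate_dataset(
    params: AgentParams, design: StudyDesign, rng: np.random.Generator | int | None = None
) -> QuestionDataset:
    """Simulate a question dataset under the agent model; fully seed-deterministic."""
    rng = np.random.default_rng(params.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    records: list[QuestionRecord] = []
    for spec in design.participant_specs:
        exposure = spec.get("exposure")
        memory: list[QuestionProgram] = []
        if exposure == "exposure":
            memory.append(TARGET_PROGRAMS[spec["target_id"]])
        rho = params.rho_reuse
        if exposure == "exposure" and spec.get("previous_quality") == "informative":
            rho = min(1.0, rho * params.informative_rho_multiplier)
        for t, array_id in enumerate(spec["array_ids"]):
            array = design.arrays[array_id]
            program = _ask(params, rho, memory, array, rng)
            memory.append(program)
            if params.drop_rate > 0 and rng.random() < params.drop_rate:
                continue  # question was invalid/untranscribable; trial dropped
            conditions = {
                k: spec[k] for k in ("exposure", "previous_quality", "target_id") if k in spec
            }
            if "trial_types" in spec:
                conditions["trial_type"] = spec["trial_types"][t]
            records.append(
                QuestionRecord(
                    participant_id=spec["participant_id"],
                    trial_index=t,
                    array_id=array_id,
                    program=program,
                    **conditions,
                )
            )
    return QuestionDataset(records=records, arrays=dict(design.arrays))


def _ask(
    params: AgentParams,
    rho: float,
    memory: list[QuestionProgram],
    array: TrialArray,
    rng: np.random.Generator,
) -> QuestionProgram:
    if memory and rng.random() < rho:
        # reuse: pick a prior template, preferring currently informative ones
        templates: dict[str, Template] = {}
        for prog in memory:
            t = extract_template(prog)
            templates.setdefault(t.key, t)
        candidates = [instantiate_template(t, rng) for t in templates.values()]
        if params.beta_eig > 0 and len(candidates) > 1:
            eig = np.array([expected_information_gain(c, array) for c in candidates])
            probs = _softmax(params.beta_eig * eig)
        else:
            probs = np.full(len(candidates), 1.0 / len(candidates))
        return candidates[rng.choice(len(candidates), p=probs)]
    if memory and rng.random() < params.kappa_recombine:
        base = memory[rng.integers(len(memory))]
        program = base
        try:
            for _ in range(params.n_edits):
                program = random_tree_edit(program, rng)
            return program
        except ValueError:
            pass  # no valid edit; fall through to fresh sampling
    return sample_program(params.grammar_weights, params.max_depth, rng)
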