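"""Grammar-based and text-based question similarity.

Grammar-based similarity rescales tree edit distance to [0, 1]:
``1 - d / norm`` with ``norm`` defaulting to the largest pairwise distance
in the analyzed dataset (so 1 means identical templates, 0 means as far
apart as anything in the data).  Text-based similarity is the cosine
between embeddings of the *standardized* English renderings; the embedding
backend is pluggable, with a deterministic term-frequency fallback that
runs offline.  The fallback approximates — it does not reproduce — results
obtained with a pretrained sentence embedding.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .language import QuestionProgram
from .render import render_english
from .treedist import program_distance


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    measure: str


# ---------------------------------------------------------------------------
# Grammar-based

def grammar_similarity(
    a: QuestionProgram, b: QuestionProgram, norm_constant: float
) -> SimilarityScore:
    """1 - TED/norm, clipped to [0, 1]."""
    if norm_constant <= 0:
        raise ValueError("norm_constant must be positive")
    d = program_distance(a, b)
    return SimilarityScore(float(np.clip(1.0 - d / norm_constant, 0.0, 1.0)), "grammar")


def max_pairwise_distance(programs) -> int:
    """Dataset-wide normalization constant: the largest pairwise TED."""
    progs = list(programs)
    best = 0
    for i in range(len(progs)):
        for j in range(i + 1, len(progs)):
            best = max(best, program_distance(progs[i], progs[j]))
    return best


# ---------------------------------------------------------------------------
# Text-based

_WORD_RE = re.compile(r"[a-z']+")


def _tokens(text: str) -> list[str]:
    return _WORD_RE.findall(text.lower())


class TermFrequencyEmbedder:
    """Deterministic offline embedder: term-frequency vectors over a fixed vocabulary.

    The vocabulary grows as texts are embedded; vectors are padded on
    comparison, so cosine values do not depend on embedding order.
    """

    name = "fallback"

    def __init__(self) -> None:
        self._vocab: dict[str, int] = {}

    def __call__(self, text: str) -> np.ndarray:
        counts = Counter(_tokens(text))
        for w in sorted(counts):
            self._vocab.setdefault(w, len(self._vocab))
        vec = np.zeros(len(self._vocab))
        for w, n in counts.items():
            vec[self._vocab[w]] = n
        return vec


def get_embedder(name: str = "fallback"):
    if name == "fallback":
        return TermFrequencyEmbedder()
    raise ValueError(
        f"unknown embedder {name!r}; pass a callable mapping text to a numeric vector "
        "to use a pretrained sentence-embedding backend"
    )


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    n = max(len(u), len(v))
    u = np.pad(np.asarray(u, dtype=float), (0, n - len(u)))
    v = np.pad(np.asarray(v, dtype=float), (0, n - len(v)))
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-norm embedding")
    return float(u @ v / (nu * nv))


def text_similarity(a: QuestionProgram, b: QuestionProgram, embedder=None) -> SimilarityScore:
    """Cosine similarity of standardized-rendering embeddings, clipped to [0, 1]."""
    embedder = embedder or get_embedder()
    sim = cosine(embedder(render_english(a)), embedder(render_english(b)))
    return SimilarityScore(float(np.clip(sim, 0.0, 1.0)), "text")


# ---------------------------------------------------------------------------
# Pairwise matrices

def pairwise_table(
    programs: dict[str, QuestionProgram],
    norm_constant: float | None = None,
    embedder=None,
) -> pd.DataFrame:
    """All-pairs TED, grammar similarity, and text similarity.

    Returns a tidy frame (id_a, id_b, ted, grammar_sim, text_sim) with the
    norm constant and embedder name attached as ``DataFrame.attrs``.
    """
    ids = list(programs)
    embedder = embedder or get_embedder()
    ted = {}
    for i, ia in enumerate(ids):
        for ib in ids[i + 1:]:
            ted[(ia, ib)] = program_distance(programs[ia], programs[ib])
    if norm_constant is None:
        norm_constant = max(ted.values(), default=0)
    rows = []
    for (ia, ib), d in ted.items():
        gsim = 1.0 if norm_constant == 0 else float(np.clip(1 - d / norm_constant, 0, 1))
        tsim = text_similarity(programs[ia], programs[ib], embedder).value
        rows.append({"id_a": ia, "id_b": ib, "ted": d, "grammar_sim": gsim, "text_sim": tsim})
    out = pd.DataFrame(rows, columns=["id_a", "id_b", "ted", "grammar_sim", "text_sim"])
    out.attrs["norm_constant"] = norm_constant
    out.attrs["embedder"] = getattr(embedder, "name", "custom")
    return out
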