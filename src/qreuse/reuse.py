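"""Reuse and recombination analysis.

*Reuse* is repeating an earlier question template (same functions in the
same configuration, parameters free within type).  *Recombination* is how
similar an innovated (non-reused) question is to the most similar earlier
question.  Both are tested against trial-matched simulated nulls: each
previously-asked question is replaced by a random question drawn from all
questions asked for that same trial array (by any participant), so the null
represents question asking that respects each trial's informational demands
but is independent of one's own history.

The module exposes the individual statistics as functions and wraps the two
study-level analyses as model objects with ``fit()``/``summary()``:

* :class:`AcrossTrialModel` — within-participant reuse/recombination with
  simulated null distributions (the Study-1-style analysis).
* :class:`ExposureModel` — exposure vs. no-exposure effects on
  target-matching and target similarity (the Study-2-style analysis), with
  participant-level bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DatasetError, QuestionDataset, QuestionRecord
from .information import expected_information_gain, max_eig
from .language import QuestionProgram, Template, extract_template, parse, complexity_metrics
from .render import render_english
from .sampling import enumerate_simple_programs
from .similarity import cosine, get_embedder, max_pairwise_distance
from .treedist import program_distance

# ---------------------------------------------------------------------------
# Study-2 target questions

TARGET_PROGRAMS: dict[str, QuestionProgram] = {
    # "How many monsters have a square head?" — head shape is a free slot,
    # so the circle-head variant matches the same template.
    "square_head_count": parse(
        "(+ (map (lambda x0 (== (shape x0) Square)) (set Blue Red Purple)))"
    ),
    # "How many legs do all the monsters have combined together?" — a sum
    # over the full monster set; the template has no free parameters.
    "combined_legs": parse(
        "(+ (map (lambda x0 (legs x0)) (set Blue Red Purple)))"
    ),
}


def target_matching(question: QuestionProgram, target_id: str) -> bool:
    """Does a question share the target question's template?"""
    if target_id not in TARGET_PROGRAMS:
        raise KeyError(f"unknown target_id {target_id!r}; known: {sorted(TARGET_PROGRAMS)}")
    return extract_template(question) == extract_template(TARGET_PROGRAMS[target_id])


# ---------------------------------------------------------------------------
# Record-level statistics

def _ordered_records(dataset: QuestionDataset) -> list[tuple[int, QuestionRecord]]:
    idx = list(range(len(dataset.records)))
    idx.sort(key=lambda i: (dataset.records[i].participant_id, dataset.records[i].trial_index))
    return [(i, dataset.records[i]) for i in idx]


def _priors(dataset: QuestionDataset) -> dict[int, list[int]]:
    """record index -> indices of the same participant's earlier records."""
    out: dict[int, list[int]] = {}
    history: dict[str, list[int]] = {}
    for i, rec in _ordered_records(dataset):
        h = history.setdefault(rec.participant_id, [])
        out[i] = list(h)
        h.append(i)
    return out


def detect_across_trial_reuse(dataset: QuestionDataset) -> dict[int, bool]:
    """Per-record reuse flag: does the template repeat an earlier same-participant one?

    Keys are record indices; records with no valid prior question (each
    participant's first) are absent — they are excluded from reuse
    denominators.
    """
    templates = [extract_template(r.program) for r in dataset.records]
    out = {}
    for i, prior in _priors(dataset).items():
        if prior:
            out[i] = any(templates[i] == templates[j] for j in prior)
    return out


def max_prior_similarity(
    dataset: QuestionDataset,
    measure: str = "grammar",
    norm_constant: float | None = None,
    embedder=None,
) -> dict[int, float]:
    """Max similarity of each innovated question to the participant's earlier questions.

    Records classified as reuse are excluded (recombination is defined for
    innovated questions only), as are records with no prior question.
    """
    sim = _similarity_lookup(dataset, measure, norm_constant, embedder)
    reuse = detect_across_trial_reuse(dataset)
    out = {}
    for i, prior in _priors(dataset).items():
        if prior and not reuse[i]:
            out[i] = max(sim(i, j) for j in prior)
    return out


def template_diversity(records) -> float:
    """Fraction of records whose template occurs exactly once in the group."""
    templates = [
        extract_template(r.program if isinstance(r, QuestionRecord) else r) for r in records
    ]
    if not templates:
        raise ValueError("no records supplied")
    counts: dict[Template, int] = {}
    for t in templates:
        counts[t] = counts.get(t, 0) + 1
    return sum(1 for t in templates if counts[t] == 1) / len(templates)


# ---------------------------------------------------------------------------
# Similarity plumbing (shared by observed statistics and the nulls)

def _unique_programs(dataset: QuestionDataset):
    key_to_pid: dict[str, int] = {}
    programs: list[QuestionProgram] = []
    pid_of_record = []
    for rec in dataset.records:
        k = rec.program.key
        if k not in key_to_pid:
            key_to_pid[k] = len(programs)
            programs.append(rec.program)
        pid_of_record.append(key_to_pid[k])
    return programs, np.array(pid_of_record)


def _similarity_matrix(
    programs, measure: str, norm_constant: float | None, embedder
) -> tuple[np.ndarray, float | None]:
    n = len(programs)
    S = np.eye(n)
    if measure == "grammar":
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = program_distance(programs[i], programs[j])
        if norm_constant is None:
            norm_constant = D.max()
        if norm_constant <= 0:
            return np.ones((n, n)), norm_constant  # all distances zero
        S = np.clip(1.0 - D / norm_constant, 0.0, 1.0)
        np.fill_diagonal(S, 1.0)
        return S, norm_constant
    if measure == "text":
        embedder = embedder or get_embedder()
        vecs = [embedder(render_english(p)) for p in programs]
        for i in range(n):
            for j in range(i + 1, n):
                S[i, j] = S[j, i] = max(0.0, cosine(vecs[i], vecs[j]))
        return S, norm_constant
    raise ValueError(f"unknown measure {measure!r} (expected 'grammar' or 'text')")


def _similarity_lookup(dataset, measure, norm_constant, embedder):
    programs, pid = _unique_programs(dataset)
    if measure == "grammar" and norm_constant is None:
        norm_constant = max_pairwise_distance(programs) or None
        if norm_constant is None:  # all programs share one template
            return lambda i, j: 1.0
    S, _ = _similarity_matrix(programs, measure, norm_constant, embedder)
    return lambda i, j: float(S[pid[i], pid[j]])


# ---------------------------------------------------------------------------
# Simulated null distributions

@dataclass(frozen=True)
class NullDistribution:
    """Observed statistic vs. its trial-matched simulated null."""

    statistic: str
    observed: float
    null_values: np.ndarray
    one_tailed_p: float
    n_sims: int
    n_records: int

    def quantiles(self, qs=(0.025, 0.25, 0.5, 0.75, 0.975)) -> dict[float, float]:
        return {q: float(v) for q, v in zip(qs, np.quantile(self.null_values, qs))}

    def to_json(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "n_sims": self.n_sims,
            "n_records": self.n_records,
            "one_tailed_p": self.one_tailed_p,
            "null_quantiles": {str(k): v for k, v in self.quantiles().items()},
        }


def _one_tailed_p(null_values: np.ndarray, observed: float) -> float:
    k = int(np.sum(null_values >= observed - 1e-12))
    return (k + 1) / (len(null_values) + 1)


def simulate_null(
    dataset: QuestionDataset,
    statistic: str = "reuse_rate",
    n_sims: int = 1000,
    rng: np.random.Generator | int | None = None,
    measure: str = "grammar",
    norm_constant: float | None = None,
    embedder=None,
) -> NullDistribution:
    """Trial-matched simulated null for across-trial reuse or recombination.

    In each of ``n_sims`` simulated datasets, every previously-asked
    question is replaced by a random question drawn from all questions asked
    for that same trial array (any participant; the current question is held
    fixed), and the statistic is recomputed.  For
    ``statistic="mean_recombination"`` the sampled previous questions
    additionally may not match the current question's template (which would
    be reuse, not recombination).  One-tailed p with add-one smoothing,
    extremity direction ">= observed".
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    records = dataset.records
    programs, pid = _unique_programs(dataset)
    templates = [extract_template(p) for p in programs]
    tkeys = {t.key: n for n, t in enumerate(dict.fromkeys(templates).keys())}
    tid_of_program = np.array([tkeys[t.key] for t in templates])
    tid = tid_of_program[pid]

    pools: dict[str, np.ndarray] = {}
    for i, rec in enumerate(records):
        pools.setdefault(rec.array_id, [])
        pools[rec.array_id].append(pid[i])
    pools = {k: np.array(v) for k, v in pools.items()}

    priors = _priors(dataset)
    eligible = [i for i, pr in priors.items() if pr]
    if not eligible:
        raise DatasetError("no record has a valid prior question")

    if statistic == "reuse_rate":
        reuse = detect_across_trial_reuse(dataset)
        observed = float(np.mean([reuse[i] for i in eligible]))
        hit = np.zeros(n_sims)
        for i in eligible:
            matched = np.zeros(n_sims, dtype=bool)
            for j in priors[i]:
                pool = pools[records[j].array_id]
                draws = pool[rng.integers(len(pool), size=n_sims)]
                matched |= tid_of_program[draws] == tid[i]
            hit += matched
        null_values = hit / len(eligible)
    elif statistic == "mean_recombination":
        if measure == "grammar" and norm_constant is None:
            norm_constant = max_pairwise_distance(programs) or None
        if measure == "grammar" and norm_constant is None:
            S = np.ones((len(programs), len(programs)))
        else:
            S, _ = _similarity_matrix(programs, measure, norm_constant, embedder)
        reuse = detect_across_trial_reuse(dataset)
        observed_vals = [
            max(S[pid[i], pid[j]] for j in priors[i])
            for i in eligible
            if not reuse[i]
        ]
        if not observed_vals:
            raise DatasetError("every eligible record is classified as reuse")
        observed = float(np.mean(observed_vals))
        total = np.zeros(n_sims)
        for i in eligible:
            best = np.full(n_sims, -np.inf)
            for j in priors[i]:
                pool = pools[records[j].array_id]
                pool = pool[tid_of_program[pool] != tid[i]]
                if len(pool) == 0:
                    raise DatasetError(
                        f"array {records[j].array_id!r}: question pool is empty after "
                        "excluding the current template"
                    )
                draws = pool[rng.integers(len(pool), size=n_sims)]
                best = np.maximum(best, S[pid[i], draws])
            total += best
        null_values = total / len(eligible)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    return NullDistribution(
        statistic=statistic,
        observed=observed,
        null_values=null_values,
        one_tailed_p=_one_tailed_p(null_values, observed),
        n_sims=n_sims,
        n_records=len(eligible),
    )


# ---------------------------------------------------------------------------
# Study-2 trial-type construction

def rank_arrays_for_target(target_program: QuestionProgram, arrays) -> pd.DataFrame:
    """Order candidate arrays by the target question's EIG and assign trial types.

    Returns a frame (array_id, eig, max_eig, too_complex, trial_type) sorted
    by decreasing EIG.  ``too_complex`` flags arrays where the target is
    maximally informative but a strictly simpler program (fewer total
    functions) achieves the same EIG.  Trial types: ``best`` = highest-EIG
    unflagged array, ``worst`` = lowest-EIG array, ``too_complex`` =
    highest-EIG flagged array (if any), ``medium`` = remaining array closest
    to the midpoint of best and worst.
    """
    _, target_size = complexity_metrics(target_program)
    battery = [(p, s) for p, s in enumerate_simple_programs() if s < target_size]
    rows = []
    for arr in arrays:
        eig = expected_information_gain(target_program, arr)
        ceiling = max_eig(arr)
        too_complex = False
        if ceiling > 0 and abs(eig - ceiling) < 1e-9:
            too_complex = any(
                abs(expected_information_gain(p, arr) - ceiling) < 1e-9 for p, _ in battery
            )
        rows.append(
            {"array_id": arr.array_id, "eig": eig, "max_eig": ceiling, "too_complex": too_complex}
        )
    df = pd.DataFrame(rows).sort_values("eig", ascending=False, kind="stable").reset_index(drop=True)
    df["trial_type"] = None

    unflagged = df.index[~df["too_complex"]]
    if len(unflagged) == 0:
        raise ValueError("no unflagged candidate array for the 'best' trial")
    best_i = unflagged[0]
    df.loc[best_i, "trial_type"] = "best"
    flagged = df.index[df["too_complex"]]
    if len(flagged) > 0:
        df.loc[flagged[0], "trial_type"] = "too_complex"
    rest = df.index[df["trial_type"].isna()]
    if len(rest) > 0:
        worst_i = rest[df.loc[rest, "eig"].values.argmin()]
        df.loc[worst_i, "trial_type"] = "worst"
        rest = df.index[df["trial_type"].isna()]
        if len(rest) > 0:
            mid = (df.loc[best_i, "eig"] + df.loc[worst_i, "eig"]) / 2
            med_i = rest[np.abs(df.loc[rest, "eig"].values - mid).argmin()]
            df.loc[med_i, "trial_type"] = "medium"
    return df


# ---------------------------------------------------------------------------
# Exposure effects (Study-2-style)

REUSE_EFFECT_TRIAL_TYPES = ("best", "medium", "too_complex")


@dataclass(frozen=True)
class EffectEstimate:
    name: str
    estimate: float
    ci_low: float
    ci_high: float
    n_exposure: int
    n_no_exposure: int

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_exposure": self.n_exposure,
            "n_no_exposure": self.n_no_exposure,
        }


def _participant_bootstrap(values: dict[str, tuple[float, float]], n_boot, rng):
    """Bootstrap a ratio-of-totals proportion/mean over participants.

    ``values`` maps participant -> (numerator, denominator).
    Returns (point, boot_samples).
    """
    num = np.array([v[0] for v in values.values()], dtype=float)
    den = np.array([v[1] for v in values.values()], dtype=float)
    point = num.sum() / den.sum()
    n = len(num)
    idx = rng.integers(n, size=(n_boot, n))
    boot = num[idx].sum(axis=1) / den[idx].sum(axis=1)
    return point, boot


def exposure_effects(
    dataset: QuestionDataset,
    measure: str = "text",
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    norm_constant: float | None = None,
    embedder=None,
) -> list[EffectEstimate]:
    """Reuse and recombination effects of target-question exposure.

    Reuse effect: difference in the proportion of target-matching questions,
    exposure minus no-exposure, restricted to the best, medium, and
    too-complex trial types (the target is completely uninformative on the
    worst trial).  Recombination effect: difference in mean similarity to
    the target question among non-matching questions, over all trial types.
    Percentile bootstrap CIs resample participants within condition.
    """
    if not dataset.has_conditions:
        raise DatasetError("exposure_effects requires exposure/trial_type/target_id labels")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    match = {
        i: target_matching(rec.program, rec.target_id)
        for i, rec in enumerate(dataset.records)
    }

    # --- reuse effect
    cells: dict[str, dict[str, tuple[float, float]]] = {"exposure": {}, "no_exposure": {}}
    for i, rec in enumerate(dataset.records):
        if rec.trial_type not in REUSE_EFFECT_TRIAL_TYPES:
            continue
        cell = cells[rec.exposure]
        num, den = cell.get(rec.participant_id, (0.0, 0.0))
        cell[rec.participant_id] = (num + match[i], den + 1)
    for name, cell in cells.items():
        if not cell:
            raise DatasetError(f"empty condition cell: {name}")
    p_exp, boot_exp = _participant_bootstrap(cells["exposure"], n_boot, rng)
    p_ctl, boot_ctl = _participant_bootstrap(cells["no_exposure"], n_boot, rng)
    boot_diff = boot_exp - boot_ctl
    effects = [
        EffectEstimate(
            name="reuse_effect",
            estimate=float(p_exp - p_ctl),
            ci_low=float(np.quantile(boot_diff, 0.025)),
            ci_high=float(np.quantile(boot_diff, 0.975)),
            n_exposure=len(cells["exposure"]),
            n_no_exposure=len(cells["no_exposure"]),
        )
    ]

    # --- recombination effect: similarity of non-matching questions to the target
    target_sim = _target_similarity(dataset, measure, norm_constant, embedder)
    cells = {"exposure": {}, "no_exposure": {}}
    for i, rec in enumerate(dataset.records):
        if match[i]:
            continue
        cell = cells[rec.exposure]
        num, den = cell.get(rec.participant_id, (0.0, 0.0))
        cell[rec.participant_id] = (num + target_sim[i], den + 1)
    for name, cell in cells.items():
        if not cell:
            raise DatasetError(f"empty condition cell for recombination: {name}")
    m_exp, boot_exp = _participant_bootstrap(cells["exposure"], n_boot, rng)
    m_ctl, boot_ctl = _participant_bootstrap(cells["no_exposure"], n_boot, rng)
    boot_diff = boot_exp - boot_ctl
    effects.append(
        EffectEstimate(
            name=f"recombination_effect_{measure}",
            estimate=float(m_exp - m_ctl),
            ci_low=float(np.quantile(boot_diff, 0.025)),
            ci_high=float(np.quantile(boot_diff, 0.975)),
            n_exposure=len(cells["exposure"]),
            n_no_exposure=len(cells["no_exposure"]),
        )
    )
    return effects


def _target_similarity(dataset, measure, norm_constant, embedder) -> dict[int, float]:
    programs, pid = _unique_programs(dataset)
    extended = list(programs) + [TARGET_PROGRAMS[t] for t in sorted(TARGET_PROGRAMS)]
    target_pos = {t: len(programs) + k for k, t in enumerate(sorted(TARGET_PROGRAMS))}
    if measure == "grammar" and norm_constant is None:
        norm_constant = max_pairwise_distance(extended) or None
        if norm_constant is None:
            return {i: 1.0 for i in range(len(dataset.records))}
    S, _ = _similarity_matrix(extended, measure, norm_constant, embedder)
    return {
        i: float(S[pid[i], target_pos[rec.target_id]])
        for i, rec in enumerate(dataset.records)
    }


# ---------------------------------------------------------------------------
# Model / Results layer

@dataclass(frozen=True)
class AcrossTrialResults:
    """Across-trial reuse/recombination estimates with simulated nulls."""

    reuse: NullDistribution
    recombination: NullDistribution
    measure: str
    norm_constant: float | None
    n_sims: int

    @property
    def reuse_rate(self) -> float:
        return self.reuse.observed

    @property
    def mean_recombination(self) -> float:
        return self.recombination.observed

    def summary(self) -> str:
        lines = [
            "Across-trial reuse and recombination",
            f"  eligible records            : {self.reuse.n_records}",
            f"  reuse rate (observed)       : {self.reuse.observed:.3f}",
            f"    null mean ({self.n_sims} sims)      : {float(np.mean(self.reuse.null_values)):.3f}",
            f"    one-tailed p              : {self.reuse.one_tailed_p:.4g}",
            f"  mean recombination ({self.measure}) : {self.recombination.observed:.3f}",
            f"    null mean                 : {float(np.mean(self.recombination.null_values)):.3f}",
            f"    one-tailed p              : {self.recombination.one_tailed_p:.4g}",
        ]
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "measure": self.measure,
            "norm_constant": self.norm_constant,
            "reuse": self.reuse.to_json(),
            "recombination": self.recombination.to_json(),
        }


@dataclass
class AcrossTrialModel:
    """Within-participant reuse/recombination analysis of a question dataset."""

    dataset: QuestionDataset
    measure: str = "grammar"
    norm_constant: float | None = None
    embedder: object = None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, arrays=None, **kwargs) -> "AcrossTrialModel":
        from .dataset import _record_from_row

        records = [_record_from_row(row, i) for i, row in enumerate(frame.to_dict("records"))]
        return cls(QuestionDataset(records=records, arrays=arrays or {}), **kwargs)

    def fit(self, n_sims: int = 1000, rng=None) -> AcrossTrialResults:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        norm = self.norm_constant
        if self.measure == "grammar" and norm is None:
            programs, _ = _unique_programs(self.dataset)
            norm = max_pairwise_distance(programs) or None
        reuse = simulate_null(
            self.dataset, "reuse_rate", n_sims=n_sims, rng=rng,
            measure=self.measure, norm_constant=norm, embedder=self.embedder,
        )
        recomb = simulate_null(
            self.dataset, "mean_recombination", n_sims=n_sims, rng=rng,
            measure=self.measure, norm_constant=norm, embedder=self.embedder,
        )
        return AcrossTrialResults(
            reuse=reuse, recombination=recomb, measure=self.measure,
            norm_constant=norm, n_sims=n_sims,
        )


@dataclass(frozen=True)
class ExposureResults:
    """Exposure-condition effects on target-question reuse and recombination."""

    effects: list[EffectEstimate] = field(default_factory=list)
    measure: str = "text"
    n_boot: int = 1000

    def effect(self, name: str) -> EffectEstimate:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def reuse_effect(self) -> EffectEstimate:
        return self.effect("reuse_effect")

    @property
    def recombination_effect(self) -> EffectEstimate:
        return self.effect(f"recombination_effect_{self.measure}")

    def summary(self) -> str:
        lines = ["Exposure effects (bootstrap 95% CI over participants)"]
        for e in self.effects:
            lines.append(
                f"  {e.name:<28s}: {e.estimate:+.4f}  [{e.ci_low:+.4f}, {e.ci_high:+.4f}]"
                f"  (n={e.n_exposure}/{e.n_no_exposure})"
            )
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {"n_boot": self.n_boot, "measure": self.measure,
                "effects": [e.to_json() for e in self.effects]}


@dataclass
class ExposureModel:
    """Study-2-style exposure analysis of a condition-labeled dataset."""

    dataset: QuestionDataset
    measure: str = "text"
    norm_constant: float | None = None
    embedder: object = None

    def fit(self, n_boot: int = 1000, rng=None) -> ExposureResults:
        effects = exposure_effects(
            self.dataset, measure=self.measure, n_boot=n_boot, rng=rng,
            norm_constant=self.norm_constant, embedder=self.embedder,
        )
        return ExposureResults(effects=effects, measure=self.measure, n_boot=n_boot)
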