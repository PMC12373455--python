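"""Question datasets: per-participant, per-trial question records.

JSONL is the canonical on-disk format (one record per line; programs
contain parentheses and commas), with a quoted-CSV alternative.  Reading
validates the schema, parses and type-checks every program, and checks
trial ordering, attaching row numbers to every complaint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import pandas as pd

from .domain import TrialArray
from .language import QuestionProgram, parse

_CONDITION_FIELDS = ("exposure", "previous_quality", "target_id", "trial_type")

EXPOSURE_LEVELS = ("exposure", "no_exposure")
TRIAL_TYPES = ("best", "medium", "worst", "too_complex")


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class QuestionRecord:
    """One asked question: who, when, facing which array, and the program."""

    participant_id: str
    trial_index: int
    array_id: str
    program: QuestionProgram
    exposure: str | None = None
    previous_quality: str | None = None
    target_id: str | None = None
    trial_type: str | None = None

    def to_json(self) -> dict:
        out = {
            "participant_id": self.participant_id,
            "trial_index": self.trial_index,
            "array_id": self.array_id,
            "program": str(self.program),
        }
        for f in _CONDITION_FIELDS:
            v = getattr(self, f)
            if v is not None:
                out[f] = v
        return out


@dataclass
class QuestionDataset:
    """Ordered question records plus the trial arrays they refer to."""

    records: list[QuestionRecord]
    arrays: dict[str, TrialArray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        last: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            key = (rec.participant_id, rec.trial_index)
            if key in seen:
                raise DatasetError(
                    f"record {i}: duplicate trial_index {rec.trial_index} "
                    f"for participant {rec.participant_id}"
                )
            seen.add(key)
            prev = last.get(rec.participant_id)
            if prev is not None and rec.trial_index <= prev:
                raise DatasetError(
                    f"record {i}: trial_index not strictly increasing for "
                    f"participant {rec.participant_id}"
                )
            last[rec.participant_id] = rec.trial_index
            if self.arrays and rec.array_id not in self.arrays:
                raise DatasetError(f"record {i}: unknown array_id {rec.array_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def participants(self) -> list[str]:
        out, seen = [], set()
        for rec in self.records:
            if rec.participant_id not in seen:
                seen.add(rec.participant_id)
                out.append(rec.participant_id)
        return out

    def by_participant(self) -> dict[str, list[QuestionRecord]]:
        out: dict[str, list[QuestionRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.participant_id, []).append(rec)
        return out

    def array_for(self, rec: QuestionRecord) -> TrialArray:
        return self.arrays[rec.array_id]

    @property
    def has_conditions(self) -> bool:
        return all(
            rec.exposure in EXPOSURE_LEVELS and rec.trial_type in TRIAL_TYPES
            and rec.target_id is not None
            for rec in self.records
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_json() for r in self.records])


def _record_from_row(row: dict, rownum: int) -> QuestionRecord:
    try:
        program = parse(str(row["program"]))
    except Exception as exc:  # noqa: BLE001 - re-raised with row context
        raise DatasetError(f"row {rownum}: cannot parse program {row.get('program')!r}: {exc}") from exc
    missing = [k for k in ("participant_id", "trial_index", "array_id") if k not in row or pd.isna(row[k])]
    if missing:
        raise DatasetError(f"row {rownum}: missing field(s) {missing}")
    conditions = {}
    for f in _CONDITION_FIELDS:
        v = row.get(f)
        if v is not None and not (isinstance(v, float) and pd.isna(v)):
            conditions[f] = str(v)
    return QuestionRecord(
        participant_id=str(row["participant_id"]),
        trial_index=int(row["trial_index"]),
        array_id=str(row["array_id"]),
        program=program,
        **conditions,
    )


def read_dataset(path, arrays_path=None) -> QuestionDataset:
    """Read a dataset from JSONL (or CSV, by extension), validating everything."""
    path = str(path)
    rows: list[dict]
    if path.endswith(".csv"):
        rows = pd.read_csv(path).to_dict("records")
    else:
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise DatasetError(f"row {i}: invalid JSON: {exc}") from exc
    records = [_record_from_row(row, i) for i, row in enumerate(rows)]
    arrays = read_arrays(arrays_path) if arrays_path else {}
    return QuestionDataset(records=records, arrays=arrays)


def write_dataset(dataset: QuestionDataset, path) -> None:
    path = str(path)
    if path.endswith(".csv"):
        dataset.to_frame().to_csv(path, index=False)
        return
    with open(path, "w") as fh:
        for rec in dataset.records:
            fh.write(json.dumps(rec.to_json()) + "\n")


def read_arrays(path) -> dict[str, TrialArray]:
    """Trial arrays from a JSON file: a list of TrialArray objects."""
    with open(path) as fh:
        items = json.load(fh)
    arrays = {}
    for obj in items:
        arr = TrialArray.from_json(obj)
        arrays[arr.array_id] = arr
    return arrays


def write_arrays(arrays: dict[str, TrialArray], path) -> None:
    with open(path, "w") as fh:
        json.dump([a.to_json() for a in arrays.values()], fh, indent=1)


def strip_truth(dataset: QuestionDataset) -> QuestionDataset:
    """Drop the stored true worlds (e.g. before sharing a dataset)."""
    arrays = {k: replace(a, truth=None) for k, a in dataset.arrays.items()}
    return QuestionDataset(records=list(dataset.records), arrays=arrays)
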