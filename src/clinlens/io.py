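"""CSV / YAML / JSON input and output.

File schemas
------------
cases.csv
    ``case_id, sbp, hr, rr, temp, consciousness, criterion`` with
    consciousness as the letters A/V/P (mapped to the ordinal 0/1/2
    internally) and criterion in {0, 1}.
presentations.csv
    ``presentation_index, case_id, is_repeat, first_occurrence_index``
    in presentation order; ``first_occurrence_index`` is empty for first
    occurrences.
judgements.csv
    ``participant_id, condition, presentation_index, judgement`` with
    judgement in {0, 1}; condition labels are arbitrary strings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .synthetic import (
    CONSCIOUSNESS_LEVELS,
    CaseRecord,
    JudgementSet,
    ScenarioSet,
)

_LEVEL_TO_ORD = {lvl: i for i, lvl in enumerate(CONSCIOUSNESS_LEVELS)}


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns {missing}")


def write_cases_csv(cases: Sequence[CaseRecord], path) -> None:
    pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "sbp": [c.sbp for c in cases],
            "hr": [c.hr for c in cases],
            "rr": [c.rr for c in cases],
            "temp": [c.temp for c in cases],
            "consciousness": [c.consciousness_label for c in cases],
            "criterion": [c.criterion for c in cases],
        }
    ).to_csv(path, index=False)


def read_cases_csv(path) -> list[CaseRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df, ["case_id", "sbp", "hr", "rr", "temp", "consciousness", "criterion"], str(path)
    )
    cases = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.consciousness not in _LEVEL_TO_ORD:
            raise SchemaError(
                f"{path} row {row_no}: consciousness {row.consciousness!r} not in A/V/P"
            )
        if int(row.criterion) not in (0, 1):
            raise SchemaError(f"{path} row {row_no}: criterion must be 0 or 1")
        cases.append(
            CaseRecord(
                case_id=int(row.case_id),
                sbp=float(row.sbp),
                hr=float(row.hr),
                rr=float(row.rr),
                temp=float(row.temp),
                consciousness=_LEVEL_TO_ORD[str(row.consciousness)],
                criterion=int(row.criterion),
            )
        )
    return cases


def write_presentations_csv(scenario_set: ScenarioSet, path) -> None:
    rows = []
    for idx, cid in enumerate(scenario_set.presentations):
        first = scenario_set.repeat_map.get(idx)
        rows.append(
            {
                "presentation_index": idx,
                "case_id": cid,
                "is_repeat": int(first is not None),
                "first_occurrence_index": "" if first is None else first,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scenario_set(cases: Sequence[CaseRecord], presentations_path) -> ScenarioSet:
    df = pd.read_csv(presentations_path)
    _require_columns(
        df,
        ["presentation_index", "case_id", "is_repeat", "first_occurrence_index"],
        str(presentations_path),
    )
    df = df.sort_values("presentation_index")
    presentations = tuple(int(c) for c in df["case_id"])
    repeat_map = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        if int(row.is_repeat):
            if pd.isna(row.first_occurrence_index):
                raise SchemaError(
                    f"{presentations_path} row {row_no}: repeat without first_occurrence_index"
                )
            repeat_map[int(row.presentation_index)] = int(row.first_occurrence_index)
    used = set(presentations)
    return ScenarioSet(
        presentations=presentations,
        repeat_map=repeat_map,
        unique_cases=tuple(c for c in cases if c.case_id in used),
    )


def write_judgements_csv(judgement_sets: Sequence[JudgementSet], path) -> None:
    rows = []
    for js in judgement_sets:
        for idx, j in enumerate(js.judgements):
            rows.append(
                {
                    "participant_id": js.participant_id,
                    "condition": js.condition,
                    "presentation_index": idx,
                    "judgement": j,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_judgements_csv(path, n_presentations: int) -> list[JudgementSet]:
    df = pd.read_csv(path)
    _require_columns(
        df, ["participant_id", "condition", "presentation_index", "judgement"], str(path)
    )
    bad = df[~df["judgement"].isin([0, 1])]
    if len(bad):
        raise SchemaError(
            f"{path} row {bad.index[0] + 2}: judgement must be 0 or 1"
        )
    bad = df[
        (df["presentation_index"] < 0) | (df["presentation_index"] >= n_presentations)
    ]
    if len(bad):
        raise SchemaError(
            f"{path} row {bad.index[0] + 2}: presentation_index outside scenario set"
        )
    sets = []
    for (pid, condition), grp in df.groupby(["participant_id", "condition"], sort=True):
        grp = grp.sort_values("presentation_index")
        if list(grp["presentation_index"]) != list(range(n_presentations)):
            raise SchemaError(
                f"{path}: participant {pid} condition {condition!r} does not cover "
                f"presentations 0..{n_presentations - 1} exactly once"
            )
        sets.append(
            JudgementSet(
                participant_id=int(pid),
                condition=str(condition),
                judgements=tuple(int(v) for v in grp["judgement"]),
            )
        )
    return sets


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    return data
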