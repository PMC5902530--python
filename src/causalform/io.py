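"""Reading and writing model specification files and trial tables.

Model files are JSON or YAML (chosen by extension) with the schema::

    effect_range:
      lower: 0        # magnitude L, a number or "inf"
      upper: 1        # magnitude U, a number or "inf"
    causes:
      - {label: g1, role: generator, strength: 0.5, max_value: 1}

Roles are generator, reducer, blocker; max_value may be "inf" and defaults
to 1.  Read-then-write is the identity on valid models.  Trial tables are
plain CSV with one column per cause label plus an ``effect`` column, written
at full repr precision so round trips are lossless.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CapacityModel, Cause, EffectRange, ModelError, AssignmentError
from .simulate import TrialTable

__all__ = [
    "model_from_dict",
    "model_to_dict",
    "read_model",
    "write_model",
    "read_trials",
    "write_trials",
]


def _parse_number(value, fieldname: str, allow_inf: bool = True) -> float:
    if isinstance(value, str):
        if allow_inf and value.strip().lower() in ("inf", "+inf", "infinity"):
            return math.inf
        raise ModelError(f"{fieldname}: expected a number or 'inf', got {value!r}")
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ModelError(f"{fieldname}: expected a number, got {value!r}")
    return float(value)


def _emit_number(v: float):
    return "inf" if math.isinf(v) else v


def model_from_dict(data: dict) -> CapacityModel:
    """Build and validate a model from the documented schema dict."""
    if not isinstance(data, dict):
        raise ModelError(f"model file must contain a mapping, got {type(data).__name__}")
    try:
        er_raw = data["effect_range"]
    except KeyError:
        raise ModelError("missing field 'effect_range'") from None
    if not isinstance(er_raw, dict):
        raise ModelError("'effect_range' must be a mapping with 'lower' and 'upper'")
    for key in ("lower", "upper"):
        if key not in er_raw:
            raise ModelError(f"missing field 'effect_range.{key}'")
    er = EffectRange(
        lower=_parse_number(er_raw["lower"], "effect_range.lower"),
        upper=_parse_number(er_raw["upper"], "effect_range.upper"),
    )
    causes_raw = data.get("causes", [])
    if not isinstance(causes_raw, list):
        raise ModelError("'causes' must be a list")
    causes = []
    for i, c in enumerate(causes_raw):
        where = f"causes[{i}]"
        if not isinstance(c, dict):
            raise ModelError(f"{where}: expected a mapping")
        for key in ("label", "role", "strength"):
            if key not in c:
                raise ModelError(f"missing field '{where}.{key}'")
        causes.append(
            Cause(
                label=str(c["label"]),
                role=c["role"],
                strength=_parse_number(c["strength"], f"{where}.strength", allow_inf=False),
                max_value=_parse_number(c.get("max_value", 1.0), f"{where}.max_value"),
            )
        )
    return CapacityModel(er, causes)


def model_to_dict(model: CapacityModel) -> dict:
    return {
        "effect_range": {
            "lower": _emit_number(model.effect_range.lower),
            "upper": _emit_number(model.effect_range.upper),
        },
        "causes": [
            {
                "label": c.label,
                "role": c.role,
                "strength": c.strength,
                "max_value": _emit_number(c.max_value),
            }
            for c in model.causes
        ],
    }


def read_model(path) -> CapacityModel:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ModelError(f"{path}: empty model file")
    try:
        data = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as e:
        raise ModelError(f"{path}: cannot parse: {e}") from None
    return model_from_dict(data)


def write_model(model: CapacityModel, path) -> None:
    path = Path(path)
    data = model_to_dict(model)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def read_trials(path, model: CapacityModel | None = None) -> TrialTable:
    """Read a trial CSV; with a model, validate columns and value ranges."""
    path = Path(path)
    if not path.read_text().strip():
        raise AssignmentError(f"{path}: empty trial table")
    df = pd.read_csv(path)
    if df.empty:
        raise AssignmentError(f"{path}: trial table has a header but no rows")
    if TrialTable.EFFECT_COLUMN not in df.columns:
        raise AssignmentError(f"{path}: missing '{TrialTable.EFFECT_COLUMN}' column")
    if model is not None:
        expected = set(model.labels) | {TrialTable.EFFECT_COLUMN}
        got = set(df.columns)
        if expected != got:
            raise AssignmentError(
                f"{path}: column mismatch; missing {sorted(expected - got)}, "
                f"unexpected {sorted(got - expected)}"
            )
        for c in model.causes:
            vals = df[c.label].to_numpy(dtype=float)
            bad = np.flatnonzero((vals < 0) | (vals > c.max_value))
            if bad.size:
                raise AssignmentError(
                    f"{path}: row {int(bad[0]) + 1}: cause {c.label!r} value "
                    f"{vals[bad[0]]} outside [0, {c.max_value}]"
                )
        er = model.effect_range
        e = df[TrialTable.EFFECT_COLUMN].to_numpy(dtype=float)
        bad = np.flatnonzero((e < -er.lower) | (e > er.upper))
        if bad.size:
            raise AssignmentError(
                f"{path}: row {int(bad[0]) + 1}: effect {e[bad[0]]} outside "
                f"[{-er.lower}, {er.upper}]"
            )
    return TrialTable(data=df)


def write_trials(table: TrialTable, path) -> None:
    table.data.to_csv(Path(path), index=False)
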