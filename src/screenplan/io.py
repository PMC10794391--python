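"""File I/O: item-level cohort CSVs, characteristics tables, plan reports.

The item-level schema is one row per participant with a true ``device``
column (headphones/loudspeakers), an optional ``self_report`` column, and
0/1 trial-outcome columns ``testA_1..testA_6`` (analogously B, C); missing
tests simply lack their columns.  Characteristics tables are CSV or JSON
with columns ``test_id, threshold, sen, spe, n_pos, n_neg`` (sen/spe as
proportions).  Reports are JSON with an explicit provenance block so
planning decisions are auditable.
"""

from __future__ import annotations

import json
import re
from dataclasses import fields, is_dataclass
from fractions import Fraction
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any

import pandas as pd

from .combiner import Procedure, get_combiner
from .metrics import DEVICE_COLUMN, NEGATIVE_DEVICE, POSITIVE_DEVICE, InputError

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_characteristics",
    "write_characteristics",
    "parse_procedure",
    "write_report",
]

_CHAR_COLUMNS = ["test_id", "threshold", "sen", "spe", "n_pos", "n_neg"]


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read an item-level cohort CSV and validate the schema."""
    frame = pd.read_csv(path)
    if len(frame) == 0:
        raise InputError(f"{path}: empty cohort file")
    if DEVICE_COLUMN not in frame.columns:
        raise InputError(f"{path}: missing required column {DEVICE_COLUMN!r}")
    devices = set(frame[DEVICE_COLUMN].dropna().unique())
    allowed = {POSITIVE_DEVICE, NEGATIVE_DEVICE}
    if not devices <= allowed:
        raise InputError(f"{path}: unknown device labels {sorted(devices - allowed)}")
    trial_cols = [c for c in frame.columns if re.fullmatch(r"test[A-Z]_\d+", c)]
    if not trial_cols:
        raise InputError(f"{path}: no trial-outcome columns (testX_i)")
    bad = [
        c for c in trial_cols
        if not frame[c].dropna().isin([0, 1]).all()
    ]
    if bad:
        raise InputError(f"{path}: non-binary trial outcomes in columns {bad}")
    return frame


def write_cohort_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_characteristics(path: str | Path) -> pd.DataFrame:
    """Read a characteristics table (CSV, or JSON list of row objects)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()))
    else:
        frame = pd.read_csv(path)
    if "procedure" in frame.columns:  # combined-characteristics schema
        missing = [c for c in ("sen", "spe") if c not in frame.columns]
    else:
        missing = [c for c in _CHAR_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing characteristics columns {missing}")
    if ((frame["sen"] < 0) | (frame["sen"] > 1) | (frame["spe"] < 0) | (frame["spe"] > 1)).any():
        raise InputError(f"{path}: sen/spe must be proportions in [0, 1]")
    return frame


def write_characteristics(frame: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
    else:
        frame.to_csv(path, index=False)


_PROC_RE = re.compile(r"EK(\d+):((?:[A-Z]\d+,)*[A-Z]\d+)")


def parse_procedure(spec: str) -> Procedure:
    """Parse a procedure spec string such as ``EK11:A5,B5,C6``."""
    m = _PROC_RE.fullmatch(spec.strip())
    if not m:
        raise InputError(f"malformed procedure spec {spec!r}")
    combiner = get_combiner(int(m.group(1)))
    thresholds = {}
    for part in m.group(2).split(","):
        thresholds[part[0]] = int(part[1:])
    return Procedure(combiner=combiner, thresholds=thresholds)


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        if isinstance(obj, Procedure):
            return obj.spec
        return {f.name: _jsonable(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Fraction):
        return str(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_report(
    payload: dict[str, Any],
    path: str | Path | None,
    provenance: dict[str, Any] | None = None,
) -> str:
    """Serialize a report with a provenance block; returns the JSON text.

    Provenance records where characteristics came from (fixture, user table
    or simulation), the seed, and the package version, so a plan can be
    audited and reproduced.
    """
    try:
        ver = version("screenplan")
    except PackageNotFoundError:
        ver = "unknown"
    doc = {"provenance": {"software": f"screenplan {ver}", **(provenance or {})}}
    doc.update(_jsonable(payload))
    text = json.dumps(doc, indent=1, sort_keys=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
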