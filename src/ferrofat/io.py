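"""Schema-validated delimited-text readers and writers.

The cohort table is a wide CSV, one row per patient, whose column
dictionary (names, units, plausible physiologic ranges) is versioned
here.  Row-level range violations are collected and reported, not fatal;
a missing mandatory column or an empty file is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .signal_model import EchoTrain

__all__ = [
    "COHORT_SCHEMA_VERSION",
    "COHORT_COLUMNS",
    "SchemaError",
    "EmptyInputError",
    "RowIssue",
    "read_cohort",
    "write_cohort",
    "write_report",
    "read_echo_train",
    "cohort_schema",
]

COHORT_SCHEMA_VERSION = "1.0"

#: Column dictionary: name -> (unit, required, plausible (lo, hi) or None).
#: Ranges are physiologic plausibility bounds used for row flagging only.
COHORT_COLUMNS: dict[str, tuple[str, bool, tuple[float, float] | None]] = {
    "id": ("", True, None),
    "sex": ("M|F", False, None),
    "age_yr": ("years", False, (0.0, 120.0)),
    "bmi_kg_m2": ("kg/m^2", False, (8.0, 80.0)),
    "splenectomy": ("bool", False, None),
    "hcv_status": ("negative|eradicated|chronic", False, None),
    "ferritin_ng_ml": ("ng/mL", False, (0.0, 30000.0)),
    "hemoglobin_g_dl": ("g/dL", False, (3.0, 20.0)),
    "fpg_mg_dl": ("mg/dL", False, (20.0, 1000.0)),
    "glucose_1h_mg_dl": ("mg/dL", False, (20.0, 1000.0)),
    "glucose_2h_mg_dl": ("mg/dL", False, (20.0, 1000.0)),
    "insulin_uu_ml": ("uU/mL", False, (0.0, 300.0)),
    "known_diabetes": ("bool", False, None),
    "glucose_class": ("NGT|IFG|IGT|DM", False, None),
    "pancreas_head_t2s_ms": ("ms", False, (0.1, 200.0)),
    "pancreas_body_t2s_ms": ("ms", False, (0.1, 200.0)),
    "pancreas_tail_t2s_ms": ("ms", False, (0.1, 200.0)),
    "pancreas_head_ff_pct": ("%", False, (0.0, 100.0)),
    "pancreas_body_ff_pct": ("%", False, (0.0, 100.0)),
    "pancreas_tail_ff_pct": ("%", False, (0.0, 100.0)),
    "pancreas_global_t2s_ms": ("ms", True, (0.1, 200.0)),
    "pancreas_global_ff_pct": ("%", True, (0.0, 100.0)),
    "liver_t2s_ms": ("ms", False, (0.1, 200.0)),
    "lic_mg_g_dw": ("mg/g dw", False, (0.0, 60.0)),
    "heart_global_t2s_ms": ("ms", False, (0.1, 200.0)),
    "n_pathological_segments": ("count", False, (0, 16)),
    "lvef_pct": ("%", False, (0.0, 100.0)),
    "rvef_pct": ("%", False, (0.0, 100.0)),
    "edvi_ml_m2": ("mL/m^2", False, (10.0, 400.0)),
    "esvi_ml_m2": ("mL/m^2", False, (0.0, 400.0)),
    "myocardial_fibrosis": ("present|absent|not_assessed", False, None),
    "jet_velocity_m_s": ("m/s", False, (0.0, 8.0)),
    "heart_failure": ("bool", False, None),
    "arrhythmia": ("bool", False, None),
    "arrhythmia_subtype": ("supraventricular|ventricular|", False, None),
    "waist_cm": ("cm", False, (30.0, 250.0)),
    "hdl_mg_dl": ("mg/dL", False, (5.0, 200.0)),
    "triglycerides_mg_dl": ("mg/dL", False, (10.0, 3000.0)),
    "sbp_mmhg": ("mmHg", False, (50.0, 280.0)),
    "dbp_mmhg": ("mmHg", False, (20.0, 180.0)),
    "lipid_treatment": ("bool", False, None),
    "bp_treatment": ("bool", False, None),
    "metabolic_syndrome": ("bool", False, None),
}
for _k in range(16):
    COHORT_COLUMNS[f"heart_seg{_k + 1:02d}_t2s_ms"] = ("ms", False, (0.1, 200.0))


class SchemaError(ValueError):
    """Fatal schema violation (missing mandatory column)."""


class EmptyInputError(ValueError):
    """The input file contains no data rows."""


@dataclass(frozen=True)
class RowIssue:
    row: int
    column: str
    message: str


def cohort_schema() -> dict:
    """The versioned column dictionary as a JSON-serializable object."""
    return {
        "version": COHORT_SCHEMA_VERSION,
        "columns": {
            name: {"unit": unit, "required": required, "range": rng}
            for name, (unit, required, rng) in COHORT_COLUMNS.items()
        },
    }


def read_cohort(path) -> tuple[pd.DataFrame, list[RowIssue]]:
    """Read and validate a cohort CSV.

    Returns the typed frame plus collected row-level issues (out-of-range
    values).  Missing mandatory columns raise :class:`SchemaError`; an
    empty file raises :class:`EmptyInputError`.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"empty cohort file: {path}") from exc
    if df.empty:
        raise EmptyInputError(f"cohort file has no data rows: {path}")

    required = [name for name, (_, req, _) in COHORT_COLUMNS.items() if req]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing mandatory columns: {missing}")

    issues: list[RowIssue] = []
    for name, (_, _, rng) in COHORT_COLUMNS.items():
        if rng is None or name not in df.columns:
            continue
        values = pd.to_numeric(df[name], errors="coerce")
        lo, hi = rng
        bad = values.notna() & ((values < lo) | (values > hi))
        for idx in df.index[bad]:
            issues.append(
                RowIssue(
                    row=int(idx),
                    column=name,
                    message=f"value {df.at[idx, name]!r} outside plausible range [{lo}, {hi}]",
                )
            )
    return df, issues


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _jsonify(obj):
    """Recursively convert report structures to JSON-serializable types."""
    import dataclasses

    if obj is None or isinstance(obj, (str, bool, int)):
        return obj
    if isinstance(obj, float):
        return None if not np.isfinite(obj) else obj
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _jsonify(float(obj))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset, np.ndarray)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    return str(obj)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)


def read_echo_train(path, organ: str | None = None, region: str | None = None) -> EchoTrain:
    return EchoTrain.from_csv(path, organ=organ, region=region)
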