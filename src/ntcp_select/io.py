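"""CSV/JSON contracts: readers with row-level validation, report writers.

All tables are UTF-8 CSV with fixed header names. Validation reports the
offending column and 1-based data line; unknown extra columns are accepted
with a warning for forward compatibility. Probabilities are serialised to
four decimals and percentage points to one decimal — decisions are always
taken on the unrounded values upstream of this module.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .models import (
    BOOLEAN_FACTORS,
    CLINICAL_COLUMNS,
    DEFAULT_DOSE_CAP,
    DOSE_COLUMNS,
    ENUM_FACTORS,
    ModelSpec,
    load_models,
)
from .selection import TUMOR_SITES, SelectionDecision, ThresholdPolicy

__all__ = [
    "SchemaError",
    "read_plan_table",
    "read_patient_table",
    "load_policy",
    "write_decisions_csv",
    "write_summary_json",
    "decisions_frame",
    "models_version_hash",
]

_GATE_COLUMNS = {"tumor_site", "distant_metastases", "curative_intent"}
_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "True": True, "False": False,
}


class SchemaError(ValueError):
    """Input violates a CSV contract; message names column and line."""


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except (FileNotFoundError, pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def _require(df: pd.DataFrame, required: Sequence[str], known: set[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=3)


def _parse_bool(value: str, column: str, line: int, path) -> bool:
    try:
        return _BOOL_MAP[value.strip()]
    except KeyError:
        raise SchemaError(
            f"{path}: line {line}, column {column!r}: expected a boolean, got {value!r}"
        ) from None


def read_plan_table(path, dose_cap: float = DEFAULT_DOSE_CAP) -> pd.DataFrame:
    """Read a plan table: patient_id, plan_id, five OAR mean-dose columns (Gy)."""
    df = _read_csv(path)
    required = ["patient_id", *DOSE_COLUMNS]
    _require(df, required, set(required) | {"plan_id"}, path)
    out = pd.DataFrame({"patient_id": df["patient_id"].astype(str)})
    if "plan_id" in df.columns:
        out["plan_id"] = df["plan_id"].astype(str)
    for col in DOSE_COLUMNS:
        doses = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[doses.isna()]:
            raise SchemaError(
                f"{path}: line {idx + 2}, column {col!r}: not a number ({df.at[idx, col]!r})"
            )
        bad = df.index[(doses < 0) | (doses > dose_cap)]
        if len(bad):
            idx = bad[0]
            raise SchemaError(
                f"{path}: line {idx + 2}, column {col!r}: dose {doses[idx]} Gy "
                f"outside [0, {dose_cap}]"
            )
        out[col] = doses.astype(float)
    if out["patient_id"].duplicated().any():
        dup = out["patient_id"][out["patient_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate patient_id {dup!r}")
    return out


def read_patient_table(path) -> pd.DataFrame:
    """Read the patient table: patient_id, clinical factors, eligibility columns."""
    df = _read_csv(path)
    required = ["patient_id", *CLINICAL_COLUMNS]
    _require(df, required, set(required) | _GATE_COLUMNS, path)
    out = pd.DataFrame({"patient_id": df["patient_id"].astype(str)})
    for factor, levels in ENUM_FACTORS.items():
        values = df[factor].str.strip()
        bad = df.index[~values.isin(levels)]
        if len(bad):
            idx = bad[0]
            raise SchemaError(
                f"{path}: line {idx + 2}, column {factor!r}: unknown level "
                f"{df.at[idx, factor]!r}; expected one of {levels}"
            )
        out[factor] = values
    for factor in BOOLEAN_FACTORS:
        out[factor] = [
            _parse_bool(v, factor, i + 2, path) for i, v in enumerate(df[factor])
        ]
    if "tumor_site" in df.columns:
        values = df["tumor_site"].str.strip()
        bad = df.index[~values.isin(TUMOR_SITES)]
        if len(bad):
            idx = bad[0]
            raise SchemaError(
                f"{path}: line {idx + 2}, column 'tumor_site': unknown site "
                f"{df.at[idx, 'tumor_site']!r}; expected one of {TUMOR_SITES}"
            )
        out["tumor_site"] = values
    for col in ("distant_metastases", "curative_intent"):
        if col in df.columns:
            out[col] = [_parse_bool(v, col, i + 2, path) for i, v in enumerate(df[col])]
    if out["patient_id"].duplicated().any():
        dup = out["patient_id"][out["patient_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate patient_id {dup!r}")
    return out


def load_policy(path) -> ThresholdPolicy:
    """Load a threshold policy JSON ({"single": {...}, "summed": {...}})."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return ThresholdPolicy.from_dict(payload)
    except (OSError, json.JSONDecodeError, KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: invalid policy file: {exc}") from exc


def _fmt_prob(x: float | None) -> str:
    return "" if x is None else f"{x:.4f}"


def _fmt_pp(x: float | None) -> str:
    return "" if x is None else f"{x:.1f}"


def decisions_frame(decisions: Sequence[SelectionDecision], endpoints: Sequence[str]) -> pd.DataFrame:
    """Flatten decisions to the report table (probabilities 4 dp, pp 1 dp)."""
    rows = []
    for d in decisions:
        row = {
            "patient_id": d.patient_id or "",
            "gate_passed": str(d.gate_passed).lower(),
        }
        for name in endpoints:
            row[f"ntcp_photon_{name}"] = _fmt_prob(d.ntcp_photon.get(name))
            row[f"ntcp_proton_{name}"] = _fmt_prob(d.ntcp_proton.get(name))
            row[f"delta_max_pp_{name}"] = _fmt_pp(d.delta_max_pp.get(name))
            row[f"delta_pp_{name}"] = _fmt_pp(d.delta_pp.get(name))
        row["plan_comparison_indicated"] = str(d.plan_comparison_indicated).lower()
        row["qualifies"] = str(d.qualifies).lower()
        row["triggered_rules"] = ";".join(
            f"{r.rule}:grade{r.grade}:{'+'.join(r.endpoints)}:{r.value_pp:.1f}>={r.threshold_pp:g}"
            for r in d.triggered_rules
        )
        rows.append(row)
    columns = ["patient_id", "gate_passed"]
    for name in endpoints:
        columns += [
            f"ntcp_photon_{name}", f"ntcp_proton_{name}",
            f"delta_max_pp_{name}", f"delta_pp_{name}",
        ]
    columns += ["plan_comparison_indicated", "qualifies", "triggered_rules"]
    return pd.DataFrame(rows, columns=columns)


def write_decisions_csv(
    decisions: Sequence[SelectionDecision], endpoints: Sequence[str], path
) -> None:
    decisions_frame(decisions, endpoints).to_csv(path, index=False, encoding="utf-8")


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def models_version_hash(models: Sequence[ModelSpec]) -> str:
    """Stable short hash of a coefficient set, for reproducibility audits."""
    canonical = json.dumps([m.to_dict() for m in models], sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:12]
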