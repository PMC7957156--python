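"""Readers, writers and run configuration.

CSV dialect throughout: UTF-8, comma-separated, ISO-8601 dates, ``.``
decimal separator.  Reports are written as deterministic JSON — sorted
keys, floats at 10 significant digits, absent/NaN confidence bounds as
explicit nulls — so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .msm import FitResult, LRTResult, PanelDataset, Subject
from .records import (
    DrugProgram,
    Indication,
    Phase,
    TrialRecord,
    build_state_history,
    program_biomarker_flag,
)

__all__ = [
    "SchemaError",
    "RowError",
    "RunConfig",
    "read_trials_csv",
    "read_biomarker_registry",
    "panel_to_dataframe",
    "write_panel_csv",
    "read_panel_csv",
    "programs_to_panel",
    "write_report",
    "report_to_dict",
]


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


class RowError(ValueError):
    """A data row failed validation; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


TRIALS_COLUMNS = (
    "drug_id", "indication", "phase", "start_date", "completion_date",
    "uses_biomarker_selection", "biomarker_ids", "fda_approved",
    "approval_date", "withdrawn", "failed_endpoint",
)


def _parse_date(value, line: int, column: str) -> Optional[dt.date]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as e:
        raise RowError(line, f"unparseable {column} {value!r}: {e}") from None


def _parse_bool(value, line: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no", "", "nan"):
        return False
    raise RowError(line, f"invalid boolean in {column}: {value!r}")


def read_trials_csv(
    path: Union[str, Path], errors: Optional[List[RowError]] = None
) -> List[DrugProgram]:
    """Read a curated trial table (one row per trial) into drug programs.

    Drug-level fields (approval, withdrawal, endpoint failure) are expected
    to be constant within a drug; the first row's values win, with a
    warning-level error recorded on disagreement.  If ``errors`` is a list,
    malformed rows are collected there and skipped; otherwise the first
    malformed row raises.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    collected = errors if errors is not None else None

    def _record(line: int, exc: RowError):
        if collected is None:
            raise exc
        collected.append(exc)

    trials: Dict[str, List[TrialRecord]] = {}
    meta: Dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            indication = Indication(row["indication"])
        except ValueError:
            _record(line, RowError(line, f"unknown indication {row['indication']!r}"))
            continue
        try:
            phase = Phase(row["phase"])
        except ValueError:
            _record(line, RowError(line, f"unknown phase {row['phase']!r}"))
            continue
        try:
            start = _parse_date(row["start_date"], line, "start_date")
            if start is None:
                raise RowError(line, "start_date is mandatory")
            completion = _parse_date(row["completion_date"], line, "completion_date")
            biomarkers = tuple(
                b for b in str(row["biomarker_ids"]).split(";") if b
            )
            trial = TrialRecord(
                trial_id=f"{row['drug_id']}:{line}",
                phase=phase,
                start_date=start,
                completion_date=completion,
                indication=indication,
                uses_biomarker_selection=_parse_bool(
                    row["uses_biomarker_selection"], line, "uses_biomarker_selection"
                ),
                biomarker_ids=biomarkers,
            )
        except RowError as e:
            _record(line, e)
            continue
        except ValueError as e:
            _record(line, RowError(line, str(e)))
            continue
        drug = row["drug_id"]
        trials.setdefault(drug, []).append(trial)
        if drug not in meta:
            try:
                meta[drug] = {
                    "indication": indication,
                    "fda_approved": _parse_bool(row["fda_approved"], line, "fda_approved"),
                    "approval_date": _parse_date(row["approval_date"], line, "approval_date"),
                    "withdrawn": _parse_bool(row["withdrawn"], line, "withdrawn"),
                    "failed_endpoint": _parse_bool(
                        row["failed_endpoint"], line, "failed_endpoint"
                    ),
                }
            except RowError as e:
                _record(line, e)
                trials[drug].pop()
                continue

    programs = []
    for drug, ts in trials.items():
        if not ts:
            continue
        m = meta[drug]
        programs.append(
            DrugProgram(
                drug_id=drug,
                indication=m["indication"],
                trials=tuple(sorted(ts, key=lambda t: t.start_date)),
                fda_approved=m["fda_approved"],
                approval_date=m["approval_date"],
                withdrawn_by_manufacturer=m["withdrawn"],
                failed_primary_endpoint=m["failed_endpoint"],
            )
        )
    return programs


def read_biomarker_registry(path: Union[str, Path]) -> Dict[Tuple[str, str], dt.date]:
    """Registry CSV (biomarker_id, indication, fda_approval_date) -> mapping."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = ("biomarker_id", "indication", "fda_approval_date")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    registry = {}
    for idx, row in df.iterrows():
        line = idx + 2
        ind = Indication(row["indication"]).value
        date = _parse_date(row["fda_approval_date"], line, "fda_approval_date")
        if date is None:
            raise RowError(line, "fda_approval_date is mandatory")
        registry[(row["biomarker_id"], ind)] = date
    return registry


# ---------------------------------------------------------------------------
# Panel CSV


def programs_to_panel(
    programs: Sequence[DrugProgram],
    reference_date: dt.date,
    biomarker_rule: str = "any",
    inactivity_window_days: int = 730,
) -> PanelDataset:
    """Classify every program and assemble the panel dataset with the
    drug-level biomarker covariate."""
    subjects = []
    for prog in programs:
        history = build_state_history(
            prog, reference_date, inactivity_window_days=inactivity_window_days
        )
        subjects.append(
            Subject(
                drug_id=prog.drug_id,
                times=np.array([o.time for o in history]),
                states=tuple(
                    o.state if o.state is not None else o.censor_set for o in history
                ),
                covariates={
                    "biomarker": float(program_biomarker_flag(prog, biomarker_rule))
                },
                indication=prog.indication.value,
            )
        )
    return PanelDataset(subjects)


def panel_to_dataframe(data: PanelDataset) -> pd.DataFrame:
    cov_names = sorted({c for s in data.subjects for c in s.covariates})
    rows = []
    for subj in data.subjects:
        for t, s in zip(subj.times, subj.states):
            censored = isinstance(s, (frozenset, set))
            row = {
                "drug_id": subj.drug_id,
                "time_years": float(t),
                "state": "" if censored else int(s),
                "censor_set": ",".join(str(x) for x in sorted(s)) if censored else "",
                "indication": subj.indication or "",
            }
            for c in cov_names:
                row[c] = subj.covariates.get(c, 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


def write_panel_csv(data: PanelDataset, path: Union[str, Path]) -> None:
    panel_to_dataframe(data).to_csv(path, index=False)


def read_panel_csv(path: Union[str, Path]) -> PanelDataset:
    df = pd.read_csv(path, dtype={"drug_id": str, "state": "Int64"})
    needed = ("drug_id", "time_years", "state", "censor_set")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    cov_names = [
        c for c in df.columns if c not in needed and c != "indication"
    ]
    subjects = []
    for drug_id, g in df.groupby("drug_id", sort=False):
        g = g.sort_values("time_years")
        states = []
        for _, row in g.iterrows():
            if isinstance(row["censor_set"], str) and row["censor_set"]:
                states.append(frozenset(int(x) for x in row["censor_set"].split(",")))
            elif pd.notna(row["state"]):
                states.append(int(row["state"]))
            else:
                raise RowError(0, f"drug {drug_id}: row with neither state nor censor_set")
        first = g.iloc[0]
        subjects.append(
            Subject(
                drug_id=str(drug_id),
                times=g["time_years"].to_numpy(dtype=float),
                states=tuple(states),
                covariates={c: float(first[c]) for c in cov_names},
                indication=(str(first["indication"]) if "indication" in g.columns
                            and str(first.get("indication", "")) else None),
            )
        )
    return PanelDataset(subjects)


# ---------------------------------------------------------------------------
# Report JSON


def _round_sig(x: float, sig: int = 10) -> float:
    return float(f"{x:.{sig}g}")


def _jsonify(obj):
    if obj is None or isinstance(obj, (str, int, bool)):
        return obj
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        return None if not math.isfinite(x) else _round_sig(x)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    raise TypeError(f"cannot serialize {type(obj)}")


def _fit_dict(fit: Optional[FitResult]) -> Optional[dict]:
    if fit is None:
        return None
    hrs = {
        ("shared" if key == "shared" else f"{key[0]}->{key[1]}") + f"|{cov}": list(v)
        for (key, cov), v in fit.hazard_ratios.items()
    }
    return {
        "param_names": list(fit.spec.param_names),
        "estimates": fit.params,
        "std_errors": fit.std_errors(),
        "log_likelihood": fit.log_likelihood,
        "covariance": fit.covariance,
        "hazard_ratios": hrs,
        "converged": fit.converged,
        "n_subjects": fit.n_subjects,
        "n_observations": fit.n_observations,
    }


def _lrt_dict(lrt: Optional[LRTResult]) -> Optional[dict]:
    if lrt is None:
        return None
    return {"statistic": lrt.statistic, "df": lrt.df, "p_value": lrt.p_value}


def report_to_dict(report) -> dict:
    """Serialize an AnalysisReport / SubtypeReport to plain JSON types."""
    out = {}
    for f in dataclasses.fields(report):
        v = getattr(report, f.name)
        if isinstance(v, FitResult):
            v = _fit_dict(v)
        elif isinstance(v, LRTResult):
            v = _lrt_dict(v)
        elif f.name in ("per_phase_hazards",):
            v = {k: {lvl: list(ci) for lvl, ci in d.items()} for k, d in v.items()}
        elif f.name in ("overall_hr", "exploratory_hr") and v is not None:
            v = list(v)
        elif v is None or isinstance(v, (str, dict, list, int, float)):
            pass
        else:
            v = _fit_dict(v) if isinstance(v, FitResult) else v
        out[f.name] = _jsonify(v) if not isinstance(v, (dict, list)) else _jsonify(v)
    return out


def write_report(report, path: Union[str, Path]) -> None:
    """Deterministic JSON: sorted keys, 10-significant-digit floats,
    NaN/absent values as nulls."""
    d = report if isinstance(report, dict) else report_to_dict(report)
    text = json.dumps(_jsonify(d), sort_keys=True, indent=2, allow_nan=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Documented defaults for a full run; unknown YAML keys are rejected."""

    data: Optional[str] = None
    registry: Optional[str] = None
    output: Optional[str] = None
    covariate: str = "biomarker"
    shared_overall: bool = True
    exact_absorbing: Tuple[int, ...] = (4, 5)
    inactivity_window_days: int = 730
    validation_window_days: int = 730
    biomarker_rule: str = "any"
    gtol: float = 1e-6
    max_iter: int = 500
    seed: int = 20210223
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "exact_absorbing" in raw:
            raw["exact_absorbing"] = tuple(raw["exact_absorbing"])
        return cls(**raw)
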