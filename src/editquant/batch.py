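"""Batch analysis: parameters table, missing-file accounting, batch runs.

One analysis per spreadsheet row.  Row failures are isolated: a sample
whose motif is absent or whose files are unreadable records an error
status without aborting the remaining rows, and the same control file
may serve any number of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd

from .detect import EditDetectionResult, RunParameters, detect_edits
from .noise import NoiseModel
from .signal import DEFAULT_PHRED_CUTOFF

__all__ = [
    "PARAMETER_COLUMNS",
    "ParametersTable",
    "BatchResult",
    "ParameterError",
    "parse_parameters",
    "missing_files",
    "detect_edits_batch",
    "save_batch_skeleton",
    "percent_loss",
]

PARAMETER_COLUMNS = [
    "sample_name",
    "sample_file",
    "ctrl_file",
    "motif",
    "motif_fwd",
    "wt",
    "edit",
    "phred_cutoff",
    "p_value",
]

_DEFAULTS = {"phred_cutoff": DEFAULT_PHRED_CUTOFF, "p_value": 0.01}

_TRUE = {"true", "t", "yes", "1"}
_FALSE = {"false", "f", "no", "0"}


class ParameterError(ValueError):
    """Invalid batch parameters spreadsheet."""


@dataclass
class ParametersTable:
    """Validated batch specification, one analysis per row."""

    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    def rows(self):
        return self.data.itertuples(index=False)


@dataclass
class BatchResult:
    """Combined per-position results plus per-sample status and models."""

    combined: pd.DataFrame
    statuses: dict[str, str]  # sample_name -> "ok" | "error: ..."
    models: dict[str, NoiseModel]
    results: dict[str, EditDetectionResult] = field(default_factory=dict)

    @property
    def ok_samples(self) -> list[str]:
        return [s for s, st in self.statuses.items() if st == "ok"]

    def status_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_name": list(self.statuses), "status": list(self.statuses.values())}
        )

    def stats_table(self) -> pd.DataFrame:
        rows = [
            {"sample_name": name, **model.summary()}
            for name, model in self.models.items()
        ]
        return pd.DataFrame(rows)


def _parse_bool(value, row_number: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ParameterError(
        f"row {row_number}: cannot parse motif_fwd value {value!r} as true/false"
    )


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, dtype=str)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path, dtype=str)
    raise ParameterError(
        f"unsupported parameters file extension {path.suffix!r} (use .xlsx or .csv)"
    )


def parse_parameters(path: str | Path) -> ParametersTable:
    """Read and validate a parameters spreadsheet (.xlsx or .csv).

    Blank phred_cutoff/p_value cells get the defaults (0.001 and 0.01).
    Unknown columns are ignored with a warning; duplicate sample names,
    missing required columns and unparseable booleans are errors naming
    the offending row.
    """
    import warnings

    path = Path(path)
    raw = _read_table(path)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    missing_cols = [c for c in PARAMETER_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ParameterError(
            f"{path.name}: missing required column(s): {', '.join(missing_cols)}"
        )
    extra = [c for c in raw.columns if c not in PARAMETER_COLUMNS]
    if extra:
        warnings.warn(
            f"{path.name}: ignoring unknown column(s): {', '.join(extra)}",
            stacklevel=2,
        )
    raw = raw[PARAMETER_COLUMNS].copy()
    # Drop fully blank rows (trailing spreadsheet cruft).
    raw = raw.dropna(how="all").reset_index(drop=True)

    records = []
    seen: set[str] = set()
    for i, row in raw.iterrows():
        rownum = i + 2  # 1-based plus header, matching what the user sees
        rec = {}
        for col in ("sample_name", "sample_file", "ctrl_file", "motif", "wt", "edit"):
            val = row[col]
            if pd.isna(val) or str(val).strip() == "":
                raise ParameterError(f"row {rownum}: required cell {col!r} is blank")
            rec[col] = str(val).strip()
        if rec["sample_name"] in seen:
            raise ParameterError(
                f"row {rownum}: duplicate sample_name {rec['sample_name']!r}"
            )
        seen.add(rec["sample_name"])
        rec["motif"] = rec["motif"].upper()
        rec["wt"] = rec["wt"].upper()
        rec["edit"] = rec["edit"].upper()
        if rec["wt"] == rec["edit"]:
            raise ParameterError(f"row {rownum}: wt and edit base are both {rec['wt']!r}")
        rec["motif_fwd"] = _parse_bool(row["motif_fwd"], rownum)
        for col in ("phred_cutoff", "p_value"):
            val = row[col]
            if pd.isna(val) or str(val).strip() == "":
                rec[col] = _DEFAULTS[col]
            else:
                try:
                    rec[col] = float(val)
                except ValueError:
                    raise ParameterError(
                        f"row {rownum}: cannot parse {col} value {val!r} as a number"
                    ) from None
        records.append(rec)
    data = pd.DataFrame(records, columns=PARAMETER_COLUMNS)
    return ParametersTable(data=data)


def missing_files(table: ParametersTable, provided: set[str]) -> list[str]:
    """Referenced file names absent from ``provided`` (deduplicated, sorted)."""
    needed = set(table.data["sample_file"]) | set(table.data["ctrl_file"])
    return sorted(needed - set(provided))


def detect_edits_batch(
    table: ParametersTable,
    file_resolver: Callable[[str], Path] | str | Path,
) -> BatchResult:
    """Run :func:`detect_edits` independently for every parameters row.

    ``file_resolver`` maps a file name from the table to a path; passing
    a directory uses simple joining.  A failing row records its error
    message in the status map and contributes no combined rows.
    """
    if not callable(file_resolver):
        base = Path(file_resolver)
        file_resolver = lambda name: base / name  # noqa: E731

    combined_frames = []
    statuses: dict[str, str] = {}
    models: dict[str, NoiseModel] = {}
    results: dict[str, EditDetectionResult] = {}
    for row in table.rows():
        name = row.sample_name
        try:
            params = RunParameters(
                phred_cutoff=row.phred_cutoff, p_threshold=row.p_value
            )
            result = detect_edits(
                sample_path=file_resolver(row.sample_file),
                control_path=file_resolver(row.ctrl_file),
                motif=row.motif,
                motif_fwd=row.motif_fwd,
                wt=row.wt,
                edit=row.edit,
                params=params,
            )
        except Exception as exc:  # row isolation: capture, continue
            statuses[name] = f"error: {exc}"
            continue
        statuses[name] = "ok"
        models[name] = result.statistical_parameters
        results[name] = result
        tagged = result.sample_data.copy()
        tagged.insert(0, "sample_name", name)
        combined_frames.append(tagged)
    if combined_frames:
        combined = pd.concat(combined_frames, ignore_index=True)
    else:
        combined = pd.DataFrame()
    return BatchResult(
        combined=combined, statuses=statuses, models=models, results=results
    )


def save_batch_skeleton(path: str | Path) -> None:
    """Write an empty parameters spreadsheet with the required header.

    ``parse_parameters`` on the skeleton yields an empty, valid table.
    Extension chooses the format (.xlsx via openpyxl, .csv as text).
    """
    path = Path(path)
    empty = pd.DataFrame(columns=PARAMETER_COLUMNS)
    if path.suffix.lower() == ".csv":
        empty.to_csv(path, index=False)
    else:
        empty.to_excel(path, index=False)


def percent_loss(group_values, control_values) -> float:
    """Percent loss of expression relative to an unedited control.

    (1 - mean(group) / mean(control)) * 100.
    """
    import numpy as np

    group = np.asarray(group_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    control_mean = control.mean()
    if control_mean <= 0:
        raise ValueError(f"control mean must be positive, got {control_mean}")
    return float((1.0 - group.mean() / control_mean) * 100.0)
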