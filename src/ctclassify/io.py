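"""Readers and writers for every file format the tool touches.

Tabular data travel as TSV/CSV (instrument software exports tab-delimited
well tables), structured objects (classifier specification, calibration
model) as JSON.  Numeric serialization keeps full double precision so a
write/read round trip is exact.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .models import CalibrationModel, ClassifierSpec, CtWell, ExpressionMatrix, SurvivalRecord

PathLike = Union[str, Path]

#: Ct cell values treated as "no amplification detected" (case-insensitive).
UNDETERMINED_TOKENS = frozenset({"undetermined", "undet", "n/a", ""})

#: Default column names of a Ct export; override via ``column_map``.
DEFAULT_CT_COLUMNS = {
    "sample": "sample",
    "gene": "gene",
    "replicate": "replicate",
    "role": "role",
    "ct": "ct",
}


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


def read_ct_export(
    path: PathLike,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[CtWell]:
    """Read a tab-delimited real-time PCR well export.

    Parameters
    ----------
    path
        Tab-delimited file with a header row naming at least the sample,
        gene, replicate, role and Ct columns.
    column_map
        Maps the logical names ``sample``, ``gene``, ``replicate``,
        ``role``, ``ct`` to the column headers actually present, for
        vendor exports with different naming.

    Notes
    -----
    An empty or "Undetermined" Ct cell becomes ``ct=None``; it is never
    silently coerced to a number.
    """
    cols = dict(DEFAULT_CT_COLUMNS)
    if column_map:
        cols.update(column_map)
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for logical, actual in cols.items():
            if actual not in header:
                raise FormatError(
                    f"{path}: missing required column {actual!r} (for {logical})"
                )
        wells: list[CtWell] = []
        for lineno, row in enumerate(reader, start=2):
            raw_ct = (row[cols["ct"]] or "").strip()
            if raw_ct.lower() in UNDETERMINED_TOKENS:
                ct: Optional[float] = None
            else:
                try:
                    ct = float(raw_ct)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric Ct value {raw_ct!r}"
                    ) from exc
            try:
                replicate = int(row[cols["replicate"]])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer replicate index "
                    f"{row[cols['replicate']]!r}"
                ) from exc
            wells.append(
                CtWell(
                    sample_id=row[cols["sample"]],
                    gene_id=row[cols["gene"]],
                    replicate_index=replicate,
                    role=row[cols["role"]],
                    ct=ct,
                )
            )
    return wells


def write_ct_export(wells: Sequence[CtWell], path: PathLike) -> None:
    """Write wells as a tab-delimited export with the default columns."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "gene", "replicate", "role", "ct"])
        for w in wells:
            ct = "Undetermined" if w.ct is None else repr(w.ct)
            writer.writerow([w.sample_id, w.gene_id, w.replicate_index, w.role, ct])


def read_expression_matrix(path: PathLike) -> ExpressionMatrix:
    """Read a genes-by-samples TSV of log-normalized expression."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups}")
    for gene in frame.index:
        for sample in frame.columns:
            cell = frame.loc[gene, sample]
            try:
                float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric cell at gene {gene!r}, sample {sample!r}: "
                    f"{cell!r}"
                ) from None
    try:
        return ExpressionMatrix(frame)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_matrix(matrix: ExpressionMatrix, path: PathLike) -> None:
    matrix.frame.to_csv(Path(path), sep="\t", float_format="%.17g")


def write_classifier_spec(spec: ClassifierSpec, path: PathLike) -> None:
    Path(path).write_text(spec.model_dump_json(indent=2) + "\n")


def read_classifier_spec(path: PathLike) -> ClassifierSpec:
    return ClassifierSpec.model_validate_json(Path(path).read_text())


def write_calibration_model(model: CalibrationModel, path: PathLike) -> None:
    Path(path).write_text(model.model_dump_json(indent=2) + "\n")


def read_calibration_model(path: PathLike) -> CalibrationModel:
    return CalibrationModel.model_validate_json(Path(path).read_text())


def read_survival_table(path: PathLike) -> list[SurvivalRecord]:
    """Read a survival CSV with columns sample_id, time, event[, group]."""
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"sample_id", "time", "event"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        group = row.get("group")
        records.append(
            SurvivalRecord(
                sample_id=str(row["sample_id"]),
                time=float(row["time"]),
                event=bool(int(row["event"])),
                group_label=None if pd.isna(group) else str(group),
            )
        )
    return records


def write_survival_table(records: Sequence[SurvivalRecord], path: PathLike) -> None:
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "time": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "group": [r.group_label for r in records],
        }
    )
    frame.to_csv(Path(path), index=False, float_format="%.17g")
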