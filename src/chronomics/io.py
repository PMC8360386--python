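"""Readers and writers for the plain-text interchange formats.

Canonical formats: TSV matrices (first column = feature ids, remaining
columns = sample ids, empty cell = missing), TSV sample sheets
(sample_id, condition_id, replicate, layer), and standard GMT gene sets
(set id, description, members; tab-separated).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    Condition,
    GeneSetCollection,
    OmicsMatrix,
    SampleSheet,
    ValidationError,
    default_study_conditions,
)


def load_sample_sheet(path, conditions: dict[str, Condition] | None = None
                      ) -> SampleSheet:
    """Read a sample sheet TSV and validate it against a condition registry.

    The registry defaults to the built-in 14-condition chronological HCC
    design; pass ``conditions`` to analyse a different design.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty sample sheet") from None
    if df.empty:
        raise ValidationError(f"{path}: sample sheet has no data rows")
    df.columns = [c.strip().lower() for c in df.columns]
    if "replicate" in df.columns:
        try:
            df["replicate"] = df["replicate"].astype(int)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer replicate: {exc}")
    return SampleSheet(df, conditions or default_study_conditions())


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.entries.to_csv(path, sep="\t", index=False)


def load_matrix(path, layer: str) -> OmicsMatrix:
    """Read a features × samples TSV matrix.

    Empty cells parse to missing and are accepted only on the protein
    layer; any other non-numeric cell is an error reported with its
    coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    df.index = df.index.astype(str)
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        blank = raw.str.strip() == ""
        parsed = pd.to_numeric(raw.where(~blank), errors="coerce")
        bad = parsed.isna() & ~blank
        if bad.any():
            feat = df.index[bad][0]
            raise ValidationError(
                f"{path}: non-numeric value {raw[bad].iloc[0]!r} at "
                f"feature {feat!r}, sample {col!r}"
            )
        if blank.any() and layer != "protein":
            feat = df.index[blank][0]
            raise ValidationError(
                f"{path}: missing value at feature {feat!r}, sample "
                f"{col!r} not allowed in layer {layer!r}"
            )
        values[col] = parsed
    return OmicsMatrix(layer, values)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Write a matrix TSV; missing entries become empty cells.

    Values are printed with 12 significant digits so a load/write round
    trip is numerically faithful.
    """
    matrix.values.to_csv(path, sep="\t", float_format="%.12g", na_rep="")


def load_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (id, description, members per line).

    Duplicate members within one set are removed, keeping first
    occurrence; set order is preserved.
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    n_lines = 0
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            n_lines += 1
            if len(row) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(row)}"
                )
            set_id, desc, *members = [f.strip() for f in row]
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if set_id in sets:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate set id {set_id!r}"
                )
            sets[set_id] = (desc, deduped)
    if n_lines == 0:
        raise ValidationError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for sid, (name, members) in collection.sets.items():
            w.writerow([sid, name, *members])
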