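"""Delimited-text formats for records, series, features and frames.

The canonical records dialect is a long-format CSV: one row per cell
per cycle with columns ``condition, cell_id, cycle, alive`` and the 11
parameter columns under their canonical keys.  Instrument exports with
foreign column names, delimiters or decimal marks are read through a
:class:`RecordsTableSchema` column map (one parameter per column, the
"wide" dialect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .fft_profiler import FEATURE_COLUMNS, FeatureMatrix
from .params import PARAM_KEYS
from .simulate import FieldFrame

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A records file does not match its declared schema."""


@dataclass(frozen=True)
class RecordsTableSchema:
    """How to read a delimited records table.

    ``column_map`` maps external column names to internal labels; it
    must cover all 11 parameters plus ``cell_id`` and ``cycle``
    (``condition`` and ``alive`` are optional and defaulted).
    """

    dialect: str = "long"
    column_map: dict[str, str] = field(default_factory=dict)
    delimiter: str = ","
    decimal: str = "."

    def __post_init__(self) -> None:
        if self.dialect not in ("long", "wide"):
            raise SchemaError(f"unknown dialect {self.dialect!r}")
        if self.dialect == "wide":
            targets = list(self.column_map.values())
            for key in PARAM_KEYS:
                if targets.count(key) != 1:
                    raise SchemaError(
                        f"parameter {key!r} must be mapped exactly once")
            for key in ("cell_id", "cycle"):
                if key not in targets:
                    raise SchemaError(f"required column {key!r} not mapped")


CANONICAL_SCHEMA = RecordsTableSchema()


def write_records(records: pd.DataFrame, path) -> None:
    """Write records in the canonical long dialect."""
    records.to_csv(path, index=False)


def read_records(path, schema: RecordsTableSchema | None = None) -> pd.DataFrame:
    """Read and validate a records table under a schema.

    Unknown columns are ignored with a warning; a missing mapped column
    or a non-numeric parameter cell raises :class:`SchemaError`.
    """
    schema = schema or CANONICAL_SCHEMA
    df = pd.read_csv(path, sep=schema.delimiter, decimal=schema.decimal)
    if schema.dialect == "wide":
        missing = [c for c in schema.column_map if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mapped column(s): {missing}")
        df = df.rename(columns=schema.column_map)
    expected = {"cell_id", "cycle", *PARAM_KEYS}
    missing = sorted(expected - set(df.columns))
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    known = {"condition", "alive", "volume", *expected}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("ignoring unknown column(s): %s", unknown)
        df = df.drop(columns=unknown)
    if "condition" not in df.columns:
        df["condition"] = "unknown"
    if "alive" not in df.columns:
        df["alive"] = True
    for col in PARAM_KEYS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(values.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if bad.size:
            raise SchemaError(
                f"non-numeric value in column {col!r} at data row {bad[0] + 1}")
        df[col] = values
    df["cycle"] = df["cycle"].astype(int)
    n_cells = df.groupby("condition")["cell_id"].nunique()
    logger.info("read %d records; cells per condition: %s",
                len(df), n_cells.to_dict())
    cols = ["condition", "cell_id", "cycle", "alive", *PARAM_KEYS]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]


def write_series(series, path) -> None:
    """Write a ConditionSeries as cycle, mean_<p>, sd_<p>, n_cells."""
    out = pd.concat(
        [series.mean.add_prefix("mean_"), series.sd.add_prefix("sd_")], axis=1)
    out["n_cells"] = series.n_cells
    out.to_csv(path, index_label="cycle")


def write_feature_matrix(matrix: FeatureMatrix, path,
                         precision: int | None = None) -> None:
    """Write a feature matrix in the printed two-block layout
    (factor, sample, 11 parameter columns)."""
    from .datasets import export_reference_features
    if precision == 2:
        Path(path).write_text(export_reference_features(matrix))
        return
    from .params import PARAM_LABELS
    labels = [PARAM_LABELS[k] for k in PARAM_KEYS]
    lines = ["factor,sample," + ",".join(labels)]
    for factor, prefix in (("amplitude", "amp"), ("phase", "phase")):
        for cond in matrix.conditions:
            vals = [repr(float(matrix.data.loc[cond, f"{prefix}_{key}"]))
                    for key in PARAM_KEYS]
            lines.append(f"{factor},{cond}," + ",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_matrix(path, normalized: bool = False) -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    from .params import LABEL_TO_KEY
    long = pd.read_csv(path, float_precision="round_trip")
    conditions = list(dict.fromkeys(long["sample"]))
    data = pd.DataFrame(index=pd.Index(conditions, name="condition"),
                        columns=list(FEATURE_COLUMNS), dtype=float)
    prefixes = {"amplitude": "amp", "phase": "phase"}
    for _, row in long.iterrows():
        prefix = prefixes[row["factor"]]
        for label, key in LABEL_TO_KEY.items():
            data.loc[row["sample"], f"{prefix}_{key}"] = row[label]
    return FeatureMatrix(data=data, normalized=normalized)


# ---------------------------------------------------------------------------
# frame grids as portable plain text

def write_frames(frames, out_dir) -> int:
    """Write each frame as three plain-text grids; returns frame count."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = 0
    for frame in frames:
        stem = out / f"cycle_{frame.cycle:04d}"
        np.savetxt(f"{stem}_mask.txt", frame.label_mask, fmt="%d")
        np.savetxt(f"{stem}_ri.txt", frame.ri_map, fmt="%.6f")
        np.savetxt(f"{stem}_height.txt", frame.height_map, fmt="%.4f")
        n += 1
    return n


def read_frames(in_dir) -> Iterator[FieldFrame]:
    """Read frames written by :func:`write_frames`, in cycle order."""
    masks = sorted(Path(in_dir).glob("cycle_*_mask.txt"))
    if not masks:
        raise FileNotFoundError(f"no frame files under {in_dir}")
    for mask_path in masks:
        cycle = int(mask_path.stem.split("_")[1])
        stem = str(mask_path)[: -len("_mask.txt")]
        yield FieldFrame(
            cycle=cycle,
            label_mask=np.loadtxt(f"{stem}_mask.txt", dtype=int, ndmin=2),
            ri_map=np.loadtxt(f"{stem}_ri.txt", ndmin=2),
            height_map=np.loadtxt(f"{stem}_height.txt", ndmin=2),
        )
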