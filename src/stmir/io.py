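"""File readers/writers for the formats the CLI consumes and emits.

Delimited text carries expression matrices (features in rows, header =
sample IDs); HDF5 carries the integrated training set and activity
matrices; GMT carries gene sets; two-column TSV carries miRNA-target pairs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Tuple

import h5py
import numpy as np
import pandas as pd

from .types import ActivityMatrix, ExprMatrix, IntegratedTrainingSet


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expr_table(path, modality: str, cohort: str, stage: str = "raw") -> ExprMatrix:
    """Read a features x samples delimited table into an ExprMatrix."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return ExprMatrix(values=df, modality=modality, cohort=cohort, stage=stage)


def write_expr_table(m: ExprMatrix, path) -> None:
    path = Path(path)
    m.values.to_csv(path, sep=_sep_for(path))


def _write_df(grp: h5py.Group, name: str, df: pd.DataFrame) -> None:
    g = grp.create_group(name)
    g.create_dataset("values", data=df.to_numpy(dtype=float))
    g.create_dataset("index", data=np.array(df.index.astype(str), dtype="S"))
    g.create_dataset("columns", data=np.array(df.columns.astype(str), dtype="S"))


def _read_df(grp: h5py.Group, name: str) -> pd.DataFrame:
    g = grp[name]
    return pd.DataFrame(
        g["values"][...],
        index=[x.decode() for x in g["index"][...]],
        columns=[x.decode() for x in g["columns"][...]],
    )


def write_training_set(ts: IntegratedTrainingSet, path) -> None:
    """Persist an integrated training set to an HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "stmir-integrated"
        fh.attrs["format_version"] = 1
        _write_df(fh, "X", ts.X)
        _write_df(fh, "Y", ts.Y)
        _write_df(fh, "x_scaler", ts.x_scaler)
        _write_df(fh, "y_scaler", ts.y_scaler)
        fh.create_dataset(
            "cohort_of_sample",
            data=np.array(ts.cohort_of_sample.astype(str), dtype="S"),
        )


def read_training_set(path) -> IntegratedTrainingSet:
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("format") != "stmir-integrated":
            raise ValueError(f"{path} is not a stmir integrated training set")
        X = _read_df(fh, "X")
        cohorts = pd.Series(
            [x.decode() for x in fh["cohort_of_sample"][...]], index=X.index
        )
        return IntegratedTrainingSet(
            X=X,
            Y=_read_df(fh, "Y"),
            x_scaler=_read_df(fh, "x_scaler"),
            y_scaler=_read_df(fh, "y_scaler"),
            cohort_of_sample=cohorts,
        )


def write_activity(act: ActivityMatrix, path) -> None:
    """Write an activity matrix; .h5 -> HDF5 container, otherwise TSV."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.attrs["format"] = "stmir-activity"
            fh.attrs["model_id"] = act.model_id
            _write_df(fh, "activity", act.values)
    else:
        act.values.to_csv(path, sep="\t")


def read_activity(path) -> ActivityMatrix:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            if fh.attrs.get("format") != "stmir-activity":
                raise ValueError(f"{path} is not a stmir activity matrix")
            return ActivityMatrix(
                values=_read_df(fh, "activity"),
                model_id=str(fh.attrs.get("model_id", "unknown")),
            )
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ActivityMatrix(values=df)


def read_abundance(path) -> pd.DataFrame:
    """Spot x cell-type abundance table (deconvolution tool export)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.select_dtypes(exclude="number").shape[1]:
        raise ValueError("abundance table must be numeric")
    return df


def read_pairs(path) -> List[Tuple[str, str]]:
    """Two-column (miRNA, target gene) TSV, no header."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed pair line: {line!r}")
        pairs.append((parts[0], parts[1]))
    return pairs


def read_gmt(path) -> Dict[str, List[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: Dict[str, List[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
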