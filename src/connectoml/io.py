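"""Plain-text readers and writers for every pipeline artifact.

All tabular artifacts are TSV with fixed, documented headers; reports and
NBS components are JSON.  Floats are written with 12 significant digits so
matrices round-trip through decimal text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from connectoml.errors import DataError

FLOAT_FMT = "%.12g"

MANIFEST_REQUIRED = ("subject_id", "label", "age", "sex", "education")


def write_matrix_tsv(path: Path | str, values: np.ndarray, row_prefix: str = "roi") -> None:
    """Square or rectangular matrix with a `roi_id` header column."""
    values = np.asarray(values)
    n, m = values.shape
    with open(path, "w") as fh:
        fh.write("roi_id\t" + "\t".join(f"c{j}" for j in range(m)) + "\n")
        for i in range(n):
            row = "\t".join(FLOAT_FMT % v for v in values[i])
            fh.write(f"{i}\t{row}\n")


def read_matrix_tsv(path: Path | str) -> np.ndarray:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "roi_id":
            raise DataError(f"{path}: line 1: expected 'roi_id' header column")
        width = len(header) - 1
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != width + 1:
                raise DataError(
                    f"{path}: line {lineno}: expected {width + 1} fields, got {len(parts)}"
                )
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from None
    return np.asarray(rows)


def write_timeseries_tsv(path: Path | str, matrix: np.ndarray) -> None:
    """One subject's ROI x time matrix (rows = ROIs)."""
    write_matrix_tsv(path, matrix)


read_timeseries_tsv = read_matrix_tsv


def write_manifest(path: Path | str, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_manifest(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in MANIFEST_REQUIRED:
        if col not in df.columns:
            raise DataError(f"{path}: manifest missing column {col!r}")
    bad = df[list(MANIFEST_REQUIRED)].isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise DataError(f"{path}: line {line}: missing required covariate value")
    return df


def write_node_table(path: Path | str, module_assignment: np.ndarray) -> None:
    df = pd.DataFrame(
        {
            "roi_id": np.arange(len(module_assignment), dtype=int),
            "label": [f"ROI_{i:03d}" for i in range(len(module_assignment))],
            "module_id": np.asarray(module_assignment, dtype=int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_node_table(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("roi_id", "module_id"):
        if col not in df.columns:
            raise DataError(f"{path}: node table missing column {col!r}")
    return df


def write_json(path: Path | str, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: Path | str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_stack(directory: Path | str, grid, networks) -> None:
    """One TSV per grid value plus a JSON index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for s, A in zip(grid, networks):
        name = f"sparsity_{round(float(s) * 100):03d}.tsv"
        write_matrix_tsv(directory / name, np.asarray(A, dtype=int))
        names.append({"sparsity": round(float(s), 4), "file": name})
    write_json(directory / "index.json", {"networks": names})


def load_stack(directory: Path | str):
    """Inverse of :func:`save_stack`; returns (grid, networks)."""
    directory = Path(directory)
    index = read_json(directory / "index.json")
    grid, networks = [], []
    for entry in index["networks"]:
        grid.append(entry["sparsity"])
        networks.append(read_matrix_tsv(directory / entry["file"]).astype(np.int8))
    return np.asarray(grid), networks


def write_table(path: Path | str, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
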