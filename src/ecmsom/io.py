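"""Plain-text readers and writers for every pipeline artifact.

All tabular artifacts are TSV/CSV with headers; nested results are
JSON. Each writer has a reader that round-trips to an equal in-memory
object, which the test suite asserts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SpectraMatrix

__all__ = [
    "write_counts", "read_counts", "write_meta", "read_meta",
    "write_chemistry", "read_chemistry", "write_spectra", "read_spectra",
    "write_annotations", "read_annotations", "write_markers", "read_markers",
    "write_json", "read_json",
]


def write_counts(counts: pd.DataFrame, path) -> None:
    """Genes x samples integer counts as TSV (gene ids in the first column)."""
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_meta(meta: pd.DataFrame, path) -> None:
    """Sample metadata (sample_id, time_point, replicate) as TSV."""
    meta.to_csv(path, sep="\t", index=False)


def read_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_chemistry(chem: pd.DataFrame, path) -> None:
    chem.to_csv(path, index=False)


def read_chemistry(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spectra(spectra: SpectraMatrix, path, axis_name: str = "axis") -> None:
    """Spectra as CSV: first column the energy/wavenumber axis, one column per sample."""
    df = pd.DataFrame(spectra.intensities.T, columns=list(spectra.sample_ids))
    df.insert(0, axis_name, spectra.axis)
    df.to_csv(path, index=False)


def read_spectra(path) -> SpectraMatrix:
    df = pd.read_csv(path)
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    return SpectraMatrix(
        axis=axis,
        intensities=df.iloc[:, 1:].to_numpy(dtype=float).T,
        sample_ids=tuple(df.columns[1:]),
    )


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_markers(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, sep="\t", index_label="sample_id")


def read_markers(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
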