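"""Reading and writing datasets and reports.

Datasets travel as CSV/TSV (rows = stimuli, header names the input
dimensions, optional ``label`` column with 1-based classes) or as a
compressed ``.npz`` array container with keys ``Y``, ``labels``, ``true_z``,
``true_c``.  Model and circuit parameters serialize to JSON through their
own ``to_json`` / ``from_json`` methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import Dataset

__all__ = ["read_dataset", "write_dataset"]


def write_dataset(data: Dataset, path) -> None:
    path = str(path)
    if path.endswith(".npz"):
        arrays = {"Y": data.Y}
        for key in ("labels", "true_z", "true_c"):
            val = getattr(data, key)
            if val is not None:
                arrays[key] = val
        np.savez_compressed(path, **arrays)
        return
    sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    df = pd.DataFrame(data.Y, columns=[f"d{i}" for i in range(data.n_dims)])
    if data.labels is not None:
        df["label"] = data.labels
    df.to_csv(path, sep=sep, index=False)


def read_dataset(path) -> Dataset:
    path = str(path)
    if path.endswith(".npz"):
        with np.load(path) as npz:
            return Dataset(
                Y=npz["Y"],
                labels=npz["labels"] if "labels" in npz else None,
                true_z=npz["true_z"] if "true_z" in npz else None,
                true_c=npz["true_c"] if "true_c" in npz else None,
            )
    sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy()
    return Dataset(Y=df.to_numpy(dtype=float), labels=labels)
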