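"""HDF5 container for paired (source layout, stationary field) datasets.

Layout: datasets ``/inputs`` and ``/targets`` of shape (n, L, L) float32,
index arrays ``/train_idx`` and ``/test_idx``, and a ``/meta`` group whose
attributes record the generating conditions (L, D, gamma, radius, n_samples,
seed, split_fraction, format_version).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .solver import DatasetSplit

__all__ = ["save_dataset", "load_dataset"]


def save_dataset(path: str | Path, ds: DatasetSplit) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=ds.inputs.astype(np.float32))
        f.create_dataset("targets", data=ds.targets.astype(np.float32))
        f.create_dataset("train_idx", data=np.asarray(ds.train_idx, dtype=np.int64))
        f.create_dataset("test_idx", data=np.asarray(ds.test_idx, dtype=np.int64))
        meta = f.create_group("meta")
        for k, v in ds.meta.items():
            meta.attrs[k] = v


def load_dataset(path: str | Path) -> DatasetSplit:
    with h5py.File(path, "r") as f:
        ds = DatasetSplit(
            inputs=f["inputs"][...],
            targets=f["targets"][...],
            train_idx=f["train_idx"][...],
            test_idx=f["test_idx"][...],
            meta={k: _scalar(v) for k, v in f["meta"].attrs.items()},
        )
    return ds


def _scalar(v):
    return v.item() if isinstance(v, np.generic) else v
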