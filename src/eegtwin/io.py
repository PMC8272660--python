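"""Interchange formats.

Epoch sets are stored as one directory per subject:

    <dir>/epochs.npz    — array "data" (trial x channel x sample, float64)
    <dir>/labels.tsv    — columns: trial, label
    <dir>/metadata.yaml — sampling_rate, channel_names, optional band

Feature matrices round-trip through delimited text: a header row of feature
names plus a trailing "label" column.  Fitted binary models round-trip
through the JSON container in :mod:`eegtwin.classifiers`.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .containers import EpochSet, FeatureMatrix

PathLike = Union[str, os.PathLike]


def save_epochs(epochs: EpochSet, directory: PathLike) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(d / "epochs.npz", data=epochs.data)
    pd.DataFrame({
        "trial": np.arange(epochs.n_trials),
        "label": epochs.labels,
    }).to_csv(d / "labels.tsv", sep="\t", index=False)
    meta = {
        "sampling_rate": float(epochs.sampling_rate),
        "channel_names": list(epochs.channel_names),
        "band": None if epochs.band is None else [float(b) for b in epochs.band],
    }
    with open(d / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_epochs(directory: PathLike) -> EpochSet:
    d = Path(directory)
    data = np.load(d / "epochs.npz")["data"]
    labels = pd.read_csv(d / "labels.tsv", sep="\t")["label"].to_numpy()
    with open(d / "metadata.yaml") as fh:
        meta = yaml.safe_load(fh)
    band = meta.get("band")
    return EpochSet(
        data=data,
        labels=labels,
        sampling_rate=meta["sampling_rate"],
        channel_names=meta["channel_names"],
        band=None if band is None else tuple(band),
    )


def save_features(features: FeatureMatrix, path: PathLike) -> None:
    df = pd.DataFrame(features.values, columns=list(features.feature_names))
    df["label"] = features.labels
    df.to_csv(path, sep="\t", index=False)


def load_features(path: PathLike) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    labels = df.pop("label").to_numpy()
    return FeatureMatrix(values=df.to_numpy(dtype=float), labels=labels,
                         feature_names=list(df.columns))
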