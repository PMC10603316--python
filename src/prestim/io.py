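"""On-disk CSV formats for epochs, features and results.

Epoch layout (one file per condition): an initial comment line ``# fs=<Hz>``
followed by a header ``epoch_id,channel_id,label,s0,...,s{n-1}`` and one row
per epoch-channel. All rows of an epoch must agree on the label and carry
the same number of samples; labels must be binary.

Feature matrices are written with one column per feature, named
``<channel>_<kind>_<index>``, plus a leading ``label`` column. Result
writers produce tidy tables (one row per repeat/classifier/segment).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .classification import CVResult, DynamicResult
from .features import FeatureMatrix
from .selection import SelectionResult
from .signal import EpochSet

__all__ = [
    "write_epochs_csv",
    "read_epochs_csv",
    "write_features_csv",
    "read_features_csv",
    "selection_to_frame",
    "cv_result_to_frame",
    "dynamic_result_to_frame",
    "best_points_to_frame",
]


class EpochCsvError(ValueError):
    """Raised when an epoch CSV violates the documented layout."""


def write_epochs_csv(epochs: EpochSet, path: str | Path) -> None:
    """Write an EpochSet in the documented per-epoch-channel row layout."""
    path = Path(path)
    n_e, n_c, n_s = epochs.data.shape
    cols = [f"s{i}" for i in range(n_s)]
    frame = pd.DataFrame(epochs.data.reshape(n_e * n_c, n_s), columns=cols)
    frame.insert(0, "epoch_id", np.repeat(np.arange(n_e), n_c))
    frame.insert(1, "channel_id", np.tile(epochs.channel_ids, n_e))
    frame.insert(2, "label", np.repeat(epochs.labels, n_c))
    with open(path, "w") as fh:
        fh.write(f"# fs={epochs.fs}\n")
        frame.to_csv(fh, index=False)


def read_epochs_csv(path: str | Path, fs: float | None = None) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs_csv`.

    ``fs`` overrides (or supplies, for files lacking the comment line) the
    sampling rate.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# fs="):
            fs = float(first[len("# fs="):]) if fs is None else fs
            frame = pd.read_csv(fh)
        else:
            if fs is None:
                raise EpochCsvError(f"{path}: no '# fs=' line and no fs argument")
            fh.seek(0)
            frame = pd.read_csv(fh)
    required = {"epoch_id", "channel_id", "label"}
    if not required <= set(frame.columns):
        raise EpochCsvError(f"{path}: missing required columns {required - set(frame.columns)}")
    sample_cols = [c for c in frame.columns if c not in required]
    if frame[sample_cols].isna().any().any():
        bad = int(frame.index[frame[sample_cols].isna().any(axis=1)][0])
        raise EpochCsvError(f"{path}: ragged or non-numeric row at data row {bad}")
    if not frame["label"].isin((0, 1)).all():
        bad = int(frame.index[~frame["label"].isin((0, 1))][0])
        raise EpochCsvError(f"{path}: non-binary label at data row {bad}")

    epoch_ids = frame["epoch_id"].to_numpy()
    unique_epochs, first_pos = np.unique(epoch_ids, return_index=True)
    order = unique_epochs[np.argsort(first_pos)]
    groups = [frame[epoch_ids == e] for e in order]
    n_channels = len(groups[0])
    channel_ids = groups[0]["channel_id"].astype(str).tolist()
    labels, blocks = [], []
    for e, g in zip(order, groups):
        if len(g) != n_channels:
            raise EpochCsvError(f"{path}: epoch {e} has {len(g)} channel rows, expected {n_channels}")
        if g["label"].nunique() != 1:
            raise EpochCsvError(f"{path}: epoch {e} carries inconsistent labels")
        labels.append(int(g["label"].iloc[0]))
        blocks.append(g[sample_cols].to_numpy(dtype=float))
    data = np.stack(blocks)
    return EpochSet(data=data, fs=fs, labels=np.array(labels), channel_ids=channel_ids)


def _feature_names(fm: FeatureMatrix) -> list[str]:
    names, per_channel_counter = [], {}
    for ch_idx in fm.feature_channel_map:
        ch = fm.channel_ids[ch_idx] if fm.channel_ids else f"ch{ch_idx}"
        k = per_channel_counter.get(ch_idx, 0)
        per_channel_counter[ch_idx] = k + 1
        names.append(f"{ch}_{fm.feature_kind}_{k}")
    return names


def write_features_csv(fm: FeatureMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(fm.values, columns=_feature_names(fm))
    frame.insert(0, "label", fm.labels)
    frame.to_csv(path, index=False)


def read_features_csv(path: str | Path, feature_kind: str) -> FeatureMatrix:
    frame = pd.read_csv(path)
    labels = frame.pop("label").to_numpy()
    channels = [c.rsplit(f"_{feature_kind}_", 1)[0] for c in frame.columns]
    channel_ids = list(dict.fromkeys(channels))
    index = {ch: i for i, ch in enumerate(channel_ids)}
    fmap = np.array([index[ch] for ch in channels])
    return FeatureMatrix(values=frame.to_numpy(dtype=float), labels=labels,
                         feature_channel_map=fmap, feature_kind=feature_kind,
                         channel_ids=channel_ids)


def selection_to_frame(sel: SelectionResult) -> pd.DataFrame:
    flag = np.zeros(sel.r2.size, dtype=bool)
    flag[sel.selected] = True
    return pd.DataFrame({"feature": np.arange(sel.r2.size), "r2": sel.r2,
                         "selected": flag})


def cv_result_to_frame(cv: CVResult) -> pd.DataFrame:
    rows = [
        {"repeat": r, "classifier": kind, "accuracy": cv.mean_accuracy[r, c]}
        for r in range(cv.mean_accuracy.shape[0])
        for c, kind in enumerate(cv.classifier_kinds)
    ]
    return pd.DataFrame(rows)


def dynamic_result_to_frame(dyn: DynamicResult) -> pd.DataFrame:
    n_class, n_rep, n_seg = dyn.acc_sequences.shape
    rows = []
    for c, kind in enumerate(dyn.classifier_kinds):
        for r in range(n_rep):
            for s in range(n_seg):
                rows.append({"classifier": kind, "repeat": r, "segment": s,
                             "time_s": dyn.segment_times[s],
                             "accuracy": dyn.acc_sequences[c, r, s]})
    return pd.DataFrame(rows)


def best_points_to_frame(best_points: dict) -> pd.DataFrame:
    """Table of significant best accuracies: classifier, accuracy, time."""
    rows = [
        {"classifier": kind, "accuracy": bp.accuracy, "time_s": bp.time_s,
         "segment": bp.segment_index}
        for kind, bp in best_points.items() if bp is not None
    ]
    return pd.DataFrame(rows, columns=["classifier", "accuracy", "time_s", "segment"])
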