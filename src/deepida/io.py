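"""Delimited-text input/output for view matrices, labels and results.

View matrices are TSV or CSV, samples in rows: a header row of feature
names and a first column of sample identifiers.  Labels are two columns
(sample_id, class).  The delimiter is auto-detected from the header line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_view_matrix",
    "write_view_matrix",
    "read_labels",
    "write_labels",
    "write_rankings",
    "write_predictions",
    "write_json",
]


def _sniff_delim(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_view_matrix(path):
    """Read one view; returns (matrix, feature_names, sample_ids)."""
    sep = _sniff_delim(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen = set()
    for name in header:           # pandas would silently mangle duplicates
        if name in seen:
            raise ValueError(f"duplicate feature name {name!r} in {path}")
        seen.add(name)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = header
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    try:
        X = df.to_numpy(dtype=float)
    except ValueError as err:
        raise ValueError(f"non-numeric cell in {path}: {err}") from err
    if not np.all(np.isfinite(X)):
        raise ValueError(f"non-finite value in {path}")
    return X, list(df.columns), [str(i) for i in df.index]


def write_view_matrix(path, X, feature_names, sample_ids, sep: str = "\t") -> None:
    pd.DataFrame(X, index=sample_ids, columns=feature_names).to_csv(path, sep=sep)


def read_labels(path):
    """Read (sample_id, class) pairs; returns (labels array, sample_ids)."""
    df = pd.read_csv(path, sep=_sniff_delim(path))
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs sample_id and class columns")
    ids = [str(v) for v in df.iloc[:, 0]]
    return df.iloc[:, 1].to_numpy(), ids


def write_labels(path, labels, sample_ids, sep: str = "\t") -> None:
    pd.DataFrame({"sample_id": sample_ids, "class": labels}).to_csv(
        path, sep=sep, index=False)


def write_rankings(path, ranking, feature_names, view: int, sep: str = "\t") -> None:
    """Per-view ranking table with normalized importance."""
    pr = ranking.proportions[view]
    peak = pr.max() if pr.max() > 0 else 1.0
    order = ranking.order[view]
    rank = np.empty_like(order)
    rank[order] = np.arange(1, order.size + 1)
    pd.DataFrame({
        "feature_name": feature_names,
        "n_k": ranking.hits[view],
        "N_k": ranking.exposures[view],
        "proportion": pr,
        "normalized_importance": pr / peak,
        "rank": rank,
    }).sort_values("rank").to_csv(path, sep=sep, index=False)


def write_predictions(path, sample_ids, predicted, H_pooled, centroids,
                      true_labels=None, sep: str = "\t") -> None:
    """Prediction table: ids, labels, and per-class pooled distances."""
    d2 = ((np.asarray(H_pooled)[:, None, :] - centroids.pooled[None]) ** 2).sum(2)
    cols = {"sample_id": sample_ids}
    if true_labels is not None:
        cols["true_label"] = true_labels
    cols["predicted_label"] = predicted
    for k, cls in enumerate(centroids.classes):
        cols[f"dist_class{cls}"] = np.sqrt(d2[:, k])
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
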