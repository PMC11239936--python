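"""Prediction-table CSV dialect: read, validate, write.

Each base classifier's per-sample class probabilities are exchanged as a
UTF-8 comma-separated file with header

    sample_id,true_label,p_<class1>,...,p_<classK>

``true_label`` may be empty for unlabeled data.  The class set is declared
by the header (never inferred from labels), the probability column order is
the class order, and a fusion run requires identical headers across its N
input files.  Rows whose probabilities drift from summing to 1 by more than
1e-3 are renormalized with a logged warning; a drift above 0.05 is a hard
error.  Floats are written repr-faithfully so a read-back reproduces the
table bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionTable",
    "read_predictions",
    "read_fused",
    "write_predictions",
    "write_run_metadata",
]

ROW_SUM_WARN = 1e-3
ROW_SUM_FAIL = 0.05


@dataclass
class PredictionTable:
    """In-memory form of one classifier's prediction CSV."""

    sample_ids: list
    class_labels: list
    probabilities: np.ndarray  # (n_samples, K)
    true_labels: list | None = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.class_labels = [str(c) for c in self.class_labels]
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 2:
            if self.probabilities.size == 0:
                self.probabilities = self.probabilities.reshape(
                    0, len(self.class_labels)
                )
            else:
                raise ValueError(
                    f"probabilities must be 2-D, got {self.probabilities.shape}"
                )
        n, k = self.probabilities.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} probability rows"
            )
        if k != len(self.class_labels):
            raise ValueError(
                f"{len(self.class_labels)} class labels for {k} probability columns"
            )
        if self.true_labels is not None and len(self.true_labels) != n:
            raise ValueError(
                f"{len(self.true_labels)} true labels for {n} rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            seen: set = set()
            dupes = sorted({s for s in self.sample_ids if s in seen or seen.add(s)})
            raise ValueError(f"duplicate sample id(s): {dupes!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def argmax_labels(self) -> np.ndarray:
        """Predicted label per row (highest probability, first on ties)."""
        labels = np.asarray(self.class_labels, dtype=object)
        return labels[np.argmax(self.probabilities, axis=1)]

    def accuracy(self) -> float:
        if self.true_labels is None:
            raise ValueError("table carries no true labels")
        return float(
            np.mean(self.argmax_labels() == np.asarray(self.true_labels, dtype=object))
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids})
        df["true_label"] = (
            self.true_labels if self.true_labels is not None else [""] * self.n_samples
        )
        for j, lab in enumerate(self.class_labels):
            df[f"p_{lab}"] = self.probabilities[:, j]
        return df


def read_predictions(path) -> PredictionTable:
    """Read and validate one prediction CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"prediction file not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "true_label": str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty prediction file: {path}") from exc
    cols = list(df.columns)
    if cols[:2] != ["sample_id", "true_label"]:
        raise ValueError(
            f"{path}: header must start 'sample_id,true_label', got {cols[:2]!r}"
        )
    prob_cols = cols[2:]
    if not prob_cols or any(not c.startswith("p_") for c in prob_cols):
        raise ValueError(
            f"{path}: probability columns must be named p_<class>; got {prob_cols!r}"
        )
    class_labels = [c[2:] for c in prob_cols]
    try:
        probs = df[prob_cols].apply(pd.to_numeric, errors="raise").to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric probability value: {exc}") from exc
    if probs.size and (np.any(probs < 0) or np.any(probs > 1)):
        raise ValueError(f"{path}: probabilities must lie in [0, 1]")
    if probs.size:
        sums = probs.sum(axis=1)
        bad = np.abs(sums - 1.0) > ROW_SUM_FAIL
        if np.any(bad):
            rows = np.flatnonzero(bad)[:10].tolist()
            raise ValueError(
                f"{path}: row(s) {rows} deviate from sum 1 by more than "
                f"{ROW_SUM_FAIL}"
            )
        drift = np.abs(sums - 1.0) > ROW_SUM_WARN
        if np.any(drift):
            logger.warning(
                "%s: renormalized %d row(s) with |sum - 1| > %g",
                path,
                int(drift.sum()),
                ROW_SUM_WARN,
            )
            probs[drift] = probs[drift] / sums[drift, None]
    true_raw = df["true_label"]
    if true_raw.isna().all() or (true_raw.astype(str) == "").all():
        true_labels = None
    else:
        true_labels = ["" if pd.isna(v) else str(v) for v in true_raw]
    return PredictionTable(
        sample_ids=df["sample_id"].tolist(),
        class_labels=class_labels,
        probabilities=probs,
        true_labels=true_labels,
    )


def write_predictions(table: PredictionTable, path) -> Path:
    """Write a table in the dialect; read(write(t)) reproduces t exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = ["sample_id", "true_label"] + [f"p_{c}" for c in table.class_labels]
    lines = [",".join(header)]
    truth = (
        table.true_labels
        if table.true_labels is not None
        else [""] * table.n_samples
    )
    for i in range(table.n_samples):
        probs = [repr(float(v)) for v in table.probabilities[i]]
        lines.append(",".join([table.sample_ids[i], str(truth[i])] + probs))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_fused(path) -> pd.DataFrame:
    """Read a fused output CSV: p_ columns hold raw fused scores.

    Unlike :func:`read_predictions`, fused max--min scores need not sum to
    1, and the frame carries a ``predicted_label`` column recording the
    fusion rule's own tie-broken decision.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "true_label": str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty fused file: {path}") from exc
    cols = list(df.columns)
    if cols[:2] != ["sample_id", "true_label"]:
        raise ValueError(
            f"{path}: header must start 'sample_id,true_label', got {cols[:2]!r}"
        )
    prob_cols = [c for c in cols[2:] if c.startswith("p_")]
    if not prob_cols:
        raise ValueError(f"{path}: no p_<class> score columns found")
    return df


def write_run_metadata(path, metadata: dict) -> Path:
    """JSON sidecar recording a run's densities, lambda, strategy, seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o).__name__}")

    path.write_text(
        json.dumps(metadata, indent=2, sort_keys=True, default=_default) + "\n",
        encoding="utf-8",
    )
    return path
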