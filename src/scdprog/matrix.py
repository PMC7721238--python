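"""Subjects-by-features container shared by every pipeline stage.

The :class:`FeatureMatrix` is the universal currency of the package: a dense
real matrix of subjects x named features, optionally carrying a binary outcome
label per subject (1 = progressive, converting to MCI at follow-up;
0 = stable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix"]


@dataclass
class FeatureMatrix:
    """Dense subjects x features matrix with named columns and optional labels.

    Parameters
    ----------
    subject_ids
        One identifier per row, unique.
    feature_names
        One name per column, unique.
    values
        Real matrix of shape ``(n_subjects, n_features)``; no missing values.
    labels
        Optional binary outcome per subject (1 = progressive, 0 = stable).
    """

    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_names)} features"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing or non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.subject_ids),):
                raise ValueError("labels must have one entry per subject")
            if not np.isin(self.labels, [0, 1]).all():
                raise ValueError("labels must be binary (0 = stable, 1 = progressive)")

    # -- basic geometry -----------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    # -- slicing ------------------------------------------------------------

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        """Restrict to the given feature columns (in the given order)."""
        idx = [self.feature_index(n) for n in names]
        return FeatureMatrix(
            subject_ids=list(self.subject_ids),
            feature_names=[self.feature_names[i] for i in idx],
            values=self.values[:, idx].copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def subset_subjects(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            subject_ids=[self.subject_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            values=self.values[idx, :].copy(),
            labels=None if self.labels is None else self.labels[idx].copy(),
        )

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.subject_ids, columns=self.feature_names)
        df.index.name = "subject_id"
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_column: str | None = "label") -> "FeatureMatrix":
        df = df.copy()
        labels = None
        if label_column is not None and label_column in df.columns:
            labels = df.pop(label_column).to_numpy()
        return cls(
            subject_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            labels=labels,
        )

    def to_csv(self, path: str | Path, manifest_path: str | Path | None = None) -> None:
        """Write the matrix as CSV plus an optional JSON manifest."""
        path = Path(path)
        self.to_frame().to_csv(path)
        if manifest_path is not None:
            manifest = {
                "schema_version": 1,
                "n_subjects": self.n_subjects,
                "n_features": self.n_features,
                "has_labels": self.labels is not None,
                "feature_order": self.feature_names,
            }
            Path(manifest_path).write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, label_column: str | None = "label") -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls.from_frame(df, label_column=label_column)
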