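"""Cohort container: a subjects x features table with a binary survival label.

The label column follows the clinical-trial convention of a death flag:
1 = the patient died during follow-up, 0 = survived. Survivors double as the
reference ("control") population when pairwise baselines are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_LABEL = "DEATH"


@dataclass
class Cohort:
    """Subjects x features table plus a binary survival label.

    Parameters
    ----------
    frame:
        DataFrame indexed by subject id, containing the label column and one
        numeric column per feature. All feature values are expected finite
        unless missingness was explicitly introduced upstream.
    label_column:
        Name of the binary label column (1 = died, 0 = survived).
    """

    frame: pd.DataFrame
    label_column: str = DEFAULT_LABEL

    def __post_init__(self) -> None:
        if self.label_column not in self.frame.columns:
            raise KeyError(f"label column {self.label_column!r} not in table")
        labels = self.frame[self.label_column]
        bad = set(pd.unique(labels)) - {0, 1}
        if bad:
            raise ValueError(f"label must be binary 0/1; found {sorted(bad)!r}")
        names = self.feature_names
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.label_column]

    @property
    def labels(self) -> np.ndarray:
        return self.frame[self.label_column].to_numpy(dtype=int)

    @property
    def subject_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def feature_matrix(self, features: list[str] | None = None) -> np.ndarray:
        cols = self.feature_names if features is None else list(features)
        return self.frame[cols].to_numpy(dtype=float)

    def survivors(self) -> "Cohort":
        """Subset of subjects with label 0 (the reference population)."""
        return Cohort(self.frame[self.frame[self.label_column] == 0],
                      self.label_column)

    def subset(self, subject_ids) -> "Cohort":
        return Cohort(self.frame.loc[subject_ids], self.label_column)

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="subject_id")

    @classmethod
    def read_csv(cls, path, label_column: str = DEFAULT_LABEL) -> "Cohort":
        frame = pd.read_csv(path, index_col="subject_id")
        return cls(frame, label_column)

    def __eq__(self, other) -> bool:  # value semantics, used in determinism tests
        if not isinstance(other, Cohort):
            return NotImplemented
        return (self.label_column == other.label_column
                and self.frame.equals(other.frame))
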