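"""Bundled reference tables from the 2,000-radiograph reader study.

The original study had two musculoskeletal experts annotate 2,000 knee
radiographs on the KL scale and compared the automatic grading against
each expert.  The published summary tables ship with the package as small
CSVs so the evaluation statistics can be reproduced without the image
dataset:

* the K-NN confusion matrix against each expert (rows = algorithm
  prediction, columns = expert annotation);
* the per-grade count columns used by the agreement tests (algorithm
  totals against each expert, and the two experts' own annotation counts).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .stats import ConfusionMatrix, GradeCounts

__all__ = [
    "load_expert_confusion",
    "load_grade_counts",
]


def _data_path(name: str):
    return resources.files("kneegrade").joinpath("data", name)


def load_expert_confusion(expert: int) -> ConfusionMatrix:
    """The published K-NN confusion matrix versus expert 1 or 2."""
    if expert not in (1, 2):
        raise ValueError("expert must be 1 or 2")
    with resources.as_file(_data_path(f"confusion_knn_expert{expert}.csv")) as path:
        frame = pd.read_csv(path, index_col=0)
    return ConfusionMatrix(counts=frame.to_numpy(dtype=np.int64))


def load_grade_counts() -> dict[str, GradeCounts]:
    """Per-grade count columns for the agreement tests.

    Keys: ``algorithm_vs_expert1``, ``expert1``, ``algorithm_vs_expert2``,
    ``expert2``.
    """
    with resources.as_file(_data_path("grade_counts.csv")) as path:
        frame = pd.read_csv(path)
    return {
        col: GradeCounts(counts=frame[col].to_numpy(dtype=np.int64), name=col)
        for col in frame.columns
        if col != "grade"
    }
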