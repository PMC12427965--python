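"""Phase II — stability-gap ensemble pruning.

A learner's generalization stability is the gap between its mean
training-fold and mean validation-fold score during cross-validation.
Gaps are computed for all seven metrics, oriented so that a positive
gap always signals worse generalization (score metrics: train - val;
loss metrics such as the Brier score: val - train). The pruning
decision itself is anchored to the balanced-accuracy gap with a strict
exclusion rule Δ_BA > threshold (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import LOSS_METRICS, METRIC_NAMES
from .pool import FoldScores

__all__ = ["StabilityGapReport", "stability_gaps", "prune"]

DEFAULT_THRESHOLD = 0.05
DEFAULT_ANCHOR = "balanced_accuracy"


class EmptyEnsembleError(RuntimeError):
    """Every learner was pruned; the threshold needs review."""


def stability_gaps(fs: FoldScores) -> dict[str, float]:
    """Per-metric stability gap Δ from recorded fold scores.

    Δ = mean(train) - mean(val) for score metrics and
    mean(val) - mean(train) for loss metrics, so positive Δ always
    means the model does worse out of fold.
    """
    if not fs.train or not fs.val or len(fs.train) != len(fs.val):
        raise ValueError("train and validation fold scores must be present and aligned")
    gaps = {}
    for m in METRIC_NAMES:
        if any(m not in d for d in fs.train + fs.val):
            raise ValueError(f"metric {m!r} missing from fold scores")
        tr = float(np.mean([d[m] for d in fs.train]))
        va = float(np.mean([d[m] for d in fs.val]))
        gaps[m] = va - tr if m in LOSS_METRICS else tr - va
    return gaps


@dataclass(frozen=True)
class StabilityGapReport:
    """Annotated pruning outcome."""

    table: pd.DataFrame  # index: model; columns: delta_<metric>, status
    anchor: str
    threshold: float

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["status"] == "retained"])

    @property
    def pruned(self) -> list[str]:
        return list(self.table.index[self.table["status"] == "pruned"])


def prune(
    gaps_by_model: dict[str, dict[str, float]],
    threshold: float = DEFAULT_THRESHOLD,
    anchor: str = DEFAULT_ANCHOR,
) -> StabilityGapReport:
    """Apply the anchored stability-gap exclusion rule.

    A model is pruned iff its anchor-metric gap strictly exceeds the
    threshold (Δ_anchor > threshold); a gap exactly at the threshold is
    retained. All metric gaps are reported; only the anchor decides.
    Raises :class:`EmptyEnsembleError` if nothing survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    rows = []
    for model, gaps in gaps_by_model.items():
        if anchor not in gaps:
            raise ValueError(f"{model}: anchor metric {anchor!r} missing")
        row = {f"delta_{m}": gaps[m] for m in gaps}
        row["status"] = "pruned" if gaps[anchor] > threshold else "retained"
        rows.append(pd.Series(row, name=model))
    table = pd.DataFrame(rows)
    report = StabilityGapReport(table=table, anchor=anchor, threshold=threshold)
    if not report.retained:
        raise EmptyEnsembleError(
            f"all models pruned at Δ_{anchor} > {threshold}; review the threshold"
        )
    return report
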