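"""Build per-trial feature tables: connectivity -> thresholded graphs ->
region-averaged metric vectors, as a long-format pandas DataFrame."""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .cohort import TrialRecording
from .connectivity import trial_band_connectivity
from .defs import FEATURE_NAMES
from .graph_metrics import (
    PTH_DEFAULT_RANGE,
    aggregate_regions,
    compute_node_metrics,
    proportional_threshold,
)

__all__ = ["build_feature_table", "LABEL_COLUMNS"]

LABEL_COLUMNS = ("subject_id", "trial", "band", "pth", "condition", "rt_ms", "correct")


def build_feature_table(
    trials: Sequence[TrialRecording],
    bands: Sequence[str] | None = None,
    pths: Sequence[float] = PTH_DEFAULT_RANGE,
    max_order: int = 15,
    correct_only: bool = True,
    skip_above_nyquist: bool = True,
) -> pd.DataFrame:
    """One row per (trial, band, pth) with the 27 named feature columns.

    The VAR fit and DTF are computed once per trial and re-thresholded for
    each pth value.
    """
    rows = []
    for trial_idx, trial in enumerate(trials):
        if correct_only and not trial.correct:
            continue
        band_mats = trial_band_connectivity(
            trial,
            bands=list(bands) if bands is not None else None,
            max_order=max_order,
            skip_above_nyquist=skip_above_nyquist,
        )
        for band, conn in band_mats.items():
            for pth in pths:
                g = proportional_threshold(conn, pth)
                vec = aggregate_regions(
                    compute_node_metrics(g), trial.channel_regions
                )
                row = {
                    "subject_id": trial.subject_id,
                    "trial": trial_idx,
                    "band": band,
                    "pth": pth,
                    "condition": trial.condition,
                    "rt_ms": trial.rt,
                    "correct": trial.correct,
                }
                row.update(dict(zip(FEATURE_NAMES, vec)))
                rows.append(row)
    if not rows:
        raise ValueError("no rows produced (all trials filtered out?)")
    return pd.DataFrame(rows)
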