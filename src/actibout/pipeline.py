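"""End-to-end helpers: raw recording → valid-day features, cohort → pooled
feature table, and period cluster assignment → movement matrix."""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .bouts import daily_features
from .clustering import ClusterModel, MovementMatrix, assign_periods, movement_matrix
from .config import Config, load_config
from .processing import RawRecording, assess_wear, classify_intensity, compute_svm_epochs

__all__ = ["recording_features", "cohort_features", "periods_movement"]


def recording_features(rec: RawRecording, config: Config | None = None) -> pd.DataFrame:
    """Valid-day 8-factor features for one recording (empty frame if the
    participant-period fails the minimum-valid-days rule)."""
    cfg = config or load_config()
    es = classify_intensity(compute_svm_epochs(rec), cfg.cut_points)
    wear = assess_wear(es, cfg.wear_rules)
    if not wear.participant_valid:
        return daily_features(es, wear, cfg.analysis_window).iloc[0:0]
    return daily_features(es, wear, cfg.analysis_window)


def cohort_features(recordings: Iterable[RawRecording],
                    config: Config | None = None) -> pd.DataFrame:
    """Pooled valid-day features across recordings (pre and post periods)."""
    cfg = config or load_config()
    frames = [recording_features(r, cfg) for r in recordings]
    return pd.concat(frames, ignore_index=True)


def periods_movement(model: ClusterModel, features: pd.DataFrame,
                     mode: str = "modal-day") -> tuple[pd.DataFrame, MovementMatrix]:
    """Assign participant-period clusters and cross-tabulate pre→post movement.

    Only participants with both a pre and a post assignment enter the matrix.
    """
    scores = model.transform_features(features)
    assigned = assign_periods(model, scores,
                              features[["participant", "period"]], mode=mode)
    wide = assigned.pivot(index="participant", columns="period", values="cluster")
    both = wide.dropna(subset=["pre", "post"]) if {"pre", "post"} <= set(wide.columns) \
        else wide.iloc[0:0]
    mm = movement_matrix(both["pre"].astype(int).to_dict(),
                         both["post"].astype(int).to_dict(), k=model.k)
    return assigned, mm
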