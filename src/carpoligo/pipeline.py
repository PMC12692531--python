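"""Glue between scan tables and expression matrices.

Small deterministic steps used by the CLI, the examples and the validation
designs: collapsing replicate spots of feature-extraction frames into a
probe x array signal matrix, and building LOWESS-corrected M matrices for
two-channel arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .normalize import (
    ExpressionMatrix,
    baseline_to_median,
    log2_transform,
    lowess_ma_normalize,
    percentile75_normalize,
)

__all__ = [
    "processed_signal_matrix",
    "corrected_m_matrix",
    "single_channel_normalize",
    "feature_class_map",
]


def processed_signal_matrix(
    scans: dict[str, pd.DataFrame], channel: str = "green", exclude_adverse: bool = True
) -> pd.DataFrame:
    """Probe x array matrix of processed signals, replicate spots averaged.

    Spots carrying a non-uniformity/population/saturation flag are dropped
    before averaging when ``exclude_adverse`` (a probe keeps its value if at
    least one clean spot remains).
    """
    prefix = "g" if channel == "green" else "r"
    cols = {}
    for array_id, frame in scans.items():
        f = frame
        if exclude_adverse:
            adverse = (
                (f[f"{prefix}IsFeatNonUnifOL"] == 1)
                | (f[f"{prefix}IsFeatPopnOL"] == 1)
                | (f[f"{prefix}IsSaturated"] == 1)
            )
            f = f[~adverse]
        cols[array_id] = f.groupby("ProbeID")[f"{prefix}ProcessedSignal"].mean()
    return pd.DataFrame(cols).dropna()


def corrected_m_matrix(scans: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-array LOWESS-corrected M values (red vs green), probes x arrays."""
    cols = {}
    for array_id, frame in scans.items():
        g = frame.groupby("ProbeID")["gProcessedSignal"].mean()
        r = frame.groupby("ProbeID")["rProcessedSignal"].mean()
        m_corr, _ = lowess_ma_normalize(np.log2(g.to_numpy()), np.log2(r.to_numpy()))
        cols[array_id] = pd.Series(m_corr, index=g.index)
    return pd.DataFrame(cols).dropna()


def single_channel_normalize(signal: pd.DataFrame) -> ExpressionMatrix:
    """log2 -> within-array 75th-percentile scaling -> baseline-to-median."""
    return baseline_to_median(percentile75_normalize(log2_transform(signal)))


def feature_class_map(frame: pd.DataFrame) -> pd.Series:
    """feature_id -> feature_class from any frame carrying both columns."""
    key = "ProbeID" if "ProbeID" in frame.columns else "feature_id"
    return frame.drop_duplicates(key).set_index(key)["feature_class"]
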