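"""Spot-level QC: SNR, detection calls, replicate collapsing, array metrics.

Works on feature-extraction-style per-spot tables. The core statistic is the
per-spot signal-to-noise ratio

    SNR = (median_signal - bg_median) / bg_pix_sd

with a present call requiring the well-above-background flag AND SNR >= 3;
SNR in [1.5, 3) is cautionary, below 1.5 low-confidence. Replicate spots of a
probe on one array collapse to the median SNR (means for signal/background);
arrays carrying a non-uniformity, population-outlier or saturation flag are
excluded from a probe's robustness statistics but counted.

Array-level diagnostics include DLRSpread (robust spread of adjacent
log-ratio differences, an overall two-color noise metric) and the spike-in
observed-vs-expected slope and correlation.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpotMeasurement",
    "ProbeArraySummary",
    "ProbeQCSummary",
    "compute_snr",
    "classify_detection",
    "collapse_replicate_spots",
    "summarize_probe",
    "compute_dlrs",
    "spike_in_check",
    "read_fe_table",
    "qc_pipeline",
]

logger = logging.getLogger(__name__)

SNR_ROBUST = 3.0
SNR_CAUTIONARY = 1.5


@dataclass(frozen=True)
class SpotMeasurement:
    array_id: str
    probe_id: str
    channel: str  # "green" | "red"
    median_signal: float
    bg_median: float
    bg_pix_sd: float
    processed_signal: float
    well_above_bg: bool = False
    pos_and_signif: bool = False
    feat_nonunif_outlier: bool = False
    feat_popn_outlier: bool = False
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.bg_pix_sd < 0:
            raise ValueError("bg_pix_sd must be >= 0")

    @property
    def adverse(self) -> bool:
        return self.feat_nonunif_outlier or self.feat_popn_outlier or self.saturated


@dataclass(frozen=True)
class ProbeArraySummary:
    array_id: str
    probe_id: str
    median_snr: float
    mean_signal: float
    mean_bg: float
    mean_processed: float
    well_above_bg: bool
    any_adverse_flag: bool
    detection_class: str


@dataclass(frozen=True)
class ProbeQCSummary:
    probe_id: str
    median_snr: float | None
    min_snr: float | None
    max_snr: float | None
    mean_processed_signal: float | None
    present_call_rate: float | None
    flagged_array_count: int


def compute_snr(s: SpotMeasurement) -> float:
    if s.bg_pix_sd == 0:
        raise ValueError(f"degenerate background (bg_pix_sd == 0) for {s.probe_id}")
    return (s.median_signal - s.bg_median) / s.bg_pix_sd


def classify_detection(median_snr: float, well_above_bg: bool) -> str:
    """Robust needs the flag AND SNR >= 3; SNR >= 1.5 alone is cautionary."""
    if well_above_bg and median_snr >= SNR_ROBUST:
        return "robust"
    if median_snr >= SNR_CAUTIONARY:
        return "cautionary"
    return "low_confidence"


def collapse_replicate_spots(spots: list[SpotMeasurement]) -> ProbeArraySummary:
    """Collapse replicate spots of one probe on one array.

    Median of per-spot SNRs; arithmetic means of signal and background; the
    adverse flag is true if any spot carries a non-uniformity, population or
    saturation flag. Well-above-background holds if every spot has it (a
    conservative conjunctive read for replicated features).
    """
    if not spots:
        raise ValueError("no spots to collapse")
    snrs = [compute_snr(s) for s in spots]
    med = statistics.median(snrs)
    wab = all(s.well_above_bg for s in spots)
    return ProbeArraySummary(
        array_id=spots[0].array_id,
        probe_id=spots[0].probe_id,
        median_snr=med,
        mean_signal=float(np.mean([s.median_signal for s in spots])),
        mean_bg=float(np.mean([s.bg_median for s in spots])),
        mean_processed=float(np.mean([s.processed_signal for s in spots])),
        well_above_bg=wab,
        any_adverse_flag=any(s.adverse for s in spots),
        detection_class=classify_detection(med, wab),
    )


def summarize_probe(per_array: list[ProbeArraySummary]) -> ProbeQCSummary:
    """Across-array probe summary; flagged arrays excluded but counted."""
    if not per_array:
        raise ValueError("no array summaries")
    flagged = [a for a in per_array if a.any_adverse_flag]
    clean = [a for a in per_array if not a.any_adverse_flag]
    if not clean:
        return ProbeQCSummary(per_array[0].probe_id, None, None, None, None, None, len(flagged))
    snrs = [a.median_snr for a in clean]
    return ProbeQCSummary(
        probe_id=per_array[0].probe_id,
        median_snr=statistics.median(snrs),
        min_snr=min(snrs),
        max_snr=max(snrs),
        mean_processed_signal=float(np.mean([a.mean_processed for a in clean])),
        present_call_rate=sum(a.detection_class == "robust" for a in clean) / len(clean),
        flagged_array_count=len(flagged),
    )


def compute_dlrs(log_ratios) -> float:
    """Derivative log-ratio spread: robust SD of adjacent log-ratio
    differences divided by sqrt(2), with IQR/1.349 as the robust SD."""
    lr = np.asarray(log_ratios, dtype=float)
    if lr.size < 3:
        raise ValueError("need at least 3 log ratios")
    d = np.diff(lr)
    q75, q25 = np.percentile(d, [75, 25])
    return float((q75 - q25) / 1.349 / np.sqrt(2.0))


def spike_in_check(observed, expected) -> tuple[float, float]:
    """Least-squares slope and Pearson correlation of observed vs expected
    spike-in log ratios."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.size < 3 or obs.size != exp.size:
        raise ValueError("need >= 3 paired spike levels")
    if np.var(exp) == 0:
        raise ValueError("zero variance in expected spike ratios")
    res = stats.linregress(exp, obs)
    return float(res.slope), float(res.rvalue)


# ---------------------------------------------------------------------------
# feature-extraction-style table IO

_FE_COLUMNS = {
    "green": {
        "median_signal": "gMedianSignal",
        "bg_median": "gBGMedianSignal",
        "bg_pix_sd": "gBGPixSDev",
        "processed_signal": "gProcessedSignal",
        "well_above_bg": "gIsWellAboveBG",
        "pos_and_signif": "gIsPosAndSignif",
        "feat_nonunif_outlier": "gIsFeatNonUnifOL",
        "feat_popn_outlier": "gIsFeatPopnOL",
        "saturated": "gIsSaturated",
    },
    "red": {
        "median_signal": "rMedianSignal",
        "bg_median": "rBGMedianSignal",
        "bg_pix_sd": "rBGPixSDev",
        "processed_signal": "rProcessedSignal",
        "well_above_bg": "rIsWellAboveBG",
        "pos_and_signif": "rIsPosAndSignif",
        "feat_nonunif_outlier": "rIsFeatNonUnifOL",
        "feat_popn_outlier": "rIsFeatPopnOL",
        "saturated": "rIsSaturated",
    },
}


def read_fe_table(path, array_id: str, channel: str = "green") -> list[SpotMeasurement]:
    """Read a feature-extraction-style per-spot TSV into SpotMeasurements.

    Expects the conventional column names (gMedianSignal, gBGMedianSignal,
    gBGPixSDev, gProcessedSignal and the g/rIs* flags) plus a ProbeID column;
    unknown columns are ignored with a logged notice.
    """
    df = pd.read_csv(path, sep="\t")
    return fe_frame_to_spots(df, array_id, channel)


def fe_frame_to_spots(df: pd.DataFrame, array_id: str, channel: str = "green") -> list[SpotMeasurement]:
    cols = _FE_COLUMNS[channel]
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    known = set(cols.values()) | {"ProbeID", "FeatureNum", "feature_class"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.info("ignoring unknown feature-table columns: %s", unknown)
    if "ProbeID" not in df.columns:
        raise ValueError("feature table missing ProbeID column")
    spots = []
    for row in df.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        spots.append(
            SpotMeasurement(
                array_id=array_id,
                probe_id=str(r["ProbeID"]),
                channel=channel,
                median_signal=float(r[cols["median_signal"]]),
                bg_median=float(r[cols["bg_median"]]),
                bg_pix_sd=float(r[cols["bg_pix_sd"]]),
                processed_signal=float(r[cols["processed_signal"]]),
                well_above_bg=bool(r[cols["well_above_bg"]]),
                pos_and_signif=bool(r[cols["pos_and_signif"]]),
                feat_nonunif_outlier=bool(r[cols["feat_nonunif_outlier"]]),
                feat_popn_outlier=bool(r[cols["feat_popn_outlier"]]),
                saturated=bool(r[cols["saturated"]]),
            )
        )
    return spots


def qc_pipeline(spots_by_array: dict[str, list[SpotMeasurement]]) -> pd.DataFrame:
    """Collapse replicate spots per probe per array, then summarize probes
    across arrays. Returns a tidy per-probe QC table."""
    per_probe: dict[str, list[ProbeArraySummary]] = {}
    for array_id, spots in spots_by_array.items():
        by_probe: dict[str, list[SpotMeasurement]] = {}
        for s in spots:
            by_probe.setdefault(s.probe_id, []).append(s)
        for pid, group in by_probe.items():
            per_probe.setdefault(pid, []).append(collapse_replicate_spots(group))
    rows = []
    for pid in sorted(per_probe):
        s = summarize_probe(per_probe[pid])
        rows.append(
            {
                "probe_id": s.probe_id,
                "median_snr": s.median_snr,
                "min_snr": s.min_snr,
                "max_snr": s.max_snr,
                "mean_processed_signal": s.mean_processed_signal,
                "present_call_rate": s.present_call_rate,
                "flagged_array_count": s.flagged_array_count,
            }
        )
    return pd.DataFrame(rows)
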