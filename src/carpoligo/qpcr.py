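"""qPCR standard curves, -dCt expression values and platform concordance.

Amplification efficiency follows the standard-curve convention

    E(%) = (10^(-1/slope) - 1) * 100

where slope is the least-squares slope of Ct against log10 input (a
perfectly doubling reaction has slope -1/log10(2) = -3.3219 and E = 100%).
Relative expression is -dCt = -(Ct_gene - Ct_reference); concordance against
array intensity is a least-squares fit of -dCt on mean processed signal with
Pearson correlation and its two-sided t-transform p-value (n - 2 df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QPCRRecord",
    "ConcordanceResult",
    "fit_standard_curve",
    "compute_minus_delta_ct",
    "platform_concordance",
    "read_ct_table",
]


@dataclass(frozen=True)
class StandardCurve:
    gene: str
    log10_inputs: tuple[float, ...]
    ct_values: tuple[float, ...]
    slope: float
    intercept: float
    efficiency_percent: float


@dataclass(frozen=True)
class QPCRRecord:
    gene: str
    ct_replicates: tuple[float, ...]
    ct_mean: float
    ct_reference_mean: float
    minus_delta_ct: float


@dataclass(frozen=True)
class ConcordanceResult:
    genes: tuple[str, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


def fit_standard_curve(log10_inputs, ct_values, gene: str = "") -> StandardCurve:
    x = np.asarray(log10_inputs, dtype=float)
    y = np.asarray(ct_values, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired dilution points")
    d = np.diff(x)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("inputs must be strictly monotone")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    if slope >= 0:
        raise ValueError(f"non-physical standard curve (slope {slope:.3g} >= 0)")
    eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return StandardCurve(gene, tuple(x), tuple(y), slope, float(res.intercept), float(eff))


def compute_minus_delta_ct(gene_cts, reference_cts, gene: str = "") -> QPCRRecord:
    g = np.asarray(gene_cts, dtype=float)
    r = np.asarray(reference_cts, dtype=float)
    if g.size == 0 or r.size == 0:
        raise ValueError("empty Ct replicates")
    gm, rm = float(np.mean(g)), float(np.mean(r))
    return QPCRRecord(gene, tuple(g), gm, rm, -(gm - rm))


def platform_concordance(genes, array_signal, minus_delta_ct) -> ConcordanceResult:
    """Least-squares fit of -dCt (y) on array mean processed signal (x)."""
    x = np.asarray(array_signal, dtype=float)
    y = np.asarray(minus_delta_ct, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired genes")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in paired values")
    res = stats.linregress(x, y)
    return ConcordanceResult(
        genes=tuple(genes),
        x=tuple(x),
        y=tuple(y),
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct TSV with columns gene, replicate, ct, role (target/reference)
    and optional dilution."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "replicate", "ct", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df
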