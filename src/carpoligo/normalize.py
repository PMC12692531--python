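"""Normalization and moderated-t differential expression.

Two distinct pipelines, mirroring standard two-color practice:

* two-channel contrasts: per-array MA coordinates (M = log2 R - log2 G,
  A = (log2 R + log2 G)/2), LOWESS dye correction of M against A, then a
  one-sample moderated t-test of mean corrected M against 0 (dye-balance
  self-self design);
* single-channel analyses: log2 transform, within-array 75th-percentile
  scaling, between-array baseline-to-median centering, optional gene-level
  collapsing by median, then a two-group moderated t-test
  (isolation-reproducibility design).

The moderated t shrinks per-feature residual variances s_g^2 (df d_g) toward
a prior (d0, s0^2) estimated by the standard method-of-moments on log s^2:

    stilde_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)
    t_g = logFC_g / (stilde_g * sqrt(c)),   df = d0 + d_g

with c the contrast scale (1/nA + 1/nB for two groups, 1/n for one sample).
P-values come from the t distribution with the augmented df; multiplicity is
controlled by Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ContrastResult",
    "EBayesParams",
    "log2_transform",
    "lowess_ma_normalize",
    "percentile75_normalize",
    "baseline_to_median",
    "collapse_gene_level",
    "estimate_prior",
    "fit_moderated_t",
    "bh_adjust",
    "call_significant",
    "dye_balance_contrast",
    "isolation_contrast",
]

LOWESS_SPAN = 0.3
LOWESS_ITER = 3


@dataclass
class ExpressionMatrix:
    """Log2 intensity matrix (features x arrays) with normalization provenance."""

    values: pd.DataFrame
    provenance: list[str] = field(default_factory=list)
    channel: dict[str, str] = field(default_factory=dict)

    def stamp(self, step: str) -> None:
        if step in self.provenance:
            raise ValueError(f"normalization step {step!r} already applied")
        self.provenance.append(step)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.provenance), dict(self.channel))


@dataclass
class EBayesParams:
    d0: float  # prior degrees of freedom; may be math.inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ValueError("need d0 > 0 and s0_sq > 0")


@dataclass
class ContrastResult:
    table: pd.DataFrame  # feature_id, logFC, t, df_total, p_value, q_value, significant
    prior: EBayesParams | None = None
    criterion: str | None = None


# ---------------------------------------------------------------------------
# normalization steps


def log2_transform(raw: pd.DataFrame) -> ExpressionMatrix:
    """Elementwise log2; per array, non-positive values are floored at half
    that array's smallest positive value (recorded in provenance)."""
    values = raw.astype(float).copy()
    substituted = []
    for col in values.columns:
        v = values[col]
        pos = v[v > 0]
        if pos.empty:
            raise ValueError(f"array {col!r} has no positive values")
        if (v <= 0).any():
            values[col] = v.where(v > 0, pos.min() / 2.0)
            substituted.append(str(col))
    em = ExpressionMatrix(np.log2(values))
    step = "log2"
    if substituted:
        step += f"[floored:{','.join(substituted)}]"
    em.stamp(step)
    return em


def lowess_ma_normalize(
    green_log2, red_log2, span: float = LOWESS_SPAN, iterations: int = LOWESS_ITER
):
    """LOWESS dye correction on MA coordinates for one two-channel array.

    Returns (corrected M, A). M = red - green in log2; the LOWESS trend of M
    against A is subtracted, removing intensity-dependent dye bias.
    """
    g = np.asarray(green_log2, dtype=float)
    r = np.asarray(red_log2, dtype=float)
    if g.size != r.size:
        raise ValueError("channels must be paired")
    if g.size < 10:
        raise ValueError("need >= 10 probes for a LOWESS fit")
    m = r - g
    a = (r + g) / 2.0
    fit = sm_lowess(m, a, frac=span, it=iterations, return_sorted=False)
    return m - fit, a


def percentile75_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each array's 75th percentile (linear interpolation), so the
    post-normalization 75th percentile is 0 per array."""
    out = em.copy()
    q75 = out.values.quantile(0.75, axis=0, interpolation="linear")
    out.values = out.values.sub(q75, axis=1)
    out.stamp("percentile75")
    return out


def baseline_to_median(em: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature's cross-array median (baseline transformation)."""
    out = em.copy()
    out.values = out.values.sub(out.values.median(axis=1), axis=0)
    out.stamp("baseline_to_median")
    return out


def collapse_gene_level(em: ExpressionMatrix, probe_to_gene: dict[str, str]) -> ExpressionMatrix:
    """Median across each gene's probes, per array (resistant consensus)."""
    missing = [p for p in em.values.index if p not in probe_to_gene]
    if missing:
        raise ValueError(f"probes without gene mapping: {missing[:10]}")
    genes = pd.Series({p: probe_to_gene[p] for p in em.values.index})
    collapsed = em.values.groupby(genes).median()
    out = ExpressionMatrix(collapsed, list(em.provenance), dict(em.channel))
    out.stamp("collapse_gene_level")
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(80):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-13 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> EBayesParams:
    """Method-of-moments fit of the scaled-F prior for residual variances.

    Works on z = log(s^2): the mean and excess variance of z over its known
    sampling moments give s0^2 and d0 in closed form (trigamma inversion).
    With no excess variance the prior df is infinite and s0^2 is the common
    variance exp(mean e).
    """
    s2 = np.asarray(s2, dtype=float)
    # guard exact zeros (constant features) with a tiny floor
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    if s2.size < 2:
        return EBayesParams(math.inf, math.exp(emean))
    evar = float(np.var(e, ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return EBayesParams(math.inf, math.exp(emean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return EBayesParams(d0, s0_sq)


def _moderated_stats(
    logfc: np.ndarray, s2: np.ndarray, df_resid: float, scale: float,
    prior: EBayesParams | None = None,
) -> tuple[np.ndarray, np.ndarray, float, EBayesParams]:
    prior = prior or estimate_prior(s2, df_resid)
    if math.isinf(prior.d0):
        s2_post = np.full_like(np.asarray(s2, dtype=float), prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + df_resid * s2) / (prior.d0 + df_resid)
        df_total = prior.d0 + df_resid
    t = logfc / np.sqrt(s2_post * scale)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, df_total, prior


def fit_moderated_t(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame | None = None,
    prior: EBayesParams | None = None,
) -> ContrastResult:
    """Moderated t-test per feature.

    Two-group: logFC = mean(A) - mean(B), pooled residual variance with
    nA + nB - 2 df, contrast scale 1/nA + 1/nB. One-sample (``group_b`` is
    None, e.g. paired log-ratios): logFC = mean, df n - 1, scale 1/n.
    """
    a = group_a.astype(float)
    if group_b is None:
        n = a.shape[1]
        df_resid = n - 1
        if df_resid < 1:
            raise ValueError("zero residual degrees of freedom")
        logfc = a.mean(axis=1).to_numpy()
        s2 = a.var(axis=1, ddof=1).to_numpy()
        scale = 1.0 / n
    else:
        b = group_b.astype(float)
        if not a.index.equals(b.index):
            b = b.reindex(a.index)
        na, nb = a.shape[1], b.shape[1]
        df_resid = na + nb - 2
        if df_resid < 1:
            raise ValueError("zero residual degrees of freedom")
        logfc = (a.mean(axis=1) - b.mean(axis=1)).to_numpy()
        s2 = (
            (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1))
            / df_resid
        ).to_numpy()
        scale = 1.0 / na + 1.0 / nb
    t, p, df_total, prior = _moderated_stats(logfc, s2, df_resid, scale, prior)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "feature_id": a.index,
            "logFC": logfc,
            "t": t,
            "df_total": df_total,
            "p_value": p,
            "q_value": q,
            "significant": False,
        }
    ).set_index("feature_id", drop=False)
    return ContrastResult(table, prior)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    result: ContrastResult,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    criterion: str = "bh_q",
) -> ContrastResult:
    """Significant iff |logFC| >= log2(fc_threshold) AND the p/q gate holds."""
    if criterion not in ("raw_p", "bh_q"):
        raise ValueError("criterion must be 'raw_p' or 'bh_q'")
    t = result.table
    fc_gate = np.abs(t["logFC"]) >= np.log2(fc_threshold)
    stat_gate = t["p_value"] < alpha if criterion == "raw_p" else t["q_value"] <= alpha
    t["significant"] = fc_gate & stat_gate
    result.criterion = criterion
    return result


# ---------------------------------------------------------------------------
# experimental designs


def dye_balance_contrast(
    corrected_m: pd.DataFrame,
    feature_classes: pd.Series | dict,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    criterion: str = "raw_p",
) -> tuple[ContrastResult, pd.DataFrame]:
    """Self-self dye-balance test: per-feature one-sample moderated t of the
    LOWESS-corrected M values against 0 across arrays.

    Returns the contrast and the significant features partitioned by feature
    class; any biologically classed significant feature is a dye-bias warning.
    """
    if corrected_m.shape[1] < 2:
        raise ValueError("need >= 2 self-self arrays")
    res = fit_moderated_t(corrected_m)
    res = call_significant(res, fc_threshold, alpha, criterion)
    cls = pd.Series(dict(feature_classes) if not isinstance(feature_classes, pd.Series) else feature_classes)
    sig = res.table[res.table["significant"]].copy()
    sig["feature_class"] = cls.reindex(sig.index).fillna("biological")
    sig["dye_bias_warning"] = sig["feature_class"] == "biological"
    return res, sig


def isolation_contrast(
    iso1: pd.DataFrame,
    iso2: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    criterion: str = "bh_q",
) -> ContrastResult:
    """Two-group moderated t of isolation 2 vs isolation 1 (single channel)."""
    if iso1.shape[1] == 0 or iso2.shape[1] == 0:
        raise ValueError("both isolation groups must be non-empty")
    res = fit_moderated_t(iso2, iso1)
    return call_significant(res, fc_threshold, alpha, criterion)
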