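"""Segmentation-agreement and prediction-error statistics.

Two mask metrics: the Dice similarity coefficient DSC = 2|G∩S|/(|G|+|S|)
and the absolute relative volume difference VD = |V(S)-V(G)|/V(G).
Five paired-value error statistics (ground truth x_i vs prediction y_i):

    MAE   = (1/n) Σ |y_i - x_i|
    RMSE  = sqrt((1/n) Σ (y_i - x_i)^2)
    MARE  = (1/n) Σ |y_i - x_i| / |x_i|
    RMSRE = sqrt((1/n) Σ ((y_i - x_i)/x_i)^2)
    U95   = 1.96 sqrt(sd(e)^2 + RMSE^2),  e = y - x

plus Pearson correlation, Bland-Altman agreement tables, and one-sided
t-tests (Welch by default) with Bonferroni correction for comparing a
parent model's per-case DSC against a subset-trained model's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import DataError, LabelMap


def _as_binary(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise DataError(f"mask is not binary: values {vals[:8]}")
        m = m.astype(bool)
    return m


def dice(pred, ref) -> float:
    """Dice similarity coefficient in [0, 1]; both-empty masks score 1
    (perfect agreement on the organ's absence)."""
    s, g = _as_binary(pred), _as_binary(ref)
    if s.shape != g.shape:
        raise DataError(f"mask shape mismatch {s.shape} vs {g.shape}")
    denom = int(s.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((s & g).sum()) / denom


def volume_difference(pred, ref) -> float:
    """|V(S) - V(G)| / V(G); 0 is perfect, no upper bound. Asymmetric:
    the reference mask defines the denominator and must be nonempty."""
    s, g = _as_binary(pred), _as_binary(ref)
    if s.shape != g.shape:
        raise DataError(f"mask shape mismatch {s.shape} vs {g.shape}")
    vg = int(g.sum())
    if vg == 0:
        raise DataError("reference mask is empty")
    return abs(int(s.sum()) - vg) / vg


@dataclass
class ErrorStats:
    mae: float
    rmse: float
    mare: float
    rmsre: float
    u95: float
    n: int
    n_skipped_relative: int  # entries with x == 0 excluded from MARE/RMSRE


def error_stats(x, y) -> ErrorStats:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise DataError("need two equal-length 1D series with n >= 1")
    e = y - x
    mae = float(np.abs(e).mean())
    rmse = float(np.sqrt((e ** 2).mean()))
    nz = x != 0
    n_skipped = int((~nz).sum())
    if nz.any():
        rel = e[nz] / x[nz]
        mare = float(np.abs(rel).mean())
        rmsre = float(np.sqrt((rel ** 2).mean()))
    else:
        mare = rmsre = float("nan")
    sd = float(e.std(ddof=1)) if len(e) > 1 else 0.0
    u95 = 1.96 * float(np.sqrt(sd ** 2 + rmse ** 2))
    return ErrorStats(mae=mae, rmse=rmse, mare=mare, rmsre=rmsre, u95=u95,
                      n=len(x), n_skipped_relative=n_skipped)


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise DataError("Pearson correlation needs n >= 2 paired values")
    if x.std() == 0 or y.std() == 0:
        raise DataError("zero variance in correlation input")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(x, y) -> tuple[pd.DataFrame, float, float, float]:
    """Rows of ((y+x)/2, y-x) plus (bias, lower limit, upper limit).

    Limits of agreement are bias +/- 1.96 * sd(differences).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise DataError("Bland-Altman needs n >= 2 paired values")
    diff = y - x
    table = pd.DataFrame({"mean": (y + x) / 2.0, "difference": diff})
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return table, bias, bias - 1.96 * sd, bias + 1.96 * sd


@dataclass
class ModelComparison:
    t_statistic: float
    p_one_sided: float
    alpha: float
    adjusted_alpha: float  # alpha / n_comparisons (Bonferroni)
    significant: bool  # at alpha
    significant_adjusted: bool  # at alpha / n_comparisons


def compare_models(parent_dscs, subset_dscs, n_comparisons: int = 1,
                   alpha: float = 0.05, paired: bool = False,
                   equal_var: bool = False) -> ModelComparison:
    """One-sided test of parent DSC > subset DSC, Bonferroni-adjusted.

    Welch's unequal-variance t-test by default (per-organ DSC variances
    differ markedly between organs); set ``equal_var`` for the pooled
    variant or ``paired`` when both models were scored on the same cases.
    """
    a = np.asarray(parent_dscs, dtype=float)
    b = np.asarray(subset_dscs, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each sample needs n >= 2")
    if n_comparisons < 1:
        raise DataError("n_comparisons must be >= 1")
    if paired:
        if len(a) != len(b):
            raise DataError("paired test needs equal sample sizes")
        res = stats.ttest_rel(a, b, alternative="greater")
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var,
                              alternative="greater")
    adj = alpha / n_comparisons
    p = float(res.pvalue)
    return ModelComparison(t_statistic=float(res.statistic), p_one_sided=p,
                           alpha=alpha, adjusted_alpha=adj,
                           significant=p < alpha, significant_adjusted=p < adj)


def evaluate_cases(pred_maps: list[LabelMap], ref_maps: list[LabelMap],
                   case_ids=None) -> pd.DataFrame:
    """Long-format per-case, per-organ DSC/VD table for paired label maps.

    Organs absent from the reference get DSC against an empty mask (1 only
    when the prediction is also empty) and no VD row value (NaN).
    """
    if len(pred_maps) != len(ref_maps):
        raise DataError("prediction/reference count mismatch")
    ids = case_ids or list(range(len(pred_maps)))
    rows = []
    for cid, pred, ref in zip(ids, pred_maps, ref_maps):
        if pred.data.shape != ref.data.shape:
            raise DataError(f"case {cid}: grid mismatch")
        for label, organ in sorted(ref.organ_table.items()):
            if label == 0:
                continue
            s, g = pred.mask(label), ref.mask(label)
            vd = volume_difference(s, g) if g.any() else float("nan")
            rows.append({"case": cid, "organ": organ,
                         "dsc": dice(s, g), "vd": vd})
    return pd.DataFrame(rows)


def summarize_eval(table: pd.DataFrame) -> pd.DataFrame:
    """Per-organ mean +/- sd of DSC and VD over cases."""
    return (table.groupby("organ", sort=False)
            .agg(dsc_mean=("dsc", "mean"), dsc_sd=("dsc", "std"),
                 vd_mean=("vd", "mean"), vd_sd=("vd", "std"),
                 n=("dsc", "size"))
            .reset_index())
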