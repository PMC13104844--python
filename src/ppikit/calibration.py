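"""ROC analysis, FPR-based threshold calibration, and PPI classification.

Benchmark tables are pandas DataFrames with one row per scored pair and
columns ``pair_id``, ``set_label``, ``class`` ("positive"/"control"),
``plddt_subgroup`` plus one numeric column per metric/model-choice
combination named like ``ilis_best`` or ``iptm_avg``.

Thresholds are calibrated per metric, model choice, pLDDT subgroup and FPR
level: the threshold is the smallest observed control score ``t`` such that
the fraction of controls with score >= ``t`` does not exceed the requested
FPR. Classification is inclusive (score >= threshold is positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve

__all__ = [
    "RocResult",
    "ThresholdResult",
    "roc",
    "fpr_threshold",
    "calibrate",
    "classify",
    "POSITIVE_SETS",
    "CONTROL_SETS",
    "LOWER_IS_BETTER",
    "FPR_LEVELS",
    "SUBGROUPS",
]

POSITIVE_SETS = ("PRS-yeast", "PRS-fly", "PRS-human")
CONTROL_SETS = ("RRS", "GFP", "Wg")
LOWER_IS_BETTER = frozenset({"ifpae", "ifpae_d8"})
FPR_LEVELS = (0.01, 0.05, 0.10)
SUBGROUPS = ("0-50", "50-70", "70-100", "total")


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ThresholdResult:
    threshold: float
    achieved_fpr: float
    n_controls: int
    degenerate: bool = False


def roc(scores, labels, lower_is_better: bool = False) -> RocResult:
    """Standard ROC curve and trapezoidal AUC.

    ``labels`` is boolean/0-1 (1 = positive). Missing scores are dropped
    together with their labels. Metrics where lower values indicate higher
    confidence are negated before ranking so that all curves share the same
    directionality.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep]
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes to be present")
    if lower_is_better:
        scores = -scores
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(_auc(fpr, tpr)))


def fpr_threshold(control_scores, fpr: float) -> ThresholdResult:
    """Threshold at which at most ``fpr`` of control pairs score >= it.

    Returns the smallest observed control score ``t`` with
    ``mean(controls >= t) <= fpr``. When ties at the maximum make the
    nominal level unattainable, the maximum observed score is returned with
    the achieved FPR and a warning (``degenerate=True``).
    """
    if not 0.0 < fpr < 1.0:
        raise ValueError(f"fpr must lie in (0, 1), got {fpr}")
    s = np.sort(np.asarray(control_scores, dtype=float))
    s = s[~np.isnan(s)]
    n = len(s)
    if n == 0:
        raise ValueError("control set is empty")
    uniq = np.unique(s)
    frac_ge = (n - np.searchsorted(s, uniq, side="left")) / n
    ok = frac_ge <= fpr
    if not ok.any():
        warnings.warn(
            f"requested FPR {fpr} unattainable on {n} controls (ties at maximum); "
            f"returning max observed score with achieved FPR {frac_ge[-1]:.3f}",
            stacklevel=2,
        )
        return ThresholdResult(float(uniq[-1]), float(frac_ge[-1]), n, degenerate=True)
    idx = int(np.argmax(ok))  # smallest qualifying observed score
    return ThresholdResult(float(uniq[idx]), float(frac_ge[idx]), n)


def _metric_columns(table: pd.DataFrame) -> list[tuple[str, str]]:
    """(metric, model_choice) pairs inferred from *_best / *_avg columns."""
    out = []
    for col in table.columns:
        for suffix, choice in (("_best", "best"), ("_avg", "average")):
            if col.endswith(suffix):
                out.append((col[: -len(suffix)], choice))
    return out


def calibrate(
    table: pd.DataFrame,
    positive_sets=POSITIVE_SETS,
    control_sets=CONTROL_SETS,
    fpr_levels=FPR_LEVELS,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Calibrate FPR thresholds and bootstrap AUCs on a benchmark table.

    Parameters
    ----------
    table : DataFrame
        Benchmark table (see module docstring).
    positive_sets, control_sets
        ``set_label`` values defining the positive and control rows used.
    fpr_levels : sequence of float
        Nominal FPR levels to calibrate at.
    n_boot : int
        Bootstrap resamples for the AUC summaries (0 disables).
    seed : int
        Seed for the bootstrap resampling.

    Returns
    -------
    (thresholds, aucs)
        ``thresholds`` has one row per metric x model_choice x subgroup x
        FPR level (threshold NaN for empty subgroups); ``aucs`` one row per
        metric x model_choice x subgroup with point and bootstrap AUC.
    """
    rng = np.random.default_rng(seed)
    pos = table[table["set_label"].isin(positive_sets)]
    ctrl = table[table["set_label"].isin(control_sets)]
    thr_rows, auc_rows = [], []
    for metric, choice in _metric_columns(table):
        col = f"{metric}_{'best' if choice == 'best' else 'avg'}"
        lower = metric in LOWER_IS_BETTER
        for subgroup in SUBGROUPS:
            if subgroup == "total":
                p_sub, c_sub = pos, ctrl
            else:
                p_sub = pos[pos["plddt_subgroup"] == subgroup]
                c_sub = ctrl[ctrl["plddt_subgroup"] == subgroup]
            c_scores = c_sub[col].dropna().to_numpy(dtype=float)
            p_scores = p_sub[col].dropna().to_numpy(dtype=float)
            for level in fpr_levels:
                row = {
                    "metric": metric,
                    "model_choice": choice,
                    "subgroup": subgroup,
                    "fpr_level": level,
                    "threshold": np.nan,
                    "achieved_fpr": np.nan,
                    "n_controls": len(c_scores),
                }
                if len(c_scores):
                    oriented = -c_scores if lower else c_scores
                    res = fpr_threshold(oriented, level)
                    row["threshold"] = -res.threshold if lower else res.threshold
                    row["achieved_fpr"] = res.achieved_fpr
                thr_rows.append(row)
            # AUC (point + bootstrap) when both classes present
            arow = {
                "metric": metric,
                "model_choice": choice,
                "subgroup": subgroup,
                "auc": np.nan,
                "auc_boot_mean": np.nan,
                "auc_ci_lo": np.nan,
                "auc_ci_hi": np.nan,
                "n_pos": len(p_scores),
                "n_ctrl": len(c_scores),
            }
            if len(p_scores) and len(c_scores):
                scores = np.concatenate([p_scores, c_scores])
                labels = np.concatenate([np.ones(len(p_scores)), np.zeros(len(c_scores))])
                arow["auc"] = roc(scores, labels, lower_is_better=lower).auc
                if n_boot:
                    boots = np.empty(n_boot)
                    for b in range(n_boot):
                        idx = rng.integers(0, len(scores), len(scores))
                        lab_b = labels[idx]
                        if lab_b.min() == lab_b.max():
                            boots[b] = np.nan
                            continue
                        boots[b] = roc(scores[idx], lab_b, lower_is_better=lower).auc
                    arow["auc_boot_mean"] = float(np.nanmean(boots))
                    arow["auc_ci_lo"] = float(np.nanpercentile(boots, 2.5))
                    arow["auc_ci_hi"] = float(np.nanpercentile(boots, 97.5))
            auc_rows.append(arow)
    return pd.DataFrame(thr_rows), pd.DataFrame(auc_rows)


def classify(scores: pd.DataFrame, metric: str, threshold: float) -> pd.DataFrame:
    """Label pairs positive/negative by an inclusive score threshold.

    Rows with a missing score are labelled negative and flagged in the
    ``missing_score`` column.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if metric not in scores.columns:
        raise KeyError(f"metric column {metric!r} not in table")
    out = scores.copy()
    vals = out[metric].to_numpy(dtype=float)
    missing = np.isnan(vals)
    out["label"] = np.where(~missing & (vals >= threshold), "positive", "negative")
    out["missing_score"] = missing
    return out
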