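"""Accuracy metrics, ensemble summaries, area estimation and burn QC.

Implements good-practice map assessment: confusion matrices over
zone-disjoint validation pixels, overall/user's/producer's accuracies,
median + IQR summaries over ensemble runs, one-way ANOVA with Tukey HSD
pairwise comparison of feature spaces, stratified class-area estimation
with standard errors and 95% confidence intervals, and commission/omission
error scoring of burned-area products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .classify import TwoStageResult
from .scheme import ClassScheme, DEFAULT_SCHEME

__all__ = [
    "ConfusionMatrix", "AccuracyReport", "AreaEstimate", "BurnEvalResult",
    "confusion_matrix", "accuracy_metrics", "summarize_runs",
    "compare_feature_spaces", "estimate_areas", "evaluate_burned_area",
    "burn_frequency", "stage1_run_accuracies", "stage2_run_accuracies",
]


# ---------------------------------------------------------------------------
# confusion matrices and accuracies
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Cross-counts of map class (rows) x reference class (columns).

    ``rejected`` counts unclassified pixels per reference class (a
    dedicated rejection row kept outside the square matrix). Map-side
    labels outside the class list (e.g. a formation code on a combined
    physiognomy-level assessment) are folded into the square matrix only
    if listed; otherwise they land in ``rejected`` as well — pass a class
    list containing the formations to count them explicitly.
    """

    classes: tuple[str, ...]
    counts: np.ndarray  # (n, n) int
    rejected: np.ndarray  # (n,) unclassified per reference class

    def __post_init__(self) -> None:
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError("confusion matrix must be square over classes")
        if (self.counts < 0).any() or (self.rejected < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.classes),
                          columns=list(self.classes))
        df.loc["(unclassified)"] = self.rejected
        return df


def confusion_matrix(truth, predicted, classes,
                     unclassified_label: str = "") -> ConfusionMatrix:
    """Tally validation pixels into a confusion matrix.

    ``truth`` and ``predicted`` are same-length label sequences;
    predictions equal to ``unclassified_label`` or outside ``classes`` go
    to the rejection row of their reference class.
    """
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.size == 0:
        raise ValueError("empty validation set")
    if truth.shape != predicted.shape:
        raise ValueError("truth/prediction length mismatch")
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    rejected = np.zeros(len(classes), dtype=np.int64)
    for t, p in zip(truth, predicted):
        j = idx.get(str(t))
        if j is None:
            raise ValueError(f"reference label {t!r} not in class list")
        i = idx.get(str(p))
        if i is None or str(p) == unclassified_label:
            rejected[j] += 1
        else:
            counts[i, j] += 1
    return ConfusionMatrix(classes, counts, rejected)


@dataclass
class AccuracyReport:
    """Overall, user's and producer's accuracies in percent.

    Classes with an empty map row (UA) or reference column (PA) are
    reported as NaN (undefined), never as 0. By default unclassified
    pixels are excluded from the OA denominator and reported separately.
    """

    oa: float
    ua: dict[str, float]
    pa: dict[str, float]
    n_unclassified: int = 0


def accuracy_metrics(cm: ConfusionMatrix,
                     count_unclassified_as_error: bool = False
                     ) -> AccuracyReport:
    c = cm.counts.astype(float)
    total = c.sum()
    n_rej = int(cm.rejected.sum())
    if total + n_rej == 0:
        raise ValueError("empty confusion matrix")
    denom = total + n_rej if count_unclassified_as_error else total
    oa = 100.0 * np.trace(c) / denom if denom else np.nan
    ua, pa = {}, {}
    for i, cls in enumerate(cm.classes):
        row = c[i].sum()
        col = c[:, i].sum()
        if count_unclassified_as_error:
            col += cm.rejected[i]
        ua[cls] = 100.0 * c[i, i] / row if row else np.nan
        pa[cls] = 100.0 * c[i, i] / col if col else np.nan
    return AccuracyReport(float(oa), ua, pa, n_rej)


def summarize_runs(values) -> tuple[float, float]:
    """Median and interquartile range (P75 - P25, linear interpolation)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to summarize")
    p25, p75 = np.percentile(v, [25, 75])
    return float(np.median(v)), float(p75 - p25)


def compare_feature_spaces(oa_by_config: dict[str, list]) -> dict:
    """One-way ANOVA + Tukey HSD over per-run accuracies grouped by
    feature-space configuration; pairs at p <= 0.05 are flagged."""
    if len(oa_by_config) < 2:
        raise ValueError("need at least two groups")
    groups = {k: np.asarray(v, float) for k, v in oa_by_config.items()}
    if any(g.size < 2 for g in groups.values()):
        raise ValueError("each group needs at least two values")
    arrays = list(groups.values())
    if all(np.allclose(g, g[0]) for g in arrays) and \
            len({float(g[0]) for g in arrays}) <= 1:
        return {"F": 0.0, "p": 1.0, "pairs": [], "note":
                "zero within-group variance with equal means"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*arrays)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    labels = np.concatenate([[k] * g.size for k, g in groups.items()])
    vals = np.concatenate(arrays)
    tk = pairwise_tukeyhsd(vals, labels, alpha=0.05)
    pairs = []
    for (g1, g2, md, padj, lo, hi, rej) in tk.summary().data[1:]:
        pairs.append({"a": str(g1), "b": str(g2), "meandiff": float(md),
                      "p_adj": float(padj), "significant": bool(rej)})
    return {"F": float(F), "p": float(p), "pairs": pairs}


# ---------------------------------------------------------------------------
# stratified area estimation
# ---------------------------------------------------------------------------

@dataclass
class AreaEstimate:
    """Per-class stratified area estimates.

    ``table`` columns: class, mapped_ha, estimated_ha, se_ha, ci95_ha.
    The stratum weights W_i are the mapped-area proportions; the estimated
    proportion of class k is sum_i W_i n_ik / n_i. and its standard error
    sqrt(sum_i W_i^2 p_i(1-p_i)/(n_i.-1)) with p_i = n_ik/n_i. — the
    standard stratified (map-class stratum) estimator.
    """

    table: pd.DataFrame
    total_area_ha: float
    weights: dict[str, float]


def estimate_areas(cm: ConfusionMatrix, mapped_counts: dict[str, int],
                   pixel_area_m2: float, z: float = 1.96) -> AreaEstimate:
    classes = cm.classes
    n_map = np.array([float(mapped_counts.get(c, 0)) for c in classes])
    if n_map.sum() <= 0:
        raise ValueError("no mapped pixels")
    W = n_map / n_map.sum()
    total_ha = n_map.sum() * pixel_area_m2 / 10_000.0
    counts = cm.counts.astype(float)
    n_i = counts.sum(axis=1)  # validation pixels per map-class stratum
    for i, c in enumerate(classes):
        if W[i] > 0 and n_i[i] <= 1:
            raise ValueError(
                f"stratum {c!r} has {int(n_i[i])} validation pixel(s); "
                "variance is undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n_i[:, None]  # p_ij = n_ij / n_i.
    p = np.nan_to_num(p)
    p_hat = W @ p  # estimated proportion per reference class k
    est_ha = total_ha * p_hat
    var = np.zeros(len(classes))
    for i in range(len(classes)):
        if n_i[i] > 1:
            var += W[i] ** 2 * p[i] * (1 - p[i]) / (n_i[i] - 1)
    se_ha = total_ha * np.sqrt(var)
    table = pd.DataFrame({
        "class": list(classes),
        "mapped_ha": n_map * pixel_area_m2 / 10_000.0,
        "estimated_ha": est_ha,
        "se_ha": se_ha,
        "ci95_ha": z * se_ha,
    })
    return AreaEstimate(table, float(total_ha),
                        {c: float(w) for c, w in zip(classes, W)})


# ---------------------------------------------------------------------------
# burned-area product evaluation
# ---------------------------------------------------------------------------

@dataclass
class BurnEvalResult:
    """Commission/omission errors (%) and area bias of a burned-area
    product against a reference burn map."""

    ce: float
    oe: float
    bias: float
    min_scar_area_m2: float | None = None
    n_tp: int = 0
    n_fp: int = 0
    n_fn: int = 0
    n_tn: int = 0


def _filter_small_scars(mask: np.ndarray, pixel_size: float,
                        min_area_m2: float) -> np.ndarray:
    """Remove 8-connected components below the area threshold."""
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return mask
    areas = ndimage.sum_labels(np.ones_like(mask, dtype=float), lab,
                               index=np.arange(1, n + 1)) * pixel_size ** 2
    keep = np.zeros(n + 1, bool)
    keep[1:] = areas >= min_area_m2
    return keep[lab]


def evaluate_burned_area(product_masks, reference_masks,
                         pixel_size: float,
                         min_scar_area_m2: float | None = None,
                         ce_definition: str = "standard") -> BurnEvalResult:
    """Score a burned-area product against a reference over a period.

    Masks are lists of co-gridded boolean layers; the comparison is on
    their unions. Default definitions: CE = FP/(TP+FP),
    OE = FN/(TP+FN), bias = (TP+FP)/(TP+FN) (product / reference burned
    area). ``ce_definition="all-unburned"`` switches the commission error
    to FP/(FP+TN). An optional scar-area filter removes reference scars
    (8-connected components) below the threshold before scoring.
    """
    prod = np.any(np.stack(list(product_masks)), axis=0)
    ref = np.any(np.stack(list(reference_masks)), axis=0)
    if prod.shape != ref.shape:
        raise ValueError("product and reference masks are not co-gridded")
    if min_scar_area_m2 is not None:
        ref = _filter_small_scars(ref, pixel_size, min_scar_area_m2)
    tp = int((prod & ref).sum())
    fp = int((prod & ~ref).sum())
    fn = int((~prod & ref).sum())
    tn = int((~prod & ~ref).sum())
    if ce_definition == "standard":
        ce = 100.0 * fp / (tp + fp) if (tp + fp) else 0.0
    elif ce_definition == "all-unburned":
        ce = 100.0 * fp / (fp + tn) if (fp + tn) else 0.0
    else:
        raise ValueError(f"unknown CE definition {ce_definition!r}")
    if tp + fn == 0:
        warnings.warn("reference contains no burned pixels; OE undefined")
        oe = np.nan
        bias = np.nan
    else:
        oe = 100.0 * fn / (tp + fn)
        bias = (tp + fp) / (tp + fn)
    return BurnEvalResult(float(ce), float(oe), float(bias),
                          min_scar_area_m2, tp, fp, fn, tn)


def burn_frequency(masks) -> tuple[np.ndarray, dict[str, float]]:
    """Per-pixel burn-event counts and the fractions burned >= 1 and >= 2
    times."""
    freq = np.sum(np.stack([np.asarray(m, bool) for m in masks]), axis=0)
    n = freq.size
    return freq, {
        "burned_once_or_more": float((freq >= 1).sum() / n),
        "burned_twice_or_more": float((freq >= 2).sum() / n),
    }


# ---------------------------------------------------------------------------
# per-run accuracies from the two-stage routine
# ---------------------------------------------------------------------------

def stage1_run_accuracies(result: TwoStageResult,
                          scheme: ClassScheme = DEFAULT_SCHEME
                          ) -> list[float]:
    """Per-run formation-level OA on each run's unused pool samples."""
    oas = []
    for truth, pred in result.run_stage1_holdout:
        cm = confusion_matrix(truth, pred, scheme.stage1_classes)
        oas.append(accuracy_metrics(cm).oa)
    return oas


def stage2_run_accuracies(result: TwoStageResult,
                          scheme: ClassScheme = DEFAULT_SCHEME,
                          native_only: bool = True) -> list[float]:
    """Per-run combined stage-1+2 OA on the withheld validation samples.

    Misclassification at either stage counts against the run: a native
    pixel sent to the wrong formation, left at the formation level, or
    given the wrong physiognomy is an error for its true physiognomy.
    """
    classes = tuple(scheme.terminal_classes) + tuple(scheme.formations)
    oas = []
    for truth_t, truth_f, pred in result.run_validation:
        if native_only:
            keep = np.isin(truth_t.astype(str),
                           list(scheme.physiognomies))
            truth, p = truth_t[keep], pred[keep]
        else:
            truth, p = truth_t, pred
        cm = confusion_matrix(truth, p, classes)
        oas.append(accuracy_metrics(cm, count_unclassified_as_error=True).oa)
    return oas
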