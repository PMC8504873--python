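"""Prediction-model comparison statistics for binary risk scores.

Implements, from their defining formulas, the full comparison suite used
to judge a pair of diagnostic risk models on the same validation cohort:

* ROC curve and AUC with DeLong variance / confidence interval, and the
  paired DeLong test for correlated AUCs,
* confusion-matrix metrics at an operating cutoff with exact
  Clopper-Pearson binomial confidence intervals,
* the two-category net reclassification index (NRI), each model
  classifying at its own operating cutoff,
* Brier score and binned calibration curves,
* decision-curve analysis (net benefit against treat-all / treat-none).

Conventions: labels are 0 (benign) / 1 (malignant); a lesion is
predicted malignant when its score is >= the cutoff.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DomainError

# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


@dataclass(frozen=True)
class ROCCurve:
    """Operating points ordered from the +inf threshold to the -inf end."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    variance: float  # DeLong


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise DomainError("labels must contain both classes, coded 0/1")
    return labels


def roc_points(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """Full ROC curve, starting at (0, 0) and ending at (1, 1)."""
    labels = _check_binary(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged) — scipy's average ranking."""
    return stats.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-observation placement values (DeLong's V10, V01)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n  # one per positive
    v01 = 1.0 - (all_r[m:] - neg_r) / m  # one per negative
    return float(auc), v10, v01


def auc(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05) -> AUCResult:
    """AUC with DeLong variance and normal CI (clipped to [0, 1]).

    The trapezoidal area under :func:`roc_points` equals the
    Mann-Whitney statistic (ties counted one half), which is what the
    placement formulation computes.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    a, v10, v01 = _delong_placements(scores, labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return AUCResult(auc=a, ci_low=float(max(0.0, a - half)),
                     ci_high=float(min(1.0, a + half)), variance=float(var))


def compare_auc_delong(scores_a: np.ndarray, scores_b: np.ndarray,
                       labels: np.ndarray) -> tuple[float, float, float]:
    """Paired DeLong test; returns (AUC_A - AUC_B, z, two-sided p).

    Both score vectors must refer to the same lesions in the same
    order.  A model compared with itself gives (0, 0, 1).
    """
    labels = _check_binary(labels)
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    if scores_a.shape != scores_b.shape or len(scores_a) != len(labels):
        raise DomainError("paired comparison needs aligned score vectors")
    a1, v10_1, v01_1 = _delong_placements(scores_a, labels)
    a2, v10_2, v01_2 = _delong_placements(scores_b, labels)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = a1 - a2
    if var_diff <= 0:
        return float(delta), 0.0, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(delta), float(z), float(p)


# ---------------------------------------------------------------------------
# Confusion metrics


@dataclass(frozen=True)
class MetricCI:
    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ConfusionAtCutoff:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: MetricCI
    specificity: MetricCI
    accuracy: MetricCI
    ppv: MetricCI
    npv: MetricCI


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> MetricCI:
    """Exact binomial CI; degenerate n=0 gives the full [0, 1] interval."""
    if n == 0:
        return MetricCI(float("nan"), 0.0, 1.0)
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return MetricCI(k / n, float(lo), float(hi))


def confusion_metrics(scores: np.ndarray, labels: np.ndarray,
                      cutoff: float) -> ConfusionAtCutoff:
    """Confusion counts and ratio metrics at one cutoff (>= is positive).

    Confidence intervals are exact Clopper-Pearson binomial intervals —
    unlike normal-approximation (Wald) intervals these can never leave
    [0, 1].
    """
    labels = np.asarray(labels)
    pred = np.asarray(scores, dtype=np.float64) >= cutoff
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    return ConfusionAtCutoff(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_clopper_pearson(tp, tp + fn),
        specificity=_clopper_pearson(tn, tn + fp),
        accuracy=_clopper_pearson(tp + tn, tp + tn + fp + fn),
        ppv=_clopper_pearson(tp, tp + fp),
        npv=_clopper_pearson(tn, tn + fn),
    )


# ---------------------------------------------------------------------------
# NRI


@dataclass(frozen=True)
class NRIResult:
    nri_events: float
    nri_nonevents: float
    nri_total: float
    z: float
    p_value: float
    n_events: int
    n_nonevents: int


def nri(scores_old: np.ndarray, scores_new: np.ndarray, labels: np.ndarray,
        cutoff_old: float, cutoff_new: float) -> NRIResult:
    """Two-category net reclassification index, old model -> new model.

    Each model classifies at its own operating cutoff; "up" means a
    lesion moves from predicted-benign to predicted-malignant.
    NRI+ = (up - down)/n among events (malignant), NRI- = (down - up)/n
    among nonevents (benign); the total is their exact sum.  z uses the
    standard asymptotic variance, the sum of the two components'
    binomial-difference variances.
    """
    labels = _check_binary(labels)
    old_pos = np.asarray(scores_old, dtype=np.float64) >= cutoff_old
    new_pos = np.asarray(scores_new, dtype=np.float64) >= cutoff_new
    up = ~old_pos & new_pos
    down = old_pos & ~new_pos
    ev, ne = labels == 1, labels == 0
    n_ev, n_ne = int(ev.sum()), int(ne.sum())
    pu_e = up[ev].sum() / n_ev
    pd_e = down[ev].sum() / n_ev
    pu_n = up[ne].sum() / n_ne
    pd_n = down[ne].sum() / n_ne
    nri_e = pu_e - pd_e
    nri_n = pd_n - pu_n
    total = nri_e + nri_n
    var = ((pu_e + pd_e - (pu_e - pd_e) ** 2) / n_ev
           + (pu_n + pd_n - (pu_n - pd_n) ** 2) / n_ne)
    if var <= 0:
        z, p = 0.0, 1.0 if total == 0 else 0.0
    else:
        z = total / np.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
    return NRIResult(nri_events=float(nri_e), nri_nonevents=float(nri_n),
                     nri_total=float(total), z=float(z), p_value=float(p),
                     n_events=n_ev, n_nonevents=n_ne)


# ---------------------------------------------------------------------------
# Calibration


def brier(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean squared difference between score and binary outcome."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise DomainError("labels must be 0/1")
    return float(np.mean((scores - labels) ** 2))


@dataclass(frozen=True)
class CalibrationCurve:
    mean_predicted: np.ndarray  # per non-empty bin
    observed_fraction: np.ndarray
    counts: np.ndarray
    bin_edges: np.ndarray
    brier: float


def calibration_curve(scores: np.ndarray, labels: np.ndarray,
                      n_bins: int = 10) -> CalibrationCurve:
    """Equal-width reliability diagram on [0, 1]; empty bins are omitted."""
    if n_bins < 2:
        raise DomainError("need at least 2 calibration bins")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.floor(scores * n_bins).astype(int), 0, n_bins - 1)
    mean_pred, obs, counts = [], [], []
    for b in range(n_bins):
        in_bin = idx == b
        if in_bin.any():
            mean_pred.append(scores[in_bin].mean())
            obs.append(labels[in_bin].mean())
            counts.append(int(in_bin.sum()))
    return CalibrationCurve(
        mean_predicted=np.asarray(mean_pred), observed_fraction=np.asarray(obs),
        counts=np.asarray(counts), bin_edges=edges,
        brier=brier(scores, labels),
    )


# ---------------------------------------------------------------------------
# Decision curves


@dataclass(frozen=True)
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


def decision_curve(scores: np.ndarray, labels: np.ndarray,
                   pt_grid: np.ndarray | None = None) -> DecisionCurve:
    """Net benefit NB(pt) = TP/n - FP/n * pt/(1-pt) over a threshold grid.

    Positive classification at score >= pt.  The treat-all strategy
    calls every lesion positive; treat-none is identically zero.  The
    default grid is 0.01..0.99 in steps of 0.01 (pt = 1 is excluded —
    its odds weight diverges).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if pt_grid is None:
        pt_grid = np.arange(0.01, 1.0, 0.01)
    pt_grid = np.asarray(pt_grid, dtype=np.float64)
    if pt_grid.min() <= 0 or pt_grid.max() >= 1:
        raise DomainError("threshold grid must lie strictly inside (0, 1)")
    n = len(labels)
    prevalence = (labels == 1).sum() / n
    odds = pt_grid / (1.0 - pt_grid)
    nb = np.empty_like(pt_grid)
    for i, pt in enumerate(pt_grid):
        pred = scores >= pt
        tp = (pred & (labels == 1)).sum() / n
        fp = (pred & (labels == 0)).sum() / n
        nb[i] = tp - fp * odds[i]
    treat_all = prevalence - (1.0 - prevalence) * odds
    return DecisionCurve(thresholds=pt_grid, net_benefit=nb,
                         treat_all=treat_all,
                         treat_none=np.zeros_like(pt_grid))


# ---------------------------------------------------------------------------
# Reports


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class EvalReport:
    """Everything reported for one model on one cohort."""

    model: str
    cohort: str
    cutoff: float
    auc: AUCResult
    confusion: ConfusionAtCutoff
    brier: float
    calibration: CalibrationCurve
    decision: DecisionCurve

    def to_dict(self) -> dict:
        return _to_jsonable(asdict(self))


@dataclass
class ComparisonReport:
    """Paired comparison of two models on the same validation lesions."""

    model_a: str
    model_b: str
    delta_auc: float
    delong_z: float
    delong_p: float
    nri: NRIResult
    brier_a: float
    brier_b: float

    def to_dict(self) -> dict:
        return _to_jsonable(asdict(self))


def evaluate_model(model_name: str, cohort: str, scores: np.ndarray,
                   labels: np.ndarray, cutoff: float,
                   n_calibration_bins: int = 10) -> EvalReport:
    """Assemble the full single-model report."""
    return EvalReport(
        model=model_name, cohort=cohort, cutoff=float(cutoff),
        auc=auc(scores, labels),
        confusion=confusion_metrics(scores, labels, cutoff),
        brier=brier(scores, labels),
        calibration=calibration_curve(scores, labels, n_calibration_bins),
        decision=decision_curve(scores, labels),
    )


def compare_models(name_a: str, name_b: str, scores_a: np.ndarray,
                   scores_b: np.ndarray, labels: np.ndarray,
                   cutoff_a: float, cutoff_b: float) -> ComparisonReport:
    """DeLong + NRI + Brier comparison of model A (new) vs model B (old)."""
    delta, z, p = compare_auc_delong(scores_a, scores_b, labels)
    return ComparisonReport(
        model_a=name_a, model_b=name_b, delta_auc=delta, delong_z=z,
        delong_p=p,
        nri=nri(scores_b, scores_a, labels, cutoff_b, cutoff_a),
        brier_a=brier(scores_a, labels), brier_b=brier(scores_b, labels),
    )


def write_report(report, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
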