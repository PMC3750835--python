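"""Voxelwise statistical evaluation of derived maps.

The protocol compares cancer-class against healthy-class voxel scores
with four tools:

* a binormal ROC model (Gaussian class-conditional scores) summarised by
  the area A_z = Phi(a / sqrt(1 + b^2)) with intercept
  a = (mu1 - mu0) / sigma1 and slope b = sigma0 / sigma1;
* a nonparametric empirical ROC (Mann-Whitney AUC) as cross-check;
* a two-class Gaussian maximum-likelihood voxel classifier without class
  priors, scored by sensitivity / specificity / accuracy, with
  leave-one-out cross-validation across cases;
* a Fisher-style separability ratio (mu1 - mu0)^2 / (sigma0^2 + sigma1^2).

Cancer is the positive class throughout.  CDI maps are used as-is
(lesions hyperintense); ADC maps should be negated before entering the
ROC or classifier so that higher always means more cancer-like.
Orientation is never auto-flipped: scores with mu1 < mu0 yield A_z < 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr, ndtri
from sklearn.metrics import roc_auc_score, roc_curve

from .dwi_io import LabelMap, ScalarMap
from .errors import ValidationError
from .phantom import CANCER_LABEL, HEALTHY_LABEL

#: Relative SD floor keeping degenerate (constant) classes evaluable.
_SD_FLOOR_SCALE = 1e-12


@dataclass
class ROCResult:
    """Binormal ROC fit: intercept a, slope b, area Az, sampled curve.

    ``curve`` is an (n, 2) array of (FPR, TPR) pairs running from (0, 0)
    to (1, 1) with TPR nondecreasing in FPR.
    """

    a: float
    b: float
    Az: float
    curve: np.ndarray


@dataclass
class ClassifierModel:
    """Per-class Gaussian intensity model (maximum-likelihood estimates)."""

    mean_healthy: float
    sd_healthy: float
    mean_cancer: float
    sd_cancer: float

    def __post_init__(self) -> None:
        if self.sd_healthy <= 0 or self.sd_cancer <= 0:
            raise ValidationError("class standard deviations must be > 0")


@dataclass
class CaseData:
    """One case: a score map and its gland-restricted tissue labels."""

    case_id: str
    score_map: ScalarMap
    labels: LabelMap

    def __post_init__(self) -> None:
        if self.score_map.values.shape != self.labels.labels.shape:
            raise ValidationError(
                f"case {self.case_id}: map shape {self.score_map.values.shape} "
                f"!= label shape {self.labels.labels.shape}"
            )

    def class_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """(cancer scores, healthy scores) for gland voxels."""
        values = self.score_map.values
        return (
            values[self.labels.labels == CANCER_LABEL],
            values[self.labels.labels == HEALTHY_LABEL],
        )


@dataclass
class EvalMetrics:
    """Confusion counts and the rates derived from them (cancer = positive)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        pos = self.tp + self.fn
        neg = self.tn + self.fp
        total = pos + neg
        if total == 0:
            raise ValidationError("no voxels to evaluate")
        self.sensitivity = self.tp / pos if pos else float("nan")
        self.specificity = self.tn / neg if neg else float("nan")
        self.accuracy = (self.tp + self.tn) / total


def _as_scores(values, name: str, min_len: int) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size < min_len:
        raise ValidationError(f"{name} needs >= {min_len} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def binormal_roc_from_moments(
    mu_healthy: float,
    sigma_healthy: float,
    mu_cancer: float,
    sigma_cancer: float,
    n_thresholds: int = 201,
) -> ROCResult:
    """Binormal ROC from class-conditional Gaussian moments.

    With FPR = Phi(z) at a threshold parameterised by z, the binormal
    curve is TPR = Phi(a + b z); its area is
    Az = Phi(a / sqrt(1 + b^2)) = Phi((mu1 - mu0) / sqrt(sigma0^2 + sigma1^2)).
    """
    if sigma_healthy <= 0 or sigma_cancer <= 0:
        raise ValidationError("class standard deviations must be > 0")
    a = (mu_cancer - mu_healthy) / sigma_cancer
    b = sigma_healthy / sigma_cancer
    az = float(ndtr(a / np.sqrt(1.0 + b * b)))
    fpr = np.linspace(0.0, 1.0, max(int(n_thresholds), 201))
    z = ndtri(np.clip(fpr, 1e-300, 1.0 - 1e-16))
    tpr = ndtr(a + b * z)
    tpr[0], tpr[-1] = 0.0, 1.0
    curve = np.column_stack([fpr, np.maximum.accumulate(tpr)])
    return ROCResult(a=float(a), b=float(b), Az=az, curve=curve)


def binormal_roc(
    scores_cancer: Sequence[float],
    scores_healthy: Sequence[float],
    n_thresholds: int = 201,
) -> ROCResult:
    """Fit the binormal ROC model to two voxel-score samples.

    Class-conditional normals are fitted by sample mean and SD; identical
    samples give Az = 0.5 exactly, and mu1 < mu0 gives Az < 0.5 (no
    orientation flip).
    """
    cancer = _as_scores(scores_cancer, "scores_cancer", 2)
    healthy = _as_scores(scores_healthy, "scores_healthy", 2)
    sd_c = float(np.std(cancer, ddof=1))
    sd_h = float(np.std(healthy, ddof=1))
    if sd_c == 0 or sd_h == 0:
        raise ValidationError("zero-variance score sample")
    return binormal_roc_from_moments(
        float(np.mean(healthy)), sd_h, float(np.mean(cancer)), sd_c, n_thresholds
    )


def empirical_roc(
    scores_cancer: Sequence[float], scores_healthy: Sequence[float]
) -> tuple[np.ndarray, float]:
    """Nonparametric ROC curve and trapezoidal AUC.

    The AUC equals the Mann-Whitney U statistic scaled to [0, 1], with
    ties counted half; it is invariant under strictly increasing
    transforms of the scores.
    """
    cancer = _as_scores(scores_cancer, "scores_cancer", 1)
    healthy = _as_scores(scores_healthy, "scores_healthy", 1)
    y = np.concatenate([np.ones(cancer.size), np.zeros(healthy.size)])
    s = np.concatenate([cancer, healthy])
    if np.all(s == s[0]):
        # Degenerate single-valued scores: all comparisons tie.
        curve = np.array([[0.0, 0.0], [1.0, 1.0]])
        return curve, 0.5
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return np.column_stack([fpr, tpr]), auc


def separability(
    scores_cancer: Sequence[float], scores_healthy: Sequence[float]
) -> float:
    """Fisher separability ratio (mu1 - mu0)^2 / (sigma0^2 + sigma1^2).

    Zero for identical class distributions; grows with the squared mean
    gap at fixed within-class variances.  Population (biased-denominator)
    variances are used, consistent with the ML classifier fit.
    """
    cancer = _as_scores(scores_cancer, "scores_cancer", 1)
    healthy = _as_scores(scores_healthy, "scores_healthy", 1)
    var_sum = float(np.var(cancer) + np.var(healthy))
    if var_sum == 0:
        raise ValidationError("zero total variance; separability undefined")
    return float((np.mean(cancer) - np.mean(healthy)) ** 2 / var_sum)


def _sd_with_floor(values: np.ndarray, floored: list[str], name: str) -> float:
    sd = float(np.std(values))  # ML estimate: biased denominator
    floor = _SD_FLOOR_SCALE * (abs(float(np.mean(values))) + 1.0)
    if sd < floor:
        floored.append(name)
        return floor
    return sd


def fit_ml_classifier(train: Sequence[CaseData]) -> ClassifierModel:
    """Fit per-class Gaussians to voxel intensities pooled across cases.

    Maximum-likelihood estimates: sample mean and biased-denominator SD,
    each voxel counted once.  A tiny SD floor keeps degenerate constant
    classes evaluable (flooring is logged).
    """
    if not train:
        raise ValidationError("empty training set")
    cancer = np.concatenate([case.class_scores()[0] for case in train])
    healthy = np.concatenate([case.class_scores()[1] for case in train])
    if cancer.size == 0 or healthy.size == 0:
        raise ValidationError("training pool must contain both classes")
    floored: list[str] = []
    model = ClassifierModel(
        mean_healthy=float(np.mean(healthy)),
        sd_healthy=_sd_with_floor(healthy, floored, "healthy"),
        mean_cancer=float(np.mean(cancer)),
        sd_cancer=_sd_with_floor(cancer, floored, "cancer"),
    )
    if floored:
        import logging

        logging.getLogger(__name__).warning(
            "SD floor applied to class(es): %s", ", ".join(floored)
        )
    return model


def _log_likelihood(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * ((values - mean) / sd) ** 2 - np.log(sd)


def classify(
    model: ClassifierModel, score_map: ScalarMap, mask: LabelMap
) -> tuple[np.ndarray, EvalMetrics]:
    """Assign each gland voxel to its higher-likelihood class.

    Pure maximum likelihood — no class priors.  Returns a boolean map
    (True = predicted cancer; False elsewhere, including outside the
    gland) and the confusion-count metrics against the mask, with cancer
    as the positive class.  Likelihood ties resolve to healthy.
    """
    if score_map.values.shape != mask.labels.shape:
        raise ValidationError(
            f"map shape {score_map.values.shape} != mask shape {mask.labels.shape}"
        )
    gland = (mask.labels == HEALTHY_LABEL) | (mask.labels == CANCER_LABEL)
    values = score_map.values[gland]
    ll_cancer = _log_likelihood(values, model.mean_cancer, model.sd_cancer)
    ll_healthy = _log_likelihood(values, model.mean_healthy, model.sd_healthy)
    pred_cancer = ll_cancer > ll_healthy

    truth_cancer = mask.labels[gland] == CANCER_LABEL
    tp = int(np.count_nonzero(pred_cancer & truth_cancer))
    fp = int(np.count_nonzero(pred_cancer & ~truth_cancer))
    fn = int(np.count_nonzero(~pred_cancer & truth_cancer))
    tn = int(np.count_nonzero(~pred_cancer & ~truth_cancer))

    prediction = np.zeros(score_map.values.shape, dtype=bool)
    prediction[gland] = pred_cancer
    return prediction, EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def loocv(cases: Sequence[CaseData]) -> tuple[list[EvalMetrics], EvalMetrics]:
    """Leave-one-out cross-validation over cases.

    Each case is held out once; the classifier is fitted on the rest and
    evaluated on the held-out case.  Pooled metrics come from the summed
    confusion counts across folds.
    """
    if len(cases) < 2:
        raise ValidationError(f"LOOCV needs >= 2 cases, got {len(cases)}")
    per_case: list[EvalMetrics] = []
    totals = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for k, held_out in enumerate(cases):
        train = [c for j, c in enumerate(cases) if j != k]
        model = fit_ml_classifier(train)
        _, metrics = classify(model, held_out.score_map, held_out.labels)
        per_case.append(metrics)
        for key in totals:
            totals[key] += getattr(metrics, key)
    return per_case, EvalMetrics(**totals)
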