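"""Evaluation statistics for the classifier comparison.

The malignant class is scored against normal+benign combined: the ROC
and its AUC, an operating point maximising the Youden index J =
sensitivity + specificity - 1 subject to sensitivity >= 90%, percentile
bootstrap confidence intervals (B = 1000), balanced accuracy over the
three classes, the Fréchet distance between feature Gaussians (FID with
a pluggable feature extractor), the paired DeLong test for correlated
AUCs, and Holm–Bonferroni stepdown correction over all pairwise
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from . import _nn
from .classifier import ScoreSet
from .records import CLASSES, CohortManifest, pixel_stack

__all__ = [
    "RocCurve", "OperatingPoint", "GaussianStats", "SignificanceMatrix",
    "binarize_malignant", "auc", "roc_points", "constrained_youden",
    "bootstrap_ci", "sens_spec_at_threshold_ci", "balanced_accuracy",
    "frechet_distance", "fit_gaussian", "fid", "RandomConvExtractor",
    "delong_paired", "holm_bonferroni", "significance_matrix",
]


# ---------------------------------------------------------------------------
# ROC machinery


@dataclass
class RocCurve:
    """(threshold, sensitivity, specificity) triples, thresholds descending."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def J(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def binarize_malignant(score_set: ScoreSet) -> tuple[np.ndarray, np.ndarray]:
    """Score = p_malignant; label 1 iff the true class is malignant."""
    scores = score_set.probabilities[:, CLASSES.index("malignant")]
    labels = np.array([1 if c == "malignant" else 0 for c in score_set.true_classes])
    return scores, labels


def _check_two_classes(labels):
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("both positive and negative labels are required")
    return labels


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(score+ > score-) + 0.5 P(tie)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def roc_points(scores, labels) -> RocCurve:
    labels = _check_two_classes(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr)


def constrained_youden(roc: RocCurve, min_sensitivity: float = 0.90) -> OperatingPoint:
    """Maximise J over thresholds with sensitivity >= the floor.

    If no threshold reaches the floor (possible only without positives)
    the unconstrained maximiser is returned. Ties break toward higher
    specificity, then higher threshold.
    """
    if len(roc.thresholds) == 0:
        raise ValueError("empty ROC curve")
    sens, spec, thr = roc.sensitivity, roc.specificity, roc.thresholds
    feasible = sens >= min_sensitivity
    idx = np.flatnonzero(feasible) if feasible.any() else np.arange(len(sens))
    j = sens[idx] + spec[idx] - 1.0
    key = np.lexsort((thr[idx], spec[idx], j))  # last key dominates
    best = idx[key[-1]]
    return OperatingPoint(float(thr[best]), float(sens[best]), float(spec[best]))


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_ci(score_set: ScoreSet, metric_fn, B: int = 1000, seed: int = 0,
                 patient_level: bool = False) -> tuple[float, float]:
    """Percentile 95% CI of a metric over B resamples of the test set.

    Resampling is image-level by default (``patient_level=True`` resamples
    whole patients). Resamples on which the metric is undefined (e.g. a
    single-class draw for AUC) are redrawn; the redraw count is recorded
    on the function as ``bootstrap_ci.last_redraws``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(score_set)
    ids = np.asarray(score_set.patient_ids)
    uniq = list(dict.fromkeys(score_set.patient_ids))
    values = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            if patient_level:
                chosen = rng.choice(len(uniq), size=len(uniq), replace=True)
                idx = np.concatenate([np.flatnonzero(ids == uniq[c]) for c in chosen])
            else:
                idx = rng.integers(0, n, size=n)
            resampled = ScoreSet(score_set.probabilities[idx],
                                 [score_set.true_classes[i] for i in idx],
                                 [score_set.patient_ids[i] for i in idx],
                                 score_set.combination_id)
            try:
                values[b] = metric_fn(resampled)
                break
            except ValueError:
                redraws += 1
                if redraws > 100 * B:
                    raise
    bootstrap_ci.last_redraws = redraws
    return float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5))


def sens_spec_at_threshold_ci(score_set: ScoreSet, threshold: float, B: int = 1000,
                              seed: int = 0) -> dict[str, tuple[float, float]]:
    """Bootstrap CIs for sensitivity and specificity at a fixed threshold."""
    def sens(ss):
        s, y = binarize_malignant(ss)
        if y.sum() == 0:
            raise ValueError("no positives")
        return float(np.mean(s[y == 1] >= threshold))

    def spec(ss):
        s, y = binarize_malignant(ss)
        if (y == 0).sum() == 0:
            raise ValueError("no negatives")
        return float(np.mean(s[y == 0] < threshold))

    return {"sensitivity": bootstrap_ci(score_set, sens, B=B, seed=seed),
            "specificity": bootstrap_ci(score_set, spec, B=B, seed=seed + 1)}


def balanced_accuracy(score_set: ScoreSet) -> float:
    """Unweighted mean of per-class recalls; predicted class = argmax."""
    pred = np.argmax(score_set.probabilities, axis=1)
    true = np.array([CLASSES.index(c) for c in score_set.true_classes])
    recalls = []
    for k in range(len(CLASSES)):
        mask = true == k
        if not mask.any():
            raise ValueError(f"class {CLASSES[k]!r} absent from the true labels")
        recalls.append(float(np.mean(pred[mask] == k)))
    return float(np.mean(recalls))


# ---------------------------------------------------------------------------
# Fréchet distance / FID


@dataclass
class GaussianStats:
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=np.float64))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=np.float64))
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


def fit_gaussian(features: np.ndarray) -> GaussianStats:
    features = np.asarray(features, dtype=np.float64)
    if len(features) < 2:
        raise ValueError("at least 2 feature vectors are required")
    return GaussianStats(features.mean(axis=0), np.cov(features, rowvar=False))


def frechet_distance(stats_a: GaussianStats, stats_b: GaussianStats) -> float:
    """||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^(1/2)).

    Numerical negative-eigenvalue noise in the matrix square root is
    clipped; the clip magnitude is recorded on the function as
    ``frechet_distance.last_imag_clip``.
    """
    if stats_a.mu.size != stats_b.mu.size:
        raise ValueError("dimension mismatch between the two Gaussians")
    diff = stats_a.mu - stats_b.mu
    prod = stats_a.sigma @ stats_b.sigma
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank-deficient products warn; clip below
        covmean = scipy.linalg.sqrtm(prod)
    clip = float(np.abs(covmean.imag).max()) if np.iscomplexobj(covmean) else 0.0
    frechet_distance.last_imag_clip = clip
    covmean = covmean.real
    d = float(diff @ diff + np.trace(stats_a.sigma + stats_b.sigma - 2.0 * covmean))
    return max(d, 0.0)


class RandomConvExtractor:
    """Fixed-seed random-convolution image embedding (no pretrained weights).

    Two strided random convolution layers with ReLU, followed by per-map
    mean and standard-deviation pooling. Features are comparable only
    within one extractor instance (same seed/width).
    """

    def __init__(self, seed: int = 0, width: int = 32):
        rng = np.random.default_rng(seed)
        self.width = width
        self.conv1 = _nn.Conv2d(1, width // 2, 5, stride=2, pad=2, rng=rng)
        self.conv2 = _nn.Conv2d(width // 2, width, 5, stride=2, pad=2, rng=rng)
        self.extractor_id = f"randconv-s{seed}-w{width}"

    def __call__(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """images: (N, H, W) in [0, 1] -> (N, 2*width) features."""
        feats = []
        for start in range(0, len(images), batch_size):
            x = np.asarray(images[start: start + batch_size], dtype=np.float64)[:, None]
            h, _ = self.conv1.forward(x)
            h = np.maximum(h, 0.0)
            h, _ = self.conv2.forward(h)
            h = np.maximum(h, 0.0)
            feats.append(np.concatenate([h.mean(axis=(2, 3)), h.std(axis=(2, 3))], axis=1))
        return np.vstack(feats)


def fid(images_a, images_b, extractor=None) -> float:
    """Fréchet distance between feature Gaussians of two image sets.

    Accepts (N, H, W) arrays in [0, 1] or cohort manifests. With fewer
    images than feature dimension + 1 the covariances are rank-deficient;
    the value is still computed but should be compared only against
    values from the same sample sizes.
    """
    if isinstance(images_a, CohortManifest):
        images_a = pixel_stack(images_a)
    if isinstance(images_b, CohortManifest):
        images_b = pixel_stack(images_b)
    if len(images_a) < 2 or len(images_b) < 2:
        raise ValueError("each side needs at least 2 images")
    extractor = extractor or RandomConvExtractor()
    return frechet_distance(fit_gaussian(extractor(images_a)),
                            fit_gaussian(extractor(images_b)))


# ---------------------------------------------------------------------------
# DeLong test and multiplicity correction


def _placements(scores, labels):
    """Per-positive and per-negative placement values (ties half-weighted)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).astype(np.float64)
    gt += 0.5 * (pos[:, None] == neg[None, :])
    return gt.mean(axis=1), 1.0 - gt.mean(axis=0)  # V10 (per pos), V01 (per neg)


def delong_paired(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """Paired DeLong test for two correlated AUCs on one test set.

    Returns (auc_a, auc_b, z, p). The AUC covariance is estimated from
    the empirical covariance of the placement values, var(diff) =
    S11 + S22 - 2 S12; a zero variance with equal AUCs yields p = 1.
    """
    labels = _check_two_classes(labels)
    v10_a, v01_a = _placements(scores_a, labels)
    v10_b, v01_b = _placements(scores_b, labels)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 0:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUC estimate."""
    labels = _check_two_classes(labels)
    v10, v01 = _placements(scores, labels)
    return float(v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01))


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm stepdown: adjusted p-values and reject flags (in input order)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return adjusted, reject


@dataclass
class SignificanceMatrix:
    """Pairwise comparison of classifiers on one shared test set."""

    ids: list
    aucs: dict
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    stars: list[list[str]]   # "ns", "*", or "**"
    alpha: float

    def star(self, id_a, id_b) -> str:
        return self.stars[self.ids.index(id_a)][self.ids.index(id_b)]


def significance_matrix(score_sets: dict, alpha: float = 0.05) -> SignificanceMatrix:
    """All-pairs paired DeLong tests, jointly Holm-adjusted.

    Stars follow the usual convention: ** if adjusted p < 0.01, * if
    < 0.05, else ns; the diagonal is ns.
    """
    ids = list(score_sets)
    if len(ids) < 2:
        raise ValueError("at least two score sets are required")
    ref = score_sets[ids[0]]
    binar = {}
    for i in ids:
        ss = score_sets[i]
        if ss.true_classes != ref.true_classes or ss.patient_ids != ref.patient_ids:
            raise ValueError("score sets must share one identical test set")
        binar[i] = binarize_malignant(ss)
    labels = binar[ids[0]][1]
    k = len(ids)
    raw = np.zeros((k, k))
    aucs = {}
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    flat = []
    for i, j in pairs:
        auc_a, auc_b, _, p = delong_paired(binar[ids[i]][0], binar[ids[j]][0], labels)
        aucs[ids[i]] = auc_a
        aucs[ids[j]] = auc_b
        raw[i, j] = raw[j, i] = p
        flat.append(p)
    adj_flat, _ = holm_bonferroni(np.array(flat), alpha=alpha)
    adjusted = np.zeros((k, k))
    stars = [["ns"] * k for _ in range(k)]
    for (i, j), p_adj in zip(pairs, adj_flat):
        adjusted[i, j] = adjusted[j, i] = p_adj
        mark = "**" if p_adj < 0.01 else ("*" if p_adj < alpha else "ns")
        stars[i][j] = stars[j][i] = mark
    np.fill_diagonal(raw, 1.0)
    np.fill_diagonal(adjusted, 1.0)
    return SignificanceMatrix(ids, aucs, raw, adjusted, stars, alpha)
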