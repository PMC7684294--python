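"""Pain/no-pain single-interval classification and the somatovisceral
network-similarity classifier.

The network classifier represents each subject map by its Fisher-z
point-biserial correlations with the seven atlas parcels and fits an
unregularized logistic regression (somatic coded 1) by iteratively
reweighted least squares. Cross-validation is stratified tenfold; the
deployable model is the unweighted mean of the fold coefficient vectors,
applied prospectively to held-out studies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .imgcore import BinaryMask, BrainVolume
from .sigexpr import spatial_similarity

__all__ = [
    "SeparationWarning",
    "LogisticModel",
    "ClassificationReport",
    "BinormalROC",
    "network_features",
    "network_feature_matrix",
    "fit_logistic",
    "NetworkSimilarityClassifier",
    "SingleIntervalClassifier",
    "single_interval_classify",
    "empirical_auroc",
    "binormal_roc",
    "crossval_classifier",
    "stability_assessment",
    "apply_classifier",
    "binomial_test_two_sided",
    "proportion_se",
]


class SeparationWarning(UserWarning):
    """Complete or quasi-separation detected in a logistic fit."""


@dataclass
class LogisticModel:
    """Fitted logistic model over network features (somatic coded 1)."""

    intercept: float
    coef: np.ndarray
    feature_names: list
    se: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    threshold: float = 0.5
    separation: bool = False
    seed: int | None = None
    fold_assignments: np.ndarray | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return expit(self.intercept + X @ np.asarray(self.coef))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) > self.threshold).astype(int)

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("coef", "se", "pvalues", "fold_assignments"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        d = json.loads(text)
        for key in ("coef", "se", "pvalues", "fold_assignments"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key])
        return cls(**d)


@dataclass
class ClassificationReport:
    auroc: float
    auroc_binormal: float
    d_a: float
    sensitivity: float
    specificity: float
    accuracy: float
    accuracy_se: float
    balanced_accuracy: float
    balanced_accuracy_se: float
    cutoff: float
    n_pos: int
    n_neg: int


@dataclass
class BinormalROC:
    """ROC curve from Gaussian models of the two class score
    distributions (no equal-variance assumption)."""

    mu0: float
    mu1: float
    sd0: float
    sd1: float

    @property
    def auc(self) -> float:
        return float(
            stats.norm.cdf((self.mu1 - self.mu0) / np.hypot(self.sd0, self.sd1))
        )

    @property
    def d_a(self) -> float:
        """Discriminability index: AUC = Phi(d_a / sqrt(2))."""
        return float(
            (self.mu1 - self.mu0) / np.sqrt((self.sd0**2 + self.sd1**2) / 2.0)
        )

    def tpr_at(self, fpr) -> np.ndarray:
        """Fitted curve: TPR = Phi(a + b * Phi^-1(FPR))."""
        a = (self.mu1 - self.mu0) / self.sd1
        b = self.sd0 / self.sd1
        return stats.norm.cdf(a + b * stats.norm.ppf(np.asarray(fpr, dtype=float)))


def proportion_se(p: float, n: int) -> float:
    """Standard error of a proportion, sqrt(p(1-p)/n)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return float(np.sqrt(p * (1.0 - p) / n))


def network_features(
    volume: BrainVolume, atlas, mask: BinaryMask | None = None
) -> np.ndarray:
    """Fisher-z point-biserial correlations of one map with each parcel,
    computed over the atlas analysis mask, in fixed atlas order."""
    mask = atlas.mask if mask is None else mask
    z = np.empty(atlas.n_networks)
    for k, parcel in enumerate(atlas.parcels):
        r = spatial_similarity(volume, parcel, mask, kind="point_biserial")
        if abs(r) >= 1 - 1e-12:
            raise ValueError(
                f"parcel {atlas.names[k]!r}: |r| = 1 gives infinite Fisher z"
            )
        z[k] = np.arctanh(r)
    return z


def network_feature_matrix(volumes, atlas, mask: BinaryMask | None = None) -> np.ndarray:
    return np.vstack([network_features(v, atlas, mask) for v in volumes])


def _logistic_irls(X1: np.ndarray, y: np.ndarray, tol: float, max_iter: int):
    """Newton/IRLS for unregularized logistic ML. Returns (beta, se,
    separation flag, n_iter). Separation is flagged when the deviance
    collapses toward 0 while coefficients grow; iterations are then
    capped and the last iterate returned."""
    n, p = X1.shape
    beta = np.zeros(p)
    dev = np.inf
    separation = False
    eps = 1e-10
    for it in range(max_iter):
        eta = X1 @ beta
        mu = np.clip(expit(eta), eps, 1 - eps)
        new_dev = -2.0 * float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu))
        w = mu * (1.0 - mu)
        if new_dev < 1e-6 or (
            np.max(np.abs(beta)) > 30 and dev - new_dev < tol * 100
        ):
            separation = True
            dev = new_dev
            break
        if abs(dev - new_dev) < tol:
            dev = new_dev
            break
        dev = new_dev
        z = eta + (y - mu) / w
        xtw = X1.T * w
        beta = np.linalg.solve(xtw @ X1, xtw @ z)
    else:
        it = max_iter
    eta = X1 @ beta
    mu = np.clip(expit(eta), eps, 1 - eps)
    w = mu * (1.0 - mu)
    try:
        cov = np.linalg.inv((X1.T * w) @ X1)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        separation = True
    return beta, se, separation, it + 1


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names=None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticModel:
    """Unregularized maximum-likelihood logistic regression (IRLS).

    ``labels`` are 0/1 with somatic coded 1. Wald standard errors and
    two-tailed normal p-values accompany the coefficients. Separation is
    surfaced as a :class:`SeparationWarning`, not silently regularized.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > number of features + intercept")
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, se, separation, _ = _logistic_irls(X1, y, tol, max_iter)
    if separation:
        warnings.warn(
            "complete/quasi-separation detected; coefficients are unstable",
            SeparationWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{j + 1}" for j in range(X.shape[1])]
    )
    return LogisticModel(
        intercept=float(beta[0]),
        coef=beta[1:].copy(),
        feature_names=names,
        se=se[1:].copy(),
        pvalues=pvals[1:].copy(),
        separation=separation,
    )


class NetworkSimilarityClassifier(BaseEstimator, ClassifierMixin):
    """Logistic classifier over network-similarity features.

    Parameters
    ----------
    threshold : float
        Decision threshold on the predicted probability of class 1.
    tol, max_iter : IRLS convergence controls.

    Fitted attributes: ``intercept_``, ``coef_``, ``se_``, ``pvalues_``,
    ``separation_``, ``classes_``.
    """

    def __init__(self, threshold: float = 0.5, tol: float = 1e-8, max_iter: int = 100):
        self.threshold = threshold
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("need exactly two classes")
        y01 = (y == self.classes_[1]).astype(float)
        model = fit_logistic(X, y01, tol=self.tol, max_iter=self.max_iter)
        self.intercept_ = model.intercept
        self.coef_ = model.coef
        self.se_ = model.se
        self.pvalues_ = model.pvalues
        self.separation_ = model.separation
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        p1 = self.predict_proba(X)[:, 1]
        return self.classes_[(p1 > self.threshold).astype(int)]


def empirical_auroc(scores, labels) -> float:
    """Area under the empirical ROC curve; equals the Mann-Whitney U
    statistic divided by n1*n0, with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def binormal_roc(scores, labels) -> BinormalROC:
    """Fit class-conditional Gaussians; AUC = Phi((mu1-mu0)/sqrt(s1^2+s0^2))."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 scores per class")
    sd0, sd1 = neg.std(ddof=1), pos.std(ddof=1)
    if sd0 == 0 or sd1 == 0:
        raise ValueError("zero within-class variance: binormal fit degenerate")
    return BinormalROC(
        mu0=float(neg.mean()), mu1=float(pos.mean()), sd0=float(sd0), sd1=float(sd1)
    )


def _best_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Lowest cutoff maximizing overall accuracy of 'score > cutoff ->
    positive', scanning midpoints between adjacent distinct scores plus
    the two outer boundaries."""
    uniq = np.unique(scores)
    cands = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    accs = np.array([np.mean((scores > c) == labels) for c in cands])
    return float(cands[int(np.argmax(accs))])  # argmax -> lowest on ties


def single_interval_classify(scores, labels, cutoff: float | None = None) -> ClassificationReport:
    """Pain/no-pain classification of scores against one fixed cutoff.

    When ``cutoff`` is None it is selected to maximize overall accuracy
    on the given data (the in-sample convention). SEs are binomial
    proportion SEs; the balanced-accuracy SE combines the class-wise
    ones as sqrt(se_sens^2 + se_spec^2)/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if cutoff is None:
        cutoff = _best_cutoff(scores, labels)
    pred = scores > cutoff
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    sens = float(pred[labels].mean())
    spec = float((~pred[~labels]).mean())
    acc = float((pred == labels).mean())
    n = len(labels)
    bacc = (sens + spec) / 2.0
    bacc_se = 0.5 * np.hypot(proportion_se(sens, n_pos), proportion_se(spec, n_neg))
    try:
        roc = binormal_roc(scores, labels)
        auc_bn, d_a = roc.auc, roc.d_a
    except ValueError:  # a class too small/degenerate for a Gaussian fit
        auc_bn, d_a = float("nan"), float("nan")
    return ClassificationReport(
        auroc=empirical_auroc(scores, labels),
        auroc_binormal=auc_bn,
        d_a=d_a,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        accuracy_se=proportion_se(acc, n),
        balanced_accuracy=float(bacc),
        balanced_accuracy_se=float(bacc_se),
        cutoff=float(cutoff),
        n_pos=n_pos,
        n_neg=n_neg,
    )


class SingleIntervalClassifier(BaseEstimator, ClassifierMixin):
    """Threshold classifier on a scalar score (e.g. signature expression).

    ``fit`` selects the accuracy-maximizing cutoff (lowest on ties) and
    stores ``cutoff_`` and an in-sample ``report_``.
    """

    def __init__(self):
        pass

    def fit(self, X, y):
        scores = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("need exactly two classes")
        labels = y == self.classes_[1]
        self.cutoff_ = _best_cutoff(scores, labels)
        self.report_ = single_interval_classify(scores, labels, cutoff=self.cutoff_)
        return self

    def predict(self, X):
        scores = np.asarray(X, dtype=float).reshape(-1)
        return self.classes_[(scores > self.cutoff_).astype(int)]


@dataclass
class CrossValResult:
    probabilities: np.ndarray  # per-subject held-out P(class 1)
    fold_assignments: np.ndarray
    model: LogisticModel  # unweighted mean of fold coefficients
    report: ClassificationReport
    optimal_threshold: float  # accuracy-maximizing threshold on CV probs


def crossval_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    feature_names=None,
) -> CrossValResult:
    """Stratified k-fold cross-validation of the logistic network model.

    Each subject's probability comes from the model not trained on it;
    the deployable model averages the fold coefficient vectors. The
    report is computed from the CV probabilities at the accuracy-
    maximizing probability threshold (also stored; the default decision
    threshold of the averaged model stays 0.5).
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    probs = np.empty(len(y))
    folds = np.empty(len(y), dtype=int)
    coefs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        for f, (tr, te) in enumerate(skf.split(X, y)):
            m = fit_logistic(X[tr], y[tr], feature_names=feature_names)
            probs[te] = m.predict_proba(X[te])
            folds[te] = f
            coefs.append(np.concatenate([[m.intercept], m.coef]))
    mean_coef = np.mean(coefs, axis=0)
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{j + 1}" for j in range(X.shape[1])]
    )
    model = LogisticModel(
        intercept=float(mean_coef[0]),
        coef=mean_coef[1:].copy(),
        feature_names=names,
        seed=seed,
        fold_assignments=folds,
    )
    opt = _best_cutoff(probs, y.astype(bool))
    report = single_interval_classify(probs, y.astype(bool), cutoff=opt)
    return CrossValResult(
        probabilities=probs,
        fold_assignments=folds,
        model=model,
        report=report,
        optimal_threshold=float(opt),
    )


def stability_assessment(
    features: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 1000,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Repeat the whole k-fold procedure ``n_iter`` times with fresh fold
    randomizations; return (SD of CV classification error, mean pairwise
    Pearson correlation of the fold-averaged coefficient vectors)."""
    if n_iter < 2:
        raise ValueError("need n_iter >= 2 to form an SD")
    y = np.asarray(labels, dtype=float)
    errors = np.empty(n_iter)
    params = []
    for i in range(n_iter):
        cv = crossval_classifier(features, labels, k=k, seed=seed + i)
        errors[i] = np.mean((cv.probabilities > 0.5) != y.astype(bool))
        params.append(np.concatenate([[cv.model.intercept], cv.model.coef]))
    corr = np.corrcoef(np.vstack(params))
    off = corr[np.triu_indices(n_iter, k=1)]
    return float(errors.std(ddof=1)), float(off.mean())


def apply_classifier(model: LogisticModel, features: np.ndarray):
    """Apply a trained model prospectively to a held-out study.

    Returns (per-subject 0/1 class, proportion classified somatic, its
    binomial SE)."""
    X = np.asarray(features, dtype=float)
    if X.shape[1] != len(model.coef):
        raise ValueError(
            f"feature contract violated: model has {len(model.coef)} "
            f"features, data has {X.shape[1]}"
        )
    pred = model.predict(X)
    p = float(pred.mean())
    return pred, p, proportion_se(p, len(pred))


def binomial_test_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value, doubled-smaller-tail convention:
    p = min(1, 2 * min(P(X <= k), P(X >= k))) under Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    lo = stats.binom.cdf(k, n, p0)
    hi = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lo, hi)))
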