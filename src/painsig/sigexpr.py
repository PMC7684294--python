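"""Signature-expression scoring and its statistics.

A signature response is the dot product of a vectorized contrast map with
a fixed multivariate weight map, optionally scaled by the two l2 norms to
a cosine similarity (the default, which removes per-study scaling
differences). Per-study statistics treat each contrast-versus-baseline
map as the paired difference itself, so the baseline condition's score is
exactly 0 by construction: the effect size d_a is mean/SD of the scores
and forced-choice accuracy is the fraction of positive scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .imgcore import (
    BinaryMask,
    BrainVolume,
    SignaturePattern,
    joint_valid_mask,
    vectorize,
)

__all__ = [
    "EffectSizeResult",
    "SimilarityTest",
    "RMANOVAResult",
    "signature_response",
    "SignatureScorer",
    "study_signature_stats",
    "hedges_olkin_ci",
    "spatial_similarity",
    "group_similarity_test",
    "compare_signatures_rm_anova",
    "fdr_bh",
]


class DegenerateVarianceError(ValueError):
    """Zero variance where a t statistic is required."""


@dataclass
class EffectSizeResult:
    """One study x one signature: mean response, t test, d_a with CI,
    forced-choice accuracy."""

    mean: float
    se: float
    t: float
    df: int
    p: float
    d_a: float
    ci_low: float
    ci_high: float
    accuracy: float
    n: int


@dataclass
class SimilarityTest:
    """One-sample inference on Fisher-z transformed spatial correlations."""

    mean_r: float
    se_r: float
    t: float
    df: int
    p: float
    d_a: float
    n: int


@dataclass
class RMANOVAResult:
    F: float
    df1: int
    df2: int
    p: float
    pairwise_p: dict  # signature -> Bonferroni-corrected paired-t p vs first


def hedges_olkin_ci(
    d: float, n1: int, n2: int, coverage: float = 0.95
) -> tuple[float, float]:
    """Normal-theory CI for a standardized mean difference.

    Uses the two-independent-group large-sample variance
    var(d) = (n1+n2)/(n1*n2) + d^2 / (2*(n1+n2)) and a normal quantile
    (1.96 for 95% coverage). For one-sample contrast designs both group
    sizes are set to the study N.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    var = (n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2))
    z = stats.norm.ppf(0.5 + coverage / 2.0)
    half = z * np.sqrt(var)
    return float(d - half), float(d + half)


def signature_response(
    volume: BrainVolume,
    pattern: SignaturePattern,
    mask: BinaryMask,
    scaling: str = "cosine",
) -> float:
    """Scalar expression of a signature in one contrast map.

    dot:    sum_v x_v * w_v over the joint valid mask;
    cosine: dot / (||x||_2 * ||w||_2), in [-1, 1].
    """
    if scaling not in ("dot", "cosine"):
        raise ValueError(f"unknown scaling {scaling!r}")
    valid = joint_valid_mask([volume, pattern.volume], mask)
    x = vectorize(volume, valid).values
    w = vectorize(pattern.volume, valid).values
    dot = float(x @ w)
    if scaling == "dot":
        return dot
    nx, nw = float(np.linalg.norm(x)), float(np.linalg.norm(w))
    if nx == 0 or nw == 0:
        raise ValueError("zero-norm input: cosine scaling undefined")
    return dot / (nx * nw)


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping contrast maps to signature-expression scores.

    Parameters
    ----------
    pattern : SignaturePattern
        Fixed, pre-published weight map (or a synthetic stand-in).
    mask : BinaryMask
        Analysis mask; scoring uses the joint valid mask of each map with
        the pattern inside this mask.
    scaling : {'cosine', 'dot'}

    After :meth:`fit` the vectorized pattern restricted to the analysis
    mask is cached in ``weights_``.
    """

    def __init__(self, pattern=None, mask=None, scaling: str = "cosine"):
        self.pattern = pattern
        self.mask = mask
        self.scaling = scaling

    def fit(self, X=None, y=None):
        if self.pattern is None or self.mask is None:
            raise ValueError("pattern and mask are required")
        if self.scaling not in ("dot", "cosine"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if self.pattern.norm_within(self.mask) == 0:
            raise ValueError("pattern has zero norm within the mask")
        self.weights_ = vectorize(self.pattern.volume, self.mask, drop_nonfinite=True)
        self.n_voxels_ = len(self.weights_)
        return self

    def transform(self, X) -> np.ndarray:
        """Score a sequence of BrainVolumes; returns shape (n_maps,)."""
        if not hasattr(self, "weights_"):
            self.fit()
        return np.array(
            [
                signature_response(vol, self.pattern, self.mask, self.scaling)
                for vol in X
            ]
        )


def study_signature_stats(scores) -> EffectSizeResult:
    """One-sample statistics of signature scores for one study.

    Two-tailed one-sample t test against 0; d_a = mean/SD (the baseline
    score of a contrast-vs-baseline design is 0 by construction); CI via
    :func:`hedges_olkin_ci` with n1 = n2 = N; forced-choice accuracy =
    fraction of strictly positive scores (ties at 0 counted incorrect).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 2:
        raise ValueError("need at least 2 scores")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    accuracy = float((scores > 0).mean())
    if sd == 0:
        raise DegenerateVarianceError("zero score variance: t undefined")
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df))
    d_a = mean / sd
    lo, hi = hedges_olkin_ci(d_a, n, n)
    return EffectSizeResult(
        mean=mean, se=float(se), t=float(t), df=df, p=p,
        d_a=float(d_a), ci_low=lo, ci_high=hi, accuracy=accuracy, n=n,
    )


def spatial_similarity(
    volume: BrainVolume,
    reference,
    mask: BinaryMask,
    kind: str = "pearson",
) -> float:
    """Whole-brain spatial correlation between a map and a reference.

    ``kind='pearson'`` for a continuous reference (another BrainVolume);
    ``kind='point_biserial'`` for a BinaryMask reference, i.e. Pearson
    correlation with the 0/1 parcel indicator.
    """
    if kind not in ("pearson", "point_biserial"):
        raise ValueError(f"unknown kind {kind!r}")
    if kind == "point_biserial":
        ref_vol = BrainVolume(
            data=reference.data.astype(float), affine=reference.affine
        )
    else:
        ref_vol = reference
    valid = joint_valid_mask([volume, ref_vol], mask)
    if valid.n_voxels < 3:
        raise ValueError("need at least 3 jointly valid voxels")
    x = vectorize(volume, valid).values
    y = vectorize(ref_vol, valid).values
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def group_similarity_test(similarities) -> SimilarityTest:
    """One-sample t test of per-subject spatial correlations on the
    Fisher-z scale; the reported mean stays on the r scale."""
    r = np.asarray(similarities, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 subjects")
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| = 1 gives infinite Fisher z")
    z = np.arctanh(r)
    sd = z.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("zero variance of Fisher z values")
    n = r.size
    t = z.mean() / (sd / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return SimilarityTest(
        mean_r=float(r.mean()),
        se_r=float(r.std(ddof=1) / np.sqrt(n)),
        t=float(t),
        df=n - 1,
        p=p,
        d_a=float(z.mean() / sd),
        n=n,
    )


def compare_signatures_rm_anova(z_table: np.ndarray, names=None) -> RMANOVAResult:
    """One-way repeated-measures ANOVA across signatures (columns) on the
    Fisher-z scale, plus Bonferroni-corrected paired t tests of each
    signature against the first (reference) column.

    df1 = k-1, df2 = (k-1)(n-1); the error term is the subject-by-
    signature interaction.
    """
    z = np.asarray(z_table, dtype=float)
    if z.ndim != 2 or z.shape[1] < 2:
        raise ValueError("need a complete subjects x signatures matrix (k >= 2)")
    if not np.all(np.isfinite(z)):
        raise ValueError("incomplete design: non-finite cells")
    n, k = z.shape
    names = list(names) if names is not None else [f"sig{j}" for j in range(k)]
    grand = z.mean()
    ss_cond = n * ((z.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((z.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((z - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond, ms_err = ss_cond / df1, ss_err / df2
    if ms_err == 0:
        raise DegenerateVarianceError("zero error variance (0/0 F)")
    F = ms_cond / ms_err
    p = float(stats.f.sf(F, df1, df2))
    pairwise = {}
    n_comp = k - 1
    for j in range(1, k):
        pj = stats.ttest_rel(z[:, 0], z[:, j]).pvalue
        pairwise[names[j]] = float(min(1.0, pj * n_comp))
    return RMANOVAResult(F=float(F), df1=df1, df2=df2, p=p, pairwise_p=pairwise)


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: significance flags and the attained
    p-value threshold (0 when nothing passes)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold
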