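"""Voxel-wise second-level GLM, FDR thresholding, minimum-statistic
conjunction, and inclusively masked difference maps.

The second-level model is an ordinary multiple regression fitted
independently at every voxel of the joint valid mask: subject contrast
maps are the rows, the design holds modality cell-mean columns plus
study nuisance dummies centered within modality (one reference study per
modality dropped to keep the design full rank). Contrasts are linear
combinations of the regressors; inference is two-tailed with
df = n - rank(X).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

from .imgcore import BinaryMask, BrainVolume, devectorize, joint_valid_mask, vectorize
from .sigexpr import fdr_bh

__all__ = [
    "build_design",
    "StatMaps",
    "ThresholdedMap",
    "GroupLevelGLM",
    "fit_group_glm",
    "threshold_map",
    "conjunction",
    "masked_difference",
    "cluster_table",
]


def build_design(metadata: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Design matrix and standard contrasts from cohort metadata.

    Columns: one indicator per modality present (cell means), plus study
    dummies centered within modality with one reference study per
    modality dropped. Standard contrasts (when both modalities present):
    somatic, visceral, common (their average), somatic_minus_visceral,
    visceral_minus_somatic.
    """
    modalities = list(dict.fromkeys(metadata["modality"]))
    cols = {}
    for mod in modalities:
        cols[mod] = (metadata["modality"] == mod).astype(float).to_numpy()
    for mod in modalities:
        studies = list(dict.fromkeys(metadata.loc[metadata["modality"] == mod, "study"]))
        for study in studies[1:]:  # first study per modality is the reference
            dummy = (metadata["study"] == study).astype(float).to_numpy()
            in_mod = cols[mod] == 1
            dummy = dummy.copy()
            dummy[in_mod] -= dummy[in_mod].mean()  # center within modality
            cols[f"study_{study}"] = dummy
    X = pd.DataFrame(cols, index=metadata.index)
    contrasts: dict[str, np.ndarray] = {}
    p = X.shape[1]
    idx = {name: j for j, name in enumerate(X.columns)}
    for mod in modalities:
        c = np.zeros(p)
        c[idx[mod]] = 1.0
        contrasts[mod] = c
    if "somatic" in idx and "visceral" in idx:
        common = np.zeros(p)
        common[idx["somatic"]] = common[idx["visceral"]] = 0.5
        contrasts["common"] = common
        diff = np.zeros(p)
        diff[idx["somatic"]], diff[idx["visceral"]] = 1.0, -1.0
        contrasts["somatic_minus_visceral"] = diff
        contrasts["visceral_minus_somatic"] = -diff
    return X, contrasts


@dataclass
class StatMaps:
    """Per-contrast beta, t, and two-tailed p volumes plus the df."""

    beta: dict
    t: dict
    p: dict
    df: int
    mask: BinaryMask

    def contrast_names(self):
        return list(self.beta)


@dataclass
class ThresholdedMap:
    """Signed significance map: +1 activated, -1 deactivated, 0 n.s."""

    data: np.ndarray
    affine: np.ndarray
    q: float
    p_threshold: float
    contrast: str = ""

    @property
    def n_significant(self) -> int:
        return int((self.data != 0).sum())


class GroupLevelGLM(BaseEstimator):
    """Voxel-wise OLS multiple regression across subjects.

    Parameters
    ----------
    design : pd.DataFrame
        Subjects x regressors; must be full column rank.
    contrasts : dict[str, array]
        Contrast vectors over the design columns.
    mask : BinaryMask
        Base analysis mask; the fit restricts to the joint valid mask.

    Fitted attributes: ``statmaps_`` (:class:`StatMaps`), ``df_``,
    ``rank_``, ``valid_mask_``.
    """

    def __init__(self, design=None, contrasts=None, mask=None):
        self.design = design
        self.contrasts = contrasts
        self.mask = mask

    def fit(self, X, y=None):
        """X is a sequence of BrainVolumes, one per design row."""
        maps = list(X)
        design = self.design
        if len(maps) != len(design):
            raise ValueError("number of maps must match design rows")
        Xmat = np.asarray(design, dtype=float)
        n, p = Xmat.shape
        rank = np.linalg.matrix_rank(Xmat)
        if rank < p:
            cols = list(design.columns) if hasattr(design, "columns") else list(range(p))
            bad = [
                cols[j]
                for j in range(p)
                if np.linalg.matrix_rank(np.delete(Xmat, j, axis=1)) == rank
            ]
            raise ValueError(f"rank-deficient design; offending columns: {bad}")
        valid = joint_valid_mask(maps, self.mask)
        Y = np.vstack([vectorize(m, valid).values for m in maps])  # n x V
        xtx_inv = np.linalg.inv(Xmat.T @ Xmat)
        beta = xtx_inv @ Xmat.T @ Y  # p x V
        resid = Y - Xmat @ beta
        df = n - rank
        if df < 1:
            raise ValueError("no residual degrees of freedom")
        sigma2 = (resid**2).sum(axis=0) / df
        template = vectorize(maps[0], valid)
        bmaps, tmaps, pmaps = {}, {}, {}
        for name, c in self.contrasts.items():
            c = np.asarray(c, dtype=float)
            cb = c @ beta
            var = float(c @ xtx_inv @ c) * sigma2
            with np.errstate(divide="ignore", invalid="ignore"):
                tval = cb / np.sqrt(var)
            pval = 2 * stats.t.sf(np.abs(tval), df)
            aff = valid.affine
            for store, vals in ((bmaps, cb), (tmaps, tval), (pmaps, pval)):
                vec = template.__class__(
                    values=vals, indices=template.indices, shape=template.shape
                )
                store[name] = devectorize(vec, affine=aff)
        self.rank_ = int(rank)
        self.df_ = int(df)
        self.valid_mask_ = valid
        self.statmaps_ = StatMaps(beta=bmaps, t=tmaps, p=pmaps, df=df, mask=valid)
        return self


def fit_group_glm(maps, design, contrasts, mask) -> StatMaps:
    """Functional wrapper over :class:`GroupLevelGLM`."""
    return GroupLevelGLM(design=design, contrasts=contrasts, mask=mask).fit(maps).statmaps_


def threshold_map(statmaps: StatMaps, contrast: str, q: float = 0.05) -> ThresholdedMap:
    """BH-FDR threshold the voxel p-map of one contrast (two-tailed p,
    corrected within the valid mask, per contrast); sign from beta."""
    if contrast not in statmaps.p:
        raise KeyError(f"unknown contrast {contrast!r}")
    pvol = statmaps.p[contrast]
    bvol = statmaps.beta[contrast]
    mask = statmaps.mask
    pvec = vectorize(pvol, mask)
    flags, p_thr = fdr_bh(pvec.values, q=q)
    sign = np.sign(vectorize(bvol, mask).values)
    flat = np.zeros(int(np.prod(pvol.shape)), dtype=np.int8)
    flat[pvec.indices[flags]] = sign[flags].astype(np.int8)
    out = flat.reshape(pvol.shape, order="F")
    return ThresholdedMap(
        data=out, affine=pvol.affine, q=q, p_threshold=p_thr, contrast=contrast
    )


def conjunction(a: ThresholdedMap, b: ThresholdedMap) -> ThresholdedMap:
    """Minimum-statistic conjunction over already-thresholded maps:
    significant only where both are significant with the same sign."""
    if a.data.shape != b.data.shape:
        raise ValueError("grid mismatch between thresholded maps")
    out = np.zeros_like(a.data)
    out[(a.data == 1) & (b.data == 1)] = 1
    out[(a.data == -1) & (b.data == -1)] = -1
    return ThresholdedMap(
        data=out,
        affine=a.affine,
        q=max(a.q, b.q),
        p_threshold=min(a.p_threshold, b.p_threshold),
        contrast=f"conj({a.contrast},{b.contrast})",
    )


def masked_difference(
    difference: ThresholdedMap,
    inclusive: ThresholdedMap,
    direction: str = "activation",
) -> ThresholdedMap:
    """Inclusively mask a thresholded difference map.

    direction='activation': keep difference voxels at +1 where the
    inclusive map shows activation (+1) — "activation stronger for A".
    direction='deactivation': keep difference voxels at -1 where the
    inclusive map shows deactivation (-1) — "deactivation stronger for A"
    (A more negative than B where A deactivates).
    """
    if difference.data.shape != inclusive.data.shape:
        raise ValueError("grid mismatch between thresholded maps")
    out = np.zeros_like(difference.data)
    if direction == "activation":
        keep = (difference.data == 1) & (inclusive.data == 1)
        out[keep] = 1
    elif direction == "deactivation":
        keep = (difference.data == -1) & (inclusive.data == -1)
        out[keep] = -1
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return ThresholdedMap(
        data=out,
        affine=difference.affine,
        q=difference.q,
        p_threshold=difference.p_threshold,
        contrast=f"{difference.contrast}|{direction}:{inclusive.contrast}",
    )


def cluster_table(
    thresholded: ThresholdedMap, statmaps: StatMaps, contrast: str
) -> pd.DataFrame:
    """Connected-component summary (sign, extent, peak |t| voxel)."""
    tvol = statmaps.t[contrast].data
    rows = []
    for sign in (1, -1):
        labeled, n_lab = ndimage.label(thresholded.data == sign)
        for lab in range(1, n_lab + 1):
            sel = labeled == lab
            tvals = np.where(sel, np.nan_to_num(tvol), 0.0)
            peak = np.unravel_index(np.abs(tvals).argmax(), tvals.shape)
            rows.append(
                {
                    "contrast": contrast,
                    "sign": sign,
                    "extent_voxels": int(sel.sum()),
                    "peak_i": peak[0],
                    "peak_j": peak[1],
                    "peak_k": peak[2],
                    "peak_t": float(tvol[peak]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contrast", "sign", "extent_voxels", "peak_i", "peak_j", "peak_k", "peak_t",
        ],
    )
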