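"""Two-stage pipeline orchestration.

Stage 1 applies a pain signature as a single-interval pain/no-pain
classifier of signature-expression scores. Stage 2, only for maps
classified "pain", applies the network-similarity somatovisceral
classifier (trained with cross-validation on designated training
studies, fold-averaged coefficients applied prospectively to the rest).
Optional stages add the voxel-wise group GLM with FDR/conjunction/masked
differences and the robust brain-behavior regression. Every random
stage is seeded from the single pipeline seed, so a run is idempotent
given its config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brainbehav, classify, groupglm, sigexpr, synthdata
from .imgcore import write_volume

__all__ = ["PipelineConfig", "ConfigError", "load_config", "run_pipeline"]


class ConfigError(ValueError):
    """Schema violations, enumerated before any compute."""


@dataclass
class PipelineConfig:
    simulation: synthdata.SimulationConfig
    scaling: str = "cosine"
    q: float = 0.05
    cv_folds: int = 10
    train_studies: tuple = ("rectal1", "thermal2")
    p0_somatic: float = 0.6249
    run_glm: bool = True
    run_behav: bool = True
    seed: int = 0


def _validate(raw: dict) -> list[str]:
    errors = []
    if not isinstance(raw.get("studies"), list) or not raw.get("studies"):
        errors.append("'studies' must be a non-empty list")
    for i, s in enumerate(raw.get("studies") or []):
        for key in ("name", "n_subjects", "modality"):
            if key not in s:
                errors.append(f"studies[{i}]: missing {key!r}")
    if raw.get("scaling", "cosine") not in ("cosine", "dot"):
        errors.append("'scaling' must be 'cosine' or 'dot'")
    q = raw.get("q", 0.05)
    if not (0 < q < 1):
        errors.append("'q' must lie in (0, 1)")
    if raw.get("cv_folds", 10) < 2:
        errors.append("'cv_folds' must be >= 2")
    if "seed" not in raw:
        errors.append("'seed' is required (every random stage must be seeded)")
    return errors


def load_config(path) -> PipelineConfig:
    """Parse and schema-validate a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text())
    errors = _validate(raw)
    if errors:
        raise ConfigError("; ".join(errors))
    sim_kwargs = dict(raw.get("simulation") or {})
    seed = int(raw["seed"])
    studies = [synthdata.StudySpec(**s) for s in raw["studies"]]
    if "grid" in raw:
        sim_kwargs["shape"] = tuple(raw["grid"])
    sim = synthdata.SimulationConfig(studies=studies, seed=seed, **sim_kwargs)
    return PipelineConfig(
        simulation=sim,
        scaling=raw.get("scaling", "cosine"),
        q=float(raw.get("q", 0.05)),
        cv_folds=int(raw.get("cv_folds", 10)),
        train_studies=tuple(raw.get("train_studies", ("rectal1", "thermal2"))),
        p0_somatic=float(raw.get("p0_somatic", 0.6249)),
        run_glm=bool(raw.get("stages", {}).get("glm", True)),
        run_behav=bool(raw.get("stages", {}).get("behav", True)),
        seed=seed,
    )


def write_cohort(cohort: synthdata.Cohort, outdir) -> None:
    """Persist a cohort: per-subject NIfTI maps, metadata CSV, atlas,
    signature, analysis mask, and the config used."""
    outdir = Path(outdir)
    (outdir / "maps").mkdir(parents=True, exist_ok=True)
    for study in cohort.studies:
        for vol in study.maps:
            write_volume(vol, outdir / "maps" / f"{vol.name}.nii.gz")
    cohort.metadata.to_csv(outdir / "metadata.csv", index=False)
    write_volume(cohort.signature.volume, outdir / "signature.nii.gz")
    write_volume(cohort.mask, outdir / "analysis_mask.nii.gz")
    for parcel in cohort.atlas.parcels:
        write_volume(parcel, outdir / f"atlas_{parcel.name}.nii.gz")
    cfg = dataclasses.asdict(cohort.config)
    cfg["studies"] = [dataclasses.asdict(s) for s in cohort.config.studies]
    (outdir / "config.yaml").write_text(yaml.safe_dump(_yamlable(cfg)))


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the pipeline end to end; returns the run report (also written
    as JSON to the output directory alongside tidy CSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    cohort = synthdata.simulate_cohort(config.simulation)
    meta = cohort.metadata.copy()

    # Stage 1: signature expression + pain/no-pain single-interval decision
    scorer = sigexpr.SignatureScorer(
        pattern=cohort.signature, mask=cohort.mask, scaling=config.scaling
    ).fit()
    scores = scorer.transform(cohort.all_maps)
    meta["score"] = scores
    is_pain = meta["is_pain"].to_numpy(dtype=bool)
    if is_pain.all() or not is_pain.any():
        cutoff = 0.0  # no contrast between classes; fall back to sign
        meta["predicted_pain"] = scores > cutoff
        report["stage1"] = {"cutoff": cutoff, "note": "single-class cohort"}
    else:
        s1 = classify.single_interval_classify(scores, is_pain)
        cutoff = s1.cutoff
        meta["predicted_pain"] = scores > cutoff
        report["stage1"] = {
            "cutoff": s1.cutoff,
            "auroc": s1.auroc,
            "auroc_binormal": s1.auroc_binormal,
            "d_a": s1.d_a,
            "sensitivity": s1.sensitivity,
            "specificity": s1.specificity,
            "accuracy": s1.accuracy,
            "accuracy_se": s1.accuracy_se,
        }

    # Per-study effect sizes for the pain studies
    effects = []
    for study in cohort.studies:
        if not study.is_pain:
            continue
        st = sigexpr.study_signature_stats(
            meta.loc[meta["study"] == study.name, "score"].to_numpy()
        )
        effects.append({"study": study.name, "modality": study.modality,
                        **dataclasses.asdict(st)})
    effects_df = pd.DataFrame(effects)
    effects_df.to_csv(outdir / "study_effects.csv", index=False)
    report["study_effects"] = effects

    # Stage 2: somatovisceral classifier on maps classified "pain"
    pain_mask = meta["predicted_pain"].to_numpy(dtype=bool)
    report["stage2_n_input"] = int(pain_mask.sum())
    stage2_meta = meta.loc[pain_mask].reset_index(drop=True)
    name_to_map = {v.name: v for v in cohort.all_maps}
    stage2_maps = [name_to_map[s] for s in stage2_meta["subject"]]
    train_sel = stage2_meta["study"].isin(config.train_studies).to_numpy()
    train_labels = (stage2_meta.loc[train_sel, "modality"] == "somatic").to_numpy(float)
    if train_sel.sum() >= 12 and len(np.unique(train_labels)) == 2:
        feats = classify.network_feature_matrix(stage2_maps, cohort.atlas)
        cv = classify.crossval_classifier(
            feats[train_sel],
            train_labels,
            k=config.cv_folds,
            seed=config.seed,
            feature_names=cohort.atlas.names,
        )
        (outdir / "modality_model.json").write_text(cv.model.to_json())
        report["stage2_cv"] = {
            "auroc": cv.report.auroc,
            "balanced_accuracy": cv.report.balanced_accuracy,
            "d_a": cv.report.d_a,
            "optimal_threshold": cv.optimal_threshold,
        }
        stage2_meta["p_somatic"] = np.nan
        stage2_meta.loc[train_sel, "p_somatic"] = cv.probabilities
        tests = []
        for study in sorted(set(stage2_meta.loc[~train_sel, "study"])):
            sel = (~train_sel) & (stage2_meta["study"] == study).to_numpy()
            pred, p, se = classify.apply_classifier(cv.model, feats[sel])
            stage2_meta.loc[sel, "p_somatic"] = cv.model.predict_proba(feats[sel])
            tests.append(
                {
                    "study": study,
                    "n": int(sel.sum()),
                    "n_somatic": int(pred.sum()),
                    "p_somatic": p,
                    "se": se,
                    "binomial_p": classify.binomial_test_two_sided(
                        int(pred.sum()), int(sel.sum()), config.p0_somatic
                    ),
                }
            )
        pd.DataFrame(tests).to_csv(outdir / "modality_generalization.csv", index=False)
        report["stage2_tests"] = tests
    else:
        report["stage2_cv"] = None  # training studies absent or too small
    stage2_meta.to_csv(outdir / "stage2_subjects.csv", index=False)

    # Optional: voxel-wise group GLM, FDR, conjunction, masked differences
    pain_meta = meta.loc[is_pain]
    if config.run_glm and set(pain_meta["modality"]) == {"somatic", "visceral"}:
        design, contrasts = groupglm.build_design(pain_meta)
        glm_maps = [name_to_map[s] for s in pain_meta["subject"]]
        stat = groupglm.fit_group_glm(glm_maps, design, contrasts, cohort.mask)
        thr = {
            name: groupglm.threshold_map(stat, name, q=config.q)
            for name in ("somatic", "visceral", "somatic_minus_visceral")
        }
        conj = groupglm.conjunction(thr["somatic"], thr["visceral"])
        glm_summary = {
            "df": stat.df,
            "n_sig": {name: t.n_significant for name, t in thr.items()},
            "n_conjunction": conj.n_significant,
        }
        for name, t in list(thr.items()) + [("conjunction", conj)]:
            vol = synthdata.BrainVolume(
                data=t.data.astype(float), affine=t.affine, name=name
            )
            write_volume(vol, outdir / f"thresholded_{name}.nii.gz")
        report["glm"] = glm_summary

    # Optional: robust brain-behavior coupling on rated pain subjects
    rated = meta.loc[is_pain & np.isfinite(meta["rating"])]
    if config.run_behav and len(rated) > len(set(rated["study"])) + 2:
        dummies = pd.get_dummies(rated["study"], drop_first=True).to_numpy(float)
        fit = brainbehav.robust_regress(
            rated["rating"].to_numpy(), rated["score"].to_numpy(),
            covariates=dummies if dummies.shape[1] else None,
        )
        report["behav"] = {
            "beta_robust": fit.coef,
            "se": fit.se,
            "p": fit.p,
            "r_weighted": fit.r_weighted,
            "min_weight": float(fit.weights.min()),
        }
        rated = rated.assign(irls_weight=fit.weights)
        rated[["subject", "study", "score", "rating", "irls_weight"]].to_csv(
            outdir / "brain_behavior.csv", index=False
        )

    meta.to_csv(outdir / "scores.csv", index=False)
    report["stage1_n_pain_predicted"] = int(pain_mask.sum())
    (outdir / "run_report.json").write_text(json.dumps(_yamlable(report), indent=2))
    return report
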