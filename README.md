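# painsig

Multi-study analysis of somatic and visceral pain fMRI contrast maps:
signature-expression scoring, two-stage pain classification, voxel-wise
group GLMs with conjunction analysis, and robust brain–behavior
coupling — all exercised end to end on a synthetic cohort generator
that emulates the statistical structure of multi-site pain datasets.

## Who this is for

Pain-neuroimaging researchers who want a tested, scriptable
re-implementation of the common multivariate analysis stack:

1. **Signature expression** — the scalar response of a fixed
   multivariate weight map *w* (e.g. an NPS-like pattern) in a subject
   contrast map *x*: the dot product `⟨x, w⟩` over the analysis mask,
   optionally cosine-scaled by `‖x‖₂‖w‖₂`. Per-study inference gives a
   one-sample *t* test, the effect size `d_a = mean/SD` with a
   Hedges–Olkin 95% CI

       d_a ± 1.96 · √( (n₁+n₂)/(n₁n₂) + d_a² / (2(n₁+n₂)) ),  n₁ = n₂ = N,

   and forced-choice accuracy (fraction of subjects with positive
   scores).
2. **Pain / no-pain classification** — single-interval classification
   of scores against the accuracy-maximizing cutoff, with empirical
   AUROC (Mann–Whitney), binormal ("Gaussian fit") ROC where
   `AUC = Φ(d_a/√2)` under equal variances, and binomial proportion SEs.
3. **Somatovisceral network classifier** — each map is reduced to its
   Fisher-z point-biserial correlations with seven network parcels;
   an unregularized logistic regression (somatic coded 1) is trained
   with stratified tenfold cross-validation, fold-averaged coefficients
   are applied prospectively to held-out studies, and per-study somatic
   fractions are tested against a reference rate with a two-sided
   (doubled smaller tail) exact binomial test.
4. **Voxel-wise group GLM** — per-voxel multiple regression across
   subjects with modality cell means and study nuisance dummies,
   two-tailed *t* contrasts, Benjamini–Hochberg FDR at *q* = 0.05,
   minimum-statistic conjunction of the thresholded somatic and
   visceral maps, and inclusively masked difference maps.
5. **Brain–behavior coupling** — IRLS robust regression (Tukey
   bisquare, c = 4.685, MAD scale) of pain ratings on signature scores
   controlling for study, plus the IRLS-weighted correlation.

The core estimators follow scikit-learn conventions
(`fit`/`transform`/`predict`, `get_params`, trailing-underscore fitted
attributes): `SignatureScorer`, `SingleIntervalClassifier`,
`NetworkSimilarityClassifier`, `GroupLevelGLM`,
`RobustRatingRegression`. Module-level functions are thin wrappers.

Volumes are NIfTI-1 (via nibabel); metadata are plain CSV; models are
JSON; configs are YAML. All cross-volume operations require identical
grids — no resampling is performed.

## Worked example

```python
import numpy as np
from painsig import synthdata as sd
from painsig.sigexpr import SignatureScorer, study_signature_stats
from painsig.classify import network_feature_matrix, crossval_classifier

cfg = sd.SimulationConfig(
    studies=[
        sd.StudySpec("rectal", 15, "visceral", d_true=1.21),
        sd.StudySpec("thermal", 33, "somatic", d_true=2.11),
    ],
    seed=42,
)
cohort = sd.simulate_cohort(cfg)

scorer = SignatureScorer(pattern=cohort.signature, mask=cohort.mask,
                         scaling="dot").fit()
for study in cohort.studies:
    st = study_signature_stats(scorer.transform(study.maps))
    print(f"{study.name:8s} d_a = {st.d_a:.2f} [{st.ci_low:.2f}, {st.ci_high:.2f}], "
          f"t({st.df}) = {st.t:.2f}, accuracy = {100*st.accuracy:.1f}%")

feats = network_feature_matrix(cohort.all_maps, cohort.atlas)
labels = (cohort.metadata["modality"] == "somatic").to_numpy(float)
cv = crossval_classifier(feats, labels, k=10, seed=42,
                         feature_names=cohort.atlas.names)
print(f"CV AUROC = {cv.report.auroc:.2f}, "
      f"balanced accuracy = {100*cv.report.balanced_accuracy:.0f}%")
```

prints

```
rectal   d_a = 1.28 [0.50, 2.07], t(14) = 4.97, accuracy = 86.7%
thermal  d_a = 2.62 [1.96, 3.27], t(32) = 15.03, accuracy = 100.0%
CV AUROC = 0.92, balanced accuracy = 87%
```

The per-study `d_a` estimates recover the planted effect sizes (1.21
and 2.11) up to sampling error; the CIs come from the Hedges–Olkin
formula above; forced-choice accuracy approaches `Φ(d_a)`. The
cross-validated AUROC of 0.92 reflects the planted network-loading
separation between modalities (somatomotor/attention networks more
active in somatic pain, frontoparietal/default in visceral).

## Command line

```bash
painsig simulate config.yaml --out cohort/       # write a synthetic cohort
painsig run-all  config.yaml --out run/          # full two-stage pipeline
```

`run-all` scores every map, classifies pain vs. no-pain at the
accuracy-maximizing cutoff, sends the maps classified "pain" through
the somatovisceral network classifier, and (optionally) runs the group
GLM/conjunction and robust brain–behavior stages. Outputs are tidy
CSVs, JSON reports/models and NIfTI statistic maps, all regenerable
from the config and seed alone. Exit codes: 0 success, 2 config error,
3 data-contract error.

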