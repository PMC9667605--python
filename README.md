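# radsurv

CT radiomics survival-status modelling for locally advanced non-small cell
lung cancer treated with concurrent chemoradiotherapy — for researchers who
want to study **tumor + whole-lung ("organismal") radiomics** as a long-term
prognostic signal, and who need every stage of that pipeline to be testable
without patient data.

The package implements, end to end:

1. **Imaging preprocessing** — tumor (GTV) and lung ROI masks on a planning
   CT; tight 3D bounding boxes; zero-marking of non-ROI voxels; resampling
   to 1 × 1 × 5 mm; absolute discretization into 400 bins of 10 HU over
   −1000..3000 HU.
2. **A 92-feature pool** (46 per ROI × 2 ROIs): GLCM, GLRLM, NGLDM and
   GLZLM texture families plus shape, conventional and histogram
   first-order indices, every texture feature locked to an independent
   brute-force enumerator by the test suite.
3. **Integrated feature selection and model training** — a genetic
   algorithm over binary feature templates, each template scored by the
   leave-one-out cross-validated balanced accuracy of a linear SVM
   (fold-wise standardization), followed by exhaustive search over the
   regularization C and a final fit. The decision variable is the signed
   distance to the hyperplane, (w·x + b)/‖w‖.
4. **Evaluation** — ROC/AUC by threshold sweep; TPR/TNR/F1/overall and
   average accuracy = (TPR + TNR)/2 with death as the positive class;
   per-feature importance weights IW = AUC(full) − AUC(without feature);
   whole-group ablation (e.g. drop every `LUNG_` feature); 2:1 cohort
   splitting; risk stratification from the predicted status; Kaplan–Meier
   + log-rank survival comparison; Pearson correlation of features against
   pulmonary-function/blood-gas indicators.
5. **Synthetic data** — textured ellipsoidal phantoms in HU and labelled
   feature cohorts with planted informative features, so the whole pipeline
   runs with no external input.

See `docs/methods.md` for the model conventions and their rationale.

## Worked example

Fit the model on a synthetic 60-patient cohort in which four features (two
lung, two tumor) carry a standardized mean shift of 1.5 between survivors
and non-survivors:

```python
import radsurv as rs

names = rs.default_catalog().columns              # the 92 feature names
spec = rs.CohortSpec(
    n=60, seed=11,
    informative={"LUNG_SHAPE_Volume_mL": 1.5, "TUMOR_GLRLM_SRE": 1.5,
                 "LUNG_GLRLM_RP": 1.5, "TUMOR_CONV_SUVstd": 1.5},
)
table, labels, truth = rs.make_feature_cohort(spec, names)

ga = rs.GAConfig(population_size=24, generations=15, stagnation=8, seed=11)
res = rs.GeneticSVM(table, labels, ga_config=ga).fit()
print(res.summary())

records = rs.make_survival(labels, spec)
records["predicted_status"] = res.predict()
report = rs.survival_report(rs.stratify(records), horizon_months=36.0)
print(f"3-year OS  low-risk : {100*report['groups']['low']['survival_at_horizon']:.1f}%")
print(f"3-year OS  high-risk: {100*report['groups']['high']['survival_at_horizon']:.1f}%")
print(f"log-rank p          : {report['logrank_p']:.2e}")
```

Output (summary truncated to the five largest weights):

```
Survival-status SVM (GA-selected features, linear kernel)
============================================================
n patients:            60
n candidate features:  92
n selected features:   38
GA LOOCV fitness:      0.9857
LOOCV (best C):        0.9857
C (exhaustive search): 1
training AUC:          1.0000
------------------------------------------------------------
feature                                       weight
TUMOR_GLRLM_SRE                               0.9681
TUMOR_CONV_HUmean                            -0.5451
LUNG_CONV_HUmean                              0.3617
TUMOR_NGLDM_Contrast                         -0.3312
TUMOR_NGLDM_Busyness                          0.3280
...
3-year OS  low-risk : 75.5%
3-year OS  high-risk: 12.5%
log-rank p          : 7.73e-07
```

The GA's LOOCV fitness (0.9857) is the held-out balanced accuracy of the
selected template; the strongest planted feature tops the weight ranking;
and stratifying patients by the predicted status separates the survival
curves sharply. On real cohorts the same objects work from CSV feature
tables (`GeneticSVM.from_dataframe`) or from NIfTI volumes through
`extract_features`.

A CLI mirrors the stages:

```bash
radsurv simulate --out run/sim --n-patients 24 --seed 5
radsurv extract  --volume ct.nii.gz --tumor-mask gtv.nii.gz \
                 --lung-mask lungs.nii.gz --out run/features
radsurv train    --features run/sim/features.csv --labels run/sim/clinical.csv \
                 --seed 5 --out run/model
radsurv evaluate --features run/sim/features.csv --labels run/sim/clinical.csv \
                 --model run/model/model.json --exclude-group LUNG_ --out run/eval
radsurv stratify --features run/sim/features.csv --clinical run/sim/clinical.csv \
                 --model run/model/model.json --out run/strat
```

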