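# sonomtl

Multi-task classification of breast-ultrasound lesion images with a
**hierarchical consistency loss**, plus everything needed to exercise the
method end to end on synthetic data: a seeded speckle-image generator,
patient-level splitting, training/ablation harness, inconsistency metrics,
Grad-CAM interpretability and a radiomics baseline.

## The problem

From a grayscale ultrasound image of a primary breast mass, two clinical
questions are asked at once:

* **BM** — is the mass benign or malignant?
* **ALNM** — has the tumor metastasized to the axillary lymph nodes
  (and, as graded variants, are there ≥2, ≥3, ≥4 metastatic nodes)?

The labels are hierarchical: a node-positive tumor is necessarily
malignant. A model that predicts "node-positive" and "benign" for the same
image is clinically incoherent. `sonomtl` couples the two tasks through a
shared convolutional feature extractor with independent sigmoid heads
ŷ₁ (malignancy) and ŷ₂ (nodal metastasis), trained with

```
L_all = λ · L_HL + L_BCE,      L_HL = (1/N) Σᵢ max(0, ŷᵢ₂ − ŷᵢ₁ − m)
```

where `L_BCE` is the per-task binary cross-entropy and the hinge `L_HL`
penalizes any sample whose nodal score exceeds its malignancy score by more
than the margin `m` (default 0.1). The hinge produces gradients only when
the hierarchy is violated beyond the margin, so it acts as a targeted
consistency regularizer rather than a generic coupling.

Evaluation reports ACC/SE/SP/Prec/F1/AUC per task at threshold 0.5, with
mean ± SD and 95% bands across five seeded repeats, plus two
**inconsistency-error rates** over paired scores (y₁, y₂):

* type 1 — thresholded contradiction: `y₂ > 0.5` and `y₁ ≤ 0.5`;
* type 2 — margin violation: `y₂ − y₁ > m`.

Because clinical ultrasound archives are private, the package ships a
synthetic cohort generator: hypoechoic spiculated masses on multiplicative
Rayleigh speckle, multiple views per patient, a nested (weaker) nodal
signal carried by a peritumoral halo, and class ratios mirroring a
~2000-patient breast cohort. See `docs/methods.md` for the model of the
generator and every tunable parameter.

## Worked example

```python
from sonomtl.synthgen import SyntheticConfig, generate_dataset
from sonomtl.dataio import SplitAssignment, split_by_patient
from sonomtl.model import BackboneSpec
from sonomtl.losses import LossConfig
from sonomtl.train import TrainConfig, train_arm, evaluate_on_split

records = split_by_patient(generate_dataset(SyntheticConfig(seed=0)),
                           SplitAssignment(seed=0))
model, history = train_arm(records, BackboneSpec(), LossConfig(),
                           TrainConfig(arm="multitask_hl", base_seed=0))
report = evaluate_on_split(model, records)
print("test AUC per task:", {t: round(m["auc"], 3) for t, m in report["tasks"].items()})
print("type-1 inconsistency:", round(report["inconsistency_type1"], 4),
      " type-2:", round(report["inconsistency_type2"], 4))
```

prints (≈40 s on one CPU):

```
test AUC per task: {'bm': 0.913, 'alnm': 0.738}
type-1 inconsistency: 0.0149  type-2: 0.0396
```

That is: on the held-out patients of the default 300-patient synthetic
cohort, the hinge-trained model separates benign from malignant lesions
with AUC 0.91 and detects the (deliberately weaker) nodal signal with AUC
0.74, while only ~1.5% of test images receive contradictory thresholded
predictions. Training the `multitask` arm instead (same seeds, hinge off)
raises the five-repeat mean inconsistency rates about two- to three-fold
(type 1: 1.2% → 3.2%; type 2: 3.2% → 5.5%) at AUCs unchanged within
0.006 — the package's desk-scale reproduction of the consistency effect.

The same pipeline is scriptable from the shell:

```bash
sonomtl init --out run.yaml          # write every default explicitly
sonomtl run --config run.yaml        # 4 arms x repeats + baseline + report
sonomtl synth --n-patients 300 --seed 0 --out data/   # PNG + VOC XML + CSV
sonomtl baseline --data data/ --task bm               # radiomics baseline
```

A run directory contains `config.yaml` (full provenance), `summary.json`
(arms × tasks × metrics with repeat bands and inconsistency rates),
`metrics.csv`, Grad-CAM overlays and radial profiles, and per-repeat
checkpoints.

Bounding boxes use 0-based, half-open pixel coordinates everywhere;
1-based inclusive VOC files can be ingested with `voc_one_based=True`.

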