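# myodetect

Automatic localization of the left-ventricular myocardium on short-axis
cardiac MR slices. Locating the LV region of interest (the myocardial
annulus plus the blood pool it encloses) is the usual first step of cardiac
image analysis pipelines — registration, segmentation, functional
quantification all start from a reliable bounding box — yet it is hard to
automate because blood-pool/endocardium contrast varies slice to slice, the
epicardium blends into surrounding tissue and lung, and apical slices carry
small, ill-defined targets.

`myodetect` is a two-stage detector for this task, aimed at researchers in
medical image analysis who want a transparent, fully inspectable pipeline
rather than an end-to-end black box:

1. **Region proposals** — SLIC-style superpixels whose affinity is a hybrid
   structural similarity
   `S = Spm·Sim·Scm·Ssm·Sdm`
   (phase-congruency, intensity, contrast, structure and coordinate terms,
   each a stabilized ratio in (0,1]), followed by bottom-up merging of the
   most-similar adjacent regions down to K regions, whose tight boxes (and
   adjacent-pair unions) are the candidates.
2. **Classification and refinement** — each candidate crop is encoded by a
   stacked sparse autoencoder (layerwise pretraining under a KL sparsity
   penalty `β Σ_j KL(ρ‖ρ̂_j)`, softmax fine-tuning with balanced batches);
   a within-class neighborhood preserved C-SVC separates myocardium from
   background in a kernel feature space reshaped by
   `S = I + η/(2N)·S_w` (S_w the within-class neighborhood-preserving
   scatter over KPCA coordinates); hard negatives are mined and
   re-injected; NMS removes duplicates; and a multi-output ε-SVR sharing
   the same embedding refines the surviving box via the anchor
   parameterization `z = ((x_g−x_a)/w_a, (y_g−y_a)/h_a, w_g/w_a, h_g/h_a)`.

A phantom generator produces synthetic short-axis slices (body/fat-rim/lung
anatomy, myocardial annulus with bright pool and papillary spots, bias
field, Rician noise, base-to-apex stacks) with exact ground-truth boxes, so
the whole pipeline is trainable and testable without any data download.
See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
from myodetect import make_dataset, MyocardiumDetector, DetectorConfig

# 12 synthetic subjects, 5 slices each (train/val/test split by subject)
dataset = make_dataset(n_subjects=12, slices_per_subject=5, seed=7,
                       variability={"image_size": (128, 160)})

config = DetectorConfig.small()        # 24x24 crops, {576,400,300,200} SSAE
results = MyocardiumDetector(dataset, config).fit(seed=1)
print(results.summary(split="test"))
```

prints

```
          Myocardium Detection Model Results
========================================================
Training samples:           572
  positives / negatives:    131 / 441
Hard negatives mined:       120
Regressor samples:          55
SSAE layers:                (576, 400, 300, 200)
Kernel r / C / eta / t:     auto / 8.0 / 2.0 / 7
SVR epsilon / C:            0.05 / 30.0
Training time (s):          39.7
--------------------------------------------------------
Evaluation on split 'test' (15 slices)
  Tpr (recall):             0.744
  Ppv (precision):          0.944
  F1:                       0.832
  AUC (detection level):    0.731
  Overlap 2|AnB|/|AuB|:     1.000
  Dice (classical):         0.832
  Detection rate IoU>0.5:   0.867
  Mean IoU:                 0.738
========================================================
```

Reading the table: the detector was trained on 572 proposal crops from the
7 training subjects (120 hard negatives re-mined from the full proposal
pool); on the 15 held-out test slices the single reported box per slice
covers 74% of true myocardium-box pixels (Tpr) while 94% of reported
pixels are correct (Ppv), 87% of slices are localized at IoU > 0.5, and
the mean box IoU is 0.74 — respectable for a 12-subject toy run; the
40-subject benchmark below reaches mean IoU ≈ 0.81. The overlap ratio
`2|A∩B|/|A∪B|` is reported as printed alongside the classical Dice; it
saturates at 1 whenever the aggregate IoU exceeds 0.5.

Detecting on a single slice:

```python
s = dataset.slices(split="test")[0]
det = results.detect(s)
print(det.top_box, float(det.probabilities[0]))
```

The command-line interface wraps the same library:

```bash
myodetect phantom -n 10 -k 8 -s 0 -o data/          # synthesize + CSV boxes
myodetect train -d data/ --small -s 0 -o model.pkl
myodetect detect -b model.pkl -i data/subject003_slice04.png -o boxes.csv
myodetect evaluate -b model.pkl -d data/
```

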