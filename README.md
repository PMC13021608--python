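# lesionbai

Lesion-aware brain-age estimation for glioma, and prediction of
glioma-related epilepsy from the resulting Brain Age Index combined with
lesion radiomics.

## The problem

Brain-age models estimate a person's age from structural T1 MRI; the gap
between predicted and chronological age is a compact marker of
accelerated brain aging in disease. Standard models assume intact
anatomy, so they break on brain tumors. This package implements a
lesion-aware framework for glioma:

* a **Brain Age Network (BAN)** — a residual 3D convolutional regressor
  that excludes the tumor and peritumoral edema via binary masks and
  pools the irregular remaining tissue with **ROI-Align**, so age is
  estimated from structurally preserved regions only;
* **bias correction** of the raw predictions on a healthy cohort,

  `corrected = predicted + [Ω − (α·Ω + β)] + MAE`,

  where Ω is chronological age and (α, β) the fitted slope/intercept of
  predicted on Ω — removing the regression-to-the-mean trend while
  preserving lesion-driven deviations;
* the **Brain Age Index**,

  `BAI = (corrected − Ω) / (corrected + Ω)`,

  a normalized deviation in (−1, 1) comparable across ages; and
* a **clinic-radiomic fusion model** of glioma-related epilepsy: LASSO
  selection of lesion radiomics, two LightGBM classifiers (radiomic and
  clinical blocks, the latter including the BAI) tuned by seeded random
  search, stacked through logistic regression on out-of-fold
  probabilities.

Because clinical imaging cannot be redistributed, the package ships a
**phantom generator** producing 3D cohorts with known ground truth: an
age-encoding structural signal, lesions with edema shells, a planted
"accelerated aging" perturbation (larger in non-epileptic than epileptic
glioma phantoms), and epilepsy labels from a known logistic model. Every
stage of the framework is testable end-to-end against that ground truth.

It is intended for methods researchers in neuro-oncological imaging who
want a transparent, fully seeded reference implementation of this
pipeline, usable from Python or a thin `lesionbai` CLI.

## Worked example

```python
import numpy as np
from lesionbai.phantom import PhantomConfig, generate_cohort
from lesionbai.ban import BanConfig, build_network, split_dataset, train, predict_age
from lesionbai.bai import fit_bias_correction, predictions_table

cohort = generate_cohort(PhantomConfig(n_subjects=80, glioma_fraction=0.0, seed=7))
ages = cohort.subjects["age"].to_numpy()
cohort.subjects["age_bin"] = (cohort.subjects["age"] // 10).astype(int).astype(str)
tr, va, te = split_dataset(cohort.subjects, stratify_on=["age_bin"], seed=0)

cfg = BanConfig(conv_channels=(4, 8), blocks_per_stage=(1, 1),
                max_epochs=15, batch_size=16, learning_rate=0.01, seed=0)
trained = train(build_network(cfg), cohort.volumes, cohort.masks, ages, (tr, va), cfg)

preds = np.array([predict_age(trained, cohort.volumes[i], cohort.masks[i]) for i in te])
print(np.mean(np.abs(preds - ages[te])))
```

This trains in about two minutes on one CPU and prints a held-out mean
absolute error of

```
1.75
```

years — far below the ~12.9-year error of always predicting the training
mean age, i.e. the network has learned the phantoms' age signal. The
`examples/` directory has one short script per capability (cohort
simulation, brain-age training, bias correction and BAI, feature
selection, fusion prediction), each printing the numbers it computes with
a note on what they mean. Example output of the bias-correction script:

```
fitted slope alpha=0.691, intercept beta=18.37, MAE term=4.72 years
age-dependence of the gap: raw -0.309 -> corrected 0.000 per year (removed)
```

The full pipeline (simulate → train → BAI → group statistics → feature
selection → fusion) runs as one seeded, manifest-tracked command:

```bash
lesionbai run --out run/ --seed 0
```

## Layout

```
src/lesionbai/
  phantom.py    synthetic cohorts and feature tables with known truth
  imaging.py    NIfTI I/O, normalization, resampling, Dice, ICC(2,1)
  ban.py        the Brain Age Network and its training protocol
  _nn.py        numpy conv-net machinery (hand-derived backprop)
  bai.py        bias correction, Brain Age Index, group statistics
  features.py   lesion radiomics and the selection chain
  fusion.py     random search, OOF stacking, classifier evaluation
  pipeline.py   end-to-end orchestration with run manifests
  cli.py        thin typer CLI over the library
```
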