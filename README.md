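# ldq — lumbar Dixon quantification

Automated quantification of intramuscular fat (IMF) in the lumbar-spine
muscles from Dixon MRI, for researchers studying muscle health,
sarcopenia and spinal degeneration who need per-muscle fat fraction
without weeks of manual 3D segmentation.

A Dixon acquisition yields co-registered water (W) and fat (F) images
with the in-phase image IP = W + F. The voxel-wise proton-density fat
fraction is

    FF = F / (W + F)

and a muscle's IMF is the mean FF over its 3D mask. `ldq` provides the
whole chain around that measurement for the four bilateral lumbar muscle
groups — psoas (P), iliacus (I), quadratus lumborum (QL), erector spinae
+ multifidus (ES+M):

- **phantom** — synthetic Dixon cohorts with known per-muscle FF, smooth
  inter-subject deformations and covariate-linked FF (age, sex, BMI,
  activity), standing in for clinical data that cannot be redistributed;
- **preprocess** — rigid registration to a reference and in-plane
  downsampling by 2 (block average / nearest-neighbour labels);
- **augment** — flip + small-rotation variants and early-stopped pairwise
  B-spline registration that synthesises "virtual anatomies" (10·n linear
  + n(n−1) nonlinear training images from n subjects);
- **unet** — a 3D U-Net segmentation engine written in numpy (shifted-GEMM
  convolutions, instance norm, sigmoid + binary cross-entropy, Adam,
  early stopping), exposed as the scikit-learn style `UNetSegmenter`;
- **multiatlas** — the classical baseline: affine + B-spline registration
  of every atlas, NCC ranking, top-5 majority-vote fusion, soft-tissue
  masking and hole filling (`MultiAtlasSegmenter`);
- **fat_fraction** — FF maps with validity masks, per-muscle means with
  axial crops, unweighted left/right bilateral averaging;
- **eval_stats** — Dice / relative volume difference / Hausdorff distance
  (oracle-checked), Monte-Carlo cross-validation planning, Bland–Altman
  agreement, Kruskal–Wallis, Type III ANCOVA with partial η², and
  median (IQR) normative reference tables;
- **pipeline** — end-to-end orchestration with one global seed, plus a
  thin `ldq` command-line interface.

See `docs/methods.md` for the model, parameter and design documentation.

## Worked example

Generate a small synthetic cohort, train the desk-scale U-Net, and
measure fat fraction on a held-out subject:

```python
from ldq import CohortSpec, UNetSegmenter, generate_cohort
from ldq.fat_fraction import measure_subject, records_to_frame

pairs, table = generate_cohort(CohortSpec(n_subjects=10, seed=0))
train, held_out = pairs[:9], pairs[9]

seg = UNetSegmenter(seed=0, max_epochs=30)
seg.fit([v for v, _ in train], [m for _, m in train])

vol, truth = held_out
pred = seg.predict(vol)
df = records_to_frame(measure_subject(vol, pred, allow_missing=True))
print(df[df.side == "LR"][["muscle", "side", "mean_ff_pct"]])
```

```
   muscle side  mean_ff_pct
2       P   LR    18.290927
5       I   LR     7.194893
8      QL   LR    20.589974
11    ESM   LR    17.637133
```

Each row is the bilateral (left/right averaged) mean fat fraction of one
muscle in percent, measured inside the U-Net's predicted masks. The
generative values for this held-out subject were P 18.4%, I 7.1%,
QL 20.5%, ES+M 17.7% — the predicted-mask measurements land within about
a tenth of a percentage point, the agreement regime the pipeline is
built for.

The same flow runs from the shell:

```sh
ldq demo --out demo_run --seed 0      # phantom cohort -> both engines -> CSVs
ldq cohort --out cohort_dir --n 20    # covariate/FF ground-truth table
```

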