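# magseg — multi-atlas graph-convolutional segmentation of volumetric MRI

`magseg` labels an unlabeled 3D volume (the *target*) by fusing information
from a library of registered, expert-labeled reference volumes (*atlases*).
It was built for knee-joint MRI, where the clinically interesting
structures — femoral and tibial cartilage — are thin sheets a few voxels
thick whose segmentation both matters and fails most often, and it treats
the task as five-class voxel classification: background, femoral bone,
femoral cartilage, tibial bone, tibial cartilage.

## Method in brief

Nodes are 5×5×5 patches described by 20-bin 3D histograms of oriented
gradients, x = f_enc(p) ∈ R²⁰. Root nodes sampled in the target's region of
interest are replicated at the same coordinate across the target and the
nA selected atlases, forming aligned sequences S(i) = {x_T(i); x_A1(i), …,
x_AnA(i)} (Nr = nT·(nA+1) roots in total); each sequence is expanded into
multi-scale *sequence libraries* SL_s(i) of stride-2 neighborhoods whose
member patches tile 9³ and 13³ volumes. Two convolutional units operate on
this graph:

* **Lconv** — multi-head, multi-scale attention within sequence libraries:
  α_ij = softmax_j LeakyReLU(a·[Wh_i ‖ Wh_j]), aggregated per scale and
  concatenated over heads and scales. Attention never crosses sequences.
* **Gconv** — a global convolution over root nodes of different sequences
  with a *learned* adjacency Ã = σ(H̃Wφ (H̃Wφ)ᵀ) (masked, sparsified at a
  threshold τ, plus identity), applied as H = σ(D̃^-1/2 Ã D̃^-1/2 S Wg).
  A GraphSAGE max-pool aggregator is an alternative backend.

Four units form a building block (cross-talk or sequential wiring), and M
blocks form a densely connected network in which block i receives the
concatenation of the initial d-dimensional embedding and all previous block
outputs (input widths d, 2d, …, Md). A two-layer MLP head yields per-node
class probabilities; training minimizes cross-entropy over labeled (atlas)
nodes. Segmentation is transductive and three-staged: (1) train on the
graph of an initial target batch and label it, (2) sweep the remaining
candidate roots in warm-started, refreshed batches, (3) label every
remaining ROI voxel by a spectral×spatial-weighted vote over the
surrounding labeled vertices. The per-class report covers DSC, VOE, VD,
precision and recall, with VOE = 100·(1 − DSC/(200 − DSC)).

The graph network runs on a small reverse-mode automatic-differentiation
engine over numpy arrays that ships with the package (`magseg.autodiff`) —
no deep-learning framework is required.

## Worked example

Everything below runs from scratch in a couple of minutes; no external data
are needed — the package generates a synthetic 5-class phantom (two "bone"
ellipsoids with thin "cartilage" sheets on their facing surfaces) and
perturbed atlas copies standing in for imperfectly registered atlases.

```python
import numpy as np
from magseg import (PhantomSpec, generate_phantom, generate_atlas_set,
                    MultiAtlasSegmenter, evaluate_segmentation)

spec = PhantomSpec(seed=1, misalignment_sd=1.0)   # 64^3, 5 classes
target_vol, target_lab = generate_phantom(spec)
atlases = generate_atlas_set((target_vol, target_lab), 5, spec)

seg = MultiAtlasSegmenter(n_atlases=5, n_blocks=1, d=32, n_heads=4,
                          scales=1, n_candidates=768, batch_size=128,
                          max_epochs=90, refresh_epochs=2, seed=1)
pred = seg.fit(atlases).predict(target_vol)
report = evaluate_segmentation(pred, target_lab, roi=seg.library_.roi)
print(report.as_table())
```

```
class                  DSC     VOE       VD    prec     rec
femoral_bone         88.91   19.96    17.56   82.27   96.72
femoral_cartilage    83.65   28.11    -6.82   86.71   80.80
tibial_bone          96.06    7.57    -4.42   98.29   93.94
tibial_cartilage     82.75   29.42   -20.21   93.23   74.39
```

DSC is the Dice overlap in percent (100 = perfect), VOE the corresponding
volume overlap error, VD the signed relative volume difference (negative =
undersegmentation), all computed one-vs-rest inside the cartilage ROI. Both
cartilage sheets — the hard part of the task — are recovered above 80 DSC
despite the 1-voxel simulated registration error.

The same pipeline is scriptable from the shell:

```bash
magseg phantom --out-dir ph --n-atlases 5 --seed 1
magseg segment ph/target.nii.gz ph --out seg.nii.gz --n-atlases 5 \
    --n-blocks 1 --d 32 --n-heads 4 --scales 1 --n-candidates 768 \
    --max-epochs 90 --refresh-epochs 2
magseg evaluate seg.nii.gz ph/target_labels.nii.gz
```

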