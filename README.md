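# fhpose

Forward head posture (FHP) — the head jutting anterior to the shoulder line —
is a common consequence of prolonged sedentary device use and a risk factor
for chronic neck pain. Clinically it is assessed via the craniovertebral
angle, which needs landmarks (C7, tragus) that generic vision-based pose
estimators do not produce. `fhpose` implements an accessible alternative for
researchers in movement biomechanics and digital health: classify FHP
directly from the 17-joint 3D keypoints (Human3.6M convention) that standard
2D→3D lifting tools emit, using a skeleton-graph convolutional network.

The pipeline:

1. **Normalization** — each pose is pelvis-centred, rotated about the
   vertical axis so the pelvis→left-hip vector points along +y, and scaled so
   max |coordinate| = 1. Only yaw is removed; postural pitch (the FHP signal)
   is preserved. Classification is thereby invariant to viewing direction,
   camera distance and translation.
2. **Upper-body graph** — 13 of the 17 joints (lower body is occluded when
   seated) form a skeleton graph; the pelvis connects to both hips and the
   spine, giving adjacency row 0 = `[0 1 1 1 0 0 0 0 0 0 0 0 0]`.
3. **Classifier** — a graph convolutional network (GCN): two graph
   convolutions over the symmetric renormalized adjacency with self-loops,
   Â = D^(−1/2)(A+I)D^(−1/2), with dropout after each, flattened into a
   64-unit dense layer and a softmax head. Per layer:
   H′ = ReLU(Â H W + b). A feedforward network (39 → 128 → 64 → 2) serves as
   the baseline.
4. **Protocol** — stratified 70/15/15 train/validation/test split, Adam on
   categorical cross-entropy, batch 16, dropout rate selected by grid search
   on validation accuracy. Reported metrics: per-class precision/recall/F1
   (harmonic mean), overall accuracy, macro F1 (unweighted mean of per-class
   F1).
5. **Latent analysis** — t-SNE of the 64-dimensional penultimate activations
   and the anisotropy ratio λ2/λ1 of their covariance eigenvalues (≈1:
   isotropic feature cloud; ≈0: stretched along one principal direction).

Because no labeled keypoint dataset is released with this package, a
**synthetic generator** articulates sedentary upper-body poses with
class-conditional head pitch and shoulder protraction, labels them by the
tragus/acromion proxy (head keypoint anterior to the shoulder midpoint by
more than a margin), and adds global yaw plus keypoint noise. See
`docs/methods.md` for the model and generator details.

## Worked example

```python
import fhpose as f

ds = f.generate_dataset(f.GeneratorConfig(n_samples=400, seed=0))
tr, va, te = f.split_dataset(ds, seed=0)
Xtr = f.poses_to_model_inputs(tr.poses, "gcn")
Xva = f.poses_to_model_inputs(va.poses, "gcn")
Xte = f.poses_to_model_inputs(te.poses, "gcn")

model = f.GCNClassifier(f.build_upper_body_graph().adjacency,
                        f.GCNConfig(dropout_rate=0.2), seed=0)
_, hist = f.train_model(model, (Xtr, tr.labels), (Xva, va.labels),
                        f.TrainConfig(seed=0, max_epochs=100))
print(f.evaluate(model, Xte, te.labels).to_text())
lat = f.latent_report(model, Xte, te.labels, perplexity=15, seed=0)
print(f"anisotropy ratio: {lat.anisotropy_ratio:.4f}")
```

prints

```
Precision (class 0)   97.50
Recall (class 0)      100.00
F1-score (class 0)    98.73
Precision (class 1)   100.00
Recall (class 1)      95.24
F1-score (class 1)    97.56
Overall accuracy      98.33
F1-score (macro)      98.15
anisotropy ratio: 0.0278
```

Class 0 is Normal, class 1 is FHP; metrics are percentages on the held-out
test split (60 of 400 samples). Accuracy here is higher than one should
expect on image-derived data: the synthetic classes are separable by
construction up to the injected noise, so this demonstrates the pipeline
recovers the generator's ground-truth mechanism, not real-world performance.
The anisotropy ratio near 0 says the learned feature cloud is strongly
stretched along one direction — unsurprising when one latent feature
(anterior head offset) suffices to separate the synthetic classes.

The same pipeline is available from the shell:

```bash
fhpose --seed 0 simulate --n 400 --out data/ds
fhpose --seed 0 train --data data/ds.npz --model gcn --out runs/gcn.npz
fhpose evaluate --checkpoint runs/gcn.npz --data data/ds.npz
fhpose inspect-graph
```

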