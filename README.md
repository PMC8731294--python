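# spinereg

Deformable registration and segmentation for spine MRI, built around three
components and a synthetic-phantom test bed:

* **Cubic B-spline free-form deformation (FFD) registration.** A transform
  `G_mu` parameterized by a lattice of control-point displacements `phi`,
  interpolated by the uniform cubic B-spline basis

  ```
  R0(n) = (1-n)^3/6          R1(n) = (3n^3 - 6n^2 + 4)/6
  R2(n) = (-3n^3+3n^2+3n+1)/6    R3(n) = n^3/6
  ```

  is fitted by minimizing the composite cost

  ```
  C(mu) = alpha1 * ( -MI(A, B∘G_mu) ) + alpha2 * V(mu)
  ```

  where `MI(A,B) = K(A) + K(B) - K(A,B)` is the mutual information from the
  joint intensity histogram (equivalently the double sum
  `sum p(a,b) log p(a,b)/(p(a)p(b))`, computed both ways and cross-checked),
  and `V` is the bending (distortion) energy — the mean over image points of
  the summed squared second derivatives of the displacement field. The
  optimizer is a deterministic multiresolution greedy coordinate descent
  with a global-translation phase and adaptive step halving.

* **A U-net segmenter trained with a soft-Dice objective.** A small
  encoder–decoder CNN (two 3×3 conv + ReLU per level, 2×2 max-pooling,
  nearest-upsampling with skip concatenation, softmax output energy
  `h_a(z) = exp(s_a(z)) / sum_a' exp(s_a'(z))`), implemented directly in
  numpy with manual backpropagation and Adam, sized for desk-scale training
  on 64×64 slices.

* **Evaluation metrics.** Dice `2|Q∩W|/(|Q|+|W|)`, voxelwise Jaccard
  `|Q∩W|/|Q∪W|` (related by `D = 2J/(1+J)`, verified exactly), mean target
  registration error `mTRE = (1/l) sum ||G(x_i) - x'_i||`, and a normalized
  ROI noise measure.

Because no public gold-standard spine dataset accompanies the method, the
package ships a phantom generator: stacks of bright vertebral bodies
separated by disc bands plus a vessel tube, with exact label masks,
centroid landmarks, controllable Gaussian noise, and ground-truth
deformations drawn from the package's own FFD model — so registration and
segmentation accuracy can be scored against known truth.

## Worked example

```python
import spinereg as sr

cfg = sr.PhantomConfig(seed=0)                    # 64x64, five vertebrae
volume, mask, landmarks = sr.generate_phantom(cfg)
truth = sr.random_deformation(cfg, max_displacement=3.0)
reference = truth.warp_image(volume)              # a "second acquisition"

est = sr.BSplineRegistration().fit(reference, volume)
paired = sr.LandmarkSet(landmarks.points,
                        truth.transform_points(landmarks.points))
print("mTRE before:", sr.mean_tre(None, paired))
print("mTRE after: ", sr.mean_tre(est.transform_, paired))
print("vertebra Dice before:",
      sr.dice(truth.warp_mask(mask).labels > 0, mask.labels > 0))
print("vertebra Dice after: ",
      sr.dice(truth.warp_mask(mask).labels > 0,
              est.transform_.warp_mask(mask).labels > 0))
```

prints (seed 0):

```
mTRE before: 1.462153357139768
mTRE after:  0.36141946082318094
vertebra Dice before: 0.9058536585365854
vertebra Dice after:  0.9876243630186848
```

i.e. registration cuts the landmark error from ~1.5 mm to ~0.36 mm and
raises the warped-mask overlap from 0.91 to 0.99. Training the segmenter:

```python
data = sr.segmentation_dataset(50, sr.PhantomConfig(seed=1))
model = sr.train(data, sr.SegNetConfig(seed=0))
pred = sr.segment(model, volume)                  # LabelMask, 0/1
```

reaches held-out vertebra Dice ≈ 0.98 on phantoms from the same generator.

The same operations are available from the shell:

```bash
spinereg simulate --out-dir phantom/ --max-displacement 3
spinereg register --reference phantom/warped.nii.gz \
    --floating phantom/volume.nii.gz --out-transform T.yaml \
    --out-warped warped_back.nii.gz --log trace.tsv
spinereg evaluate --ref-mask phantom/warped_mask.nii.gz \
    --test-mask phantom/mask.nii.gz --label 1 --transform T.yaml \
    --landmarks phantom/landmarks.txt --out report.json
spinereg segment-train --out model.npz
spinereg segment --model model.npz --in phantom/volume.nii.gz --out seg.nii.gz
```

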