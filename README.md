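# ellipstack

Semiautomatic organ delineation by **stacked best-fitting ellipses** with a
statistical shape prior — built for radiotherapy treatment planning of the
prostate, where a physician otherwise delineates the target volume slice by
slice on axial MR images.

## The method

The organ outline in axial slice *l* is modeled by an ellipse
ρ<sup>l</sup> = (θ<sup>l</sup>, α<sup>l</sup>, φ<sup>l</sup>): in-plane
center, semi-axis lengths and rotation angle. For a delineated case the
**best-fitting ellipse (BFE)** of each slice minimizes the geometric error

g(ρ) = Σ<sub>k</sub> ‖x<sub>k</sub> − c<sub>k</sub>(ρ)‖²,

the summed squared *orthogonal* distances of the contour points
x<sub>k</sub> to their nearest boundary points c<sub>k</sub>(ρ). After axis
reordering, circularity relaxation and rotation smoothing establish
parameter correspondence across slices, each training case is mapped by a
control-point-derived similarity transform Λ into a common sample space and
interpolated to L canonical slices. Per slice the model stores Gaussian
statistics of the center offsets η = θ − ξ from the control-point center
curve ξ, of a = log α (so α is log-normal and positive by construction) and
of φ, with unbiased 1/(N−1) variances — the **mean best-fitting ellipses
(MBFE)** and their spread.

For a new patient the user clicks 18 control points (6 on each of the
organ's first, center and last slice). These determine Λ and ξ, and the
deformed MBFE θ<sup>l</sup> = ξ<sup>l</sup> + μ<sub>η</sub><sup>l</sup>,
α<sup>l</sup> = exp(μ<sub>a</sub><sup>l</sup>),
φ<sup>l</sup> = μ<sub>φ</sub><sup>l</sup> is mapped back to the patient
frame — a deterministic initial delineation computed in well under a
second. Optionally an empirical-Bayes posterior

π(ρ | S, CP) ∝ L(S | ρ) · π(ρ | CP)

refines the template against the image gray levels S by blocked
random-walk Metropolis, with the two-population gray model (inside vs
outside the delineation) estimated from the image itself.

Delineations are scored slice-wise by the Hausdorff distance (with the
clinically motivated 3 mm exceedance count), and volumetrically by Dice
overlap 2|X∩Y|/(|X|+|Y|) and accuracy 1 − (|FP|+|FN|)/(|TP|+|FN|); cohorts
are summarized by median and (unscaled) median absolute deviation.

Because clinical contours are not distributable, the package ships a
phantom generator emulating the target acquisition (0.559 mm in-plane
spacing, 288×288 grid, 3.3 mm slice distance, 6–15 contour slices per
case, two-population gray levels) so every stage is testable end to end.

## Worked example

```python
import numpy as np
from ellipstack.phantom import PhantomSpec, generate_population, split_population
from ellipstack.model import StackedEllipseModel
from ellipstack.experiments import evaluate_case

spec = PhantomSpec(n_cases=12, seed=7, bumpy=True)
cases = generate_population(spec)
train_cases, test_cases = split_population(cases, n_train=9)

model = StackedEllipseModel.from_contours(
    [c.contours for c in train_cases],
    control_points=[c.cp for c in train_cases],
    L=11,
)
results = model.fit()
print(results.summary())

case = test_cases[0]
delineation = results.deform(case.cp, case.slice_z)
print(evaluate_case(case, delineation))
```

The summary prints one row per canonical slice (excerpt):

```
Stacked-ellipse shape model
  canonical slices L = 11, training cases N = 9, position mode = eta
  alpha columns are geometric means exp(mu_a) [sample-space units];
  eta are center offsets from the control-point center curve.

      t  mu_eta1  mu_eta2  sd_eta1  sd_eta2  alpha1  alpha2  sd_log_a1  sd_log_a2  mu_phi  sd_phi
 0.0000   0.0049   0.0056   0.0218   0.0302  0.5039  0.4054     0.1163     0.0844  0.0462  0.1876
 0.5000   0.0081  -0.0044   0.0162   0.0270  1.0962  0.8827     0.0295     0.0710  0.0312  0.1752
 1.0000  -0.0017   0.0092   0.0299   0.0144  0.5025  0.4047     0.1184     0.0871  0.0501  0.1961
```

`t` is the normalized slice position; lengths are in sample-space units
(the center-slice control-point radius is 1), so the mid-gland geometric
mean axes ≈ 1.10/0.88 and the tapered ends ≈ 0.50/0.41 describe the
relative organ profile; the small `sd_eta` values say the centers stay
within a few percent of the center curve. Scoring the deformed mean shape
against the held-out case's ground truth prints

```
dice_3d: 0.952   accuracy: 0.904   hd_mean: 1.978 mm   n_hd_gt_3mm: 0 / 9
```

i.e. 95% volume overlap and a mean slice-wise Hausdorff distance under
2 mm from 18 control points alone — a starting contour the physician only
has to touch up. `results.predict(cp, volume=vol, refine=True)` runs the
MCMC refinement on top.

The same pipeline is available from the shell:

```sh
ellipstack --seed 7 simulate --out pop --cases 12 --bumpy
ellipstack train --data pop --out model.json --slices 11
ellipstack deform --model model.json --cp pop/case_009/cp.json \
    --slices pop/case_009/geometry.json --out delineation.json
ellipstack evaluate --ref pop/case_009/truth_contours.json \
    --test delineation.json --volume-grid pop/case_009/geometry.json \
    --out report.csv
```

## Documentation

`docs/methods.md` describes the model assumptions, the numerical choices
(projection solver, fit initialization, angle unwrapping, sampler
adaptation), what the phantom generator does and does not emulate, and
known limitations.
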