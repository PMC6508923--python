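# thighseg

Automatic segmentation and quantification of dual-contrast thigh MRI.

Thigh muscle volume and fat infiltration are key outcomes in conditions
such as spinal cord injury, where muscle atrophies and adipose tissue
infiltrates the limb.  Given a co-registered pair of 3-D volumes per
subject — one fat-suppressed (FS: muscle bright, fat dark) and one
water-suppressed (WS: reversed) — `thighseg`:

1. **extracts tissues** with a Linear Combination of Discrete Gaussians
   (LCDG) intensity model: the FS+WS sum yields the whole-thigh and bone
   masks, FS yields total muscle, WS yields fat, and overlaying the muscle
   envelope splits fat into subcutaneous (SAT) and intermuscular (IMAT)
   adipose tissue;
2. **partitions the muscle** into knee extensors, knee flexors and the
   medial compartment with a joint Markov–Gibbs random field that fuses an
   atlas-based shape prior, a second-order Potts spatial model and a
   first-order (per-compartment LCDG) intensity model, optimized by
   iterated conditional modes (ICM);
3. **quantifies and evaluates**: compartment volumes in mL, Dice,
   precision, recall and Hausdorff distance (mm) against reference maps.

The core models, in standard notation:

- **LCDG**: the gray-level density over Q = 256 levels is
  `p(q) = Σ_dom w_i ψ(q|θ_i) + Σ_add w_j ψ(q|θ_j) − Σ_sub w_k ψ(q|θ_k)`,
  with ψ a discrete Gaussian; the two dominant components define the
  dark/light classes and the Bayes cut between their conditional densities
  gives the binarization threshold.
- **FFD registration**: `T(x) = x + Σ_ζ B(‖x − ζ‖) Δζ`, cubic B-spline
  weights over a sparse control grid, minimizing the sum of absolute
  differences by discrete ICM over control-point displacements.
- **Shape prior**: `P_sp(m) = Π_x p_sp:x(m_x)`, voxel-wise empirical label
  probabilities from gated (slice-wise correlation ≥ 0.5), registered
  atlases.
- **Potts MGRF**: pairwise potentials on the 26-neighborhood,
  `v_eq = −v_ne ≈ 2 f_eq(m) − 1`, giving voxel-wise spatial label
  conditionals.
- **Fusion**: `P(g, m) = P(g|m) · P_sp(m) · P_V(m)`, maximized per voxel in
  raster order.

A synthetic dual-contrast phantom (concentric SAT ring / muscle annulus
with IMAT streaks / cortical bone / marrow, three angular compartments,
known ground truth) makes every stage testable without any data download.

## Worked example

```python
import thighseg as ts
from thighseg.phantom import PhantomSpec, make_phantom
from thighseg.metrics import confusion, dice_precision_recall, volume_ml

case = make_phantom(PhantomSpec(noise_sigma=0.05, seed=1))   # FS/WS pair + truth
masks = ts.segment_tissues(case.fs, case.ws)                 # step-1 tissue masks

for name in ("thigh", "muscle", "sat", "imat"):
    pred = getattr(masks, name)
    truth = getattr(case.truth_tissues, name)
    dc, _, _ = dice_precision_recall(confusion(pred, truth))
    mm3, ml = volume_ml(pred)
    print(f"{name:6s}  Dice {dc:.4f}  volume {ml:8.2f} mL")
```

prints

```
thigh   Dice 1.0000  volume   847.80 mL
muscle  Dice 0.9990  volume   517.73 mL
sat     Dice 1.0000  volume   260.55 mL
imat    Dice 0.9999  volume    33.42 mL
```

i.e. at 5% noise every tissue mask agrees with the generating truth to
within a tenth of a percent of Dice, and the voxel-count volumes are ready
for downstream comparison.  Muscle-group segmentation runs the same way
from an atlas family:

```python
from thighseg.phantom import make_atlas_family
from thighseg.fusion import segment_groups

family = make_atlas_family(PhantomSpec(jitter_mm=3.0, seed=11), 6)
target, atlases = family[0], [(c.fs, c.truth_groups) for c in family[1:]]
masks, result = segment_groups(target.fs, target.ws, atlases)
# result.map: 0 background, 1 extensors, 2 flexors, 3 medial compartment
```

A command-line interface mirrors the library
(`thighseg phantom | preprocess | lcdg-fit | tissues | register | prior |
segment | evaluate`); see `thighseg --help`.

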