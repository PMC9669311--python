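# emervis

Emergent object selectivity and viewpoint-invariant tuning in **untrained**
convolutional networks.

## What this package is for

Object recognition in primates is robust to viewpoint changes, and the
textbook account is that such invariance is learned from visual
experience.  `emervis` implements the complementary computational
hypothesis: that both object selectivity and a degree of viewpoint
invariance are *innate* properties of random feedforward hierarchies.  It
is aimed at computational neuroscientists and vision researchers who want
a reproducible, fully synthetic testbed for that claim — no model
downloads, no training, every stimulus generated by code.

The pipeline:

1. **Stimuli** — parametric 3-D furniture-like objects (cuboid
   compositions) rendered orthographically on phase-randomized 1/f
   backgrounds at controlled azimuths, every image calibrated to pixel
   mean 127.5 and sd 51.0, plus block-scrambled controls.
2. **Network** — an AlexNet-style five-layer conv stack (group
   convolutions, ReLU, max pooling; the conv5 map of a 227×227 input has
   13 × 13 × 256 = 43,264 units), weights i.i.d. N(0, 2/fan_in) (He
   initialization), biases zero, never trained.
3. **Selectivity** — a unit is object-selective when its mean response to
   a class beats every other class and the scrambled set, and a two-sided
   Wilcoxon rank-sum test of target vs pooled non-target responses gives
   p < 0.001.  Tuning indices:

   - z-scored response = (R̄_target − R̄_secondmax) / σ_allobject
   - OSI = (R̄_target − R̄_nontarget) / √((σ²_target + σ²_nontarget)/2)

4. **Invariance** — per-viewpoint tuning curves; the *effective range*
   (angular span of significant target-above-nontarget responses, with a
   half-grid-step margin per side, so ±45° significance on a 15° grid
   reads 105°); viewpoint-specific vs -invariant classification (one-way
   ANOVA with single-peak filtering at α = 0.05 on held-out identities);
   the invariance index 1/sd of per-viewpoint means.
5. **PFI** — preferred feature images by reverse correlation on random
   dot stimuli, and the convex-combination analysis showing invariant-unit
   PFIs are well fit by mixtures of specific-unit PFIs.
6. **Connectivity** — backtracking of group convolutions to the source
   layer; the homogeneous index (1/sd of per-preferred-angle average
   input weights, cohort-normalized so specific targets average 1)
   quantifying that invariant units receive evenly spread input from
   specific units of all preferred angles.
7. **Detection** — a linear SVM reading out target-vs-rest from unit
   subsets under viewpoint-varied vs front-view-only training.

## Worked example

```python
from emervis import workbench as wb

study = wb.run_study(master_seed=1, n_networks=2)
for r in study["per_seed"]:
    meds = {k: round(v, 2) for k, v in r["invariance_medians"].items()}
    accs = {k: round(v, 3) for k, v in r["detection"].items()}
    print(r["counts"], meds, accs)
```

prints:

```
{'toilet': 528, 'sofa': 692, 'monitor': 1077, 'table': 216, 'chair': 179, 'bed': 61, 'desk': 382, 'dresser': 73, 'nightstand': 29} {'conv3': 11.75, 'conv4': 12.36, 'conv5': 13.01} {'invariant': 0.894, 'specific_center': 0.781, 'non_selective': 0.631}
{'toilet': 604, 'sofa': 566, 'monitor': 1029, 'table': 123, 'chair': 135, 'bed': 52, 'desk': 338, 'dresser': 55, 'nightstand': 21} {'conv3': 11.0, 'conv4': 11.91, 'conv5': 12.25} {'invariant': 0.875, 'specific_center': 0.662, 'non_selective': 0.55}
```

Reading: in each untrained network, hundreds of conv5 units are
object-selective at p < 0.001, with selectivity concentrated in a few
geometrically simple classes (here monitor, sofa, toilet, desk) and
sparse in the rest; the median invariance index of the toilet-selective
units rises monotonically from conv3 to conv5 (flatter viewpoint tuning
deeper in the hierarchy); and with front-view-only SVM training tested
across the full ±90° orbit, viewpoint-invariant units decode the object
better than front-preferring specific units, while units selective for
no class sit closest to the 0.5 chance level.

The file-based pipeline with per-stage resume, manifests and figures is
available as a CLI:

```bash
emervis run-all --out runs/demo --smoke --seed 0
```

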