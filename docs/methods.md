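# Methods

## Scientific question and overall design

Neurons in higher visual cortex respond selectively to object categories
and keep responding when the object is seen from a different viewpoint.
This package asks how much of that behaviour is already present in a
purely random feedforward hierarchy: an AlexNet-style convolutional
network whose kernels are drawn from zero-mean Gaussians and never
trained.  The pipeline renders controlled synthetic object stimuli,
records unit activations in the convolutional layers, identifies
object-selective units, measures how their tuning survives horizontal
viewpoint rotation, visualizes their preferred features by reverse
correlation, traces the feedforward wiring that produces
viewpoint-invariant tuning, and quantifies what the different unit
populations contribute to a linear object-detection read-out.

## Stimulus model (`stimgen`)

Objects are compositions of axis-aligned cuboids evoking nine furniture
silhouettes (toilet, sofa, monitor, table, chair, bed, desk, dresser,
nightstand).  Identities within a class are produced by per-primitive
multiplicative size jitter (default ±12%) and additive position jitter
(default ±0.03 in unit-cube coordinates), seeded so a (class, identity)
pair always materializes the same geometry.  Rendering is orthographic
along the viewing axis after rotation about the vertical axis by the
azimuth; faces are flat-shaded from their outward normal with a fixed
ambient + diffuse model whose light direction has no horizontal
component, which keeps rendering exactly equivariant to left-right
mirroring.  Occlusion uses a painter's sort by mean face depth, which is
exact for these convex-primitive scenes at the rendered scales.

Backgrounds are random-phase 1/f textures (power-law amplitude, uniform
random phases), a statistical stand-in for phase-scrambled photographs:
they share the spatial-frequency profile of natural scenes while carrying
no shape information.  Scrambled control images are block-permutation
scrambles (default 8×8 grid) of the target-class images; the permutation
preserves the pixel multiset, so first-order statistics are untouched
before recalibration.

Every emitted image is affinely rescaled to pixel mean 127.5 and sd 51.0
and clipped to [0, 255]; because clipping perturbs the moments, the
rescale+clip step iterates (at most five times) until the post-clip mean
is within 0.5 and the sd within 1.5 of target.  For Gaussian-like images
the rails sit at ±2.5 sd, so roughly 1.2% of pixels saturate — an
irreducible property of fixing both moments on a bounded range.

Three builders mirror the three experimental protocols:

* **object** dataset — default 200 identities per class at azimuths drawn
  uniformly in [−30°, +30°], plus one scrambled set of the target class;
* **viewpoint** dataset — 13 azimuths evenly spaced over [−90°, +90°]
  (15° steps), default 250 identities per class of which 50 are held out:
  the held-out identities never participate in finding selective units and
  are reserved for classifying units as viewpoint-specific or -invariant;
* **svm** dataset — fresh identities (disjoint by construction via an
  identity offset), one subset per viewpoint-variation range V with
  azimuths uniform in [−V/2, +V/2], plus a front-view (V = 0) subset used
  by the fixed-viewpoint training regime.

What the generator deliberately does not emulate: CAD-level shape
variety, texture, perspective, lighting changes, or natural backgrounds.
Passing tests therefore demonstrate the statistical machinery and the
qualitative phenomenon on controlled geometry, not performance on
photographs; class discriminability is higher here than for natural
stimuli at equal sample sizes.

## Untrained network (`network`)

The hierarchy is the classical five-conv-layer AlexNet feature stack:
96@11×11 stride 4; 256@5×5 pad 2, 2 groups; 384@3×3 pad 1; 384@3×3 pad 1,
2 groups; 256@3×3 pad 1, 2 groups; 3×3 stride-2 max pooling after layers
1, 2 and 5.  A 227×227 input yields a 13×13×256 = 43,264-unit final conv
map.  Weights are i.i.d. N(0, 2/fan_in) (He initialization, the standard
way to keep signal variance stable across random ReLU layers); biases are
zero.  Local response normalization is omitted: the analyses are built on
rank statistics and ANOVA of per-unit responses, which monotone
channel-wise rescalings do not disturb.  Activations are recorded
post-ReLU, pre-pool.  With zero biases the network is positively
homogeneous, so the input scaling convention ([0, 1]) is immaterial to
every rank-based result.

The convolution is implemented directly with `sliding_window_view` +
matrix multiplication, which keeps the forward pass transparent to the
brute-force nested-loop oracle used in the tests and to
`receptive_sources`, the inverse lookup that enumerates exactly the
source-layer units and kernel weights feeding a given target unit.  Where
a max pool sits between two layers, connectivity is defined structurally:
every member of a pooled window is a source, carrying its pooled
position's kernel weight (which unit wins the max is stimulus-dependent,
so anatomical connectivity cannot commit to one member).

## Selectivity (`selectivity`)

A unit is object-selective for a class when its mean response to that
class exceeds its mean response to every other class and to the scrambled
set, and a two-sided Wilcoxon rank-sum test of target vs pooled
non-target responses gives p < 0.001.  No multiple-testing correction is
applied — the fixed α is part of the protocol, and the null
false-positive rate is verified empirically in the tests.  The scrambled
set qualifies the mean ordering but stays out of the rank-sum pool,
keeping the test two-sample.

Two indices summarize tuning:

* z-scored response = (R̄_target − R̄_secondmax) / σ_allobject, where
  R̄_secondmax is the highest non-target class mean and σ_allobject the sd
  of the unit's responses over all object-class images (scrambled
  excluded).  Per-image sd was chosen for the denominator as the standard
  z-score convention.  The value is positive exactly when the target
  class has the strictly highest mean.
* OSI = (R̄_target − R̄_nontarget) / sqrt((σ²_target + σ²_nontarget)/2), a
  d′-style contrast.

Constant-response units (common under ReLU) are flagged degenerate and
excluded from selection and from index denominators.

The cluster audit embeds image responses in 2-D with t-SNE and computes
per-class silhouettes on the embedding, then the Pearson correlation
between class silhouette and selective-unit count across classes.

## Viewpoint invariance (`invariance`)

**Effective range.**  Per viewpoint, a one-sided rank-sum test asks
whether the target response at that viewpoint exceeds the pooled
non-target responses (α = 0.05).  Only the contiguous block of
significant viewpoints around 0° counts; isolated significant outliers
beyond a gap are excluded (the contiguity rule is a design choice — gaps
are ambiguous and a front-anchored span is what "tuning is retained out
to ±X°" means).  The span runs from the outermost contiguous significant
viewpoints plus half a grid step on each side: significance at −45..+45
on a 15° grid gives 90 + 15 = 105°.  If 0° itself is not significant the
range is 0 and the unit is flagged.  The same rule, applied to
pixel-correlation distributions (each rotated image against its own front
view, null pool = front views against non-target images), gives the
raw-image-correlation control that shows unit tuning outlasts mere image
similarity.

**Classification.**  On held-out identities over the −60..+60° grid
(5 viewpoint classes), a one-way fixed-effects ANOVA across viewpoint
classes labels a unit *invariant* when p > 0.05 and *specific* when
p < 0.05 with exactly one peak, a peak being a per-viewpoint mean above
the grand mean plus one sd of the per-viewpoint means.  Multi-peaked
significant units stay unclassified.  A complementary tentative split
takes the top and bottom 30% of units by effective range (ties broken by
unit id, all-ties warned).

**Invariance index** = 1 / population sd of the per-viewpoint mean
responses; flat curves are capped at 10⁶ rather than mapped to infinity,
and capped values are flagged.  Larger = flatter = more invariant.  The
index is scale-covariant (scaling responses by c divides it by c), which
is acceptable across layers here because He initialization approximately
preserves activation scale through the hierarchy.

## Preferred feature images (`pfi`)

The estimator is spike-triggered averaging over random dot stimuli:
fields of bright/dark Gaussian blobs (defaults: 10 dots of sd 8 px,
amplitude ±60 around the 127.5 background for full-size images; tests use
smaller canvases) on a mid-gray field.  Responses are ensemble-mean-
subtracted before the weighted sum — classical STA centering.  A subtlety
follows: once responses are centered, a term common to every stimulus
(the previous iteration's PFI) cancels identically from the weighted sum,
so literal "re-estimate from PFI-plus-noise stimuli" carries nothing
forward.  The estimator therefore accumulates the per-iteration
normalized STA with equal weight while presenting each iteration's
stimuli superimposed on the current PFI (which matters for rectified
units: the PFI baseline holds the unit in its responsive regime), with
dot amplitude halved every 25 iterations so late iterations refine rather
than explore.  The final PFI is normalized to zero mean and unit
variance, making it exactly invariant to positive rescaling of the
responses.  Units with zero response variance at the first iteration are
flagged undefined.

The combination analysis searches the simplex of convex weights
(grid step 0.05) for the mixture of specific-unit PFIs that maximizes
pixel-wise Pearson correlation with an invariant unit's PFI, returning
the full correlation surface; Pearson correlation makes the surface
invariant to common affine transforms of the PFIs.

## Connectivity (`connectivity`)

For each target unit, the backtracked sources are partitioned by the
source layer's tuning labels into same-object viewpoint-specific (grouped
by preferred angle), same-object invariant, other-object selective, and
non-selective, and *signed* kernel weights are averaged per category —
signed, because homogeneity of per-angle inputs is only meaningful if
excitation and suppression are allowed to cancel.  The homogeneous index
of a target is 1 / population sd of its per-angle average weights
(capped as above) and is cohort-normalized by the mean raw index over
viewpoint-specific targets, so that cohort sits at exactly 1 and
"above 1" reads as "more homogeneously wired than a typical specific
unit".  The wiring-bias ANOVA for specific targets runs within the
largest cohort sharing a preferred angle — pooling targets with rotating
preferred angles would average the bias away — while invariant targets
enter as one pool.

## Detection task (`detection`)

A linear-kernel SVM (default regularization) reads out target-vs-rest
from the responses of a chosen unit subset, with features z-scored per
unit on the training fold.  Thirty target and thirty non-target
identities (non-targets drawn uniformly from the remaining classes) are
split 40/20 at the identity level; under the front-view regime the
training responses come from V = 0 renders and the test responses from
renders within the configured variation range, so train and test always
use disjoint identities.  Unit subsets (invariant, all specific,
front-preferring specific, non-selective, whole layer) are equalized by
random subsampling to the smallest subset so that accuracy differences
reflect tuning, not dimensionality.  "Non-selective" means selective for
no object class at all; units selective for a non-target class are
excluded because they trivially solve target-vs-that-class discrimination.

## End-to-end study and problem sizes

`workbench.run_study` executes the whole chain at desk scale: all nine
object classes at 16 identities each (plus scrambled controls) — the full
class roster matters because the detection task's non-target pool and the
"selective for no class" control are only meaningful against diverse
non-targets — a 13-step viewpoint set with 25 identities (10 held out for
the classification ANOVA), a detection set of 12 identities per class,
and five independently seeded networks, all built from one master seed.
Identity counts were chosen as the smallest at which the selectivity test
retains overwhelming power (a 16-vs-128 rank-sum can reach p ≪ 10⁻¹⁰)
and the viewpoint ANOVA keeps ten observations per cell; layer medians of
the invariance index are taken over the full selective population rather
than a subsample, so they carry no subsampling noise.  The qualitative
pattern — selective units exist, concentrated in the geometrically
simpler classes; median invariance index non-decreasing conv3 → conv4 →
conv5; front-view-trained detection ranking invariant >
front-preferring specific with non-selective closest to chance — is
reproducible in minutes on one CPU, holding in the majority of network
seeds (the per-seed detection ordering is the noisiest of the three and
is a majority-level, not a per-seed, property at this scale).  The file-based pipeline
(`workbench.run_pipeline`, CLI `emervis`) exposes the same stages at any
scale with per-stage seeds derived from the master seed, checksummed
outputs and stage-level resume.

## Numerical and degenerate-input conventions

* Azimuths are normalized to (−180°, 180°] before trig so mirroring is
  bit-exact; rasterization uses an inclusive half-plane rule on
  counter-clockwise-oriented convex polygons.
* All hypothesis tests report raw p values.
* ANOVA on a unit with zero variance everywhere yields an undefined F;
  such units are left unclassified.
* Flat-curve indices are capped (10⁶) and flagged rather than infinite.
* Ties in the percentile split are broken by unit id for determinism.
* Every random stage derives its seed deterministically from a master
  seed plus the stage name; builders called twice with the same seed are
  byte-identical.

## Known limitations

Cuboid silhouettes are easier to discriminate than natural objects, so
absolute unit counts and decoding accuracies are not comparable to what
richer stimuli would give; only the qualitative orderings and the
statistical machinery transfer.  Painter's-algorithm occlusion can
misorder faces for interpenetrating primitives (not used by the built-in
classes).  Invariance is studied for horizontal viewpoint rotation only;
position, size and in-plane rotation are out of scope.  The detection
task is binary target detection, not 9-way classification.
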