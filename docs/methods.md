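# Methods

`budtrack` estimates single-cell volumes, tracks, mother–bud lineages and
instantaneous growth rates of budding cells from label-free time-lapse
image stacks.  This note describes the models and procedures, the
parameters that matter, the synthetic study conditions the test suite
runs under, and the numerical choices that were genuinely open.

## Overlapping-instance segmentation from semantic maps

Budding cells overlap — a growing bud shares pixels with its mother and
often with a neighbour — so a single per-pixel labelling cannot represent
the instances.  The pipeline instead predicts a fixed 8-channel semantic
stack per frame:

```
[interior_S, interior_M, interior_L, edge_S, edge_M, edge_L, overlap, budneck]
```

Cells are stratified into small/medium/large by mask area.  Two area
thresholds define half-open intervals `[0, b1) [b1, b2) [b2, ∞)`; they
are chosen by exhaustive search over area quantiles minimising the total
overlap area between same-category cells (ties broken toward the area
terciles, making the search deterministic).  Overlapping cells then
rarely share a channel, and a per-category morphological erosion (disc
element; depth 1/2/3 px for S/M/L by default, with per-cell back-off so
no interior shrinks below `min_seed_area` = 5 px²) separates the
instances that still do.  The depth-1 element is the full 3×3 square
rather than the 4-neighbour cross so that one erosion step removes every
8-connected boundary pixel.  Edge channels carry the un-eroded
8-connected outlines; the overlap channel is the union of all pairwise
mask intersections; the bud-neck channel marks a ~3 px band at each
annotated mother–bud interface.

Instance recovery inverts this construction: threshold each interior
channel at `p_interior` (default 0.5), take 4-connected components of
area ≥ `min_seed_area` as seeds, dilate each seed with the same element
used for its category's erosion ("reversing" the erosion), then refine
the boundary with a star-convex radial spline.  The spline has 4/6/8
rays for S/M/L cells; each ray's knot radius is the weighted median of
candidate edge-pixel radii in the ray's angular sector, where a
candidate's weight is its edge-channel probability attenuated by a
Gaussian (σ_w = 3 px) in its distance from the grown mask's own
boundary and doubled inside predicted overlap regions (the true edge is
hidden under another cell there).  Sectors without evidence fall back to
the grown mask's own boundary radius.  Knot radii get a +0.6 px offset,
calibrated on rasterised discs, because outline pixels sit inside the
continuum boundary by about that much.  Interpolation between knots is a
periodic cubic spline; rasterising `r ≤ ρ(θ)` guarantees star-convexity.

Refinement is *guarded*: the spline outline replaces the reversed-erosion
mask only when its mean edge-channel support along the outline is at
least that of the grown mask.  When the interiors are already accurate
(as with idealised maps) the reversed erosion is kept; when they are
sloppy, the edge evidence corrects them.  Refinement therefore never
degrades accuracy, which is the property the test suite asserts.

A cell near a category boundary can seed in two channels; greedy
non-maximum suppression keeps the higher-scoring instance and removes
any other instance with mask IoU > 0.5 against a kept one.  Genuine
mother–bud overlaps are far below this cut-off and survive.  An
instance's score is the mean interior probability under its mask.

## The multi-target network

The semantic stack is predicted by a four-level U-net (two 3×3 conv +
ReLU blocks per level, 2×2 max pooling, nearest-neighbour upsampling
with skip concatenation, 1×1 sigmoid head; 8 base filters doubling per
level).  It accepts 1 or 5 bright-field Z-sections as input channels.
The implementation is pure NumPy — im2col convolutions, explicit
backward passes verified against finite differences, Adam — and is
deliberately small: with 64×64 tiles it trains on a few hundred images
in well under a minute per epoch on one CPU, and a fixed seed reproduces
training bit-for-bit.

The loss is per-channel binary cross-entropy with channel weights
(default 1 everywhere except ×2 on the bud-neck channel, whose thin
targets are hardest) and a positive-pixel weight of 3 to counter the
foreground/background imbalance.  Default learning rate 3e-3, batch
size 1 (single images), 3 epochs.  The train/validation split holds out
whole colonies, never individual frames.  The headline sanity metric is
the held-out *interior pixel F1*: since the three size-category interior
targets are disjoint, the probability of "interior of any size" is the
sum of the three channel probabilities, thresholded at 0.5.

For testing the downstream stages independently of training,
`oracle_predict` emits the ground-truth target stack as probabilities;
with σ > 0 each channel is softened with a Gaussian halo while the true
support keeps probability ≥ 0.75, so thresholding never loses true
target pixels for σ ≤ 1.

## Tracking

Pairs of outlines (one at t−1 or earlier, one at t) are scored by
gradient-boosted classifiers for the probability of being the same cell.
Classifier A sees only morphology: absolute differences and signed
log-ratios of area, perimeter, axis lengths and mean spline radius,
eccentricity and radius-sd differences, a same-category flag, the mask
IoU, and the pair's mean log-area and mean eccentricity as context.
Signed ratios matter because growth is directional — a young bud gaining
30 % area per frame is plausible, one losing 30 % is not — and the size
context matters because growth tolerances are strongly size-dependent.
Classifier B adds the centroid distance.  A is consulted first; if its
probability lies in (0.25, 0.75) the decision defers to B.  Difference
features are divided by the frame gap, so the same classifiers serve
comparisons at gaps 1–3.

Per track, probabilities are averaged over the last three observed time
points, which rides out one bad frame.  The frame assignment is the
optimal one-to-one matching (Hungarian on −log p).  A pairing is
accepted outright at p ≥ p_min (default 0.3 inside the `Tracker`, 0.15
in the end-to-end pipeline benchmarks); otherwise a *likelihood-ratio*
acceptance applies: a pairing whose probability exceeds a floor (0.005)
and dominates every still-available alternative for both the track and
the instance by a factor ≥ 8 is also accepted, but only for tracks seen
in the immediately previous frame — resurrecting a lost track on weak
absolute evidence too easily hijacks a later new bud.  This rescues
poorly calibrated but unambiguous links, e.g. small cells after a rigid
colony rotation where all probabilities are tiny but the matrix is
cleanly diagonal.  Unmatched instances open new tracks; tracks
unmatched for more than `lost_patience` = 2 frames close.

Training pairs come from simulated movies (all cross-frame outline
pairs at gaps 1–3, labelled by track identity).  Every third frame also
contributes pairs against a rigidly rotated and translated copy of
itself, so the classifiers learn that a displaced outline with unchanged
morphology is the same cell — the situation pivoting colonies produce.

## Lineage

Every ordered (larger, smaller) pair of instances within ~40 px is
scored by a third classifier whose features add, to the pair features,
the mother/bud size ratio and the *bud-neck evidence*: the fraction of
the frame's bud-neck probability mass lying within a 3-px dilation of
the two masks' contact zone.  Per-frame probabilities are accumulated
(running sum) per (mother-track, bud-track); each bud is assigned the
candidate with the highest accumulated probability, ties broken by
higher mean probability then lower track id.  A candidate qualifies only
after at least three jointly observed time points; buds seen with a
candidate for two frames are never assigned.  A bud born in a movie's
final two frames is therefore structurally unassignable, and the lineage
benchmarks score recall over assignable pairs only.

## Volumes and growth rates

The conical estimator elevates each mask pixel to its Euclidean distance
from the boundary and integrates the resulting solid, doubled for the
two mirror-symmetric halves: `V = 2·px³·Σ h`.  Heights are the distance
transform less 0.25 px: the discrete transform measures to background
pixel *centres* across a staircase boundary, which overestimates the
continuum distance by about a quarter pixel on average; with the
correction the estimator is within 1 % of `(2/3)πr³` on rasterised discs
of radius 20–40 px.

Growth rate is the time derivative of volume.  Rather than a parametric
growth law, each track's volume series (missing time points omitted;
at least four points required) is fitted with a Gaussian process —
Matérn-5/2 kernel plus white noise by default, RBF as an option — and
differentiated analytically: the posterior over dV/dt has closed-form
mean and variance for these kernels.  Hyperparameters maximise the log
marginal likelihood (L-BFGS-B on log-parameters, 3 seeded restarts);
the length-scale is bounded between one sampling interval and the
observation window and the noise variance floored at 10⁻³ of the volume
variance.  A mother's total growth rate is the sum of its own and its
current bud's derivative posteriors (variances add under an
independence assumption).

Cytokinesis is estimated as the end of the peak in the bud's growth
rate: the first time after the rate maximum at which the rate falls to
α (default 0.5) of that maximum; monotone profiles return the last time
point with a flag.  The escape-fraction statistic for real-time control
reports the fraction of mother cells with at least one bud or daughter
whose growth rate exceeded a threshold (default 15 µm³/h) at or before
the query time; it is non-decreasing in time and non-increasing in the
threshold by construction.

## Evaluation metrics

Masks are matched greedily in descending IoU, one-to-one; unmatched
predictions score zero.  Average precision sweeps IoU thresholds
0.50–0.95 in 0.05 steps and takes the trapezoidal area under the
resulting (recall, precision) points, anchored at recall 0 (precision
is non-interpolated).  Track IoU is the number of frames where the
mapped labels agree (mask IoU > 0.5 defines the per-frame label map)
over the frames where either track exists — splitting a truth track
into k pieces scores 1/k.  Tracks are matched greedily in descending
track IoU.  MOTA follows the CLEAR convention, 1 − (FN+FP+IDSW)/total
truth objects, with correspondences valid at mask IoU ≥ 0.5 and an
identity switch counted whenever a truth track's corresponding predicted
label changes.  Lineage precision/recall counts a true positive when the
truth bud track has a matching predicted track whose assigned mother
matches the truth mother's matched track.  Growth-rate accuracy is the
RMSE between GP rate estimates on matched predicted volumes and on the
truth volumes, matching per frame by highest IoU (ignoring tracking),
with a seeded bootstrap over 90 % subsamples.  The greedy mask matcher
is cross-checked against exhaustive enumeration on small instances in
the tests; greedy can in principle be suboptimal, and any such case
surfaces in that comparison rather than being hidden.

## Synthetic study conditions

The generator emulates trapped-yeast colonies: elliptical cells (axis
ratio ≥ 0.8, i.e. eccentricity ≤ 0.6), 0.25 µm/px, five Z-sections
0.6 µm apart, 5-minute sampling, three trapped mothers of 9–13 px
radius.  Mothers cyclically nucleate buds on their boundary; placement
points at the nearest neighbour with probability `overlap_bias` (so
bud–neighbour overlap grows with the bias) and the attachment depth puts
15–40 % of the bud's area inside the mother.  Buds are born at
3.5–7.5 µm³ (birth-size variability is what makes same-aged buds
morphologically distinguishable), grow linearly at 20–45 µm³/h —
reaching the division volume of 40 µm³ in roughly an hour, matching a
glucose-like cell cycle — and continue as independent daughter tracks
growing at 15 % of their bud rate after cytokinesis.  Buds pivot about
their mothers with per-frame probability `pivot_prob`; whole colonies
rotate rigidly (a jolt of the medium flow) with probability
`colony_rotation_prob`; non-mother cells wash out with probability
`washout_prob`.  The 2D mask area follows the sphere-equivalent
cross-section of the true volume, so the conical estimate is a monotone
transform of the truth.  Rendering is schematic — bright interior, dark
rim, per-Z defocus blur growing with distance from the cell's focal
plane, additive Gaussian noise — not an optics simulation.

What passing tests therefore show: the *algorithmic* pipeline recovers
overlapping instances, tracks through pivots and washouts, assigns
lineages and recovers growth rates under geometry and dynamics like
those of trapped colonies.  What they do not show: performance on real
bright-field appearance (halos, debris, traps, focus drift) or on
star-convex but non-elliptical cell shapes; those require curated
microscopy data.

Benchmark problem sizes were chosen to exercise the conditions while
keeping the full suite fast on a single CPU: 12–40 frame movies of
three mothers at 128×128 px for segmentation/tracking/lineage, 200
64×64 training tiles for the network, 50 series for the GP recovery,
10³-scale bootstraps.

## Known limitations

- Two same-category cells that overlap deeply while growing through a
  category boundary can merge into one seed for several frames; a
  static pair of thresholds cannot separate them.  This is the dominant
  residual segmentation failure and shows up as split tracks.
- Morphology-only tracking cannot distinguish two truly identical cells;
  the likelihood-ratio acceptance resolves such cases only when the
  assignment matrix is unambiguous.
- The cytokinesis α-crossing detector assumes the daughter's growth
  slows markedly after division; gradual slowdowns blur the estimate.
- GP derivative uncertainties assume independent mother and bud fits;
  shared segmentation errors violate this mildly.
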