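# Methods

`cacuda` implements an unsupervised adversarial domain-adaptation pipeline
for coronary artery calcium (CAC) scoring: a voxel-wise detector trained on
labeled non-contrast cardiac/chest CT (NCCT, the *source* domain) is
transferred to contrast-enhanced coronary CT angiography (CCTA, the
*target* domain) without any target labels, and its detections are turned
into per-artery calcium volume scores. Because the clinical cohorts this
kind of method is trained on are restricted, the package ships a seeded
phantom generator that reproduces the *structure* of the problem — two
domains separated by a contrast shift, a scan-specific detection threshold,
skewed lesion volumes, extra-coronary decoys — at desk scale.

## The detection model

Every candidate voxel is classified from three co-centered 2D patches on
the orthogonal planes (2.5D input). Candidates are supra-threshold voxels
in 6-connected clusters of at least 3 voxels; the threshold is the fixed
130 HU convention in NCCT and the scan-specific aortic threshold
`mean_ROI + 3·SD_ROI` in CCTA (computed with the population SD over an ROI
box placed in the ascending aorta). Patches are normalized by a fixed HU
window (center 300, width 1400, mapped to [0, 1], clipped).

The network is factored into

* a **feature generator G**: one learned 5×5 stride-2 convolution with 6
  filters, shared across the three planes, ReLU, then a dense layer (48
  units) to a 16-dimensional feature vector;
* a **classifier C**: a linear softmax head over the four classes
  (background, LAD, LCX, RCA; left-main lesions are folded into LAD by
  convention);
* a **discriminator D**: a dense head (32 units, sigmoid output) that
  scores a feature vector as source vs target.

The split is structural: `C` and `D` consume only feature batches, never
patches. All forward/backward passes are written directly in NumPy with
hand-derived gradients (verified against central finite differences in the
test suite), and Adam/RMSProp are implemented likewise, so training is
bit-reproducible from an integer seed. The convolutional first layer is
essential to the domain-shift behaviour, not an optimization: shared
filters respond *coherently* to region-wise contrast enhancement (each
filter's DC gain shifts every activation inside a bright region by the same
amount), which is how convolutional detectors actually degrade on contrast
scans. A pooled-MLP trunk (`g_conv=None`) is retained for comparison; its
per-pixel weights have effectively random signs against a region-wise
shift, the shift cancels, and no meaningful transfer gap appears.

Supervised source training minimizes categorical cross-entropy with Adam
(learning rate 5e-4) on class-balanced minibatches of candidate voxels,
with ±2-voxel patch-center jitter as augmentation. Background candidates
are capped per scan (default 60, by a deterministic stride): bone alone
contributes thousands of supra-130-HU voxels per non-contrast scan.

## Adversarial adaptation

With the source-trained detector as initialization, the generator and a
freshly initialized discriminator are trained adversarially:

    L_adv = E_t[ log D(G(x_t)) ] − E_s[ log D(G(x_s)) ]
    D: max L_adv        G: min L_adv + α·L_cls ,   α = 2

`L_cls` is the source-domain cross-entropy through the **frozen**
classifier — the constraint that prevents the adversarial updates from
forgetting the classification task. The schedule follows the
Wasserstein-GAN heuristics: the discriminator is pretrained alone for 1,000
iterations, then updated 20 times per generator step; its weights are
clipped into [−0.1, 0.1] after every update; both use RMSProp
(discriminator 5e-4, generator 5e-5 at full scale). `L_adv` is implemented
literally as written above on a sigmoid discriminator (computed stably via
softplus of logits); a linear Wasserstein-style critic is available behind
`UdaConfig(critic="linear")` because the schedule's provenance mixes the
two formalisms.

Two choices here were genuinely open and are pinned as follows:

* **Adversarial sampling protocol.** The adversarial pairing uses patches
  at *random in-heart locations*, drawn with the same protocol in both
  domains (60 per scan), while `L_cls` uses the labeled source candidates.
  Pairing the candidate sets themselves is a mistake we measured: candidate
  class composition differs across domains (bone-dominated in NCCT,
  variable in CCTA), the discriminator keys on composition rather than
  appearance, and "alignment" maps target lesions onto the source
  background cluster — worse than no adaptation. Matched-location sampling
  leaves appearance (contrast) as the only domain signal.
* **Desk-scale schedule.** The published schedule (200 epochs over hundreds
  of scans) is ~100× more generator steps than a desk run. The desk default
  (15 epochs over ~2,400 target patches, ~1,100 generator steps)
  compensates with a larger generator step size (2e-3); the full-scale
  values remain the `UdaConfig` defaults.

## Quantification

Detected voxels are grown into 6-connected supra-threshold neighbours
(region growing; a whole grown component takes the majority artery label of
its seeds, ties to the lower class id; idempotent). Lesions are connected
components per artery class under 6-connectivity; the score is the volume
score (voxel count × voxel volume, mm³ — the Agatston score is not defined
on contrast scans). Rule-based false-positive reduction discards lesions
smaller than 1 mm³ (noise), larger than 500 mm³ (beyond plausible CAC), or
with centroid outside the heart mask dilated by a 10.0 mm-diameter sphere
(converted to voxels per-axis by the spacing). The centroid convention (vs
any-voxel) makes the heart rule robust for lesions straddling the mask
edge. Volume bounds are strict inequalities; 1 and 500 mm³ exactly are
kept. The size cap can discard a genuinely large true lesion — the same
outlier behaviour reported for the clinical pipeline — and such removals
are logged with their rule.

## Evaluation

Volume-wise metrics compare label maps voxel-by-voxel per artery;
sensitivity = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN). The *total* row is
label-agnostic (any-calcium vs background), so artery mislabels still count
as detected calcium; this interpretation of the total is pinned here.
Lesion-wise matching declares a predicted lesion true-positive if it shares
at least one voxel with a reference lesion of the same artery; a reference
lesion matched by several fragments counts once (fragments are tallied).
Cohort summaries are mean (population SD) across scans; zero-calcium scans
are excluded from sensitivity/F1 means but included in false-positive
volumes. Rank agreement uses Spearman correlation (average ranks on ties;
undefined and flagged for constant input).

Agreement of volume scores uses Bland–Altman limits with heteroskedastic
(nonuniform-difference) modeling: |auto − reference| is regressed by
ordinary least squares on the square root of the pairwise mean, and since
absolute differences of a centered normal are half-normal, the fitted line
is multiplied by 1.96·(π/2)^0.5 to give the 95% limits
±1.96·(π/2)^0.5·(b + a·mean^0.5). The recovery simulation draws pair means
in two clusters at the ends of the volume range (small-burden pairs anchor
the intercept where the proportional errors are small; high-burden pairs
pin the slope) — with uniformly drawn means the OLS intercept is too noisy
at n = 2000 to be a meaningful check.

## The phantom

Each scan is a 64³ grid at 1.5 mm isotropic spacing (configurable): an air
background, an ellipsoidal soft-tissue body, spine/sternum/rib structures
of heterogeneous bone density, an ellipsoidal heart (myocardial shell at
55 HU around a blood-pool compartment), three tubular coronary arteries
(radius 2 mm) on the heart surface (LAD anterior, LCX left, RCA right), an
ascending aorta holding the thresholding ROI, compact ellipsoidal lesions
attached to artery walls, and optional curvilinear aortic-wall/valve decoy
calcifications. The whole cardiac complex is rotated by a random ±20° per
axis per scan (pose variability) and jittered in position and size.
Gaussian noise (SD 10 HU) is added everywhere.

The two domains differ *only* in the blood pool: in NCCT, chambers, aorta
and artery lumina are blood-density (45 HU, indistinguishable from
myocardium); in CCTA they take a per-scan contrast level drawn uniformly
from [250, 600] HU. Lesion and decoy voxels are set to the applicable
detection threshold plus a margin (default 170 HU) plus noise, which
guarantees the labeling invariant that every reference calcium voxel
exceeds the threshold its annotation protocol would use — in CCTA the
threshold measured from the generated ROI itself.

Lesion volumes are drawn from a log-normal fitted by least squares on the
normal-quantile scale to a published clinical summary (median 7.1 mm³,
quartiles 1.6 / 29.2 mm³, 95th percentile 188 mm³), giving
μ = 1.916, σ = 2.052 (implied median 6.8 mm³, 95th percentile 199 mm³).
Draws are truncated at 625 mm³ — the largest lesion reported clinically,
and about the volume of the entire phantom artery tube — by resampling;
without the cap the fitted tail places a >500 mm³ lesion in most 20-scan
cohorts, where its removal by the size rule dominates cohort F1 in a way a
313-scan clinical cohort absorbs as a single outlier. Lesion placements
that would merge two lesions (6-adjacency), enter the aorta, or touch bone
(face-adjacency at 1.5 mm voxels is a rasterization artifact) are retried a
bounded number of times and then dropped and counted.

What the phantom does and does not show: it reproduces the *mechanism* of
the transfer problem — a detector whose background class is anchored by
bone and whose features respond coherently to contrast loses a large
fraction of calcium volume to the background class on contrast scans, and
adversarial feature alignment recovers it without degrading the source
domain — under schematic geometry, a uniform per-scan contrast level, and
synthetic noise. It does not emulate anatomy, partial-volume blur at
sub-millimetre resolution, within-scan contrast gradients, motion or
beam-hardening artifacts, so absolute sensitivities/F1 here do not predict
clinical numbers; orderings and effect directions are the meaningful
outputs. The clinical headline numbers (sensitivity 0.41 → 0.80 after
adaptation on 313 CCTA scans) require restricted data and trained weights
and are not reproducible here; the desk-scale analog reproduces the
direction and approximate magnitude of the gain.

## Desk-scale experiment defaults

40 source + 40 target training phantoms, 12 source + 20 target test
phantoms; patch 21 px; conv trunk (6 filters, 5×5, stride 2) → dense 48 →
16 features; source training 40 epochs; adaptation 15 epochs (1,000-step
discriminator pretrain, 20:1 schedule); ~2.5 minutes per replicate on one
CPU. The ablation grid evaluates {source-only}, {+L_adv} (α = 0),
{+L_adv+L_cls}, {+L_adv+L_cls+FP reduction} on the target test cohort and
re-evaluates the source test cohort before/after adaptation to measure
forgetting. The α = 0 arm is deliberately unstable — without the
classification constraint the generator freely degenerates (in different
runs it collapses everything to background or to calcium) — which is the
ablation's point.

## Numerical conventions and degenerate cases

Voxel arrays are indexed (x, y, z), 0-based, physical position =
origin + index·spacing, half-open extents. Slice re-gridding models
thickness/increment as overlapping slab averages along z; label maps are
re-gridded by nearest neighbour, never averaged. Class ties in prediction
resolve toward background, then the lowest class id (argmax order). The
adversarial loss clamps scores to [1e-7, 1−1e-7] before logarithms at the
public surface and works on logits internally; training aborts with a
diagnostic if |L_adv| exceeds a configured bound (default 50). Empty
candidate lists, zero-lesion scans and zero-calcium cohorts are legal
inputs everywhere except supervised training, which refuses a cohort with
no calcium to learn from; undefined ratios (sensitivity with empty
reference, Spearman on constant input) are flagged rather than silently
zeroed.
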