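# Methods

This note documents the models, estimators and numerical choices behind
`oirpipe`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic benchmark does and does not
demonstrate about real data.

## Synthetic wholemount generator

The generator emulates a lectin-stained rodent retinal wholemount at a
configurable scale (default 10 µm/px; a 512² image is a ~4.8 mm wholemount,
256² is used for routine analysis and testing). The retina support is a
disc with four thin relaxing-cut notches mimicking the flattening incisions
of the wholemount preparation; the cuts are cosmetic and carry no signal.

**Vasculature.** Major vessels grow as biased random walks from the optic
disc: `n_primary_vessels` trunks (default 12) step outward at 2 px
increments; each step the heading receives Gaussian wiggle of amplitude
`tortuosity` (dimensionless; 0 gives perfectly straight radial vessels) and
is pulled back toward the local radial direction with gain 0.2, so vessels
always progress outward. Branching is a Poisson process along the arc
length (`branch_rate`, default 0.008 events/px — chosen so the tip spacing
at the periphery is of the order of 20 px, i.e. a space-filling major-vessel
plexus at this resolution). The emitted vessel graph stores per-edge
polylines with arc and chord lengths, so tortuosity can be audited as the
arc/chord ratio. Between major vessels the perfused retina carries a fine
**capillary lattice** (a randomly rotated ~1 px grid at 8 px spacing,
rendered dimmer than major vessels). This reflects how wholemounts actually
look — a continuous capillary bed everywhere that is perfused — and it is
what makes "avascular" well defined: the avascular zone is the absence of
*any* signal, not merely the gaps between arterioles.

**Phenotypes.** Vaso-obliteration erases vessels and capillaries inside a
central disc (mouse mode) or an outer annulus (rat mode). The boundary
radius is the order statistic of retina-pixel radii matching the target
fraction, so the realised fraction equals `round(target·n)/n` exactly and
the reported ground truth is a pixel count, not an approximation.
Neovascular tufts are additive Gaussian blobs (σ = 3 px, peak 1.5× vessel
intensity, clipped at 1.0 — i.e. saturating) planted on the vascular front
bordering the avascular territory, at least 18 px apart. Haemorrhages are
dark discs (radius 3.5 px, intensity 0.03) planted at least 25 px apart and
away from tufts. Both lesion types avoid the relaxing cuts. Rendering adds
Gaussian noise (σ = 0.05 on a [0, 1] scale, SNR ≈ 10 for vessel/background
contrast) and clips to [0, 1]; pixels outside the retina are exactly 0.

**TUNEL tables.** Per-section counts are Poisson(rate × length) per nuclear
layer (GCL, INL, ONL) with section lengths uniform on [1.5, 2.5] mm —
`tunel_rates` has units of profiles/mm.

**Cohorts and presets.** A cohort derives per-sample seeds from a master
seed by CRC32 of `"{seed}:{sample_id}"`, so cohorts are reproducible and
samples independent. The mouse presets encode the four-arm design with
obliteration fractions 0 / 0 / 0.289 / 0.20 and the rat presets
0 / 0 / 0.041 / 0.032 with haemorrhage means 2.3 / 0.4 in the OIR and
rescued arms — the group-mean values reported for these models. Tortuosity
and branch-rate contrasts are not quantified anywhere in the literature for
this design; the presets set the OIR arm strongly abnormal (0.60 / 0.015 vs
0.15 / 0.008 in controls) and the light-treated OIR arm rescued most of the
way back (0.30 / 0.0105): far enough from control to be detectable at
n = 12/group, close enough that it clusters with the healthy arms rather
than with OIR. ONL TUNEL rates are elevated 4× in OIR and 2× in the rescued
arm.

## Chan-Vese segmentation

The two-phase piecewise-constant energy is minimised by level-set descent
with a smoothed Heaviside H_ε (arctan form, ε = 1 px). Two numerical
choices matter:

1. **Line search on the smoothed functional.** Each iteration computes the
   standard force δ_ε(φ)[μκ − λ_in(I−c_in)² + λ_out(I−c_out)²] — with the
   curvature κ evaluated on H_ε(φ) itself, so the force is the
   discretisation-consistent gradient of the total-variation term —
   normalises it to a maximum step of `dt`, and backtracks
   (dt, dt/2, … dt/32) against E_ε(φ), the total variation of H_ε plus the
   Heaviside-weighted data terms. Accepted steps therefore never increase
   the objective and recorded trajectory energies are non-increasing by
   construction. When no local step decreases E_ε, the solver tries the
   alternating-minimisation jump (the data-optimal region for the current
   phase means, accepted only on strict decrease), which escapes spurious
   stationary states such as residual far-field islands; eight consecutive
   stalls (or eight sub-tolerance relative changes with a static region,
   tol = 1e-4) end the evolution. φ is clipped to ±2.5 so the far field
   keeps a responsive δ_ε. Backtracking against the *binary* region energy
   instead deadlocks: a level-set step moves thousands of borderline
   pixels as one correlated block whose discrete energy change is
   discontinuous.
2. **Symmetry breaking at initialisation.** The default period-16
   checkerboard level set splits both phases so evenly that c_in = c_out
   and the data force vanishes identically — a saddle the descent cannot
   leave. The initial φ therefore adds a small intensity-proportional bias,
   (I − Ī)/(3·sd(I)), which breaks the tie deterministically toward
   bright-inside.

The contour weight μ defaults to 0.25 for generic use but to **0.02 for
vessel segmentation** (`VESSEL_CV_PARAMS`): for a 2–4 px-wide vessel
network the perimeter of the true segmentation is enormous, and at μ = 0.25
the energy minimum is a single compact blob over the retina rather than the
vasculature — thin elongated structures need a weak contour penalty.
Support masks restrict the data terms (and phase means) to the retina or
any ROI; the reported foreground is always the brighter phase (lectin
stains bright), and a run whose phases do not separate (mean difference
under 0.2× the intensity spread — e.g. a vessel-free retina) yields an
empty vessel mask rather than an arbitrary noise split.

On noiseless two-level images the method agrees with the midpoint-threshold
oracle to Dice ≥ 0.99; on the synthetic wholemounts at σ = 0.05 noise it
recovers the ground-truth vasculature at Dice ≈ 0.97.

## Wholemount quantification

Percentages are pixel fractions of the retina support. The avascular
territory is `retina ∖ closing(vessel mask, disk r)` with r = 12 px by
default (the capillary lattice spacing of 8 px is what makes this
well-conditioned; components under 0.1% of the retina are discarded).
Recovered obliteration fractions track the generated truth with a mean
absolute error well under 1 percentage point across 5–40% targets.

Tuft detection thresholds the 1 px-Gaussian-smoothed image at the 0.95
quantile of vessel-pixel intensity, opens with a 2 px disc (severing thin
super-threshold vessel stretches), and keeps 8-connected components with
area in [10, 500] px², solidity ≥ 0.8 and **peak intensity ≥ 0.9**: tufts
are saturating hyperfluorescent lesions, and the peak criterion is what
separates them from bright vessel crossings and noise lumps. Smoothing is
essential — at SNR ≈ 10 the solidity of an unsmoothed component is
meaningless. Haemorrhage counting takes compact components (area ≥ 10 px²,
solidity ≥ 0.7) below the 0.005 intensity quantile, excluding any on the
vessel skeleton. With well-separated planted lesions both detectors recover
counts exactly.

## SMIA branching morphometrics

Area (pixel count), perimeter (4-direction Crofton) and Euler number
(8-connected foreground, 4-connected holes — the standard digital-topology
pairing) are tracked over the recorded Chan-Vese trajectory. The feature
ROI is the **peripheral annulus** (outside 0.55 of the retinal radius by
default): peripheral branching is where the pathology of interest lives,
and in the mouse model this keeps the central avascular zone from flooding
the feature set — without it, the feature vectors measure lesion area, and
the rescued arm (20% obliteration) clusters with OIR (29%) regardless of
its branching. The Chan-Vese evolution runs with the annulus as its
support, so phase means, trajectory and features all describe the periphery
only. Each recorded region is additionally opened with a 1 px disc before
measurement: this strips the sub-calibre capillary bed, whose random
texture otherwise dominates the Euler-number and perimeter variance, so
the features describe the arborisation of the major vessel network.

"Critical points" of the evolution are selected deterministically: the
final state always; then topology-change events (Euler jumps) ranked by
jump magnitude; then local extrema of the energy-decrease rate; then
uniform subsamples — K = 5 states by default, giving a 15-vector
(area, perimeter, euler) with area normalised by ROI area and perimeter by
its square root. Topology changes are taken as the moments the shape
representation changes qualitatively; the rule is configurable since no
canonical definition exists.

## Group statistics

SMIA vectors are z-scored per column (the three feature families live on
incommensurate scales), reduced by PCA (SVD; deterministic sign convention:
the largest-magnitude loading of each component is positive; m = smallest
number of components explaining ≥ 90% variance, capped at n − k − 1 so the
pooled covariance stays invertible). The MANOVA reports Wilks'
Λ = det(E)/det(E+H) with Rao's F approximation. Mahalanobis distances
between group centroids use W = E/(n−k), the pooled within-group
covariance, and are clustered by hand-rolled single linkage with
lexicographic tie-breaking (deterministic dendrograms); distances are
reported both pairwise and relative to the control group. Note W is
estimated at n − k degrees of freedom, so distances between two groups with
*identical* population distributions are still positive at finite n —
"indistinguishable" means small relative to the pathological contrasts, not
zero.

Scalar metrics use one-way fixed-effects ANOVA with Tukey's HSD
(statsmodels, studentised-range distribution). A degenerate input (zero
within-group variance and equal means) is flagged rather than given a
p-value. TUNEL frequencies are per-animal totals Σcounts/Σlength per layer
(animals with fewer than three sections are excluded), summarised as group
mean ± SE with per-layer ANOVA/Tukey; no additional correction is applied
across the three layers, which is a documented limitation.

## Problem sizes and determinism

Routine analyses and the acceptance script use 256² images, cohorts of
12 animals per arm, 10,000-replicate Monte-Carlo calibrations and
200-grid / 50-matrix oracle comparisons; the generator's exact-fraction
invariant is additionally exercised at 512². All stochastic stages consume
`numpy.random.Generator` streams derived from explicit integer seeds, and
the pipeline manifest records SHA-256 checksums — identical configs
reproduce identical artefacts byte for byte.

## What the synthetic benchmark does not show

The generator's vessels are random walks, not haemodynamically plausible
trees; capillaries are a lattice, not a plexus; lesions are geometric
idealisations with known separation; noise is Gaussian and stationary,
with no illumination gradients, stitching seams or staining artefacts.
Passing the recovery tests therefore demonstrates that the estimators are
correct and well-calibrated *under the stated model*, not that they are
robust to every property of real confocal wholemounts. Parameters most
likely to need retuning on real data: the contour weight μ and noise scale
in segmentation, the tuft peak/solidity criteria, and the closing radius
(which should scale with capillary spacing in pixels).
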