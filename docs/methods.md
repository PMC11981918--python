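# Methods

This note records how each stage of the pipeline is computed, the defaults
that matter, the numerical choices made where the design was genuinely open,
what the synthetic data do and do not emulate, and the known limitations.

## Coordinate and unit conventions

Label volumes are integer arrays indexed `[x, y, z]` with an anisotropic
voxel resolution in nm (reference 64 × 64 × 40 nm) and a world offset.
Meshes are in nm in world coordinates. Depth follows image-style
conventions: cortical depth increases along a configured axis (`y` by
default) from a flat pial plane at a configured coordinate; curved-
streamline depth corrections are out of scope. The sectioning axis for slab
normalization is `z`. Lengths are reported in µm, areas in µm², volumes in
µm³.

## Nucleus morphometry

Meshes come from marching cubes on the binary label mask at the stated voxel
resolution, keeping only the largest connected component (by enclosed
volume, falling back to area for open fragments).

**Shrink wrap.** The envelope used to measure infoldings is the convex hull
of the nucleus mesh, subdivided to roughly 4× the input edge length, with a
single projection pass: wrap vertices within 25 nm of the input surface snap
exactly onto it; vertices bridging an invagination mouth stay on the hull.
The projection is deliberately one-shot and snap-only. We implemented and
rejected an iterative attraction + smoothing relaxation: on phantoms with
steep-walled invaginations the wrap vertices that first touch the wall are
dragged down it step by step (each snap lands slightly deeper), collapsing
the measured fold distances; the snap-only rule cannot descend. The cost of
this choice is that a gentle concavity of the whole nucleus (a bean-shaped
cell, as opposed to an invagination) is bridged rather than followed, which
slightly overstates the fold area of strongly non-convex nuclei. Nuclear
shapes are near-convex apart from their infoldings, so we accept this bias
and document it here.

**Fold features.** Each nucleus vertex gets its unsigned nearest-point
distance to the wrap surface (KD-tree candidate triangles + exact
point–triangle distance). Vertices strictly deeper than 150 nm are inside an
infolding. Fold area is accounted per face in proportion to how many of its
three vertices are folded (0, ⅓, ⅔ or all of the face area). An
all-or-nothing face rule was measured to be biased low by up to ~0.05 in
fold fraction on steep-walled folds, because the boundary ring consists of
strongly stretched faces; the proportional rule is unbiased at the same mesh
resolution and is what the recovery tolerance of ±0.02 is validated against.

## Soma morphometry

Matching uses the symmetric one-voxel (6-connectivity) dilation ring of the
nucleus mask; the soma id must cover strictly more than 80 % of the ring,
otherwise the cell is unmatched and excluded downstream. The 15-µm cutout is
cleaned in voxel units exactly — dilation 5, hole fill, erosion 3, all with
the 6-connectivity structuring element — matching the anisotropic
voxel-space procedure rather than isotropic nm. The net +2-voxel dilation
biases the cutout volume upward by ~5 % at 64 × 64 × 40 nm (≈ +12 % at
128 × 128 × 80 nm); tests assert volumes with this bias in mind. Cutout
boxes that exit the volume are flagged truncated, not silently computed.
A synapse counts as "on the somatic cutout" when its post id matches, it
lies within the cutout radius of the nucleus centroid, and it is within
500 nm of the cutout mesh surface (the tolerance is a package choice; the
association rule is not otherwise specified by the procedure).

## Postsynaptic shapes

**Region cutouts** keep faces with a vertex within 3,500 nm of the synapse,
restricted to the connected component containing the synapse-nearest vertex.

**Local thickness** is the shrinking-ball shape diameter: the maximal ball
tangent at a face (centre along the inward normal) is shrunk until
maximally inscribed; the local diameter is twice its radius, which equals
the ray-cast chord on tubes. Three robustness rules matter: (i) query
normals are vertex-averaged, because raw face normals of faceted walls are
tilted off the true surface normal and make the ball drift inward without
bound; (ii) a contact only counts when it penetrates the current ball by
more than 2 %, which stops discretization ridges from shrinking the ball
endlessly; (iii) contacts must lie genuinely inward of the tangent plane
(cos > 0.2). Radii are capped at 3,500 nm — open soma patches never converge
below their curvature radius and simply saturate, which is the desired
"much thicker than any dendrite" signal. On meshes above 1,500 faces the
ball is evaluated on a 1,500-face subsample and interpolated by nearest
centroid.

**Segmentation** clusters log-thickness with a Gaussian mixture (components
selected by BIC on the genuinely measured subsample, then components whose
means differ by less than 0.30 in log — about a 1.35× thickness contrast —
are merged), majority-smooths the face labels over the adjacency graph, and
takes same-label connected components; segments below 2 % of the region
area are merged into the neighbour with the longest shared boundary.

**PSS extraction** approximates the local skeleton by the segment-adjacency
graph: the main shaft is the thickest segment plus adjacent segments within
75 % of its thickness; the PSS is the flood-fill from the synapse-bearing
segment with the shaft removed (spine head + neck), or the synapse segment
itself when the synapse is on the shaft (shaft stretch, soma patch). A
mesh-contraction skeleton was considered and not used: at the 3.5-µm cutout
scale the segment graph makes the same branch decisions deterministically
and with far less machinery. Failures fall back to the synapse-bearing
segment alone, flagged.

**Pose normalization** samples the surface uniformly by area (fixed seed),
centres the cloud, rotates into principal axes (descending variance) and
fixes signs by the third moment along each axis (falling back to the
extremal coordinate for near-symmetric shapes), enforcing right-handedness.
Scale is preserved — absolute size separates soma patches from spines.

**Embedding.** Two encoders expose the same interface. The default
`DeterministicShapeEncoder` computes classical descriptors (per-axis scale,
skewness, kurtosis, cross moments, covariance spectrum, radial statistics
and a 16-bin radial histogram) zero-padded to the 1,024-long latent; it is
deterministic, CPU-trivial, and shape-discriminative, which is all the
dictionary semantics require. `PointCloudAutoencoder` is a small numpy
point-cloud autoencoder (pointwise 3→64 tanh layer, max-pool over points,
linear map to the 1,024 latent; decoder 1,024→64→n×3) trained with Adam on
an L2 loss against nearest-target correspondences refreshed each epoch;
training is deterministic under its seed. Neither claims fidelity to any
particular trained network; the dictionary only needs the embedding to
separate shape families, which both encoders do (phantom classes are
linearly separable from either latent at ≥ 90 % CV accuracy).

**Dictionary and histogram.** k-means with k = 30 (k-means++, 50 restarts,
fixed seed) on the latent corpus; assignment is nearest centre by Euclidean
distance with ties to the lowest index; display order is by descending
cluster population. Histograms use raw counts (not per-cell normalized)
over 30 shape bins × four 15-µm radial bins, [lo, hi) except the closed
last bin, flattened row-major to 120-D; cohort-level z-scoring happens in
feature assembly.

## Feature assembly

The object filter runs sequentially with strict thresholds: volume
< 25 µm³, then error-id-0 bounding-box fraction > 0.20, then membership in
the classifier-predicted error set; the report reconciles counts exactly.
The predicted-error step is naturally a second pass after a first cascade
fit; single-pass runs simply omit it. Slab normalization divides the five
size features (nucleus volume/area/fold area, soma volume/area) by their
800-nm z-slab mean and recomputes the derived ratios afterwards — the
artifact being corrected is a section-thickness scaling, which cancels in
ratios, so normalizing ratios directly would inject noise. Z-scoring uses
the population (n) standard deviation; constant columns are dropped with a
warning, and the fitted means/σ are returned for reuse on new cells. The
PSS block is z-scored over the cells that have it; cells without PSS are
flagged, not dropped.

## Hierarchical classification

The five levels are trained from a single labelled, standardized table.
Levels 1–4 see the 13 nucleus + soma features; level 5 adds the 120 PSS
columns. The per-level randomized search draws hyperparameters for each
candidate family (linear SVM, RBF SVM, nearest neighbours, random forest,
decision tree, MLP — search spaces pinned in `FAMILY_SEARCH_SPACES`),
scores each draw by stratified k-fold CV accuracy, and selects by accuracy,
then macro F1, then family simplicity in a fixed order. Folds shrink with a
warning when the rarest class is smaller than the requested folds. Desk-
scale defaults (5 draws over linear + RBF SVMs, 3 folds) keep a full
cascade training under ~5 s on one CPU while reliably finding the RBF model
that the multi-cluster level-1 problem needs; the family list, draw count
and folds are all parameters.

The excitatory re-routing rule is a logistic regression on PSS-augmented
features, trained on the labelled neurons that have PSS features, with the
decision threshold at posterior 0.5; predicted-inhibitory cells it calls
excitatory are re-run through the excitatory subclass model and logged.
Weighted accuracy uses reference-set class frequencies. Models serialize
with joblib and reload to bit-identical predictions.

## Connectivity analyses

φ is the angle between the pia direction (−depth axis) and the vector from
the target soma centroid to the synapse, so φ = 0° is directly above the
soma (pial side) and 180° directly below, where the axon initial segment of
an excitatory cell sits. AIS synapses satisfy φ ∈ [160°, 180°] and
r ≤ 60 µm; the chandelier call is strict (> 40 % of all outputs). The 5P-NP
preference defaults to the inclusive reading (≥ 30 % of labelled outputs)
with a `strict` flag for the exclusive one. Axons with fewer than 100
outputs warn rather than error — the minimum is an input-quality
expectation, not a mathematical precondition. The Fisher test is
`scipy.stats.fisher_exact` (two-sided, probability-mass definition), cross-
checked in tests against a full hypergeometric enumeration to 10⁻¹⁰.
Nearest-neighbour queries use a KD-tree with ties broken by ascending cell
id and the query excluded. Percentiles use linear interpolation between
order statistics. Density maps count cells in 50-µm square x–z bins and
scale by 1/(0.05 mm)² = 400 to cells/mm².

## Synthetic data: what it emulates, and what it does not

All generators derive their randomness from one seed through spawn-key
splitting, so every sub-generator is independently reproducible.

**Nucleus phantoms** are icospheres with radial inward dimples: a flat floor
at the requested depth joined to the sphere by a narrow smoothstep rim whose
150-nm crossing defines the planted boundary. A pure Gaussian dimple profile
was rejected because its displacement gradient at the threshold contour is
~0.1 nm/nm, making the planted area ill-conditioned against tens of nm of
measurement noise. Pulling a cap inward shrinks its floor area while the
walls add membrane, so the cap angle is calibrated by 1-D quadrature on the
surface-of-revolution meridian until the *deformed-surface* area fraction
displaced beyond 150 nm equals the request; the returned truth is the
mesh-level bookkeeping of that quantity. `calibrate=False` keeps the
uncalibrated cap (sized on the undeformed sphere) for monotonicity
experiments in fold depth. Wrap-based measurement needs the dimple floor to
sit below the hull chord plane, so test configurations use several
moderate-size deep folds; a single very wide, very shallow dimple is not
measurable by any mouth-bridging envelope and is outside the generator's
intended regime.

**Cell volumes** are concentric voxelized spheres (point-in-sphere at voxel
centres) with label 0 reserved for error/void, planted by converting the
exact requested count of background voxels inside the 15-µm bounding box.
Lost sections (`gap_slab`) blank a z-slab of the soma; merged fragments
(`fragment`) plant a detached run of soma-labelled voxels. A fragment
literally touching the soma cannot be removed by the dilate/fill/erode
procedure (net +2 voxels keeps it attached), so the planted fragment sits
beyond twice the dilation distance, where the largest-component rule drops
it — the in-box-disconnected geometry that actual merged fragments have.
The nucleus is rasterized as a plain sphere; mesh-level infoldings are
irrelevant at the voxel tests' scale.

**PSS phantoms**: the spine (shaft + thin neck + head) is voxelized from an
implicit union at 25 nm and Taubin-smoothed into one connected watertight
surface, mirroring how real surfaces arise from segmentation masks; shafts
are subdivided capsules; soma patches are open spherical caps of 6-µm
radius. Instances jitter ±12 % in scale so corpora have diversity.

**Cohorts** draw features from class-conditional Gaussians. Class means sit
on random unit directions scaled by the separation (in SD units) within the
13 nucleus/soma dimensions; inhibitory subclasses get an additional mean
component in the PSS block, emulating the fact that postsynaptic shapes
carry the extra subtype information. Planted chandelier axons place an
exact fraction (default 0.8) of their outputs in the AIS window of random
target somata; planted NP-targeting axons place an exact fraction (default
0.5) onto 5P-NP cells; bookkeeping returns the planted fractions.

What passing tests on these phantoms shows: the geometry, normalization,
routing and statistics are implemented correctly against analytically known
ground truth. What they do not show: performance on real EM data — real
nuclei are not spheres, real thickness distributions are continuous rather
than well-separated, real class-conditional feature distributions are
neither Gaussian nor isotropic, and segmentation errors are structured
rather than uniform voxel noise. Dataset-scale accuracy claims require the
real volumes and labels.

## Problem sizes

Defaults used by the test suite and the acceptance script, chosen to keep a
full run a few minutes on one CPU: phantom nuclei at 200–250 nm mesh
resolution (~10 k vertices), voxel phantoms at 64–160 nm resolution,
PSS corpora of 65–150 shapes, 100 spine extractions for the head-assignment
rate, cohorts of 400–600 cells, cascade searches of 5 draws × 3 folds over
two SVM families, and 40–60 random Fisher tables against the enumeration
oracle. All are parameters, not limits.

## Known limitations

* The wrap envelope treats any bridged concavity as fold-bearing; strongly
  non-convex (non-invagination) nuclear shapes will read high.
* Thickness segmentation assumes contrasts of ≥ ~1.35× between compartments;
  smoothly tapering dendrites segment as one piece.
* The deterministic encoder uses ~44 informative dimensions of the 1,024
  latent; distances in latent space are dominated by those dimensions.
* The excitatory re-routing classifier needs labelled excitatory cells with
  PSS features at training time; otherwise re-routing is disabled.
* `match_soma_id` and the filters assume the error/void label is 0.
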