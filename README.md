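# perisoma

Cell-type classification from perisomatic ultrastructure in large-scale
electron-microscopy (EM) connectomics volumes.

Dense EM reconstructions of cortex contain on the order of 10⁵ cells, but
only a small, heavily proofread subset has complete dendrites and axons.
The region around the cell body — the nucleus, the somatic surface within
15 µm of the nucleus centre, and the shapes of postsynaptic compartments
within 60 µm — is reconstructed precisely for nearly every cell, and it
carries enough information to assign cell classes and subclasses at scale.
`perisoma` implements that idea as a reusable pipeline for anyone working
with dense segmentations, nucleus detections and synapse tables: it extracts
perisomatic features, trains a hierarchical classifier cascade, and searches
the feature space for rare connectivity-defined cell types such as
chandelier (axo-axonic) cells.

## The method

**Nucleus features (6).** For each nucleus label, a marching-cubes mesh
(largest component) gives volume *V*, surface area *A* and *A/V*. Nuclear
envelope infoldings are quantified with a *shrink-wrap* mesh — an outer
envelope that bridges the mouths of invaginations — by measuring each
vertex's distance *d* to the wrap: vertices with *d* > 150 nm are inside an
infolding, giving the folded area *A_f* and fold fraction *A_f / A*. Cortical
depth is the distance from a configured pial plane.

**Soma features (7).** The somatic segment is the segmentation id
surrounding > 80 % of the nucleus (one-voxel shell). Its binary mask within
15 µm of the nucleus centre is cleaned by 5-voxel dilation, hole filling and
3-voxel erosion (bridging lost sections, isolating merged fragments), meshed
and reduced to the largest component. Features: soma volume, area, *A/V*,
synapse count and surface density on the cutout, nucleus-to-soma volume
ratio and nucleus–soma centroid offset.

**Postsynaptic shapes (PSS, 120-D).** Around every synapse within 60 µm of
the nucleus centre a 3,500-nm surface cutout is segmented by local thickness
(shape-diameter via shrinking maximal inscribed balls) and reduced to the
postsynaptic compartment — spine head + neck, shaft stretch, or soma patch.
Each shape is pose-normalized, embedded as a 1,024-long latent vector (a
point-cloud autoencoder, or a deterministic classical shape descriptor), and
assigned to one of *k* = 30 dictionary shape types from k-means over a shape
corpus. Counts over 30 shape types × four 15-µm radial bins give the 120-D
spatial shape histogram.

**Normalization.** Size features are divided by their 800-nm z-slab mean
(section-thickness correction; ratios recomputed), then every feature is
independently z-scored across cells (population σ).

**Hierarchical classification.** Five classifiers sort each cell at
increasingly fine distinctions: (1) neuron / non-neuron / error,
(2) non-neuronal subclass (astrocyte, microglia, oligodendrocyte, OPC,
pericyte), (3) excitatory / inhibitory, (4) excitatory subclass (23P, 4P,
5P-IT, 5P-ET, 5P-NP, 6P-IT, 6P-CT), (5) inhibitory subclass (BC, BPC, MC,
NGC) using the PSS block. Each level's model is picked by randomized search
over several families with stratified k-fold CV; predicted errors are not
routed further; inhibitory-routed cells that separate as excitatory-like in
PSS-augmented space are re-routed through the excitatory model. The reported
score is weighted accuracy, Σ_c w_c · recall_c with w_c the class sampling
rate.

**Rare-cell search and targeting statistics.** k-nearest-neighbour queries
(KD-tree, Euclidean) in the standardized feature space propose candidate
cells. For each axon, every output synapse gets an angle φ (0° = directly
above the target soma on the pial side, 180° = directly below) and distance
*r* to the target soma. Synapses with φ ∈ [160°, 180°] and *r* ≤ 60 µm count
as axon-initial-segment (AIS) synapses; a cell with > 40 % AIS synapses is a
chandelier cell. Cells placing ≥ 30 % of outputs onto 5P-NP neurons have the
near-projecting-targeting preference. Enrichment over controls uses the
two-tailed Fisher exact test. Proofreading deltas, 97th-percentile dendritic
radial extents, border-distance truncation estimates and 50-µm-binned
subclass density maps (cells/mm²) round out the analyses.

Because no external dataset is needed to develop or validate the code, the
`perisoma.synthetic` module generates phantoms with analytically known
ground truth: nuclei with planted infolding fractions, voxelized
nucleus-in-soma volumes with planted error voids, lost sections and merged
fragments, spine/shaft/soma-patch shape phantoms, and cohorts with
class-conditional feature distributions and planted chandelier /
NP-targeting axons.

## Worked example

```python
from perisoma.synthetic import NucleusPhantomSpec, make_nucleus_phantom
from perisoma.nucleus import shrink_wrap, fold_features
from perisoma.connectivity import fisher_enrichment

spec = NucleusPhantomSpec(radius_um=5.0, n_folds=4, fold_depth_nm=1500,
                          fold_area_fraction=0.2, seed=1)
mesh, planted = make_nucleus_phantom(spec)
wrap = shrink_wrap(mesh)
fold_area, fold_fraction = fold_features(mesh, wrap)
print(f"planted fold fraction : {planted:.3f}")
print(f"measured fold fraction: {fold_fraction:.3f}")
print(f"fold area             : {fold_area:.1f} um^2")

result = fisher_enrichment(16, 4, 0, 20)
print(f"chandelier enrichment : p = {result.p_two_tailed:.2e}")
```

prints

```
planted fold fraction : 0.190
measured fold fraction: 0.182
fold area             : 61.1 um^2
chandelier enrichment : p = 1.54e-07
```

The phantom nucleus (radius 5 µm) carries four 1.5-µm-deep invaginations
covering a planted 19.0 % of its membrane; the shrink-wrap measurement
recovers 18.2 %. The Fisher test shows that finding 16 chandelier cells
among 20 nearest neighbours, versus 0 among 20 random interneurons, is a
strong enrichment (p ≈ 1.5 × 10⁻⁷).

A command-line interface mirrors the pipeline stages
(`perisoma nucleus / soma / pss / assemble / train / predict / neighbors /
targeting / enrich`); run `perisoma --help` for the file formats.

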