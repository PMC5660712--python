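# Methods

`exmtool` simulates confocal imaging of 20x expansion-microscopy (ExM)
specimens of densely membrane-labeled neural tissue and reconstructs
neuron morphology from the simulated stacks, optionally guided by
error-free cell-identity barcodes. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Forward model

**Ground truth.** Tissue is a dense 3-D label volume on an isotropic 6 nm
grid (`volume.generate_ground_truth`). Neurites are tubes along
persistent random walks (persistence `1 - 0.9 * tortuosity`), dilated to
radii drawn log-uniformly from `radius_range`; a fraction of structures
are ellipsoidal blobs standing in for somata and boutons. Voxels covered
by no tube join the nearest structure (Euclidean distance transform), so
the tissue tiles space with zero extracellular gap by default, as in
cortical neuropil; a configurable gap width exists. Thick structures are
painted first and every skeleton is re-asserted afterwards so thin
processes survive crossings; a guarantee pass ensures each requested
structure owns at least one voxel. Membranes are voxels whose label
differs from any of the six face neighbors; volume faces do not create
membrane.

**Labeling.** Fluorophores are placed per neuron with an areal density
drawn uniformly from 4,000–10,000 puncta/um^2 of membrane (each neuron
draws its own density, reproducing the dim/bright neuron variability of
real data); positions are membrane-voxel centers plus isotropic Gaussian
jitter of SD 20 nm, the combined localization error of a primary plus a
secondary antibody (sqrt(14^2 + 14^2) ~ 20 nm). Cytosolic label
(2,000–4,000 /um^3) and non-specific background (1,000–2,000 /um^3) are
uniform in their compartments with Poisson counts. Each fluorophore
becomes a punctum: a Gaussian cluster with SD drawn uniformly from
1–48 nm. A BrainBow mode assigns each neuron a random point on the RGB
simplex and each fluorophore exactly one channel, multinomially.

**Optics.** The scalar Debye integral gives the focal field
`U(v, u) = (2 pi / lambda) * integral_0^alpha P(theta) J0(v sin(theta)/sin(alpha))
exp(i u sin^2(theta/2) / (2 sin^2(alpha/2))) sin(theta) dtheta`
with aplanatic apodization `P = sqrt(cos theta)`, immersion index 1.33
(water-dipped objective in expanded hydrogel) and normalized coordinates
`v = k r sin(alpha)`, `u = 4 k z sin^2(alpha/2)`, `k = 2 pi n / lambda`.
Gauss–Legendre quadrature starts at order 32 and doubles until the field
changes by < 1e-6 (relative to the on-axis amplitude). The confocal PSF
is `|U_ex|^2 |U_em|^2` (ideal point pinhole), truncated at 4x FWHM per
axis and normalized to unit sum. Defaults: NA 1.15, magnification 40,
lambda_ex 561 nm / lambda_em 590 nm (wavelengths are a package choice for
a red membrane channel; they are configurable). Expansion is ideal and
isotropic: instead of enlarging the specimen 20x, the PSF pitch is
divided by 20. At the defaults the confocal FWHM is ~180 nm lateral /
~560 nm axial, i.e. ~9 x 28 nm in pre-expansion sample units.

**Rendering.** Puncta are deposited on the fine grid with trilinear
(cloud-in-cell) weights; per-point Gaussian spreads are applied in eight
sigma bins (`gaussian_filter` per bin); the field is convolved with the
scaled PSF by FFT with reflective padding; focal planes are sampled every
120 nm (z step) at the 6 nm xy pitch (4.8 um physical pixel pitch / 40x
magnification / 20x expansion). Intensities are scaled so the brightest
pixel's expected photon count is `snr_poisson^2` with `snr_poisson ~
U(7, 12)`, Poisson-sampled, then Gaussian read noise with SD = brightest
expected value / `snr_read`, `snr_read ~ U(50, 100)`, clipped at zero.
All randomized parameters are drawn uniformly over their ranges. All
lengths and densities are pre-expansion.

## Reconstruction

**Boundary detector.** A small sequential ConvNet implemented directly on
numpy: valid-mode convolutions evaluated as one GEMM per kernel offset,
in-plane 2x2 max pooling, ReLU, two fully-connected layers realised as
convolutions, softmax over {boundary, interior} at the patch center.
Training is patch-based SGD (lr 0.001, momentum 0.9, batch 100) on
class-balanced samples with dihedral (flip/rotate) augmentation; an
in-plane (depth-1 kernel) variant is trained first and its weights
initialize the 3-D net (layers whose kernels deepen embed the 2-D kernel
at the central depth slice, preserving the function initially). Two
presets: the full-scale architecture (nine convolutions — the last three
with depth-3 kernels — three pools, two FC layers, 85x85x7 patches
sampling every third slice) and a reduced preset for CPU runs (five
convolutions, one pool, 19x19x5 patches, widths 8-8-12-12-12). Ground
truth for training is the membrane mask max-pooled into each anisotropic
image voxel (the full 120 nm slab by default; a narrower axial window is
available but gives weaker watershed walls, because membranes between
focal planes then carry no label anywhere).

Dense inference is sliding-window equivalent: pooling becomes a stride-1
max filter and downstream kernel offsets dilate by 2 per pool (the
shift-and-stitch construction), verified voxel-exact against patchwise
evaluation. Inference runs in three orientations (xy, and the
transposed-volume net applied with the thin axis along y and along x);
the final boundary probability map (BPM) is the voxelwise median of the
three, followed by a 3x3x3 median filter. At the reduced scale the
transposed orientations are individually weaker (the 120 nm z pitch
becomes a lateral axis) yet they supply the z-direction walls the xy net
cannot see between focal planes; the median ensemble gives markedly
better watershed behavior than the xy map alone.

**Watershed.** The BPM is treated as a landscape: H-minima suppression at
depth T = 0.01 (morphological reconstruction), then a 6-connected seeded
watershed from the surviving regional minima (scikit-image; its queue
order is deterministic, so results are bit-reproducible).

**Learned agglomeration.** A region graph over supervoxels carries, per
body and per contact interface, additive sufficient statistics (voxel
count; raw moment sums to order four; 10-bin histogram counts) of the BPM
and the globally normalized image — merging two regions adds the
statistics, so features after any merge are exact and O(1). The feature
vector per candidate edge is: moments + histogram over the interface, the
elementwise min and max of the two body blocks (making it symmetric under
swapping the pair), and the log contact area (85 features). The merge
policy is a 100-tree random forest trained by iterative agglomerative
learning: in each round every current edge contributes an example labeled
by whether the two bodies share the same majority ground-truth label, and
all true merges are applied before the next round (3 rounds). Greedy
agglomeration by ascending cost = 1 - P(merge) (lazy-invalidation heap)
records every merge into a hierarchy whose node thresholds are made
non-decreasing toward the root; levels at the nine thresholds 0.1–0.9
are nested coarsenings.

**Barcode consolidation.** Barcodes are uniform random points with
identity equal to the true parent neuron (error-free readout). A barcode
is assigned to the supervoxel containing it unless it lies within 30 nm
of a supervoxel boundary. That distance combines a per-slice in-plane
Euclidean distance transform (exact to a few nm at the 6 nm pitch) with
the continuous distance to the nearest z face across which the label
changes: on a 120 nm z grid the face position, not the voxel center, is
the physically meaningful boundary, and a voxel-center distance would
declare every supervoxel thinner than three slices to be all boundary
and silently drop nearly every barcode. Selection then finds the highest
nodes whose subtrees contain at most one distinct identity, starting from
the tree's top level — the 0.9-threshold partition, since the hierarchy
is built with thresholds up to 0.9 (starting from an all-merging root is
available via `top_threshold=None`, but with sparse barcodes it lets a
near-root node with one observed identity swallow the volume). Selected
nodes become segments; segments sharing an identity merge into one label
even when spatially disconnected; zero-barcode nodes keep their own
labels and never merge across.

## Evaluation

Foreground-restricted Rand and information-theoretic scores from the
contingency table `n_ij` between prediction X and truth Y:
Rand split = sum n_ij^2 / sum_i (row_i)^2, Rand merge = sum n_ij^2 /
sum_j (col_j)^2; VI split = I(X,Y)/H(X), VI merge = I(X,Y)/H(Y); each
F-score is the harmonic mean of its pair. Natural logs (the ratios are
base-invariant); 0 log 0 = 0. Restriction drops voxels on the
ground-truth membrane (6-connectivity). The printed conventions are kept
literally: a strict over-segmentation scores a perfect Rand *split* and a
perfect VI *merge*. A single-segment side makes the VI ratios undefined;
strict callers get an error, scanning callers (hierarchy levels, density
sweeps) record NaN. All scores are validated against an independent
brute-force implementation to 1e-12.

## Problem sizes and seeds

Three presets set the problem size; all stochastic stages derive their
generators from the master seed plus a stage tag, so runs are
bit-reproducible end to end.

| preset | ground truth | train/test images | detector | typical use |
|---|---|---|---|---|
| `full` | 500^3 at 6 nm (~3 um)^3, 60 neurites r 50–400 nm | 3 volumes x 4 + 1 | 9-conv | full-scale conditions (needs far more compute) |
| `ci` | 320x128x128 (1.9 x 0.77 x 0.77 um) , 18 neurites r 50–200 nm | 2 x 2 + 1 | 5-conv | the acceptance script |
| `mini` | 240x96x96, 12 neurites r 50–160 nm | 1 x 2 + 1 | 5-conv | multi-seed checks |

The reduced volumes keep the 6 nm grid, the 120 nm z step and every
density/noise range of the imaging model; only the field of view,
neurite count/caliber and the network size shrink. Neurite radii were
chosen so tubes fit the smaller fields while retaining thin processes
that stress the z anisotropy.

## What the synthetic experiments show — and what they do not

The generator emulates dense packing, caliber variation, per-neuron
labeling variability, puncta statistics, realistic SNRs and the severe
z-anisotropy of confocal ExM. It does not emulate realistic branching
statistics, organelles, expansion distortion fields, photobleaching, or
barcode readout errors (explicitly assumed error-free).

At the reduced problem sizes, the pipeline reproduces the qualitative
structure of the full-scale findings: the agglomeration curve dominates
the raw watershed sweep, and barcode consolidation improves monotonically
with barcode density. Two quantitative caveats are inherent to the scale
reduction. First, absolute F-scores (~0.85–0.95 Rand without barcodes at
the `ci` size) sit below the full-scale report, driven by detector
capacity and training data. Second, the 30 nm boundary exclusion removes
~90% of barcodes when supervoxels are only ~80 nm across, as they are
with the small detector; in that starved regime consolidation can sit
slightly below the agglomeration curve at matched merge score, whereas
with well-resolved supervoxels (e.g., a ground-truth boundary map as the
BPM) the same code shows the expected dominance and saturating gains.
Conclusions about real data should rest on the `full` preset.

## Known limitations

- Scalar (non-vectorial) PSF, ideal pinhole, no index-mismatch
  aberrations.
- The agglomeration recomputes no long-range features; interfaces are
  voxel-face sets only.
- `resample_isotropic` is nearest-neighbor by design (labels must not be
  interpolated).
- The exclusion distance slightly over-excludes near oblique in-plane
  boundaries (voxel-center evaluation, error of a few nm).
- Barcode identity is a single integer; sequence-level modeling and
  erroneous-readout handling are out of scope.
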