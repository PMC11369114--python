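# Methods

`odorvs` implements a pipeline that asks whether a molecule's vibrational
spectrum predicts its odor: spectra are turned into fixed-length
descriptors and field images, a cost-sensitive multi-label classifier maps
them to odor notes, clustering relates spectral similarity to odor
composition, and two explainability methods check that the models attend
to physically meaningful wavenumber regions. Everything runs end-to-end on
synthetic data with known ground truth.

## Spectral descriptor (GS_VS)

A spectrum arrives as a sparse peak list (wavenumber in cm⁻¹, intensity ≥ 0).
It is projected onto a bounded frequency scale (BFS), a dense 1 cm⁻¹ grid
over 1–4000 cm⁻¹ — the range covering the vibrational normal modes of
typical odorants — by depositing each peak's intensity at the nearest grid
point (rounding error ≤ 0.5 cm⁻¹, far below the kernel width). The dense
spectrum is convolved with a normalized Gaussian kernel

    K(x) = 1/(σ√(2π)) · exp(−(x − x̄)² / 2σ²),   σ = 10 cm⁻¹,

truncated at ±5σ (relative mass error < 3·10⁻⁷). Broadening lets molecules
with slightly shifted modes be compared on a common grid. The smoothed
spectrum is normalized and sampled every L = 5 cm⁻¹ at grid points
L, 2L, …, 4000, giving exactly 4000/L = 800 descriptor values.

Normalization divides by the spectrum maximum, so values lie in [0, 1].
The polar mapping used by the Gramian encodings (below) needs an arccos
argument in [0, 1], which makes max-normalization the self-consistent
choice; unit-area normalization is available via
`SmoothingParams(normalization="area")` for users who want intensities on
a comparable absolute scale.

Molecular fingerprints are Daylight-style hashed path fingerprints
(1024 bits, RDKit), which outperform circular fingerprints on odor data;
Morgan/ECFP4 (2048 bits, radius 2) is provided as a non-default
alternative. Precomputed 0/1 tables are accepted so RDKit stays an
optional dependency.

## Field images (GASF / GADF / MTF)

The 800-point descriptor is reduced to 224 points by piecewise aggregate
approximation (PAA) with fractional-boundary weighting — the mean is
preserved exactly and a divisible length reduces to block means. PAA is
applied to the series *before* field computation (not to the matrix
afterwards) so the polar-mapping semantics are preserved. The reduced
series Y is mapped to angles θᵢ = arccos(Yᵢ) ∈ [0, π/2] and expanded into

* **GASF** `cos(θᵢ + θⱼ)` — symmetric, diagonal 2Yᵢ² − 1, so the series is
  recoverable from the diagonal (the mapping is bijective);
* **GADF** `sin(θᵢ − θⱼ)` — antisymmetric, zero diagonal;
* **MTF** — the series is binned into Q quantile bins (default Q = 8;
  quantile rather than uniform binning avoids empty bins on the strongly
  skewed spectra; bins never visited get a uniform row and are flagged),
  a row-stochastic transition matrix Z is estimated from consecutive
  pairs, and the field is N_kl = Z[bin(x_k), bin(x_l)].

The three 224 × 224 fields are stacked as channels (GASF, GADF, MTF) and
min-max rescaled to [0, 1] per channel; the affine ranges are stored in
the image metadata so the raw fields remain recoverable. Flattened image
features (VS_IMG) come from a fixed-seed random-projection convolutional
encoder (two strided ReLU conv layers, 4624 features) that needs no
pretrained download; any callable accepting a 224 × 224 × 3 array — e.g.
a pretrained ResNet50 — can be plugged in instead.

## Multi-label splitting

Iterative stratification (greedy Sechidis-style): labels are processed
from rarest to most frequent and each remaining sample is assigned to the
split whose proportional quota for that label is largest; ties break by
larger remaining capacity, then a seeded shuffle. On the default
imbalanced conditions (top note ≈ 27–31% of molecules, rarest < 1%) the
mean per-label train/test frequency gap is ≈ 4–5× smaller than under
random splitting. Representativeness of one frequency vector against
another is quantified by the two-sample Kolmogorov–Smirnov test
(`scipy.stats.ks_2samp`).

## Cost-sensitive classifier (CSMLP)

A fully connected network (ReLU hidden layers sized from the input
dimension, dropout 0.3, sigmoid outputs, Adam, 100 epochs, batch 64)
minimizes the combined loss

    CL = WBCEL + λ·FL

with per-class complementary weights w_pos_j = (#negatives of j)/n,
w_neg_j = (#positives of j)/n (so each class's pair sums to 1 and rare
classes get positive-term weights near 1), smoothing exponent δ on the
weights, and focal modulating factors (1 − p)^γ / p^γ. After every epoch
the micro-F1 on the evaluation split is recorded and the weights from the
best epoch are restored at the end. Epoch selection on the test split
mirrors common practice in small-data studies, but a held-out validation
split is the statistically safer choice when enough data exists — pass a
split whose "test" indices are a validation set to get exactly that.

Loss defaults are γ = 2 (the standard focusing value), δ = 1 (full
complementary-frequency weighting) and λ = 0.1. The focal term is
class-unweighted, so a large λ re-symmetrizes the cost of positive and
negative errors and cancels the class weighting — measured on the default
skewed conditions, δ = 0.5 or λ = 1 leave minority-class recall at zero,
indistinguishable from plain BCE. Keeping the weighted term dominant and
the focal term as a mild hard-example refinement preserves the
cost-sensitivity the loss exists for; all three parameters are
config-exposed. All losses reduce over classes by summation and over
samples by the mean, are validated against brute-force per-element
accumulation to 10⁻¹⁰, and collapse to plain BCE at γ = δ = λ = 0 (up to
the ε = 10⁻⁷ stability constant).

The fusion path PCA-reduces image features to min(3036, feasible)
components and fingerprints to the smallest component count reaching a
target explained variance (default 85%, sweepable 70–95%), fitting both
PCAs on training rows only and concatenating column-wise.

## Embedding, clustering, composition

2-D embeddings: PCA, t-SNE (perplexity 30, PCA initialization), UMAP
(n_neighbors = 15, min_dist = 0.1) and MDS, all seeded. Clustering on the
2-D coordinates: k-means (10 restarts) and agglomerative clustering with
Ward linkage on Euclidean distances; cluster labels are canonicalized by
decreasing size. Diagnostics: the elbow curve (k-means inertia per k) and
the mean silhouette score. Cluster composition uses two exact
integer-ratio percentages per (cluster, note):

    %ON = 100 · (occurrences of the note in the cluster) / (total occurrences of the note)
    %OM = 100 · (occurrences of the note in the cluster) / (cluster size)

whose numerators sum over clusters to each note's dataset total.
Functional-group profiles count RDKit fragment descriptors (fr_*, ~85
substructures) per cluster, filtered to groups reaching 5% in at least
one cluster.

## Explainability

**Permutation feature importance** permutes one feature column at a time
and reports the error change; the default sign is e_perm − e_orig so
informative features score positive (a flag emits the opposite
orientation). The error function defaults to the combined loss; any
(y, p) → scalar callable works. Constant columns are reported as exactly
zero. Importances on the 800-point grid map directly to wavenumbers;
2-D saliency maps are reduced to a wavenumber profile by column means.
Top-ranked features are reported as contiguous wavenumber intervals.

**GradCAM++** weights the last convolutional layer's activation maps φ_k
by w_k = Σᵢⱼ α_kij · relu(∂Y/∂A_kij), with the closed-form
α = g² / (2g² + ΣA·g³) evaluated for Y = exp(score) (the canonical
Chattopadhay et al. formulation; a published transcription with pairwise
activation products is nonstandard and not used), then applies
ReLU(Σ_k w_k φ_k), bilinear upsampling to 224 × 224 and min-max
rescaling. Because the published classifier operates on flattened
pretrained features without accessible conv maps, saliency attaches to a
small end-to-end CNN (`SmallCNN`: two strided conv layers, a dense head
on the flattened 17 × 17 × 16 map, decoupled L2 decay and dropout on the
head). The dense head is deliberate: with global average pooling the
network is translation-invariant and cannot separate classes that differ
only in band position.

A geometric caveat governs the saliency ground-truth test: in a Gramian
field image, evidence at series positions [a, b] occupies the *cross
region* — rows [a, b] and columns [a, b] in full — not an isolated
quadrant, because every band generates full-length row/column stripes.
The recovery experiment therefore generates single-label molecules whose
peaks all lie inside the class band, and scores the fraction of
top-decile saliency mass inside the band's cross region (~23–26% of the
image); values of 67–80% (≈3× enrichment over area) indicate the model
attends to the generating band.

## Synthetic data

The generator emulates the statistical structure of expert-annotated odor
datasets. Note frequencies decay as rank^(−s) with s = 0.8; the number of
notes per molecule is truncated-geometric with mean 3; at the default
3000 molecules × 109 notes the most frequent note covers ≈ 27–31% of
molecules and the rarest < 1%. Each note is tied to a wavenumber band
cycled from an IR-motivated catalogue (carbonyl-like 1600–1800 cm⁻¹,
C–H stretch 2850–3100 cm⁻¹, O–H 3200–3600 cm⁻¹, …, with shifted
sub-windows when classes outnumber catalogue regions), a molecule's peaks
are drawn from its positive notes' bands plus a uniform-background share
(default 70% of the peak budget — functional-group modes plus
skeletal/background modes), and intensities are exponential with mean 50.
One global seed drives all draws through named, crc32-keyed substreams,
so generation is reproducible across processes.

What the generator does *not* emulate: real note co-occurrence structure
(notes are drawn independently given the count), anharmonic shifts,
intensity correlations within a molecule, or instrument noise. Passing
tests therefore show that each pipeline stage behaves correctly under the
assumed band-to-odor model, not that vibrational spectra predict human
odor ratings.

## Problem sizes and numerical choices

The shipped experiments (`odorvs.experiments`, also run by
`scripts/acceptance.py`) use sizes chosen to finish in minutes on one
CPU: the split comparison uses 3000 molecules × 109 notes over 20 seeds;
the minority-recall comparison 1000 molecules × 20 notes over 3 paired
seeds at 100 epochs; the band-recovery experiments a 600-molecule ×
4-note dataset for PFI (80 epochs, 5 permutation repeats) and 120
constructed-evidence images for GradCAM++ (15 epochs). Determinism: all
randomness flows from explicit integer seeds; k-means uses 10 restarts;
quantile-bin edge ties merge bins; the all-zero spectrum, out-of-range
peaks, degenerate splits and k > n clustering all raise informative
errors rather than propagating NaNs.

## Known limitations

* The NumPy networks are small by design; they demonstrate the loss and
  saliency machinery, not state-of-the-art accuracy. Any framework model
  exposing `predict_proba` (and, for GradCAM++, last-conv activations and
  gradients) can be substituted.
* Micro-F1-based epoch restoration on the evaluation split leaks label
  information when that split is also the final test set; prefer a
  three-way split for unbiased estimates.
* GradCAM++ localization is limited by the translation equivariance of
  convolutions: classes distinguished *only* by band position with
  identical local appearance localize less sharply than classes with
  distinct spectral textures.
* The %ON/%OM statistics are descriptive; no significance test is
  attached to cluster-note associations.
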