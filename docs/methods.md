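# Methods

## Scope and data model

`gelclust` analyzes series of 2DE gel images (or pre-extracted spot
lists) qualitatively: each gel is reduced to a binary vector over a
master spot universe, and all between-sample inference happens on
presence/absence. Quantitative (normalized intensity) information is
kept alongside for replicate quality control and for testing intensity
differences of spots shared between clusters, but it never drives the
clustering — silver-stain intensities are too irreproducible for that.

The five analysis stages and the synthetic-data generator are described
below with their assumptions, defaults and numerical choices.

## Spot detection

Detection is scale-normalized Laplacian-of-Gaussian blob detection.
The polarity-corrected image (spots bright, background near zero) is
filtered with `σ² · (−∇²G_σ)` at `n_scales` sigmas spaced geometrically
in `[sigma_min, sigma_max]` (defaults 2–10 px, 8 scales). Candidates are
strict local maxima of the 3-D (scale, y, x) response stack exceeding
`threshold_rel` (default 0.1) times the global maximum response; they
are accepted greedily by descending response, discarding any candidate
whose center lies within `√2·σ` of an accepted spot. `√2·σ` is the
zero-crossing radius of the LoG kernel at the detected scale, and the
same radius defines the spot's region: a disk clipped to the image
bounds. The spot's raw intensity is the plain pixel sum over that
region.

Numerical choices:

- **Polarity correction** anchors the baseline at the observed extremum:
  `max − pixel` for dark-spots-on-light images (silver stain on a
  densitometer scan, the default), `pixel − min` for light-on-dark.
  Anchoring both polarities at the observed baseline makes inversion an
  exact involution (inverting an image and flipping the flag yields the
  identical spot list) and keeps raw intensities exactly equivariant
  under rescaling the image by a positive constant. The cost is that
  "sum of pixels" is background-anchored rather than absolute; since
  all downstream use is per-gel normalized, only the anchoring
  convention matters.
- A **noise floor** guard treats a response below `1e-9 ×` the image's
  dynamic range as zero, so constant images return no spots instead of
  amplifying the separable filter's rounding residue.
- Images smaller than the largest filter support (`8·sigma_max + 1`)
  are rejected.
- Relative (not absolute) thresholding makes detection invariant to
  image rescaling; the threshold that trades recall against false
  maxima from pixel noise scales with the ratio of the weakest true
  spot to the strongest — 0.1 is appropriate when spot amplitudes span
  less than a decade.

Manual spot curation is supported as a CSV patch (add/delete rows)
applied to a detected spot list; interactive editing is out of scope.

## Matching and matrix assembly

Each gel's spot list is matched to a designated master gel by **mutual
nearest neighbors** within a pixel `tolerance` (default 5 px), accepted
greedily by ascending distance with ties broken by ascending spot id —
fully deterministic, and one-to-one by construction. Coordinates are
0-based pixel centers; distances are Euclidean.

An optional **pre-registration** estimates a similarity transform
(translation + rotation + scale) by best-of-N two-point minimal samples
scored on inlier count, refined by least squares on the inliers. It is
off by default: spot lists produced from images in a common scanner
frame (or from the simulator) are already aligned, and an automatic
transform should never silently distort aligned data.

The binary matrix's columns are the master's spots plus, optionally,
**union columns**: an unmatched gel spot opens a new column only when
unmatched spots from ≥ 2 distinct gels co-locate within tolerance
(greedy centroid agglomeration, iterated in gel order then spot order).
This explains how a spot universe can exceed any single gel's count
without inflating the matrix with singleton noise; a master-only mode
is available. Intensities in the companion matrix are per-gel raw sums
normalized by the gel's total over all column-assigned spots; cells
without an assigned spot are missing (NaN), never zero.

## Replicate quality control

All statistics operate on replicates-by-spots normalized intensity
matrices with NaN for non-detected spots:

- **Pearson r** between two runs is computed over the common-presence
  subset only (no zero-imputation), requiring ≥ 3 shared spots. The
  mean over replicate pairs is reported with a `1.96·SD/√(#pairs)`
  half-width (the mean ± 95% CI convention).
- **Q–Q points** pair order statistics after interpolating both samples
  to a common length (plotting positions `(i−0.5)/m`).
- **Per-spot CV** is sample SD (n−1 denominator, appropriate for the
  typical 3–4 replicates) over mean, computed for spots present in all
  replicates.
- **Consensus counts** tally spots present in ≥ k replicates for each k.
- **Abundance classes** use boundaries 0.02 / 0.04 / 0.1 relative
  units, left-closed (a value of exactly 0.02 falls in the second
  class).
- Spot-count summaries report integer-rounded mean ± sample SD.

## Clustering and partition comparison

The distance between gels is the **Hamming distance** (bit-difference
count). Agglomeration is **Ward's method** through the Lance–Williams
recurrence

    D(i∪j, k) = [(n_i+n_k) D(i,k) + (n_j+n_k) D(j,k) − n_k D(i,j)] / (n_i+n_j+n_k)

applied to the input distances as given — the `ward.D` convention that
was the default in the hierarchical-clustering implementations of the
R ecosystem this workflow originated in. The `ward.D2` variant (squared
inputs, square-root heights) is available by flag; on generic point
clouds it reproduces scipy's Ward linkage. Ties in the minimum
inter-cluster distance (within 1e-9 relative, covering float error in
exactly tied rational costs) are broken by the lexicographically
smallest cluster-id pair, making the merge sequence deterministic
across platforms. For 0/1 vectors the Hamming distance equals the
squared Euclidean distance, so `ward.D`-on-Hamming is classic Ward on
the binary vectors; the test suite exploits this with an exact rational
centroid-based brute-force oracle.

`cut_tree` undoes the last k−1 merges and labels clusters 1..k in order
of first sample appearance, so cuts are reproducible. **Silhouette
widths** `(b−a)/max(a,b)` come straight from the distance matrix with
singleton clusters assigned width 0. Because no distributional theory
is attached to the mean silhouette of a dendrogram cut, cluster
validity is assessed by a **label permutation test**: shuffle the
labels (preserving cluster sizes) `n_perm` times and report
`p = (1 + #{permuted mean ≥ observed}) / (n_perm + 1)`. This is a
pragmatic stand-in for an unspecified historical procedure, not a
reconstruction of it.

Partitions are compared with the **Hubert–Arabie adjusted Rand index**
computed from the pair-count contingency table. The comparison object
carries the full-precision value plus a 2-decimal rounding. For the two
published 18-sample HLC partitions (contingency [[10, 1], [1, 6]]) the
adjusted index is 0.5817 → 0.58; the unadjusted Rand index of the same
pair is 121/153 ≈ 0.79, so the historically reported 0.58 is the
*adjusted* form,
and that is what this package reports.

## Differential spots

Cluster-exclusive spots are called by presence frequency: spot j is
exclusive to cluster c iff its frequency is ≥ `tau_present` in c and
≤ `tau_absent` in every other cluster. The defaults (1.0 / 0.0) encode
the strict "present only in one cluster" rule; relaxing them tolerates
detection noise, and the exclusive lists can only grow as the
thresholds relax.

Intensity differences of shared spots use **Welch's unequal-variance
t-test** — cluster sizes are typically unequal (e.g. 11 vs 7) and no
variance homogeneity is assumed — on spots present in at least
`min_presence` (default 3) gels of each cluster, with absent spots
treated as missing, never imputed as zero. P-values are
**Bonferroni**-corrected over the number of tested spots, and the
cluster-mean fold change is reported at full precision (1-decimal
rounding for display).

## Synthetic data generator

The generator's defaults encode the 18-gel HLC study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_spots_universe` | 389 | master spot universe (matrix columns) |
| `cluster_sizes` | [11, 7] | gels per planted cluster |
| `shared_spot_fraction` | 0.66 | universe fraction present in every prototype (~257 spots, so per-gel counts land near the observed ~271 average) |
| `specific_spot_counts` | [3, 12] | planted cluster-exclusive spots |
| `flip_rate` | 0.02 | per-bit toggle probability per gel |
| `intensity_class_fractions` | 0.96/0.02/0.01/0.01 | abundance classes <0.02 / 0.02–0.04 / 0.04–0.1 / >0.1 |
| `replicate_cv` | 0.5 | target per-spot CV across technical replicates |
| `replicate_dropout` | 0.15 | per-replicate non-detection probability |
| `psf_sigma` | 3 px | Gaussian spot width in rendered images |

Cluster prototypes share the `shared_spot_fraction` backbone and differ
only in their disjoint exclusive sets; each gel copies its prototype
and flips bits independently. Spots outside the backbone and the
exclusive sets stay absent from prototypes and enter gels only through
flips — mirroring how a union spot universe exceeds any single gel's
count.

**Intensity model.** Present spots are assigned to abundance classes by
largest-remainder stratified allocation at the configured fractions
(rather than a raw multinomial draw — the rare >0.1 class carries ~35%
of a gel's total intensity, and stratifying its count keeps the per-gel
renormalization factor within a few percent of 1 so class membership
survives normalization). Values are drawn from lognormals whose medians
sit at the geometric centers of classes 2–4 (0.0283, 0.0632, 0.13; σ =
0.10/0.15/0.20, clipped inside class margins); the class-1 median
adapts per gel so the expected total is 1. Each gel is then renormalized
to sum exactly 1. The only unprinted class fraction (0.04–0.1) defaults
to 0.01 so the four fractions close to 1 — an inference, flagged here.

**Replicates** multiply each present spot by lognormal noise with
`σ = √log(1 + CV²)` (mean 1, coefficient of variation `replicate_cv`),
drop it with probability `replicate_dropout`, and renormalize. With the
default CV 0.5, the median per-spot CV lands in [0.4, 0.6] and most
spots fall below the CV < 0.6 benchmark.

**Images** are a constant background plus isotropic Gaussian bumps
(truncated at 5σ, mass error < 1e-5) plus optional white noise, clipped
at zero; spot centers are rejection-sampled uniformly with a minimum
separation of `3·psf_sigma` inside a `4·psf_sigma` margin, avoiding the
pathological overlaps a manual analysis would have resolved by hand.
Rendering can emit either polarity.

**What the generator does not emulate.** Streaks, background gradients
and pH-gradient warping; the large between-gel spot-count spread of
real series (per-gel counts concentrate near the mean; the observed
±99 SD is not reproduced); the cluster-wise spot-count asymmetry
(~219 vs ~342) of the real data; and replicate correlations in the
0.7–0.8 range — per-gel renormalization cancels correlated noise on
the dominant spots, so simulated replicate Pearson r runs higher
(~0.9) than on real silver stains at the same per-spot CV. Passing
tests therefore demonstrate algorithmic correctness on structured data,
not robustness to every artifact of real gels.

**Determinism.** A `SimulationConfig` seed fixes every artifact
bit-for-bit; intensity and replicate draws use child streams of the
same seed.

## Test-suite design and problem sizes

The differential power check simulates the published effect regime —
cluster means 0.0174 vs 0.0114 (1.5-fold), 11 vs 7 gels — with additive
Gaussian noise of SD 0.3 × the reference (lower) cluster mean in both
clusters, giving Welch power ≈ 0.93 at α = 0.05; the test requires
rejection in ≥ 80% of 200 seeds. Family-wise error control is checked
over 500 null datasets of 18 gels × 50 spots. Partition recovery runs
100 seeds of the full 18 × 389 default configuration; the Ward oracle
covers 200 random binary matrices with n ≤ 8 in exact rational
arithmetic; the detection benchmark plants 200 spots on a 512×512
image at SNR 10 and up. These sizes keep the full suite around a minute
on one core while leaving each check statistically meaningful.

## Known limitations

- Matching assumes a similarity transform suffices; elastic/warp-field
  gel registration is out of scope.
- Union-column assembly is order-dependent (greedy); with the default
  deterministic iteration order the result is reproducible, but it is
  not a global optimum.
- The permutation validity test conditions on the observed cluster
  sizes; it does not account for the selection effect of cutting the
  dendrogram at the best-looking k.
- `ward.D` heights on non-Euclidean-compatible distance matrices have
  no within-cluster-variance interpretation; they are still monotone
  and deterministic.
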