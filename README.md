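# gelclust

Analysis pipeline for two-dimensional electrophoresis (2DE) gel images:
detect protein spots, match them across gels to a master gel, reduce the
series to a binary presence/absence matrix, cluster the gels, and call
cluster-specific spots.

2DE separates a proteome by isoelectric point and molecular weight,
yielding one spot image per sample. Spot *intensities* on silver-stained
gels are poorly reproducible between runs, but spot *presence* is robust —
so samples can be compared qualitatively: gel *i* becomes a binary vector
with `d_ij = 1` when master spot *j* is present. `gelclust` implements
this workflow end to end for studies of the kind that motivated it: an
18-sample human liver cytosol (HLC) series whose gels split into two
clusters (11 + 7) that mirror an independent biochemical (cytochrome
P450 activity) partition of the same patients.

## Method

1. **Spot detection** — scale-normalized Laplacian-of-Gaussian (LoG) blob
   detection: local maxima of `σ² · (−∇²G_σ ∗ I)` over a geometric ladder
   of scales, above a relative threshold, with greedy overlap
   suppression. A spot's intensity is the sum of polarity-corrected
   pixels over a disk of radius `√2·σ`; per-gel intensities are
   normalized by the total over matched spots.
2. **Matching** — mutual nearest neighbors within a pixel tolerance
   against a master gel (optionally after similarity pre-registration),
   assembled into the binary matrix **D** (gels × spots) and a normalized
   intensity matrix.
3. **Clustering** — Ward's minimum-variance agglomeration on pairwise
   Hamming distances via the Lance–Williams recurrence
   (`ward.D` convention; `ward.D2` by flag), cut at *k* clusters;
   validity via silhouette widths `s(i) = (b−a)/max(a,b)` and a
   label-permutation test.
4. **Partition comparison** — the Hubert–Arabie adjusted Rand index
   (ARI) from the pair-count contingency table; 1 = identical
   partitions, ≈0 = chance.
5. **Differential spots** — cluster-exclusive spots by presence
   frequency thresholds (strict by default: present in every gel of one
   cluster, absent from all others), and Welch *t*-tests with Bonferroni
   correction on normalized intensities of shared spots.

A synthetic-data module generates binary matrices, intensity matrices
and rendered gel images with planted cluster structure and full ground
truth, so every stage is testable without raw scans.

## Worked example

```python
import gelclust as g
from gelclust.reference import proteomic_partition, biochemical_partition

# 18 synthetic gels, 389-spot universe, planted 11 + 7 clusters,
# 2% bit-flip noise
config = g.SimulationConfig(flip_rate=0.02, seed=42)
binary, truth = g.simulate_binary_dataset(config)

dm = g.hamming_matrix(binary)
dend = g.ward_linkage(dm)              # ward.D on Hamming distances
part = g.cut_tree(dend, k=2)
widths, mean_w = g.silhouette(dm, part)
p_value, _ = g.permutation_validity_test(dm, part, n_perm=999, seed=0)
print("cluster sizes:", sorted(part.labels.count(l) for l in set(part.labels)))
print(f"mean silhouette width: {mean_w:.3f}  (permutation p = {p_value:.4f})")
print(f"recovery ARI: {g.adjusted_rand_index(part, truth.true_partition).adjusted_rand:.2f}")

# concordance of the two published 18-sample partitions
comp = g.adjusted_rand_index(proteomic_partition(), biochemical_partition())
print(f"published-partition ARI: {comp.adjusted_rand:.4f} -> {comp.adjusted_rand_2dp:.2f}")

# cluster-specific spots (frequency thresholds tolerate the flip noise)
exc = g.cluster_specific_spots(binary, part, tau_present=0.85, tau_absent=0.15)
print("exclusive spots per cluster:", {l: len(df) for l, df in exc.items()})
```

Output:

```
cluster sizes: [7, 11]
mean silhouette width: 0.477  (permutation p = 0.0010)
recovery ARI: 1.00
published-partition ARI: 0.5817 -> 0.58
exclusive spots per cluster: {1: 3, 2: 12}
```

The planted 11/7 structure is recovered perfectly (ARI 1.0 against the
generating truth; the two-cluster cut is significant under the
permutation null), and the two published partitions — which disagree on
exactly two of the 18 samples — agree at ARI 0.58, well above chance.
The relaxed presence thresholds recover the planted 3 and 12
cluster-exclusive spots exactly.

The same pipeline runs from the shell:

```bash
gelclust simulate --seed 42 --n-images 3 --outdir sim/
gelclust detect sim/gel01.tiff --polarity dark-on-light --out spots.csv
gelclust cluster sim/binary_matrix.csv --k 2 --outdir clu/
gelclust compare clu/partition.csv sim/true_partition.csv
gelclust diff sim/intensity_matrix.csv clu/partition.csv --outdir diff/
```

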