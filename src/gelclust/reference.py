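"""Published benchmark inputs from the 18-sample human liver cytosol
(HLC) 2DE study the pipeline defaults are modeled on.

These are *inputs* (printed partitions, replicate spot counts and cluster
mean intensities); every derived statistic — the adjusted Rand index, the
spot-count summary, the fold change — is recomputed by the package at run
time.  Sample 4 was excluded from the original series as an outlier, so
the sample set is 1-3, 5-19 (18 samples).
"""

from __future__ import annotations

from .cluster import Partition

__all__ = [
    "hlc_sample_ids",
    "proteomic_partition",
    "biochemical_partition",
    "REPLICATE_SPOT_COUNTS",
    "SPOT_210_CLUSTER_MEANS",
]

#: Spot counts of the four technical replicate runs of the master sample.
REPLICATE_SPOT_COUNTS = (449, 420, 444, 406)

#: Normalized intensity of spot #210 (ALDH1): cluster 1 mean, cluster 2 mean.
SPOT_210_CLUSTER_MEANS = (0.0174, 0.0114)

_SAMPLES = [1, 2, 3] + list(range(5, 20))

# 2DE gel clustering: cluster 1 = gels 1-3, 5, 7-13; cluster 2 = 6, 14-19.
_PROTEOMIC_CLUSTER_1 = {1, 2, 3, 5, 7, 8, 9, 10, 11, 12, 13}

# Enzyme-activity clustering of the matching microsomal fractions:
# cluster 1 = samples 1-3, 5-12; cluster 2 = samples 13-19.
_BIOCHEMICAL_CLUSTER_1 = {1, 2, 3, 5, 6, 7, 8, 9, 10, 11, 12}


def hlc_sample_ids() -> list[str]:
    return [str(s) for s in _SAMPLES]


def proteomic_partition() -> Partition:
    """Two-cluster partition of the 18 gels from presence/absence
    clustering (Ward on Hamming distances)."""
    labels = [1 if s in _PROTEOMIC_CLUSTER_1 else 2 for s in _SAMPLES]
    return Partition(hlc_sample_ids(), labels)


def biochemical_partition() -> Partition:
    """Two-cluster partition of the same 18 samples from cytochrome
    P450-dependent enzyme activity profiling."""
    labels = [1 if s in _BIOCHEMICAL_CLUSTER_1 else 2 for s in _SAMPLES]
    return Partition(hlc_sample_ids(), labels)
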