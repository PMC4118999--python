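"""Cluster-specific spot calling and intensity difference testing.

Qualitative differences: a spot is exclusive to a cluster when its
presence frequency is at least ``tau_present`` there and at most
``tau_absent`` in every other cluster (defaults 1.0 / 0.0, i.e. strictly
present in every gel of one cluster and absent from all others).

Quantitative differences: spots detected in enough gels of both clusters
are tested with Welch's unequal-variance t-test on normalized intensities
(absent spots are missing, not zero), with Bonferroni correction over the
number of tested spots, and the cluster-mean fold change is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import Partition

__all__ = [
    "DifferentialReport",
    "cluster_specific_spots",
    "intensity_difference_test",
    "fold_change",
]


@dataclass
class DifferentialReport:
    cluster_exclusive: dict[int, pd.DataFrame]  # label -> spots with frequencies
    tested_spots: pd.DataFrame
    parameters: dict


def _check_samples(matrix: pd.DataFrame, p: Partition) -> None:
    mat_samples = set(map(str, matrix.index))
    part_samples = set(map(str, p.sample_ids))
    if mat_samples != part_samples:
        raise ValueError(
            "partition and matrix sample sets differ; "
            f"matrix only: {sorted(mat_samples - part_samples)}; "
            f"partition only: {sorted(part_samples - mat_samples)}"
        )


def cluster_specific_spots(
    binary: pd.DataFrame,
    p: Partition,
    tau_present: float = 1.0,
    tau_absent: float = 0.0,
) -> dict[int, pd.DataFrame]:
    """Per-cluster lists of cluster-exclusive spots.

    Spot j is exclusive to cluster c iff its presence frequency is
    >= ``tau_present`` within c and <= ``tau_absent`` in every other
    cluster.  Returns a DataFrame per cluster label with the spot ids and
    their presence frequencies in each cluster.
    """
    if not 0.0 <= tau_absent < tau_present <= 1.0:
        raise ValueError("require 0 <= tau_absent < tau_present <= 1")
    _check_samples(binary, p)
    assign = pd.Series(p.as_dict())
    labels = sorted(set(p.labels))
    freq = pd.DataFrame(
        {
            lab: binary.loc[assign[assign == lab].index].mean(axis=0)
            for lab in labels
        }
    )
    out: dict[int, pd.DataFrame] = {}
    for lab in labels:
        others = [o for o in labels if o != lab]
        mask = (freq[lab] >= tau_present) & (freq[others] <= tau_absent).all(axis=1)
        df = freq.loc[mask].copy()
        df.columns = [f"freq_cluster_{o}" for o in labels]
        df.index.name = "spot_id"
        out[lab] = df
    return out


def intensity_difference_test(
    intensities: pd.DataFrame,
    p: Partition,
    min_presence: int = 3,
    alpha: float = 0.05,
    tau_present: float = 1.0,
    tau_absent: float = 0.0,
) -> DifferentialReport:
    """Welch t-tests with Bonferroni correction for shared spots.

    Only spots present (non-missing) in at least ``min_presence`` gels of
    each cluster are tested; absence is treated as missing, never imputed
    as zero.  Requires a 2-cluster partition.  The report also carries the
    qualitative cluster-exclusive lists for the same partition.
    """
    _check_samples(intensities, p)
    labels = sorted(set(p.labels))
    if len(labels) != 2:
        raise ValueError("intensity testing requires exactly 2 clusters")
    assign = pd.Series(p.as_dict())
    g1 = assign[assign == labels[0]].index
    g2 = assign[assign == labels[1]].index
    rows = []
    for spot in intensities.columns:
        v1 = intensities.loc[g1, spot].dropna().to_numpy()
        v2 = intensities.loc[g2, spot].dropna().to_numpy()
        if len(v1) < min_presence or len(v2) < min_presence:
            continue
        res = stats.ttest_ind(v1, v2, equal_var=False)
        m1, m2 = float(v1.mean()), float(v2.mean())
        rows.append(
            {
                "spot_id": spot,
                "n_1": len(v1),
                "n_2": len(v2),
                "mean_1": m1,
                "sd_1": float(v1.std(ddof=1)),
                "mean_2": m2,
                "sd_2": float(v2.std(ddof=1)),
                "fold_change": fold_change(m1, m2),
                "p_raw": float(res.pvalue),
            }
        )
    tested = pd.DataFrame(
        rows,
        columns=[
            "spot_id",
            "n_1",
            "n_2",
            "mean_1",
            "sd_1",
            "mean_2",
            "sd_2",
            "fold_change",
            "p_raw",
            "p_bonferroni",
            "significant",
        ],
    )
    if tested.empty:
        warnings.warn("no spot meets the min_presence requirement in both clusters")
    else:
        m = len(tested)
        tested["p_bonferroni"] = np.minimum(tested["p_raw"] * m, 1.0)
        tested["significant"] = tested["p_bonferroni"] < alpha
        tested = tested.set_index("spot_id")
    binary = intensities.notna().astype(int)
    exclusive = cluster_specific_spots(binary, p, tau_present, tau_absent)
    return DifferentialReport(
        cluster_exclusive=exclusive,
        tested_spots=tested,
        parameters={
            "min_presence": min_presence,
            "alpha": alpha,
            "tau_present": tau_present,
            "tau_absent": tau_absent,
            "n_tested": 0 if tested.empty else len(tested),
        },
    )


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of cluster mean intensities (full precision; round to 1 dp
    for reporting)."""
    if mean_b <= 0:
        raise ValueError("denominator mean must be positive")
    return float(mean_a) / float(mean_b)
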