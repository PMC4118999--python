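"""Replicate reproducibility statistics for 2DE gels.

Technical replicates of one sample are compared through pairwise Pearson
correlation of normalized spot intensities (over spots present in both
runs), quantile-quantile agreement, per-spot coefficients of variation,
abundance-class histograms, replicate consensus counts and per-gel spot
count summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import INTENSITY_CLASS_EDGES

__all__ = [
    "QCReport",
    "pearson_between_runs",
    "qq_points",
    "spot_cv",
    "consensus_counts",
    "summarize_spot_counts",
    "intensity_class_histogram",
    "qc_report",
    "save_qc_plots",
]

CLASS_LABELS = ("<0.02", "0.02-0.04", "0.04-0.1", ">0.1")


@dataclass
class QCReport:
    sample_id: str
    pairwise_r: dict[tuple[str, str], float]
    mean_r: float
    r_half_width: float  # 1.96 * SD / sqrt(#pairs), the 95% CI convention
    cv_per_spot: pd.Series
    cv_histogram: pd.Series
    class_fractions: pd.Series
    consensus_counts: pd.Series  # index k, value #spots present in >= k replicates
    spot_counts: pd.Series  # per replicate
    spot_count_mean: int = field(init=False)
    spot_count_sd: int = field(init=False)

    def __post_init__(self) -> None:
        self.spot_count_mean, self.spot_count_sd = summarize_spot_counts(
            self.spot_counts.tolist()
        )


def pearson_between_runs(a, b) -> float:
    """Pearson correlation over spots present (non-missing) in both runs.

    Returns NaN (with a warning) when either vector has zero variance on
    the common subset.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("runs must have equal length")
    common = ~np.isnan(a) & ~np.isnan(b)
    if common.sum() < 3:
        raise ValueError("need >= 3 spots present in both runs")
    x, y = a[common], b[common]
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in one run; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def qq_points(a, b) -> np.ndarray:
    """Quantile-quantile pairs of two intensity samples.

    Both samples are interpolated to a common length m = max(len(a),
    len(b)) at plotting positions (i - 0.5) / m; the k-th pair is the
    k-th quantile of each.  Missing values are dropped first.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both vectors must be nonempty")
    m = max(a.size, b.size)
    probs = (np.arange(1, m + 1) - 0.5) / m
    qa = np.quantile(a, probs)
    qb = np.quantile(b, probs)
    return np.column_stack([qa, qb])


def spot_cv(values) -> float:
    """Coefficient of variation (sample SD / mean) of one spot's
    intensities across replicates; NaN if present in < 2 replicates."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("spot mean intensity must be positive")
    return float(v.std(ddof=1) / mean)


def consensus_counts(binary) -> pd.Series:
    """Spots present in at least k replicates, for each k = 1..R.

    ``binary`` is a replicates-by-spots 0/1 (or boolean / NaN-presence)
    matrix; counts are by column-sum thresholding and are non-increasing
    in k.
    """
    mat = pd.DataFrame(binary)
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 replicate rows")
    present = mat.notna() & (mat.fillna(0) != 0)
    colsum = present.sum(axis=0)
    ks = range(1, mat.shape[0] + 1)
    return pd.Series({k: int((colsum >= k).sum()) for k in ks}, name="n_spots")


def summarize_spot_counts(counts) -> tuple[int, int]:
    """Mean and sample SD of per-gel spot counts, rounded to integers."""
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("need >= 2 counts")
    return int(round(c.mean())), int(round(c.std(ddof=1)))


def intensity_class_histogram(values) -> pd.Series:
    """Fractions of spots per abundance class (<0.02, 0.02-0.04,
    0.04-0.1, >0.1 relative units), boundaries left-closed (0.02 falls
    in the 0.02-0.04 class)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no intensity values supplied")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("normalized intensities must lie in [0, 1]")
    idx = np.digitize(v, INTENSITY_CLASS_EDGES, right=False)
    counts = np.bincount(idx, minlength=4)
    return pd.Series(counts / v.size, index=list(CLASS_LABELS), name="fraction")


def qc_report(
    replicates: pd.DataFrame, sample_id: str = "", cv_bins=None
) -> QCReport:
    """Full reproducibility report for one replicate set.

    ``replicates`` is a replicates-by-spots normalized intensity matrix
    with NaN for undetected spots.  CVs are computed over spots present
    in every replicate (the highly reproducible subset).
    """
    if replicates.shape[0] < 2:
        raise ValueError("need >= 2 replicates")
    reps = replicates.index.tolist()
    pairwise = {}
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            pairwise[(str(reps[i]), str(reps[j]))] = pearson_between_runs(
                replicates.iloc[i].to_numpy(), replicates.iloc[j].to_numpy()
            )
    rvals = np.array(list(pairwise.values()), dtype=float)
    mean_r = float(np.nanmean(rvals))
    half = float(1.96 * np.nanstd(rvals, ddof=1) / np.sqrt(len(rvals)))
    full = replicates.dropna(axis=1, how="any")
    cvs = full.apply(lambda col: spot_cv(col.to_numpy()), axis=0)
    if cv_bins is None:
        cv_bins = np.arange(0.0, 2.01, 0.2)
    hist, _edges = np.histogram(cvs.dropna(), bins=cv_bins)
    cv_hist = pd.Series(
        hist,
        index=[f"{lo:.1f}-{hi:.1f}" for lo, hi in zip(cv_bins[:-1], cv_bins[1:])],
        name="n_spots",
    )
    all_vals = replicates.to_numpy().ravel()
    fractions = intensity_class_histogram(all_vals[~np.isnan(all_vals)])
    consensus = consensus_counts(replicates)
    counts = replicates.notna().sum(axis=1)
    return QCReport(
        sample_id=sample_id,
        pairwise_r=pairwise,
        mean_r=mean_r,
        r_half_width=half,
        cv_per_spot=cvs,
        cv_histogram=cv_hist,
        class_fractions=fractions,
        consensus_counts=consensus,
        spot_counts=counts,
    )


def save_qc_plots(replicates: pd.DataFrame, report: QCReport, outdir) -> list[str]:
    """Write X-Y, Q-Q and CV-histogram plots (PNG) for a replicate set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    a = replicates.iloc[0].to_numpy()
    b = replicates.iloc[1].to_numpy()
    common = ~np.isnan(a) & ~np.isnan(b)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(a[common], b[common], s=8, alpha=0.6)
    ax.set_xlabel(f"{replicates.index[0]} normalized intensity")
    ax.set_ylabel(f"{replicates.index[1]} normalized intensity")
    ax.set_title(f"X-Y, r = {report.mean_r:.3f} (mean over pairs)")
    path = outdir / "xy_plot.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(str(path))

    qq = qq_points(a, b)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(qq[:, 0], qq[:, 1], ".", ms=4)
    lim = [qq.min(), qq.max()]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("quantiles, run 1")
    ax.set_ylabel("quantiles, run 2")
    ax.set_title("Q-Q")
    path = outdir / "qq_plot.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(str(path))

    fig, ax = plt.subplots(figsize=(5, 3.5))
    report.cv_histogram.plot.bar(ax=ax)
    ax.set_xlabel("CV")
    ax.set_ylabel("spots")
    ax.set_title("Per-spot CV across replicates")
    path = outdir / "cv_histogram.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(str(path))
    return written
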