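"""Synthetic 2DE gel data with planted cluster structure.

Generates binary presence/absence matrices, per-gel normalized intensity
matrices, technical-replicate intensity sets and rendered gel images, all
with known ground truth, so the full detection -> matching -> clustering ->
differential pipeline can be exercised without real gel scans.

The default configuration mimics an 18-gel human liver cytosol (HLC)
series: two clusters of 11 and 7 gels over a universe of 389 master spots,
with 3 spots exclusive to cluster 1 and 12 exclusive to cluster 2, per-gel
normalized spot intensities concentrated below 0.02 relative units
(96% / 2% / 1% / 1% across the four abundance classes), and technical
replicates with a target coefficient of variation around 0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import Partition

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_prototypes",
    "simulate_binary_dataset",
    "simulate_intensities",
    "simulate_replicates",
    "render_gel_image",
    "spotlists_from_binary",
    "INTENSITY_CLASS_EDGES",
]

#: Normalized-intensity class boundaries (relative units): <0.02, 0.02-0.04,
#: 0.04-0.1, >0.1.  Left-closed: a value of exactly 0.02 belongs to class 2.
INTENSITY_CLASS_EDGES = (0.02, 0.04, 0.1)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic gel series.

    Attributes
    ----------
    n_spots_universe : int
        Size of the master spot universe (matrix columns).
    cluster_sizes : list of int
        Gels per planted cluster; rows total ``sum(cluster_sizes)``.
    shared_spot_fraction : float
        Fraction of the universe present in every cluster prototype.
    specific_spot_counts : list of int
        Per-cluster counts of cluster-exclusive spots (disjoint sets).
    flip_rate : float
        Probability of toggling each presence bit independently per gel.
    intensity_class_fractions : tuple of 4 floats
        Target fractions of present spots per abundance class
        (<0.02, 0.02-0.04, 0.04-0.1, >0.1); must sum to 1.  The fraction
        of the 0.04-0.1 class is an inference (it is the only one not
        pinned down by the published class summary) chosen so the four
        fractions close to 1.
    replicate_cv : float
        Target per-spot coefficient of variation across technical
        replicates (multiplicative lognormal noise).
    replicate_dropout : float
        Per-replicate probability that a truly present spot is not
        detected (emulates spots matched in only k of 4 replicates).
    image_shape : tuple of int
        (rows, cols) of rendered gel images.
    psf_sigma : float
        Gaussian spot width in pixels for rendered images; true spot
        centers keep a minimum separation of ``3 * psf_sigma``.
    seed : int
        Seed fixing every generated artifact bit-for-bit.
    """

    n_spots_universe: int = 389
    cluster_sizes: list[int] = field(default_factory=lambda: [11, 7])
    shared_spot_fraction: float = 0.66
    specific_spot_counts: list[int] = field(default_factory=lambda: [3, 12])
    flip_rate: float = 0.02
    intensity_class_fractions: tuple[float, float, float, float] = (
        0.96,
        0.02,
        0.01,
        0.01,
    )
    replicate_cv: float = 0.5
    replicate_dropout: float = 0.15
    image_shape: tuple[int, int] = (512, 512)
    psf_sigma: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.shared_spot_fraction <= 1.0:
            raise ValueError("shared_spot_fraction must be in [0, 1]")
        if not 0.0 <= self.flip_rate <= 1.0:
            raise ValueError("flip_rate must be in [0, 1]")
        if not 0.0 <= self.replicate_dropout < 1.0:
            raise ValueError("replicate_dropout must be in [0, 1)")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        fr = np.asarray(self.intensity_class_fractions, dtype=float)
        if fr.shape != (4,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(
                "intensity_class_fractions must be 4 nonnegative values summing to 1"
            )
        if len(self.cluster_sizes) < 1 or any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes must all be >= 1")
        if len(self.specific_spot_counts) != len(self.cluster_sizes):
            raise ValueError("specific_spot_counts must align with cluster_sizes")
        if any(c < 0 for c in self.specific_spot_counts):
            raise ValueError("specific_spot_counts must be >= 0")
        n_shared = int(round(self.shared_spot_fraction * self.n_spots_universe))
        if n_shared + sum(self.specific_spot_counts) > self.n_spots_universe:
            raise ValueError(
                "shared + cluster-exclusive spots exceed the spot universe"
            )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated dataset."""

    true_partition: Partition
    prototype_presence: np.ndarray  # (n_clusters, n_spots_universe) of {0,1}
    #: (n_spots_universe, 3) array of x, y, amplitude for rendered images.
    true_spot_positions: np.ndarray
    shared_spots: np.ndarray  # universe indices present in every prototype
    exclusive_spots: list[np.ndarray]  # per-cluster universe indices


def _spot_positions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample spot centers with 3*psf_sigma minimum separation."""
    h, w = config.image_shape
    margin = 4.0 * config.psf_sigma
    min_sep = 3.0 * config.psf_sigma
    n = config.n_spots_universe
    pts: list[tuple[float, float]] = []
    accepted = np.empty((0, 2))
    max_tries = 200 * n
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place spots with the requested separation; "
                "enlarge image_shape or reduce n_spots_universe"
            )
        x = rng.uniform(margin, w - 1 - margin)
        y = rng.uniform(margin, h - 1 - margin)
        if len(pts):
            d2 = (accepted[:, 0] - x) ** 2 + (accepted[:, 1] - y) ** 2
            if d2.min() < min_sep**2:
                continue
        pts.append((x, y))
        accepted = np.asarray(pts)
    amp = rng.lognormal(mean=0.0, sigma=0.4, size=n)
    return np.column_stack([accepted, amp])


def make_prototypes(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Build per-cluster binary prototype vectors over the spot universe.

    Returns ``(prototypes, shared_idx, exclusive_idx)`` where prototypes is
    an (n_clusters, n_spots_universe) 0/1 array.  Shared spots appear in
    every prototype; each cluster additionally carries its configured count
    of exclusive spots, and the exclusive sets are disjoint.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    u = config.n_spots_universe
    n_shared = int(round(config.shared_spot_fraction * u))
    perm = rng.permutation(u)
    shared = np.sort(perm[:n_shared])
    cursor = n_shared
    exclusive: list[np.ndarray] = []
    for count in config.specific_spot_counts:
        exclusive.append(np.sort(perm[cursor : cursor + count]))
        cursor += count
    protos = np.zeros((len(config.cluster_sizes), u), dtype=np.int8)
    for c in range(len(config.cluster_sizes)):
        protos[c, shared] = 1
        protos[c, exclusive[c]] = 1
    return protos, shared, exclusive


def simulate_binary_dataset(config: SimulationConfig):
    """Simulate the gels-by-spots binary presence matrix.

    Each gel copies its cluster prototype and then toggles every bit
    independently with probability ``flip_rate``.  Returns a
    ``(DataFrame, GroundTruth)`` pair; rows are gels (``gel01`` ...),
    columns master spots (``spot001`` ...).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    protos, shared, exclusive = make_prototypes(config, rng)
    positions = _spot_positions(config, rng)
    n_gels = sum(config.cluster_sizes)
    labels = np.repeat(
        np.arange(1, len(config.cluster_sizes) + 1), config.cluster_sizes
    )
    rows = np.repeat(protos, config.cluster_sizes, axis=0).astype(np.int8)
    flips = rng.random(rows.shape) < config.flip_rate
    rows = np.where(flips, 1 - rows, rows).astype(np.int8)
    sample_ids = [f"gel{i + 1:02d}" for i in range(n_gels)]
    columns = [f"spot{j + 1:03d}" for j in range(config.n_spots_universe)]
    binary = pd.DataFrame(rows, index=sample_ids, columns=columns)
    truth = GroundTruth(
        true_partition=Partition(sample_ids, labels.tolist()),
        prototype_presence=protos,
        true_spot_positions=positions,
        shared_spots=shared,
        exclusive_spots=exclusive,
    )
    return binary, truth


# -- intensity model ---------------------------------------------------------

# Geometric-center medians for classes 2-4 and lognormal sigmas per class.
# Class-1 median adapts per gel so the expected per-gel total is ~1, which
# keeps the final renormalization factor close to 1 and class membership
# stable under it.
_CLASS_MEDIANS = (None, 0.0283, 0.0632, 0.13)
_CLASS_SIGMAS = (0.6, 0.10, 0.15, 0.20)
_CLASS_CLIPS = ((1e-6, 0.018), (0.021, 0.039), (0.042, 0.098), (0.102, 0.4))


def _stratified_classes(m: int, fractions: np.ndarray, rng) -> np.ndarray:
    """Assign m spots to 4 classes with counts near m*fractions.

    Largest-remainder allocation with the leftover units assigned by a
    seeded draw; damps the total-intensity variance a pure multinomial
    draw would inject through the rare high-abundance class.
    """
    raw = m * fractions
    base = np.floor(raw).astype(int)
    rem = m - base.sum()
    if rem > 0:
        frac_part = raw - base
        p = frac_part / frac_part.sum() if frac_part.sum() > 0 else fractions
        extra = rng.choice(4, size=rem, p=p)
        np.add.at(base, extra, 1)
    classes = np.repeat(np.arange(4), base)
    rng.shuffle(classes)
    return classes


def simulate_intensities(
    binary: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-gel normalized intensities for every present spot.

    Intensities come from a lognormal mixture whose components sit inside
    the four abundance classes; each gel is then renormalized so its
    present-spot intensities sum to exactly 1.  Absent spots are NaN.
    """
    if binary.size == 0:
        raise ValueError("binary matrix is empty")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    fractions = np.asarray(config.intensity_class_fractions, dtype=float)
    out = np.full(binary.shape, np.nan)
    values = binary.to_numpy()
    for i in range(binary.shape[0]):
        present = np.flatnonzero(values[i])
        m = present.size
        if m == 0:
            raise ValueError(f"gel {binary.index[i]!r} has zero present spots")
        classes = _stratified_classes(m, fractions, rng)
        # expected contribution of classes 2-4 per spot
        tail = sum(
            fractions[k] * _CLASS_MEDIANS[k] * np.exp(_CLASS_SIGMAS[k] ** 2 / 2)
            for k in (1, 2, 3)
        )
        med1 = (1.0 / m - tail) / max(fractions[0], 1e-12)
        med1 /= np.exp(_CLASS_SIGMAS[0] ** 2 / 2)
        med1 = float(np.clip(med1, 1e-5, 0.015))
        medians = (med1,) + _CLASS_MEDIANS[1:]
        vals = np.empty(m)
        for k in range(4):
            sel = classes == k
            if not sel.any():
                continue
            draw = medians[k] * rng.lognormal(0.0, _CLASS_SIGMAS[k], size=sel.sum())
            lo, hi = _CLASS_CLIPS[k]
            vals[sel] = np.clip(draw, lo, hi)
        vals /= vals.sum()
        out[i, present] = vals
    return pd.DataFrame(out, index=binary.index, columns=binary.columns)


def simulate_replicates(
    intensities: pd.Series | np.ndarray,
    config: SimulationConfig,
    n_replicates: int = 4,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate technical replicates of one gel's normalized intensities.

    Each replicate multiplies every present spot by lognormal noise with
    coefficient of variation ``replicate_cv``, drops it with probability
    ``replicate_dropout`` (non-detection), and renormalizes the surviving
    spots to sum to 1.  Rows are replicates, columns spots; NaN marks a
    spot not detected in that replicate.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    base = pd.Series(intensities).astype(float)
    present = base.notna().to_numpy() & (base.to_numpy() > 0)
    sigma = np.sqrt(np.log1p(config.replicate_cv**2))
    rows = np.full((n_replicates, base.size), np.nan)
    for r in range(n_replicates):
        noise = rng.lognormal(-(sigma**2) / 2, sigma, size=base.size)
        keep = present & (rng.random(base.size) >= config.replicate_dropout)
        if not keep.any():  # force at least one survivor
            keep = present.copy()
        vals = base.to_numpy(copy=True) * noise
        vals[~keep] = np.nan
        vals /= np.nansum(vals)
        rows[r] = vals
    index = [f"rep{r + 1}" for r in range(n_replicates)]
    return pd.DataFrame(rows, index=index, columns=getattr(base, "index", None))


# -- image rendering ---------------------------------------------------------


def render_gel_image(
    spots: np.ndarray,
    image_shape: tuple[int, int] = (512, 512),
    psf_sigma: float = 3.0,
    background_level: float = 0.1,
    noise_sd: float = 0.01,
    seed: int = 0,
    polarity: str = "light-on-dark",
):
    """Render a synthetic gel image from ground-truth spots.

    Parameters
    ----------
    spots : (n, 2) or (n, 3) array
        x, y centers and optional amplitudes (default 1).
    polarity : str
        ``"light-on-dark"`` renders additive bright bumps;
        ``"dark-on-light"`` inverts the scene, mimicking silver-stained
        densitometer scans.

    Returns a ``(GelImage, SpotList)`` pair where the spot list is the
    ground truth (centers, sigma, injected amplitude as raw intensity).
    """
    from .detect import GelImage, Spot, SpotList, disk_region

    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    spots = np.atleast_2d(np.asarray(spots, dtype=float))
    if spots.size == 0:
        spots = spots.reshape(0, 3)
    if spots.shape[1] == 2:
        spots = np.column_stack([spots, np.ones(len(spots))])
    h, w = image_shape
    bad = [
        i
        for i, (x, y, _a) in enumerate(spots)
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1)
    ]
    if bad:
        raise ValueError(f"spot centers outside image bounds: indices {bad}")
    yy, xx = np.mgrid[0:h, 0:w]
    scene = np.full((h, w), float(background_level))
    for x, y, a in spots:
        r2 = (xx - x) ** 2 + (yy - y) ** 2
        near = r2 <= (5 * psf_sigma) ** 2  # truncate far tails for speed
        scene[near] += a * np.exp(-r2[near] / (2 * psf_sigma**2))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        scene = scene + rng.normal(0.0, noise_sd, size=scene.shape)
    scene = np.clip(scene, 0.0, None)
    if polarity == "dark-on-light":
        scene = scene.max() - scene
    elif polarity != "light-on-dark":
        raise ValueError("polarity must be 'light-on-dark' or 'dark-on-light'")
    image = GelImage(pixels=scene, bit_depth=16, stain_polarity=polarity)
    truth_spots = [
        Spot(
            spot_id=i,
            x=float(x),
            y=float(y),
            sigma=float(psf_sigma),
            region=disk_region(x, y, np.sqrt(2) * psf_sigma, image_shape),
            raw_intensity=float(a),
        )
        for i, (x, y, a) in enumerate(spots)
    ]
    return image, SpotList(gel_id="truth", spots=truth_spots, detection_params={})


def spotlists_from_binary(binary: pd.DataFrame, truth: GroundTruth):
    """Expand a binary matrix into per-gel ground-truth spot lists.

    Spot ids equal universe indices and coordinates come from
    ``truth.true_spot_positions``, so all lists share one coordinate
    frame — the ideal input for master matching without detection noise.
    """
    from .detect import Spot, SpotList

    pos = truth.true_spot_positions
    lists = []
    for gel_id, row in binary.iterrows():
        present = np.flatnonzero(row.to_numpy())
        spots = [
            Spot(
                spot_id=int(j),
                x=float(pos[j, 0]),
                y=float(pos[j, 1]),
                sigma=3.0,
                region=np.array([[int(round(pos[j, 1])), int(round(pos[j, 0]))]]),
                raw_intensity=float(pos[j, 2]),
            )
            for j in present
        ]
        lists.append(SpotList(gel_id=str(gel_id), spots=spots, detection_params={}))
    return lists
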