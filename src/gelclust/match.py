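"""Spot matching to a master gel and assembly of the data matrices.

Each gel's spot list is matched to the master gel's list by mutual nearest
neighbors within a pixel tolerance, assigned greedily by ascending
distance (ties by ascending spot id), optionally after a similarity
pre-registration.  Matched assignments across gels are then assembled into
the gels-by-spots binary presence matrix and the companion normalized
intensity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detect import SpotList

__all__ = [
    "SpotCorrespondence",
    "match_to_master",
    "build_matrices",
    "estimate_similarity",
]


@dataclass
class SpotCorrespondence:
    """Assignment of one gel's spots to master spot identities."""

    gel_id: str
    pairs: dict[int, int]  # gel spot_id -> master spot_id
    unmatched_gel_spots: set[int]
    distances: dict[int, float]  # gel spot_id -> pixel distance to its master spot
    #: positions of unmatched gel spots in the master coordinate frame
    unmatched_positions: dict[int, tuple[float, float]] = field(default_factory=dict)
    transform: object | None = None

    def __post_init__(self) -> None:
        masters = list(self.pairs.values())
        if len(masters) != len(set(masters)):
            raise ValueError("a master spot is claimed by two gel spots")


def estimate_similarity(
    src: np.ndarray,
    dst: np.ndarray,
    tolerance: float,
    n_trials: int = 500,
    seed: int = 0,
):
    """Consensus similarity transform (translation+rotation+scale).

    Best-of-N minimal samples: each trial picks 2 source points and 2
    candidate destination points among near neighbors, fits a 2-point
    similarity, and counts source points landing within ``tolerance`` of
    some destination point.  The winning hypothesis is refined by a
    least-squares fit on its inlier pairs.  Returns a
    ``skimage.transform.SimilarityTransform``.
    """
    from skimage.transform import SimilarityTransform

    if len(src) < 2 or len(dst) < 2:
        return SimilarityTransform()  # identity
    rng = np.random.default_rng(seed)
    tree = cKDTree(dst)
    k_cand = min(5, len(dst))
    _dists, cand = tree.query(src, k=k_cand)
    cand = np.atleast_2d(cand)
    best_inliers = -1
    best_tf = SimilarityTransform()
    for _ in range(n_trials):
        i, j = rng.choice(len(src), size=2, replace=False)
        ci = cand[i, rng.integers(k_cand)]
        cj = cand[j, rng.integers(k_cand)]
        if ci == cj:
            continue
        tf = _fit_similarity(src[[i, j]], dst[[ci, cj]])
        if tf is None:
            continue
        moved = tf(src)
        d, _idx = tree.query(moved)
        inliers = int((d <= tolerance).sum())
        if inliers > best_inliers:
            best_inliers = inliers
            best_tf = tf
    # least-squares refinement on the inlier pairs of the best hypothesis
    moved = best_tf(src)
    d, idx = tree.query(moved)
    ok = d <= tolerance
    if ok.sum() >= 2:
        refined = _fit_similarity(src[ok], dst[idx[ok]])
        if refined is not None:
            best_tf = refined
    return best_tf


def _fit_similarity(src: np.ndarray, dst: np.ndarray):
    """Least-squares similarity fit; None when degenerate."""
    from skimage.transform import SimilarityTransform

    if hasattr(SimilarityTransform, "from_estimate"):
        tf = SimilarityTransform.from_estimate(src, dst)
        if not tf or not np.isfinite(tf.params).all():
            return None
        return tf
    tf = SimilarityTransform()
    if not tf.estimate(src, dst) or not np.isfinite(tf.params).all():
        return None
    return tf


def match_to_master(
    spots: SpotList,
    master: SpotList,
    tolerance: float = 5.0,
    pre_register: bool = False,
    seed: int = 0,
) -> SpotCorrespondence:
    """Match a gel's spots to the master gel's spots.

    Pairs are mutual nearest neighbors within ``tolerance`` pixels,
    accepted greedily by ascending distance and then ascending spot ids.
    With ``pre_register`` a consensus similarity transform is estimated
    and applied to the gel coordinates first (for lists not already in
    the master's coordinate frame).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if len(master) == 0:
        raise ValueError("master spot list is empty")
    gel_ids = spots.ids()
    if len(spots) == 0:
        return SpotCorrespondence(spots.gel_id, {}, set(), {})
    coords = spots.coords()
    tf = None
    if pre_register:
        tf = estimate_similarity(coords, master.coords(), tolerance, seed=seed)
        coords = tf(coords)
    mcoords = master.coords()
    mids = master.ids()
    mtree = cKDTree(mcoords)
    gtree = cKDTree(coords)
    d_gm, nn_m = mtree.query(coords)  # for each gel spot: nearest master
    _d_mg, nn_g = gtree.query(mcoords)  # for each master spot: nearest gel
    candidates = []
    for gi in range(len(coords)):
        mi = nn_m[gi]
        if nn_g[mi] == gi and d_gm[gi] <= tolerance:
            candidates.append((float(d_gm[gi]), gel_ids[gi], mids[mi], gi))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    pairs: dict[int, int] = {}
    dists: dict[int, float] = {}
    used_masters: set[int] = set()
    for dist, gid, mid, _gi in candidates:
        if gid in pairs or mid in used_masters:
            continue
        pairs[gid] = mid
        dists[gid] = dist
        used_masters.add(mid)
    unmatched = set(gel_ids) - set(pairs)
    unmatched_pos = {
        gel_ids[gi]: (float(coords[gi, 0]), float(coords[gi, 1]))
        for gi in range(len(coords))
        if gel_ids[gi] in unmatched
    }
    return SpotCorrespondence(
        gel_id=spots.gel_id,
        pairs=pairs,
        unmatched_gel_spots=unmatched,
        distances=dists,
        unmatched_positions=unmatched_pos,
        transform=tf,
    )


def _union_columns(
    correspondences: list[SpotCorrespondence], tolerance: float
) -> dict[str, dict[str, int]]:
    """Cluster recurrent unmatched spots into new columns.

    Greedy centroid agglomeration over all unmatched spots (in master
    frame, iterated in gel order then spot-id order): a spot joins the
    first existing group whose centroid lies within ``tolerance``, else
    opens a new group.  Only groups touched by >= 2 distinct gels become
    columns; per gel at most one spot counts toward a group.
    """
    groups: list[dict] = []  # {"sum": (sx, sy), "n": int, "gels": {gel_id: spot_id}}
    for corr in correspondences:
        for sid in sorted(corr.unmatched_positions):
            x, y = corr.unmatched_positions[sid]
            placed = False
            for g in groups:
                cx, cy = g["sum"][0] / g["n"], g["sum"][1] / g["n"]
                if (cx - x) ** 2 + (cy - y) ** 2 <= tolerance**2:
                    if corr.gel_id not in g["gels"]:
                        g["gels"][corr.gel_id] = sid
                    g["sum"] = (g["sum"][0] + x, g["sum"][1] + y)
                    g["n"] += 1
                    placed = True
                    break
            if not placed:
                groups.append({"sum": (x, y), "n": 1, "gels": {corr.gel_id: sid}})
    out: dict[str, dict[str, int]] = {}
    u = 0
    for g in groups:
        if len(g["gels"]) >= 2:
            out[f"u{u + 1:03d}"] = g["gels"]
            u += 1
    return out


def build_matrices(
    correspondences: list[SpotCorrespondence],
    master: SpotList,
    spotlists: list[SpotList],
    union_columns: bool = True,
    tolerance: float = 5.0,
):
    """Assemble the binary presence matrix and normalized intensity matrix.

    Columns are the master's spots (``m<id>``) plus, with
    ``union_columns``, new columns (``u<k>``) for unmatched spots that
    co-locate across at least two gels.  ``d_ij = 1`` exactly when gel i
    has a spot assigned to column j.  The intensity matrix holds each
    gel's raw spot intensities normalized by that gel's total over all
    column-assigned spots; cells without an assigned spot are NaN.
    """
    gel_ids = [c.gel_id for c in correspondences]
    if len(gel_ids) != len(set(gel_ids)):
        raise ValueError("duplicate gel_id across correspondences")
    lists = {sl.gel_id: sl for sl in spotlists}
    missing = [g for g in gel_ids if g not in lists]
    if missing:
        raise ValueError(f"no spot list for gels: {missing}")
    columns = [f"m{mid}" for mid in master.ids()]
    union = (
        _union_columns(correspondences, tolerance) if union_columns else {}
    )
    columns = columns + sorted(union)
    binary = pd.DataFrame(0, index=gel_ids, columns=columns, dtype=np.int8)
    intensity = pd.DataFrame(np.nan, index=gel_ids, columns=columns)
    # column assignment per gel: column id -> gel spot id
    for corr in correspondences:
        assigned: dict[str, int] = {
            f"m{mid}": gid for gid, mid in corr.pairs.items()
        }
        for col, gels in union.items():
            if corr.gel_id in gels:
                assigned[col] = gels[corr.gel_id]
        raw = {s.spot_id: s.raw_intensity for s in lists[corr.gel_id].spots}
        total = sum(raw[gid] for gid in assigned.values())
        for col, gid in assigned.items():
            binary.loc[corr.gel_id, col] = 1
            if total > 0:
                intensity.loc[corr.gel_id, col] = raw[gid] / total
    return binary, intensity
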