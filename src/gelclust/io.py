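"""Reading and writing the pipeline's file formats.

Gel images are grayscale TIFF/PNG (8/16-bit); spot lists, matrices and
partitions travel as plain CSV so every intermediate is inspectable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import Dendrogram, Partition
from .detect import GelImage, Spot, SpotList, disk_region

__all__ = [
    "read_gel_image",
    "write_gel_image",
    "read_spotlist",
    "write_spotlist",
    "apply_spot_patch",
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "write_linkage",
    "write_newick",
]


def read_gel_image(
    path,
    sample_id: str = "",
    replicate_id: str = "",
    stain_polarity: str = "dark-on-light",
) -> GelImage:
    """Load a grayscale TIFF/PNG gel scan."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"{path}: expected a grayscale image, got shape {arr.shape}")
    bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    return GelImage(
        pixels=arr.astype(float),
        bit_depth=bit_depth,
        sample_id=sample_id or Path(path).stem,
        replicate_id=replicate_id,
        stain_polarity=stain_polarity,
    )


def write_gel_image(image: GelImage, path) -> None:
    """Write pixels as 16-bit TIFF/PNG, rescaled to the full range."""
    import imageio.v3 as iio

    px = image.pixels
    hi = px.max() if px.max() > 0 else 1.0
    scaled = np.clip(px / hi, 0, 1)
    iio.imwrite(path, (scaled * 65535).astype(np.uint16))


_SPOT_COLS = ["gel_id", "spot_id", "x", "y", "sigma", "raw_intensity", "normalized_intensity"]


def write_spotlist(spots: SpotList, path) -> None:
    rows = [
        {
            "gel_id": spots.gel_id,
            "spot_id": s.spot_id,
            "x": s.x,
            "y": s.y,
            "sigma": s.sigma,
            "raw_intensity": s.raw_intensity,
            "normalized_intensity": (
                "" if s.normalized_intensity is None else s.normalized_intensity
            ),
        }
        for s in spots.spots
    ]
    pd.DataFrame(rows, columns=_SPOT_COLS).to_csv(path, index=False)


def read_spotlist(path, image_shape: tuple[int, int] | None = None) -> SpotList:
    """Load a SpotList CSV; spot regions are reconstructed as disks of
    radius sqrt(2)*sigma when an image shape is given, else single pixels."""
    df = pd.read_csv(path)
    gel_id = str(df["gel_id"].iloc[0]) if len(df) else Path(path).stem
    spots = []
    for _, row in df.iterrows():
        if image_shape is not None:
            region = disk_region(row["x"], row["y"], np.sqrt(2) * row["sigma"], image_shape)
        else:
            region = np.array([[int(round(row["y"])), int(round(row["x"]))]])
        norm = row.get("normalized_intensity")
        spots.append(
            Spot(
                spot_id=int(row["spot_id"]),
                x=float(row["x"]),
                y=float(row["y"]),
                sigma=float(row["sigma"]),
                region=region,
                raw_intensity=float(row["raw_intensity"]),
                normalized_intensity=None if pd.isna(norm) else float(norm),
            )
        )
    return SpotList(gel_id=gel_id, spots=spots, detection_params={})


def apply_spot_patch(spots: SpotList, patch_path) -> SpotList:
    """Apply manual spot edits from a CSV patch.

    Patch columns: ``action`` (add|delete), ``spot_id``, and for adds
    ``x``, ``y``, ``sigma``, ``raw_intensity``.  The stand-in for
    interactive spot editing: the edits are data, the GUI is not.
    """
    patch = pd.read_csv(patch_path)
    out = list(spots.spots)
    for _, row in patch.iterrows():
        action = str(row["action"]).lower()
        sid = int(row["spot_id"])
        if action == "delete":
            out = [s for s in out if s.spot_id != sid]
        elif action == "add":
            out.append(
                Spot(
                    spot_id=sid,
                    x=float(row["x"]),
                    y=float(row["y"]),
                    sigma=float(row["sigma"]),
                    region=np.array([[int(round(row["y"])), int(round(row["x"]))]]),
                    raw_intensity=float(row["raw_intensity"]),
                )
            )
        else:
            raise ValueError(f"unknown patch action: {action!r}")
    return SpotList(gel_id=spots.gel_id, spots=out, detection_params=dict(spots.detection_params))


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index_label="sample_id")


def read_matrix(path, binary: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    df.index = df.index.map(str)
    if binary:
        df = df.fillna(0).astype(np.int8)
    return df


def write_partition(p: Partition, path) -> None:
    pd.DataFrame({"sample_id": p.sample_ids, "cluster": p.labels}).to_csv(
        path, index=False
    )


def read_partition(path) -> Partition:
    df = pd.read_csv(path)
    return Partition(
        [str(s) for s in df["sample_id"]], [int(c) for c in df["cluster"]]
    )


def write_linkage(dend: Dendrogram, path) -> None:
    rows = [
        {"step": t, "node_a": a, "node_b": b, "height": h, "new_size": s}
        for t, (a, b, h, s) in enumerate(dend.merges)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_newick(dend: Dendrogram, path) -> None:
    from .cluster import to_newick

    Path(path).write_text(to_newick(dend) + "\n")
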