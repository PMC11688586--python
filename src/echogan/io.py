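"""Image and manifest I/O.

Images are grayscale PNG (8-bit default) or TIFF (8/16-bit); intensities are
scaled by the container maximum (255 or 65535) to the unit interval on read,
and the bit depth is recorded so peak-signal conventions stay predictable.
A dataset on disk is ``<root>/low/<id>.png``, ``<root>/high/<id>.png`` and a
``manifest.csv`` with columns id, registered, split, low_path, high_path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .phantom import ImagePair

__all__ = [
    "read_image",
    "write_image",
    "save_dataset",
    "load_dataset",
    "load_manifest",
    "write_manifest",
]

SPLIT_LABELS = ("train", "val", "test", "unassigned")


def read_image(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a grayscale PNG/TIFF; return ([0,1] float array, bit depth)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4):
            rgb = arr[..., :3]
            if not (rgb[..., 0] == rgb[..., 1]).all() or not (
                rgb[..., 1] == rgb[..., 2]
            ).all():
                raise ValueError(f"{path.name}: multi-channel non-gray image")
            arr = rgb[..., 0]
        else:
            raise ValueError(f"{path.name}: unexpected shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"{path.name}: unsupported dtype {arr.dtype}")
    max_i = float(2**depth - 1)
    return (arr.astype(np.float32) / max_i), depth


def write_image(
    image: np.ndarray,
    path: str | Path,
    bit_depth: int = 8,
    clip: bool = False,
) -> None:
    """Quantize a [0,1] image to the requested depth, losslessly stored."""
    path = Path(path)
    image = np.asarray(image)
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16: {bit_depth}")
    if image.min() < 0.0 or image.max() > 1.0:
        if not clip:
            raise ValueError(
                f"{path.name}: image outside [0, 1] "
                f"(min {image.min():.4g}, max {image.max():.4g}); "
                "pass clip=True to clip"
            )
        image = np.clip(image, 0.0, 1.0)
    max_i = 2**bit_depth - 1
    q = np.round(image * max_i).astype(np.uint8 if bit_depth == 8 else np.uint16)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, q)
    elif suffix == ".png":
        mode = "L" if bit_depth == 8 else "I;16"
        Image.fromarray(q, mode=mode).save(path)
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def write_manifest(df: pd.DataFrame, root: str | Path) -> None:
    bad = set(df["split"]) - set(SPLIT_LABELS)
    if bad:
        raise ValueError(f"unknown split labels: {sorted(bad)}")
    if df["id"].duplicated().any():
        raise ValueError("manifest identifiers must be unique")
    df.to_csv(Path(root) / "manifest.csv", index=False)


def load_manifest(root: str | Path) -> pd.DataFrame:
    root = Path(root)
    path = root / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"id": str})
    for _, row in df.iterrows():
        for col in ("low_path", "high_path"):
            if not (root / row[col]).exists():
                raise FileNotFoundError(root / row[col])
    return df


def save_dataset(
    pairs: list[ImagePair],
    root: str | Path,
    bit_depth: int = 8,
    fmt: str = "png",
) -> pd.DataFrame:
    """Write pairs to the on-disk layout and return the manifest frame."""
    root = Path(root)
    (root / "low").mkdir(parents=True, exist_ok=True)
    (root / "high").mkdir(parents=True, exist_ok=True)
    rows = []
    for pair in pairs:
        low_rel = f"low/{pair.identifier}.{fmt}"
        high_rel = f"high/{pair.identifier}.{fmt}"
        write_image(pair.low, root / low_rel, bit_depth)
        write_image(pair.high, root / high_rel, bit_depth)
        rows.append(
            {
                "id": pair.identifier,
                "registered": pair.registered,
                "split": "unassigned",
                "low_path": low_rel,
                "high_path": high_rel,
            }
        )
    df = pd.DataFrame(rows)
    write_manifest(df, root)
    return df


def load_dataset(
    root: str | Path, split: str | None = None
) -> list[ImagePair]:
    """Read pairs back from the on-disk layout (optionally one split)."""
    root = Path(root)
    df = load_manifest(root)
    if split is not None:
        df = df[df["split"] == split]
    pairs = []
    for _, row in df.iterrows():
        low, _ = read_image(root / row["low_path"])
        high, _ = read_image(root / row["high_path"])
        pairs.append(
            ImagePair(
                identifier=str(row["id"]),
                low=low,
                high=high,
                registered=bool(row["registered"]),
            )
        )
    return pairs
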