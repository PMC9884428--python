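"""Reading and writing images, masks and result tables."""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classify import PixelCounts
from .scoring import HScoreResult

logger = logging.getLogger("ihcquant")

COUNTS_COLUMNS = ["sample_id", "n_weak", "n_medium", "n_strong", "n_negative", "n_total"]
SCORES_COLUMNS = [
    "sample_id",
    "frac_weak",
    "frac_medium",
    "frac_strong",
    "frac_positive",
    "h_score",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG or TIFF image as 8-bit RGB.

    16-bit images are rescaled to 8-bit with a logged warning; an alpha
    channel is dropped; single-channel images are replicated to RGB.
    """
    arr = np.asarray(iio.imread(Path(path)))
    if arr.dtype == np.uint16:
        logger.warning("%s: 16-bit image rescaled to 8-bit", path)
        arr = (arr / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported image dtype {arr.dtype}")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return arr


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel PNG mask; nonzero pixels are included."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr != 0


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    write_image(path, np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def counts_to_frame(counts: dict[str, PixelCounts]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": sid,
            "n_weak": c.n_weak,
            "n_medium": c.n_medium,
            "n_strong": c.n_strong,
            "n_negative": c.n_negative,
            "n_total": c.n_total,
        }
        for sid, c in counts.items()
    ]
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


def scores_to_frame(scores: list[HScoreResult]) -> pd.DataFrame:
    """Per-sample scores table; fractional columns rounded to 4 decimals."""
    rows = [
        {
            "sample_id": s.sample_id,
            "frac_weak": round(s.fractions.frac_weak, 4),
            "frac_medium": round(s.fractions.frac_medium, 4),
            "frac_strong": round(s.fractions.frac_strong, 4),
            "frac_positive": round(s.fractions.frac_positive, 4),
            "h_score": round(s.h_score, 4),
        }
        for s in scores
    ]
    return pd.DataFrame(rows, columns=SCORES_COLUMNS)


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample_id", "h_score"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: scores CSV missing columns {sorted(missing)}")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest CSV missing columns {sorted(missing)}")
    return df
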