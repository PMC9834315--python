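"""Disk formats: 8-bit grayscale PNG stimuli, CSV trial tables and features.

Image ids are filename stems; a stem's prefix up to the first underscore
is taken as the expression class when it matches one of the known labels.
The trial CSV carries the columns
``trial_id, condition, left_image_id, right_image_id, left_class,
right_class, response_side, rt_seconds, subject``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import DataError
from .spectra import CLASSES
from .synth import GrayImage, TrialRecord

__all__ = [
    "write_image",
    "read_image",
    "write_images",
    "read_images",
    "write_trials",
    "read_trials",
]

TRIAL_COLUMNS = [
    "trial_id", "condition", "left_image_id", "right_image_id",
    "left_class", "right_class", "response_side", "rt_seconds", "subject",
]


def write_image(image: GrayImage, path: Path) -> Path:
    path = Path(path)
    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")
    return path


def read_image(path: Path, class_label: Optional[str] = None) -> GrayImage:
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    stem = path.stem
    if class_label is None:
        prefix = stem.split("_", 1)[0]
        class_label = prefix if prefix in CLASSES else None
    return GrayImage(pixels=arr, image_id=stem, class_label=class_label)


def write_images(images: Sequence[GrayImage], directory: Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [write_image(img, directory / f"{img.image_id}.png") for img in images]


def read_images(directory: Path) -> list[GrayImage]:
    directory = Path(directory)
    paths = sorted(directory.glob("*.png"))
    if not paths:
        raise DataError(f"no PNG images found under {directory}")
    return [read_image(p) for p in paths]


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trial_id": t.trial_id,
                "condition": t.condition,
                "left_image_id": t.left_image_id,
                "right_image_id": t.right_image_id,
                "left_class": t.left_class,
                "right_class": t.right_class,
                "response_side": t.response_side if t.response_side else "",
                "rt_seconds": t.rt_seconds if t.rt_seconds is not None else "",
                "subject": t.subject,
            }
            for t in trials
        ],
        columns=TRIAL_COLUMNS,
    )


def write_trials(trials: Sequence[TrialRecord], path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials_to_frame(trials).to_csv(path, index=False)
    return path


def read_trials(path: Path) -> list[TrialRecord]:
    df = pd.read_csv(path, dtype={"left_image_id": str, "right_image_id": str})
    missing = set(TRIAL_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise DataError(f"trial CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        side = row["response_side"]
        side = None if (pd.isna(side) or side == "") else str(side)
        rt = row["rt_seconds"]
        rt = None if (pd.isna(rt) or rt == "") else float(rt)
        out.append(
            TrialRecord(
                trial_id=int(row["trial_id"]),
                condition=str(row["condition"]),
                left_image_id=str(row["left_image_id"]),
                right_image_id=str(row["right_image_id"]),
                left_class=str(row["left_class"]),
                right_class=str(row["right_class"]),
                response_side=side,
                rt_seconds=rt,
                subject=str(row.get("subject", "S01")) if "subject" in df.columns else "S01",
            )
        )
    return out
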