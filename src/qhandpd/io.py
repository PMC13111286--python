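"""Dataset readers/writers for the HandPD-style exam layout.

A dataset directory holds one sub-folder per class of PNG/JPEG exam drawings
plus a ``meta.csv`` joining each image to its subject's clinical record:

    <root>/Healthy/*.png
    <root>/Patient/*.png
    <root>/meta.csv   # exam_id,image_name,patient_id,class_label,gender,
                      # handedness,age,rms,mrt,std_diff
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

log = logging.getLogger("qhandpd")

#: metadata CSV schema, in column order
META_COLUMNS = ["exam_id", "image_name", "patient_id", "class_label",
                "gender", "handedness", "age", "rms", "mrt", "std_diff"]

#: structured features fed to the tabular track, in order
FEATURE_COLUMNS = ["gender", "handedness", "age", "rms", "mrt", "std_diff"]

NUMERIC_FEATURES = ["age", "rms", "mrt", "std_diff"]
CATEGORICAL_MAPS = {"gender": {"M": 0.0, "F": 1.0},
                    "handedness": {"R": 0.0, "L": 1.0}}

#: accepted class-label dialects, normalised to {H, P}
CLASS_ALIASES = {"H": "H", "P": "P", "Healthy": "H", "Patient": "P",
                 "0": "H", "1": "P", 0: "H", 1: "P"}
CLASS_TO_INT = {"H": 0, "P": 1}
CLASS_FOLDERS = {"H": "Healthy", "P": "Patient"}


@dataclass
class DatasetManifest:
    """Joined view of a dataset directory: image paths + metadata rows."""

    root: Path
    records: pd.DataFrame          # META_COLUMNS plus ``image_path``
    n_excluded: int = 0
    class_map: dict = field(default_factory=lambda: dict(CLASS_TO_INT))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return self.records["class_label"].map(self.class_map).to_numpy()


def normalize_class_labels(series: pd.Series) -> pd.Series:
    out = series.map(lambda v: CLASS_ALIASES.get(v, CLASS_ALIASES.get(str(v))))
    if out.isna().any():
        bad = series[out.isna()].unique()
        raise ValueError(f"unrecognised class labels: {list(bad)}")
    return out


def read_exam_directory(path: str | Path, meta_name: str = "meta.csv"
                        ) -> DatasetManifest:
    """Read a class-per-folder exam directory into a :class:`DatasetManifest`.

    Images are joined to metadata rows by ``image_name``; images without a row
    (or rows without an image) are excluded with a logged count.
    """
    root = Path(path)
    csv_path = root / meta_name
    if not csv_path.exists():
        raise FileNotFoundError(f"metadata CSV not found: {csv_path}")
    meta = pd.read_csv(csv_path)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(
            f"metadata CSV {csv_path} lacks required column(s): "
            f"{', '.join(missing)}")
    meta = meta.copy()
    meta["class_label"] = normalize_class_labels(meta["class_label"])
    if meta["exam_id"].duplicated().any():
        raise ValueError("exam_id values must be unique")

    images: dict[str, Path] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        for img in sorted(sub.iterdir()):
            if img.suffix.lower() in {".png", ".jpg", ".jpeg"}:
                images[img.name] = img

    matched = meta["image_name"].isin(images)
    n_row_excl = int((~matched).sum())
    n_img_excl = len(set(images) - set(meta["image_name"]))
    if n_row_excl or n_img_excl:
        log.warning("read_exam_directory: excluded %d metadata rows without "
                    "images and %d images without metadata",
                    n_row_excl, n_img_excl)
    records = meta[matched].reset_index(drop=True)
    records["image_path"] = records["image_name"].map(
        lambda n: str(images[n]))
    for p in records["image_path"]:
        try:
            with Image.open(p) as im:
                im.verify()
        except Exception as exc:
            raise ValueError(f"undecodable image: {p}") from exc
    return DatasetManifest(root=root, records=records,
                           n_excluded=n_row_excl + n_img_excl)


def load_image(path: str | Path) -> np.ndarray:
    """Decode an image file to an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


# ---------------------------------------------------------------------------
# prediction records
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = ["sample_id", "true_label", "predicted_label",
                      "p_healthy", "p_pd"]


def write_predictions(records: pd.DataFrame, path: str | Path) -> None:
    """Write per-sample predictions; probabilities keep 8 decimals so the
    bootstrap is reproducible from the file alone."""
    df = records.loc[:, PREDICTION_COLUMNS]
    df.to_csv(path, index=False, float_format="%.8f")


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"predictions file lacks column(s): {missing}")
    return df
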