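"""Image preprocessing and structured-feature preparation.

Image pipeline: mean + median denoising, grayscale suppression that whitens
every near-gray pixel (all pairwise RGB differences strictly below the
threshold — printed template and background) while keeping the saturated pen
trace, then bilinear resize to 512×512 and rescale to [0, 1].

Structured pipeline: mean/mode imputation and per-feature min–max mapping to
[0, π], both fitted on the training split only; out-of-range values seen at
test time are clipped so the angle encoding's domain stays valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .io import CATEGORICAL_MAPS, FEATURE_COLUMNS, NUMERIC_FEATURES

__all__ = [
    "denoise", "suppress_grayscale", "resize_and_scale", "preprocess_image",
    "impute_features", "FeaturePipeline",
    "GRAYSCALE_THRESHOLD", "IMAGE_SIDE",
]

GRAYSCALE_THRESHOLD = 45
IMAGE_SIDE = 512


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got {image.shape}")
    return image


def denoise(image: np.ndarray, mean_kernel: int = 3, median_kernel: int = 3
            ) -> np.ndarray:
    """Mean filter then median filter, per channel, edges replicated."""
    image = _check_rgb(image)
    for k in (mean_kernel, median_kernel):
        if k < 1 or k % 2 == 0:
            raise ValueError(f"kernel sizes must be odd and >= 1, got {k}")
    out = image.astype(np.float64)
    if mean_kernel > 1:
        out = ndimage.uniform_filter(out, size=(mean_kernel, mean_kernel, 1),
                                     mode="nearest")
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if median_kernel > 1:
        out = ndimage.median_filter(out, size=(median_kernel, median_kernel, 1),
                                    mode="nearest")
    return out


def suppress_grayscale(image: np.ndarray, threshold: int = GRAYSCALE_THRESHOLD
                       ) -> np.ndarray:
    """Whiten every pixel whose three pairwise channel differences are all
    strictly below ``threshold`` (template/background); keep the rest."""
    image = _check_rgb(image)
    if not 0 < threshold < 256:
        raise ValueError("threshold must lie in (0, 256)")
    r = image[..., 0].astype(np.int16)
    g = image[..., 1].astype(np.int16)
    b = image[..., 2].astype(np.int16)
    near_gray = ((np.abs(r - g) < threshold)
                 & (np.abs(r - b) < threshold)
                 & (np.abs(g - b) < threshold))
    out = image.copy()
    out[near_gray] = 255
    return out


def resize_and_scale(image: np.ndarray, side: int = IMAGE_SIDE) -> np.ndarray:
    """Bilinear resize to ``side``×``side`` and rescale intensities to [0, 1]."""
    if side <= 0:
        raise ValueError("side must be positive")
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    out = image.astype(np.float64) / 255.0
    if image.shape[:2] != (side, side):
        out = _sk_resize(out, (side, side), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def preprocess_image(image: np.ndarray, mean_kernel: int = 3,
                     median_kernel: int = 3,
                     threshold: int = GRAYSCALE_THRESHOLD,
                     side: int = IMAGE_SIDE) -> np.ndarray:
    """Full pipeline: denoise → grayscale suppression → resize/scale."""
    out = denoise(image, mean_kernel, median_kernel)
    out = suppress_grayscale(out, threshold)
    return resize_and_scale(out, side)


# ---------------------------------------------------------------------------
# structured features
# ---------------------------------------------------------------------------

def _encode(records: pd.DataFrame) -> pd.DataFrame:
    """Map categorical fields to {0, 1} and order the feature columns."""
    df = records.copy()
    for col, mapping in CATEGORICAL_MAPS.items():
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map(lambda v: mapping.get(v, np.nan))
    return df


def impute_features(records: pd.DataFrame,
                    statistics: dict[str, float] | None = None
                    ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fill missing feature values; numeric → column mean, categorical → mode.

    When ``statistics`` is None they are fitted on ``records`` (the fitting
    split); pass the returned dict to apply training statistics to held-out
    records.  A feature column with no observed value in the fitting split is
    rejected.
    """
    if len(records) < 1:
        raise ValueError("need at least one record")
    df = _encode(records)
    if statistics is None:
        statistics = {}
        for col in FEATURE_COLUMNS:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.notna().sum() == 0:
                raise ValueError(f"feature '{col}' entirely missing in the "
                                 "fitting split")
            if col in NUMERIC_FEATURES:
                statistics[col] = float(vals.mean())
            else:
                statistics[col] = float(vals.mode().iloc[0])
    for col in FEATURE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        df[col] = vals.fillna(statistics[col])
    return df, statistics


@dataclass
class FeaturePipeline:
    """Impute then min–max map the 6 structured features onto [0, π].

    x' = π (x − min) / (max − min), fitted on the training split; a constant
    feature maps to 0 and held-out values outside the fitted range are clipped
    to [0, π].
    """

    statistics: dict[str, float] | None = None
    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None
    feature_names: list[str] = field(
        default_factory=lambda: list(FEATURE_COLUMNS))

    @property
    def fitted(self) -> bool:
        return self.mins is not None

    def fit(self, records: pd.DataFrame) -> "FeaturePipeline":
        df, self.statistics = impute_features(records)
        mat = df[self.feature_names].to_numpy(dtype=float)
        self.mins = mat.min(axis=0)
        self.maxs = mat.max(axis=0)
        return self

    def transform(self, records: pd.DataFrame) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("FeaturePipeline must be fitted on the "
                               "training split before transform")
        df, _ = impute_features(records, self.statistics)
        mat = df[self.feature_names].to_numpy(dtype=float)
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        out = np.pi * (mat - self.mins) / safe
        out[:, span == 0] = 0.0
        return np.clip(out, 0.0, np.pi)

    def fit_transform(self, records: pd.DataFrame) -> np.ndarray:
        return self.fit(records).transform(records)
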