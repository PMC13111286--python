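"""Bridging exam directories to in-memory training arrays."""

from __future__ import annotations

import numpy as np

from .io import CLASS_TO_INT, DatasetManifest, FEATURE_COLUMNS, load_image
from .preprocessing import (FeaturePipeline, GRAYSCALE_THRESHOLD, IMAGE_SIDE,
                            preprocess_image)
from .training import ArrayDataset, make_folds

__all__ = ["preprocess_manifest", "split_holdout", "refit_features"]


def preprocess_manifest(manifest: DatasetManifest, side: int = IMAGE_SIDE,
                        mean_kernel: int = 3, median_kernel: int = 3,
                        threshold: int = GRAYSCALE_THRESHOLD,
                        dtype=np.float32) -> ArrayDataset:
    """Run the full image pipeline over a manifest and attach raw feature rows.

    The returned dataset's feature matrix is min–max fitted on the *whole*
    manifest; use :func:`split_holdout` (or grouped CV with ``feature_frame``)
    to refit imputation and scaling on a training split only.
    """
    recs = manifest.records
    images = np.stack([
        preprocess_image(load_image(p), mean_kernel, median_kernel,
                         threshold, side).astype(dtype)
        for p in recs["image_path"]])
    frame = recs[FEATURE_COLUMNS].copy()
    features = FeaturePipeline().fit_transform(frame).astype(dtype)
    return ArrayDataset(
        images=images, features=features,
        labels=recs["class_label"].map(CLASS_TO_INT).to_numpy(),
        sample_ids=recs["exam_id"].to_numpy(),
        patient_ids=recs["patient_id"].to_numpy(),
        feature_frame=frame)


def refit_features(train: ArrayDataset, *others: ArrayDataset
                   ) -> FeaturePipeline:
    """Refit imputation + [0, π] scaling on ``train`` and re-transform all
    given datasets in place (requires ``feature_frame``)."""
    if train.feature_frame is None:
        raise ValueError("datasets lack raw feature frames")
    pipe = FeaturePipeline().fit(train.feature_frame)
    for ds in (train, *others):
        ds.features = pipe.transform(ds.feature_frame).astype(
            ds.features.dtype)
    return pipe


def split_holdout(dataset: ArrayDataset, val_fraction: float = 0.2,
                  seed: int = 0, group_by_patient: bool = True
                  ) -> tuple[ArrayDataset, ArrayDataset]:
    """Stratified (optionally patient-grouped) train/validation split with
    feature statistics refitted on the training part."""
    k = max(2, int(round(1.0 / val_fraction)))
    groups = dataset.patient_ids if group_by_patient else None
    tr, va = make_folds(dataset.labels, k=k, patient_ids=groups, seed=seed)[0]
    train, val = dataset.subset(tr), dataset.subset(va)
    if train.feature_frame is not None:
        refit_features(train, val)
    return train, val
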