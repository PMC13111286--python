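"""Desk-scale end-to-end experiments on the synthetic exam generator.

These routines reproduce the study design — generate exams, preprocess, train
the dual-track model, evaluate, and probe explainability — at sizes a single
CPU handles in minutes: 40 control + 40 patient subjects with 4 draws each,
128×128 inputs and a two-stage CDAB plan.  They are the substance behind the
package's verification suite and the reproduction script.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from . import synthetic as syn
from .datasets import preprocess_manifest, split_holdout
from .explain import grad_cam, perturbation_sensitivity
from .io import FEATURE_COLUMNS
from .network import HybridModel, ModelConfig, build_model, reduced_config
from .preprocessing import FeaturePipeline, preprocess_image
from .training import (ArrayDataset, Metrics, TrainingConfig, evaluate,
                       train)

__all__ = ["DeskRun", "desk_scale_run", "gradcam_trace_overlap",
           "planted_feature_recovery", "DESK_N_SUBJECTS", "DESK_SIDE"]

DESK_N_SUBJECTS = 40      # per class
DESK_DRAWS = 4
DESK_SIDE = 128
DESK_EPOCHS = 8


@dataclass
class DeskRun:
    model: HybridModel
    train_set: ArrayDataset
    val_set: ArrayDataset
    metrics: Metrics
    history: list[dict]
    pipeline: FeaturePipeline


def desk_scale_run(seed: int = 0, quantum: bool = True,
                   data_dir: str | None = None,
                   n_subjects: int = DESK_N_SUBJECTS,
                   max_epochs: int = DESK_EPOCHS) -> DeskRun:
    """Generate the default synthetic cohort, train the reduced model on a
    stratified patient-grouped holdout split, and evaluate it.

    ``quantum=False`` trains the classical-ablation configuration (circuits
    replaced by dense layers of the same output width) under the identical
    harness.
    """
    from .io import read_exam_directory
    if data_dir is None:
        data_dir = tempfile.mkdtemp(prefix="qhandpd_desk_")
        syn.generate_dataset(n_subjects, n_subjects, DESK_DRAWS,
                             seed=seed, out_dir=data_dir)
    manifest = read_exam_directory(data_dir)
    full = preprocess_manifest(manifest, side=DESK_SIDE)
    train_set, val_set = split_holdout(full, val_fraction=0.2, seed=seed)
    model = build_model(reduced_config(quantum=quantum), seed=seed)
    cfg = TrainingConfig(max_epochs=max_epochs, seed=seed)
    model, history = train(model, train_set, val_set, cfg)
    metrics = evaluate(model, val_set)
    pipeline = FeaturePipeline().fit(train_set.feature_frame)
    return DeskRun(model=model, train_set=train_set, val_set=val_set,
                   metrics=metrics, history=history, pipeline=pipeline)


def gradcam_trace_overlap(model: HybridModel,
                          pipeline: FeaturePipeline | None = None,
                          seed: int = 0, n_exams: int = 10,
                          layer: str | None = None,
                          top_fraction: float = 0.05,
                          dilation_px: int = 5) -> dict:
    """Fraction of top-saliency pixels on the (dilated) pen-trace mask.

    Renders fresh patient exams with known trace geometry and computes
    Grad-CAM for the patient class at ``layer`` (default: the last CDAB
    stage); each exam is fed with its *own* derived structured features
    (rms/mrt/std from the simulated traces, patient-typical demographics),
    normalised by the training run's fitted ``pipeline`` — saliency explains
    the model's decision for a coherent sample, so pairing a patient image
    with foreign covariates would degrade it.
    """
    side = model.config.image_side
    rng = np.random.default_rng(seed)
    cfg = syn.TremorConfig()
    ages = syn.AgeModel()
    overlaps = []
    for i in range(n_exams):
        kind = "spiral" if i % 2 == 0 else "meander"
        template = syn.generate_template(kind, 3, 512)
        subject = syn.simulate_subject_trace(
            template, syn.TremorParams(cfg.pd_amplitude, cfg.pd_frequency,
                                       cfg.pd_jitter_sd,
                                       seed=int(rng.integers(2 ** 31))))
        image = preprocess_image(syn.rasterize_exam(template, subject),
                                 side=side).astype(np.float32)
        mask = _sk_resize(syn.trace_mask(subject, 512).astype(float),
                          (side, side), order=0) > 0
        mask = ndimage.binary_dilation(mask, iterations=dilation_px)
        rms, mrt, std_diff = syn.compute_structured_features(template, subject)
        row = pd.DataFrame([{"gender": "M", "handedness": "R",
                             "age": ages.sample("P", rng), "rms": rms,
                             "mrt": mrt, "std_diff": std_diff}])
        if pipeline is not None:
            features = pipeline.transform(row)[0].astype(np.float32)
        else:
            features = np.full(model.config.n_features, np.pi / 2,
                               dtype=np.float32)
        sal = grad_cam(model, image, features, target_class=1, layer=layer)
        top = sal.values >= np.quantile(sal.values, 1.0 - top_fraction)
        overlaps.append(float((top & mask).sum() / max(top.sum(), 1)))
    return {"overlaps": overlaps, "mean_overlap": float(np.mean(overlaps)),
            "n_exams": n_exams, "layer": sal.source_layer}


def _single_signal_records(seed: int, planted: str = "rms",
                           n_subjects: int = 15) -> pd.DataFrame:
    """Generator-derived records where only ``planted`` carries class signal.

    All other feature columns are permuted across samples, which preserves
    their marginal distributions but destroys any class association (the
    generator's ages and sex ratios are class-conditional by design).
    """
    recs = syn.simulate_feature_records(n_subjects, n_subjects, 4, seed=seed)
    rng = np.random.default_rng(seed + 1)
    for col in FEATURE_COLUMNS:
        if col != planted:
            recs[col] = rng.permutation(recs[col].to_numpy())
    return recs


def planted_feature_recovery(n_trials: int = 20, seed: int = 0,
                             planted: str = "rms",
                             n_repeats: int = 3) -> dict:
    """Recovery rate of a planted single-signal structured feature.

    Per trial: build a single-signal cohort, train the tabular-only circuit
    model (plain cross-entropy — the cohort is balanced), and check that
    permutation sensitivity ranks the planted feature first.
    """
    wins = 0
    accs = []
    for t in range(n_trials):
        trial_seed = seed * 1000 + t
        recs = _single_signal_records(trial_seed, planted)
        feats = FeaturePipeline().fit_transform(recs).astype(np.float32)
        labels = (recs["class_label"] == "P").to_numpy().astype(int)
        n = len(labels)
        ds = ArrayDataset(images=np.zeros((n, 1, 1, 3), np.float32),
                          features=feats, labels=labels,
                          sample_ids=recs["exam_id"].to_numpy())
        rng = np.random.default_rng(trial_seed)
        idx = rng.permutation(n)
        n_tr = int(n * 0.67)
        tr, va = ds.subset(idx[:n_tr]), ds.subset(idx[n_tr:])
        model = build_model(ModelConfig(use_image_track=False),
                            seed=trial_seed)
        model, hist = train(model, tr, va, TrainingConfig(
            max_epochs=60, lr=0.08, batch_size=16, focal_gamma=0.0,
            early_stopping_patience=15, seed=trial_seed))
        rep = perturbation_sensitivity(model, va, n_repeats=n_repeats,
                                       seed=trial_seed,
                                       feature_names=list(FEATURE_COLUMNS))
        wins += int(rep.top_feature() == planted)
        accs.append(hist[-1]["val_accuracy"])
    return {"n_trials": n_trials, "recovered": wins,
            "recovery_rate": wins / n_trials,
            "val_accuracies": accs}
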