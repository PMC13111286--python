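"""Explainability: Grad-CAM for the image track, perturbation sensitivity
for the structured track.

Grad-CAM weights a convolutional stage's activation maps by the spatial mean
of the class-score gradient and keeps the positive part; on tremor exams the
resulting saliency should concentrate on the wobbling pen trace.  The
structured-feature analysis perturbs one feature column at a time (permutation
by default, which preserves the marginal distribution) and scores each feature
by the resulting drop in accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from .autodiff import Tensor
from .network import HybridModel
from .training import ArrayDataset, _predict_probs

__all__ = ["SaliencyMap", "SensitivityReport", "grad_cam",
           "perturbation_sensitivity", "render_overlay"]


@dataclass
class SaliencyMap:
    values: np.ndarray            # (side, side) in [0, 1]
    target_class: int
    source_layer: str


@dataclass
class SensitivityReport:
    scores: np.ndarray            # per-feature, >= 0
    ranking: np.ndarray           # feature indices, descending score
    feature_names: list[str]
    mode: str
    n_repeats: int
    seed: int
    baseline_accuracy: float

    def top_feature(self) -> str:
        return self.feature_names[int(self.ranking[0])]


def grad_cam(model: HybridModel, image: np.ndarray,
             features: np.ndarray | None, target_class: int = 1,
             layer: str | None = None) -> SaliencyMap:
    """Class-activation saliency for one preprocessed image.

    ``layer`` names a captured stage ("stem", "stage0", …); default is the
    last CDAB stage.  The map is ReLU(Σ_k w_k A_k) with w_k the spatial mean
    of ∂(class logit)/∂A_k, bilinearly upsampled to the input size and min–max
    normalised (an all-zero map stays all-zero).
    """
    if not model.config.use_image_track:
        raise ValueError("grad_cam needs the image track")
    if layer is None:
        layer = f"stage{len(model.config.stage_channels) - 1}"
    model.eval()
    capture: dict[str, Tensor] = {}
    img_out, tab_out = model.track_outputs(image, features, capture=capture)
    if layer not in capture:
        raise ValueError(
            f"unknown layer '{layer}'; available: {sorted(capture)}")
    logits = model.fusion.logits(img_out, tab_out)
    score = logits[0, int(target_class)]
    model.zero_grad()
    score.backward()
    acts = capture[layer]
    grads = acts.grad
    if grads is None:
        grads = np.zeros_like(acts.data)
    weights = grads.mean(axis=(2, 3))                    # (1, C)
    cam = np.maximum((weights[0][:, None, None] * acts.data[0]).sum(0), 0.0)
    side = model.config.image_side
    cam = _sk_resize(cam, (side, side), order=1, mode="edge",
                     preserve_range=True, anti_aliasing=False)
    peak = cam.max()
    if peak > 0:
        cam = (cam - cam.min()) / (peak - cam.min())
    return SaliencyMap(values=cam.astype(np.float64),
                       target_class=int(target_class), source_layer=layer)


def perturbation_sensitivity(model: HybridModel, dataset: ArrayDataset,
                             mode: str = "permute", n_repeats: int = 5,
                             seed: int = 0,
                             feature_names: list[str] | None = None
                             ) -> SensitivityReport:
    """Score each structured feature by the accuracy drop its perturbation
    causes; ``mode`` is "permute" (shuffle the column) or "noise" (add
    Gaussian noise with the column's standard deviation)."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if len(dataset) < 2:
        raise ValueError("need at least 2 samples")
    if mode not in ("permute", "noise"):
        raise ValueError(f"unknown mode '{mode}'")
    rng = np.random.default_rng(seed)
    d = dataset.features.shape[1]
    names = feature_names or [f"feature_{j}" for j in range(d)]
    base_pred = _predict_probs(model, dataset).argmax(axis=1)
    baseline = float((base_pred == dataset.labels).mean())
    scores = np.zeros(d)
    for j in range(d):
        drops = []
        for _ in range(n_repeats):
            feats = dataset.features.copy()
            if mode == "permute":
                feats[:, j] = rng.permutation(feats[:, j])
            else:
                sd = feats[:, j].std()
                feats[:, j] = np.clip(
                    feats[:, j] + rng.normal(0, sd, size=len(feats)),
                    0.0, np.pi)
            ds = ArrayDataset(images=dataset.images, features=feats,
                              labels=dataset.labels,
                              sample_ids=dataset.sample_ids)
            pred = _predict_probs(model, ds).argmax(axis=1)
            drops.append(baseline - float((pred == dataset.labels).mean()))
        scores[j] = max(0.0, float(np.mean(drops)))
    ranking = np.argsort(-scores, kind="stable")
    return SensitivityReport(scores=scores, ranking=ranking,
                             feature_names=list(names), mode=mode,
                             n_repeats=n_repeats, seed=seed,
                             baseline_accuracy=baseline)


def render_overlay(image: np.ndarray, saliency: SaliencyMap,
                   colormap: str = "jet", alpha: float = 1.0) -> np.ndarray:
    """Alpha-blend the saliency heatmap over the drawing.

    The per-pixel blend weight is ``alpha * saliency``, so unsalient pixels
    show the original image and (with alpha 1) fully salient pixels show the
    pure colormap.  Returns an (H, W, 3) uint8 image.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.max() > 1.0:
        img = img / 255.0
    s = saliency.values
    if img.shape[:2] != s.shape:
        raise ValueError(
            f"image {img.shape[:2]} and saliency {s.shape} sizes differ")
    heat = colormaps[colormap](s)[..., :3]
    w = np.clip(alpha * s, 0.0, 1.0)[..., None]
    out = (1.0 - w) * img + w * heat
    return np.clip(np.rint(out * 255), 0, 255).astype(np.uint8)
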