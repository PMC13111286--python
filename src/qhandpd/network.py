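"""Assembly of the dual-track hybrid classifier.

Image track (TVSFE): 7×7 stem convolution, CDAB attention stages, global
average pooling, an embedding head ending in a layer-normalised, L2-normalised
256-vector, amplitude-embedded into 8 qubits and read out as 8 Pauli-Z
expectations.

Tabular track (VQFMN): the six structured features in [0, π], RY-encoded one
per qubit, passed through strongly entangling layers, read out as 6 Pauli-Z
expectations.

Fusion: per-track layer normalisation, concatenation and a small dense head
with a 2-class softmax.  All quantum pieces can be swapped for classical
layers of the same output width via config flags, so the three ablation
variants (image-only, tabular-only, no-quantum) are configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, concatenate
from .attention import BlockConfig, CDABBlock
from .quantum import (CircuitParams, amplitude_embed, angle_embed_ry,
                      entangling_layers, pauli_z_expectations)

__all__ = ["ModelConfig", "TVSFE", "VQFMN", "FusionClassifier",
           "HybridModel", "build_model", "count_parameters",
           "reduced_config"]


@dataclass
class ModelConfig:
    """Architecture knobs; the defaults are the full-size model."""

    image_side: int = 512
    in_channels: int = 3
    stem_channels: int = 32
    stem_kernel: int = 7
    stem_stride: int = 2
    stem_pool: int = 2
    stage_channels: tuple[int, ...] = (32, 64, 128, 256)
    stage_strides: tuple[int, ...] = (1, 2, 2, 2)
    stage_variants: tuple[str, ...] = ("CA_SE", "CA_SE", "TRIPLET", "TRIPLET")
    ghost_ratio: int = 2
    se_reduction: int = 8
    ca_reduction: int = 8
    embedding_dim: int = 256
    head_hidden: tuple[int, ...] = (2048,)
    leaky_relu_slope: float = 0.01
    image_qubits: int = 8
    image_circuit_depth: int = 2
    n_features: int = 6
    tabular_circuit_depth: int = 4
    fusion_hidden: tuple[int, ...] = (64, 32)
    use_image_track: bool = True
    use_tabular_track: bool = True
    quantum: bool = True

    def __post_init__(self):
        if self.use_image_track and 2 ** self.image_qubits != self.embedding_dim:
            raise ValueError(
                f"amplitude embedding needs 2^image_qubits == embedding_dim; "
                f"got 2^{self.image_qubits} != {self.embedding_dim}")
        if not (self.use_image_track or self.use_tabular_track):
            raise ValueError("at least one track must be enabled")
        if not (len(self.stage_channels) == len(self.stage_strides)
                == len(self.stage_variants)):
            raise ValueError("stage plan lists must have equal length")


def reduced_config(**overrides) -> ModelConfig:
    """Desk-scale configuration: 128×128 inputs, two CDAB stages."""
    base = dict(
        image_side=128,
        stem_channels=16,
        stage_channels=(16, 32),
        stage_strides=(1, 2),
        stage_variants=("CA_SE", "TRIPLET"),
        head_hidden=(128,),
    )
    base.update(overrides)
    return ModelConfig(**base)


class TVSFE(nn.Module):
    """Image track: attention CNN → 256-dim unit embedding → 8-qubit circuit."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        cfg = config
        self.config = cfg
        self.stem = nn.Conv2d(cfg.in_channels, cfg.stem_channels,
                              cfg.stem_kernel, stride=cfg.stem_stride,
                              padding=cfg.stem_kernel // 2, rng=rng)
        self.stem_bn = nn.BatchNorm2d(cfg.stem_channels)
        blocks = []
        in_ch = cfg.stem_channels
        for out_ch, stride, variant in zip(cfg.stage_channels,
                                           cfg.stage_strides,
                                           cfg.stage_variants):
            blocks.append(CDABBlock(BlockConfig(
                in_channels=in_ch, out_channels=out_ch, stride=stride,
                attention_variant=variant, ghost_ratio=cfg.ghost_ratio,
                se_reduction=cfg.se_reduction, ca_reduction=cfg.ca_reduction),
                rng=rng))
            in_ch = out_ch
        self.stages = nn.Sequential(*blocks)
        head = []
        width = in_ch
        for h in cfg.head_hidden:
            head.append(nn.Linear(width, h, rng=rng))
            head.append(nn.LeakyReLU(cfg.leaky_relu_slope))
            width = h
        head.append(nn.Linear(width, cfg.embedding_dim, rng=rng))
        self.head = nn.Sequential(*head)
        self.layer_norm = nn.LayerNorm(cfg.embedding_dim)
        if cfg.quantum:
            self.circuit = CircuitParams.random(
                cfg.image_qubits, cfg.image_circuit_depth, rng)
            self.circuit_angles = self.circuit.angles  # registered parameter
        else:
            self.readout = nn.Linear(cfg.embedding_dim, cfg.image_qubits,
                                     rng=rng)

    def embed(self, x: Tensor, capture: dict | None = None) -> Tensor:
        """Pre-quantum 256-dim embedding with unit L2 norm.

        ``capture`` (optional dict) collects the named intermediate feature
        maps ("stem", "stage0", …) for saliency analysis.
        """
        side = self.config.image_side
        if x.shape[2] != side or x.shape[3] != side:
            raise ValueError(
                f"expected {side}x{side} inputs, got {x.shape[2]}x{x.shape[3]}")
        h = self.stem_bn(self.stem(x)).relu()
        if capture is not None:
            capture["stem"] = h
        if self.config.stem_pool > 1:
            h = nn.max_pool2d(h, self.config.stem_pool)
        for i, block in enumerate(self.stages.layers):
            h = block(h)
            if capture is not None:
                capture[f"stage{i}"] = h
        h = nn.global_avg_pool(h)
        emb = self.head(h)
        emb = self.layer_norm(emb)
        norm = ((emb ** 2).sum(axis=1, keepdims=True) ** 0.5).clamp_min(1e-12)
        return emb / norm

    def forward(self, x: Tensor, capture: dict | None = None) -> Tensor:
        emb = self.embed(x, capture)
        if not self.config.quantum:
            return self.readout(emb)
        state = amplitude_embed(emb, self.config.image_qubits)
        state = entangling_layers(state, self.circuit)
        return pauli_z_expectations(state)


class VQFMN(nn.Module):
    """Tabular track: RY encoding → strongly entangling layers → ⟨Z⟩ vector."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        d = config.n_features
        if config.quantum:
            self.circuit = CircuitParams.random(
                d, config.tabular_circuit_depth, rng)
            self.circuit_angles = self.circuit.angles
        else:
            self.mlp = nn.Sequential(
                nn.Linear(d, 4 * d, rng=rng), nn.ReLU(),
                nn.Linear(4 * d, d, rng=rng))

    def forward(self, features: Tensor) -> Tensor:
        if features.shape[-1] != self.config.n_features:
            raise ValueError(
                f"expected {self.config.n_features} features, "
                f"got {features.shape[-1]}")
        if not self.config.quantum:
            return self.mlp(features)
        state = angle_embed_ry(features)
        state = entangling_layers(state, self.circuit)
        return pauli_z_expectations(state)


class FusionClassifier(nn.Module):
    """Per-track layer norm → concatenation → dense head → 2-class softmax."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        cfg = config
        self.config = cfg
        width = 0
        if cfg.use_image_track:
            self.norm_img = nn.LayerNorm(cfg.image_qubits)
            width += cfg.image_qubits
        if cfg.use_tabular_track:
            self.norm_tab = nn.LayerNorm(cfg.n_features)
            width += cfg.n_features
        layers = []
        for h in cfg.fusion_hidden:
            layers.append(nn.Linear(width, h, rng=rng))
            layers.append(nn.LeakyReLU(cfg.leaky_relu_slope))
            width = h
        layers.append(nn.Linear(width, 2, rng=rng))
        self.head = nn.Sequential(*layers)

    def logits(self, img_out: Tensor | None, tab_out: Tensor | None) -> Tensor:
        parts = []
        if self.config.use_image_track:
            parts.append(self.norm_img(img_out))
        if self.config.use_tabular_track:
            parts.append(self.norm_tab(tab_out))
        z = parts[0] if len(parts) == 1 else concatenate(parts, axis=1)
        return self.head(z)

    def forward(self, img_out: Tensor | None, tab_out: Tensor | None) -> Tensor:
        return nn.softmax(self.logits(img_out, tab_out), axis=1)


class HybridModel(nn.Module):
    """The full dual-track classifier (or an ablated variant)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        if config.use_image_track:
            self.tvsfe = TVSFE(config, rng)
        if config.use_tabular_track:
            self.vqfmn = VQFMN(config, rng)
        self.fusion = FusionClassifier(config, rng)

    @staticmethod
    def _to_nchw(images) -> Tensor:
        if isinstance(images, Tensor):
            return images
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.shape[-1] in (1, 3):
            arr = arr.transpose(0, 3, 1, 2)
        if arr.shape[1] == 1:
            arr = np.repeat(arr, 3, axis=1)
        return Tensor(arr)

    def track_outputs(self, images=None, features=None,
                      capture: dict | None = None
                      ) -> tuple[Tensor | None, Tensor | None]:
        img_out = tab_out = None
        if self.config.use_image_track:
            img_out = self.tvsfe(self._to_nchw(images), capture)
        if self.config.use_tabular_track:
            t = features if isinstance(features, Tensor) else Tensor(
                np.asarray(features, dtype=np.float32))
            if t.ndim == 1:
                t = t.reshape(1, -1)
            tab_out = self.vqfmn(t)
        return img_out, tab_out

    def forward(self, images=None, features=None) -> Tensor:
        return self.fusion(*self.track_outputs(images, features))

    def predict_proba(self, images=None, features=None) -> np.ndarray:
        from .autodiff import no_grad
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                p = self.forward(images, features).data
        finally:
            if was_training:
                self.train()
        return p


def build_model(config: ModelConfig | None = None, seed: int = 0
                ) -> HybridModel:
    """Construct a model with seeded weight initialisation."""
    return HybridModel(config or ModelConfig(), np.random.default_rng(seed))


def count_parameters(model: HybridModel) -> dict[str, int]:
    """Trainable scalar parameter counts per track and total."""
    counts = {}
    if model.config.use_image_track:
        counts["tvsfe"] = model.tvsfe.count_parameters()
    if model.config.use_tabular_track:
        counts["vqfmn"] = model.vqfmn.count_parameters()
    counts["fusion"] = model.fusion.count_parameters()
    counts["total"] = model.count_parameters()
    return counts
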