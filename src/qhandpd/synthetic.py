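"""Synthetic spiral/meander exam generator with controllable tremor.

Emulates the HandPD exam format end-to-end: a printed near-gray template curve
(Archimedean spiral or square-wave meander) overdrawn by a saturated pen trace,
plus the per-sample metadata CSV with clinical fields and the three
handwriting-derived statistics (RMS, MRT, standard deviation of template–trace
deviations).  Patient traces wobble sinusoidally along the local curve normal
— a first-order stand-in for resting tremor — while control traces carry only
small Gaussian pen jitter.

Class-conditional ages follow the published HandPD cohort statistics:
controls ~ N(44.22, 16.53²), patients ~ N(58.75, 7.51²), truncated to
[18, 90] years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .io import CLASS_FOLDERS, DatasetManifest, META_COLUMNS, read_exam_directory

__all__ = [
    "PolylineTrace", "TremorParams", "TremorConfig", "AgeModel",
    "generate_template", "simulate_subject_trace", "rasterize_exam",
    "compute_structured_features", "generate_dataset",
    "DEFAULT_TEMPLATE_COLOR", "DEFAULT_PEN_COLOR", "trace_mask",
]

#: printed template: near-gray ink (suppressed by the grayscale predicate)
DEFAULT_TEMPLATE_COLOR = (110, 110, 110)
#: subject pen: saturated blue (survives suppression)
DEFAULT_PEN_COLOR = (30, 30, 200)

STROKE_WIDTH = 3  # px; anti-aliasing off so the suppression predicate is crisp


@dataclass
class PolylineTrace:
    """Ordered 2-D point sequence in canvas pixel coordinates."""

    points: np.ndarray          # (n, 2) float
    kind: str                   # "spiral" | "meander"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 \
                or len(self.points) < 2:
            raise ValueError("a trace needs >= 2 two-dimensional points")
        if self.kind not in ("spiral", "meander"):
            raise ValueError(f"unknown trace kind '{self.kind}'")


@dataclass
class TremorParams:
    """Sinusoidal-plus-jitter displacement model along the curve normal.

    ``amplitude`` (px) and ``frequency`` (oscillation cycles over the whole
    trace) shape the deterministic tremor; ``jitter_sd`` (px) adds i.i.d.
    Gaussian pen noise.  ``amplitude == jitter_sd == 0`` reproduces the
    template exactly.
    """

    amplitude: float = 0.0
    frequency: float = 0.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0 or self.frequency < 0 or self.jitter_sd < 0:
            raise ValueError("tremor amplitude/frequency/jitter must be >= 0")


@dataclass
class TremorConfig:
    """Class-conditional tremor settings for dataset generation."""

    pd_amplitude: float = 6.0      # px, produces clearly visible wobble
    pd_frequency: float = 30.0     # cycles along the full trace (~4-6/turn)
    pd_jitter_sd: float = 1.0      # px
    control_jitter_sd: float = 0.75  # px; controls have amplitude 0


@dataclass
class AgeModel:
    """Truncated-normal age distributions per class (years)."""

    control_mean: float = 44.22
    control_sd: float = 16.53
    pd_mean: float = 58.75
    pd_sd: float = 7.51
    lo: float = 18.0
    hi: float = 90.0

    def sample(self, label: str, rng: np.random.Generator) -> float:
        mu, sd = ((self.control_mean, self.control_sd) if label == "H"
                  else (self.pd_mean, self.pd_sd))
        for _ in range(1000):
            a = rng.normal(mu, sd)
            if self.lo <= a <= self.hi:
                return float(round(a, 1))
        return float(np.clip(mu, self.lo, self.hi))


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def generate_template(kind: str, n_turns: int = 3, canvas_size: int = 512,
                      seed: int = 0, points_per_turn: int = 400
                      ) -> PolylineTrace:
    """Deterministic template curve centred on the canvas.

    ``spiral`` is an Archimedean curve r = a + bθ sampled densely over
    ``n_turns`` revolutions; ``meander`` is a square-wave path sweeping the
    canvas with ``n_turns`` periods.
    """
    if kind not in ("spiral", "meander"):
        raise ValueError(f"invalid template kind '{kind}'")
    if n_turns < 1:
        raise ValueError("n_turns must be >= 1")
    if canvas_size < 64:
        raise ValueError("canvas_size must be >= 64")
    margin = canvas_size * 0.12
    c = canvas_size / 2.0
    if kind == "spiral":
        theta = np.linspace(0.0, 2.0 * np.pi * n_turns,
                            int(points_per_turn * n_turns))
        a = canvas_size * 0.01
        b = (c - margin - a) / (2.0 * np.pi * n_turns)
        r = a + b * theta
        pts = np.stack([c + r * np.cos(theta), c + r * np.sin(theta)], axis=1)
    else:
        # horizontal square wave: n_turns full periods across the canvas
        lo, hi = margin, canvas_size - margin
        period = (hi - lo) / n_turns
        xs: list[float] = []
        ys: list[float] = []
        y0, y1 = lo + (hi - lo) * 0.25, lo + (hi - lo) * 0.75
        x = lo
        level = y0
        xs.append(x), ys.append(level)
        for _ in range(2 * n_turns):
            x2 = min(x + period / 2.0, hi)
            xs.extend([x2, x2])
            other = y1 if level == y0 else y0
            ys.extend([level, other])
            x, level = x2, other
        corners = np.stack([xs, ys], axis=1)
        # densify so arc-length sampling is smooth
        pts_list = []
        per_seg = max(8, int(points_per_turn / 4))
        for p, q in zip(corners[:-1], corners[1:]):
            t = np.linspace(0.0, 1.0, per_seg, endpoint=False)
            pts_list.append(p[None, :] * (1 - t[:, None]) + q[None, :] * t[:, None])
        pts_list.append(corners[-1:])
        pts = np.concatenate(pts_list, axis=0)
    pts = np.clip(pts, 0, canvas_size - 1)
    return PolylineTrace(points=pts, kind=kind)


def _unit_normals(points: np.ndarray) -> np.ndarray:
    """Unit normal at each vertex from central-difference tangents."""
    tang = np.gradient(points, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tang = tang / norms
    return np.stack([-tang[:, 1], tang[:, 0]], axis=1)


def _arc_length_fraction(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1] if s[-1] > 0 else 1.0
    return s / total


def simulate_subject_trace(template: PolylineTrace, tremor: TremorParams
                           ) -> PolylineTrace:
    """Displace each template point along its local normal.

    displacement_i = amplitude * sin(2π * frequency * s_i) + N(0, jitter_sd²)
    with s_i the normalised arc length, so zero tremor reproduces the template
    point-for-point.
    """
    pts = template.points
    normals = _unit_normals(pts)
    s = _arc_length_fraction(pts)
    disp = tremor.amplitude * np.sin(2.0 * np.pi * tremor.frequency * s)
    if tremor.jitter_sd > 0:
        rng = np.random.default_rng(tremor.seed)
        disp = disp + rng.normal(0.0, tremor.jitter_sd, size=len(pts))
    return PolylineTrace(points=pts + disp[:, None] * normals,
                         kind=template.kind)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _is_near_grayscale(color: tuple[int, int, int], threshold: int = 45) -> bool:
    r, g, b = color
    return abs(r - g) < threshold and abs(r - b) < threshold \
        and abs(g - b) < threshold


def rasterize_exam(template: PolylineTrace, subject: PolylineTrace,
                   canvas_size: int = 512,
                   template_color: tuple[int, int, int] = DEFAULT_TEMPLATE_COLOR,
                   pen_color: tuple[int, int, int] = DEFAULT_PEN_COLOR
                   ) -> np.ndarray:
    """Render template then subject strokes on a white canvas (RGB uint8).

    The template ink must be near-grayscale (all pairwise channel differences
    < 45, so preprocessing suppresses it) and the pen ink saturated (at least
    one difference >= 45, so it survives); the subject stroke is drawn last
    and occludes the template where they overlap.
    """
    if not _is_near_grayscale(template_color):
        raise ValueError("template_color must be near-grayscale "
                         "(pairwise channel differences < 45)")
    if _is_near_grayscale(pen_color):
        raise ValueError("pen_color must be saturated (>= one pairwise "
                         "channel difference >= 45); a near-gray pen would "
                         "be removed by grayscale suppression")
    img = Image.new("RGB", (canvas_size, canvas_size), (255, 255, 255))
    draw = ImageDraw.Draw(img)  # PIL lines are not anti-aliased
    for trace, color in ((template, template_color), (subject, pen_color)):
        xy = [tuple(p) for p in np.clip(trace.points, 0, canvas_size - 1)]
        draw.line(xy, fill=color, width=STROKE_WIDTH, joint="curve")
    return np.asarray(img)


def trace_mask(trace: PolylineTrace, canvas_size: int = 512) -> np.ndarray:
    """Boolean mask of the pixels a trace's stroke covers."""
    img = Image.new("L", (canvas_size, canvas_size), 0)
    draw = ImageDraw.Draw(img)
    xy = [tuple(p) for p in np.clip(trace.points, 0, canvas_size - 1)]
    draw.line(xy, fill=255, width=STROKE_WIDTH, joint="curve")
    return np.asarray(img) > 0


# ---------------------------------------------------------------------------
# derived features
# ---------------------------------------------------------------------------

def compute_structured_features(template: PolylineTrace,
                                subject: PolylineTrace
                                ) -> tuple[float, float, float]:
    """(rms, mrt, std_diff) of the point-wise template–trace deviations.

    d_i is the Euclidean deviation of point i; RMS = sqrt(mean d²);
    MRT = mean |d_{i+1} − d_i| (mean absolute first difference — the dataset's
    "mean relative tremor" is not formally defined, this stand-in captures
    deviation oscillation rather than magnitude); std_diff = population
    standard deviation of d.
    """
    if len(template.points) != len(subject.points):
        raise ValueError("template and subject must have equal point counts")
    d = np.linalg.norm(subject.points - template.points, axis=1)
    rms = float(np.sqrt(np.mean(d ** 2)))
    mrt = float(np.mean(np.abs(np.diff(d))))
    std_diff = float(np.std(d))
    return rms, mrt, std_diff


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def simulate_feature_records(n_control: int, n_pd: int,
                             draws_per_subject: int = 4,
                             tremor_config: TremorConfig | None = None,
                             seed: int = 0, canvas_size: int = 512,
                             n_turns: int = 3,
                             age_model: AgeModel | None = None
                             ) -> pd.DataFrame:
    """Metadata rows only (no rasterization) — fast path for tabular studies.

    Same sampling scheme as :func:`generate_dataset` but skips image I/O.
    """
    if n_control < 1 or n_pd < 1 or draws_per_subject < 1:
        raise ValueError("subject and draw counts must be >= 1")
    cfg = tremor_config or TremorConfig()
    ages = age_model or AgeModel()
    rng = np.random.default_rng(seed)
    rows = []
    exam_id = 0
    for label, count, prefix in (("H", n_control, "C"), ("P", n_pd, "D")):
        for idx in range(count):
            patient_id = f"{prefix}{idx + 1:03d}"
            age = ages.sample(label, rng)
            p_male = 6 / 18 if label == "H" else 59 / 74
            gender = "M" if rng.random() < p_male else "F"
            handedness = "R" if rng.random() < 0.9 else "L"
            for d in range(draws_per_subject):
                kind = "spiral" if d % 2 == 0 else "meander"
                template = generate_template(kind, n_turns=n_turns,
                                             canvas_size=canvas_size)
                if label == "P":
                    tremor = TremorParams(cfg.pd_amplitude, cfg.pd_frequency,
                                          cfg.pd_jitter_sd,
                                          seed=int(rng.integers(2 ** 31)))
                else:
                    tremor = TremorParams(0.0, 0.0, cfg.control_jitter_sd,
                                          seed=int(rng.integers(2 ** 31)))
                subject = simulate_subject_trace(template, tremor)
                rms, mrt, std_diff = compute_structured_features(template,
                                                                 subject)
                exam_id += 1
                rows.append({
                    "exam_id": exam_id,
                    "image_name": f"{patient_id}_{d + 1}_{kind}.png",
                    "patient_id": patient_id, "class_label": label,
                    "gender": gender, "handedness": handedness, "age": age,
                    "rms": rms, "mrt": mrt, "std_diff": std_diff})
    return pd.DataFrame(rows, columns=META_COLUMNS)


def generate_dataset(n_control: int, n_pd: int, draws_per_subject: int = 4,
                     tremor_config: TremorConfig | None = None,
                     seed: int = 0, out_dir: str | Path = "synthetic_handpd",
                     canvas_size: int = 512, n_turns: int = 3,
                     age_model: AgeModel | None = None) -> DatasetManifest:
    """Write a HandPD-layout synthetic dataset and return its manifest.

    Each subject contributes ``draws_per_subject`` exams alternating spiral
    and meander.  Control subjects draw with pen jitter only (tremor amplitude
    0); patients add the sinusoidal tremor from ``tremor_config``.  Fully
    deterministic per ``seed``.
    """
    if n_control < 1 or n_pd < 1 or draws_per_subject < 1:
        raise ValueError("subject and draw counts must be >= 1")
    cfg = tremor_config or TremorConfig()
    ages = age_model or AgeModel()
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    for folder in CLASS_FOLDERS.values():
        (out / folder).mkdir(parents=True, exist_ok=True)

    rows = []
    exam_id = 0
    subjects = [("H", i) for i in range(n_control)] + \
               [("P", i) for i in range(n_pd)]
    for label, idx in subjects:
        patient_id = f"{'C' if label == 'H' else 'D'}{idx + 1:03d}"
        age = ages.sample(label, rng)
        # cohort sex ratios: controls 6M/12F, patients 59M/15F
        p_male = 6 / 18 if label == "H" else 59 / 74
        gender = "M" if rng.random() < p_male else "F"
        handedness = "R" if rng.random() < 0.9 else "L"
        for d in range(draws_per_subject):
            kind = "spiral" if d % 2 == 0 else "meander"
            template = generate_template(kind, n_turns=n_turns,
                                         canvas_size=canvas_size)
            if label == "P":
                tremor = TremorParams(
                    amplitude=cfg.pd_amplitude, frequency=cfg.pd_frequency,
                    jitter_sd=cfg.pd_jitter_sd,
                    seed=int(rng.integers(2 ** 31)))
            else:
                tremor = TremorParams(
                    amplitude=0.0, frequency=0.0,
                    jitter_sd=cfg.control_jitter_sd,
                    seed=int(rng.integers(2 ** 31)))
            subject = simulate_subject_trace(template, tremor)
            image = rasterize_exam(template, subject, canvas_size=canvas_size)
            rms, mrt, std_diff = compute_structured_features(template, subject)
            image_name = f"{patient_id}_{d + 1}_{kind}.png"
            folder = CLASS_FOLDERS[label]
            Image.fromarray(image).save(out / folder / image_name)
            exam_id += 1
            rows.append({
                "exam_id": exam_id, "image_name": image_name,
                "patient_id": patient_id, "class_label": label,
                "gender": gender, "handedness": handedness, "age": age,
                "rms": round(rms, 6), "mrt": round(mrt, 6),
                "std_diff": round(std_diff, 6),
            })
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    meta.to_csv(out / "meta.csv", index=False)
    return read_exam_directory(out)
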