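"""Synthetic cohort generator with known ground truth.

Emulates a two-group body-image study end to end: group-structured spatial
concern probabilities on the manikin raster (concern outlines are sampled
ellipses), concern-type/affect/intensity annotations, tape-measured body
sizes, and avatar slider settings derived from a perceived size (true size
plus a per-group perception bias plus noise) pushed through the inverse
calibration map.  Every draw is reproducible from ``(config, config.seed)``.

Region geometry is specified in normalized coordinates (fractions of raster
width/height) so the same configuration scales to any raster size.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .avatar import CalibrationAnchors, CalibrationTable, cm_to_slider
from .cohort import (
    DEFAULT_CONCERN_TYPES,
    MEASURED_PARTS,
    NEGATIVE_AFFECTS,
    NEUTRAL_POSITIVE_AFFECTS,
    Affect,
    AvatarSettings,
    BodyMeasurements,
    Cohort,
    ConcernEntry,
    SubjectRecord,
    validate_cohort,
)
from .geometry import rasterize_outline

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSpec",
    "GeneratorConfig",
    "default_config",
    "planted_effect_config",
    "null_config",
    "generate_cohort",
    "null_cohort",
    "region_mask",
    "default_calibration",
]


@dataclass(frozen=True)
class RegionSpec:
    """An elliptical concern region in normalized raster coordinates.

    ``center``/``axes`` are fractions of (width, height); ``center_jitter``
    is the SD of the per-subject center displacement (fraction of the raster
    diagonal-ish min dimension) and ``axes_jitter`` the lognormal SD of the
    per-subject axis scaling.
    """

    name: str
    center: tuple[float, float]
    axes: tuple[float, float]
    center_jitter: float = 0.02
    axes_jitter: float = 0.15
    n_vertices: int = 24


@dataclass
class GroupSpec:
    """Per-group generative parameters."""

    n: int
    region_probs: dict[str, float]
    true_size_mean: dict[str, float]
    true_size_sd: dict[str, float]
    bias_cm: dict[str, float]
    intensity_mean: float = 32.0
    intensity_sd: float = 30.0
    demographics_mean: dict[str, float] = field(default_factory=dict)
    demographics_sd: dict[str, float] = field(default_factory=dict)
    usability_mean: dict[str, float] = field(default_factory=dict)
    usability_sd: dict[str, float] = field(default_factory=dict)


@dataclass
class GeneratorConfig:
    raster_dims: tuple[int, int]
    regions: list[RegionSpec]
    groups: dict[str, GroupSpec]
    calibration: CalibrationTable
    concern_type_weights: dict[str, float] = field(default_factory=dict)
    affect_weights: dict[str, float] = field(default_factory=dict)
    perception_noise_sd: float = 4.0
    with_3d: bool = True
    seed: int = 0

    def __post_init__(self):
        for name, g in self.groups.items():
            if g.n < 1:
                raise ValueError(f"group '{name}' size must be >= 1, got {g.n}")
            for rname, p in g.region_probs.items():
                if not (0 <= p <= 1):
                    raise ValueError(
                        f"group '{name}' region '{rname}' probability {p} outside [0, 1]"
                    )
        if self.perception_noise_sd < 0:
            raise ValueError("perception_noise_sd must be >= 0")


def default_calibration() -> CalibrationTable:
    """Calibration anchors of the default female avatar mesh.

    Baselines (m05) approximate the scanned volunteer's part sizes; the
    sliders span half to one-and-a-half times the baseline, wide enough to
    represent the population spread of each part.
    """
    baseline = {
        "shoulders": 34.0, "bust": 83.0, "biceps": 25.0, "waist": 69.0,
        "hips": 92.0, "thighs": 45.0, "calves": 36.0,
    }
    return CalibrationTable(
        anchors={
            part: CalibrationAnchors(0.5 * m, m, 1.5 * m)
            for part, m in baseline.items()
        },
        mesh="female",
    )


_DEFAULT_REGIONS = [
    RegionSpec("bust", center=(0.50, 0.32), axes=(0.14, 0.045)),
    RegionSpec("waist", center=(0.50, 0.42), axes=(0.15, 0.035)),
    RegionSpec("abdomen", center=(0.50, 0.47), axes=(0.13, 0.055)),
    RegionSpec("buttocks", center=(0.50, 0.55), axes=(0.15, 0.05)),
    RegionSpec("thighs", center=(0.50, 0.65), axes=(0.16, 0.08)),
]

# study-anchored group parameters: true part sizes, perception biases (cm),
# demographics and usability summaries per group
_MODEL = GroupSpec(
    n=65,
    region_probs={"thighs": 0.50, "buttocks": 0.30, "abdomen": 0.20,
                  "bust": 0.10, "waist": 0.10},
    true_size_mean={"shoulders": 35.18, "bust": 80.58, "biceps": 22.37,
                    "waist": 64.68, "hips": 89.03, "thighs": 44.58, "calves": 32.51},
    true_size_sd={"shoulders": 2.17, "bust": 3.99, "biceps": 2.30,
                  "waist": 4.94, "hips": 4.65, "thighs": 3.02, "calves": 2.75},
    bias_cm={"shoulders": -3.83, "bust": -3.23, "biceps": 0.01,
             "waist": -4.30, "hips": 0.58, "thighs": -12.95, "calves": -2.86},
    intensity_mean=26.8,
    intensity_sd=29.3,
    demographics_mean={"age": 25.4, "height_cm": 175.9, "weight_kg": 57.5},
    demographics_sd={"age": 5.2, "height_cm": 5.1, "weight_kg": 4.4},
    usability_mean={"ease": 8.4, "enjoyment": 5.9, "identification": 4.9,
                    "closeness": 72.7},
    usability_sd={"ease": 2.42, "enjoyment": 2.34, "identification": 2.75,
                  "closeness": 20.17},
)
_NONMODEL = GroupSpec(
    n=38,
    region_probs={"thighs": 0.25, "buttocks": 0.15, "abdomen": 0.45,
                  "bust": 0.20, "waist": 0.35},
    true_size_mean={"shoulders": 32.11, "bust": 85.76, "biceps": 28.61,
                    "waist": 74.11, "hips": 96.11, "thighs": 46.53, "calves": 42.08},
    true_size_sd={"shoulders": 2.22, "bust": 6.01, "biceps": 6.18,
                  "waist": 6.45, "hips": 7.09, "thighs": 7.09, "calves": 6.09},
    bias_cm={"shoulders": -0.59, "bust": -6.54, "biceps": -4.34,
             "waist": -11.91, "hips": -5.04, "thighs": -12.05, "calves": -10.53},
    intensity_mean=38.4,
    intensity_sd=31.4,
    demographics_mean={"age": 23.4, "height_cm": 162.5, "weight_kg": 56.9},
    demographics_sd={"age": 5.5, "height_cm": 6.3, "weight_kg": 8.4},
    usability_mean={"ease": 8.5, "enjoyment": 7.4, "identification": 5.6,
                    "closeness": 75.2},
    usability_sd={"ease": 1.76, "enjoyment": 2.43, "identification": 2.34,
                  "closeness": 17.09},
)


def default_config(seed: int = 0, raster_dims: tuple[int, int] = (400, 800)) -> GeneratorConfig:
    """Two-group configuration mirroring the pilot study conditions."""
    return GeneratorConfig(
        raster_dims=raster_dims,
        regions=list(_DEFAULT_REGIONS),
        groups={"model": copy.deepcopy(_MODEL), "nonmodel": copy.deepcopy(_NONMODEL)},
        calibration=default_calibration(),
        concern_type_weights={t: 1.0 for t in DEFAULT_CONCERN_TYPES},
        affect_weights={
            **{a: 2.0 for a in NEGATIVE_AFFECTS[:6]},
            **{a: 1.0 for a in NEGATIVE_AFFECTS[6:]},
            **{a: 1.0 for a in NEUTRAL_POSITIVE_AFFECTS},
        },
        seed=seed,
    )


def _slim_group(n: int, probs: dict[str, float], bias: float = 0.0) -> GroupSpec:
    g = copy.deepcopy(_MODEL)
    g.n = n
    g.region_probs = dict(probs)
    g.bias_cm = {part: bias for part in MEASURED_PARTS}
    return g


def planted_effect_config(
    p_a: float = 0.6,
    p_b: float = 0.2,
    n_a: int = 40,
    n_b: int = 40,
    raster_dims: tuple[int, int] = (64, 128),
    seed: int = 0,
    region: RegionSpec | None = None,
) -> GeneratorConfig:
    """Single planted elliptical region with different concern probability
    per group; used for power/recovery studies."""
    region = region or RegionSpec(
        "planted", center=(0.5, 0.55), axes=(0.18, 0.10),
        center_jitter=0.02, axes_jitter=0.10,
    )
    return GeneratorConfig(
        raster_dims=raster_dims,
        regions=[region],
        groups={
            "a": _slim_group(n_a, {region.name: p_a}),
            "b": _slim_group(n_b, {region.name: p_b}),
        },
        calibration=default_calibration(),
        concern_type_weights={t: 1.0 for t in DEFAULT_CONCERN_TYPES[:4]},
        affect_weights={a: 1.0 for a in NEGATIVE_AFFECTS[:4]},
        with_3d=False,
        seed=seed,
    )


def null_config(
    p: float = 0.35,
    n_per_group: tuple[int, int] = (20, 20),
    raster_dims: tuple[int, int] = (64, 128),
    seed: int = 0,
) -> GeneratorConfig:
    """Both groups share one spatial concern model (for type-I error studies)."""
    cfg = planted_effect_config(
        p_a=p, p_b=p, n_a=n_per_group[0], n_b=n_per_group[1],
        raster_dims=raster_dims, seed=seed,
    )
    return cfg


def region_mask(config: GeneratorConfig, name: str) -> np.ndarray:
    """Ground-truth binary mask of a region's nominal (jitter-free) ellipse."""
    for r in config.regions:
        if r.name == name:
            poly = _ellipse_polygon(
                np.array(r.center) * config.raster_dims,
                np.array(r.axes) * config.raster_dims,
                0.0, r.n_vertices, config.raster_dims,
            )
            return rasterize_outline(poly, config.raster_dims)
    raise KeyError(f"no region named '{name}'")


def _ellipse_polygon(center, axes, angle, k, dims):
    t = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    x = axes[0] * np.cos(t)
    y = axes[1] * np.sin(t)
    c, s = np.cos(angle), np.sin(angle)
    px = center[0] + c * x - s * y
    py = center[1] + s * x + c * y
    w, h = dims
    px = np.clip(px, 0.0, float(w))
    py = np.clip(py, 0.0, float(h))
    return list(zip(px.tolist(), py.tolist()))


def _sample_labels(rng, weights: dict[str, float], k: int) -> list[str]:
    if not weights or k <= 0:
        return []
    labels = list(weights)
    w = np.asarray([weights[l] for l in labels], dtype=float)
    w = w / w.sum()
    k = min(k, len(labels))
    picked = rng.choice(len(labels), size=k, replace=False, p=w)
    return [labels[i] for i in picked]


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a full cohort from the configured generative model.

    Deterministic under a fixed ``config.seed``.  Perceived sizes that fall
    outside the calibration range are clipped to it before inversion; clip
    counts are logged per part, and a part whose perceived size clips for an
    entire group raises (the configured bias is unrepresentable — extend the
    calibration range).
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.raster_dims
    dims = (w, h)
    region_by_name = {r.name: r for r in config.regions}
    subjects: list[SubjectRecord] = []
    clip_counts: dict[str, int] = {}
    group_clip_all: dict[tuple[str, str], bool] = {}

    for gname, gspec in config.groups.items():
        part_clipped = {part: 0 for part in MEASURED_PARTS}
        for i in range(gspec.n):
            sid = f"{gname}-{i:03d}"
            concerns = []
            for rname, p in gspec.region_probs.items():
                if rng.random() >= p:
                    continue
                r = region_by_name[rname]
                center = (np.array(r.center) + rng.normal(0, r.center_jitter, 2)) * dims
                axes = np.array(r.axes) * dims * np.exp(rng.normal(0, r.axes_jitter, 2))
                axes = np.maximum(axes, 1.0)
                angle = rng.uniform(0, np.pi)
                center = np.clip(center, axes * 0, [w, h])
                poly = _ellipse_polygon(center, axes, angle, r.n_vertices, dims)
                n_types = int(rng.integers(1, 4))
                n_affects = int(rng.integers(1, 3))
                concerns.append(
                    ConcernEntry(
                        polygon=poly,
                        concern_types=_sample_labels(rng, config.concern_type_weights, n_types),
                        affects=[Affect(l) for l in _sample_labels(rng, config.affect_weights, n_affects)],
                        intensity=float(np.clip(rng.normal(gspec.intensity_mean, gspec.intensity_sd), 0, 100)),
                    )
                )

            avatar = None
            measured = None
            if config.with_3d:
                sizes = {}
                sliders = {}
                for part in MEASURED_PARTS:
                    true = max(rng.normal(gspec.true_size_mean[part], gspec.true_size_sd[part]), 1.0)
                    sizes[part] = true
                    perceived = true + gspec.bias_cm.get(part, 0.0)
                    if config.perception_noise_sd > 0:
                        perceived += rng.normal(0, config.perception_noise_sd)
                    a = config.calibration.anchors[part]
                    lo, hi = min(a.m0, a.m1), max(a.m0, a.m1)
                    clipped = np.clip(perceived, lo, hi)
                    if clipped != perceived:
                        part_clipped[part] += 1
                        clip_counts[part] = clip_counts.get(part, 0) + 1
                    slider_name = "bicep" if part == "biceps" else part
                    sliders[slider_name] = cm_to_slider(config.calibration, part, float(clipped))
                avatar = AvatarSettings(sliders=sliders)
                measured = BodyMeasurements(sizes_cm=sizes)

            demo: dict[str, object] = {}
            if gspec.demographics_mean:
                dm, ds = gspec.demographics_mean, gspec.demographics_sd
                height = rng.normal(dm.get("height_cm", 165.0), ds.get("height_cm", 6.0))
                weight = max(rng.normal(dm.get("weight_kg", 60.0), ds.get("weight_kg", 6.0)), 30.0)
                demo = {
                    "age": float(np.round(max(rng.normal(dm.get("age", 24.0), ds.get("age", 5.0)), 18.0), 1)),
                    "height_cm": float(np.round(height, 1)),
                    "weight_kg": float(np.round(weight, 1)),
                }
                demo["bmi"] = float(np.round(demo["weight_kg"] / (demo["height_cm"] / 100) ** 2, 2))

            usab = None
            if gspec.usability_mean:
                usab = {}
                for item, mu in gspec.usability_mean.items():
                    sd = gspec.usability_sd.get(item, 1.0)
                    top = 100.0 if item == "closeness" else 10.0
                    usab[item] = float(np.round(np.clip(rng.normal(mu, sd), 0, top), 1))

            subjects.append(
                SubjectRecord(
                    id=sid, group=gname, concerns=concerns,
                    avatar=avatar, measured=measured,
                    demographics=demo, usability=usab,
                )
            )
        if config.with_3d:
            for part, c in part_clipped.items():
                if c == gspec.n:
                    raise ValueError(
                        f"perceived '{part}' sizes for every subject of group "
                        f"'{gname}' fall outside the calibration range; the "
                        f"configured bias is unrepresentable — extend the "
                        f"calibration anchors for '{part}'"
                    )

    for part, c in sorted(clip_counts.items()):
        logger.warning(
            "calibration clipping: %d perceived '%s' value(s) clipped into range",
            c, part,
        )

    cohort = Cohort(
        subjects=subjects,
        raster_dims=dims,
        vocabulary={
            "concern_types": list(config.concern_type_weights),
            "affects": list(config.affect_weights),
        },
    )
    validate_cohort(cohort)
    return cohort


def null_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a cohort whose groups share one generative model.

    Raises if any per-group parameter (region probabilities, perception
    bias, true sizes) differs between groups: a 'null' cohort with unequal
    groups would invalidate type-I error studies.
    """
    specs = list(config.groups.values())
    first = specs[0]
    for name, g in list(config.groups.items())[1:]:
        for attr in ("region_probs", "bias_cm", "true_size_mean", "true_size_sd"):
            if getattr(g, attr) != getattr(first, attr):
                raise ValueError(
                    f"null cohort requires identical group parameters; "
                    f"'{attr}' differs for group '{name}'"
                )
    return generate_cohort(config)
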