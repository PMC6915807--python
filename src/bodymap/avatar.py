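"""Avatar slider calibration and perceived-vs-actual discrepancy scores.

Avatar sliders are arbitrary units in [0, 1]; an in-engine ruler measured
each body part at slider 0, 0.5 and 1 (anchors m0, m05, m1, in cm).
Slider values convert to centimeters by two linear segments joined at 0.5:

    s in [0, 0.5]:  cm = m05 * (r0 + (1 - r0) * s / 0.5),   r0 = m0 / m05
    s in [0.5, 1]:  cm = m05 * (1 + (r1 - 1) * (s - 0.5) / 0.5),  r1 = m1 / m05

i.e. the anchor ratios act as scale factors relative to the 0.5 baseline
(e.g. r0 = 0.75 means the part at slider 0 is 75 % of its baseline size).
A discrepancy score is perceived cm minus tape-measured cm; negative means
the subject perceives the part as slimmer than it actually is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import MEASURED_PARTS, AvatarSettings, BodyMeasurements

__all__ = [
    "CalibrationTable",
    "DiscrepancyProfile",
    "slider_to_cm",
    "cm_to_slider",
    "discrepancy_profile",
    "load_calibration",
    "save_calibration",
]


@dataclass(frozen=True)
class CalibrationAnchors:
    m0: float
    m05: float
    m1: float

    def __post_init__(self):
        if min(self.m0, self.m05, self.m1) <= 0:
            raise ValueError(f"anchors must be positive, got {self}")
        if not self.m0 < self.m1:
            raise ValueError(
                f"anchors must satisfy m0 < m1 for an invertible mapping, got {self}"
            )


@dataclass
class CalibrationTable:
    """Per-part cm anchors of one avatar mesh at slider 0, 0.5 and 1."""

    anchors: dict[str, CalibrationAnchors]
    mesh: str = "female"

    def __post_init__(self):
        self.anchors = {
            part: a if isinstance(a, CalibrationAnchors) else CalibrationAnchors(*a)
            for part, a in self.anchors.items()
        }

    def parts(self) -> list[str]:
        return list(self.anchors)

    def _get(self, part: str) -> CalibrationAnchors:
        try:
            return self.anchors[part]
        except KeyError:
            raise KeyError(
                f"unknown body part '{part}'; calibrated parts: {sorted(self.anchors)}"
            ) from None


def slider_to_cm(calib: CalibrationTable, part: str, s: float) -> float:
    """Convert a slider position to centimeters by piecewise-linear
    interpolation through the three calibration anchors."""
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"slider value {s} outside [0, 1]")
    a = calib._get(part)
    if s <= 0.5:
        return a.m0 + (a.m05 - a.m0) * (s / 0.5)
    return a.m05 + (a.m1 - a.m05) * ((s - 0.5) / 0.5)


def cm_to_slider(calib: CalibrationTable, part: str, cm: float) -> float:
    """Exact inverse of :func:`slider_to_cm` on each linear segment."""
    a = calib._get(part)
    lo, hi = min(a.m0, a.m1), max(a.m0, a.m1)
    if not (lo <= cm <= hi):
        raise ValueError(
            f"{cm} cm for part '{part}' outside the representable interval "
            f"[{lo}, {hi}] cm; extend the calibration range to represent it"
        )
    if (cm <= a.m05) == (a.m0 <= a.m05):
        lo_seg = (cm - a.m0) / (a.m05 - a.m0) if a.m05 != a.m0 else 0.0
        return 0.5 * min(max(lo_seg, 0.0), 1.0)
    hi_seg = (cm - a.m05) / (a.m1 - a.m05)
    return 0.5 + 0.5 * min(max(hi_seg, 0.0), 1.0)


@dataclass
class DiscrepancyProfile:
    """Per-part perceived and actual sizes (cm), their difference, and
    scaled body averages (mean over parts of size / reference size)."""

    perceived_cm: dict[str, float]
    actual_cm: dict[str, float]
    discrepancy_cm: dict[str, float] = field(default_factory=dict)
    scaled_perceived: float = float("nan")
    scaled_actual: float = float("nan")
    scaled_difference: float = float("nan")

    def as_frame(self) -> pd.DataFrame:
        parts = list(self.discrepancy_cm)
        return pd.DataFrame(
            {
                "part": parts,
                "perceived_cm": [self.perceived_cm[p] for p in parts],
                "actual_cm": [self.actual_cm[p] for p in parts],
                "discrepancy_cm": [self.discrepancy_cm[p] for p in parts],
            }
        )


def discrepancy_profile(
    avatar: AvatarSettings,
    calib: CalibrationTable,
    actual: BodyMeasurements,
    reference: BodyMeasurements | None = None,
    parts: tuple[str, ...] = MEASURED_PARTS,
    slider_part_map: dict[str, str] | None = None,
) -> DiscrepancyProfile:
    """Perceived minus actual size per measured part, plus scaled averages.

    The scaled body average normalizes each part by a reference size before
    averaging, so parts of very different girth weigh equally; by default
    the reference is the calibration baseline (the part size at slider 0.5,
    i.e. the scanned volunteer's body).  ``slider_part_map`` maps measured
    part names to avatar slider names where they differ (default: biceps ->
    bicep, otherwise identical).
    """
    spmap = {"biceps": "bicep"}
    if slider_part_map:
        spmap.update(slider_part_map)

    missing = []
    perceived: dict[str, float] = {}
    act: dict[str, float] = {}
    for part in parts:
        slider_name = spmap.get(part, part)
        if slider_name not in avatar.sliders:
            missing.append(f"avatar slider '{slider_name}' (for part '{part}')")
            continue
        if part not in actual.sizes_cm:
            missing.append(f"actual measurement '{part}'")
            continue
        calib_name = part if part in calib.anchors else slider_name
        perceived[part] = slider_to_cm(calib, calib_name, avatar.sliders[slider_name])
        act[part] = actual.sizes_cm[part]
    if missing:
        raise ValueError("missing inputs for discrepancy profile: " + "; ".join(missing))

    disc = {p: perceived[p] - act[p] for p in perceived}

    if reference is None:
        ref = {p: calib._get(p if p in calib.anchors else spmap.get(p, p)).m05 for p in perceived}
    else:
        ref = {p: reference.sizes_cm[p] for p in perceived}
    if any(v <= 0 for v in ref.values()):
        raise ValueError("reference sizes must be strictly positive")

    n = len(perceived)
    scaled_perc = sum(perceived[p] / ref[p] for p in perceived) / n
    scaled_act = sum(act[p] / ref[p] for p in perceived) / n
    return DiscrepancyProfile(
        perceived_cm=perceived,
        actual_cm=act,
        discrepancy_cm=disc,
        scaled_perceived=scaled_perc,
        scaled_actual=scaled_act,
        scaled_difference=scaled_perc - scaled_act,
    )


def load_calibration(path: str | Path, mesh: str = "female") -> CalibrationTable:
    """Read a calibration table from CSV with columns part, m0, m05, m1."""
    df = pd.read_csv(path)
    required = {"part", "m0", "m05", "m1"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"calibration CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    anchors = {
        str(r.part): CalibrationAnchors(float(r.m0), float(r.m05), float(r.m1))
        for r in df.itertuples()
    }
    return CalibrationTable(anchors=anchors, mesh=mesh)


def save_calibration(calib: CalibrationTable, path: str | Path) -> None:
    rows = [
        {"part": p, "m0": a.m0, "m05": a.m05, "m1": a.m1}
        for p, a in calib.anchors.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
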