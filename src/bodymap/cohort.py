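"""Cohort data model: subjects, outlined body concerns, avatar sliders, measurements.

A cohort is the unit of analysis: a list of subjects, each carrying a group
label, zero or more outlined concern areas on a shared manikin raster,
optional avatar slider settings, optional tape measurements, and
demographics.  One cohort per JSON file; :func:`save_cohort` /
:func:`load_cohort` round-trip the model exactly.

Coordinates are 0-based raster pixels, origin top-left, x rightward,
y downward.  Polygon vertices may be fractional.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AVATAR_PARTS",
    "MEASURED_PARTS",
    "NEGATIVE_AFFECTS",
    "NEUTRAL_POSITIVE_AFFECTS",
    "DEFAULT_CONCERN_TYPES",
    "Affect",
    "ConcernEntry",
    "AvatarSettings",
    "BodyMeasurements",
    "SubjectRecord",
    "Cohort",
    "CohortValidationError",
    "load_cohort",
    "save_cohort",
]

#: The 13 avatar regions whose girth/width can be adjusted independently.
AVATAR_PARTS: tuple[str, ...] = (
    "neck", "shoulders", "torso", "bust", "bicep", "forearm", "hands",
    "hips", "waist", "buttocks", "thighs", "calves", "feet",
)

#: The seven regions with a tape-measure counterpart.
MEASURED_PARTS: tuple[str, ...] = (
    "shoulders", "bust", "biceps", "waist", "hips", "thighs", "calves",
)

#: Controlled affect vocabulary, grouped by emotional valence.
NEGATIVE_AFFECTS: tuple[str, ...] = (
    "frustrated", "anxious/tense/worried/nervous", "ashamed", "hopeless",
    "sad", "disgusted", "defective", "depressed", "fearful", "angry",
    "overwhelmed", "lonely", "numb/unreal/dead", "embarrassed",
)
NEUTRAL_POSITIVE_AFFECTS: tuple[str, ...] = (
    "looks ok/fine", "hopeful", "satisfied/content",
)

#: Default concern-type vocabulary (free text is also accepted).
DEFAULT_CONCERN_TYPES: tuple[str, ...] = (
    "acne", "bloated", "bulgy", "too thin", "too large", "too fat",
    "protrudes", "too round", "too much cellulite", "too much muscularity",
    "flawed", "scarred", "too wide", "asymmetric",
)

VALENCE_CLASSES = ("negative", "neutral_positive", "unclassified")


class CohortValidationError(ValueError):
    """Raised when a cohort (or a file claiming to be one) violates the model.

    ``errors`` holds one itemized message per violation, each naming the
    subject id and offending field.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            "cohort validation failed with %d error(s):\n  %s"
            % (len(self.errors), "\n  ".join(self.errors))
        )


def default_valence(label: str) -> str:
    """Valence class for an affect label: controlled vocabulary labels map to
    their fixed class; free text is 'unclassified' (excluded from valence
    tallies) unless explicitly flagged by the caller."""
    key = label.strip().lower()
    if key in NEGATIVE_AFFECTS:
        return "negative"
    if key in NEUTRAL_POSITIVE_AFFECTS:
        return "neutral_positive"
    return "unclassified"


@dataclass(frozen=True)
class Affect:
    """One emotion endorsed for a concern area, with its valence class."""

    label: str
    valence: str = ""

    def __post_init__(self):
        if not self.valence:
            object.__setattr__(self, "valence", default_valence(self.label))


@dataclass
class ConcernEntry:
    """One outlined area of body concern.

    polygon
        Ordered (x, y) vertices in manikin-raster pixel coordinates; the
        outline is implicitly closed (last vertex connects back to the first).
    concern_types
        Labels describing the nature of the concern (controlled vocabulary
        plus free text).
    affects
        Emotions associated with the concern.
    intensity
        Magnitude rating on a 0-100 slider.
    """

    polygon: list[tuple[float, float]]
    concern_types: list[str] = field(default_factory=list)
    affects: list[Affect] = field(default_factory=list)
    intensity: float = 0.0


@dataclass
class AvatarSettings:
    """Slider positions in [0, 1] over the 13 adjustable avatar regions."""

    sliders: dict[str, float] = field(default_factory=dict)


@dataclass
class BodyMeasurements:
    """Tape-measured circumferences/widths in cm for the seven measured parts."""

    sizes_cm: dict[str, float] = field(default_factory=dict)


@dataclass
class SubjectRecord:
    id: str
    group: str
    concerns: list[ConcernEntry] = field(default_factory=list)
    avatar: AvatarSettings | None = None
    measured: BodyMeasurements | None = None
    demographics: dict[str, object] = field(default_factory=dict)
    usability: dict[str, float] | None = None


@dataclass
class Cohort:
    """A study cohort over one shared manikin raster.

    raster_dims is (width, height) in pixels; every concern polygon must fit
    inside it.
    """

    subjects: list[SubjectRecord]
    raster_dims: tuple[int, int] = (400, 800)
    vocabulary: dict[str, list[str]] = field(default_factory=dict)

    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.subjects:
            seen.setdefault(s.group, None)
        return list(seen)

    def by_group(self) -> dict[str, list[SubjectRecord]]:
        out: dict[str, list[SubjectRecord]] = {}
        for s in self.subjects:
            out.setdefault(s.group, []).append(s)
        return out


# ---------------------------------------------------------------------------
# validation

def _validate_subject(s: SubjectRecord, dims: tuple[int, int], errors: list[str]) -> None:
    w, h = dims
    sid = s.id or "<missing id>"
    if not s.group:
        errors.append(f"subject {sid}: group label is empty")
    for ci, c in enumerate(s.concerns):
        where = f"subject {sid} concern[{ci}]"
        if len(c.polygon) < 3:
            errors.append(f"{where}: polygon has {len(c.polygon)} vertices (< 3)")
        for x, y in c.polygon:
            if not (0 <= x <= w and 0 <= y <= h):
                errors.append(
                    f"{where}: vertex ({x}, {y}) outside raster bounds {w}x{h}"
                )
                break
        if not (0 <= c.intensity <= 100):
            errors.append(f"{where}: intensity {c.intensity} outside [0, 100]")
        for a in c.affects:
            if a.valence not in VALENCE_CLASSES:
                errors.append(
                    f"{where}: affect '{a.label}' has invalid valence '{a.valence}'"
                )
    if s.avatar is not None:
        for part, v in s.avatar.sliders.items():
            if part not in AVATAR_PARTS:
                errors.append(f"subject {sid}: unknown avatar part '{part}'")
            if not (0 <= v <= 1):
                errors.append(
                    f"subject {sid}: avatar slider '{part}'={v} outside [0, 1]"
                )
    if s.measured is not None:
        for part, v in s.measured.sizes_cm.items():
            if part not in MEASURED_PARTS:
                errors.append(f"subject {sid}: unknown measured part '{part}'")
            if not v > 0:
                errors.append(f"subject {sid}: measurement '{part}'={v} is not > 0")
    demo = s.demographics
    if demo:
        hgt, wgt, bmi = (demo.get(k) for k in ("height_cm", "weight_kg", "bmi"))
        if all(isinstance(v, (int, float)) for v in (hgt, wgt, bmi)):
            expect = wgt / (hgt / 100.0) ** 2
            if abs(bmi - expect) > 0.1:
                errors.append(
                    f"subject {sid}: bmi={bmi} inconsistent with "
                    f"weight/(height/100)^2={expect:.2f} (tolerance 0.1)"
                )


def validate_cohort(cohort: Cohort) -> None:
    """Check every model invariant; raise :class:`CohortValidationError`
    listing all violations at once."""
    errors: list[str] = []
    w, h = cohort.raster_dims
    if not (isinstance(w, int) and isinstance(h, int) and w > 0 and h > 0):
        errors.append(f"raster_dims {cohort.raster_dims} must be positive integers")
    if not cohort.subjects:
        errors.append("cohort has no subjects (>= 1 required)")
    ids = [s.id for s in cohort.subjects]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        errors.append(f"duplicate subject ids: {dupes}")
    for s in cohort.subjects:
        _validate_subject(s, cohort.raster_dims, errors)
    if errors:
        raise CohortValidationError(errors)


# ---------------------------------------------------------------------------
# JSON (de)serialization

def _concern_to_json(c: ConcernEntry) -> dict:
    return {
        "polygon": [[float(x), float(y)] for x, y in c.polygon],
        "concern_types": list(c.concern_types),
        "affects": [{"label": a.label, "valence": a.valence} for a in c.affects],
        "intensity": float(c.intensity),
    }


def _subject_to_json(s: SubjectRecord) -> dict:
    out: dict = {
        "id": s.id,
        "group": s.group,
        "concerns": [_concern_to_json(c) for c in s.concerns],
    }
    if s.avatar is not None:
        out["avatar"] = {"sliders": {k: float(v) for k, v in s.avatar.sliders.items()}}
    if s.measured is not None:
        out["measured"] = {"sizes_cm": {k: float(v) for k, v in s.measured.sizes_cm.items()}}
    if s.demographics:
        out["demographics"] = dict(s.demographics)
    if s.usability is not None:
        out["usability"] = dict(s.usability)
    return out


def cohort_to_json(cohort: Cohort) -> dict:
    return {
        "format": "bodymap-cohort",
        "version": 1,
        "raster_dims": [int(cohort.raster_dims[0]), int(cohort.raster_dims[1])],
        "vocabulary": {k: list(v) for k, v in cohort.vocabulary.items()},
        "subjects": [_subject_to_json(s) for s in cohort.subjects],
    }


def _concern_from_json(d: Mapping) -> ConcernEntry:
    return ConcernEntry(
        polygon=[(float(x), float(y)) for x, y in d.get("polygon", [])],
        concern_types=list(d.get("concern_types", [])),
        affects=[
            Affect(label=a["label"], valence=a.get("valence", ""))
            for a in d.get("affects", [])
        ],
        intensity=float(d.get("intensity", 0.0)),
    )


def _subject_from_json(d: Mapping) -> SubjectRecord:
    avatar = None
    if "avatar" in d:
        avatar = AvatarSettings(sliders={k: float(v) for k, v in d["avatar"].get("sliders", {}).items()})
    measured = None
    if "measured" in d:
        measured = BodyMeasurements(sizes_cm={k: float(v) for k, v in d["measured"].get("sizes_cm", {}).items()})
    return SubjectRecord(
        id=str(d.get("id", "")),
        group=str(d.get("group", "")),
        concerns=[_concern_from_json(c) for c in d.get("concerns", [])],
        avatar=avatar,
        measured=measured,
        demographics=dict(d.get("demographics", {})),
        usability=dict(d["usability"]) if "usability" in d else None,
    )


def cohort_from_json(doc: Mapping) -> Cohort:
    if not isinstance(doc, Mapping):
        raise CohortValidationError(["top-level JSON value is not an object"])
    dims = doc.get("raster_dims", [400, 800])
    cohort = Cohort(
        subjects=[_subject_from_json(s) for s in doc.get("subjects", [])],
        raster_dims=(int(dims[0]), int(dims[1])),
        vocabulary={k: list(v) for k, v in doc.get("vocabulary", {}).items()},
    )
    validate_cohort(cohort)
    return cohort


def load_cohort(path: str | Path) -> Cohort:
    """Load and validate a cohort JSON file.

    Raises :class:`CohortValidationError` with itemized messages on any
    model violation, ``OSError`` if the file cannot be read.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise CohortValidationError([f"not valid JSON: {e}"]) from e
    return cohort_from_json(doc)


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    """Validate and write a cohort to JSON (deterministic key order)."""
    validate_cohort(cohort)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(cohort_to_json(cohort), fh, indent=1, sort_keys=True)
        fh.write("\n")
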