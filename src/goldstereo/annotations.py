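"""Annotation data model for immunogold EM scenes.

A micrograph annotation is a vector description of one observed field of a
thawed cryo-section: membrane profiles traced as polylines (each tagged with
a compartment class), gold particle centre coordinates, and acquisition
metadata (antibody, native vs peptide-inhibited condition, experiment
replicate, sampling stream). All geometry is stored in nanometres with the
origin at the top-left of the field and y increasing downward; the pixel
scale ``nm_per_px`` is carried as provenance metadata only.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Compartment",
    "MEMBRANE_COMPARTMENTS",
    "CONDITIONS",
    "SAMPLING_STREAMS",
    "AnnotationError",
    "Profile",
    "MicrographAnnotation",
    "polyline_length",
]


class Compartment(str, enum.Enum):
    """Membrane compartment classes; ``NONE`` marks unassigned gold only."""

    PLASMA_MEMBRANE = "plasma_membrane"
    NUCLEAR_ENVELOPE = "nuclear_envelope"
    ENDO_MEMBRANE = "endo_membrane"
    MITOSOME = "mitosome"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Compartments a membrane profile may be labelled with ("none" is reserved
#: for gold particles associated with no membrane), in lexicographic order.
MEMBRANE_COMPARTMENTS: tuple[Compartment, ...] = tuple(
    sorted(
        (c for c in Compartment if c is not Compartment.NONE),
        key=lambda c: c.value,
    )
)

CONDITIONS = ("native", "inhibited")
SAMPLING_STREAMS = ("sur", "comprehensive")


class AnnotationError(ValueError):
    """Raised when an annotation violates the schema; names file and field."""


def polyline_length(points: np.ndarray) -> float:
    """Exact length of a polyline: the sum of its segment lengths."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must be an (n>=2, 2) array")
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


@dataclass(frozen=True)
class Profile:
    """One traced membrane profile: a polyline with a compartment label."""

    compartment: Compartment
    points: np.ndarray  # (n, 2), nm
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise AnnotationError("profile polyline must have >= 2 points")
        if not np.isfinite(pts).all():
            raise AnnotationError("profile coordinates must be finite")
        if self.compartment is Compartment.NONE:
            raise AnnotationError("'none' is not a valid membrane label")
        if self.closed and not np.array_equal(pts[0], pts[-1]):
            raise AnnotationError("closed profile must repeat its first point")

    @property
    def length_nm(self) -> float:
        return polyline_length(self.points)


@dataclass
class MicrographAnnotation:
    """One observed field: profiles, gold coordinates and metadata."""

    micrograph_id: str
    experiment_id: str
    antibody_id: str
    condition: str
    sampling_stream: str
    profiles: list[Profile]
    particles: np.ndarray  # (m, 2), nm
    nm_per_px: float | None = None
    field_size_nm: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise AnnotationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.sampling_stream not in SAMPLING_STREAMS:
            raise AnnotationError(
                f"sampling_stream must be one of {SAMPLING_STREAMS}, "
                f"got {self.sampling_stream!r}"
            )
        pts = np.asarray(self.particles, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise AnnotationError("particles must be an (m, 2) array")
        if not np.isfinite(pts).all():
            raise AnnotationError("particle coordinates must be finite")
        self.particles = pts

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "schema": "goldstereo/annotation-v1",
            "micrograph_id": self.micrograph_id,
            "experiment_id": self.experiment_id,
            "antibody_id": self.antibody_id,
            "condition": self.condition,
            "sampling_stream": self.sampling_stream,
            "nm_per_px": self.nm_per_px,
            "field_size_nm": self.field_size_nm,
            "profiles": [
                {
                    "compartment": p.compartment.value,
                    "closed": p.closed,
                    "points": np.asarray(p.points).tolist(),
                }
                for p in self.profiles
            ],
            "particles": np.asarray(self.particles).tolist(),
        }

    @classmethod
    def from_dict(cls, doc: Mapping, source: str = "<dict>") -> "MicrographAnnotation":
        def _field(name: str):
            if name not in doc:
                raise AnnotationError(f"{source}: missing field {name!r}")
            return doc[name]

        profiles = []
        for i, p in enumerate(_field("profiles")):
            label = p.get("compartment")
            try:
                comp = Compartment(label)
            except ValueError:
                raise AnnotationError(
                    f"{source}: profiles[{i}].compartment: unknown label {label!r}"
                ) from None
            try:
                profiles.append(
                    Profile(comp, np.asarray(p["points"], dtype=float),
                            bool(p.get("closed", False)))
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{source}: profiles[{i}]: {exc}") from None
        try:
            return cls(
                micrograph_id=str(_field("micrograph_id")),
                experiment_id=str(_field("experiment_id")),
                antibody_id=str(_field("antibody_id")),
                condition=_field("condition"),
                sampling_stream=_field("sampling_stream"),
                profiles=profiles,
                particles=np.asarray(_field("particles"), dtype=float),
                nm_per_px=doc.get("nm_per_px"),
                field_size_nm=doc.get("field_size_nm"),
            )
        except AnnotationError as exc:
            raise AnnotationError(f"{source}: {exc}") from None

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def read_json(cls, path: str | Path) -> "MicrographAnnotation":
        path = Path(path)
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"{path}: malformed JSON: {exc}") from None
        return cls.from_dict(doc, source=str(path))


def profiles_by_compartment(
    profiles: Iterable[Profile],
) -> dict[Compartment, list[Profile]]:
    """Group profiles per membrane compartment (lexicographic key order)."""
    out: dict[Compartment, list[Profile]] = {c: [] for c in MEMBRANE_COMPARTMENTS}
    for p in profiles:
        out[p.compartment].append(p)
    return out
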