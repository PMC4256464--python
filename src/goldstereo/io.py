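"""Annotation file I/O and study configuration.

Annotations are JSON documents (one micrograph per file) following the
``goldstereo/annotation-v1`` schema; the simulation ground truth travels in
a separate sidecar file so the analysis pipeline never sees it. Tabular
outputs are CSV. The study configuration gathers the protocol parameters:
the compartment-to-grid-spacing map, the membrane-association rule, the
replication scale, and the seeds recorded in output provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .annotations import AnnotationError, Compartment, MicrographAnnotation
from .labelling import AssignmentParams
from .scene import LabellingModel, SceneParams, StudyGroundTruth
from .stereology import COARSE_SPACINGS_NM, FINE_SPACINGS_NM

__all__ = [
    "TRACE_LENGTH",
    "DEFAULT_SPACING_MAP",
    "StudyConfig",
    "read_annotations",
    "write_annotations",
    "config_hash",
]

#: Sentinel spacing value: measure the compartment's membrane length
#: directly as the analytic length of its traced polylines instead of by
#: lattice counting (used for mitosomes, which are traced completely).
TRACE_LENGTH = "trace"


def _default_spacing_map() -> dict[Compartment, float | str]:
    return {
        Compartment.PLASMA_MEMBRANE: FINE_SPACINGS_NM[0],   # 262 nm
        Compartment.NUCLEAR_ENVELOPE: FINE_SPACINGS_NM[0],  # 262 nm
        Compartment.ENDO_MEMBRANE: COARSE_SPACINGS_NM[0],   # 914 nm
        Compartment.MITOSOME: TRACE_LENGTH,
    }


DEFAULT_SPACING_MAP: dict[Compartment, float | str] = _default_spacing_map()


@dataclass
class StudyConfig:
    """Everything needed to reproduce one quantification run."""

    spacing_map: dict[Compartment, float | str] = field(
        default_factory=_default_spacing_map
    )
    assignment: AssignmentParams = field(default_factory=AssignmentParams)
    scene: SceneParams = field(default_factory=SceneParams)
    model: LabellingModel = field(default_factory=LabellingModel)
    n_experiments: int = 3
    micrographs_per_condition: int = 18
    clamp_fsp: bool = True
    section_wide_fsp: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for c, sp in self.spacing_map.items():
            if sp != TRACE_LENGTH and (not isinstance(sp, (int, float)) or sp <= 0):
                raise ValueError(
                    f"spacing_map[{c}] must be a positive spacing in nm or "
                    f"{TRACE_LENGTH!r}"
                )

    # -------------------------------------------------------------- JSON
    def to_dict(self) -> dict:
        return {
            "schema": "goldstereo/config-v1",
            "spacing_map": {c.value: sp for c, sp in self.spacing_map.items()},
            "assignment": dataclasses.asdict(self.assignment),
            "scene": dataclasses.asdict(self.scene),
            "model": {
                "specific_density": {
                    c.value: v for c, v in self.model.specific_density.items()
                },
                "background_intensity": self.model.background_intensity,
                "jitter_sd_nm": self.model.jitter_sd_nm,
                "inhibition_efficiency": self.model.inhibition_efficiency,
                "particle_diameter_nm": self.model.particle_diameter_nm,
            },
            "n_experiments": self.n_experiments,
            "micrographs_per_condition": self.micrographs_per_condition,
            "clamp_fsp": self.clamp_fsp,
            "section_wide_fsp": self.section_wide_fsp,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "StudyConfig":
        kwargs: dict = {}
        if "spacing_map" in doc:
            kwargs["spacing_map"] = {
                Compartment(k): v for k, v in doc["spacing_map"].items()
            }
        if "assignment" in doc:
            kwargs["assignment"] = AssignmentParams(**doc["assignment"])
        if "scene" in doc:
            sc = dict(doc["scene"])
            for key in ("mito_axis_range_nm", "endo_len_range_nm"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            kwargs["scene"] = SceneParams(**sc)
        if "model" in doc:
            m = dict(doc["model"])
            if "specific_density" in m:
                m["specific_density"] = {
                    Compartment(k): v for k, v in m["specific_density"].items()
                }
            kwargs["model"] = LabellingModel(**m)
        for key in (
            "n_experiments",
            "micrographs_per_condition",
            "clamp_fsp",
            "section_wide_fsp",
            "seed",
        ):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def config_hash(config: StudyConfig) -> str:
    """SHA-256 of the canonical JSON form of a config, for provenance."""
    canon = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def write_annotations(
    annotations: list[MicrographAnnotation],
    out_dir: str | Path,
    ground_truth: StudyGroundTruth | None = None,
) -> None:
    """Write one JSON file per annotation plus an optional truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ann in annotations:
        ann.write_json(out / f"{ann.micrograph_id}.json")
    if ground_truth is not None:
        ground_truth.write_json(out / "ground_truth.json")


def read_annotations(path: str | Path) -> list[MicrographAnnotation]:
    """Read and validate all annotation JSONs in a directory.

    The ground-truth sidecar (a different schema) is skipped. An empty
    directory yields an empty list with a warning, not an error; schema
    violations raise :class:`AnnotationError` naming file and field.
    """
    path = Path(path)
    out: list[MicrographAnnotation] = []
    for f in sorted(path.glob("*.json")):
        doc = json.loads(f.read_text()) if _is_json(f) else None
        if doc is None:
            raise AnnotationError(f"{f}: malformed JSON")
        schema = doc.get("schema", "goldstereo/annotation-v1")
        if schema != "goldstereo/annotation-v1":
            continue  # ground-truth sidecar, config, or other known sidecars
        out.append(MicrographAnnotation.from_dict(doc, source=str(f)))
    if not out:
        warnings.warn(f"no annotations found under {path}", stacklevel=2)
    return out


def _is_json(path: Path) -> bool:
    try:
        json.loads(path.read_text())
        return True
    except json.JSONDecodeError:
        return False
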