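"""Synthetic cryo-section scenes with known geometry and labelling.

Generates vector annotations that emulate sections through microsporidian
meronts: one closed plasma-membrane profile, a nuclear envelope,
tubulovesicular endo-membranes, and small elliptical mitosomes (minor and
major axes 50-300 nm by default). Gold labelling is simulated as a Poisson
process along each membrane at a compartment-specific rate lambda_c
(gold per micron), laterally jittered, on top of a spatially uniform
nonspecific background (gold per square micron). The peptide-inhibited
condition suppresses the specific component by a factor rho while leaving
the background untouched, mirroring the peptide-control design.

The scene's ground truth (true membrane lengths, true rates, each
particle's origin) is kept out of the annotation consumed by the analysis
pipeline, so the downstream estimators stay blind.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotations import (
    CONDITIONS,
    Compartment,
    MicrographAnnotation,
    Profile,
    polyline_length,
)

__all__ = [
    "SceneParams",
    "LabellingModel",
    "CellScene",
    "PlacedGold",
    "StudyGroundTruth",
    "make_scene",
    "place_gold",
    "simulate_study",
]

# vertex counts per generated profile; enough that polyline discretisation
# error of a smooth curve is < 0.2% of its length
_N_PLASMA = 96
_N_NUCLEUS = 64
_N_MITO = 48
_N_ENDO_STEPS = 12


@dataclass(frozen=True)
class SceneParams:
    """Geometry of one simulated meront section (lengths in nm)."""

    cell_radius_nm: float = 1000.0
    n_mitosomes: int = 4
    mito_axis_range_nm: tuple[float, float] = (50.0, 300.0)
    n_endo_tubules: int = 4
    endo_len_range_nm: tuple[float, float] = (200.0, 800.0)
    field_size_nm: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cell_radius_nm", "field_size_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("mito_axis_range_nm", "endo_len_range_nm"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0:
                raise ValueError(f"{name} must be strictly positive")
            if lo > hi:
                raise ValueError(f"{name}: min > max")
        if self.n_mitosomes < 0 or self.n_endo_tubules < 0:
            raise ValueError("profile counts must be >= 0")


def _default_densities() -> dict[Compartment, float]:
    # study conditions: strong plasma-membrane signal, minor internal
    # signal, none over the mitosome
    return {
        Compartment.PLASMA_MEMBRANE: 5.0,
        Compartment.NUCLEAR_ENVELOPE: 0.5,
        Compartment.ENDO_MEMBRANE: 1.0,
        Compartment.MITOSOME: 0.0,
    }


@dataclass(frozen=True)
class LabellingModel:
    """Stochastic gold-labelling model.

    Parameters
    ----------
    specific_density
        lambda_c, expected specific gold per micron of membrane, per
        compartment.
    background_intensity
        beta, nonspecific gold per square micron of field area. The default
        is set so that background alone yields ~1 gold/um of apparent
        membrane density through the 30 nm association band
        (beta * 0.030 um ~= 1).
    jitter_sd_nm
        SD of the lateral (perpendicular) displacement of specific gold
        from the membrane line; real label never sits exactly on the line.
    inhibition_efficiency
        rho, fraction of specific labelling suppressed in the
        peptide-inhibited condition (1 = complete blocking).
    particle_diameter_nm
        physical gold size (10 nm protein-A gold).
    """

    specific_density: Mapping[Compartment, float] = field(
        default_factory=_default_densities
    )
    background_intensity: float = 100.0 / 3.0
    jitter_sd_nm: float = 8.0
    inhibition_efficiency: float = 1.0
    particle_diameter_nm: float = 10.0

    def __post_init__(self) -> None:
        for c, lam in self.specific_density.items():
            if lam < 0:
                raise ValueError(f"specific_density[{c}] must be >= 0")
        if self.background_intensity < 0:
            raise ValueError("background_intensity must be >= 0")
        if not 0.0 <= self.inhibition_efficiency <= 1.0:
            raise ValueError("inhibition_efficiency must be in [0, 1]")
        if self.jitter_sd_nm < 0:
            raise ValueError("jitter_sd_nm must be >= 0")


@dataclass
class CellScene:
    """Ground-truth geometry of one simulated section."""

    profiles: list[Profile]
    true_length_nm: dict[Compartment, float]
    params: SceneParams


@dataclass
class PlacedGold:
    """Simulated particles plus their true origins (diagnostics only)."""

    points: np.ndarray  # (m, 2) nm
    origins: np.ndarray  # (m,) str: compartment value or "background"


def _star_curve(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    n_points: int,
    roughness: float = 0.06,
) -> np.ndarray:
    """Smoothed star-convex closed curve: low-order harmonic radius noise."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    r = np.full_like(theta, radius)
    for k in range(2, 6):
        amp = rng.uniform(0.0, roughness) * radius * 2.0 / k
        phase = rng.uniform(0.0, 2.0 * math.pi)
        r += amp * np.cos(k * theta + phase)
    pts = center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return np.vstack([pts, pts[:1]])  # close the loop


def _ellipse(
    center: np.ndarray, axis_a: float, axis_b: float, angle: float, n: int
) -> np.ndarray:
    """Closed ellipse polyline; axis_a/axis_b are full axes (diameters)."""
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    x = 0.5 * axis_a * np.cos(t)
    y = 0.5 * axis_b * np.sin(t)
    ca, sa = math.cos(angle), math.sin(angle)
    pts = center + np.column_stack([ca * x - sa * y, sa * x + ca * y])
    return np.vstack([pts, pts[:1]])


def _tubule(
    rng: np.random.Generator, start: np.ndarray, total_len: float, n_steps: int
) -> np.ndarray:
    """Open random-walk polyline with mild angular diffusion."""
    step = total_len / n_steps
    heading = rng.uniform(0.0, 2.0 * math.pi)
    pts = [start]
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.4)
        pts.append(pts[-1] + step * np.array([math.cos(heading), math.sin(heading)]))
    return np.asarray(pts)


def make_scene(params: SceneParams) -> CellScene:
    """Generate one meront section; deterministic in (params, seed)."""
    rng = np.random.default_rng(params.seed)
    center = np.full(2, params.field_size_nm / 2.0)
    R = params.cell_radius_nm
    profiles: list[Profile] = []

    pm = _star_curve(rng, center, R, _N_PLASMA)
    profiles.append(Profile(Compartment.PLASMA_MEMBRANE, pm, closed=True))

    ne_center = center + rng.uniform(-0.15 * R, 0.15 * R, size=2)
    ne = _star_curve(rng, ne_center, 0.45 * R, _N_NUCLEUS)
    profiles.append(Profile(Compartment.NUCLEAR_ENVELOPE, ne, closed=True))

    for _ in range(params.n_endo_tubules):
        start = center + _random_in_disc(rng, 0.7 * R)
        length = rng.uniform(*params.endo_len_range_nm)
        profiles.append(
            Profile(Compartment.ENDO_MEMBRANE, _tubule(rng, start, length, _N_ENDO_STEPS))
        )

    lo, hi = params.mito_axis_range_nm
    for _ in range(params.n_mitosomes):
        axes = np.sort(rng.uniform(lo, hi, size=2))
        c = center + _random_in_disc(rng, 0.7 * R)
        angle = rng.uniform(0.0, math.pi)
        profiles.append(
            Profile(
                Compartment.MITOSOME,
                _ellipse(c, float(axes[1]), float(axes[0]), angle, _N_MITO),
                closed=True,
            )
        )

    true_len = {c: 0.0 for c in Compartment if c is not Compartment.NONE}
    for p in profiles:
        true_len[p.compartment] += p.length_nm
    return CellScene(profiles=profiles, true_length_nm=true_len, params=params)


def _random_in_disc(rng: np.random.Generator, radius: float) -> np.ndarray:
    r = radius * math.sqrt(rng.uniform())
    t = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([r * math.cos(t), r * math.sin(t)])


def _sample_along(
    rng: np.random.Generator, pts: np.ndarray, n: int, jitter_sd: float
) -> np.ndarray:
    """n points uniform in arc length, displaced along the local normal."""
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = rng.uniform(0.0, cum[-1], size=n)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    base = pts[idx] + frac[:, None] * seg[idx]
    with np.errstate(invalid="ignore"):
        normal = np.column_stack([-seg[idx, 1], seg[idx, 0]]) / np.where(
            seg_len[idx][:, None] > 0, seg_len[idx][:, None], 1.0
        )
    offset = rng.normal(0.0, jitter_sd, size=n)[:, None] * normal
    return base + offset


def place_gold(
    scene: CellScene,
    model: LabellingModel,
    condition: str,
    seed: int,
) -> PlacedGold:
    """Simulate gold particles over a scene for one condition.

    Specific particles are a Poisson process along each membrane with rate
    lambda_c gold/um (scaled by ``1 - rho`` when inhibited), displaced
    perpendicular to the membrane by Normal(0, jitter_sd). Background
    particles are a uniform spatial Poisson process over the field with
    intensity beta gold/um^2.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    rng = np.random.default_rng(seed)
    scale = 1.0 - model.inhibition_efficiency if condition == "inhibited" else 1.0

    points: list[np.ndarray] = []
    origins: list[str] = []
    for p in scene.profiles:
        lam = float(model.specific_density.get(p.compartment, 0.0)) * scale
        mean = lam * p.length_nm / 1000.0  # nm -> um
        n = rng.poisson(mean) if mean > 0 else 0
        if n:
            points.append(_sample_along(rng, p.points, n, model.jitter_sd_nm))
            origins.extend([p.compartment.value] * n)

    area_um2 = (scene.params.field_size_nm / 1000.0) ** 2
    n_bg = rng.poisson(model.background_intensity * area_um2)
    if n_bg:
        points.append(rng.uniform(0.0, scene.params.field_size_nm, size=(n_bg, 2)))
        origins.extend(["background"] * n_bg)

    pts = np.vstack(points) if points else np.empty((0, 2))
    return PlacedGold(points=pts, origins=np.asarray(origins, dtype=object))


# --------------------------------------------------------------------------
# study-level simulation


@dataclass
class StudyGroundTruth:
    """Sidecar record of everything the simulated study knows to be true."""

    scene_params: SceneParams
    model: LabellingModel
    n_experiments: int
    micrographs_per_condition: int
    seed: int
    true_length_nm: dict[str, dict[str, float]]  # micrograph_id -> comp -> nm

    def to_dict(self) -> dict:
        return {
            "schema": "goldstereo/ground-truth-v1",
            "scene_params": dataclasses.asdict(self.scene_params),
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
            "seed": self.seed,
            "true_length_nm": self.true_length_nm,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "StudyGroundTruth":
        sp = dict(doc["scene_params"])
        sp["mito_axis_range_nm"] = tuple(sp["mito_axis_range_nm"])
        sp["endo_len_range_nm"] = tuple(sp["endo_len_range_nm"])
        m = doc["model"]
        model = LabellingModel(
            specific_density={
                Compartment(k): v for k, v in m["specific_density"].items()
            },
            background_intensity=m["background_intensity"],
            jitter_sd_nm=m["jitter_sd_nm"],
            inhibition_efficiency=m["inhibition_efficiency"],
            particle_diameter_nm=m["particle_diameter_nm"],
        )
        return cls(
            scene_params=SceneParams(**sp),
            model=model,
            n_experiments=doc["n_experiments"],
            micrographs_per_condition=doc["micrographs_per_condition"],
            seed=doc["seed"],
            true_length_nm={k: dict(v) for k, v in doc["true_length_nm"].items()},
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def read_json(cls, path: str | Path) -> "StudyGroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


def simulate_study(
    scene_params: SceneParams,
    model: LabellingModel,
    n_experiments: int = 3,
    micrographs_per_condition: int = 18,
    seed: int = 0,
    antibody_id: str = "antibody",
) -> tuple[list[MicrographAnnotation], StudyGroundTruth]:
    """Simulate a replicated labelling study with paired conditions.

    Each experiment replicate contributes ``micrographs_per_condition``
    fields per condition (defaults 3 x 18, the scale of three replicate
    experiments with 16-20 systematically sampled micrographs each). Every
    micrograph is an independent section: its own scene geometry and its
    own gold realisation.
    """
    if n_experiments < 1 or micrographs_per_condition < 1:
        raise ValueError("n_experiments and micrographs_per_condition must be >= 1")

    root = np.random.SeedSequence(seed)
    annotations: list[MicrographAnnotation] = []
    true_lengths: dict[str, dict[str, float]] = {}
    for e in range(1, n_experiments + 1):
        for condition in CONDITIONS:
            for m in range(1, micrographs_per_condition + 1):
                child = root.spawn(1)[0]
                scene_seed, gold_seed = (
                    int(s) % 2**31 for s in child.generate_state(2)
                )
                scene = make_scene(
                    dataclasses.replace(scene_params, seed=scene_seed)
                )
                gold = place_gold(scene, model, condition, gold_seed)
                mid = f"exp{e}_{condition}_m{m:02d}"
                annotations.append(
                    MicrographAnnotation(
                        micrograph_id=mid,
                        experiment_id=f"exp{e}",
                        antibody_id=antibody_id,
                        condition=condition,
                        sampling_stream="sur",
                        profiles=scene.profiles,
                        particles=gold.points,
                        field_size_nm=scene_params.field_size_nm,
                    )
                )
                true_lengths[mid] = {
                    c.value: L for c, L in scene.true_length_nm.items()
                }
    truth = StudyGroundTruth(
        scene_params=scene_params,
        model=model,
        n_experiments=n_experiments,
        micrographs_per_condition=micrographs_per_condition,
        seed=seed,
        true_length_nm=true_lengths,
    )
    return annotations, truth
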