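"""End-to-end pipeline: annotations -> densities -> specificity -> summary.

Stages: place a random lattice per micrograph and compartment, count
crossings, estimate membrane lengths; assign gold by the distance rule;
pool counts and lengths per experiment and condition (ratio of sums);
compute D(sp), F(sp) and the specific distribution per experiment; and
aggregate experiments as mean +/- SEM. Sampling streams (systematic
uniform random fields vs comprehensive mitosome scans) are quantified
separately and never pooled; when both streams are present, mitosome
statistics come from the comprehensive stream and all other compartments
from the SUR stream.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import (
    Compartment,
    MEMBRANE_COMPARTMENTS,
    MicrographAnnotation,
    profiles_by_compartment,
)
from .io import TRACE_LENGTH, StudyConfig, config_hash, read_annotations
from .labelling import (
    AssignmentParams,
    CompartmentQuant,
    LabellingTable,
    assign_particles,
    labelling_density,
)
from .specificity import (
    SpecificityResult,
    aggregate_experiments,
    compute_specificity,
)
from .stereology import count_polyline_intersections, estimate_length, make_grid

__all__ = [
    "MissingControlError",
    "quantify_study",
    "merge_streams",
    "run_pipeline",
]


class MissingControlError(RuntimeError):
    """An experiment lacks its inhibition control, so specificity is
    undefined by design."""


def _measure_lengths(
    ann: MicrographAnnotation,
    spacing_map: dict[Compartment, float | str],
    grid_seeds: dict[Compartment, int],
) -> dict[Compartment, float]:
    """Estimated (or traced) membrane length per compartment, in nm."""
    by_comp = profiles_by_compartment(ann.profiles)
    lengths: dict[Compartment, float] = {}
    for c in MEMBRANE_COMPARTMENTS:
        profs = by_comp[c]
        if not profs:
            lengths[c] = 0.0
            continue
        spacing = spacing_map.get(c, TRACE_LENGTH)
        if spacing == TRACE_LENGTH:
            lengths[c] = sum(p.length_nm for p in profs)
        else:
            grid = make_grid(float(spacing), grid_seeds[c])
            crossings = sum(
                count_polyline_intersections(p.points, grid) for p in profs
            )
            lengths[c] = estimate_length(crossings, float(spacing))
    return lengths


def quantify_study(
    annotations: list[MicrographAnnotation],
    spacing_map: dict[Compartment, float | str] | None = None,
    assignment: AssignmentParams | None = None,
    seed: int = 0,
) -> list[LabellingTable]:
    """Quantify labelling per (experiment, condition, stream) group.

    Grid placements are drawn independently per micrograph and compartment
    from ``seed``; counts and lengths are pooled within each group as a
    ratio of sums. Deterministic given the same annotation set and seed.
    """
    from .io import DEFAULT_SPACING_MAP

    spacing_map = dict(spacing_map or DEFAULT_SPACING_MAP)
    assignment = assignment or AssignmentParams()
    anns = sorted(
        annotations,
        key=lambda a: (a.experiment_id, a.condition, a.sampling_stream,
                       a.micrograph_id),
    )
    root = np.random.SeedSequence(seed)

    acc_n: dict[tuple, dict[Compartment, int]] = defaultdict(
        lambda: {c: 0 for c in MEMBRANE_COMPARTMENTS}
    )
    acc_l: dict[tuple, dict[Compartment, float]] = defaultdict(
        lambda: {c: 0.0 for c in MEMBRANE_COMPARTMENTS}
    )
    acc_un: dict[tuple, int] = defaultdict(int)
    acc_ids: dict[tuple, list[str]] = defaultdict(list)
    acc_ab: dict[tuple, str] = {}

    for ann in anns:
        grid_seeds = {
            c: int(s) % 2**31
            for c, s in zip(
                MEMBRANE_COMPARTMENTS,
                root.spawn(1)[0].generate_state(len(MEMBRANE_COMPARTMENTS)),
            )
        }
        lengths = _measure_lengths(ann, spacing_map, grid_seeds)
        result = assign_particles(ann.particles, ann.profiles, assignment)
        key = (ann.experiment_id, ann.condition, ann.sampling_stream)
        for c in MEMBRANE_COMPARTMENTS:
            acc_n[key][c] += result.counts[c]
            acc_l[key][c] += lengths[c]
        acc_un[key] += result.unassigned
        acc_ids[key].append(ann.micrograph_id)
        acc_ab[key] = ann.antibody_id

    tables = []
    for key in sorted(acc_n):
        exp, cond, stream = key
        tables.append(
            LabellingTable(
                experiment_id=exp,
                condition=cond,
                sampling_stream=stream,
                entries=labelling_density(acc_n[key], acc_l[key]),
                unassigned_count=acc_un[key],
                micrograph_ids=tuple(acc_ids[key]),
                antibody_id=acc_ab[key],
            )
        )
    return tables


def merge_streams(tables: list[LabellingTable]) -> LabellingTable:
    """Combine the per-stream tables of one (experiment, condition).

    Mitosome entries are taken from the comprehensive stream when present,
    every other compartment from the SUR stream; a compartment is never
    pooled across streams.
    """
    if not tables:
        raise ValueError("no tables to merge")
    by_stream = {t.sampling_stream: t for t in tables}
    base = by_stream.get("sur") or next(iter(by_stream.values()))
    entries = dict(base.entries)
    comp_t = by_stream.get("comprehensive")
    if comp_t is not None:
        entries[Compartment.MITOSOME] = comp_t.entries[Compartment.MITOSOME]
    ids = tuple(i for t in tables for i in t.micrograph_ids)
    return LabellingTable(
        experiment_id=base.experiment_id,
        condition=base.condition,
        sampling_stream="+".join(sorted(by_stream)),
        entries=entries,
        unassigned_count=sum(t.unassigned_count for t in tables),
        micrograph_ids=ids,
        antibody_id=base.antibody_id,
    )


def specificity_per_experiment(
    tables: list[LabellingTable], clamp: bool = True, section_wide: bool = False
) -> list[SpecificityResult]:
    """Pair native and inhibited tables per experiment; abort when the
    inhibition control is missing (specificity needs it by design)."""
    grouped: dict[tuple[str, str], list[LabellingTable]] = defaultdict(list)
    for t in tables:
        grouped[(t.experiment_id, t.condition)].append(t)
    experiments = sorted({exp for exp, _ in grouped})
    results = []
    for exp in experiments:
        native = grouped.get((exp, "native"))
        inhibited = grouped.get((exp, "inhibited"))
        if not native or not inhibited:
            missing = "inhibited" if native else "native"
            raise MissingControlError(
                f"experiment {exp!r} has no {missing} data; the specific "
                "labelling cannot be computed without the paired control"
            )
        results.append(
            compute_specificity(
                merge_streams(native), merge_streams(inhibited),
                clamp=clamp, section_wide=section_wide,
            )
        )
    return results


# ------------------------------------------------------------------ reports


def tables_to_frame(tables: list[LabellingTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        for c in MEMBRANE_COMPARTMENTS:
            q = t.entries[c]
            rows.append(
                {
                    "experiment_id": t.experiment_id,
                    "condition": t.condition,
                    "sampling_stream": t.sampling_stream,
                    "compartment": c.value,
                    "n_gold": q.n,
                    "length_nm": q.length_nm,
                    "density_per_um": q.density_per_um,
                    "unassigned_count": t.unassigned_count,
                    "antibody_id": t.antibody_id,
                }
            )
    return pd.DataFrame(rows)


def specificity_to_frame(results: list[SpecificityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for c in MEMBRANE_COMPARTMENTS:
            s = r.entries[c]
            rows.append(
                {
                    "experiment_id": r.experiment_id,
                    "compartment": c.value,
                    "d0_per_um": s.d0,
                    "dminus_per_um": s.dminus,
                    "dsp_per_um": s.dsp,
                    "fsp_raw": s.fsp_raw,
                    "fsp_clamped": s.fsp_clamped,
                    "n0": s.n0,
                    "ng_sp": s.ng_sp,
                    "antibody_id": r.antibody_id,
                }
            )
    return pd.DataFrame(rows)


def aggregate_to_frame(results: list[SpecificityResult]) -> pd.DataFrame:
    """Mean +/- SEM across experiments for Ng(sp) and D(sp), per compartment."""
    frames = []
    for stat, getter in (
        ("ng_sp", lambda s: s.ng_sp),
        ("dsp_per_um", lambda s: s.dsp),
    ):
        values = {
            c: [getter(r.entries[c]) for r in results]
            for c in MEMBRANE_COMPARTMENTS
        }
        agg = aggregate_experiments(values, statistic=stat)
        frames.append(
            pd.DataFrame(
                {
                    "compartment": [c.value for c in MEMBRANE_COMPARTMENTS],
                    "statistic": stat,
                    "mean": [agg.mean[c] for c in MEMBRANE_COMPARTMENTS],
                    "sem": [agg.sem[c] for c in MEMBRANE_COMPARTMENTS],
                    "n_experiments": [agg.n[c] for c in MEMBRANE_COMPARTMENTS],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_pipeline(
    config: StudyConfig,
    annotations_dir: str | Path,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Execute quantify -> specificity -> aggregate and write all CSVs.

    Re-running with identical config and inputs reproduces byte-identical
    outputs; a provenance file records the config hash and seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotations = read_annotations(annotations_dir)

    tables = quantify_study(
        annotations,
        spacing_map=config.spacing_map,
        assignment=config.assignment,
        seed=config.seed,
    )
    results = specificity_per_experiment(
        tables, clamp=config.clamp_fsp, section_wide=config.section_wide_fsp
    )

    paths = {
        "labelling": out / "labelling_tables.csv",
        "specificity": out / "specificity_per_experiment.csv",
        "summary": out / "distribution_summary.csv",
        "provenance": out / "provenance.json",
    }
    tables_to_frame(tables).to_csv(paths["labelling"], index=False)
    specificity_to_frame(results).to_csv(paths["specificity"], index=False)
    aggregate_to_frame(results).to_csv(paths["summary"], index=False)

    from . import __version__

    provenance = {
        "config": config.to_dict(),
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "goldstereo_version": __version__,
        "n_annotations": len(annotations),
        "micrograph_ids": sorted(a.micrograph_id for a in annotations),
    }
    paths["provenance"].write_text(
        json.dumps(provenance, indent=1, sort_keys=True)
    )
    return paths
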