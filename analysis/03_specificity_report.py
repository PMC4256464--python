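"""Specificity statistics and the specific gold distribution.

Pairs each experiment's native table with its inhibition control, computes
D(sp) = D(0) - D(-), F(sp) = D(sp)/D(0) (raw and clamped) and the specific
distribution Ng(sp) = F(sp) * N(0), then aggregates the three experiments
as mean +/- SEM. Writes the per-experiment density table, the aggregated
distribution, and a bar chart.
"""

import argparse
from pathlib import Path

from goldstereo.annotations import MEMBRANE_COMPARTMENTS
from goldstereo.io import StudyConfig, read_annotations
from goldstereo.pipeline import (
    aggregate_to_frame,
    quantify_study,
    specificity_per_experiment,
    specificity_to_frame,
)
from goldstereo.specificity import aggregate_experiments, plot_distribution

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--annotations", type=Path, default=ROOT / "scratch" / "annotations"
    )
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    parser.add_argument("--no-clamp", action="store_true")
    args = parser.parse_args()

    cfg_path = args.annotations / "study_config.json"
    cfg = StudyConfig.from_json(cfg_path) if cfg_path.exists() else StudyConfig()
    if args.no_clamp:
        cfg.clamp_fsp = False
    annotations = read_annotations(args.annotations)
    tables = quantify_study(annotations, cfg.spacing_map, cfg.assignment, seed=cfg.seed)
    results = specificity_per_experiment(
        tables, clamp=cfg.clamp_fsp, section_wide=cfg.section_wide_fsp
    )

    args.out.mkdir(parents=True, exist_ok=True)
    specificity_to_frame(results).to_csv(
        args.out / "specificity_per_experiment.csv", index=False
    )
    summary = aggregate_to_frame(results)
    summary.to_csv(args.out / "distribution_summary.csv", index=False)

    ng = aggregate_experiments(
        {c: [r.entries[c].ng_sp for r in results] for c in MEMBRANE_COMPARTMENTS},
        statistic="Ng(sp), mean of experiments",
    )
    fig_dir = args.out / "figures"
    fig_dir.mkdir(exist_ok=True)
    plot_distribution(ng, fig_dir / "ng_sp_distribution.svg")

    print(f"specificity over {len(results)} experiments -> {args.out}")
    print("\nspecific gold distribution Ng(sp), mean +/- SEM:")
    for c in MEMBRANE_COMPARTMENTS:
        sem = ng.sem[c]
        print(f"  {c.value:18s} {ng.mean[c]:8.1f} +/- {sem if sem is None else round(sem, 1)}")
    share = ng.mean[max(ng.mean, key=ng.mean.get)] / sum(ng.mean.values())
    print(f"\nmodal compartment: {max(ng.mean, key=ng.mean.get).value} "
          f"({100 * share:.0f}% of specific gold)")


if __name__ == "__main__":
    main()
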