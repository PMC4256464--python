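"""Validate the estimators against ground truth.

Two checks that need no real data: (i) design-unbiasedness of the lattice
length estimator on curves of known length, over many random placements;
(ii) a null-specificity control — when the "inhibited" condition is
generated with the same parameters as the native one (rho = 0), the mean
raw specific fraction must vanish. Writes results/estimator_validation.json.
"""

import argparse
import json
import math
from pathlib import Path

import numpy as np

from goldstereo.annotations import MEMBRANE_COMPARTMENTS
from goldstereo.pipeline import quantify_study, specificity_per_experiment
from goldstereo.scene import LabellingModel, SceneParams, simulate_study
from goldstereo.stereology import (
    count_polyline_intersections,
    estimate_length,
    make_grid,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    parser.add_argument("--n-grids", type=int, default=5000)
    parser.add_argument("--n-null-seeds", type=int, default=10)
    args = parser.parse_args()

    report = {}

    d = 262.0
    theta = np.linspace(0.0, 2 * math.pi, 720, endpoint=False)
    circle = np.column_stack([1000.0 * np.cos(theta), 1000.0 * np.sin(theta)]) + 4000.0
    circle = np.vstack([circle, circle[:1]])
    rng = np.random.default_rng(args.seed)
    for name, curve, true_len in (
        ("circle_r1000", circle, 2 * math.pi * 1000.0),
        ("segment_5000", np.array([[500.0, 1200.0], [5500.0, 1200.0]]), 5000.0),
    ):
        est = np.array(
            [
                estimate_length(
                    count_polyline_intersections(curve, make_grid(d, int(s))), d
                )
                for s in rng.integers(0, 2**31, size=args.n_grids)
            ]
        )
        rel_err = abs(float(est.mean()) - true_len) / true_len
        report[name] = {
            "true_length_nm": true_len,
            "mean_estimate_nm": float(est.mean()),
            "rel_error": rel_err,
            "cv": float(est.std(ddof=1) / est.mean()),
            "n_grids": args.n_grids,
        }
        print(f"{name}: mean estimate {est.mean():.0f} nm vs true "
              f"{true_len:.0f} nm ({100 * rel_err:.2f}% off)")

    model = LabellingModel(inhibition_efficiency=0.0)
    fsp = {c.value: [] for c in MEMBRANE_COMPARTMENTS}
    for k in range(args.n_null_seeds):
        annotations, _ = simulate_study(SceneParams(), model, seed=args.seed + 100 + k)
        tables = quantify_study(annotations, seed=args.seed + 200 + k)
        for res in specificity_per_experiment(tables):
            for c in MEMBRANE_COMPARTMENTS:
                raw = res.entries[c].fsp_raw
                if raw is not None:
                    fsp[c.value].append(raw)
    report["null_specificity_mean_fsp"] = {
        c: float(np.mean(v)) for c, v in fsp.items()
    }
    print("null control (rho = 0) mean raw F(sp):",
          {c: round(v, 3) for c, v in report["null_specificity_mean_fsp"].items()})

    args.out.mkdir(parents=True, exist_ok=True)
    out = args.out / "estimator_validation.json"
    out.write_text(json.dumps(report, indent=1, sort_keys=True))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
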