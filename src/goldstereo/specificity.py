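"""Specific-labelling statistics with inhibition controls.

For each compartment the raw labelling density D(0) (native antiserum) is
compared with the density D(-) obtained after pre-mixing the antiserum with
its immunising peptide. The specific density is

    D(sp) = D(0) - D(-)

(negative values are retained: they indicate induction of signal by the
inhibited antiserum), and the specific fraction is

    F(sp) = D(sp) / D(0),

clamped into [0, 1] when used to distribute gold counts; the raw value is
always reported alongside. The distribution of specific gold is obtained by
multiplying F(sp) with the initial (native) gold particle counts of each
compartment, Ng(sp) = F(sp) * N(0). Replicate experiments are summarised
as mean +/- SEM (sample SD with n-1 denominator over sqrt n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotations import Compartment, MEMBRANE_COMPARTMENTS
from .labelling import LabellingTable

__all__ = [
    "CompartmentSpecificity",
    "SpecificityResult",
    "AggregateResult",
    "specific_density",
    "specific_fraction",
    "specific_distribution",
    "compute_specificity",
    "aggregate_experiments",
]


def specific_density(d0: float | None, dminus: float | None) -> float | None:
    """D(sp) = D(0) - D(-); negatives retained; undefined inputs propagate."""
    if d0 is None or dminus is None:
        return None
    if d0 < 0 or dminus < 0:
        raise ValueError("densities must be >= 0")
    return d0 - dminus


def specific_fraction(
    d0: float | None, dminus: float | None
) -> tuple[float | None, float | None]:
    """(raw, clamped) F(sp) = (D(0) - D(-)) / D(0).

    D(0) = 0 is defined as F(sp) = 0 (no label, no specific label) so that
    empty compartments do not poison downstream reports.
    """
    if d0 is None or dminus is None:
        return None, None
    if d0 < 0 or dminus < 0:
        raise ValueError("densities must be >= 0")
    if d0 == 0:
        return 0.0, 0.0
    raw = (d0 - dminus) / d0
    return raw, min(1.0, max(0.0, raw))


def specific_distribution(
    fsp: Mapping[Compartment, float], n0: Mapping[Compartment, int]
) -> dict[Compartment, float]:
    """Ng(sp)_c = F(sp)_c * N(0)_c, over identical compartment sets."""
    if set(fsp) != set(n0):
        raise ValueError("fsp and n0 must cover the same compartments")
    out = {}
    for c, f in fsp.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"clamped fsp[{c}] must be in [0, 1]")
        if n0[c] < 0:
            raise ValueError(f"n0[{c}] must be >= 0")
        out[c] = f * n0[c]
    return out


@dataclass(frozen=True)
class CompartmentSpecificity:
    d0: float | None
    dminus: float | None
    dsp: float | None
    fsp_raw: float | None
    fsp_clamped: float | None
    n0: int
    ng_sp: float | None


@dataclass
class SpecificityResult:
    """Specificity statistics for one experiment (one antibody)."""

    experiment_id: str
    antibody_id: str
    entries: dict[Compartment, CompartmentSpecificity]
    clamped: bool = True
    section_wide: bool = False


def compute_specificity(
    native: LabellingTable,
    inhibited: LabellingTable,
    clamp: bool = True,
    section_wide: bool = False,
) -> SpecificityResult:
    """Pair a native table with its inhibition control.

    ``section_wide=True`` computes a single F(sp) from the pooled densities
    of all measured compartments and applies it to every compartment's
    counts (an alternative reading of the distribution rule; the default is
    per-compartment).
    """
    if native.experiment_id != inhibited.experiment_id:
        raise ValueError("tables must come from the same experiment")
    if native.condition != "native" or inhibited.condition != "inhibited":
        raise ValueError("expected one native and one inhibited table")

    fsp_wide_raw = fsp_wide_cl = None
    if section_wide:
        n0_tot = sum(
            q.n for q in native.entries.values() if q.density_per_um is not None
        )
        l0_tot = sum(
            q.length_nm for q in native.entries.values()
            if q.density_per_um is not None
        )
        nm_tot = sum(
            q.n for q in inhibited.entries.values() if q.density_per_um is not None
        )
        lm_tot = sum(
            q.length_nm for q in inhibited.entries.values()
            if q.density_per_um is not None
        )
        d0_tot = n0_tot / (l0_tot / 1000.0) if l0_tot > 0 else None
        dm_tot = nm_tot / (lm_tot / 1000.0) if lm_tot > 0 else None
        fsp_wide_raw, fsp_wide_cl = specific_fraction(d0_tot, dm_tot)

    entries: dict[Compartment, CompartmentSpecificity] = {}
    for c in MEMBRANE_COMPARTMENTS:
        q0 = native.entries.get(c)
        qm = inhibited.entries.get(c)
        d0 = q0.density_per_um if q0 else None
        dm = qm.density_per_um if qm else None
        n0 = q0.n if q0 else 0
        dsp = specific_density(d0, dm)
        raw, clamped_f = specific_fraction(d0, dm)
        if section_wide:
            raw, clamped_f = fsp_wide_raw, fsp_wide_cl
        use = clamped_f if clamp else raw
        ng = None if use is None else use * n0
        entries[c] = CompartmentSpecificity(
            d0=d0, dminus=dm, dsp=dsp, fsp_raw=raw, fsp_clamped=clamped_f,
            n0=n0, ng_sp=ng,
        )
    return SpecificityResult(
        experiment_id=native.experiment_id,
        antibody_id=native.antibody_id,
        entries=entries,
        clamped=clamp,
        section_wide=section_wide,
    )


@dataclass
class AggregateResult:
    """Cross-experiment mean +/- SEM of one statistic, per compartment."""

    statistic: str
    mean: dict[Compartment, float]
    sem: dict[Compartment, float | None]
    n: dict[Compartment, int]


def aggregate_experiments(
    per_experiment: Mapping[Compartment, Sequence[float]],
    statistic: str = "ng_sp",
) -> AggregateResult:
    """Mean and SEM (sample SD / sqrt n) per compartment across replicates.

    SEM requires n >= 2 and is reported as None (flagged unavailable)
    otherwise.
    """
    mean: dict[Compartment, float] = {}
    sem: dict[Compartment, float | None] = {}
    ns: dict[Compartment, int] = {}
    for c, values in per_experiment.items():
        vals = np.asarray([v for v in values if v is not None], dtype=float)
        n = vals.size
        ns[c] = n
        if n == 0:
            mean[c] = math.nan
            sem[c] = None
            continue
        mean[c] = float(vals.mean())
        sem[c] = float(vals.std(ddof=1) / math.sqrt(n)) if n >= 2 else None
    return AggregateResult(statistic=statistic, mean=mean, sem=sem, n=ns)


def plot_distribution(agg: AggregateResult, path) -> None:
    """Bar chart of the aggregated distribution with SEM error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = [c for c in MEMBRANE_COMPARTMENTS if c in agg.mean]
    means = [agg.mean[c] for c in comps]
    errs = [agg.sem[c] or 0.0 for c in comps]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(range(len(comps)), means, yerr=errs, capsize=3, color="#888888")
    ax.set_xticks(range(len(comps)))
    ax.set_xticklabels([c.value.replace("_", "\n") for c in comps], fontsize=8)
    ax.set_ylabel(agg.statistic)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
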