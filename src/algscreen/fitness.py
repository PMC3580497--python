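"""Area-under-growth-curve activity scoring against in-plate solvent controls.

The fitness readout for a well is the trapezoidal area under its OD600 time
course (OD·hours). A compound's activity score on one plate is its AUC
divided by the mean AUC of that plate's DMSO (solvent) control wells; scores
from replicate plates are averaged and a compound is called a fitness hit
when the mean growth ratio is at or below the hit threshold (default 0.65,
i.e. at least 35% growth inhibition).

By default each well's initial OD is subtracted before integration (floored
at zero), which makes ratios robust to plate-to-plate differences in
inoculum density; set ``baseline="raw"`` to integrate raw OD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .plate_io import PlateLayout, WellSeries

DEFAULT_HIT_THRESHOLD = 0.65
DEFAULT_CONTROL_CV_BOUND = 0.20

Baseline = Literal["baseline-subtracted", "raw"]


class PlateQCError(ValueError):
    """Plate-level quality control failure (e.g. dead controls)."""


class FitnessWarning(UserWarning):
    pass


@dataclass
class FitnessResult:
    """Per-compound fitness score aggregated over replicate plates.

    ``growth_ratio`` is the mean over replicates of (compound AUC / in-plate
    control AUC); ``replicate_sd`` is the sample (n-1) standard deviation of
    the per-replicate ratios, None when fewer than two replicates exist.
    """

    compound_id: str
    growth_ratio: float
    replicate_sd: float | None
    n_replicates: int
    is_hit: bool
    auc: list[float] = field(default_factory=list)
    replicate_ratios: list[float] = field(default_factory=list)
    is_cytocidal: bool | None = None
    is_cytostatic: bool | None = None


@dataclass
class ScreenSummary:
    n_screened: int
    n_hits: int
    hit_percentage: float
    threshold: float = DEFAULT_HIT_THRESHOLD


def trapezoid_auc(
    series: WellSeries,
    window: tuple[float, float] | None = None,
    baseline: Baseline = "baseline-subtracted",
) -> float:
    """Trapezoidal area under one well's growth curve, in OD·hours.

    ``window`` restricts integration to ``[t_start, t_end]`` (must lie within
    the recorded range and contain at least two samples); the default is the
    full time course. With baseline subtraction, the well's first recorded OD
    (of the full series, not the window) is subtracted and negative values
    floored at zero before integrating.
    """
    t, y = series.times, series.od
    if baseline == "baseline-subtracted":
        y = np.maximum(y - y[0], 0.0)
    elif baseline != "raw":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    if window is not None:
        t0, t1 = window
        if t0 >= t1:
            raise ValueError(f"empty integration window [{t0}, {t1}]")
        if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12:
            raise ValueError(
                f"window [{t0}, {t1}] outside recorded range [{t[0]}, {t[-1]}]"
            )
        mask = (t >= t0) & (t <= t1)
        if mask.sum() < 2:
            raise ValueError("integration window contains fewer than 2 samples")
        t, y = t[mask], y[mask]
    return float(np.trapezoid(y, t))


def growth_ratio(compound_auc: float, control_auc: float) -> float:
    """Compound AUC over the plate's mean solvent-control AUC."""
    if not control_auc > 0:
        raise PlateQCError(
            f"control AUC {control_auc!r} is not positive: plate failed QC"
        )
    return compound_auc / control_auc


def call_fitness_hit(ratio: float, threshold: float = DEFAULT_HIT_THRESHOLD) -> bool:
    """A fitness hit is a growth ratio at or below the threshold (0.65 or
    less, i.e. >= 35% inhibition). The boundary is inclusive."""
    if ratio < 0:
        raise ValueError(f"growth ratio must be >= 0, got {ratio}")
    return ratio <= threshold


def aggregate_replicates(
    ratios: Sequence[float],
    threshold: float = DEFAULT_HIT_THRESHOLD,
    compound_id: str = "",
) -> FitnessResult:
    """Mean, sample SD and hit call over per-replicate growth ratios.

    The hit call applies to the mean of the replicates; SD is None for a
    single replicate (some libraries were screened once).
    """
    if len(ratios) == 0:
        raise ValueError("no replicate ratios to aggregate")
    arr = np.asarray(ratios, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return FitnessResult(
        compound_id=compound_id,
        growth_ratio=mean,
        replicate_sd=sd,
        n_replicates=int(arr.size),
        is_hit=call_fitness_hit(mean, threshold),
        replicate_ratios=[float(r) for r in arr],
    )


def score_plate(
    layout: PlateLayout,
    series: Sequence[WellSeries],
    window: tuple[float, float] | None = None,
    baseline: Baseline = "baseline-subtracted",
    control_cv_bound: float = DEFAULT_CONTROL_CV_BOUND,
) -> dict[str, float]:
    """Per-compound growth ratio for one physical plate.

    The control AUC is the arithmetic mean over the plate's solvent-control
    wells. A control coefficient of variation above ``control_cv_bound``
    flags the plate with a warning (results are still returned).
    Returns ``{compound_id: ratio}``; compounds in multiple wells on one
    plate are averaged within the plate.
    """
    by_well = {s.well: s for s in series}
    control_aucs = []
    for w in layout.control_wells():
        if w in by_well:
            control_aucs.append(trapezoid_auc(by_well[w], window, baseline))
    if not control_aucs:
        raise PlateQCError(f"plate {layout.plate_id}: no control wells measured")
    control_mean = float(np.mean(control_aucs))
    if control_mean > 0 and len(control_aucs) >= 2:
        cv = float(np.std(control_aucs, ddof=1)) / control_mean
        if cv > control_cv_bound:
            warnings.warn(
                f"plate {layout.plate_id}: control CV {cv:.1%} exceeds "
                f"{control_cv_bound:.0%} QC bound",
                FitnessWarning,
                stacklevel=2,
            )
    per_compound: dict[str, list[float]] = {}
    for w in layout.compound_wells():
        if w not in by_well:
            continue
        cid = layout.wells[w].compound_id
        ratio = growth_ratio(trapezoid_auc(by_well[w], window, baseline), control_mean)
        per_compound.setdefault(cid, []).append(ratio)
    return {cid: float(np.mean(rs)) for cid, rs in per_compound.items()}


def score_screen(
    plates: Sequence[tuple[PlateLayout, Sequence[WellSeries]]],
    threshold: float = DEFAULT_HIT_THRESHOLD,
    window: tuple[float, float] | None = None,
    baseline: Baseline = "baseline-subtracted",
    control_cv_bound: float = DEFAULT_CONTROL_CV_BOUND,
) -> list[FitnessResult]:
    """Score a whole campaign: per-plate ratios, then replicate aggregation.

    Replicate plates are any plates that carry the same compound_id; each
    plate contributes one ratio per compound against its own controls.
    """
    per_compound: dict[str, list[float]] = {}
    for layout, series in plates:
        for cid, ratio in score_plate(
            layout, series, window, baseline, control_cv_bound
        ).items():
            per_compound.setdefault(cid, []).append(ratio)
    return [
        aggregate_replicates(ratios, threshold, compound_id=cid)
        for cid, ratios in sorted(per_compound.items())
    ]


def summarize_screen(
    results: Sequence[FitnessResult], ndigits: int = 0
) -> ScreenSummary:
    """Screen-level counts: n screened, n hits, hit percentage (rounded to
    ``ndigits`` decimal places; default nearest integer)."""
    if len(results) == 0:
        raise ValueError("cannot summarize an empty screen")
    n_hits = sum(r.is_hit for r in results)
    return ScreenSummary(
        n_screened=len(results),
        n_hits=n_hits,
        hit_percentage=percentage(n_hits, len(results), ndigits),
    )


def percentage(numerator: int | float, denominator: int | float, ndigits: int = 0) -> float:
    """100 * numerator / denominator rounded to ``ndigits`` decimals, as the
    screen tables report fractions (e.g. 2,397/5,445 -> 44)."""
    if denominator == 0:
        raise ValueError("percentage of an empty denominator")
    return round(100.0 * numerator / denominator, ndigits)
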