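"""Acute-assay phenotype classification and overlap accounting.

The acute screens expose cells to compound for a few hours (within one cell
cycle) and read out two phenotypes: phototaxis/motility, from categorical
image scores of swimming behaviour under directional light, and
photosynthetic capacity, from chlorophyll fluorescence (a higher signal
means reduced photosystem II efficiency). A regrowth assay after pinning
onto compound-free agar distinguishes cytocidal from cytostatic growth
inhibitors.

Untreated cells swim away from the light source (negative phototaxis), so a
``toward_light`` score against an ``away_from_light`` control is a reversal
of phototactic sign; ``no_movement`` and ``lysed`` wells are motility
inhibited. The imaging protocol photographs each plate twice (light from
opposite sides); the two scores are reconciled by agreement — disagreement
yields a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .fitness import FitnessResult

MOTILITY_NORMAL = "normal"
MOTILITY_INHIBITED = "motility_inhibited"
SIGN_REVERSED = "sign_reversed"
MISSING = "missing"

CYTOCIDAL = "cytocidal"
CYTOSTATIC = "cytostatic"
REVERSIBLE = "reversible"

DEFAULT_FLUOR_HIT_RATIO = 1.35

_OPPOSITE = {"toward_light": "away_from_light", "away_from_light": "toward_light"}


@dataclass
class PhenotypeCall:
    """Acute phenotype calls for one compound."""

    compound_id: str
    motility_class: str = MISSING
    photosynthesis_hit: bool | None = None
    fluorescence_ratio: float | None = None
    cytotoxicity: str = MISSING

    def __post_init__(self) -> None:
        if self.motility_class not in (
            MOTILITY_NORMAL,
            MOTILITY_INHIBITED,
            SIGN_REVERSED,
            MISSING,
        ):
            raise ValueError(f"unknown motility class {self.motility_class!r}")
        if self.fluorescence_ratio is not None and self.fluorescence_ratio < 0:
            raise ValueError("fluorescence ratio must be >= 0")

    @property
    def motility_active(self) -> bool:
        return self.motility_class in (MOTILITY_INHIBITED, SIGN_REVERSED)


@dataclass
class AcuteSummary:
    """Overlap accounting across the two acute assays and the fitness screen.

    ``n_unique_acute`` counts compounds active in either acute assay
    (inclusion–exclusion: motility + photosynthesis − both); ``n_also_fitness``
    counts acute actives that are also fitness hits.
    """

    n_screened: int
    n_motility: int
    n_photosynthesis: int
    n_both: int
    n_unique_acute: int
    n_also_fitness: int

    def __post_init__(self) -> None:
        assert self.n_unique_acute == self.n_motility + self.n_photosynthesis - self.n_both
        assert self.n_also_fitness <= self.n_unique_acute


def score_phototaxis(
    score: str | None, control_direction: str = "away_from_light"
) -> str:
    """Classify one phototaxis image score against the control direction.

    ``no_movement`` and ``lysed`` are motility inhibited (lysed wells show no
    response to directional light); movement opposite the control direction
    is a phototaxis sign reversal; movement matching the control is normal.
    """
    if control_direction not in _OPPOSITE:
        raise ValueError(f"unknown control direction {control_direction!r}")
    if score is None:
        return MISSING
    if score in ("no_movement", "lysed"):
        return MOTILITY_INHIBITED
    if score == _OPPOSITE[control_direction]:
        return SIGN_REVERSED
    if score == control_direction:
        return MOTILITY_NORMAL
    raise ValueError(f"unknown phototaxis score {score!r}")


def reconcile_phototaxis(
    score_1: str | None,
    score_2: str | None,
    control_direction: str = "away_from_light",
) -> str:
    """Reconcile the two per-well image scores (plate photographed from both
    sides): agreement gives that class, disagreement gives missing. A single
    available score is used as-is."""
    c1 = score_phototaxis(score_1, control_direction)
    c2 = score_phototaxis(score_2, control_direction)
    if c1 == MISSING:
        return c2
    if c2 == MISSING:
        return c1
    return c1 if c1 == c2 else MISSING


def score_photosynthesis(
    fluorescence: float,
    control_mean: float,
    hit_ratio_threshold: float = DEFAULT_FLUOR_HIT_RATIO,
) -> tuple[float, bool]:
    """Fluorescence ratio against the in-plate solvent-control mean and the
    hit call (ratio >= threshold; elevated fluorescence means impaired
    photosynthesis)."""
    if not control_mean > 0:
        raise ValueError(
            f"control fluorescence mean {control_mean!r} not positive: plate failed QC"
        )
    ratio = fluorescence / control_mean
    return ratio, ratio >= hit_ratio_threshold


def classify_cytotoxicity(was_growth_inhibited: bool, regrew: bool | None) -> str:
    """Cytocidal (inhibited, no regrowth), cytostatic (inhibited, regrew) or
    reversible (not inhibited). Missing regrowth data gives a missing call
    for inhibited compounds."""
    if not was_growth_inhibited:
        return REVERSIBLE
    if regrew is None:
        return MISSING
    return CYTOSTATIC if regrew else CYTOCIDAL


def summarize_acute(
    calls: Sequence[PhenotypeCall],
    fitness: Sequence[FitnessResult] = (),
) -> AcuteSummary:
    """Count motility actives, photosynthesis actives, their intersection and
    union, and the union's overlap with fitness hits."""
    seen: set[str] = set()
    for c in calls:
        if c.compound_id in seen:
            raise ValueError(f"duplicate compound_id in calls: {c.compound_id!r}")
        seen.add(c.compound_id)
    motility = {c.compound_id for c in calls if c.motility_active}
    photo = {c.compound_id for c in calls if c.photosynthesis_hit}
    union = motility | photo
    fit_hits = {f.compound_id for f in fitness if f.is_hit}
    return AcuteSummary(
        n_screened=len(calls),
        n_motility=len(motility),
        n_photosynthesis=len(photo),
        n_both=len(motility & photo),
        n_unique_acute=len(union),
        n_also_fitness=len(union & fit_hits),
    )


def call_phenotypes(
    readouts_by_compound: Mapping[str, Sequence["AcuteReadout"]],
    control_fluorescence_mean: float,
    fitness: Mapping[str, FitnessResult] | None = None,
    hit_ratio_threshold: float = DEFAULT_FLUOR_HIT_RATIO,
    control_direction: str = "away_from_light",
) -> list[PhenotypeCall]:
    """Turn per-compound acute readouts into phenotype calls.

    Multiple wells per compound are allowed; fluorescence is averaged and
    phototaxis calls must agree (else missing). Cytotoxicity is classified
    when fitness results and regrowth data are available.
    """
    calls: list[PhenotypeCall] = []
    for cid in sorted(readouts_by_compound):
        wells = readouts_by_compound[cid]
        fluors = [r.fluorescence for r in wells if r.fluorescence is not None]
        ratio: float | None = None
        photo_hit: bool | None = None
        if fluors:
            mean_fluor = sum(fluors) / len(fluors)
            ratio, photo_hit = score_photosynthesis(
                mean_fluor, control_fluorescence_mean, hit_ratio_threshold
            )
        mclasses = {
            reconcile_phototaxis(r.phototaxis_score, r.phototaxis_score_2, control_direction)
            for r in wells
            if r.phototaxis_score is not None or r.phototaxis_score_2 is not None
        }
        mclasses.discard(MISSING)
        motility = mclasses.pop() if len(mclasses) == 1 else MISSING

        cyto = MISSING
        if fitness is not None and cid in fitness:
            regrew_vals = [r.regrew for r in wells if r.regrew is not None]
            regrew = regrew_vals[0] if regrew_vals else None
            cyto = classify_cytotoxicity(fitness[cid].is_hit, regrew)
        calls.append(
            PhenotypeCall(
                compound_id=cid,
                motility_class=motility,
                photosynthesis_hit=photo_hit,
                fluorescence_ratio=ratio,
                cytotoxicity=cyto,
            )
        )
    return calls
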