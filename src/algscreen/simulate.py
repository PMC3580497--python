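"""Synthetic screening campaigns: growth-curve plates with planted
inhibition, SMILES libraries with a planted structure–activity relationship,
and acute-assay readouts with planted mechanisms.

Growth wells follow a logistic curve

    OD(t) = OD0 + K / (1 + exp(-r (t - t_m))) + eps,   eps ~ N(0, sigma^2)

clipped at zero. A compound with inhibition factor phi in [0, 1] multiplies
the carrying capacity by phi and the growth rate by (0.5 + 0.5 phi), so
partial inhibitors change curve shape as well as scale; phi = 1 is a
no-effect compound and phi = 0 kills growth outright. Defaults (OD0 = 0.1,
K = 0.9, r = 0.15/h, t_m = 30 h, 0.5-h sampling over 80 h, triplicate
plates) emulate an 80-hour algal microtiter fitness assay read every 30
minutes. The closed-form AUC ratio implied by phi is available as an oracle
(:func:`expected_growth_ratio`), via the analytic logistic antiderivative.

Libraries are assembled from a fragment grammar (scaffold templates filled
with substituents), which guarantees chemically valid SMILES; a planted
pharmacophore fragment raises a compound's activity probability from p0 to
p1, giving ranking models a recoverable structure–activity signal.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .plate_io import (
    ROLE_COMPOUND,
    ROLE_CONTROL,
    ROLE_EMPTY,
    AcuteReadout,
    CompoundRecord,
    PlateLayout,
    WellRole,
    WellSeries,
    plate_addresses,
)

# mechanisms assignable to active compounds in the acute simulator
MECH_PHOTOSYNTHESIS = "photosynthesis"
MECH_MOTILITY = "motility"
MECH_SIGN_REVERSAL = "sign_reversal"
MECH_GENERAL = "general"


@dataclass
class PlateSimConfig:
    """Configuration for simulated growth plates; defaults emulate the
    80-hour / 30-minute-sampling fitness assay."""

    geometry: int = 96
    n_controls: int = 8
    od0: float = 0.1
    carrying_capacity: float = 0.9
    growth_rate: float = 0.15  # per hour
    midpoint: float = 30.0  # hours
    noise_sd: float = 0.005  # OD units
    interval: float = 0.5  # hours
    duration: float = 80.0  # hours
    inhibition: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in (96, 384):
            raise ValueError(f"invalid geometry {self.geometry}")
        for cid, phi in self.inhibition.items():
            if not 0.0 <= phi <= 1.0:
                raise ValueError(f"{cid}: inhibition factor {phi} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.duration / self.interval < 2:
            raise ValueError("need at least 2 sampling intervals")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.interval))
        return np.arange(n + 1) * self.interval


def logistic_od(
    t: np.ndarray, od0: float, capacity: float, rate: float, midpoint: float
) -> np.ndarray:
    """Noise-free logistic growth curve OD0 + K / (1 + exp(-r (t - t_m)))."""
    return od0 + capacity / (1.0 + np.exp(-rate * (np.asarray(t, float) - midpoint)))


def inhibited_params(cfg: PlateSimConfig, phi: float) -> tuple[float, float]:
    """(capacity, rate) for a well with inhibition factor phi."""
    return cfg.carrying_capacity * phi, cfg.growth_rate * (0.5 + 0.5 * phi)


def _logistic_auc(capacity: float, rate: float, midpoint: float, duration: float) -> float:
    # integral over [0, T] of the baseline-subtracted logistic, via the
    # antiderivative (K/r) log(1 + exp(r (t - t_m)))
    if capacity == 0.0:
        return 0.0
    a = np.logaddexp(0.0, rate * (duration - midpoint))
    b = np.logaddexp(0.0, rate * (0.0 - midpoint))
    sigmoid0 = 1.0 / (1.0 + math.exp(rate * midpoint))
    return capacity * ((a - b) / rate - duration * sigmoid0)


def expected_growth_ratio(phi: float, cfg: PlateSimConfig | None = None) -> float:
    """Closed-form baseline-subtracted AUC ratio implied by inhibition phi:
    the continuous-time integral of the inhibited logistic over that of the
    control, on the configured window. Independent oracle for the discrete
    trapezoid pipeline."""
    cfg = cfg or PlateSimConfig()
    k_c, r_c = inhibited_params(cfg, phi)
    num = _logistic_auc(k_c, r_c, cfg.midpoint, cfg.duration)
    den = _logistic_auc(cfg.carrying_capacity, cfg.growth_rate, cfg.midpoint, cfg.duration)
    return num / den


def make_layout(
    plate_id: str,
    compound_ids: Sequence[str],
    geometry: int = 96,
    n_controls: int = 8,
    dose_uM: float = 25.0,
) -> PlateLayout:
    """Row-major layout with ``n_controls`` solvent controls spread evenly
    across the plate and compounds filling the remaining wells."""
    addresses = plate_addresses(geometry)
    capacity = len(addresses) - n_controls
    if len(compound_ids) > capacity:
        raise ValueError(
            f"{len(compound_ids)} compounds exceed plate capacity {capacity}"
        )
    control_idx = set(
        int(i) for i in np.linspace(0, len(addresses) - 1, n_controls).round()
    )
    wells: dict[str, WellRole] = {}
    it = iter(compound_ids)
    for i, addr in enumerate(addresses):
        if i in control_idx:
            wells[addr] = WellRole(ROLE_CONTROL)
        else:
            cid = next(it, None)
            wells[addr] = (
                WellRole(ROLE_COMPOUND, compound_id=cid, dose_uM=dose_uM)
                if cid is not None
                else WellRole(ROLE_EMPTY)
            )
    return PlateLayout(plate_id=plate_id, wells=wells, geometry=geometry)


def simulate_plate(
    cfg: PlateSimConfig, plate_id: str = "sim-1", replicate: int = 0
) -> tuple[PlateLayout, list[WellSeries]]:
    """Simulate one plate carrying every compound in ``cfg.inhibition``.

    Control wells follow the uninhibited logistic; compound wells use the
    phi-scaled capacity and rate. Gaussian measurement noise of sd
    ``cfg.noise_sd`` is added and OD clipped at zero. Deterministic for a
    fixed (seed, plate_id, replicate)."""
    layout = make_layout(
        plate_id, sorted(cfg.inhibition), geometry=cfg.geometry, n_controls=cfg.n_controls
    )
    rng = np.random.default_rng([cfg.seed, replicate, _stable_hash(plate_id)])
    t = cfg.times
    series: list[WellSeries] = []
    for addr in sorted(layout.wells):
        role = layout.wells[addr]
        if role.role == ROLE_EMPTY:
            continue
        if role.role == ROLE_CONTROL:
            k, r = cfg.carrying_capacity, cfg.growth_rate
        else:
            k, r = inhibited_params(cfg, cfg.inhibition[role.compound_id])
        od = logistic_od(t, cfg.od0, k, r, cfg.midpoint)
        if cfg.noise_sd > 0:
            od = od + rng.normal(0.0, cfg.noise_sd, size=t.size)
        series.append(
            WellSeries(plate_id=plate_id, well=addr, times=t, od=np.clip(od, 0.0, None))
        )
    return layout, series


def simulate_screen(
    cfg: PlateSimConfig,
) -> list[tuple[PlateLayout, list[WellSeries]]]:
    """Simulate a replicated campaign: ``cfg.n_replicates`` plates (splitting
    across several plates per replicate when the compound count exceeds one
    plate's capacity)."""
    ids = sorted(cfg.inhibition)
    capacity = cfg.geometry - cfg.n_controls
    chunks = [ids[i : i + capacity] for i in range(0, len(ids), capacity)] or [[]]
    plates = []
    for rep in range(cfg.n_replicates):
        for p, chunk in enumerate(chunks):
            sub = PlateSimConfig(
                **{
                    **cfg.__dict__,
                    "inhibition": {cid: cfg.inhibition[cid] for cid in chunk},
                }
            )
            plates.append(
                simulate_plate(sub, plate_id=f"sim-r{rep + 1}p{p + 1}", replicate=rep)
            )
    return plates


def _stable_hash(text: str) -> int:
    # reproducible across processes (builtin hash() is salted)
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# SMILES library with planted structure–activity relationship

_SCAFFOLDS_1 = [
    "c1ccc({0})cc1",
    "c1ccnc({0})c1",
    "c1cc({0})oc1",
    "C1CCC({0})CC1",
    "C1CCN({0})CC1",
    "c1ccc2cc({0})ccc2c1",
]
_SCAFFOLDS_2 = [
    "c1cc({0})ccc1{1}",
    "c1cc({0})cc({1})c1",
    "C1CC({0})CCC1{1}",
]
_DECORATIONS = [
    "C",
    "CC",
    "CCC",
    "C(C)C",
    "O",
    "OC",
    "OCC",
    "N",
    "N(C)C",
    "Cl",
    "F",
    "Br",
    "C#N",
    "C(F)(F)F",
    "C(=O)O",
    "C(=O)NC",
    "CO",
    "CN",
]
DEFAULT_PHARMACOPHORES = ("S(=O)(=O)N", "C(=O)Nc1ccc(Cl)cc1")


@dataclass
class LibrarySimConfig:
    """Configuration for the planted-SAR library generator.

    A fraction ``prevalence`` of compounds carries one of the pharmacophore
    fragments; those are active with probability ``p1``, the rest with
    ``p0``. Defaults give a realized hit rate near
    prevalence*p1 + (1-prevalence)*p0 = 0.31."""

    n_compounds: int = 2000
    pharmacophores: tuple[str, ...] = DEFAULT_PHARMACOPHORES
    p0: float = 0.1
    p1: float = 0.8
    prevalence: float = 0.3
    seed: int = 0
    library: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= self.p1 <= 1.0:
            raise ValueError("need 0 <= p0 <= p1 <= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence outside [0, 1]")
        for frag in self.pharmacophores:
            if Chem.MolFromSmiles(frag) is None:
                raise ValueError(f"pharmacophore fragment is not valid SMILES: {frag!r}")


@dataclass
class LibrarySimResult:
    records: list[CompoundRecord]
    labels: list[bool]
    has_pharmacophore: list[bool]
    n_resampled: int = 0


def _assemble(rng: np.random.Generator, pharmacophore: str | None) -> str:
    if pharmacophore is not None and rng.random() < 0.5:
        tpl = _SCAFFOLDS_2[rng.integers(len(_SCAFFOLDS_2))]
        return tpl.format(pharmacophore, _DECORATIONS[rng.integers(len(_DECORATIONS))])
    sub = (
        pharmacophore
        if pharmacophore is not None
        else _DECORATIONS[rng.integers(len(_DECORATIONS))]
    )
    if pharmacophore is None and rng.random() < 0.4:
        tpl = _SCAFFOLDS_2[rng.integers(len(_SCAFFOLDS_2))]
        return tpl.format(sub, _DECORATIONS[rng.integers(len(_DECORATIONS))])
    return _SCAFFOLDS_1[rng.integers(len(_SCAFFOLDS_1))].format(sub)


def generate_library(cfg: LibrarySimConfig) -> LibrarySimResult:
    """Generate a SMILES library with a planted structure–activity signal.

    Compounds are assembled from scaffold templates and substituent
    fragments; unassemblable combinations (RDKit-invalid SMILES) are
    resampled and counted. Activity labels are Bernoulli(p1) for compounds
    carrying a pharmacophore fragment and Bernoulli(p0) otherwise.
    """
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_compounds))
    records, labels, planted_flags = [], [], []
    n_resampled = 0
    for i in range(cfg.n_compounds):
        planted = rng.random() < cfg.prevalence
        frag = (
            cfg.pharmacophores[rng.integers(len(cfg.pharmacophores))] if planted else None
        )
        while True:
            smiles = _assemble(rng, frag)
            if Chem.MolFromSmiles(smiles) is not None:
                break
            n_resampled += 1
        records.append(
            CompoundRecord(
                compound_id=f"SYN-{i + 1:0{width}d}", smiles=smiles, library=cfg.library
            )
        )
        labels.append(bool(rng.random() < (cfg.p1 if planted else cfg.p0)))
        planted_flags.append(planted)
    return LibrarySimResult(
        records=records,
        labels=labels,
        has_pharmacophore=planted_flags,
        n_resampled=n_resampled,
    )


# ---------------------------------------------------------------------------
# acute readouts with planted mechanisms


def assign_mechanisms(
    ids: Sequence[str],
    n_motility: int,
    n_photosynthesis: int,
    n_dual: int,
    n_sign_reversed: int = 0,
    seed: int = 0,
) -> dict[str, frozenset[str]]:
    """Plant acute mechanisms onto the first compounds of ``ids``:
    ``n_dual`` get both phenotypes, then motility-only (of which
    ``n_sign_reversed`` reverse phototactic sign instead of losing motility),
    then photosynthesis-only; everything else is mechanism-free ("general").
    Counts are totals per assay, dual included."""
    if n_dual > min(n_motility, n_photosynthesis):
        raise ValueError("dual count exceeds a per-assay total")
    need = n_motility + n_photosynthesis - n_dual
    if need > len(ids):
        raise ValueError(f"need {need} compounds, have {len(ids)}")
    rng = np.random.default_rng(seed)
    order = list(ids)
    mech: dict[str, frozenset[str]] = {}
    motility_only = n_motility - n_dual
    sign_left = min(n_sign_reversed, n_motility)
    k = 0
    for _ in range(n_dual):
        move = MECH_SIGN_REVERSAL if sign_left > 0 else MECH_MOTILITY
        sign_left -= move == MECH_SIGN_REVERSAL
        mech[order[k]] = frozenset({MECH_PHOTOSYNTHESIS, move})
        k += 1
    for _ in range(motility_only):
        move = MECH_SIGN_REVERSAL if sign_left > 0 else MECH_MOTILITY
        sign_left -= move == MECH_SIGN_REVERSAL
        mech[order[k]] = frozenset({move})
        k += 1
    for _ in range(n_photosynthesis - n_dual):
        mech[order[k]] = frozenset({MECH_PHOTOSYNTHESIS})
        k += 1
    for cid in order[k:]:
        mech[cid] = frozenset({MECH_GENERAL})
    return mech


def simulate_acute(
    mechanisms: Mapping[str, frozenset[str] | set[str] | str],
    seed: int = 0,
    control_fluorescence: float = 100.0,
    planted_fluor_ratio: float = 1.8,
    fluor_noise_sd: float = 3.0,
    growth_inhibited: Mapping[str, bool] | None = None,
    cytocidal_fraction: float = 0.5,
) -> tuple[dict[str, list[AcuteReadout]], float]:
    """Simulate acute-assay readouts from a mechanism assignment.

    Photosynthesis-mechanism compounds emit ``planted_fluor_ratio`` times the
    control fluorescence; motility compounds score ``no_movement`` on both
    image sides; sign-reversal compounds score ``toward_light`` (untreated
    cells swim away from light); general compounds look like controls.
    Regrowth after pinning is Bernoulli(1 - cytocidal_fraction) for
    growth-inhibited compounds and certain otherwise.

    Returns readouts grouped by compound plus the control fluorescence mean.
    """
    rng = np.random.default_rng(seed)
    addresses = plate_addresses(96)
    out: dict[str, list[AcuteReadout]] = {}
    for i, cid in enumerate(sorted(mechanisms)):
        mech = mechanisms[cid]
        if isinstance(mech, str):
            mech = {mech}
        fluor = control_fluorescence * (
            planted_fluor_ratio if MECH_PHOTOSYNTHESIS in mech else 1.0
        )
        fluor = max(0.0, fluor + rng.normal(0.0, fluor_noise_sd))
        if MECH_MOTILITY in mech:
            score = "no_movement"
        elif MECH_SIGN_REVERSAL in mech:
            score = "toward_light"
        else:
            score = "away_from_light"
        inhibited = bool(growth_inhibited.get(cid, False)) if growth_inhibited else False
        regrew = bool(rng.random() >= cytocidal_fraction) if inhibited else True
        out[cid] = [
            AcuteReadout(
                plate_id=f"acute-{i // len(addresses) + 1}",
                well=addresses[i % len(addresses)],
                fluorescence=fluor,
                phototaxis_score=score,
                phototaxis_score_2=score,
                regrew=regrew,
            )
        ]
    return out, control_fluorescence
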