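"""End-to-end campaign orchestration: simulate → fitness → acute → network
→ train → evaluate → rank, with content-hash based stage skipping.

Each stage writes its outputs into the run directory and records a hash of
its configuration and inputs; rerunning with an unchanged configuration
skips stages whose inputs did not change, and a changed upstream stage
re-triggers everything downstream. All randomness derives from the seeds in
the run configuration, so two runs from identical configuration produce
identical result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import acute as acute_mod
from . import bayes, chem, evaluation, fitness, plate_io, simulate

log = logging.getLogger("algscreen")

STAGES = ("simulate", "fitness", "acute", "network", "train", "evaluate", "rank")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Single-file configuration of a full synthetic campaign."""

    out_dir: str = "run"
    seed: int = 0
    # simulate
    library_size: int = 600
    prevalence: float = 0.3
    p0: float = 0.1
    p1: float = 0.8
    plate_geometry: int = 96
    n_controls: int = 8
    noise_sd: float = 0.005
    n_replicates: int = 3
    sampling_interval: float = 0.5
    duration: float = 80.0
    phi_active: tuple[float, float] = (0.05, 0.55)
    phi_inactive: tuple[float, float] = (0.85, 1.0)
    acute_motility_fraction: float = 0.15
    acute_photosynthesis_fraction: float = 0.35
    acute_dual_fraction: float = 0.02
    cytocidal_fraction: float = 0.5
    # scoring
    fitness_threshold: float = fitness.DEFAULT_HIT_THRESHOLD
    baseline: str = "baseline-subtracted"
    fluor_hit_ratio: float = acute_mod.DEFAULT_FLUOR_HIT_RATIO
    # network
    network_cutoff: float = chem.DEFAULT_CUTOFF
    # model evaluation
    k_folds: int = 5
    ef_fraction: float = evaluation.DEFAULT_FRACTION
    # prospective ranking
    rank_library_size: int = 300

    def validate(self) -> None:
        if not 0.0 <= self.fitness_threshold <= 1.0:
            raise ValueError("fitness threshold outside [0, 1]")
        if not 0.0 <= self.network_cutoff <= 1.0:
            raise ValueError("network cutoff outside [0, 1]")
        if not 0.0 < self.ef_fraction <= 1.0:
            raise ValueError("EF fraction outside (0, 1]")
        if self.k_folds < 2:
            raise ValueError("need k >= 2 folds")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _hash_payload(payload: Any) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def _hash_files(paths: Sequence[Path]) -> list[str]:
    return [hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(paths)]


def _write_json(path: Path, payload: Any) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


class _StageLedger:
    """Stores per-stage input hashes so unchanged stages can be skipped."""

    def __init__(self, run_dir: Path):
        self.path = run_dir / "stage_hashes.json"
        self.hashes: dict[str, str] = (
            json.loads(self.path.read_text()) if self.path.exists() else {}
        )

    def unchanged(self, stage: str, digest: str, outputs: Sequence[Path]) -> bool:
        return self.hashes.get(stage) == digest and all(p.exists() for p in outputs)

    def record(self, stage: str, digest: str) -> None:
        self.hashes[stage] = digest
        _write_json(self.path, self.hashes)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full campaign into ``cfg.out_dir``; returns the run dir.

    Stages run in dependency order; a stage whose configuration and inputs
    are unchanged since the previous run is skipped. Any stage failure
    aborts with the stage name attached.
    """
    cfg.validate()
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    ledger = _StageLedger(run_dir)
    c = asdict(cfg)

    report: dict[str, Any] = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    # --- simulate -----------------------------------------------------------
    stage = "simulate"
    sim_keys = (
        "seed library_size prevalence p0 p1 plate_geometry n_controls noise_sd "
        "n_replicates sampling_interval duration phi_active phi_inactive "
        "acute_motility_fraction acute_photosynthesis_fraction acute_dual_fraction "
        "cytocidal_fraction fluor_hit_ratio"
    ).split()
    digest = _hash_payload({k: c[k] for k in sim_keys})
    lib_path = run_dir / "library.csv"
    labels_path = run_dir / "true_labels.csv"
    acute_path = run_dir / "acute_readouts.csv"
    sim_meta_path = run_dir / "simulate_meta.json"
    plates_dir = run_dir / "plates"
    outputs = [lib_path, labels_path, acute_path, sim_meta_path]
    if ledger.unchanged(stage, digest, outputs):
        log.info("[simulate] unchanged, skipped")
    else:
        try:
            _stage_simulate(cfg, run_dir, lib_path, labels_path, acute_path, sim_meta_path, plates_dir)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        ledger.record(stage, digest)
    report["simulate"] = json.loads(sim_meta_path.read_text())

    # --- fitness ------------------------------------------------------------
    stage = "fitness"
    plate_files = sorted(plates_dir.glob("plate_*.csv")) + sorted(
        plates_dir.glob("layout_*.csv")
    )
    digest = _hash_payload(
        {
            "threshold": cfg.fitness_threshold,
            "baseline": cfg.baseline,
            "inputs": _hash_files(plate_files),
        }
    )
    fitness_path = run_dir / "fitness_results.csv"
    fit_summary_path = run_dir / "screen_summary.json"
    if ledger.unchanged(stage, digest, [fitness_path, fit_summary_path]):
        log.info("[fitness] unchanged, skipped")
    else:
        try:
            _stage_fitness(cfg, plates_dir, fitness_path, fit_summary_path)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        ledger.record(stage, digest)
    report["fitness"] = json.loads(fit_summary_path.read_text())

    # --- acute --------------------------------------------------------------
    stage = "acute"
    digest = _hash_payload(
        {
            "fluor_hit_ratio": cfg.fluor_hit_ratio,
            "inputs": _hash_files([acute_path, fitness_path, sim_meta_path]),
        }
    )
    calls_path = run_dir / "acute_calls.csv"
    acute_summary_path = run_dir / "acute_summary.json"
    if ledger.unchanged(stage, digest, [calls_path, acute_summary_path]):
        log.info("[acute] unchanged, skipped")
    else:
        try:
            _stage_acute(cfg, acute_path, fitness_path, sim_meta_path, calls_path, acute_summary_path)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        ledger.record(stage, digest)
    report["acute"] = json.loads(acute_summary_path.read_text())

    # --- network ------------------------------------------------------------
    stage = "network"
    digest = _hash_payload(
        {
            "cutoff": cfg.network_cutoff,
            "inputs": _hash_files([lib_path, fitness_path, calls_path]),
        }
    )
    net_paths = [
        run_dir / "network.graphml",
        run_dir / "network.sif",
        run_dir / "node_attributes.csv",
        run_dir / "cluster_summary.csv",
        run_dir / "network_stats.json",
    ]
    if ledger.unchanged(stage, digest, net_paths):
        log.info("[network] unchanged, skipped")
    else:
        try:
            _stage_network(cfg, lib_path, fitness_path, calls_path, run_dir)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        ledger.record(stage, digest)
    report["network"] = json.loads((run_dir / "network_stats.json").read_text())

    # --- train --------------------------------------------------------------
    stage = "train"
    digest = _hash_payload({"inputs": _hash_files([lib_path, fitness_path])})
    model_path = run_dir / "model.json"
    if ledger.unchanged(stage, digest, [model_path]):
        log.info("[train] unchanged, skipped")
    else:
        try:
            _stage_train(lib_path, fitness_path, model_path)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        ledger.record(stage, digest)
    report["train"] = {"model": model_path.name}

    # --- evaluate -----------------------------------------------------------
    stage = "evaluate"
    digest = _hash_payload(
        {
            "k": cfg.k_folds,
            "fraction": cfg.ef_fraction,
            "seed": cfg.seed,
            "inputs": _hash_files([lib_path, fitness_path]),
        }
    )
    cv_path = run_dir / "cv_results.json"
    curves_path = run_dir / "enrichment_curves.csv"
    if ledger.unchanged(stage, digest, [cv_path, curves_path]):
        log.info("[evaluate] unchanged, skipped")
    else:
        try:
            _stage_evaluate(cfg, lib_path, fitness_path, cv_path, curves_path)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        ledger.record(stage, digest)
    report["evaluate"] = json.loads(cv_path.read_text())

    # --- rank ---------------------------------------------------------------
    stage = "rank"
    digest = _hash_payload(
        {
            "rank_library_size": cfg.rank_library_size,
            "seed": cfg.seed,
            "inputs": _hash_files([model_path]),
        }
    )
    ranked_path = run_dir / "ranked_prospective.csv"
    if ledger.unchanged(stage, digest, [ranked_path]):
        log.info("[rank] unchanged, skipped")
    else:
        try:
            _stage_rank(cfg, model_path, ranked_path)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        ledger.record(stage, digest)
    report["rank"] = {"ranked": ranked_path.name, "n": cfg.rank_library_size}

    _write_json(run_dir / "report.json", report)
    _write_json(run_dir / "run_metadata.json", {"config": asdict(cfg), "config_hash": cfg.config_hash()})
    return run_dir


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg, run_dir, lib_path, labels_path, acute_path, sim_meta_path, plates_dir):
    log.info("[simulate] library of %d compounds", cfg.library_size)
    lib = simulate.generate_library(
        simulate.LibrarySimConfig(
            n_compounds=cfg.library_size,
            prevalence=cfg.prevalence,
            p0=cfg.p0,
            p1=cfg.p1,
            seed=cfg.seed,
        )
    )
    plate_io.write_compound_library(lib.records, lib_path)
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in lib.records],
            "active": [int(l) for l in lib.labels],
            "has_pharmacophore": [int(f) for f in lib.has_pharmacophore],
        }
    ).to_csv(labels_path, index=False)

    rng = np.random.default_rng([cfg.seed, 1])
    lo_a, hi_a = cfg.phi_active
    lo_i, hi_i = cfg.phi_inactive
    inhibition = {
        r.compound_id: float(
            rng.uniform(lo_a, hi_a) if active else rng.uniform(lo_i, hi_i)
        )
        for r, active in zip(lib.records, lib.labels)
    }
    plates = simulate.simulate_screen(
        simulate.PlateSimConfig(
            geometry=cfg.plate_geometry,
            n_controls=cfg.n_controls,
            noise_sd=cfg.noise_sd,
            interval=cfg.sampling_interval,
            duration=cfg.duration,
            inhibition=inhibition,
            n_replicates=cfg.n_replicates,
            seed=cfg.seed,
        )
    )
    plates_dir.mkdir(exist_ok=True)
    for layout, series in plates:
        plate_io.write_layout(layout, plates_dir / f"layout_{layout.plate_id}.csv")
        plate_io.write_growth_table(series, plates_dir / f"plate_{layout.plate_id}.csv")

    actives = [r.compound_id for r, a in zip(lib.records, lib.labels) if a]
    n_act = len(actives)
    n_mot = int(round(cfg.acute_motility_fraction * n_act))
    n_photo = int(round(cfg.acute_photosynthesis_fraction * n_act))
    n_dual = min(int(round(cfg.acute_dual_fraction * n_act)), min(n_mot, n_photo))
    mech = simulate.assign_mechanisms(
        actives + [r.compound_id for r, a in zip(lib.records, lib.labels) if not a],
        n_motility=n_mot,
        n_photosynthesis=n_photo,
        n_dual=n_dual,
        n_sign_reversed=max(1, n_mot // 4) if n_mot else 0,
        seed=cfg.seed,
    )
    readouts, control_fluor = simulate.simulate_acute(
        mech,
        seed=cfg.seed,
        growth_inhibited={r.compound_id: a for r, a in zip(lib.records, lib.labels)},
        cytocidal_fraction=cfg.cytocidal_fraction,
    )
    rows = [
        {
            "compound_id": cid,
            "plate_id": r.plate_id,
            "well": r.well,
            "fluorescence": r.fluorescence,
            "phototaxis_score_1": r.phototaxis_score or "",
            "phototaxis_score_2": r.phototaxis_score_2 or "",
            "regrew": "" if r.regrew is None else int(r.regrew),
        }
        for cid, rs in sorted(readouts.items())
        for r in rs
    ]
    pd.DataFrame(rows).to_csv(acute_path, index=False)
    _write_json(
        sim_meta_path,
        {
            "n_compounds": cfg.library_size,
            "n_plates": len(plates),
            "n_resampled_smiles": lib.n_resampled,
            "control_fluorescence_mean": control_fluor,
            "planted": {"n_motility": n_mot, "n_photosynthesis": n_photo, "n_dual": n_dual},
        },
    )


def _load_fitness(fitness_path: Path) -> list[fitness.FitnessResult]:
    df = pd.read_csv(fitness_path)
    out = []
    for _, row in df.iterrows():
        out.append(
            fitness.FitnessResult(
                compound_id=row["compound_id"],
                growth_ratio=float(row["mean_ratio"]),
                replicate_sd=None if pd.isna(row["sd"]) else float(row["sd"]),
                n_replicates=int(row["n"]),
                is_hit=bool(row["is_hit"]),
            )
        )
    return out


def _stage_fitness(cfg, plates_dir, fitness_path, fit_summary_path):
    plates = []
    for layout_file in sorted(plates_dir.glob("layout_*.csv")):
        plate_id = layout_file.stem.removeprefix("layout_")
        layout = plate_io.read_layout(layout_file, plate_id=plate_id, geometry=cfg.plate_geometry)
        series = plate_io.read_growth_table(plates_dir / f"plate_{plate_id}.csv", layout)
        plates.append((layout, series))
    if not plates:
        raise FileNotFoundError(f"no plates found under {plates_dir}")
    log.info("[fitness] scoring %d plates", len(plates))
    results = fitness.score_screen(
        plates, threshold=cfg.fitness_threshold, baseline=cfg.baseline
    )
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in results],
            "mean_ratio": [r.growth_ratio for r in results],
            "sd": [r.replicate_sd for r in results],
            "n": [r.n_replicates for r in results],
            "is_hit": [int(r.is_hit) for r in results],
        }
    ).to_csv(fitness_path, index=False)
    s = fitness.summarize_screen(results)
    _write_json(
        fit_summary_path,
        {
            "n_screened": s.n_screened,
            "n_hits": s.n_hits,
            "hit_percentage": s.hit_percentage,
            "threshold": cfg.fitness_threshold,
        },
    )


def _stage_acute(cfg, acute_path, fitness_path, sim_meta_path, calls_path, acute_summary_path):
    df = pd.read_csv(acute_path, dtype={"compound_id": str}, keep_default_na=False)
    by_compound: dict[str, list[plate_io.AcuteReadout]] = {}
    for _, row in df.iterrows():
        by_compound.setdefault(row["compound_id"], []).append(
            plate_io.AcuteReadout(
                plate_id=row["plate_id"],
                well=row["well"],
                fluorescence=float(row["fluorescence"]) if row["fluorescence"] != "" else None,
                phototaxis_score=row["phototaxis_score_1"] or None,
                phototaxis_score_2=row["phototaxis_score_2"] or None,
                regrew=bool(int(row["regrew"])) if str(row["regrew"]) != "" else None,
            )
        )
    control_fluor = json.loads(sim_meta_path.read_text())["control_fluorescence_mean"]
    fit_results = {r.compound_id: r for r in _load_fitness(fitness_path)}
    calls = acute_mod.call_phenotypes(
        by_compound,
        control_fluorescence_mean=control_fluor,
        fitness=fit_results,
        hit_ratio_threshold=cfg.fluor_hit_ratio,
    )
    pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in calls],
            "motility_class": [c.motility_class for c in calls],
            "photosynthesis_hit": [
                "" if c.photosynthesis_hit is None else int(c.photosynthesis_hit)
                for c in calls
            ],
            "fluorescence_ratio": [c.fluorescence_ratio for c in calls],
            "cytotoxicity": [c.cytotoxicity for c in calls],
        }
    ).to_csv(calls_path, index=False)
    summary = acute_mod.summarize_acute(calls, list(fit_results.values()))
    _write_json(
        acute_summary_path,
        {
            "n_screened": summary.n_screened,
            "n_motility": summary.n_motility,
            "n_photosynthesis": summary.n_photosynthesis,
            "n_both": summary.n_both,
            "n_unique_acute": summary.n_unique_acute,
            "n_also_fitness": summary.n_also_fitness,
        },
    )


def _load_calls(calls_path: Path) -> list[acute_mod.PhenotypeCall]:
    df = pd.read_csv(calls_path, dtype=str, keep_default_na=False)
    return [
        acute_mod.PhenotypeCall(
            compound_id=row["compound_id"],
            motility_class=row["motility_class"] or acute_mod.MISSING,
            photosynthesis_hit=(
                None if row["photosynthesis_hit"] == "" else bool(int(row["photosynthesis_hit"]))
            ),
            fluorescence_ratio=(
                None if row["fluorescence_ratio"] == "" else float(row["fluorescence_ratio"])
            ),
            cytotoxicity=row["cytotoxicity"] or acute_mod.MISSING,
        )
        for _, row in df.iterrows()
    ]


def _stage_network(cfg, lib_path, fitness_path, calls_path, run_dir):
    lib = plate_io.read_compound_library(lib_path)
    fit_results = _load_fitness(fitness_path)
    calls = _load_calls(calls_path)
    active_ids = {r.compound_id for r in fit_results if r.is_hit} | {
        c.compound_id for c in calls if c.motility_active or c.photosynthesis_hit
    }
    records = [r for r in lib.records if r.compound_id in active_ids]
    log.info("[network] %d active compounds", len(records))
    fps = chem.fingerprint_library(records)
    net = chem.build_network(fps, cutoff=cfg.network_cutoff)
    chem.annotate_network(net, fit_results, calls)
    chem.write_graphml(net, run_dir / "network.graphml")
    chem.write_sif(net, run_dir / "network.sif")
    chem.write_node_attributes(net, run_dir / "node_attributes.csv")
    summary = chem.cluster_summary(net)
    summary.to_csv(run_dir / "cluster_summary.csv", index=False)
    import networkx as nx

    _write_json(
        run_dir / "network_stats.json",
        {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "n_singletons": sum(1 for _, d in net.nodes(data=True) if d.get("singleton")),
            "n_components": nx.number_connected_components(net),
            "cutoff": cfg.network_cutoff,
        },
    )


def _labelled_fingerprints(lib_path, fitness_path):
    lib = plate_io.read_compound_library(lib_path)
    hits = {r.compound_id: r.is_hit for r in _load_fitness(fitness_path)}
    records = [r for r in lib.records if r.compound_id in hits]
    fps = chem.fingerprint_library(records)
    labels = [hits[r.compound_id] for r in records]
    return fps, labels


def _stage_train(lib_path, fitness_path, model_path):
    fps, labels = _labelled_fingerprints(lib_path, fitness_path)
    model = bayes.train(fps, labels)
    model.to_json(model_path)
    log.info("[train] %d features, base rate %.3f", len(model.feature_weights), model.base_rate)


def _stage_evaluate(cfg, lib_path, fitness_path, cv_path, curves_path):
    fps, labels = _labelled_fingerprints(lib_path, fitness_path)
    cv = evaluation.evaluate_model(
        fps, labels, k=cfg.k_folds, fraction=cfg.ef_fraction, seed=cfg.seed
    )
    _write_json(
        cv_path,
        {
            "fold_efs": cv.fold_efs,
            "mean_ef": cv.mean_ef,
            "se_ef": cv.se_ef,
            "fraction": cv.fraction,
            "k": cv.n_folds,
            "seed": cv.seed,
            "stratified": cv.stratified,
            "top_rule": cv.top_rule,
        },
    )
    rows = []
    for i, curve in enumerate(cv.curves):
        for f, ca in zip(curve.fractions, curve.cumulative_actives):
            rows.append(
                {
                    "fold": i,
                    "fraction": float(f),
                    "cumulative_actives": int(ca),
                    "random_expected": float(f) * curve.n_active,
                }
            )
    pd.DataFrame(rows).to_csv(curves_path, index=False)


def _stage_rank(cfg, model_path, ranked_path):
    model = bayes.BayesModel.from_json(model_path)
    prospective = simulate.generate_library(
        simulate.LibrarySimConfig(
            n_compounds=cfg.rank_library_size,
            seed=cfg.seed + 1,  # an unscreened library, distinct from training
            library="prospective",
        )
    )
    fps = chem.fingerprint_library(prospective.records)
    ranked = bayes.rank_library(model, fps)
    truth = {r.compound_id: l for r, l in zip(prospective.records, prospective.labels)}
    pd.DataFrame(
        {
            "rank": range(1, len(ranked) + 1),
            "compound_id": [cid for cid, _ in ranked],
            "score": [s for _, s in ranked],
            "true_active": [int(truth[cid]) for cid, _ in ranked],
        }
    ).to_csv(ranked_path, index=False)
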