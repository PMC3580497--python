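"""Laplacian-corrected naive Bayes activity model on fingerprint features.

Each circular-substructure feature F seen in training gets a log-weight

    w(F) = log[ (A_F + 1) / ((T_F + 1/P_a) * P_a) ]

where T_F is the number of training compounds containing F, A_F the number
of active ones among them, and P_a the training base rate of actives. This
is the Laplacian-corrected per-feature estimator used by ligand-based
virtual-screening pipelines: it shrinks low-count features toward zero
evidence — a never-seen feature (T_F = 0, A_F = 0) would score exactly
log 1 = 0, which is also the score assigned to features absent from the
model. A compound's activity score is the sum of its features' weights;
scores are relative ranks, not calibrated probabilities.

Features are presence/absence (set semantics); duplicated substructures in
one molecule do not count twice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .chem import Fingerprint


@dataclass
class FeatureStats:
    """Occurrence counts for one feature: compounds containing it (T_F) and
    active compounds containing it (A_F)."""

    feature_id: int
    total_count: int
    active_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.active_count <= self.total_count:
            raise ValueError("need 0 <= A_F <= T_F")
        if self.total_count < 1:
            raise ValueError("stored features must occur at least once")


@dataclass
class BayesModel:
    """Trained model: per-feature log-weights plus the training base rate."""

    base_rate: float
    feature_weights: dict[int, float]
    n_train: int
    feature_stats: dict[int, FeatureStats] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.base_rate < 1.0:
            raise ValueError(f"degenerate base rate {self.base_rate}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "base_rate": self.base_rate,
            "n_train": self.n_train,
            "feature_weights": {str(k): v for k, v in self.feature_weights.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "BayesModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            base_rate=payload["base_rate"],
            feature_weights={int(k): v for k, v in payload["feature_weights"].items()},
            n_train=payload["n_train"],
        )


def feature_weight(active_count: int, total_count: int, base_rate: float) -> float:
    """Laplacian-corrected log-weight for one feature."""
    return math.log((active_count + 1) / ((total_count + 1.0 / base_rate) * base_rate))


def train(fps: Sequence[Fingerprint], labels: Sequence[bool]) -> BayesModel:
    """Fit the model from fingerprints and boolean activity labels.

    Requires at least one active and one inactive compound (otherwise the
    base rate is degenerate). Training is permutation-invariant in compound
    order.
    """
    if len(fps) != len(labels):
        raise ValueError("fps and labels must align")
    n = len(fps)
    n_active = sum(bool(l) for l in labels)
    if n_active == 0 or n_active == n:
        raise ValueError(
            f"degenerate training set: {n_active}/{n} actives (need both classes)"
        )
    base_rate = n_active / n
    totals: dict[int, int] = {}
    actives: dict[int, int] = {}
    for fp, label in zip(fps, labels):
        for f in fp.features:
            totals[f] = totals.get(f, 0) + 1
            if label:
                actives[f] = actives.get(f, 0) + 1
    weights = {
        f: feature_weight(actives.get(f, 0), t, base_rate) for f, t in totals.items()
    }
    stats = {
        f: FeatureStats(feature_id=f, total_count=t, active_count=actives.get(f, 0))
        for f, t in totals.items()
    }
    return BayesModel(
        base_rate=base_rate, feature_weights=weights, n_train=n, feature_stats=stats
    )


def score_compound(model: BayesModel, fp: Fingerprint) -> float:
    """Sum of feature log-weights; features unseen in training contribute 0."""
    if not fp.features:
        raise ValueError(f"{fp.compound_id}: cannot score an empty fingerprint")
    w = model.feature_weights
    return sum(w.get(f, 0.0) for f in fp.features)


def rank_library(
    model: BayesModel, fps: Sequence[Fingerprint]
) -> list[tuple[str, float]]:
    """Rank compounds by descending score; ties broken by compound_id so the
    ordering is deterministic."""
    scored = [(fp.compound_id, score_compound(model, fp)) for fp in fps]
    return sorted(scored, key=lambda t: (-t[1], t[0]))
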