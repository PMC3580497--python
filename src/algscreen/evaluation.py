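"""Enrichment-factor evaluation of ranking models under repeated holdout.

The evaluation scheme trains on four-fifths of a labelled library, ranks the
held-out fifth, and reads the enrichment factor at a fixed fraction of the
ranked list (default: top 10%), repeating so every fifth serves once as the
holdout; the summary is the mean EF over the five folds with its standard
error. EF at fraction f is

    EF = (actives in top m / m) / (n_active / n),   m = ceil(f * n)

i.e. the hit rate among the top-ranked m compounds relative to the hit rate
of the whole set; random ordering gives EF ≈ 1 and a perfect ranking attains
the combinatorial maximum min(m, n_active) / (m * n_active / n).

Folds are stratified by label so each fold's active fraction matches the
global fraction within rounding, which stabilises per-fold EF estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import bayes
from .chem import Fingerprint

DEFAULT_FRACTION = 0.10
DEFAULT_K = 5
DEFAULT_BASELINE_SEED = 20121118  # recorded in output metadata


class EvaluationWarning(UserWarning):
    pass


@dataclass
class EnrichmentCurve:
    """Cumulative actives found versus fraction of the ranked list screened."""

    fractions: np.ndarray
    cumulative_actives: np.ndarray
    n_total: int
    n_active: int

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.cumulative_actives = np.asarray(self.cumulative_actives, dtype=int)
        assert np.all(np.diff(self.cumulative_actives) >= 0)
        assert self.cumulative_actives[-1] == self.n_active


@dataclass
class CrossValResult:
    """Per-fold enrichment factors at a stated fraction plus mean and
    standard error (sd over folds / sqrt(k))."""

    fold_efs: list[float]
    mean_ef: float
    se_ef: float | None
    fraction: float
    n_folds: int
    seed: int
    stratified: bool = True
    top_rule: str = "ceil"
    curves: list[EnrichmentCurve] = field(default_factory=list)


def kfold_split(
    ids: Sequence[str],
    labels: Sequence[bool],
    k: int = DEFAULT_K,
    seed: int = 0,
) -> list[list[str]]:
    """Disjoint stratified folds of the id list; sizes differ by at most one
    and each fold's active fraction matches the global one within rounding.
    Deterministic for a fixed seed."""
    n = len(ids)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if len(labels) != n:
        raise ValueError("ids and labels must align")
    y = np.asarray([bool(l) for l in labels])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [[ids[i] for i in test_idx] for _, test_idx in skf.split(np.zeros(n), y)]


def top_m(n: int, fraction: float) -> int:
    """Size of the top slice: ceil(fraction * n)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return math.ceil(fraction * n)


def enrichment_factor(ranked_labels: Sequence[bool], fraction: float) -> float:
    """EF at ``fraction``: hit rate among the top ceil(fraction*n) ranked
    compounds divided by the overall hit rate. Requires >= 1 active."""
    y = np.asarray([bool(l) for l in ranked_labels])
    n = y.size
    n_active = int(y.sum())
    if n_active == 0:
        raise ValueError("enrichment factor undefined with no actives")
    m = top_m(n, fraction)
    return float((y[:m].sum() / m) / (n_active / n))


def max_enrichment_factor(n: int, n_active: int, fraction: float) -> float:
    """Combinatorial EF upper bound, attained by a perfect ranking."""
    m = top_m(n, fraction)
    return min(m, n_active) / (m * n_active / n)


def enrichment_curve(ranked_labels: Sequence[bool]) -> EnrichmentCurve:
    """Cumulative actives found after screening each prefix of the ranking."""
    y = np.asarray([bool(l) for l in ranked_labels], dtype=int)
    n = y.size
    if n == 0:
        raise ValueError("empty ranking")
    return EnrichmentCurve(
        fractions=np.arange(1, n + 1) / n,
        cumulative_actives=np.cumsum(y),
        n_total=n,
        n_active=int(y.sum()),
    )


def expected_hits(
    n_library: int, fraction: float, hit_rate: float, ef: float
) -> tuple[int, int]:
    """Worked screening economics: hits expected from screening the top
    ``fraction`` of a library of ``n_library`` compounds at base ``hit_rate``,
    under random ordering versus a ranking with enrichment ``ef``.

    For example a 10,000-compound library screened at its top 10% with a 44%
    hit rate yields 440 hits at random and 704 from a 1.6x-enriched ranking.
    Both values are rounded to the nearest compound; a prioritized count that
    would exceed the number of compounds screened is capped with a warning.
    """
    if n_library <= 0 or hit_rate <= 0 or ef < 0:
        raise ValueError("n_library, hit_rate must be positive and ef >= 0")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_screened = n_library * fraction
    random_hits = n_screened * hit_rate
    prioritized = random_hits * ef
    if prioritized > n_screened:
        warnings.warn(
            f"enrichment {ef}x would imply {prioritized:.0f} hits among "
            f"{n_screened:.0f} screened; capping",
            EvaluationWarning,
            stacklevel=2,
        )
        prioritized = n_screened
    return round(random_hits), round(prioritized)


def evaluate_model(
    fps: Sequence[Fingerprint],
    labels: Sequence[bool],
    k: int = DEFAULT_K,
    fraction: float = DEFAULT_FRACTION,
    seed: int = DEFAULT_BASELINE_SEED,
) -> CrossValResult:
    """k-fold holdout evaluation of the naive Bayes ranking model.

    Each fold: train on the other k-1 folds, rank the held-out fold
    (deterministic tie-breaking by compound id), and compute EF at
    ``fraction``. Folds with no actives have undefined EF and are excluded
    with a warning. Returns per-fold EFs, their mean and standard error, and
    the per-fold enrichment curves.
    """
    if len(fps) != len(labels):
        raise ValueError("fps and labels must align")
    by_id = {fp.compound_id: (fp, bool(l)) for fp, l in zip(fps, labels)}
    ids = [fp.compound_id for fp in fps]
    folds = kfold_split(ids, labels, k=k, seed=seed)
    efs: list[float] = []
    curves: list[EnrichmentCurve] = []
    for fold in folds:
        fold_set = set(fold)
        train_fps = [by_id[i][0] for i in ids if i not in fold_set]
        train_y = [by_id[i][1] for i in ids if i not in fold_set]
        test_fps = [by_id[i][0] for i in fold]
        model = bayes.train(train_fps, train_y)
        ranked = bayes.rank_library(model, test_fps)
        ranked_labels = [by_id[cid][1] for cid, _ in ranked]
        if not any(ranked_labels):
            warnings.warn(
                "fold with zero actives: EF undefined, excluded",
                EvaluationWarning,
                stacklevel=2,
            )
            continue
        efs.append(enrichment_factor(ranked_labels, fraction))
        curves.append(enrichment_curve(ranked_labels))
    if not efs:
        raise ValueError("no fold produced a defined enrichment factor")
    mean_ef = float(np.mean(efs))
    se = float(np.std(efs, ddof=1) / math.sqrt(len(efs))) if len(efs) >= 2 else None
    return CrossValResult(
        fold_efs=efs,
        mean_ef=mean_ef,
        se_ef=se,
        fraction=fraction,
        n_folds=len(efs),
        seed=seed,
        curves=curves,
    )
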