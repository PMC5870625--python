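"""ROC/PR benchmarking of activity scores against a gold standard.

The gold standard lists (kinase, condition) pairs where regulation is
expected from the experimental design, with its direction. Negative pairs
are drawn uniformly from the Cartesian product of gold-standard kinases and
conditions (excluding positives), matched in number to the positives, and
the draw is repeated (default 60 times) to cover the space of possible
negative sets. The classifier score is the absolute activity score: the
expected direction is used only for an optional direction-accuracy report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import ActivityScoreTable
from .network import KinaseSubstrateNetwork, KSInteraction

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandardPair",
    "BenchmarkResult",
    "read_gold_standard",
    "load_table1_gold_standard",
    "generate_negatives",
    "evaluate",
    "run_benchmark",
    "median_auc",
    "median_precision",
    "stratify_by_substrate_count",
    "downsample_substrates",
    "direction_accuracy",
]


@dataclass(frozen=True)
class GoldStandardPair:
    """An expected kinase regulation in a condition."""

    kinase_id: str
    condition_id: str
    direction: str  # "up" or "down"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


@dataclass
class BenchmarkResult:
    """ROC/PR evaluation of one positive/negative pair set."""

    randomization_id: int
    method: str
    stratum: str
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    auc: float
    precision_at_recall_05: float
    n_positives: int
    n_negatives: int
    n_dropped_positives: int = 0
    n_dropped_negatives: int = 0
    recall_05_achieved: bool = True

    def to_dict(self) -> dict:
        return {
            "randomization_id": self.randomization_id,
            "method": self.method,
            "stratum": self.stratum,
            "auc": self.auc,
            "precision_at_recall_05": self.precision_at_recall_05,
            "n_positives": self.n_positives,
            "n_negatives": self.n_negatives,
            "roc_points": self.roc_points,
            "pr_points": self.pr_points,
        }


def read_gold_standard(path: str | Path) -> list[GoldStandardPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("kinase", "condition", "direction")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns {missing} in {path}")
    pairs = [
        GoldStandardPair(
            kinase_id=row.kinase.strip(),
            condition_id=row.condition.strip(),
            direction=row.direction.strip().lower(),
        )
        for row in df.itertuples(index=False)
    ]
    seen = set()
    unique = []
    for p in pairs:
        key = (p.kinase_id, p.condition_id)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique


def load_table1_gold_standard() -> list[GoldStandardPair]:
    """Curated human kinase regulations expected under published
    perturbations (kinase inhibitors, growth-factor stimulations, cell
    cycle arrests), shipped as a package fixture."""
    ref = resources.files("kinfer.data").joinpath("gold_standard_table1.tsv")
    with resources.as_file(ref) as path:
        return read_gold_standard(path)


def generate_negatives(
    gold: Sequence[GoldStandardPair],
    seed: int | np.random.Generator,
    size: int | None = None,
) -> list[tuple[str, str]]:
    """Sample negative (kinase, condition) pairs.

    Uniform sample without replacement from the Cartesian product of
    gold-standard kinases x gold-standard conditions, excluding the
    positive pairs; sized to match the positives.
    """
    rng = np.random.default_rng(seed)
    kinases = sorted({p.kinase_id for p in gold})
    conditions = sorted({p.condition_id for p in gold})
    positives = {(p.kinase_id, p.condition_id) for p in gold}
    candidates = [
        (k, c) for k in kinases for c in conditions if (k, c) not in positives
    ]
    n = len(gold) if size is None else size
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} non-positive pairs available, {n} needed"
        )
    picks = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(picks)]


def _precision_at_recall(
    precision: np.ndarray, recall: np.ndarray, target: float = 0.5
) -> tuple[float, bool]:
    """Precision at the smallest achieved recall >= target.

    Falls back to the precision at maximum achieved recall (flagged) if the
    target recall is never reached.
    """
    achieved = recall >= target
    if achieved.any():
        idx = np.argmin(np.where(achieved, recall, np.inf))
        return float(precision[idx]), True
    idx = int(np.argmax(recall))
    return float(precision[idx]), False


def evaluate(
    scores: ActivityScoreTable,
    positives: Sequence[GoldStandardPair],
    negatives: Sequence[tuple[str, str]],
    randomization_id: int = 0,
    stratum: str = "all",
) -> BenchmarkResult:
    """ROC/PR evaluation with |activity score| as the classifier score.

    Labelled pairs without a computed score (e.g. no quantified substrate)
    are dropped from both sets, with counts recorded on the result. Ties
    are grouped into a single threshold step, so the trapezoidal AUC equals
    the Mann-Whitney concordance probability.
    """
    from sklearn import metrics

    y_true, y_score = [], []
    dropped_pos = dropped_neg = 0
    method = "?"
    for p in positives:
        s = scores.get(p.kinase_id, p.condition_id)
        if s is None:
            dropped_pos += 1
            continue
        method = s.method
        y_true.append(1)
        y_score.append(abs(s.signed_score))
    for kinase, condition in negatives:
        s = scores.get(kinase, condition)
        if s is None:
            dropped_neg += 1
            continue
        y_true.append(0)
        y_score.append(abs(s.signed_score))
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    if dropped_pos or dropped_neg:
        logger.info(
            "dropped %d positives and %d negatives without scores", dropped_pos, dropped_neg
        )
    if not (y_true == 1).any():
        raise ValueError("no scored positive pairs to evaluate")
    if not (y_true == 0).any():
        raise ValueError("no scored negative pairs to evaluate")

    fpr, tpr, _ = metrics.roc_curve(y_true, y_score, drop_intermediate=False)
    auc = float(metrics.auc(fpr, tpr))
    precision, recall, _ = metrics.precision_recall_curve(y_true, y_score)
    p_at_r, achieved = _precision_at_recall(precision, recall, 0.5)
    return BenchmarkResult(
        randomization_id=randomization_id,
        method=method,
        stratum=stratum,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        pr_points=list(zip(recall.tolist(), precision.tolist())),
        auc=auc,
        precision_at_recall_05=p_at_r,
        n_positives=int((y_true == 1).sum()),
        n_negatives=int((y_true == 0).sum()),
        n_dropped_positives=dropped_pos,
        n_dropped_negatives=dropped_neg,
        recall_05_achieved=achieved,
    )


def run_benchmark(
    scores: ActivityScoreTable,
    gold: Sequence[GoldStandardPair],
    n_randomizations: int = 60,
    seed: int | None = None,
    stratum: str = "all",
) -> list[BenchmarkResult]:
    """Evaluate against ``n_randomizations`` independent negative sets."""
    master = np.random.default_rng(seed)
    results = []
    for i in range(n_randomizations):
        negatives = generate_negatives(gold, seed=master)
        results.append(
            evaluate(scores, gold, negatives, randomization_id=i, stratum=stratum)
        )
    return results


def median_auc(results: Sequence[BenchmarkResult]) -> float:
    return float(np.median([r.auc for r in results]))


def median_precision(results: Sequence[BenchmarkResult]) -> float:
    return float(np.median([r.precision_at_recall_05 for r in results]))


def stratify_by_substrate_count(
    scores: ActivityScoreTable,
    gold: Sequence[GoldStandardPair],
    cut: int = 5,
    n_randomizations: int = 60,
    seed: int | None = None,
) -> dict[str, list[BenchmarkResult]]:
    """Benchmark separately for scores with <= cut and > cut quantified
    substrates.

    Gold pairs are partitioned by the substrate count of their score;
    negatives for a stratum are drawn from that stratum's kinases and
    conditions, and negative pairs whose score falls in the other stratum
    are treated as unscored (dropped with a count).
    """
    strata: dict[str, list[GoldStandardPair]] = {f"<={cut}": [], f">{cut}": []}
    for p in gold:
        s = scores.get(p.kinase_id, p.condition_id)
        if s is None:
            continue
        label = f"<={cut}" if s.n_quantified_substrates <= cut else f">{cut}"
        strata[label].append(p)
    out: dict[str, list[BenchmarkResult]] = {}
    master = np.random.default_rng(seed)
    for label, pairs in strata.items():
        if not pairs:
            logger.warning("stratum %s is empty; skipped", label)
            continue
        low = label.startswith("<=")
        sub_scores = ActivityScoreTable(
            [
                s
                for s in scores
                if (s.n_quantified_substrates <= cut) == low
            ]
        )
        try:
            out[label] = run_benchmark(
                sub_scores,
                pairs,
                n_randomizations=n_randomizations,
                seed=int(master.integers(0, 2**31 - 1)),
                stratum=label,
            )
        except ValueError as exc:
            logger.warning("stratum %s could not be benchmarked: %s", label, exc)
    return out


def downsample_substrates(
    network: KinaseSubstrateNetwork,
    target_size_per_kinase: int,
    n_repeats: int = 25,
    seed: int | None = None,
) -> list[KinaseSubstrateNetwork]:
    """Repeatedly subsample every regulon to a fixed size.

    Used to compare evidence classes on equal footing: each repeat
    subsamples each kinase's substrate sites without replacement down to
    ``target_size_per_kinase``; kinases with fewer sites are dropped.
    """
    master = np.random.default_rng(seed)
    out = []
    for _ in range(n_repeats):
        interactions: list[KSInteraction] = []
        for kinase in network.kinases:
            sites = network.regulon_sites(kinase)
            if len(sites) < target_size_per_kinase:
                continue
            picks = master.choice(len(sites), size=target_size_per_kinase, replace=False)
            chosen = {sites[i][:2] for i in picks}
            by_site = {}
            for ia in network.interactions:
                if ia.kinase_id == kinase and (ia.substrate_protein, ia.position) in chosen:
                    by_site.setdefault((ia.substrate_protein, ia.position), ia)
            interactions.extend(by_site.values())
        out.append(KinaseSubstrateNetwork(interactions))
    return out


def direction_accuracy(
    scores: ActivityScoreTable, gold: Sequence[GoldStandardPair]
) -> float:
    """Fraction of scored gold pairs whose activity sign matches the
    expected regulation direction."""
    hits = total = 0
    for p in gold:
        s = scores.get(p.kinase_id, p.condition_id)
        if s is None or s.signed_score == 0:
            continue
        total += 1
        expected = 1.0 if p.direction == "up" else -1.0
        if np.sign(s.signed_score) == expected:
            hits += 1
    if total == 0:
        raise ValueError("no scored gold pairs with nonzero activity")
    return hits / total


def results_to_json(results: Iterable[BenchmarkResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=1)
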