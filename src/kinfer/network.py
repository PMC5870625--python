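"""Kinase-substrate network: evidence filtering, autoregulatory-site
exclusion, minimum-regulon thresholds and degree-preserving randomization.

A kinase's *regulon* is the set of phosphosites it is known or predicted to
phosphorylate. Interactions carry an evidence class — ``in_vivo`` or
``in_vitro`` (curated experimental evidence) or ``in_silico`` (motif/context
predictions, optionally with a prediction score). Sites on a kinase's own
protein (autoregulatory sites) can be excluded to avoid trivial self-signal
when inferring that kinase's activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EVIDENCE_CLASSES",
    "KSInteraction",
    "KinaseSubstrateNetwork",
    "NetworkFormatError",
    "read_network",
    "exclude_autoregulatory",
    "filter_min_substrates",
    "filter_evidence",
    "randomize_preserving_degree",
]

EVIDENCE_CLASSES = ("in_vivo", "in_vitro", "in_silico")


class NetworkFormatError(ValueError):
    """Raised when a network table cannot be parsed."""


@dataclass(frozen=True)
class KSInteraction:
    """One kinase -> phosphosite interaction with its evidence class."""

    kinase_id: str
    substrate_protein: str
    position: int
    residue: str
    evidence: str = "in_vivo"
    score: float | None = None  # in_silico prediction score

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.evidence not in EVIDENCE_CLASSES:
            raise NetworkFormatError(
                f"unknown evidence class {self.evidence!r}; expected one of {EVIDENCE_CLASSES}"
            )

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.substrate_protein, self.position, self.residue)


class KinaseSubstrateNetwork:
    """Deduplicated set of kinase-substrate interactions with a regulon index.

    Interactions are unique on (kinase, protein, position, evidence); the
    same site supported by several evidence classes is kept once per class.
    Regulons deduplicate on (protein, position) — residue annotations often
    disagree between databases, so downstream matching against quantified
    sites uses (protein, position) only.
    """

    def __init__(self, interactions: Iterable[KSInteraction]):
        seen: dict[tuple[str, str, int, str], KSInteraction] = {}
        for ia in interactions:
            key = (ia.kinase_id, ia.substrate_protein, ia.position, ia.evidence)
            if key not in seen:
                seen[key] = ia
        self.interactions: tuple[KSInteraction, ...] = tuple(seen.values())
        self._index: dict[str, list[KSInteraction]] = {}
        for ia in self.interactions:
            self._index.setdefault(ia.kinase_id, []).append(ia)

    @property
    def kinases(self) -> list[str]:
        return sorted(self._index)

    def regulon(self, kinase_id: str) -> set[tuple[str, int]]:
        """Substrate sites of a kinase as (protein, position) pairs."""
        return {(ia.substrate_protein, ia.position) for ia in self._index.get(kinase_id, ())}

    def regulon_sites(self, kinase_id: str) -> list[tuple[str, int, str]]:
        """Substrate sites with residue, deduplicated on (protein, position)."""
        out: dict[tuple[str, int], tuple[str, int, str]] = {}
        for ia in self._index.get(kinase_id, ()):
            out.setdefault((ia.substrate_protein, ia.position), ia.site_key)
        return sorted(out.values())

    def regulon_sizes(self) -> dict[str, int]:
        return {k: len(self.regulon(k)) for k in self.kinases}

    def __len__(self) -> int:
        return len(self.interactions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KinaseSubstrateNetwork):
            return NotImplemented
        return set(self.interactions) == set(other.interactions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (ia.kinase_id, ia.substrate_protein, ia.position, ia.residue, ia.evidence, ia.score)
                for ia in self.interactions
            ],
            columns=["kinase", "protein", "position", "residue", "evidence", "score"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> KinaseSubstrateNetwork:
    """Read a kinase-substrate TSV (kinase, protein, position, residue,
    evidence[, score]); duplicate rows are merged."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("kinase", "protein", "position", "residue", "evidence")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise NetworkFormatError(f"missing required columns {missing} in {path}")
    interactions = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        score = None
        if "score" in df.columns and str(row["score"]).strip():
            score = float(row["score"])
        try:
            interactions.append(
                KSInteraction(
                    kinase_id=str(row["kinase"]).strip(),
                    substrate_protein=str(row["protein"]).strip(),
                    position=int(row["position"]),
                    residue=str(row["residue"]).strip().upper(),
                    evidence=str(row["evidence"]).strip(),
                    score=score,
                )
            )
        except NetworkFormatError as exc:
            raise NetworkFormatError(f"line {i}: {exc}") from exc
    return KinaseSubstrateNetwork(interactions)


def exclude_autoregulatory(
    n: KinaseSubstrateNetwork, kinase_to_protein: Mapping[str, str]
) -> KinaseSubstrateNetwork:
    """Drop interactions targeting a site on the kinase's own protein.

    Kinases absent from the mapping keep all their interactions (warned).
    """
    missing = {ia.kinase_id for ia in n.interactions if ia.kinase_id not in kinase_to_protein}
    if missing:
        logger.warning(
            "no protein accession for %d kinases; autoregulatory sites retained: %s",
            len(missing),
            sorted(missing),
        )
    kept = [
        ia
        for ia in n.interactions
        if kinase_to_protein.get(ia.kinase_id) != ia.substrate_protein
    ]
    return KinaseSubstrateNetwork(kept)


def filter_min_substrates(n: KinaseSubstrateNetwork, k: int) -> KinaseSubstrateNetwork:
    """Keep only kinases with at least ``k`` substrate sites."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sizes = n.regulon_sizes()
    kept = [ia for ia in n.interactions if sizes[ia.kinase_id] >= k]
    return KinaseSubstrateNetwork(kept)


def filter_evidence(
    n: KinaseSubstrateNetwork,
    classes: Sequence[str],
    min_score: float | None = None,
) -> KinaseSubstrateNetwork:
    """Restrict to interactions in the given evidence classes.

    ``min_score`` additionally thresholds in_silico interactions on their
    prediction score (scoreless in_silico edges are dropped when set).
    """
    for c in classes:
        if c not in EVIDENCE_CLASSES:
            raise NetworkFormatError(f"unknown evidence class {c!r}")
    wanted = set(classes)
    kept = []
    for ia in n.interactions:
        if ia.evidence not in wanted:
            continue
        if min_score is not None and ia.evidence == "in_silico":
            if ia.score is None or ia.score < min_score:
                continue
        kept.append(ia)
    return KinaseSubstrateNetwork(kept)


def randomize_preserving_degree(
    n: KinaseSubstrateNetwork,
    site_universe: Sequence[tuple[str, int, str]],
    seed: int | np.random.Generator,
) -> KinaseSubstrateNetwork:
    """Replace every regulon by a uniform random site sample of equal size.

    Each kinase independently receives a sample without replacement from
    ``site_universe``; regulon sizes (the network's degree sequence) are
    preserved exactly. This is the technical-noise control: inference on a
    degree-randomized network should perform no better than chance.
    """
    rng = np.random.default_rng(seed)
    universe = list(dict.fromkeys(site_universe))
    interactions = []
    for kinase in n.kinases:
        size = len(n.regulon(kinase))
        if size > len(universe):
            raise ValueError(
                f"regulon of {kinase} ({size}) exceeds site universe ({len(universe)})"
            )
        picks = rng.choice(len(universe), size=size, replace=False)
        for idx in picks:
            protein, pos, res = universe[idx]
            interactions.append(
                KSInteraction(
                    kinase_id=kinase,
                    substrate_protein=protein,
                    position=pos,
                    residue=res,
                    evidence="in_vivo",
                )
            )
    return KinaseSubstrateNetwork(interactions)
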