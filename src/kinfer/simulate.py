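"""Synthetic phosphoproteomic studies with embedded ground truth.

The generator emulates the four inputs of the inference pipeline:

* a site x condition log2 fold-change matrix — i.i.d. Gaussian background
  noise plus an additive shift on the substrate sites of regulated kinases;
* a kinase-substrate network with configurable regulon sizes and optional
  regulon overlap between kinase pairs;
* protein sequences whose substrate flanking windows follow a per-kinase
  consensus motif with tunable fidelity;
* a gold standard of the truly regulated (kinase, condition, direction)
  triples, with the underlying true shifts.

Each phosphosite lives on its own synthetic 15-residue protein with the
phosphoacceptor at position 8, so flank extraction, PWM construction and
MSS weighting run end-to-end without any external sequence resource.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .benchmark import GoldStandardPair
from .io import PhosphopeptideRecord, SiteQuantMatrix
from .network import KinaseSubstrateNetwork, KSInteraction
from .specificity import ALPHABET, FLANK, PAD, WINDOW_SIZE, build_pwm, extract_flanks, mss

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate", "simulate_sequences"]

_AMINO_ACIDS = ALPHABET[:-1]  # 20 letters, no padding symbol
_ACCEPTORS = "STY"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic phosphoproteomic experiment.

    Defaults describe a mid-sized perturbation panel with a clearly
    regulated signal: 2000 quantified sites, 20 kinases with curated-scale
    regulons (10-40 sites), 10 conditions with two regulated kinases each,
    a two-noise-SD mean shift (log2 units) on regulated regulons, 10%
    missing values and a strong but imperfect substrate motif.
    """

    n_sites: int = 2000
    n_kinases: int = 20
    regulon_size_range: tuple[int, int] = (10, 40)
    n_conditions: int = 10
    regulated_per_condition: int = 2
    effect_size: float = 2.0  # mean log2FC shift of regulated regulons
    noise_sd: float = 1.0  # background log2FC standard deviation
    missing_rate: float = 0.1
    regulon_overlap: float = 0.0  # shared-site fraction within kinase pairs
    motif_strength: float = 0.9  # P(flank letter drawn from consensus)
    direction_mix: float = 0.5  # fraction of regulated kinases that go down
    scale_signal_by_mss: bool = False  # scale each site's shift by its true MSS
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_kinases, self.n_conditions) < 1:
            raise ValueError("counts must be positive")
        if self.regulated_per_condition < 0:
            raise ValueError("regulated_per_condition must be >= 0")
        lo, hi = self.regulon_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid regulon_size_range")
        if hi > self.n_sites:
            raise ValueError("regulon_size_range max exceeds n_sites")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        for name in ("regulon_overlap", "motif_strength", "direction_mix"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SyntheticDataset:
    """A complete simulated study with its ground truth."""

    config: SimulationConfig
    quant: SiteQuantMatrix
    network: KinaseSubstrateNetwork
    sequences: dict[str, str]
    gold: list[GoldStandardPair]
    truth: dict[tuple[str, str], float]  # (kinase, condition) -> true shift
    consensus: dict[str, str]  # kinase -> 15-mer consensus motif

    def to_records(self) -> list[PhosphopeptideRecord]:
        """Expand the quant matrix into peptide records for the standard
        preprocessing entry point."""
        from .io import matrix_to_records

        return matrix_to_records(self.quant)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.quant.to_tsv(outdir / "quant.tsv")
        self.network.to_tsv(outdir / "network.tsv")
        with open(outdir / "sequences.fa", "w") as fh:
            for acc, seq in self.sequences.items():
                fh.write(f">{acc}\n{seq}\n")
        pd.DataFrame(
            [(p.kinase_id, p.condition_id, p.direction) for p in self.gold],
            columns=["kinase", "condition", "direction"],
        ).to_csv(outdir / "gold.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(k, c, v) for (k, c), v in self.truth.items()],
            columns=["kinase", "condition", "true_shift"],
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def simulate_sequences(
    network: KinaseSubstrateNetwork,
    motif_strength: float,
    seed: int | np.random.Generator,
    site_residues: Mapping[tuple[str, int], str] | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Generate per-site protein sequences following kinase consensus motifs.

    Every kinase draws a random 15-letter consensus (center restricted to
    S/T/Y). Each substrate site's flanking letters are taken from its
    kinase's consensus with probability ``motif_strength``, otherwise
    uniformly from the 20 amino acids; sites targeted by several kinases
    follow the first kinase in sorted order. Non-substrate proteins are
    uniform random. Returns (sequences, consensus-per-kinase).
    """
    rng = np.random.default_rng(seed)
    residues = dict(site_residues) if site_residues else {}
    consensus: dict[str, str] = {}
    for kinase in network.kinases:
        letters = rng.choice(list(_AMINO_ACIDS), size=WINDOW_SIZE)
        letters[FLANK] = rng.choice(list(_ACCEPTORS))
        consensus[kinase] = "".join(letters)

    site_kinase: dict[tuple[str, int], str] = {}
    for kinase in network.kinases:
        for protein, pos in sorted(network.regulon(kinase)):
            site_kinase.setdefault((protein, pos), kinase)

    sequences: dict[str, str] = {}
    universe = sorted(
        {(ia.substrate_protein, ia.position) for ia in network.interactions}
        | set(residues)
    )
    for protein, pos in universe:
        if pos != FLANK + 1:
            raise ValueError("synthetic sites must sit at the window center")
        kinase = site_kinase.get((protein, pos))
        window = []
        for i in range(WINDOW_SIZE):
            if kinase is not None and rng.random() < motif_strength:
                window.append(consensus[kinase][i])
            else:
                window.append(str(rng.choice(list(_AMINO_ACIDS))))
        center = residues.get((protein, pos))
        if center is None:
            center = consensus[kinase][FLANK] if kinase else str(rng.choice(list(_ACCEPTORS)))
        window[FLANK] = center
        sequences[protein] = "".join(window)
    return sequences, consensus


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic study. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)

    # --- site universe: one 15-mer protein per site, acceptor at center
    proteins = [f"P{i:05d}" for i in range(config.n_sites)]

    # --- network with configurable regulon sizes and pairwise overlap
    kinases = [f"KIN{j:03d}" for j in range(config.n_kinases)]
    lo, hi = config.regulon_size_range
    regulons: dict[str, list[int]] = {}
    for j, kinase in enumerate(kinases):
        size = int(rng.integers(lo, hi + 1))
        if config.regulon_overlap > 0 and j % 2 == 1:
            partner = regulons[kinases[j - 1]]
            n_shared = min(int(round(config.regulon_overlap * size)), len(partner))
            shared = list(rng.choice(partner, size=n_shared, replace=False))
            pool = np.setdiff1d(np.arange(config.n_sites), shared)
            fresh = list(rng.choice(pool, size=size - n_shared, replace=False))
            regulons[kinase] = shared + fresh
        else:
            regulons[kinase] = list(rng.choice(config.n_sites, size=size, replace=False))
    substrate_proteins = {proteins[i] for idx in regulons.values() for i in idx}
    # provisional residues; substrate residues are fixed afterwards to the
    # owning kinase's consensus phosphoacceptor
    provisional = [
        KSInteraction(
            kinase_id=kinase,
            substrate_protein=proteins[i],
            position=FLANK + 1,
            residue="S",
            evidence="in_vivo",
        )
        for kinase, idx in regulons.items()
        for i in idx
    ]
    non_substrate_res = {
        (p, FLANK + 1): str(rng.choice(list(_ACCEPTORS)))
        for p in proteins
        if p not in substrate_proteins
    }

    # --- sequences: substrate windows follow their kinase's consensus
    sequences, consensus = simulate_sequences(
        KinaseSubstrateNetwork(provisional),
        config.motif_strength,
        rng,
        site_residues=non_substrate_res,
    )
    sites = [(p, FLANK + 1, sequences[p][FLANK]) for p in proteins]
    site_res_by_protein = {p: r for p, _, r in sites}
    interactions = [
        KSInteraction(
            kinase_id=ia.kinase_id,
            substrate_protein=ia.substrate_protein,
            position=ia.position,
            residue=site_res_by_protein[ia.substrate_protein],
            evidence=ia.evidence,
        )
        for ia in provisional
    ]
    network = KinaseSubstrateNetwork(interactions)
    site_mss: dict[str, dict[tuple[str, int], float]] = {}
    if config.scale_signal_by_mss:
        for kinase in kinases:
            flanks = extract_flanks(network.regulon_sites(kinase), sequences)
            if len(flanks) < 2:
                continue
            pwm = build_pwm(flanks, kinase_id=kinase, min_sequences=2)
            site_mss[kinase] = {
                (fl.protein_id, fl.position): mss(pwm, fl) for fl in flanks
            }

    # --- gold standard: which kinases move in which conditions
    conditions = [f"COND{c:03d}" for c in range(config.n_conditions)]
    gold: list[GoldStandardPair] = []
    truth: dict[tuple[str, str], float] = {}
    values = rng.normal(0.0, config.noise_sd, size=(config.n_sites, config.n_conditions))
    site_index = {p: i for i, (p, _, _) in enumerate(sites)}
    for c, condition in enumerate(conditions):
        if config.effect_size == 0 or config.regulated_per_condition == 0:
            continue
        chosen = rng.choice(
            config.n_kinases,
            size=min(config.regulated_per_condition, config.n_kinases),
            replace=False,
        )
        for j in chosen:
            kinase = kinases[j]
            down = rng.random() < config.direction_mix
            shift = -config.effect_size if down else config.effect_size
            gold.append(
                GoldStandardPair(
                    kinase_id=kinase,
                    condition_id=condition,
                    direction="down" if down else "up",
                )
            )
            truth[(kinase, condition)] = shift
            for protein, pos in network.regulon(kinase):
                scale = 1.0
                if config.scale_signal_by_mss:
                    scale = site_mss.get(kinase, {}).get((protein, pos), 1.0)
                values[site_index[protein], c] += shift * scale

    # --- missingness, completely at random
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    index = pd.MultiIndex.from_tuples(sites, names=["protein", "position", "residue"])
    quant = SiteQuantMatrix(
        data=pd.DataFrame(values, index=index, columns=conditions), normalized=False
    )
    return SyntheticDataset(
        config=config,
        quant=quant,
        network=network,
        sequences=sequences,
        gold=gold,
        truth=truth,
        consensus=consensus,
    )
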