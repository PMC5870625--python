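"""Kinase sequence specificity: position weight matrices and MATCH-style
matrix similarity scores.

A kinase's substrate preference is modelled by a position weight matrix
(PWM) over the 15-residue window centred on the phosphoacceptor (+-7
flanking residues, '_' padding at protein termini). The matrix similarity
score (MSS) of a candidate window against a PWM is an information-weighted,
min-max normalized match score in [0, 1]; multiplying substrate fold
changes by their MSS down-weights substrates that do not fit the kinase's
binding motif before running the Z-test or KSEA (their "weighted"
variants). Only kinases with enough known substrates (default 10) get a
PWM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import ConditionVector
from .network import KinaseSubstrateNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ALPHABET",
    "WINDOW_SIZE",
    "PAD",
    "FlankSequence",
    "PWMModel",
    "MSSValue",
    "InsufficientSubstratesError",
    "read_fasta",
    "extract_flanks",
    "build_pwm",
    "mss",
    "build_pwm_library",
    "compute_mss_table",
    "weight_fold_changes",
]

PAD = "_"
#: 20 amino acids plus the terminus-padding symbol.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + PAD
_ALPHA_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}
WINDOW_SIZE = 15  # +-7 residues around the phosphoacceptor
FLANK = WINDOW_SIZE // 2


class InsufficientSubstratesError(ValueError):
    """Raised when too few flanking sequences are available for a PWM."""


@dataclass(frozen=True)
class FlankSequence:
    """A 15-mer window centred on a phosphosite."""

    protein_id: str
    position: int
    residue: str
    window: str

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_SIZE:
            raise ValueError(f"window must have length {WINDOW_SIZE}, got {len(self.window)}")

    @property
    def center(self) -> str:
        return self.window[FLANK]


@dataclass
class PWMModel:
    """Per-kinase positional amino-acid frequency model.

    ``f`` is a 15 x 21 matrix (rows sum to 1) over :data:`ALPHABET`;
    ``information`` is the per-position information content
    I(i) = sum_b f(i,b) ln(K f(i,b)) with K = 21, which reaches ln(21) for
    a single-letter column (at pseudocount 0) and 0 for a uniform one.
    """

    kinase_id: str
    f: np.ndarray
    information: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.information = np.asarray(self.information, dtype=float)
        if self.f.shape != (WINDOW_SIZE, len(ALPHABET)):
            raise ValueError(f"f must be {WINDOW_SIZE}x{len(ALPHABET)}, got {self.f.shape}")
        if not np.allclose(self.f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if np.any(self.information < -1e-12):
            raise ValueError("information content must be non-negative")

    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in np.argmax(self.f, axis=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.f, columns=list(ALPHABET))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MSSValue:
    protein_id: str
    position: int
    kinase_id: str
    mss: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mss <= 1.0):
            raise ValueError(f"mss must lie in [0, 1], got {self.mss}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {accession: sequence}, accession = first header token."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_flanks(
    sites: Iterable[tuple[str, int, str]],
    sequences: Mapping[str, str],
) -> list[FlankSequence]:
    """Extract +-7-residue windows around phosphosites.

    Sites on proteins absent from ``sequences`` or beyond the sequence end
    are skipped with a warning; windows running over a terminus are padded
    with '_'. When the recorded phosphoacceptor differs from the sequence
    residue at that position, the sequence residue wins (warned).
    """
    flanks = []
    for protein, position, residue in sites:
        seq = sequences.get(protein)
        if seq is None:
            logger.warning("protein %s not in FASTA; site %s_%d skipped", protein, protein, position)
            continue
        if position > len(seq):
            logger.warning(
                "position %d beyond end of %s (length %d); site skipped",
                position, protein, len(seq),
            )
            continue
        actual = seq[position - 1]
        if residue and actual != residue.upper():
            logger.warning(
                "residue mismatch at %s_%d: recorded %s, sequence has %s; using sequence",
                protein, position, residue, actual,
            )
        start = position - 1 - FLANK
        stop = position + FLANK
        left_pad = max(0, -start)
        right_pad = max(0, stop - len(seq))
        window = PAD * left_pad + seq[max(start, 0) : min(stop, len(seq))] + PAD * right_pad
        flanks.append(
            FlankSequence(protein_id=protein, position=position, residue=actual, window=window)
        )
    return flanks


def _window_indices(window: str) -> np.ndarray:
    try:
        return np.array([_ALPHA_INDEX[ch] for ch in window.upper()], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"window contains a letter outside the alphabet: {exc}") from exc


def build_pwm(
    flanks: Sequence[FlankSequence],
    kinase_id: str = "",
    pseudocount: float = 0.01,
    min_sequences: int = 10,
) -> PWMModel:
    """Build a PWM from substrate flanking windows.

    f(i, b) = (count(i, b) + pseudocount) / (n + 21 * pseudocount); the
    pseudocount keeps every frequency positive so the information content
    and MSS stay defined for small regulons.
    """
    if len(flanks) < min_sequences:
        raise InsufficientSubstratesError(
            f"kinase {kinase_id or '?'}: {len(flanks)} flanking sequences "
            f"available, {min_sequences} required"
        )
    counts = np.zeros((WINDOW_SIZE, len(ALPHABET)))
    for fl in flanks:
        counts[np.arange(WINDOW_SIZE), _window_indices(fl.window)] += 1.0
    n = len(flanks)
    f = (counts + pseudocount) / (n + len(ALPHABET) * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(len(ALPHABET) * f), 0.0)
    information = terms.sum(axis=1)
    # clip the tiny negative values a near-uniform column can produce
    information = np.maximum(information, 0.0)
    return PWMModel(kinase_id=kinase_id, f=f, information=information, n_sequences=n)


def mss(pwm: PWMModel, window: str | FlankSequence) -> float:
    """MATCH-style matrix similarity score of a window against a PWM.

    Current = sum_i I(i) f(i, b_i); Min/Max substitute the least/most
    frequent letter at every position; mss = (Current - Min) / (Max - Min).
    A zero-information matrix (Max = Min) scores 1 by convention.
    """
    if isinstance(window, FlankSequence):
        window = window.window
    idx = _window_indices(window)
    info = pwm.information
    current = float(np.sum(info * pwm.f[np.arange(WINDOW_SIZE), idx]))
    lo = float(np.sum(info * pwm.f.min(axis=1)))
    hi = float(np.sum(info * pwm.f.max(axis=1)))
    if hi == lo:
        logger.warning("zero-information PWM for %s: mss defined as 1", pwm.kinase_id)
        return 1.0
    value = (current - lo) / (hi - lo)
    return float(min(max(value, 0.0), 1.0))


def build_pwm_library(
    network: KinaseSubstrateNetwork,
    sequences: Mapping[str, str],
    pseudocount: float = 0.01,
    min_substrates: int = 10,
) -> dict[str, PWMModel]:
    """One PWM per kinase with at least ``min_substrates`` resolvable flanks.

    PWMs are built from all known substrate flanks of a kinase, not just
    the sites quantified in a particular condition.
    """
    library = {}
    for kinase in network.kinases:
        flanks = extract_flanks(network.regulon_sites(kinase), sequences)
        try:
            library[kinase] = build_pwm(
                flanks, kinase_id=kinase, pseudocount=pseudocount, min_sequences=min_substrates
            )
        except InsufficientSubstratesError:
            logger.info("kinase %s below %d substrates; no PWM built", kinase, min_substrates)
    return library


def compute_mss_table(
    network: KinaseSubstrateNetwork,
    sequences: Mapping[str, str],
    pwms: Mapping[str, PWMModel] | None = None,
    pseudocount: float = 0.01,
    min_substrates: int = 10,
) -> dict[str, dict[tuple[str, int], float]]:
    """kinase -> {(protein, position): mss} for every kinase with a PWM."""
    if pwms is None:
        pwms = build_pwm_library(
            network, sequences, pseudocount=pseudocount, min_substrates=min_substrates
        )
    table: dict[str, dict[tuple[str, int], float]] = {}
    for kinase, pwm in pwms.items():
        flanks = extract_flanks(network.regulon_sites(kinase), sequences)
        table[kinase] = {
            (fl.protein_id, fl.position): mss(pwm, fl) for fl in flanks
        }
    return table


def weight_fold_changes(
    cv: ConditionVector,
    regulon: Iterable,
    mss_map: Mapping[tuple[str, int], float],
    on_missing: str = "error",
) -> ConditionVector:
    """Multiply regulon-site fold changes by their MSS.

    Non-substrate fold changes are unaltered. A quantified regulon site
    without an MSS raises by default; ``on_missing="drop"`` leaves its fold
    change unweighted at weight 1 after removing it from consideration is
    not meaningful here, so the site keeps its raw value with a warning.
    """
    mask = cv.substrate_mask(regulon)
    fc = cv.fc.copy()
    for i in np.nonzero(mask)[0]:
        protein, position, _ = cv.site_keys[i]
        key = (protein, position)
        if key not in mss_map:
            if on_missing == "error":
                raise KeyError(f"no MSS for quantified regulon site {key}")
            logger.warning("no MSS for %s; fold change left unweighted", key)
            continue
        fc[i] *= mss_map[key]
    return ConditionVector(site_keys=list(cv.site_keys), fc=fc, condition_id=cv.condition_id)
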