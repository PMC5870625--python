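"""Reading, filtering and normalizing quantitative phosphoproteomic tables.

The site-level fold-change matrix produced here is the substrate
quantification backbone consumed by every inference method: rows are
phosphosites identified by (protein accession, 1-based position,
phosphoacceptor residue), columns are experimental conditions, entries are
log2 fold changes relative to a control.

Preprocessing applies, in order:

(i)   restrict to peptides mapped to canonical transcripts;
(ii)  keep only monophosphorylated peptides, so a fold change is
      attributable to a single site;
(iii) average fold changes across replicates of the same peptide/condition;
(iv)  average fold changes across distinct peptides covering the same
      site/condition;
(v)   drop conditions quantifying fewer than ``min_coverage`` sites.

Quantifications are then quantile-normalized across conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhosphopeptideRecord",
    "SiteQuantMatrix",
    "PhosphoFormatError",
    "DEFAULT_DIALECT",
    "read_phospho_table",
    "preprocess",
    "quantile_normalize",
    "matrix_to_records",
]

#: Default column-name mapping for phosphopeptide TSV tables. Keys are the
#: logical fields; values are the column headers expected in the file.
#: ``replicate``, ``canonical`` and ``peptide`` are optional.
DEFAULT_DIALECT: dict[str, str] = {
    "protein": "protein",
    "position": "position",
    "residue": "residue",
    "condition": "condition",
    "replicate": "replicate",
    "log2fc": "log2fc",
    "canonical": "canonical",
    "peptide": "peptide",
}

_REQUIRED_FIELDS = ("protein", "position", "residue", "condition", "log2fc")

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none"}

_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n"}


class PhosphoFormatError(ValueError):
    """Raised when a phosphopeptide table cannot be parsed."""


@dataclass(frozen=True)
class PhosphopeptideRecord:
    """One quantified phosphopeptide observation.

    ``positions``/``residues`` are parallel: a doubly phosphorylated peptide
    has two entries in each. ``log2fc`` is ``None`` when the quantification
    is missing. ``peptide`` identifies the peptide sequence variant so that
    replicate averaging can precede peptide-variant averaging; when absent,
    all observations of a site collapse in one step.
    """

    protein_id: str
    positions: tuple[int, ...]
    residues: tuple[str, ...]
    condition_id: str
    log2fc: float | None
    replicate_id: str = ""
    peptide: str | None = None
    is_canonical: bool = True

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("positions must be non-empty")
        if any(p < 1 for p in self.positions):
            raise ValueError(f"positions must be >= 1, got {self.positions}")
        if tuple(sorted(self.positions)) != tuple(self.positions):
            raise ValueError("positions must be sorted ascending")
        if len(self.residues) != len(self.positions):
            raise ValueError("residues and positions must be parallel")
        if self.log2fc is not None and not math.isfinite(self.log2fc):
            raise ValueError(f"log2fc must be finite, got {self.log2fc}")

    @property
    def is_monophosphorylated(self) -> bool:
        return len(self.positions) == 1

    @property
    def site_key(self) -> tuple[str, int, str]:
        """(protein, position, residue) key; only valid for monophospho records."""
        if not self.is_monophosphorylated:
            raise ValueError("site_key undefined for multiply phosphorylated peptide")
        return (self.protein_id, self.positions[0], self.residues[0])


@dataclass
class SiteQuantMatrix:
    """Sites x conditions log2 fold-change matrix with missing values.

    ``data`` is indexed by a (protein, position, residue) MultiIndex; columns
    are condition identifiers; NaN marks missing quantifications.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate site keys: {dups[:5]}")
        self.data.index.names = ["protein", "position", "residue"]

    @property
    def sites(self) -> list[tuple[str, int, str]]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def condition_coverage(self) -> pd.Series:
        """Number of non-missing sites per condition."""
        return self.data.notna().sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index = [f"{p}_{pos}_{res}" for p, pos, res in out.index]
        out.index.name = "site"
        out.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False) -> "SiteQuantMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        keys = []
        for key in df.index:
            protein, pos, res = str(key).rsplit("_", 2)
            keys.append((protein, int(pos), res))
        df.index = pd.MultiIndex.from_tuples(keys, names=["protein", "position", "residue"])
        df.columns = [str(c) for c in df.columns]
        return cls(data=df, normalized=normalized)


def _parse_bool(token: str, line_no: int) -> bool:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise PhosphoFormatError(f"line {line_no}: unrecognized boolean value {token!r}")


def read_phospho_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    canonical_accessions: Iterable[str] | None = None,
) -> list[PhosphopeptideRecord]:
    """Parse a phosphopeptide TSV into records.

    Parameters
    ----------
    path:
        Tab-separated file with a header row.
    dialect:
        Mapping from logical field names (see :data:`DEFAULT_DIALECT`) to
        column headers. Unlisted fields use the defaults.
    canonical_accessions:
        Optional whitelist of canonical protein accessions; when given it
        overrides any ``canonical`` column. Without either, every record is
        treated as canonical.

    Rows with an unparseable position/residue or a non-numeric fold change
    are collected as row errors and logged; parsing aborts only if they
    exceed half of the data rows. ``NA``-like fold changes become missing
    values, with a warning.
    """
    dmap = dict(DEFAULT_DIALECT)
    if dialect:
        dmap.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    for logical in _REQUIRED_FIELDS:
        if dmap[logical] not in df.columns:
            raise PhosphoFormatError(
                f"required column {dmap[logical]!r} (field {logical!r}) "
                f"not found in {path}; available: {list(df.columns)}"
            )
    has_replicate = dmap["replicate"] in df.columns
    has_canonical = dmap["canonical"] in df.columns
    has_peptide = dmap["peptide"] in df.columns
    canon_set = set(canonical_accessions) if canonical_accessions is not None else None

    records: list[PhosphopeptideRecord] = []
    row_errors: list[str] = []
    n_rows = len(df)
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        row = dict(zip(df.columns, row))
        try:
            positions = tuple(
                int(tok) for tok in str(row[dmap["position"]]).split(";") if tok.strip()
            )
            residues = tuple(
                tok.strip().upper() for tok in str(row[dmap["residue"]]).split(";") if tok.strip()
            )
            raw_fc = str(row[dmap["log2fc"]]).strip()
            if raw_fc.lower() in _MISSING_TOKENS:
                log2fc: float | None = None
                logger.warning("line %d: missing log2fc, recorded as missing value", i)
            else:
                log2fc = float(raw_fc)
            protein = str(row[dmap["protein"]]).strip()
            if canon_set is not None:
                canonical = protein in canon_set
            elif has_canonical:
                canonical = _parse_bool(str(row[dmap["canonical"]]), i)
            else:
                canonical = True
            records.append(
                PhosphopeptideRecord(
                    protein_id=protein,
                    positions=positions,
                    residues=residues,
                    condition_id=str(row[dmap["condition"]]).strip(),
                    log2fc=log2fc,
                    replicate_id=str(row[dmap["replicate"]]).strip() if has_replicate else "",
                    peptide=str(row[dmap["peptide"]]).strip() if has_peptide else None,
                    is_canonical=canonical,
                )
            )
        except (ValueError, PhosphoFormatError) as exc:
            row_errors.append(f"line {i}: {exc}")

    if row_errors:
        for msg in row_errors:
            logger.warning("malformed row: %s", msg)
        if n_rows > 0 and len(row_errors) > n_rows / 2:
            raise PhosphoFormatError(
                f"{len(row_errors)}/{n_rows} rows malformed; first: {row_errors[0]}"
            )
    return records


def preprocess(
    records: Sequence[PhosphopeptideRecord],
    min_coverage: int = 1000,
) -> SiteQuantMatrix:
    """Filter and collapse peptide records into an unnormalized site matrix.

    Applies, in order: drop non-canonical records; drop multiply
    phosphorylated peptides; average across replicates of the same
    (site, condition, peptide); average across peptide variants of the same
    (site, condition); drop conditions quantifying fewer than
    ``min_coverage`` sites.
    """
    rows = [
        (
            r.protein_id,
            r.positions[0],
            r.residues[0],
            r.condition_id,
            r.peptide if r.peptide is not None else "",
            r.log2fc,
        )
        for r in records
        if r.is_canonical and r.is_monophosphorylated and r.log2fc is not None
    ]
    if not rows:
        raise ValueError("no quantified canonical monophosphorylated records to preprocess")
    df = pd.DataFrame(
        rows, columns=["protein", "position", "residue", "condition", "peptide", "log2fc"]
    )
    # replicate-first averaging, then across peptide variants
    per_peptide = df.groupby(
        ["protein", "position", "residue", "condition", "peptide"], sort=True
    )["log2fc"].mean()
    per_site = per_peptide.groupby(["protein", "position", "residue", "condition"]).mean()
    matrix = per_site.unstack("condition")
    matrix.columns.name = None

    coverage = matrix.notna().sum(axis=0)
    keep = coverage[coverage >= min_coverage].index
    if len(keep) == 0:
        detail = ", ".join(f"{c}={int(n)}" for c, n in coverage.items())
        raise ValueError(
            f"all conditions fall below min_coverage={min_coverage} "
            f"(quantified sites per condition: {detail})"
        )
    dropped = [c for c in matrix.columns if c not in set(keep)]
    if dropped:
        logger.info("dropping %d low-coverage conditions: %s", len(dropped), dropped)
    matrix = matrix[list(keep)].dropna(how="all")
    return SiteQuantMatrix(data=matrix, normalized=False)


def quantile_normalize(m: SiteQuantMatrix) -> SiteQuantMatrix:
    """Quantile-normalize conditions onto a shared reference distribution.

    The reference is the across-condition mean of each condition's sorted
    observed values, interpolated to a common grid whose length is the
    largest observed count. Each condition's observed values are ranked
    (average ranks on ties) and mapped onto the reference at their rank
    quantiles; missing entries stay missing. Columns with equal numbers of
    observed values therefore end up with identical sorted values.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    values = m.data.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(values), axis=0)
    if values.shape[1] < 2:
        logger.warning("single-condition matrix: quantile normalization is a no-op")
        return SiteQuantMatrix(data=m.data.copy(), normalized=True)
    if np.any(n_obs == 0):
        raise ValueError("cannot quantile-normalize a condition with no observed values")

    grid_len = int(n_obs.max())
    grid_q = (np.arange(grid_len) + 0.5) / grid_len
    ref = np.zeros(grid_len)
    for j in range(values.shape[1]):
        col = np.sort(values[~np.isnan(values[:, j]), j])
        q = (np.arange(col.size) + 0.5) / col.size
        ref += np.interp(grid_q, q, col)
    ref /= values.shape[1]

    from scipy.stats import rankdata

    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        mask = ~np.isnan(values[:, j])
        col = values[mask, j]
        ranks = rankdata(col, method="average")  # ties -> average ranks
        q = (ranks - 0.5) / col.size
        out[mask, j] = np.interp(q, grid_q, ref)
    return SiteQuantMatrix(
        data=pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        normalized=True,
    )


def matrix_to_records(m: SiteQuantMatrix) -> list[PhosphopeptideRecord]:
    """Expand a site matrix back into one record per quantified cell.

    Useful for round-tripping a collapsed matrix through :func:`preprocess`
    (under which preprocessing is idempotent) and for feeding simulated
    matrices into the standard pipeline entry point.
    """
    records = []
    for (protein, pos, res), row in m.data.iterrows():
        for condition, value in row.items():
            if pd.notna(value):
                records.append(
                    PhosphopeptideRecord(
                        protein_id=protein,
                        positions=(int(pos),),
                        residues=(res,),
                        condition_id=str(condition),
                        log2fc=float(value),
                    )
                )
    return records
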