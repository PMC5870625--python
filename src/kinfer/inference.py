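"""Substrate-based kinase activity inference.

All methods share one premise: when a kinase is regulated in a condition,
the phosphorylation fold changes of its substrate sites shift relative to
the background of all quantified sites in that condition. Five statistics
quantify that shift:

``ztest``
    One-sample Z-test: z = (m_S - m_P) * sqrt(n_S) / delta, comparing the
    mean substrate fold change m_S against the mean m_P and standard
    deviation delta of *all* fold changes in the condition.
``ks``
    Two-sample Kolmogorov-Smirnov test between substrate and non-substrate
    fold-change distributions (asymptotic p).
``wilcoxon``
    Two-sample Wilcoxon rank-sum test between substrates and
    non-substrates (normal approximation with tie and continuity
    correction).
``gsea``
    KSEA: a weighted Kolmogorov-Smirnov running-sum enrichment score over
    the fold-change-ranked site list, with an empirical permutation null of
    random same-size substrate sets (default 10 000 permutations).
``mlr``
    Multiple linear regression Y = X beta + psi with ridge (L2) penalty,
    where X is the binary site-by-kinase connectivity matrix; beta_j is the
    activity score of kinase j. All kinases are fitted jointly, which
    shares explanatory credit between kinases with overlapping regulons.

For the test-based methods the reported activity score is
sign(mean substrate fold change) * (-log10 p): positive scores indicate
inferred activation, negative inhibition. For ``mlr`` the score is beta.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import SiteQuantMatrix
from .network import KinaseSubstrateNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "ConditionVector",
    "ActivityScore",
    "ActivityScoreTable",
    "MLRFit",
    "DegenerateBackgroundError",
    "ztest",
    "ks_test",
    "wilcoxon_test",
    "ksea",
    "mlr_fit",
    "infer_all",
]

METHODS = ("ztest", "ks", "wilcoxon", "gsea", "mlr", "ztest_weighted", "gsea_weighted")


class DegenerateBackgroundError(ValueError):
    """Raised when a condition's fold changes carry no usable variation."""


@dataclass
class ConditionVector:
    """Non-missing fold changes of one condition, with their site keys."""

    site_keys: list[tuple[str, int, str]]
    fc: np.ndarray
    condition_id: str = ""

    def __post_init__(self) -> None:
        self.fc = np.asarray(self.fc, dtype=float)
        if len(self.site_keys) != self.fc.size:
            raise ValueError("site_keys and fc must be parallel")
        if not np.all(np.isfinite(self.fc)):
            raise ValueError("fold changes must be finite")

    @classmethod
    def from_matrix(cls, m: SiteQuantMatrix, condition: str) -> "ConditionVector":
        col = m.data[condition]
        mask = col.notna()
        return cls(
            site_keys=list(col.index[mask]),
            fc=col[mask].to_numpy(dtype=float),
            condition_id=condition,
        )

    def substrate_mask(self, regulon: Iterable) -> np.ndarray:
        """Boolean mask of sites belonging to a regulon.

        Regulon entries may be (protein, position) or (protein, position,
        residue); matching ignores the residue, which often disagrees
        between network and quantification annotations.
        """
        wanted = {(entry[0], entry[1]) for entry in regulon}
        return np.fromiter(
            ((key[0], key[1]) in wanted for key in self.site_keys),
            dtype=bool,
            count=len(self.site_keys),
        )


@dataclass
class ActivityScore:
    """One kinase/condition activity estimate from one method."""

    kinase_id: str
    condition_id: str
    method: str
    statistic: float
    p_value: float | None
    n_quantified_substrates: int
    mean_substrate_fc: float
    signed_score: float

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")
        if self.n_quantified_substrates < 1:
            raise ValueError("n_quantified_substrates must be >= 1")


def _signed_score(p_value: float, mean_substrate_fc: float) -> float:
    return float(np.sign(mean_substrate_fc) * (-math.log10(p_value)))


def _prepare(cv: ConditionVector, regulon: Iterable) -> tuple[np.ndarray, np.ndarray]:
    mask = cv.substrate_mask(regulon)
    if not mask.any():
        raise ValueError("no quantified substrate in condition vector")
    return mask, cv.fc


def ztest(
    cv: ConditionVector,
    regulon: Iterable,
    kinase_id: str = "",
) -> ActivityScore:
    """One-sample Z-test of substrate mean against the condition background.

    The background includes the substrate sites themselves ("all fold
    changes in the same condition"); delta is the sample standard deviation.
    """
    mask, fc = _prepare(cv, regulon)
    if fc.size < 2:
        raise ValueError("need at least two quantified sites")
    sub = fc[mask]
    delta = float(np.std(fc, ddof=1))
    if delta == 0.0:
        raise DegenerateBackgroundError("zero background standard deviation")
    m_s = float(np.mean(sub))
    m_p = float(np.mean(fc))
    z = (m_s - m_p) * math.sqrt(sub.size) / delta
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return ActivityScore(
        kinase_id=kinase_id,
        condition_id=cv.condition_id,
        method="ztest",
        statistic=z,
        p_value=p,
        n_quantified_substrates=int(sub.size),
        mean_substrate_fc=m_s,
        signed_score=_signed_score(p, m_s),
    )


def ks_test(cv: ConditionVector, regulon: Iterable, kinase_id: str = "") -> ActivityScore:
    """Two-sample KS test: substrates vs non-substrates, asymptotic p."""
    mask, fc = _prepare(cv, regulon)
    sub, bg = fc[mask], fc[~mask]
    if bg.size == 0:
        raise DegenerateBackgroundError("no non-substrate sites in condition")
    # D = max |ECDF_sub - ECDF_bg| over the pooled sample points
    pooled = np.sort(np.concatenate([sub, bg]))
    cdf_sub = np.searchsorted(np.sort(sub), pooled, side="right") / sub.size
    cdf_bg = np.searchsorted(np.sort(bg), pooled, side="right") / bg.size
    d = float(np.max(np.abs(cdf_sub - cdf_bg)))
    # Smirnov's asymptotic formula with effective sample size
    # n1*n2/(n1+n2), the finite-size form scipy's asymptotic mode uses;
    # far better calibrated than the limiting Kolmogorov distribution when
    # the substrate set is small.
    en = sub.size * bg.size / (sub.size + bg.size)
    p = float(stats.kstwo.sf(d, int(round(en))))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    m_s = float(np.mean(sub))
    return ActivityScore(
        kinase_id=kinase_id,
        condition_id=cv.condition_id,
        method="ks",
        statistic=d,
        p_value=p,
        n_quantified_substrates=int(sub.size),
        mean_substrate_fc=m_s,
        signed_score=_signed_score(p, m_s),
    )


def wilcoxon_test(cv: ConditionVector, regulon: Iterable, kinase_id: str = "") -> ActivityScore:
    """Two-sample Wilcoxon rank-sum test, normal approximation.

    Uses average ranks on ties with the usual tie-corrected variance and a
    0.5 continuity correction toward the null.
    """
    mask, fc = _prepare(cv, regulon)
    sub, bg = fc[mask], fc[~mask]
    if bg.size == 0:
        raise DegenerateBackgroundError("no non-substrate sites in condition")
    n1, n2 = sub.size, bg.size
    n = n1 + n2
    ranks = stats.rankdata(fc, method="average")
    r1 = float(np.sum(ranks[mask]))
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, counts = np.unique(fc, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma_sq <= 0.0:
        # every value identical: no rank information
        p = 1.0
        z = 0.0
    else:
        # continuity correction shrinks |U - mu| by 0.5
        num = abs(u1 - mu) - 0.5
        z = math.copysign(max(num, 0.0) / math.sqrt(sigma_sq), u1 - mu)
        p = float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
    p = max(p, np.nextafter(0, 1))
    m_s = float(np.mean(sub))
    return ActivityScore(
        kinase_id=kinase_id,
        condition_id=cv.condition_id,
        method="wilcoxon",
        statistic=u1,
        p_value=p,
        n_quantified_substrates=int(n1),
        mean_substrate_fc=m_s,
        signed_score=_signed_score(p, m_s),
    )


# ---------------------------------------------------------------------------
# KSEA / GSEA


def _rank_descending(fc: np.ndarray) -> np.ndarray:
    """Indices sorting fold changes descending; stable, so input order
    breaks ties."""
    return np.argsort(-fc, kind="stable")


def _enrichment_scores(
    abs_fc_ranked: np.ndarray, positions: np.ndarray, weight_exponent: float = 1.0
) -> np.ndarray:
    """Weighted KS enrichment scores for batches of substrate sets.

    ``positions`` is a (batch, k) integer array of 0-based ranks (ascending
    within each row) of the substrate sites in the descending-fold-change
    ordering. The running sum over the ranked list gains |fc|^w / N_R at
    substrate ranks and loses 1/(N - k) elsewhere; the ES is the signed
    maximum deviation from zero, which is always attained immediately
    before or immediately after a substrate rank.
    """
    positions = np.atleast_2d(positions)
    batch, k = positions.shape
    n = abs_fc_ranked.size
    w = abs_fc_ranked[positions] ** weight_exponent
    n_r = w.sum(axis=1, keepdims=True)
    if np.any(n_r == 0):
        raise DegenerateBackgroundError("all substrate fold changes are zero")
    cum_hit = np.cumsum(w, axis=1) / n_r
    decrement = 1.0 / (n - k) if n > k else 0.0
    j = np.arange(1, k + 1)
    # value just after the j-th substrate rank, and just before it
    after = cum_hit - (positions + 1 - j) * decrement
    before = cum_hit - w / n_r - (positions - (j - 1)) * decrement
    # interleave in scan order (…, before_j, after_j, …) so that an equal-
    # magnitude tie resolves to the extremum reached first along the list,
    # matching a sequential running-sum scan
    candidates = np.empty((batch, 2 * k))
    candidates[:, 0::2] = before
    candidates[:, 1::2] = after
    idx = np.argmax(np.abs(candidates), axis=1)
    return candidates[np.arange(batch), idx]


def _sample_position_sets(
    rng: np.random.Generator, n: int, k: int, n_sets: int
) -> np.ndarray:
    """n_sets sorted uniform samples of k distinct ranks from range(n)."""
    # argpartition of uniforms gives a uniform k-subset per row
    u = rng.random((n_sets, n))
    picks = np.argpartition(u, k, axis=1)[:, :k]
    picks.sort(axis=1)
    return picks


def ksea(
    cv: ConditionVector,
    regulon: Iterable,
    kinase_id: str = "",
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    weight_exponent: float = 1.0,
    null: str = "montecarlo",
    _null_scores: np.ndarray | None = None,
) -> ActivityScore:
    """KSEA enrichment score with an empirical permutation p-value.

    Sites are ranked by fold change descending; the enrichment score (ES)
    is the signed maximum deviation of the weighted KS running sum. The
    two-sided empirical p compares |ES| against ``n_perm`` random substrate
    sets of the same size, with a +1 pseudo-count so p never reaches zero:
    p = (1 + #{|ES_null| >= |ES|}) / (1 + n_perm).

    ``null="exhaustive"`` enumerates every same-size subset instead (exact
    p, no pseudo-count); feasible only for small instances.
    ``_null_scores`` lets callers reuse a precomputed null ES sample (the
    null depends only on the condition and the regulon size, so it can be
    shared across kinases with equal quantified-substrate counts).
    """
    mask, fc = _prepare(cv, regulon)
    n = fc.size
    order = _rank_descending(fc)
    abs_ranked = np.abs(fc[order])
    sub_positions = np.sort(np.nonzero(mask[order])[0])
    k = sub_positions.size
    if k == n:
        raise DegenerateBackgroundError("regulon covers every quantified site")
    es = float(_enrichment_scores(abs_ranked, sub_positions[None, :], weight_exponent)[0])

    if _null_scores is not None:
        null_es = _null_scores
        p = float((1 + np.sum(np.abs(null_es) >= abs(es))) / (1 + null_es.size))
    elif null == "exhaustive":
        sets = np.array(list(combinations(range(n), k)), dtype=np.intp)
        null_es = _enrichment_scores(abs_ranked, sets, weight_exponent)
        p = float(np.sum(np.abs(null_es) >= abs(es)) / null_es.size)
        p = max(p, np.nextafter(0, 1))
    elif null == "montecarlo":
        rng = np.random.default_rng(seed)
        positions = _sample_position_sets(rng, n, k, n_perm)
        null_es = _enrichment_scores(abs_ranked, positions, weight_exponent)
        p = float((1 + np.sum(np.abs(null_es) >= abs(es))) / (1 + n_perm))
    else:
        raise ValueError(f"unknown null scheme {null!r}")

    m_s = float(np.mean(fc[mask]))
    return ActivityScore(
        kinase_id=kinase_id,
        condition_id=cv.condition_id,
        method="gsea",
        statistic=es,
        p_value=p,
        n_quantified_substrates=int(k),
        mean_substrate_fc=m_s,
        signed_score=_signed_score(p, m_s),
    )


@dataclass
class MLRFit:
    """Ridge regression fit of fold changes on kinase connectivity."""

    kinases: list[str]
    beta: np.ndarray
    ridge_lambda: float
    residual: np.ndarray
    X: np.ndarray
    Y: np.ndarray


def mlr_fit(
    cv: ConditionVector,
    network: KinaseSubstrateNetwork,
    ridge_lambda: float = 0.1,
) -> tuple[list[ActivityScore], MLRFit]:
    """Jointly estimate all kinase activities by ridge regression.

    Y (quantified fold changes) is modelled as X beta + psi with X the
    binary site-by-kinase connectivity matrix restricted to quantified
    sites; beta minimizes ||Y - X beta||^2 + lambda ||beta||^2 with no
    intercept. Kinases without quantified substrates are excluded. The L2
    penalty stabilizes the shared-credit assignment between kinases with
    overlapping regulons.
    """
    from sklearn.linear_model import Ridge

    kinases = []
    columns = []
    for kinase in network.kinases:
        mask = cv.substrate_mask(network.regulon(kinase))
        if mask.any():
            kinases.append(kinase)
            columns.append(mask.astype(float))
    if not kinases:
        raise ValueError("no kinase has a quantified substrate in this condition")
    X = np.column_stack(columns)
    Y = cv.fc
    if ridge_lambda > 0:
        model = Ridge(alpha=ridge_lambda, fit_intercept=False, solver="cholesky")
        model.fit(X, Y)
        beta = model.coef_.astype(float)
    else:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fit = MLRFit(
        kinases=kinases,
        beta=beta,
        ridge_lambda=ridge_lambda,
        residual=Y - X @ beta,
        X=X,
        Y=Y,
    )
    scores = []
    for j, kinase in enumerate(kinases):
        mask = X[:, j].astype(bool)
        scores.append(
            ActivityScore(
                kinase_id=kinase,
                condition_id=cv.condition_id,
                method="mlr",
                statistic=float(beta[j]),
                p_value=None,
                n_quantified_substrates=int(mask.sum()),
                mean_substrate_fc=float(np.mean(Y[mask])),
                signed_score=float(beta[j]),
            )
        )
    return scores, fit


# ---------------------------------------------------------------------------
# Driver


class ActivityScoreTable:
    """Kinases x conditions activity scores in long format."""

    COLUMNS = (
        "kinase",
        "condition",
        "method",
        "statistic",
        "p_value",
        "n_quantified_substrates",
        "mean_substrate_fc",
        "signed_score",
    )

    def __init__(self, scores: Sequence[ActivityScore]):
        self.scores = list(scores)
        self._by_pair = {(s.kinase_id, s.condition_id): s for s in self.scores}

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self):
        return iter(self.scores)

    def get(self, kinase_id: str, condition_id: str) -> ActivityScore | None:
        return self._by_pair.get((kinase_id, condition_id))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    s.kinase_id,
                    s.condition_id,
                    s.method,
                    s.statistic,
                    s.p_value if s.p_value is not None else np.nan,
                    s.n_quantified_substrates,
                    s.mean_substrate_fc,
                    s.signed_score,
                )
                for s in self.scores
            ],
            columns=list(self.COLUMNS),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def activity_matrix(self) -> pd.DataFrame:
        """Pivot of signed scores, kinases x conditions."""
        return self.to_frame().pivot(index="kinase", columns="condition", values="signed_score")


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def infer_all(
    m: SiteQuantMatrix,
    network: KinaseSubstrateNetwork,
    method: str = "gsea",
    n_perm: int = 10_000,
    seed: int | None = None,
    ridge_lambda: float = 0.1,
    min_quantified: int = 1,
    mss_table: Mapping[str, Mapping[tuple[str, int], float]] | None = None,
    require_normalized: bool = True,
) -> ActivityScoreTable:
    """Score every (kinase, condition) pair with one method.

    Pairs with fewer than ``min_quantified`` quantified substrates are
    absent from the output (distinct from a zero score). For the weighted
    variants (``ztest_weighted``, ``gsea_weighted``) an ``mss_table``
    mapping kinase -> {(protein, position): mss} is required; each kinase's
    quantified substrate fold changes are multiplied by their matrix
    similarity score before testing, and kinases absent from the table
    (fewer than the minimum substrates needed to build a PWM) are skipped.

    The GSEA permutation null is drawn once per (condition, regulon size)
    and shared across kinases with equal quantified-substrate counts — the
    null distribution depends only on those two quantities. Each (condition,
    size) stream is seeded from ``seed`` deterministically.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if require_normalized and not m.normalized:
        logger.warning("inferring on an unnormalized matrix")
    if method.endswith("_weighted") and mss_table is None:
        raise ValueError(f"method {method!r} requires an mss_table")

    base = method.removesuffix("_weighted")
    weighted = method.endswith("_weighted")
    master = np.random.default_rng(seed)
    scores: list[ActivityScore] = []

    for condition in m.conditions:
        cv = ConditionVector.from_matrix(m, condition)
        if cv.fc.size < 2:
            logger.warning("condition %s has <2 quantified sites; skipped", condition)
            continue
        cond_seed = _spawn_seed(master)
        if base == "mlr":
            cond_scores, _ = mlr_fit(cv, network, ridge_lambda=ridge_lambda)
            scores.extend(
                s for s in cond_scores if s.n_quantified_substrates >= min_quantified
            )
            continue

        null_cache: dict[int, np.ndarray] = {}
        for kinase in network.kinases:
            regulon = network.regulon(kinase)
            if weighted and kinase not in mss_table:
                continue
            use_cv = cv
            if weighted:
                from .specificity import weight_fold_changes

                use_cv = weight_fold_changes(cv, regulon, mss_table[kinase])
            mask = use_cv.substrate_mask(regulon)
            k = int(mask.sum())
            if k < min_quantified or k == 0 or k == use_cv.fc.size:
                continue
            try:
                if base == "ztest":
                    score = ztest(use_cv, regulon, kinase_id=kinase)
                elif base == "ks":
                    score = ks_test(use_cv, regulon, kinase_id=kinase)
                elif base == "wilcoxon":
                    score = wilcoxon_test(use_cv, regulon, kinase_id=kinase)
                elif base == "gsea":
                    if weighted:
                        # weighting changes the ranked list per kinase; the
                        # null must be drawn on the same weighted vector
                        score = ksea(
                            use_cv,
                            regulon,
                            kinase_id=kinase,
                            n_perm=n_perm,
                            seed=np.random.default_rng([cond_seed, _stable_hash(kinase)]),
                        )
                    else:
                        if k not in null_cache:
                            order = _rank_descending(use_cv.fc)
                            abs_ranked = np.abs(use_cv.fc[order])
                            rng = np.random.default_rng([cond_seed, k])
                            positions = _sample_position_sets(rng, use_cv.fc.size, k, n_perm)
                            null_cache[k] = _enrichment_scores(abs_ranked, positions)
                        score = ksea(
                            use_cv, regulon, kinase_id=kinase, _null_scores=null_cache[k]
                        )
                else:  # pragma: no cover
                    raise AssertionError(base)
            except DegenerateBackgroundError as exc:
                logger.warning("%s/%s: %s; skipped", kinase, condition, exc)
                continue
            score.method = method
            scores.append(score)
    return ActivityScoreTable(scores)


def _stable_hash(text: str) -> int:
    """Deterministic 31-bit hash (process-independent, unlike hash())."""
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h
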