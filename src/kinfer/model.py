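"""Model/Results front-end over the inference library.

``KinaseActivityModel`` binds the data (site fold-change matrix,
kinase-substrate network, optional protein sequences) and its ``fit``
returns a ``KinaseActivityResults`` carrying the per-kinase, per-condition
activity scores, a text ``summary()`` and benchmarking/plotting helpers —
the same model-then-results idiom statsmodels users expect.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import benchmark as bench
from .inference import ActivityScoreTable, METHODS, infer_all
from .io import SiteQuantMatrix, quantile_normalize
from .network import KinaseSubstrateNetwork
from .specificity import build_pwm_library, compute_mss_table

__all__ = ["KinaseActivityModel", "KinaseActivityResults"]


class KinaseActivityModel:
    """Substrate-based kinase activity model for one phosphoproteomic study.

    Parameters
    ----------
    quant:
        Site x condition log2 fold-change matrix. Quantile-normalized
        automatically unless already normalized or ``normalize=False``.
    network:
        Kinase-substrate network defining each kinase's regulon.
    sequences:
        Protein sequences (accession -> sequence); required only for the
        MSS-weighted methods.
    min_quantified:
        Minimum quantified substrates for a (kinase, condition) score.
    min_pwm_substrates:
        Minimum substrate flanks to build a kinase PWM (weighted methods).
    """

    def __init__(
        self,
        quant: SiteQuantMatrix,
        network: KinaseSubstrateNetwork,
        sequences: Mapping[str, str] | None = None,
        normalize: bool = True,
        min_quantified: int = 1,
        min_pwm_substrates: int = 10,
    ):
        if normalize and not quant.normalized:
            quant = quantile_normalize(quant)
        self.quant = quant
        self.network = network
        self.sequences = dict(sequences) if sequences is not None else None
        self.min_quantified = min_quantified
        self.min_pwm_substrates = min_pwm_substrates
        self._pwms = None
        self._mss_table = None

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        network: KinaseSubstrateNetwork,
        normalized: bool = False,
        **kwargs,
    ) -> "KinaseActivityModel":
        """Build from a DataFrame indexed by (protein, position, residue)."""
        if not isinstance(data.index, pd.MultiIndex):
            keys = []
            for key in data.index:
                protein, pos, res = str(key).rsplit("_", 2)
                keys.append((protein, int(pos), res))
            data = data.copy()
            data.index = pd.MultiIndex.from_tuples(keys)
        return cls(SiteQuantMatrix(data=data, normalized=normalized), network, **kwargs)

    @classmethod
    def from_files(
        cls,
        matrix_tsv,
        network_tsv,
        fasta=None,
        matrix_normalized: bool = True,
        **kwargs,
    ) -> "KinaseActivityModel":
        from .network import read_network
        from .specificity import read_fasta

        quant = SiteQuantMatrix.from_tsv(matrix_tsv, normalized=matrix_normalized)
        network = read_network(network_tsv)
        sequences = read_fasta(fasta) if fasta else None
        return cls(quant, network, sequences=sequences, **kwargs)

    @property
    def mss_table(self):
        if self._mss_table is None:
            if self.sequences is None:
                raise ValueError("weighted methods require protein sequences")
            self._pwms = build_pwm_library(
                self.network, self.sequences, min_substrates=self.min_pwm_substrates
            )
            self._mss_table = compute_mss_table(
                self.network, self.sequences, pwms=self._pwms
            )
        return self._mss_table

    @property
    def pwms(self):
        self.mss_table  # builds lazily
        return self._pwms

    def fit(
        self,
        method: str = "gsea",
        n_perm: int = 10_000,
        ridge_lambda: float = 0.1,
        seed: int | None = None,
    ) -> "KinaseActivityResults":
        """Estimate kinase activities for every condition with one method."""
        mss_table = self.mss_table if method.endswith("_weighted") else None
        scores = infer_all(
            self.quant,
            self.network,
            method=method,
            n_perm=n_perm,
            seed=seed,
            ridge_lambda=ridge_lambda,
            min_quantified=self.min_quantified,
            mss_table=mss_table,
        )
        return KinaseActivityResults(self, method, scores)


class KinaseActivityResults:
    """Fitted kinase activities with diagnostics and benchmarking."""

    def __init__(self, model: KinaseActivityModel, method: str, scores: ActivityScoreTable):
        self.model = model
        self.method = method
        self.scores = scores

    def to_frame(self) -> pd.DataFrame:
        return self.scores.to_frame()

    def activity_matrix(self) -> pd.DataFrame:
        return self.scores.activity_matrix()

    def top_regulations(self, n: int = 10) -> pd.DataFrame:
        df = self.to_frame()
        return df.reindex(df.signed_score.abs().sort_values(ascending=False).index).head(n)

    def summary(self, top: int = 10) -> str:
        df = self.to_frame()
        lines = [
            "Kinase activity inference",
            "=" * 60,
            f"method:              {self.method}",
            f"kinases scored:      {df.kinase.nunique()}",
            f"conditions scored:   {df.condition.nunique()}",
            f"scores computed:     {len(df)}",
            f"median |activity|:   {df.signed_score.abs().median():.3f}",
            "",
            f"strongest inferred regulations (top {top}):",
            self.top_regulations(top)
            .loc[:, ["kinase", "condition", "n_quantified_substrates", "signed_score"]]
            .to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def benchmark(
        self,
        gold: Sequence[bench.GoldStandardPair],
        n_randomizations: int = 60,
        seed: int | None = None,
    ) -> list[bench.BenchmarkResult]:
        """ROC/PR evaluation against a gold standard of expected
        regulations; see :func:`kinfer.benchmark.run_benchmark`."""
        return bench.run_benchmark(
            self.scores, gold, n_randomizations=n_randomizations, seed=seed
        )

    def plot_roc(self, results: Sequence[bench.BenchmarkResult], ax=None):
        """Overlay per-randomization ROC curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for r in results:
            fpr, tpr = zip(*r.roc_points)
            ax.plot(fpr, tpr, alpha=0.2, color="C0")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(
            f"{self.method}: median AUC = {bench.median_auc(results):.3f} "
            f"({len(results)} negative sets)"
        )
        return ax
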