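"""Model/Results surface tying the pipeline stages together.

:class:`CrosstalkModel` wraps a four-condition count matrix; ``fit()``
runs size-factor normalization, the NB Wald tests for the three
treatment-versus-control contrasts, and response-type classification of
the DE genes, returning a :class:`CrosstalkResults` carrying the DE
table, the per-gene response calls, the category summary and diagnostic
counts.  Network analyses (hubs, chains, neighborhoods, permutation
enrichment) hang off the results object once a pathway collection is
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from . import clustering, de, network
from .clustering import ClusterSummary, DEFAULT_T, DEFAULT_TAU_CALL
from .de import CountMatrix
from .network import InteractionNetwork, PathwayCollection

__all__ = ["CrosstalkModel", "CrosstalkResults"]


class CrosstalkModel:
    """Hormone-crosstalk analysis of a CTRL / T3 / CORT / T3+CORT design.

    Parameters
    ----------
    counts
        :class:`~hormonet.de.CountMatrix` (or a genes x samples DataFrame
        with ``COND_rep`` column names via :meth:`from_dataframe`).
    fdr_threshold
        Per-contrast BH FDR cutoff for calling a gene DE (default 0.05).
    t
        Crosstalk distance threshold in z-space (default 0.9).
    tau_call
        u/d/n call threshold on z deltas versus control (default ``t``).
    """

    def __init__(
        self,
        counts: CountMatrix,
        fdr_threshold: float = 0.05,
        t: float = DEFAULT_T,
        tau_call: float = DEFAULT_TAU_CALL,
    ) -> None:
        if fdr_threshold <= 0 or t <= 0 or tau_call <= 0:
            raise ValueError("thresholds must be positive")
        self.counts = counts
        self.fdr_threshold = fdr_threshold
        self.t = t
        self.tau_call = tau_call

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, **kwargs) -> "CrosstalkModel":
        return cls(CountMatrix.from_dataframe(counts), **kwargs)

    def fit(self, de_table: pd.DataFrame | None = None) -> "CrosstalkResults":
        """Run DE calling (unless a table is supplied) and classification."""
        factors = de.size_factors(self.counts)
        if de_table is None:
            de_table = de.run_de(
                self.counts, fdr_threshold=self.fdr_threshold, factors=factors
            )
        de_genes = sorted(de.de_gene_ids(de_table))
        means = self.counts.condition_means(factors)
        calls, unclassified = clustering.classify_genes(
            means.loc[[g for g in de_genes if g in means.index]],
            t=self.t,
            tau_call=self.tau_call,
        )
        summary = clustering.summarize(_iter_calls(calls))
        return CrosstalkResults(
            model=self,
            size_factors=factors,
            de_table=de_table,
            condition_means=means,
            calls=calls,
            unclassified=unclassified,
            cluster_summary=summary,
        )


def _iter_calls(calls: pd.DataFrame):
    for row in calls.itertuples(index=False):
        yield clustering.ResponseCall(
            gene_id=row.gene_id,
            letters=(row.L_T3, row.L_CORT, row.L_TC),
            delta_t3=row.z_t3 - row.z_ctrl,
            delta_cort=row.z_cort - row.z_ctrl,
            delta_tc=row.z_t3cort - row.z_ctrl,
            d_T=row.d_T,
            d_G=row.d_G,
            fourth_letter=row.fourth_letter,
            cluster_name=row.cluster,
            category=None if row.category == "other" else row.category,
        )


@dataclass
class CrosstalkResults:
    """Fitted crosstalk analysis: estimates, calls and summaries."""

    model: CrosstalkModel = field(repr=False)
    size_factors: pd.Series
    de_table: pd.DataFrame = field(repr=False)
    condition_means: pd.DataFrame = field(repr=False)
    calls: pd.DataFrame = field(repr=False)
    unclassified: list[str]
    cluster_summary: ClusterSummary

    # ---- gene sets -------------------------------------------------
    @property
    def de_gene_ids(self) -> set[str]:
        return de.de_gene_ids(self.de_table)

    @property
    def crosstalk_gene_ids(self) -> set[str]:
        """DE genes in crosstalk categories (fourth letter != N)."""
        mask = self.calls["fourth_letter"] != "N"
        return set(self.calls.loc[mask, "gene_id"])

    def de_counts_per_contrast(self) -> pd.Series:
        t = self.de_table
        return t.loc[t["is_de"]].groupby("contrast").size()

    # ---- network stage --------------------------------------------
    def build_network(self, collection: PathwayCollection) -> InteractionNetwork:
        """Pathway-union network annotated with this fit's DE calls."""
        return network.merge_pathways(
            collection, self.de_gene_ids, self.crosstalk_gene_ids
        )

    # ---- reporting -------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fitted analysis."""
        lines = []
        lines.append("Hormone crosstalk analysis (T3 x CORT)")
        lines.append("=" * 54)
        n_genes, n_samples = self.model.counts.counts.shape
        lines.append(f"genes: {n_genes}    samples: {n_samples}    "
                     f"FDR <= {self.model.fdr_threshold:g}, "
                     f"t = {self.model.t:g}, tau = {self.model.tau_call:g}")
        lines.append("")
        lines.append("DE genes per contrast:")
        for contrast, n in self.de_counts_per_contrast().items():
            lines.append(f"  {contrast:<16s} {n:>6d}")
        lines.append(f"  union            {len(self.de_gene_ids):>6d}")
        lines.append(f"  classified       {self.cluster_summary.total:>6d}"
                     f"    unclassified {len(self.unclassified)}")
        lines.append("")
        lines.append("Response-type categories:")
        frame = self.cluster_summary.to_frame()
        if len(frame):
            for row in frame.itertuples(index=False):
                lines.append(
                    f"  {row.category:<6s}{row.gene_number:>6d}  "
                    f"{row.pct_of_de_genes:>6.2f}%  {row.clusters}"
                )
        ct = self.cluster_summary.crosstalk_total
        lines.append(
            f"  crosstalk (D-G): {ct} "
            f"({self.cluster_summary.crosstalk_percentage:.2f}%)"
        )
        return "\n".join(lines)
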