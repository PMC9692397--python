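"""Differential expression on a four-condition count matrix.

A deliberately simple negative-binomial Wald test: median-of-ratios size
factors, a per-gene method-of-moments dispersion pooled over all four
conditions, and a Wald statistic on the difference of condition log-means
referred to a t distribution with the pooled within-condition degrees of
freedom.  Benjamini-Hochberg controls the FDR per contrast (default 5%).

This stage is a sound stand-in for a full DESeq-style fit; it does not
implement dispersion shrinkage, sharing modes or independent filtering.
An externally computed DE table can be supplied downstream instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import CONDITIONS

__all__ = [
    "CountMatrix",
    "CONTRASTS",
    "size_factors",
    "nb_test",
    "bh_adjust",
    "run_de",
    "ddct_fold_change",
]

#: The three treatment-versus-control contrasts.
CONTRASTS = (("T3", "CTRL"), ("CORT", "CTRL"), ("T3CORT", "CTRL"))

#: Floor for the per-gene dispersion estimate.
ALPHA_FLOOR = 1e-8

#: Pseudo-count (normalized-count units) used for log2 fold-change display
#: and to guard the Wald statistic against zero condition means.
PSEUDO_COUNT = 0.5


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with condition labels.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers indexed by gene id, one column
        per sample.
    conditions
        Mapping sample id -> condition; all four conditions (CTRL, T3,
        CORT, T3CORT) must be present with at least two samples each.
    """

    counts: pd.DataFrame
    conditions: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions)
        if list(self.conditions.index) != list(self.counts.columns):
            self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            missing = self.conditions.index[self.conditions.isna()].tolist()
            raise ValueError(f"samples without a condition label: {missing}")
        if not self.counts.index.is_unique:
            raise ValueError("duplicate gene ids")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate sample ids")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0) or np.any(values != np.floor(values)):
            raise ValueError("counts must be non-negative integers")
        tally = self.conditions.value_counts()
        for cond in CONDITIONS:
            if tally.get(cond, 0) < 2:
                raise ValueError(
                    f"condition {cond!r} needs at least two samples "
                    f"(found {tally.get(cond, 0)})"
                )
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame) -> "CountMatrix":
        """Infer conditions from sample names of the form ``COND_rep``."""
        conds = pd.Series(
            {s: str(s).rsplit("_", 1)[0] for s in counts.columns}
        )
        return cls(counts=counts, conditions=conds)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    def normalized(self, factors: pd.Series) -> pd.DataFrame:
        return self.counts / factors.reindex(self.counts.columns)

    def condition_means(self, factors: pd.Series | None = None) -> pd.DataFrame:
        """Mean of size-factor-normalized counts per condition."""
        if factors is None:
            factors = size_factors(self)
        q = self.normalized(factors)
        out = {c: q[self.samples_of(c)].mean(axis=1) for c in CONDITIONS}
        return pd.DataFrame(out)


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, geometric mean rescaled to 1.

    The reference profile is the per-gene geometric mean over samples,
    restricted to genes with all counts positive; each sample's factor is
    the median count-to-reference ratio over those genes.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    values = df.to_numpy(dtype=float)
    all_positive = np.all(values > 0, axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; supply size "
            "factors computed externally or filter to a pseudo-reference"
        )
    logs = np.log(values[all_positive])
    log_ref = logs.mean(axis=1)
    log_factors = np.median(logs - log_ref[:, None], axis=0)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=df.columns, name="size_factor")


def _pooled_dispersion(
    q: np.ndarray,
    inv_s: np.ndarray,
    groups: list[np.ndarray],
) -> np.ndarray:
    """Method-of-moments NB dispersion per gene, pooled over conditions.

    With q = k/s, Var(q) = mu/s + alpha mu^2; residual sums of squares
    within each condition estimate the left side, and the size-factor term
    is subtracted before solving for alpha.
    """
    num = np.zeros(q.shape[0])
    den = np.zeros(q.shape[0])
    for idx in groups:
        n_c = len(idx)
        qc = q[:, idx]
        m_c = qc.mean(axis=1)
        ss = ((qc - m_c[:, None]) ** 2).sum(axis=1) * n_c / (n_c - 1)
        num += ss - m_c * inv_s[idx].sum()
        den += n_c * m_c**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.maximum(alpha, ALPHA_FLOOR)


def nb_test(
    counts: CountMatrix,
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of one condition against another.

    Returns a DataFrame indexed by gene id with columns ``log2fc`` (with
    pseudo-count, display only), ``p`` (two-sided), ``mean_normalized_count``
    (grand mean over all samples) and ``dispersion``.  When ``dispersion``
    is given it is used for every gene instead of the pooled moment
    estimate (e.g. 0 for a pure Poisson model).
    """
    treat, ctrl = contrast
    for cond in contrast:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
        if not counts.samples_of(cond):
            raise ValueError(f"no samples in condition {cond!r}")
    if factors is None:
        factors = size_factors(counts)
    s = factors.reindex(counts.sample_ids).to_numpy()
    q = counts.counts.to_numpy(dtype=float) / s
    inv_s = 1.0 / s
    cols = list(counts.sample_ids)
    groups = [
        np.array([cols.index(x) for x in counts.samples_of(c)])
        for c in CONDITIONS
    ]
    if dispersion is None:
        alpha = _pooled_dispersion(q, inv_s, groups)
    else:
        if dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        alpha = np.full(q.shape[0], float(dispersion))

    def cond_stats(cond: str) -> tuple[np.ndarray, np.ndarray]:
        idx = np.array([cols.index(x) for x in counts.samples_of(cond)])
        n_c = len(idx)
        m = q[:, idx].mean(axis=1)
        mu = np.maximum(m, PSEUDO_COUNT)
        var = mu * inv_s[idx].sum() / n_c**2 + alpha * mu**2 / n_c
        return m, var / mu**2  # mean and Var(log mean)

    m_a, vlog_a = cond_stats(treat)
    m_b, vlog_b = cond_stats(ctrl)
    se = np.sqrt(vlog_a + vlog_b)
    wald = (np.log(np.maximum(m_a, PSEUDO_COUNT))
            - np.log(np.maximum(m_b, PSEUDO_COUNT))) / se
    df_resid = q.shape[1] - len(CONDITIONS)
    p = 2.0 * stats.t.sf(np.abs(wald), df=df_resid)
    p = np.minimum(p, 1.0)
    log2fc = np.log2((m_a + PSEUDO_COUNT) / (m_b + PSEUDO_COUNT))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "mean_normalized_count": q.mean(axis=1),
            "dispersion": alpha,
        },
        index=counts.gene_ids,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-value passed to bh_adjust")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: CountMatrix,
    fdr_threshold: float = 0.05,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """DE table over the three treatment-versus-control contrasts.

    Long format: one row per gene per contrast with columns gene_id,
    contrast (e.g. "T3_vs_CTRL"), log2fc, p, fdr, is_de,
    mean_normalized_count.  BH adjustment is applied within each contrast.
    """
    if factors is None:
        factors = size_factors(counts)
    frames = []
    for treat, ctrl in CONTRASTS:
        res = nb_test(counts, (treat, ctrl), factors)
        res = res.reset_index(names="gene_id")
        res.insert(1, "contrast", f"{treat}_vs_{ctrl}")
        res["fdr"] = bh_adjust(res["p"].to_numpy())
        res["is_de"] = res["fdr"] <= fdr_threshold
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    return out[
        ["gene_id", "contrast", "log2fc", "p", "fdr", "is_de",
         "mean_normalized_count", "dispersion"]
    ]


def de_gene_ids(de_table: pd.DataFrame) -> set[str]:
    """Genes DE in at least one contrast."""
    return set(de_table.loc[de_table["is_de"], "gene_id"])


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """qPCR fold change by the 2^-ddCt method.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control).
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("non-finite Ct value")
    ddct = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return float(2.0 ** (-ddct))
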