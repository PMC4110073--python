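"""Carrier expression z-scores: functional read-out of predicted NMD.

A variant predicted to trigger nonsense-mediated decay should lower the
carrier's total expression of the gene. For each gene, expression values are
standardized across samples; the impact of a variant is the average z-score
of its carriers' expression of the affected gene. Group comparisons (NMD
target vs escape, singletons vs non-singletons, ...) use the one-sided
Wilcoxon rank-sum test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from .models import VariantRecord

logger = logging.getLogger(__name__)

#: below this size per group the rank-sum test enumerates exactly
EXACT_TEST_BOUND = 25


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (e.g. RPKM or factor-normalized
    RPKM), wrapped around a pandas DataFrame."""

    values: pd.DataFrame
    normalization_label: str = "RPKM"

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("need >= 2 samples")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path: str, normalization_label: str = "RPKM") -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), normalization_label)

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.6f")


def zscore_by_gene(em: ExpressionMatrix, dropped: list | None = None) -> pd.DataFrame:
    """Standardize each gene across samples: z = (x - mean)/sd with the
    population convention (divisor n). Zero-variance genes are dropped and
    logged (optionally collected in ``dropped``)."""
    vals = em.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    zero = sd == 0
    if zero.any():
        for g in vals.index[zero]:
            logger.warning("dropping constant-expression gene %s", g)
            if dropped is not None:
                dropped.append(g)
        vals, mean, sd = vals[~zero], mean[~zero], sd[~zero]
    return vals.sub(mean, axis=0).div(sd, axis=0)


def variant_expression_z(
    v: VariantRecord, zm: pd.DataFrame, gene_id: str
) -> float:
    """Average z-score of the affected gene's expression over the variant's
    carriers — the per-variant expression impact."""
    if not v.carriers:
        raise ValueError(f"{v.variant_id}: no carriers recorded")
    if gene_id not in zm.index:
        raise KeyError(f"gene {gene_id} absent from expression matrix")
    missing = [s for s in v.carriers if s not in zm.columns]
    if missing:
        raise KeyError(
            f"{v.variant_id}: carrier sample(s) absent from matrix: {missing}"
        )
    return float(zm.loc[gene_id, list(v.carriers)].mean())


def variant_z_table(
    variants: list[VariantRecord],
    zm: pd.DataFrame,
    gene_of: dict[str, str],
) -> pd.DataFrame:
    """Per-(variant, gene) average carrier z-scores. ``gene_of`` maps
    variant_id to the affected gene (one row per pair)."""
    rows = []
    for v in variants:
        g = gene_of.get(v.variant_id)
        if g is None or g not in zm.index or not v.carriers:
            continue
        rows.append(
            {
                "variant_id": v.variant_id,
                "gene_id": g,
                "n_carriers": len(v.carriers),
                "mean_carrier_z": variant_expression_z(v, zm, g),
            }
        )
    return pd.DataFrame(rows, columns=["variant_id", "gene_id", "n_carriers", "mean_carrier_z"])


def compare_groups(
    z_a, z_b, alternative: str = "less", exact_bound: int = EXACT_TEST_BOUND
) -> float:
    """One-sided Wilcoxon rank-sum p-value comparing two z-score groups.

    ``alternative='less'`` tests whether group A is stochastically smaller
    than group B. Exact enumeration for small groups, normal approximation
    with tie correction otherwise.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.size == 0 or z_b.size == 0:
        raise ValueError("both groups must be nonempty")
    method = "exact" if max(z_a.size, z_b.size) <= exact_bound else "asymptotic"
    if method == "exact" and (len(np.unique(np.r_[z_a, z_b])) < z_a.size + z_b.size):
        method = "asymptotic"  # exact enumeration is tie-free only
    res = mannwhitneyu(z_a, z_b, alternative=alternative, method=method)
    return float(res.pvalue)


def score_expression_quintiles(
    score_rank_pct, variant_z, n_bins: int = 5
) -> tuple[pd.DataFrame, float]:
    """Score distribution within equal-count bins of carrier z-scores.

    Bin 1 holds the strongest expression decrease. Returns the per-bin
    summary and the Spearman correlation between z and score rank percentile
    (positive when stronger decrease pairs with more-pathogenic rank).
    """
    score_rank_pct = np.asarray(score_rank_pct, dtype=float)
    variant_z = np.asarray(variant_z, dtype=float)
    if score_rank_pct.size != variant_z.size or variant_z.size < n_bins:
        raise ValueError(f"need >= {n_bins} paired observations")
    bins = pd.qcut(variant_z, q=n_bins, labels=False, duplicates="drop") + 1
    df = pd.DataFrame({"bin": bins, "z": variant_z, "rank_pct": score_rank_pct})
    summary = (
        df.groupby("bin")
        .agg(
            n=("z", "size"),
            z_lo=("z", "min"),
            z_hi=("z", "max"),
            median_rank_pct=("rank_pct", "median"),
            mean_rank_pct=("rank_pct", "mean"),
        )
        .reset_index()
    )
    rho = float(spearmanr(variant_z, score_rank_pct).statistic)
    return summary, rho
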