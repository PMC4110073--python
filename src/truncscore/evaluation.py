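"""Benchmarking and population-genetics statistics.

The central benchmark mirrors repeated random-subsampling validation: many
75/25 train/validation splits of a labelled feature matrix, classifier refit
per split, and a single ROC computed from the pooled held-out scores. A
column-wise shuffling randomization destroys the feature-label coupling as a
negative control. Supporting statistics: Mann-Whitney AUC with half tie
credit, strict-count rank percentiles, product combination with gene-based
scores, the Hardy-Weinberg exact conditional test, logistic MAF-trend
regression with a heterogeneity test, and bootstrap Spearman correlation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, gammaln
from scipy.stats import norm, rankdata, spearmanr

from . import classifier as nb

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    iterations: int
    seed: int | None = None
    redrawn_splits: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: fraction of (positive, negative) pairs ranked
    correctly, ties credited one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # midranks handle ties
    r_pos = np.sum(ranks[labels == 1])
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve with one operating point per distinct score (descending
    threshold sweep), anchored at (0,0) and (1,1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    n_pos, n_neg = tp[-1], fp[-1]
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    return fpr, tpr


def _pooled_roc(scores, labels, iterations, seed, redrawn) -> ROCResult:
    fpr, tpr = roc_curve(scores, labels)
    labels = np.asarray(labels, dtype=int)
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        auc=float(np.trapezoid(tpr, fpr)),
        n_pos=int(np.sum(labels == 1)),
        n_neg=int(np.sum(labels == 0)),
        iterations=iterations,
        seed=seed,
        redrawn_splits=redrawn,
    )


def roc_subsample(
    X,
    c,
    train_frac: float = 0.75,
    iters: int = 10000,
    seed: int = 0,
    stratified: bool = False,
    fit_kwargs: dict | None = None,
    shuffle_columns: bool = False,
    shuffle_labels: bool = False,
    max_redraws: int = 1000,
) -> ROCResult:
    """Repeated random-subsampling validation.

    Per iteration: random 75/25 split, naïve Bayes refit on the training
    portion (empirical prior), held-out rows scored. All held-out
    (score, label) pairs pooled across iterations into a single ROC/AUC.
    Unstratified splits that leave a training class empty are redrawn and
    counted; a ``stratified`` option splits within each class instead.

    With ``shuffle_columns`` every feature column is independently permuted
    across rows at the start of each iteration (randomization control);
    ``shuffle_labels`` instead permutes the label vector once per iteration
    (label-permutation null). A single fixed permutation would not suffice
    for either null: train and validation rows come from the same finite
    dataset and share its spurious feature-label correlation.
    """
    X = np.asarray(X, dtype=float)
    c = np.asarray(c, dtype=int)
    if iters < 1:
        raise ValueError("iters must be >= 1")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    n_train = int(round(train_frac * n))
    if not (0 < n_train < n):
        raise ValueError("train_frac leaves an empty split")
    fit_kwargs = fit_kwargs or {}

    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    redrawn = 0
    for _ in range(iters):
        Xi, ci = X, c
        if shuffle_columns:
            Xi = np.column_stack(
                [X[rng.permutation(n), k] for k in range(X.shape[1])]
            )
        if shuffle_labels:
            ci = c[rng.permutation(n)]
        if stratified:
            train_idx = []
            for cls in (0, 1):
                idx = np.flatnonzero(ci == cls)
                k = int(round(train_frac * idx.size))
                k = min(max(k, 1), idx.size - 1)
                train_idx.append(rng.choice(idx, size=k, replace=False))
            train = np.zeros(n, dtype=bool)
            train[np.concatenate(train_idx)] = True
        else:
            for _attempt in range(max_redraws):
                perm = rng.permutation(n)
                train = np.zeros(n, dtype=bool)
                train[perm[:n_train]] = True
                if len(np.unique(ci[train])) == 2 and np.all(
                    np.bincount(ci[train], minlength=2) >= 2
                ):
                    break
                redrawn += 1
            else:
                raise RuntimeError("could not draw a split with both classes")
        ts = nb.TrainingSet(
            Xi[train], ci[train],
            feature_names=tuple(f"f{k}" for k in range(X.shape[1])),
            feature_kinds=_infer_kinds(X),
        )
        params = nb.fit(ts, **fit_kwargs)
        pooled_scores.append(nb.posterior(Xi[~train], params))
        pooled_labels.append(ci[~train])
    if redrawn:
        logger.info("redrew %d splits that left a training class empty", redrawn)
    return _pooled_roc(
        np.concatenate(pooled_scores), np.concatenate(pooled_labels),
        iters, seed, redrawn,
    )


def _infer_kinds(X: np.ndarray) -> tuple[str, ...]:
    """A column holding only 0/1 is modelled as Bernoulli, else Gaussian."""
    kinds = []
    for k in range(X.shape[1]):
        col = X[:, k]
        kinds.append("binary" if np.all((col == 0) | (col == 1)) else "continuous")
    return tuple(kinds)


def randomization_test(
    X, c, train_frac: float = 0.75, iters: int = 10000, seed: int = 0,
    stratified: bool = False, fit_kwargs: dict | None = None,
) -> ROCResult:
    """Column-wise shuffling control: identical to :func:`roc_subsample`
    except that each feature column is independently permuted across rows
    once per iteration before fitting, destroying feature-label coupling."""
    return roc_subsample(
        X, c, train_frac=train_frac, iters=iters, seed=seed,
        stratified=stratified, fit_kwargs=fit_kwargs, shuffle_columns=True,
    )


# ---------------------------------------------------------------------------
# score combination and ranking


def joint_score(sb, gb):
    """Product of the sequence-based and a gene-based probability —
    the joint probability under conditional independence."""
    sb = np.asarray(sb, dtype=float)
    gb = np.asarray(gb, dtype=float)
    for name, arr in (("sequence-based", sb), ("gene-based", gb)):
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError(f"{name} score outside [0, 1]")
    out = sb * gb
    return float(out) if out.ndim == 0 else out


def rvis_to_prob(rvis):
    """Map a raw RVIS value to a pathogenicity probability via the logistic
    of its negation: f(-RVIS) = 1/(1 + exp(RVIS))."""
    out = expit(-np.asarray(rvis, dtype=float))
    return float(out) if out.ndim == 0 else out


def rank_percentile(scores, higher_is_more_pathogenic: bool = True) -> np.ndarray:
    """Percentage of variants scored strictly more pathogenic than each one:
    0 = most pathogenic, ties share a percentile."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    s = scores if higher_is_more_pathogenic else -scores
    # strict count of more-pathogenic variants via descending min-rank
    more = rankdata(-s, method="min") - 1
    return 100.0 * more / s.size


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def _hwe_log_prob(h: int, n_minor: int, n_major: int) -> float:
    """log P(n_het = h) of the exact conditional distribution given the
    allele counts in N = (n_minor + n_major)/2 diploids."""
    n = (n_minor + n_major) // 2
    return (
        gammaln(n + 1) + gammaln(n_minor + 1) + gammaln(n_major + 1)
        - gammaln((n_minor - h) // 2 + 1) - gammaln(h + 1)
        - gammaln((n_major - h) // 2 + 1) - gammaln(2 * n + 1)
        + h * np.log(2.0)
    )


def hwe_heterozygote_distribution(n_minor: int, n_major: int):
    """All possible heterozygote counts and their exact probabilities."""
    hs = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    logp = np.array([_hwe_log_prob(int(h), n_minor, n_major) for h in hs])
    return hs, np.exp(logp)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations as or less probable than the observed one
    (two-sided, as-or-less-probable convention).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("no genotypes")
    n_alt = n_het + 2 * n_hom_alt
    n_ref = n_het + 2 * n_hom_ref
    n_minor, n_major = min(n_alt, n_ref), max(n_alt, n_ref)
    if n_minor == 0:
        return 1.0
    hs, probs = hwe_heterozygote_distribution(n_minor, n_major)
    p_obs = probs[hs == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def filter_hwe(variants, alpha: float = 0.05):
    """Keep variants whose genotype counts are consistent with HWE
    (exact-test p >= alpha). Variants without genotype counts are kept."""
    kept = []
    for v in variants:
        if v.genotype_counts is not None:
            p = hwe_exact_test(*v.genotype_counts)
            if p < alpha:
                logger.info("filtering %s: HWE p=%.3g", v.variant_id, p)
                continue
        kept.append(v)
    return kept


# ---------------------------------------------------------------------------
# MAF-trend regression and heterogeneity


def maf_trend(feature_present, mafs) -> tuple[float, float]:
    """Logistic regression of feature presence on log(MAF).

    Returns the slope and its standard error (Newton/IRLS fit). Raises with
    guidance on perfect separation.
    """
    y = np.asarray(feature_present, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0):
        raise ValueError("MAF must be positive to take logarithms")
    if len(np.unique(mafs)) < 2:
        raise ValueError("need >= 2 distinct MAF values")
    if len(np.unique(y)) < 2:
        raise ValueError("feature must be present in some and absent in other variants")
    Xd = sm.add_constant(np.log(mafs))
    try:
        res = sm.Logit(y, Xd).fit(method="newton", tol=1e-8, disp=False)
    except Exception as err:
        raise ValueError(
            "logistic fit failed (possible perfect separation between feature "
            f"presence and MAF; consider pooling MAF bins): {err}"
        ) from err
    if np.any(~np.isfinite(res.bse)):
        raise ValueError(
            "logistic fit produced non-finite standard errors "
            "(perfect separation between feature presence and MAF)"
        )
    return float(res.params[1]), float(res.bse[1])


def maf_trend_by_class(feature_present, mafs, vclass) -> dict[str, tuple[float, float]]:
    """Per-variant-class slope and standard error of the MAF trend."""
    vclass = np.asarray(vclass)
    out = {}
    for cls in pd.unique(vclass):
        m = vclass == cls
        out[str(cls)] = maf_trend(np.asarray(feature_present)[m], np.asarray(mafs)[m])
    return out


def heterogeneity_test(
    beta_a: float, se_a: float, beta_b: float, se_b: float
) -> tuple[float, float]:
    """Two-sided z test of equality of two independent regression slopes
    (disjoint variant sets, zero covariance)."""
    z = (beta_a - beta_b) / np.hypot(se_a, se_b)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# correlation


def correlate_scores(
    a, b, n_boot: int = 10000, seed: int = 0, ci: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Spearman rank correlation with a paired percentile-bootstrap CI."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho = float(spearmanr(a, b).statistic)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, a.size, size=a.size)
        boots[i] = spearmanr(a[idx], b[idx]).statistic
    lo, hi = np.nanpercentile(boots, [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100])
    return rho, (float(lo), float(hi))
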