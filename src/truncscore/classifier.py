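"""Naïve Bayes posterior probability of pathogenicity.

The model treats the K per-variant sequence features as conditionally
independent given the class (pathogenic = 1, benign = 0). Continuous
features get class-specific means with a single pooled intra-class variance
per feature,

    nu_k = E[(x_ik - mu_{c_i,k})^2]        (plain mean over all N rows),

and binary features get class-specific Bernoulli rates with Laplace
smoothing. The posterior

    P(c=1 | y) = p1 L1(y) / (p1 L1(y) + p0 L0(y))

is evaluated in log space. The ranking induced by the posterior does not
depend on the prior p1 as long as it is shared across variants and positive,
so the default empirical prior is freely overridable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import FeatureVector

#: classifier feature order and likelihood kind
FEATURES: tuple[tuple[str, str], ...] = (
    ("fraction_affected_max", "continuous"),
    ("domain_truncation_max", "continuous"),
    ("n_isoforms", "continuous"),
    ("ratio_isoforms_affected", "continuous"),
    ("principal_truncated", "binary"),
    ("nmd_target", "binary"),
)
FEATURE_NAMES = tuple(name for name, _ in FEATURES)
FEATURE_KINDS = tuple(kind for _, kind in FEATURES)

DEFAULT_VARIANCE_FLOOR = 1e-9
DEFAULT_SMOOTHING = 1.0


@dataclass
class ClassifierParams:
    """Fitted parameters; arrays are aligned with ``feature_names``.

    Continuous entries of theta arrays and binary entries of mu/nu arrays are
    NaN and never consulted.
    """

    feature_names: tuple[str, ...]
    feature_kinds: tuple[str, ...]
    mu1: np.ndarray
    mu0: np.ndarray
    nu: np.ndarray
    theta1: np.ndarray
    theta0: np.ndarray
    p1: float
    variance_floor: float = DEFAULT_VARIANCE_FLOOR
    bernoulli_smoothing: float = DEFAULT_SMOOTHING

    def __post_init__(self) -> None:
        self.mu1 = np.asarray(self.mu1, dtype=float)
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        self.theta1 = np.asarray(self.theta1, dtype=float)
        self.theta0 = np.asarray(self.theta0, dtype=float)
        if not (0.0 < self.p1 < 1.0):
            raise ValueError(f"prior p1={self.p1} outside (0, 1)")
        cont = self.continuous_mask
        if np.any(self.nu[cont] < self.variance_floor):
            raise ValueError("pooled variance below the variance floor")
        binm = ~cont
        for th in (self.theta1, self.theta0):
            if np.any((th[binm] <= 0) | (th[binm] >= 1)):
                raise ValueError("Bernoulli rate outside (0, 1) after smoothing")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def continuous_mask(self) -> np.ndarray:
        return np.array([k == "continuous" for k in self.feature_kinds])

    def swapped(self) -> "ClassifierParams":
        """Parameters with the two classes exchanged (complementary model)."""
        return ClassifierParams(
            self.feature_names, self.feature_kinds,
            mu1=self.mu0, mu0=self.mu1, nu=self.nu,
            theta1=self.theta0, theta0=self.theta1,
            p1=1.0 - self.p1,
            variance_floor=self.variance_floor,
            bernoulli_smoothing=self.bernoulli_smoothing,
        )

    def to_json(self, path: str | None = None) -> str:
        doc = {
            "feature_names": list(self.feature_names),
            "feature_kinds": list(self.feature_kinds),
            "mu1": self.mu1.tolist(),
            "mu0": self.mu0.tolist(),
            "nu": self.nu.tolist(),
            "theta1": self.theta1.tolist(),
            "theta0": self.theta0.tolist(),
            "p1": self.p1,
            "variance_floor": self.variance_floor,
            "bernoulli_smoothing": self.bernoulli_smoothing,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "ClassifierParams":
        """Load from a JSON string or a path to a JSON file."""
        if "{" not in source:
            with open(source) as fh:
                source = fh.read()
        doc = json.loads(source)
        return cls(
            feature_names=tuple(doc["feature_names"]),
            feature_kinds=tuple(doc["feature_kinds"]),
            mu1=np.array(doc["mu1"]),
            mu0=np.array(doc["mu0"]),
            nu=np.array(doc["nu"]),
            theta1=np.array(doc["theta1"]),
            theta0=np.array(doc["theta0"]),
            p1=doc["p1"],
            variance_floor=doc["variance_floor"],
            bernoulli_smoothing=doc["bernoulli_smoothing"],
        )


@dataclass
class TrainingSet:
    """N x K feature matrix with binary labels (1 = pathogenic)."""

    X: np.ndarray
    c: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    feature_kinds: tuple[str, ...] = FEATURE_KINDS

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.c = np.asarray(self.c, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.c.shape[0]:
            raise ValueError("X and c are misaligned")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("X width does not match feature_names")
        if not set(np.unique(self.c)) <= {0, 1}:
            raise ValueError("labels must be 0/1")


def impute(fv: FeatureVector) -> np.ndarray:
    """FeatureVector -> complete numeric row in classifier feature order.

    The only missingness the model supports is (i) no domain annotation,
    imputed to zero domain truncation, and (ii) no principal-isoform
    designation, for which the longest isoform already substituted upstream.
    Any NaN elsewhere is an error.
    """
    row = np.array(
        [
            fv.fraction_affected_max,
            0.0 if fv.missing_domain else fv.domain_truncation_max,
            float(fv.n_isoforms),
            fv.ratio_isoforms_affected,
            float(fv.principal_truncated),
            float(fv.nmd_target),
        ]
    )
    if np.any(np.isnan(row)):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(np.isnan(row))]
        raise ValueError(f"unsupported missing value(s) in feature(s) {bad}")
    return row


def feature_frame(fvs: list[FeatureVector]) -> pd.DataFrame:
    """Imputed feature rows for a batch of variants, one row per vector."""
    rows = [impute(fv) for fv in fvs]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.insert(0, "variant_id", [fv.variant_id for fv in fvs])
    df.insert(1, "gene_id", [fv.gene_id for fv in fvs])
    return df


def fit(
    ts: TrainingSet,
    p1: float | str = "empirical",
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    smoothing: float = DEFAULT_SMOOTHING,
) -> ClassifierParams:
    """Maximum-likelihood fit of the class-conditional models.

    Continuous features: class means, single pooled variance vector computed
    as the plain mean of squared deviations from each row's own class mean
    (divisor N). Binary features: Laplace-smoothed class rates. The prior is
    the empirical class-1 fraction unless given explicitly.
    """
    X, c = ts.X, ts.c
    n1 = int(np.sum(c == 1))
    n0 = int(np.sum(c == 0))
    if n1 < 2 or n0 < 2:
        raise ValueError(f"need >= 2 rows per class, got n1={n1}, n0={n0}")

    K = X.shape[1]
    cont = np.array([k == "continuous" for k in ts.feature_kinds])
    mu1 = np.full(K, np.nan)
    mu0 = np.full(K, np.nan)
    nu = np.full(K, np.nan)
    theta1 = np.full(K, np.nan)
    theta0 = np.full(K, np.nan)

    X1, X0 = X[c == 1], X[c == 0]
    mu1[cont] = X1[:, cont].mean(axis=0)
    mu0[cont] = X0[:, cont].mean(axis=0)
    # pooled intra-class variance: mean over ALL rows of squared deviation
    # from the row's own class mean
    dev = np.empty_like(X[:, cont])
    dev[c == 1] = X1[:, cont] - mu1[cont]
    dev[c == 0] = X0[:, cont] - mu0[cont]
    nu[cont] = np.mean(dev**2, axis=0)
    low = nu[cont] < variance_floor
    if np.any(low):
        import logging

        logging.getLogger(__name__).warning(
            "zero/near-zero variance feature(s) floored at %g", variance_floor
        )
        v = nu[cont]
        v[low] = variance_floor
        nu[cont] = v

    binm = ~cont
    theta1[binm] = (X1[:, binm].sum(axis=0) + smoothing) / (n1 + 2 * smoothing)
    theta0[binm] = (X0[:, binm].sum(axis=0) + smoothing) / (n0 + 2 * smoothing)

    if p1 == "empirical":
        p1_val = n1 / (n1 + n0)
    else:
        p1_val = float(p1)

    return ClassifierParams(
        feature_names=tuple(ts.feature_names),
        feature_kinds=tuple(ts.feature_kinds),
        mu1=mu1, mu0=mu0, nu=nu, theta1=theta1, theta0=theta0,
        p1=p1_val, variance_floor=variance_floor, bernoulli_smoothing=smoothing,
    )


def class_log_likelihood(Y: np.ndarray, params: ClassifierParams, cls: int) -> np.ndarray:
    """log L_c(y) per row under the factorized class-conditional model."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != params.n_features:
        raise ValueError(
            f"feature dimension {Y.shape[1]} != model dimension {params.n_features}"
        )
    cont = params.continuous_mask
    mu = params.mu1 if cls == 1 else params.mu0
    th = params.theta1 if cls == 1 else params.theta0
    ll = np.zeros(Y.shape[0])
    if np.any(cont):
        nu = params.nu[cont]
        d = Y[:, cont] - mu[cont]
        ll += np.sum(-0.5 * np.log(2 * np.pi * nu) - d**2 / (2 * nu), axis=1)
    binm = ~cont
    if np.any(binm):
        yb = Y[:, binm]
        if np.any((yb != 0) & (yb != 1)):
            raise ValueError("binary feature with non-0/1 value")
        ll += np.sum(yb * np.log(th[binm]) + (1 - yb) * np.log(1 - th[binm]), axis=1)
    return ll


def posterior(y: np.ndarray, params: ClassifierParams) -> float | np.ndarray:
    """P(pathogenic | y), computed in log space; accepts one row or a batch."""
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    llr = (
        np.log(params.p1) + class_log_likelihood(Y, params, 1)
        - np.log(1.0 - params.p1) - class_log_likelihood(Y, params, 0)
    )
    post = expit(llr)
    return float(post[0]) if single else post


def score_variants(
    rows: pd.DataFrame, params: ClassifierParams, score_column: str = "posterior"
) -> pd.DataFrame:
    """Attach the posterior to a feature table (vectorized, order-preserving).

    ``rows`` must carry the model's feature columns; any identifier columns
    are passed through.
    """
    out = rows.copy()
    if len(rows) == 0:
        out[score_column] = pd.Series(dtype=float)
        return out
    Y = rows[list(params.feature_names)].to_numpy(dtype=float)
    out[score_column] = posterior(Y, params)
    return out
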