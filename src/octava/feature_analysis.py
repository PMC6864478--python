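"""Feature representativity analysis: correlation, PCA, univariate scores.

Answers "could a single biomarker predict VA directly, and which features
carry information?" for a feature table: Pearson correlation of each
feature with the log-scale VA, explained-variance fractions of a PCA on
standardised features, and three univariate relevance scores — an F-test
(with its p-value, reported as the reliability column), a k-NN mutual
information estimate, and an RReliefF-style nearest-neighbour statistic
with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_regression, mutual_info_regression
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .errors import ValidationError
from .image_io import FeatureTable
from .va_model import va_to_log10


@dataclass(frozen=True)
class FeatureReport:
    correlations: pd.DataFrame  # feature, r, defined
    pca_fractions: np.ndarray  # descending, sums to 1
    pca_cumulative: np.ndarray
    scores: pd.DataFrame  # feature, f_score, f_pvalue, mutual_info, relief, relief_pvalue


def _xy(table: FeatureTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    X = table.X
    y = np.asarray(va_to_log10(table.va_decimal), dtype=float)
    return X, y, list(table.layout.names)


def correlate_features(table: FeatureTable) -> pd.DataFrame:
    """Pearson r of every feature against the log10-scale VA.

    Constant columns have no defined correlation and are flagged instead
    of producing NaN.
    """
    X, y, names = _xy(table)
    if len(X) < 3:
        raise ValidationError("need at least 3 rows for correlation")
    rows = []
    for j, name in enumerate(names):
        x = X[:, j]
        if x.std() == 0 or y.std() == 0:
            rows.append({"feature": name, "r": np.nan, "defined": False})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"feature": name, "r": r, "defined": True})
    return pd.DataFrame(rows)


def pca_variance(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Explained-variance fractions (descending) and their cumulative sum.

    Features are standardised first, so this is the eigen-spectrum of the
    feature correlation matrix; trailing zero fractions appear for
    rank-deficient tables.
    """
    X = table.X
    if len(X) < 2:
        raise ValidationError("need at least 2 rows for PCA")
    Xs = StandardScaler().fit_transform(X)
    pca = PCA()
    pca.fit(Xs)
    fractions = pca.explained_variance_ratio_
    # pad with zeros when n_samples-1 < n_features bounds the rank
    if fractions.size < X.shape[1]:
        fractions = np.concatenate(
            [fractions, np.zeros(X.shape[1] - fractions.size)]
        )
    return fractions, np.cumsum(fractions)


def _relief_scores(Xs: np.ndarray, y: np.ndarray, k: int,
                   neighbors: np.ndarray) -> np.ndarray:
    """RReliefF-style relevance given precomputed neighbour indices.

    For each sample and its k nearest neighbours, a feature is rewarded
    when it differs where the target differs and penalised when it differs
    where the target agrees; the score is the covariance-like difference
    of the two normalised accumulations.
    """
    diff_x = np.abs(Xs[:, None, :] - Xs[neighbors, :])  # n x k x d
    diff_y = np.abs(y[:, None] - y[neighbors])  # n x k
    y_span = diff_y.max() or 1.0
    w_y = diff_y / y_span
    m = diff_x.shape[0] * k
    p_diff_y = w_y.sum() / m
    if p_diff_y in (0.0, 1.0):
        return np.zeros(Xs.shape[2] if Xs.ndim == 3 else Xs.shape[1])
    p_diff_x = diff_x.sum(axis=(0, 1)) / m
    p_both = (diff_x * w_y[:, :, None]).sum(axis=(0, 1)) / m
    # P(diff x | diff y) - P(diff x | same y), RReliefF decomposition
    return p_both / p_diff_y - (p_diff_x - p_both) / (1.0 - p_diff_y)


def score_features(
    table: FeatureTable,
    n_permutations: int = 999,
    k_neighbors: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Three univariate relevance scores per feature.

    Columns: ``f_score``/``f_pvalue`` (univariate regression F-test; the
    p-value is the reliability figure), ``mutual_info`` (k-NN estimator,
    non-negative, no p-value), ``relief``/``relief_pvalue`` (RReliefF-style
    statistic; p-value from ``n_permutations`` target permutations, which
    reuse the fixed feature-space neighbourhoods and are therefore cheap).
    Constant columns score 0 with p-value 1.
    """
    X, y, names = _xy(table)
    n, d = X.shape
    if n < 10:
        raise ValidationError("need at least 10 rows for feature scoring")
    rng = np.random.default_rng(seed)
    constant = X.std(axis=0) == 0

    f_score = np.zeros(d)
    f_pval = np.ones(d)
    if (~constant).any():
        fs, fp = f_regression(X[:, ~constant], y)
        f_score[~constant] = fs
        f_pval[~constant] = fp

    mi = np.zeros(d)
    mi[~constant] = mutual_info_regression(
        X[:, ~constant], y, random_state=seed, n_neighbors=3
    )

    Xs = StandardScaler().fit_transform(np.where(constant, 0.0, X))
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xs)
    neighbors = nn.kneighbors(Xs, return_distance=False)[:, 1:]
    observed = _relief_scores(Xs, y, k, neighbors)
    exceed = np.zeros(d)
    for _ in range(n_permutations):
        perm = _relief_scores(Xs, y[rng.permutation(n)], k, neighbors)
        exceed += perm >= observed
    relief_p = (exceed + 1.0) / (n_permutations + 1.0)
    observed[constant] = 0.0
    relief_p[constant] = 1.0

    return pd.DataFrame(
        {
            "feature": names,
            "f_score": f_score,
            "f_pvalue": f_pval,
            "mutual_info": mi,
            "relief": observed,
            "relief_pvalue": relief_p,
        }
    )


def analyze(table: FeatureTable, n_permutations: int = 999,
            seed: int = 0) -> FeatureReport:
    """Run the full analysis battery on a feature table."""
    fractions, cumulative = pca_variance(table)
    return FeatureReport(
        correlations=correlate_features(table),
        pca_fractions=fractions,
        pca_cumulative=cumulative,
        scores=score_features(table, n_permutations=n_permutations, seed=seed),
    )
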