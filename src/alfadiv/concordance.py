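"""Concordance between genetic and phenotypic structure: Euclidean
distance on allele-frequency profiles, Mahalanobis distance on
standardized traits, and a permutation Mantel test with Spearman rank
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.covariance import LedoitWolf

from .geno import AlleleFrequencyMatrix


@dataclass
class DistanceMatrix:
    labels: list[str]
    D: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.D, self.D.T, atol=1e-8):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.D) > 1e-10) or np.any(self.D < -1e-12):
            raise ValueError("invalid distances (negative or nonzero diagonal)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)


@dataclass
class MantelResult:
    r_obs: float
    p_value: float
    n_permutations: int
    method: str
    seed: int


def genetic_distance(afm: AlleleFrequencyMatrix) -> DistanceMatrix:
    """Euclidean distance between accessions' allele-frequency profiles."""
    if afm.missing_mask.any():
        raise ValueError("missing values present; impute first")
    D = squareform(pdist(afm.values, metric="euclidean"))
    return DistanceMatrix(labels=list(afm.accession_ids), D=D,
                          metric="euclidean_freq")


def phenotypic_distance(
    traits: pd.DataFrame, shrinkage: float | str = "auto"
) -> DistanceMatrix:
    """Mahalanobis distance between accession trait profiles.

    The covariance is the sample covariance of the (standardized)
    traits, optionally shrunk toward a scaled identity:
    ``shrinkage`` in [0, 1] mixes Sigma_hat = (1-a) S + a mu I with
    mu = trace(S)/p; "auto" uses the Ledoit-Wolf analytic shrinkage.
    A high-dimensional panel (p approaching n) needs shrinkage > 0, and
    a numerically singular covariance at shrinkage 0 raises with that
    suggestion.
    """
    X = traits.to_numpy(float)
    n, p = X.shape
    if n <= 2:
        raise ValueError("need more than 2 accessions")
    if shrinkage == "auto":
        cov = LedoitWolf(assume_centered=False).fit(X).covariance_
    else:
        a = float(shrinkage)
        if not 0.0 <= a <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
        S = np.cov(X, rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        mu = np.trace(S) / p
        cov = (1.0 - a) * S + a * mu * np.eye(p)
    try:
        c = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "phenotypic covariance is singular; pass shrinkage > 0 "
            "(or 'auto') to regularize"
        ) from None
    # d(i,j) = || L^{-1} (x_i - x_j) ||_2
    Xw = np.linalg.solve(c, X.T).T
    D = squareform(pdist(Xw, metric="euclidean"))
    return DistanceMatrix(labels=[str(i) for i in traits.index], D=D,
                          metric="mahalanobis_pheno")


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "spearman",
) -> MantelResult:
    """One-sided (greater) permutation Mantel test.

    The statistic is the Spearman rank correlation of the strictly
    upper-triangular entries; the null permutes rows and columns of the
    second matrix jointly.  p = (1 + #{r_perm >= r_obs}) / (1 + n_perm),
    so p >= 1/(n_permutations + 1).
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices have different labels/order")
    n = len(d1.labels)
    if n < 4:
        raise ValueError("need at least 4 accessions")
    if method != "spearman":
        raise ValueError("only method='spearman' is supported")
    iu, ju = np.triu_indices(n, k=1)
    v1 = rankdata(d1.D[iu, ju])
    v1 = (v1 - v1.mean()) / v1.std()

    def corr_with(vals: np.ndarray) -> float:
        r = rankdata(vals)
        sd = r.std()
        if sd == 0:
            return 0.0
        return float(np.mean(v1 * (r - r.mean()) / sd))

    r_obs = corr_with(d2.D[iu, ju])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        vals = d2.D[perm[iu], perm[ju]]
        if corr_with(vals) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(
        r_obs=r_obs, p_value=p, n_permutations=n_permutations,
        method=method, seed=seed,
    )
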