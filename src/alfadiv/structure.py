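"""Phenotypic structure discovery: PCA, k-means with a BIC scan for the
cluster number, and DAPC (discriminant analysis of principal
components) to characterize group separation by trait loadings.

DAPC runs a linear discriminant analysis on retained PC scores and maps
the discriminant axes back through the PC loadings, so each original
trait receives a contribution per axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class ClusterSolution:
    k: int
    assignment: pd.Series            # accession -> cluster label (int)
    bic_by_k: dict[int, float]
    n_pcs_used: int

    def __post_init__(self) -> None:
        best = min(self.bic_by_k, key=lambda k: (self.bic_by_k[k], k))
        if best != self.k:
            raise ValueError("chosen k is not the BIC argmin")


@dataclass
class DapcResult:
    retained_pcs: int
    discriminant_axes: np.ndarray     # (retained_pcs, n_axes), PC-space
    trait_loadings: pd.DataFrame      # trait x axis contributions
    axis_variance_fraction: np.ndarray
    scores: pd.DataFrame              # accession x axis coordinates
    groups: list = field(default_factory=list)


def _canonicalize_signs(loadings: np.ndarray, *companions: np.ndarray):
    """Flip each column so its largest-|.| loading is positive."""
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    out = [loadings * flip]
    out.extend(c * flip for c in companions)
    return out


# ---------------------------------------------------------------------------

def run_pca(
    traits: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a standardized accession x trait matrix.

    Returns (scores, loadings, variance_fractions) with axis signs
    canonicalized (largest-magnitude loading positive) for
    reproducibility.
    """
    X = traits.to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("trait matrix contains non-finite values")
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"n_components > min(n-1, p) = {max_comp}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    load = pca.components_.T                     # p x d
    load, scores = _canonicalize_signs(load, scores)
    axes = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=traits.index, columns=axes),
        pd.DataFrame(load, index=traits.columns, columns=axes),
        pca.explained_variance_ratio_.copy(),
    )


def n_pcs_for_variance(variance_fractions: np.ndarray, target: float = 0.9) -> int:
    """Smallest number of leading PCs explaining >= target variance."""
    cum = np.cumsum(variance_fractions)
    return int(np.searchsorted(cum, target - 1e-12) + 1)


def kmeans_bic_scan(
    scores: pd.DataFrame,
    k_range: range | list[int] = range(1, 11),
    n_restarts: int = 20,
    seed: int = 0,
) -> ClusterSolution:
    """Scan k with restarted k-means; choose k at the minimal BIC.

    BIC(k) = n d ln(WSS_k / (n d)) + k d ln(n), with d the number of
    retained PCs and WSS_k the best within-cluster sum of squares over
    restarts.  Ties break toward smaller k.
    """
    X = scores.to_numpy(float)
    n, d = X.shape
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain positive integers")
    if max(ks) >= n:
        raise ValueError("max k must be < number of accessions")
    rng = np.random.default_rng(seed)
    bic_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        if k == 1:
            wss = float(((X - X.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k, n_init=n_restarts,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X)
            wss = float(km.inertia_)
            labels = km.labels_
        wss = max(wss, 1e-300)
        bic_by_k[k] = n * d * np.log(wss / (n * d)) + k * d * np.log(n)
        labels_by_k[k] = labels
    best = min(bic_by_k, key=lambda k: (round(bic_by_k[k], 12), k))
    return ClusterSolution(
        k=best,
        assignment=pd.Series(labels_by_k[best], index=scores.index,
                             name="cluster"),
        bic_by_k=bic_by_k,
        n_pcs_used=d,
    )


def run_dapc(
    traits: pd.DataFrame,
    assignment: pd.Series,
    retained_pcs: int | None = None,
    n_axes: int | None = None,
    variance_target: float = 0.9,
    shrinkage: float = 1e-6,
) -> DapcResult:
    """DAPC: LDA on retained PC scores of the standardized trait matrix.

    ``retained_pcs`` defaults to the smallest count explaining >= 90%
    of trait variance.  The within-group covariance receives a small
    ridge (``shrinkage`` x mean eigenvalue) for stability with many
    traits.  Axis signs are canonicalized via the trait contributions.
    """
    groups = assignment.reindex(traits.index)
    if groups.isna().any():
        raise ValueError("assignment does not cover all accessions")
    labels = sorted(groups.unique().tolist())
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")

    scores, loadings, var_frac = run_pca(traits)
    if retained_pcs is None:
        retained_pcs = n_pcs_for_variance(var_frac, variance_target)
    retained_pcs = min(retained_pcs, scores.shape[1])
    max_axes = min(g - 1, retained_pcs)
    if n_axes is None:
        n_axes = max_axes
    if n_axes > retained_pcs:
        raise ValueError("n_axes exceeds retained_pcs")
    n_axes = min(n_axes, max_axes)

    X = scores.iloc[:, :retained_pcs].to_numpy(float)
    n, d = X.shape
    grand = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for lab in labels:
        Xg = X[(groups == lab).to_numpy()]
        mg = Xg.mean(axis=0)
        Sw += (Xg - mg).T @ (Xg - mg)
        Sb += len(Xg) * np.outer(mg - grand, mg - grand)
    Sw /= (n - g)
    Sb /= max(g - 1, 1)
    ridge = shrinkage * (np.trace(Sw) / d if np.trace(Sw) > 0 else 1.0)
    Sw += ridge * np.eye(d)
    if shrinkage > 0:
        logger.debug("run_dapc: ridge %.3g applied to within covariance", ridge)

    # generalized eigenproblem Sb a = lambda Sw a via whitening
    L = np.linalg.cholesky(Sw)
    Li = np.linalg.inv(L)
    Mmat = Li @ Sb @ Li.T
    evals, evecs = np.linalg.eigh(Mmat)
    order = np.argsort(evals)[::-1][:n_axes]
    evals = np.clip(evals[order], 0.0, None)
    A = Li.T @ evecs[:, order]          # PC-space discriminant axes (d x n_axes)

    trait_load = loadings.iloc[:, :retained_pcs].to_numpy() @ A  # p x n_axes
    trait_load, A_t, = _canonicalize_signs(trait_load, A)
    A = A_t
    ax_names = [f"LD{i + 1}" for i in range(n_axes)]
    disc_scores = (X - grand) @ A
    total = evals.sum()
    frac = evals / total if total > 0 else np.full(n_axes, 1.0 / n_axes)
    return DapcResult(
        retained_pcs=retained_pcs,
        discriminant_axes=A,
        trait_loadings=pd.DataFrame(trait_load, index=traits.columns,
                                    columns=ax_names),
        axis_variance_fraction=frac,
        scores=pd.DataFrame(disc_scores, index=traits.index, columns=ax_names),
        groups=labels,
    )


def top_traits(dapc: DapcResult, axis: int = 1, top_n: int | None = None
               ) -> pd.Series:
    """Traits ranked by squared contribution to a discriminant axis."""
    name = f"LD{axis}"
    if name not in dapc.trait_loadings.columns:
        raise ValueError(f"axis {axis} out of range")
    sq = dapc.trait_loadings[name] ** 2
    ranked = sq.sort_values(ascending=False, kind="mergesort")
    if top_n is not None:
        ranked = ranked.head(top_n)
    ranked.name = f"squared_contribution_{name}"
    return ranked


def overlay_groups(
    scores: pd.DataFrame, grouping: pd.Series | dict
) -> pd.DataFrame:
    """Join axis coordinates with an external grouping; accessions
    without a label are marked "unassigned"."""
    grouping = pd.Series(grouping)
    out = scores.copy()
    out["group"] = grouping.reindex(scores.index).fillna("unassigned")
    return out
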