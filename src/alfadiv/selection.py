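"""All-relevant trait selection for genetic-group membership: a Pearson
correlation prefilter followed by a shadow-feature (Boruta) wrapper
around a random-forest classifier.

Each Boruta iteration appends a shuffled copy ("shadow") of every
still-undecided trait, fits a random forest on real + shadow features,
and scores a trait a "hit" when its importance exceeds the maximum
shadow importance.  Two-sided binomial tests on the accumulated hit
counts (success probability 0.5), Bonferroni-corrected across the
currently undecided traits, promote traits to confirmed or demote them
to rejected; whatever is undecided at ``max_runs`` stays tentative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

CONFIRMED = "confirmed"
TENTATIVE = "tentative"
REJECTED = "rejected"


@dataclass
class BorutaResult:
    decision: dict[str, str]
    mean_importance: dict[str, float]
    hit_counts: dict[str, int]
    n_iterations_run: int
    alpha: float
    seed: int

    def counts(self) -> dict[str, int]:
        out = {CONFIRMED: 0, TENTATIVE: 0, REJECTED: 0}
        for d in self.decision.values():
            out[d] += 1
        return out


def prefilter_correlated(
    traits: pd.DataFrame, threshold: float = 0.9
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop one member of every trait pair with
    |Pearson r| > threshold.

    Pairs are visited in a deterministic order (descending |r|, ties by
    name); the dropped member is the one with the larger mean absolute
    correlation to all other remaining traits.  Returns (kept trait
    names, table of dropped traits with the partner and |r| that
    triggered the drop).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    corr = traits.corr().abs()
    kept = list(traits.columns)
    dropped: list[dict] = []
    while True:
        sub = corr.loc[kept, kept]
        pairs = []
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                r = sub.at[a, b]
                if r > threshold:
                    pairs.append((r, a, b))
        if not pairs:
            break
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        r, a, b = pairs[0]
        mean_a = sub.loc[a, [c for c in kept if c != a]].mean()
        mean_b = sub.loc[b, [c for c in kept if c != b]].mean()
        victim, partner = (a, b) if mean_a >= mean_b else (b, a)
        kept.remove(victim)
        dropped.append({"trait": victim, "partner": partner, "abs_r": r})
    return kept, pd.DataFrame(dropped, columns=["trait", "partner", "abs_r"])


def boruta_select(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    alpha: float = 0.05,
    max_runs: int = 1000,
    n_trees: int = 500,
    seed: int = 0,
) -> BorutaResult:
    """Shadow-feature selection of traits predicting group membership.

    Parameters follow the canonical procedure: significance level
    ``alpha`` for the Bonferroni-corrected binomial tests and at most
    ``max_runs`` forest iterations.  Importances are the forest's
    impurity-based (Gini) importances.
    """
    y = pd.Series(np.asarray(y), index=X.index) if not isinstance(y, pd.Series) \
        else y.reindex(X.index)
    if y.isna().any():
        raise ValueError("labels do not cover all rows of X")
    if X.isna().any().any():
        raise ValueError("X contains missing values")
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with a single member: {bad}")

    rng = np.random.default_rng(seed)
    features = list(X.columns)
    decision: dict[str, str] = {}
    hits: dict[str, int] = {f: 0 for f in features}
    imp_sums: dict[str, float] = {f: 0.0 for f in features}
    imp_n: dict[str, int] = {f: 0 for f in features}
    Xv = X.to_numpy(float)
    yv = y.to_numpy()
    n_run = 0
    for it in range(1, max_runs + 1):
        undecided = [f for f in features if f not in decision]
        if not undecided:
            break
        n_run = it
        active = [f for f in features
                  if decision.get(f, TENTATIVE) != REJECTED]
        a_idx = [features.index(f) for f in active]
        u_idx = [features.index(f) for f in undecided]
        shadows = Xv[:, u_idx].copy()
        for c in range(shadows.shape[1]):
            rng.shuffle(shadows[:, c])
        design = np.hstack([Xv[:, a_idx], shadows])
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(design, yv)
        imp = rf.feature_importances_
        real_imp = dict(zip(active, imp[: len(active)]))
        shadow_max = imp[len(active):].max() if undecided else 0.0
        for f in active:
            imp_sums[f] += real_imp[f]
            imp_n[f] += 1
        for f in undecided:
            if real_imp[f] > shadow_max:
                hits[f] += 1
        # Bonferroni across currently undecided traits
        m = len(undecided)
        for f in undecided:
            test = binomtest(hits[f], it, 0.5, alternative="two-sided")
            if test.pvalue * m < alpha:
                decision[f] = CONFIRMED if hits[f] > it / 2 else REJECTED
                logger.debug("iteration %d: %s -> %s (hits %d/%d)",
                             it, f, decision[f], hits[f], it)
    for f in features:
        decision.setdefault(f, TENTATIVE)
    mean_imp = {
        f: (imp_sums[f] / imp_n[f]) if imp_n[f] else 0.0 for f in features
    }
    return BorutaResult(
        decision=decision, mean_importance=mean_imp, hit_counts=hits,
        n_iterations_run=n_run, alpha=alpha, seed=seed,
    )


def importance_table(result: BorutaResult) -> pd.DataFrame:
    """Traits ranked by mean importance, with decision and hit counts."""
    df = pd.DataFrame({
        "mean_importance": pd.Series(result.mean_importance),
        "decision": pd.Series(result.decision),
        "hits": pd.Series(result.hit_counts),
    })
    df.index.name = "trait"
    return df.sort_values("mean_importance", ascending=False,
                          kind="mergesort")
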