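"""Per-SNP Nei FST between genetic groups, empirical-null outlier
calling with Benjamini-Hochberg FDR control, and candidate-gene
annotation against GFF3 gene models.

For a pair of groups with allele frequencies p1, p2 at a marker,

    p_bar = (p1 + p2) / 2
    H_T   = 2 p_bar (1 - p_bar)
    H_S   = [2 p1 (1 - p1) + 2 p2 (1 - p2)] / 2
    F_ST  = (H_T - H_S) / H_T          (undefined when H_T = 0)

Because H_T - H_S = (p1 - p2)^2 / 2 identically, F_ST is never
negative.  A single seeded sample of putatively neutral markers builds
the empirical null for *every* pairwise comparison; each marker's
empirical p-value is the (+1/+1 corrected) fraction of null values at
or above its FST, followed by BH correction and a strict q < threshold
outlier call.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .geno import AlleleFrequencyMatrix

logger = logging.getLogger(__name__)


@dataclass
class GroupFrequencies:
    group_labels: list[str]
    freq: np.ndarray                    # group x marker
    group_sizes: dict[str, int]
    marker_ids: list[str]
    marker_map: pd.DataFrame | None = None
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


@dataclass
class FstScanResult:
    pair: tuple[str, str]
    table: pd.DataFrame      # marker, chrom, pos, h_t, h_s, fst, p, q, outlier
    null_markers: np.ndarray | None = None
    threshold: float | None = None

    @property
    def outliers(self) -> pd.DataFrame:
        if "outlier" not in self.table:
            raise ValueError("outliers not called yet")
        return self.table[self.table["outlier"].fillna(False)]


@dataclass
class CandidateGeneHit:
    marker: str
    chrom: str
    position: int
    gene_id: str
    relation: str            # inside | upstream_within_window | downstream...
    distance: int


# ---------------------------------------------------------------------------
# Group frequencies and Nei FST
# ---------------------------------------------------------------------------

def group_frequencies(
    afm: AlleleFrequencyMatrix,
    grouping: dict[str, str] | pd.Series,
    min_group_size: int = 3,
    weights: pd.Series | None = None,
) -> GroupFrequencies:
    """Per-group mean allele frequencies (unweighted accession mean).

    Groups with fewer than ``min_group_size`` accessions are excluded
    (logged, recorded in ``excluded``); fewer than 2 surviving groups is
    an error.  ``weights`` optionally weights accessions (e.g. by pool
    size).
    """
    if afm.missing_mask.any():
        raise ValueError("missing values present; impute first")
    grouping = pd.Series(dict(grouping)) if not isinstance(grouping, pd.Series) \
        else grouping
    labels = grouping.reindex(afm.accession_ids)
    if labels.isna().any():
        missing = [a for a, l in zip(afm.accession_ids, labels) if pd.isna(l)]
        raise ValueError(f"accessions without group: {missing[:5]}")

    sizes = labels.value_counts().to_dict()
    keep = sorted(g for g, s in sizes.items() if s >= min_group_size)
    excluded = {g: s for g, s in sizes.items() if s < min_group_size}
    for g, s in excluded.items():
        logger.info("group_frequencies: excluding group %s (%d < %d members)",
                    g, s, min_group_size)
    if len(keep) < 2:
        raise ValueError("fewer than 2 groups meet min_group_size")

    rows = []
    for g in keep:
        idx = np.flatnonzero((labels == g).to_numpy())
        if weights is None:
            rows.append(afm.values[idx].mean(axis=0))
        else:
            w = weights.reindex([afm.accession_ids[i] for i in idx]).to_numpy()
            rows.append(np.average(afm.values[idx], axis=0, weights=w))
    return GroupFrequencies(
        group_labels=keep, freq=np.vstack(rows),
        group_sizes={g: sizes[g] for g in keep},
        marker_ids=list(afm.marker_ids), marker_map=afm.marker_map,
        excluded=excluded,
    )


def nei_fst(p1, p2):
    """Nei's two-group FST from allele frequencies.

    Returns (h_t, h_s, fst) elementwise; fst is NaN where h_t = 0
    (monomorphic comparison).  Accepts scalars or arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    pbar = 0.5 * (p1 + p2)
    h_t = 2.0 * pbar * (1.0 - pbar)
    h_s = 0.5 * (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2))
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0),
                       np.nan)
    if fst.ndim == 0:
        return float(h_t), float(h_s), float(fst)
    return h_t, h_s, fst


def fst_all_pairs(gf: GroupFrequencies) -> list[FstScanResult]:
    """Per-marker Nei FST for every unordered pair of groups
    (choose(g, 2) comparisons)."""
    if gf.n_groups < 2:
        raise ValueError("need at least 2 groups")
    base = pd.DataFrame({"marker": gf.marker_ids})
    if gf.marker_map is not None:
        mm = gf.marker_map.reindex(gf.marker_ids)
        base["chrom"] = mm["chrom"].to_numpy()
        base["pos"] = mm["pos"].to_numpy()
    results = []
    for i, j in itertools.combinations(range(gf.n_groups), 2):
        h_t, h_s, fst = nei_fst(gf.freq[i], gf.freq[j])
        tab = base.copy()
        tab["h_t"] = h_t
        tab["h_s"] = h_s
        tab["fst"] = fst
        results.append(FstScanResult(
            pair=(gf.group_labels[i], gf.group_labels[j]), table=tab,
        ))
    return results


# ---------------------------------------------------------------------------
# Empirical null, p-values, FDR
# ---------------------------------------------------------------------------

def sample_neutral_markers(
    n_markers: int, neutral: int | np.ndarray | list, seed: int = 0
) -> np.ndarray:
    """Resolve the neutral-marker specification to sorted indices.

    An integer draws a single uniform random sample of that size
    (seeded) — the same set is reused for every pairwise comparison; an
    explicit index list is passed through.
    """
    if isinstance(neutral, (int, np.integer)):
        if not 0 < neutral <= n_markers:
            raise ValueError("neutral sample size out of range")
        rng = np.random.default_rng(seed)
        return np.sort(rng.choice(n_markers, size=int(neutral), replace=False))
    idx = np.sort(np.asarray(neutral, dtype=int))
    if idx.size == 0:
        raise ValueError("empty neutral marker set")
    if idx.min() < 0 or idx.max() >= n_markers:
        raise ValueError("neutral marker index out of range")
    return idx


def build_empirical_null(
    fst_values: np.ndarray, neutral_idx: np.ndarray
) -> np.ndarray:
    """Null FST multiset: this comparison's values at the neutral markers
    (undefined FSTs dropped)."""
    null = np.asarray(fst_values, dtype=float)[neutral_idx]
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise ValueError("neutral set contains no defined FST values")
    return null


def empirical_pvalues(fst_values: np.ndarray, null: np.ndarray) -> np.ndarray:
    """p = (1 + #{null >= fst}) / (1 + |null|); NaN FST -> NaN p."""
    null = np.sort(np.asarray(null, dtype=float))
    fst = np.asarray(fst_values, dtype=float)
    out = np.full(fst.shape, np.nan)
    ok = np.isfinite(fst)
    # number of null values >= x, with ties counted (conservative)
    ge = null.size - np.searchsorted(null, fst[ok], side="left")
    out[ok] = (1.0 + ge) / (1.0 + null.size)
    return out


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p propagates to NaN q."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if np.any((p[ok] <= 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_outliers(qvalues: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Strictly q < threshold; NaN q is never an outlier."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    q = np.asarray(qvalues, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(q), q < threshold, False).astype(bool)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gene_models(gff_path, feature_type: str = "gene",
                     id_attribute: str = "ID") -> pd.DataFrame:
    """Load gene intervals (1-based inclusive) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get(id_attribute, [feat.id])[0]
        rows.append({"gene_id": gid, "chrom": feat.seqid,
                     "start": feat.start, "end": feat.end,
                     "strand": feat.strand})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand"])


def annotate_outliers(
    outlier_table: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 500,
) -> pd.DataFrame:
    """Intersect outlier SNPs with gene intervals plus a flanking window.

    ``outlier_table`` needs columns marker, chrom, pos (1-based);
    ``genes`` needs gene_id, chrom, start, end (1-based inclusive,
    GFF3 convention).  A SNP hits a gene when its position lies inside
    [start, end] (relation "inside", distance 0) or within ``window``
    bp of either end (relation "upstream_within_window" when the SNP is
    left of the start, "downstream_within_window" right of the end —
    orientation is genomic, not strand-relative).  A SNP can hit
    several genes.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for _, g in genes.iterrows():
        t = trees.setdefault(str(g["chrom"]), IntervalTree())
        # pad by window; half-open tree interval over 1-based inclusive coords
        t.addi(int(g["start"]) - window, int(g["end"]) + window + 1,
               (g["gene_id"], int(g["start"]), int(g["end"])))

    snp_chroms = set(outlier_table["chrom"].dropna().astype(str))
    unmatched = snp_chroms - set(trees)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} SNP chromosome(s) absent from the annotation: "
            f"{sorted(unmatched)[:5]}", stacklevel=2,
        )

    hits = []
    for _, row in outlier_table.iterrows():
        chrom = str(row["chrom"])
        if chrom not in trees or pd.isna(row["pos"]):
            continue
        pos = int(row["pos"])
        for iv in trees[chrom][pos]:
            gid, start, end = iv.data
            if start <= pos <= end:
                relation, dist = "inside", 0
            elif pos < start:
                relation, dist = "upstream_within_window", start - pos
            else:
                relation, dist = "downstream_within_window", pos - end
            hits.append({"marker": row["marker"], "chrom": chrom,
                         "pos": pos, "gene_id": gid, "relation": relation,
                         "distance": dist})
    return pd.DataFrame(
        hits, columns=["marker", "chrom", "pos", "gene_id", "relation",
                       "distance"],
    )


def write_outlier_bed(outlier_table: pd.DataFrame, path) -> None:
    """Outlier SNPs as BED (0-based half-open)."""
    tab = outlier_table.dropna(subset=["pos"])
    with open(path, "w") as fh:
        for _, r in tab.iterrows():
            pos = int(r["pos"])
            fh.write(f"{r['chrom']}\t{pos - 1}\t{pos}\t{r['marker']}\n")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def scan(
    afm: AlleleFrequencyMatrix,
    grouping: dict[str, str] | pd.Series,
    neutral: int | np.ndarray | list = 5000,
    q_threshold: float = 0.05,
    min_group_size: int = 3,
    annotation: pd.DataFrame | None = None,
    window: int = 500,
    seed: int = 0,
) -> dict:
    """Full outlier scan: group frequencies -> all-pairs FST -> shared
    neutral null -> empirical p -> BH q -> outlier calls -> optional
    gene annotation.

    Returns {"pairs": [FstScanResult...], "hits": DataFrame | None,
    "neutral_idx": indices, "summary": DataFrame}.
    """
    gf = group_frequencies(afm, grouping, min_group_size=min_group_size)
    results = fst_all_pairs(gf)
    if isinstance(neutral, (int, np.integer)):
        neutral = min(int(neutral), len(gf.marker_ids))
    neutral_idx = sample_neutral_markers(len(gf.marker_ids), neutral, seed=seed)

    summary_rows = []
    all_outliers = []
    for res in results:
        fst = res.table["fst"].to_numpy()
        null = build_empirical_null(fst, neutral_idx)
        p = empirical_pvalues(fst, null)
        q = bh_fdr(p)
        res.table["p"] = p
        res.table["q"] = q
        res.table["outlier"] = call_outliers(q, q_threshold)
        res.null_markers = neutral_idx
        res.threshold = q_threshold
        n_out = int(res.table["outlier"].sum())
        summary_rows.append({
            "group1": res.pair[0], "group2": res.pair[1],
            "mean_fst": float(np.nanmean(fst)), "n_outliers": n_out,
        })
        if n_out:
            out = res.table[res.table["outlier"]].copy()
            out["pair"] = f"{res.pair[0]}-{res.pair[1]}"
            all_outliers.append(out)

    hits = None
    if annotation is not None and all_outliers:
        combined = (pd.concat(all_outliers)[["marker", "chrom", "pos"]]
                    .drop_duplicates("marker"))
        hits = annotate_outliers(combined, annotation, window=window)
    elif annotation is not None:
        hits = pd.DataFrame(columns=["marker", "chrom", "pos", "gene_id",
                                     "relation", "distance"])
    return {
        "pairs": results,
        "hits": hits,
        "neutral_idx": neutral_idx,
        "summary": pd.DataFrame(summary_rows),
    }
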