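"""Allele-frequency marker data: I/O, filtering, imputation, and the
genomic relationship matrix (GRM).

Genotypes here are *pooled* allele frequencies: each accession is a bulk
of many plants sequenced together, so a marker value is a continuous
frequency in [0, 1] rather than an integer dosage.  The GRM follows the
VanRaden construction adapted to frequencies: the frequency matrix M is
centered at per-marker panel means to give Z, and

    G = Z Z' / ((1/n) * sum_j p_j (1 - p_j))

where p_j is the mean panel frequency of marker j and n is a scaling
constant chosen so the mean diagonal of G is close to 1 (n = 16 for a
tetraploid pool design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"


class EmptyPanelError(ValueError):
    """Raised when filtering removes every marker."""


@dataclass
class AlleleFrequencyMatrix:
    """Accession x marker pooled allele frequencies with missing mask.

    Attributes
    ----------
    values : (n_accessions, n_markers) float array; NaN where missing.
    missing_mask : boolean array, True where the value is missing.
    accession_ids : unique accession labels, row order of ``values``.
    marker_ids : marker labels, column order of ``values``.
    marker_map : DataFrame indexed by marker with columns ``chrom`` and
        ``pos`` (1-based bp).  Markers absent from the map are retained
        but carry ``chrom = None`` / ``pos = NaN`` (position-less).
    """

    values: np.ndarray
    missing_mask: np.ndarray
    accession_ids: list[str]
    marker_ids: list[str]
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if self.values.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValueError("values shape does not match id lists")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("duplicate accession id")
        obs = self.values[~self.missing_mask]
        if obs.size and (np.nanmin(obs) < 0 or np.nanmax(obs) > 1):
            raise ValueError("non-missing allele frequencies outside [0, 1]")

    @property
    def n_accessions(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def marker_means(self) -> np.ndarray:
        """Per-marker mean frequency over non-missing accessions."""
        with np.errstate(invalid="ignore"):
            masked = np.where(self.missing_mask, np.nan, self.values)
            return np.nanmean(masked, axis=0)

    def has_position(self) -> np.ndarray:
        """Boolean per marker: True if the map provides a position."""
        pos = self.marker_map.reindex(self.marker_ids)["pos"]
        return pos.notna().to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.accession_ids, columns=self.marker_ids
        )

    def select_markers(self, keep: np.ndarray) -> "AlleleFrequencyMatrix":
        """Subset to a boolean mask or integer index array of markers."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        marker_ids = [self.marker_ids[i] for i in keep]
        return AlleleFrequencyMatrix(
            values=self.values[:, keep],
            missing_mask=self.missing_mask[:, keep],
            accession_ids=list(self.accession_ids),
            marker_ids=marker_ids,
            marker_map=self.marker_map.reindex(marker_ids),
        )


@dataclass
class GenomicRelationship:
    """Symmetric accession x accession genomic relationship matrix."""

    G: np.ndarray
    n_scale: float
    marker_freqs: np.ndarray
    m: int
    accession_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("G is not symmetric")
        if not np.all(np.isfinite(np.diag(self.G))):
            raise ValueError("non-finite diagonal in G")

    @property
    def n_accessions(self) -> int:
        return self.G.shape[0]

    def mean_diagonal(self) -> float:
        return float(np.mean(np.diag(self.G)))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _empty_map(marker_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series([None] * len(marker_ids), dtype=object),
         "pos": np.full(len(marker_ids), np.nan)},
        index=pd.Index(marker_ids, name="marker"),
    )


def read_marker_map(map_path) -> pd.DataFrame:
    """Read a marker map TSV with columns marker, chrom, pos (1-based)."""
    mm = pd.read_csv(map_path, sep="\t", dtype={0: str, 1: str})
    mm.columns = ["marker", "chrom", "pos"][: len(mm.columns)]
    mm = mm.set_index("marker")
    mm["pos"] = pd.to_numeric(mm["pos"], errors="coerce")
    return mm


def read_frequency_table(path, map_path=None) -> AlleleFrequencyMatrix:
    """Read an accession x marker frequency TSV (missing cells "NA").

    The first column holds accession ids; the header row holds marker
    ids.  Values outside [0, 1] raise with the offending row/column
    named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate accession id: {dup!r}")
    values = df.to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"allele frequency outside [0, 1] at accession {df.index[i]!r}, "
            f"marker {df.columns[j]!r}: {values[i, j]}"
        )
    marker_ids = [str(c) for c in df.columns]
    if map_path is not None:
        mm = read_marker_map(map_path).reindex(marker_ids)
        mm.index.name = "marker"
    else:
        mm = _empty_map(marker_ids)
    return AlleleFrequencyMatrix(
        values=values,
        missing_mask=np.isnan(values),
        accession_ids=[str(i) for i in df.index],
        marker_ids=marker_ids,
        marker_map=mm,
    )


def write_frequency_table(afm: AlleleFrequencyMatrix, path, map_path=None) -> None:
    df = afm.to_frame().copy()
    df[afm.missing_mask] = np.nan
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="accession")
    if map_path is not None:
        afm.marker_map.to_csv(map_path, sep="\t", index_label="marker")


def write_relationship(grm: GenomicRelationship, path) -> None:
    pd.DataFrame(
        grm.G, index=grm.accession_ids, columns=grm.accession_ids
    ).to_csv(path, sep="\t", index_label="accession")


def read_relationship(path) -> GenomicRelationship:
    df = pd.read_csv(path, sep="\t", index_col=0)
    G = df.to_numpy(dtype=float)
    return GenomicRelationship(
        G=G, n_scale=float("nan"), marker_freqs=np.array([]), m=0,
        accession_ids=[str(i) for i in df.index],
    )


# ---------------------------------------------------------------------------
# Filtering / imputation
# ---------------------------------------------------------------------------

def filter_markers(
    afm: AlleleFrequencyMatrix,
    max_missing: float = 0.05,
    maf_min: float = 0.01,
    drop_unmapped: bool = True,
) -> AlleleFrequencyMatrix:
    """Keep markers with missing fraction <= max_missing, panel MAF >=
    maf_min, and (optionally) a known map position.

    MAF for frequency data is min(p_bar, 1 - p_bar) with p_bar the mean
    non-missing frequency.
    """
    if not (0 <= max_missing <= 1 and 0 <= maf_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    miss_frac = afm.missing_mask.mean(axis=0)
    pbar = afm.marker_means()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(pbar, 1.0 - pbar)
    keep = (miss_frac <= max_missing) & (maf >= maf_min) & ~np.isnan(pbar)
    if drop_unmapped:
        keep &= afm.has_position()
    if not keep.any():
        raise EmptyPanelError("all markers removed by filtering")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_markers: dropped %d of %d markers", n_drop, afm.n_markers)
    return afm.select_markers(keep)


def split_marker_sets(
    afm: AlleleFrequencyMatrix,
    max_missing: float = 0.05,
    maf_min: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Split markers into a zero-missing set and a low-missing set.

    Returns (complete_idx, imputable_idx): complete markers have no
    missing value at all; imputable markers pass the standard missing /
    MAF thresholds (superset of the complete set when MAF allows).
    """
    miss_frac = afm.missing_mask.mean(axis=0)
    pbar = afm.marker_means()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(pbar, 1.0 - pbar)
    complete = np.flatnonzero(miss_frac == 0)
    imputable = np.flatnonzero(
        (miss_frac <= max_missing) & (maf >= maf_min) & ~np.isnan(pbar)
    )
    return complete, imputable


def impute_missing(
    afm: AlleleFrequencyMatrix, method: str = "mean"
) -> AlleleFrequencyMatrix:
    """Fill missing cells per marker and clear the mask.

    method="mean" uses the marker's mean non-missing frequency;
    method="maf" uses the minor-allele frequency min(p_bar, 1 - p_bar).
    """
    if method not in {"mean", "maf"}:
        raise ValueError(f"unknown imputation method {method!r}")
    if not afm.missing_mask.any():
        return replace(afm, values=afm.values.copy(),
                       missing_mask=afm.missing_mask.copy())
    all_missing = afm.missing_mask.all(axis=0)
    if all_missing.any():
        j = int(np.flatnonzero(all_missing)[0])
        raise ValueError(f"marker {afm.marker_ids[j]!r} has no observed values")
    pbar = afm.marker_means()
    fill = pbar if method == "mean" else np.minimum(pbar, 1.0 - pbar)
    values = np.where(afm.missing_mask, fill[None, :], afm.values)
    return replace(
        afm, values=values, missing_mask=np.zeros_like(afm.missing_mask)
    )


# ---------------------------------------------------------------------------
# Genomic relationship matrix
# ---------------------------------------------------------------------------

def compute_relationship(
    afm: AlleleFrequencyMatrix,
    n_scale: float = 16.0,
    auto_scale: bool = False,
) -> GenomicRelationship:
    """VanRaden-style GRM from pooled allele frequencies.

    Z = M - P with P the per-marker mean frequency broadcast over
    accessions; G = ZZ' / ((1/n_scale) * sum_j p_j q_j).  With
    auto_scale, n_scale is instead solved so mean(diag(G)) == 1.
    """
    if afm.missing_mask.any():
        raise ValueError("missing values present; impute before computing G")
    if afm.n_markers < 1:
        raise ValueError("need at least one marker")
    M = afm.values
    pbar = M.mean(axis=0)
    sum_pq = float(np.sum(pbar * (1.0 - pbar)))
    if sum_pq == 0.0:
        raise ValueError("all markers monomorphic: sum p(1-p) is zero")
    Z = M - pbar[None, :]
    ZZt = Z @ Z.T
    if auto_scale:
        # mean diag of ZZ'/(sum_pq/n) == 1  =>  n = sum_pq / mean(diag ZZ')
        mean_sq = float(np.mean(np.diag(ZZt)))
        if mean_sq == 0.0:
            raise ValueError("degenerate panel: all accessions at marker means")
        n_scale = sum_pq / mean_sq
        logger.info("compute_relationship: auto n_scale = %.6g", n_scale)
    G = ZZt / (sum_pq / n_scale)
    return GenomicRelationship(
        G=G, n_scale=float(n_scale), marker_freqs=pbar, m=afm.n_markers,
        accession_ids=list(afm.accession_ids),
    )
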