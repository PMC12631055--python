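"""Synthetic pooled-GBS panels, field-trial layouts, spatial surfaces and
phenotypes, with ground truth for recovery tests.

Group allele frequencies follow the Balding-Nichols model: around an
ancestral frequency p, each group draws its frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F*p(1-p).
F is the drift parameter of each group relative to the ancestral pool;
a designated minority of "outlier" loci use a larger F to mimic
divergent selection.  Accession-level pooled frequencies add binomial
sampling noise for a pool of `pool_chromosomes` chromosomes
(4 x plants for a tetraploid bulk).

Phenotypes follow the same mixed model the adjustment stage fits:
y = mu + u(accession) + s(plot) + e, with additive values u drawn
MVN(0, G * sigma_a2) and a smooth spatial field s over the trial grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno import AlleleFrequencyMatrix, GenomicRelationship, _empty_map

#: columns of a trial-layout table
LAYOUT_COLUMNS = ["plot_id", "trial_id", "row", "column", "block", "accession"]

# TrialLayout is a plain DataFrame with LAYOUT_COLUMNS; (trial, row, column)
# is unique and coordinates are 1-based.
TrialLayout = pd.DataFrame


@dataclass
class GroupFreqTruth:
    """Generating frequencies for a structured panel."""

    ancestral_freq: np.ndarray          # (n_markers,)
    group_freq: np.ndarray              # (n_groups, n_markers)
    fst_neutral: float
    outlier_index: np.ndarray           # sorted marker indices
    fst_outlier: float
    group_labels: list[str]

    @property
    def n_markers(self) -> int:
        return self.ancestral_freq.shape[0]

    @property
    def n_groups(self) -> int:
        return self.group_freq.shape[0]

    def neutral_index(self) -> np.ndarray:
        mask = np.ones(self.n_markers, dtype=bool)
        mask[self.outlier_index] = False
        return np.flatnonzero(mask)


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery of the generating process."""

    group_truth: GroupFreqTruth | None
    group_of: dict[str, str]
    breeding_value: pd.DataFrame | None      # accession x trait
    spatial_surface: pd.Series | None        # indexed by plot_id
    variance_components: dict | None         # per trait: (sa2, ss2, se2)
    mu: float | None = None

    def to_json(self, path) -> None:
        """Serialize to a JSON sidecar (arrays as lists)."""
        payload: dict = {"group_of": self.group_of, "mu": self.mu}
        if self.group_truth is not None:
            gt = self.group_truth
            payload["group_truth"] = {
                "ancestral_freq": gt.ancestral_freq.tolist(),
                "group_freq": gt.group_freq.tolist(),
                "fst_neutral": gt.fst_neutral,
                "fst_outlier": gt.fst_outlier,
                "outlier_index": gt.outlier_index.tolist(),
                "group_labels": gt.group_labels,
            }
        if self.breeding_value is not None:
            payload["breeding_value"] = self.breeding_value.to_dict()
        if self.spatial_surface is not None:
            payload["spatial_surface"] = self.spatial_surface.to_dict()
        payload["variance_components"] = self.variance_components
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Group frequencies and panels
# ---------------------------------------------------------------------------

def _bn_draw(rng, p: np.ndarray, F: float, size0: int) -> np.ndarray:
    """Balding-Nichols Beta draw: mean p, variance F p(1-p)."""
    if F <= 0:
        return np.broadcast_to(p, (size0, p.shape[0])).copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b, size=(size0, p.shape[0]))


def simulate_group_frequencies(
    n_groups: int,
    n_markers: int,
    fst_neutral: float,
    outlier_fraction: float = 0.0,
    fst_outlier: float | None = None,
    seed: int = 0,
) -> GroupFreqTruth:
    """Draw group allele frequencies under the Balding-Nichols model.

    Ancestral frequencies are uniform on [0.05, 0.95].  A random
    ceil(outlier_fraction * n_markers) subset of loci diverges with
    fst_outlier instead of fst_neutral.
    """
    if n_groups < 1 or n_markers < 1:
        raise ValueError("n_groups and n_markers must be positive")
    if not 0.0 < fst_neutral < 1.0:
        raise ValueError("fst_neutral must lie in (0, 1)")
    if not 0.0 <= outlier_fraction < 1.0:
        raise ValueError("outlier_fraction must lie in [0, 1)")
    if outlier_fraction > 0:
        if fst_outlier is None or not (fst_neutral < fst_outlier < 1.0):
            raise ValueError("need fst_neutral < fst_outlier < 1")
    elif fst_outlier is None:
        fst_outlier = fst_neutral

    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_markers)
    n_out = int(np.ceil(outlier_fraction * n_markers))
    outlier_index = np.sort(rng.choice(n_markers, size=n_out, replace=False))

    freq = _bn_draw(rng, p, fst_neutral, n_groups)
    if n_out:
        freq[:, outlier_index] = _bn_draw(
            rng, p[outlier_index], fst_outlier, n_groups
        )
    labels = [f"G{i + 1}" for i in range(n_groups)]
    return GroupFreqTruth(
        ancestral_freq=p, group_freq=freq, fst_neutral=float(fst_neutral),
        outlier_index=outlier_index, fst_outlier=float(fst_outlier),
        group_labels=labels,
    )


def simulate_panel(
    group_sizes: dict[str, int],
    truth: GroupFreqTruth,
    pool_chromosomes: int | None = 400,
    seed: int = 0,
) -> tuple[AlleleFrequencyMatrix, dict[str, str]]:
    """Sample accession-level pooled frequencies from group frequencies.

    Each accession's frequency at marker j is
    Binomial(pool_chromosomes, group_freq_j) / pool_chromosomes,
    emulating a sequenced bulk of pool_chromosomes/4 tetraploid plants.
    ``pool_chromosomes=None`` disables pool noise (accession frequency
    equals its group frequency).  Markers are mapped onto a single
    synthetic chromosome at 1 kb spacing.
    """
    if pool_chromosomes is not None and pool_chromosomes < 1:
        raise ValueError("pool_chromosomes must be >= 1")
    unknown = set(group_sizes) - set(truth.group_labels)
    if unknown:
        raise ValueError(f"groups absent from truth: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    rows, acc_ids, group_of = [], [], {}
    for g in truth.group_labels:
        size = group_sizes.get(g, 0)
        gi = truth.group_labels.index(g)
        gf = truth.group_freq[gi]
        for k in range(size):
            if pool_chromosomes is None:
                f = gf.copy()
            else:
                f = rng.binomial(pool_chromosomes, gf) / pool_chromosomes
            acc = f"{g}_a{k + 1}"
            rows.append(f)
            acc_ids.append(acc)
            group_of[acc] = g

    values = np.vstack(rows)
    marker_ids = [f"m{j + 1}" for j in range(truth.n_markers)]
    mm = _empty_map(marker_ids)
    mm["chrom"] = "chr1"
    mm["pos"] = np.arange(1, truth.n_markers + 1) * 1000
    afm = AlleleFrequencyMatrix(
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
        accession_ids=acc_ids,
        marker_ids=marker_ids,
        marker_map=mm,
    )
    return afm, group_of


# ---------------------------------------------------------------------------
# Trial layouts and spatial surfaces
# ---------------------------------------------------------------------------

def simulate_trial(
    n_rows: int,
    n_cols: int,
    accessions: list[str],
    checks_replication: dict[str, int] | None = None,
    seed: int = 0,
    trial_id: str = "T1",
    n_blocks: int = 4,
) -> TrialLayout:
    """Randomized augmented-design layout on an n_rows x n_cols grid.

    Unreplicated entries get one plot each; check accessions listed in
    ``checks_replication`` get the stated number of plots.  Blocks are
    contiguous column bands (incomplete blocks of the augmented design).
    """
    checks_replication = checks_replication or {}
    n_plots = sum(checks_replication.get(a, 1) for a in accessions)
    if n_plots > n_rows * n_cols:
        raise ValueError(
            f"grid {n_rows}x{n_cols} too small for {n_plots} plots"
        )
    rng = np.random.default_rng(seed)
    entries = []
    for a in accessions:
        entries.extend([a] * checks_replication.get(a, 1))
    entries = list(rng.permutation(entries))

    cells = [(r, c) for c in range(1, n_cols + 1) for r in range(1, n_rows + 1)]
    cells = cells[:n_plots]
    band = max(1, int(np.ceil(n_cols / n_blocks)))
    records = []
    for k, ((r, c), acc) in enumerate(zip(cells, entries)):
        records.append({
            "plot_id": f"{trial_id}_p{k + 1:04d}",
            "trial_id": trial_id,
            "row": r,
            "column": c,
            "block": f"B{(c - 1) // band + 1}",
            "accession": acc,
        })
    return pd.DataFrame.from_records(records, columns=LAYOUT_COLUMNS)


def simulate_spatial_surface(
    n_rows: int,
    n_cols: int,
    length_scale: float = 3.0,
    variance: float = 1.0,
    seed: int = 0,
    method: str = "sinusoid",
) -> np.ndarray:
    """Smooth random field on the trial grid, returned as an
    (n_rows, n_cols) array rescaled to the requested empirical variance.

    "sinusoid" sums a few random low-frequency plane waves whose
    wavelengths are >= 2 * length_scale plots; "gp" draws from a
    squared-exponential Gaussian process with the given length scale.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0.0:
        return np.zeros((n_rows, n_cols))
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(
        np.arange(n_rows, dtype=float), np.arange(n_cols, dtype=float),
        indexing="ij",
    )
    if method == "sinusoid":
        surf = np.zeros((n_rows, n_cols))
        max_freq = 1.0 / (2.0 * max(length_scale, 1e-6))
        for _ in range(8):
            f = rng.uniform(0.02, max_freq)
            theta = rng.uniform(0, 2 * np.pi)
            phase = rng.uniform(0, 2 * np.pi)
            kx, ky = f * np.cos(theta), f * np.sin(theta)
            surf += rng.normal() * np.sin(2 * np.pi * (kx * rr + ky * cc) + phase)
    elif method == "gp":
        pts = np.column_stack([rr.ravel(), cc.ravel()])
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        K = np.exp(-0.5 * d2 / length_scale**2) + 1e-8 * np.eye(len(pts))
        surf = (np.linalg.cholesky(K) @ rng.normal(size=len(pts))).reshape(
            n_rows, n_cols
        )
    else:
        raise ValueError(f"unknown surface method {method!r}")
    surf -= surf.mean()
    sd = surf.std()
    if sd == 0.0:
        return np.zeros((n_rows, n_cols))
    return surf * (np.sqrt(variance) / sd)


def surface_at_plots(surface: np.ndarray, layout: TrialLayout) -> pd.Series:
    """Evaluate a grid surface at the layout's plots (1-based coords)."""
    vals = surface[layout["row"].to_numpy() - 1, layout["column"].to_numpy() - 1]
    return pd.Series(vals, index=layout["plot_id"].to_numpy(), name="surface")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    grm: GenomicRelationship | np.ndarray,
    layout: TrialLayout,
    surface: np.ndarray | pd.Series | None,
    var_additive: float = 1.0,
    var_residual: float = 1.0,
    n_traits: int = 1,
    mu: float = 10.0,
    group_effects: dict[str, np.ndarray] | None = None,
    group_of: dict[str, str] | None = None,
    accession_ids: list[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Plot-level phenotypes from the additive + spatial + residual model.

    For each trait, breeding values u ~ MVN(0, G * var_additive); a plot
    observation is mu + u(accession) + s(plot) + N(0, var_residual).
    ``group_effects`` optionally adds a per-group shift vector of length
    n_traits (requires ``group_of``), creating group-differentiated
    traits.  Returns the plot table (layout columns + trait columns) and
    the generating truth.
    """
    if isinstance(grm, GenomicRelationship):
        G = grm.G
        ids = grm.accession_ids
    else:
        G = np.asarray(grm, dtype=float)
        if accession_ids is None:
            raise ValueError("accession_ids required with a bare G array")
        ids = list(accession_ids)
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("G is not symmetric")
    if var_additive < 0 or var_residual < 0:
        raise ValueError("variances must be >= 0")
    missing = set(layout["accession"]) - set(ids)
    if missing:
        raise ValueError(f"layout accessions absent from G: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    n = len(ids)
    if var_additive > 0:
        # sqrt via eigendecomposition; G may be PSD with tiny negatives
        w, V = np.linalg.eigh(G)
        w = np.clip(w, 0.0, None)
        L = V * np.sqrt(w)[None, :]
        U = (L @ rng.normal(size=(n, n_traits))) * np.sqrt(var_additive)
    else:
        U = np.zeros((n, n_traits))

    trait_names = [f"trait{t + 1}" for t in range(n_traits)]
    if group_effects is not None:
        if group_of is None:
            raise ValueError("group_effects requires group_of")
        for i, acc in enumerate(ids):
            shift = np.asarray(group_effects.get(group_of[acc], np.zeros(n_traits)))
            U[i] += shift

    bv = pd.DataFrame(U, index=ids, columns=trait_names)

    if surface is None:
        s_plot = pd.Series(0.0, index=layout["plot_id"].to_numpy())
    elif isinstance(surface, pd.Series):
        s_plot = surface.reindex(layout["plot_id"].to_numpy())
    else:
        s_plot = surface_at_plots(np.asarray(surface), layout)

    rows_u = bv.loc[layout["accession"].to_numpy()].to_numpy()
    eps = rng.normal(scale=np.sqrt(var_residual), size=(len(layout), n_traits)) \
        if var_residual > 0 else np.zeros((len(layout), n_traits))
    Y = mu + rows_u + s_plot.to_numpy()[:, None] + eps

    table = layout.copy()
    for t, name in enumerate(trait_names):
        table[name] = Y[:, t]
    truth = SyntheticTruth(
        group_truth=None,
        group_of=dict(group_of or {}),
        breeding_value=bv,
        spatial_surface=s_plot,
        variance_components={
            name: {"var_additive": var_additive, "var_spatial": float(np.var(s_plot)),
                   "var_residual": var_residual}
            for name in trait_names
        },
        mu=mu,
    )
    return table, truth
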