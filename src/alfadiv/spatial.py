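"""Spatial adjustment of field-trial phenotypes by genomic GBLUP with a
tensor-product B-spline surface.

Per trait and trial the model is

    y = mu * 1 + Z u + W s + e
    u ~ N(0, G sa2),   s ~ N(0, S ss2),   e ~ N(0, I se2)

where Z is the plot-to-accession incidence matrix, W the tensor product
of row-wise and column-wise B-spline bases evaluated at plot
coordinates, and S the covariance structure of the random knot effects
(identity by default, separable AR(1) optionally).  Variance components
are estimated by REML with the intercept profiled out; breeding values
u_hat and knot effects s_hat are the BLUP solutions at the optimum.
The plot-level spatial trend W s_hat is then subtracted from the raw
phenotype, accession means taken over replicates, and traits
standardized (mean 0, sample SD 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .geno import GenomicRelationship

logger = logging.getLogger(__name__)

#: relative objective change below which REML is declared converged
REML_FTOL = 1e-10


@dataclass
class SpatialModelFit:
    """One REML fit of the spatial GBLUP model for a trait x trial."""

    trait: str
    trial: str
    mu: float
    var_additive: float
    var_spatial: float
    var_residual: float
    u_hat: pd.Series            # accession breeding values
    s_hat: np.ndarray           # knot-effect vector
    knots: tuple[int, int]
    loglik: float
    aic: float
    W: np.ndarray               # plot x knot tensor design
    Z_design: np.ndarray        # plot x accession incidence
    S_structure: str
    converged: bool = True

    @property
    def spatial_trend(self) -> np.ndarray:
        """Fitted plot-level spatial effect W s_hat."""
        if self.W.size == 0:
            return np.zeros(self.Z_design.shape[0])
        return self.W @ self.s_hat


# ---------------------------------------------------------------------------
# B-spline bases
# ---------------------------------------------------------------------------

def bspline_basis(
    coordinates: np.ndarray, n_knots: int, degree: int = 3,
    span: tuple[float, float] | None = None,
) -> np.ndarray:
    """Open-uniform (clamped) B-spline basis evaluated at coordinates.

    ``n_knots`` equally spaced breakpoints over the span (default
    [min, max] of the coordinates) give n_knots + degree - 1 basis
    functions; rows sum to 1 (partition of unity).
    """
    x = np.asarray(coordinates, dtype=float)
    if n_knots < 2:
        raise ValueError("need at least 2 knots")
    lo, hi = span if span is not None else (x.min(), x.max())
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("coordinate outside knot span")
    if hi <= lo:
        hi = lo + 1.0
    breaks = np.linspace(lo, hi, n_knots)
    t = np.concatenate([[lo] * degree, breaks, [hi] * degree])
    # clamp right endpoint into the half-open last interval
    xe = np.minimum(x, hi - 1e-9 * (hi - lo))
    B = BSpline.design_matrix(xe, t, degree).toarray()
    return B


def tensor_design(
    row_basis: np.ndarray, col_basis: np.ndarray
) -> np.ndarray:
    """Row-wise Kronecker (face-splitting) product of two plot-evaluated
    bases: W[i, a*nc + b] = row_basis[i, a] * col_basis[i, b]."""
    if row_basis.shape[0] != col_basis.shape[0]:
        raise ValueError("bases evaluated at different numbers of plots")
    n, na = row_basis.shape
    nb = col_basis.shape[1]
    return (row_basis[:, :, None] * col_basis[:, None, :]).reshape(n, na * nb)


def _ar1(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def build_spatial_design(
    layout: pd.DataFrame,
    knots: tuple[int, int],
    degree: int = 3,
    s_structure: str = "identity",
    ar_rho: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Tensor design W for a layout plus the knot covariance S."""
    rb = bspline_basis(layout["row"].to_numpy(float), knots[0], degree)
    cb = bspline_basis(layout["column"].to_numpy(float), knots[1], degree)
    W = tensor_design(rb, cb)
    na, nb = rb.shape[1], cb.shape[1]
    if s_structure == "identity":
        S = np.eye(na * nb)
    elif s_structure == "ar1":
        S = np.kron(_ar1(na, ar_rho), _ar1(nb, ar_rho))
    else:
        raise ValueError(f"unknown S structure {s_structure!r}")
    return W, S


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _reml_neg_loglik(theta, y, kernels):
    """-2x restricted log-likelihood for V = sum_k exp(theta_k) K_k,
    intercept-only fixed effects profiled via the REML projection."""
    n = y.shape[0]
    V = sum(np.exp(t) * K for t, K in zip(theta, kernels))
    try:
        c = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e12
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_y = np.linalg.solve(c.T, np.linalg.solve(c, y))
    ones = np.ones(n)
    Vi_1 = np.linalg.solve(c.T, np.linalg.solve(c, ones))
    xvx = ones @ Vi_1
    mu = (ones @ Vi_y) / xvx
    r = y - mu
    Vi_r = Vi_y - mu * Vi_1
    quad = r @ Vi_r
    return logdetV + np.log(xvx) + quad


def _fit_variances(y, kernels, start, bounds=(-12.0, 12.0)):
    """Minimize the REML criterion over log-variances."""
    res = minimize(
        _reml_neg_loglik, np.asarray(start, float), args=(y, kernels),
        method="L-BFGS-B",
        bounds=[bounds] * len(start),
        options={"ftol": REML_FTOL, "gtol": 1e-9, "maxiter": 500},
    )
    # Nelder-Mead polish: L-BFGS-B on a noisy numeric gradient can stop short
    res2 = minimize(
        _reml_neg_loglik, res.x, args=(y, kernels), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    best = res2 if res2.fun <= res.fun else res
    # accepted optimum never worse than the moment-based start
    f0 = _reml_neg_loglik(np.asarray(start, float), y, kernels)
    assert best.fun <= f0 + 1e-8 * max(1.0, abs(f0))
    return np.exp(best.x), -0.5 * best.fun, bool(best.success or res.success)


def fit_spatial_gblup(
    y: np.ndarray,
    layout: pd.DataFrame,
    grm: GenomicRelationship,
    knots: tuple[int, int] = (6, 8),
    s_structure: str = "identity",
    degree: int = 3,
    ar_rho: float = 0.5,
    trait: str = "trait",
    include_spatial: bool = True,
    ridge: float = 1e-8,
) -> SpatialModelFit:
    """REML fit of y = mu + Zu + Ws + e for one trait in one trial.

    Returns variance components, BLUPs, the restricted log-likelihood
    and AIC = -2 loglik + 2 * (number of variance parameters).
    Rows with non-finite y are dropped.  A singular G is stabilized by
    a ridge jitter on its diagonal (logged).
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if not ok.all():
        layout = layout.loc[ok].reset_index(drop=True)
        y = y[ok]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 plots with data")
    trial = str(layout["trial_id"].iloc[0]) if "trial_id" in layout else "T1"

    acc_ids = list(grm.accession_ids)
    acc_pos = {a: i for i, a in enumerate(acc_ids)}
    try:
        cols = np.array([acc_pos[a] for a in layout["accession"]])
    except KeyError as e:
        raise ValueError(f"plot accession {e.args[0]!r} absent from G") from None
    used = np.unique(cols)
    Z = np.zeros((n, len(used)))
    remap = {g: i for i, g in enumerate(used)}
    Z[np.arange(n), [remap[c] for c in cols]] = 1.0
    G = grm.G[np.ix_(used, used)].copy()
    evals = np.linalg.eigvalsh(G)
    if evals[0] < ridge * max(1.0, evals[-1]):
        jit = ridge * max(1.0, evals[-1]) - min(evals[0], 0.0)
        logger.info("fit_spatial_gblup: ridge jitter %.3g added to G", jit)
        G += jit * np.eye(G.shape[0])
    used_ids = [acc_ids[i] for i in used]

    if include_spatial:
        W, S = build_spatial_design(layout, knots, degree, s_structure, ar_rho)
        n_s = W.shape[1]
    else:
        W = np.zeros((n, 0))
        S = np.zeros((0, 0))
        n_s = 0

    ybar, yvar = float(np.mean(y)), float(np.var(y))
    if yvar < 1e-14:
        # degenerate: constant response, all variances at the zero boundary
        u = pd.Series(0.0, index=used_ids, name=trait)
        fit = SpatialModelFit(
            trait=trait, trial=trial, mu=ybar, var_additive=0.0,
            var_spatial=0.0, var_residual=0.0,
            u_hat=u, s_hat=np.zeros(n_s), knots=knots, loglik=0.0,
            aic=0.0, W=W, Z_design=Z, S_structure=s_structure,
        )
        return fit

    Ka = Z @ G @ Z.T
    kernels = [Ka, np.eye(n)]
    if include_spatial:
        kernels.insert(1, W @ S @ W.T)

    v0 = np.log(max(yvar / len(kernels), 1e-6))
    start = [v0] * len(kernels)
    variances, loglik, converged = _fit_variances(y, kernels, start)
    if not converged:
        logger.warning("REML did not flag convergence for %s/%s", trait, trial)

    if include_spatial:
        sa2, ss2, se2 = variances
    else:
        sa2, se2 = variances
        ss2 = 0.0

    # BLUPs at the optimum: u_hat = sa2 G Z' P y, s_hat = ss2 S W' P y
    V = sum(v * K for v, K in zip(variances, kernels))
    c = np.linalg.cholesky(V)
    solve = lambda b: np.linalg.solve(c.T, np.linalg.solve(c, b))
    ones = np.ones(n)
    Vi_1 = solve(ones)
    mu = float((Vi_1 @ y) / (ones @ Vi_1))
    Py = solve(y - mu * ones)
    u_hat = sa2 * (G @ (Z.T @ Py))
    s_hat = ss2 * (S @ (W.T @ Py)) if include_spatial else np.zeros(0)

    n_var = len(variances)
    aic = -2.0 * loglik + 2.0 * n_var
    return SpatialModelFit(
        trait=trait, trial=trial, mu=mu,
        var_additive=float(sa2), var_spatial=float(ss2),
        var_residual=float(se2),
        u_hat=pd.Series(u_hat, index=used_ids, name=trait),
        s_hat=np.asarray(s_hat), knots=knots if include_spatial else (0, 0),
        loglik=float(loglik), aic=float(aic), W=W, Z_design=Z,
        S_structure=s_structure if include_spatial else "none",
        converged=converged,
    )


def select_knots(
    y: np.ndarray,
    layout: pd.DataFrame,
    grm: GenomicRelationship,
    knot_grid: list[tuple[int, int]],
    s_structure: str = "identity",
    **kwargs,
) -> SpatialModelFit:
    """Grid search over knot counts; return the fit with minimal AIC,
    ties broken toward fewer total knots."""
    if not knot_grid:
        raise ValueError("empty knot grid")
    fits, errors = [], []
    for kn in knot_grid:
        try:
            fits.append(fit_spatial_gblup(
                y, layout, grm, knots=tuple(kn), s_structure=s_structure,
                **kwargs,
            ))
        except Exception as e:  # propagate only if everything fails
            errors.append((kn, e))
            logger.warning("knot grid point %s failed: %s", kn, e)
    if not fits:
        raise RuntimeError(f"all knot-grid fits failed: {errors}")
    fits.sort(key=lambda f: (round(f.aic, 9), f.knots[0] + f.knots[1]))
    return fits[0]


# ---------------------------------------------------------------------------
# Adjustment / aggregation / standardization
# ---------------------------------------------------------------------------

def adjust_phenotype(fit: SpatialModelFit, y: np.ndarray) -> np.ndarray:
    """Remove the fitted plot-level spatial trend: adjusted = y - W s_hat.

    Genetic and residual parts are retained so downstream accession
    means estimate mu + u.
    """
    y = np.asarray(y, dtype=float)
    trend = fit.spatial_trend
    if len(trend) != len(y):
        raise ValueError("y length does not match the fitted design")
    return y - trend


def aggregate_accessions(
    adjusted: np.ndarray, layout: pd.DataFrame
) -> pd.Series:
    """Arithmetic mean of adjusted plot values per accession."""
    s = pd.Series(np.asarray(adjusted, float), index=layout["accession"].to_numpy())
    out = s.groupby(level=0).mean()
    out.index.name = "accession"
    return out


def standardize_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each trait column to mean 0, sample SD 1 (ddof=1).

    Constant (or all-missing) traits are dropped with a warning.
    """
    sd = traits.std(ddof=1)
    degenerate = sd.isna() | (sd == 0.0)
    if degenerate.any():
        dropped = list(traits.columns[degenerate])
        warnings.warn(f"dropping constant traits: {dropped}", stacklevel=2)
        traits = traits.loc[:, ~degenerate]
        sd = sd[~degenerate]
    return (traits - traits.mean()) / sd


def adjust_trial_traits(
    plot_table: pd.DataFrame,
    grm: GenomicRelationship,
    trait_columns: list[str] | None = None,
    knot_grid: list[tuple[int, int]] | None = None,
    knots: tuple[int, int] = (6, 8),
    s_structure: str = "identity",
) -> tuple[pd.DataFrame, dict[str, SpatialModelFit]]:
    """Fit and adjust every trait of one trial table; return the
    accession x trait matrix of adjusted means plus the fits."""
    layout_cols = [c for c in plot_table.columns
                   if c in ("plot_id", "trial_id", "row", "column", "block",
                            "accession")]
    layout = plot_table[layout_cols]
    if trait_columns is None:
        trait_columns = [c for c in plot_table.columns if c not in layout_cols]
    fits: dict[str, SpatialModelFit] = {}
    means: dict[str, pd.Series] = {}
    for tr in trait_columns:
        y = plot_table[tr].to_numpy(float)
        if knot_grid:
            fit = select_knots(y, layout, grm, knot_grid,
                               s_structure=s_structure, trait=tr)
        else:
            fit = fit_spatial_gblup(y, layout, grm, knots=knots,
                                    s_structure=s_structure, trait=tr)
        ok = np.isfinite(y)
        adj = adjust_phenotype(fit, y[ok])
        means[tr] = aggregate_accessions(adj, layout.loc[ok])
        fits[tr] = fit
    return pd.DataFrame(means), fits
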