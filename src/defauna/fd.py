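"""Functional diversity: Gower distances, PCoA, convex-hull richness.

Species are described by a mixed trait table (continuous body mass,
binary feeding-guild and locomotion-mode columns).  The Gower distance
averages range-normalised continuous differences with binary
mismatches, so it is bounded in [0, 1].  PCoA embeds the distance
matrix in Euclidean space (with the Cailliez correction when negative
eigenvalues appear); functional richness (FRic) is the convex-hull
volume of a community in the first m ordination axes, standardised by
the species pool's hull volume.  FD loss is the historical-minus-
contemporary difference in standardised FRic at each site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .idw import species_columns

__all__ = [
    "gower_matrix",
    "PCoAResult",
    "pcoa",
    "select_axes",
    "hull_volume",
    "fric",
    "fd_loss",
    "fd_site_table",
    "glm_fd",
]


def gower_matrix(
    traits: pd.DataFrame,
    continuous: tuple[str, ...] = ("body_mass_g",),
    mass_transform=np.log10,
) -> pd.DataFrame:
    """Gower distance over mixed traits with equal trait weights.

    Continuous traits contribute |x_i − x_j| / range over the pool
    (body mass log10-transformed by default, since masses span orders of
    magnitude); binary traits contribute a 0/1 mismatch.  Constant
    continuous traits are excluded with a warning (their range is 0).
    """
    if len(traits) < 2:
        raise ValueError("Gower distance needs at least two species")
    parts = []
    for col in traits.columns:
        x = traits[col].to_numpy(dtype=float)
        if col in continuous:
            if mass_transform is not None and col == "body_mass_g":
                x = mass_transform(x)
            rng = x.max() - x.min()
            if rng == 0:
                warnings.warn(f"constant continuous trait {col!r} excluded from Gower")
                continue
            parts.append(np.abs(x[:, None] - x[None, :]) / rng)
        else:
            vals = np.unique(x)
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError(f"trait {col!r} is neither continuous nor binary")
            parts.append((x[:, None] != x[None, :]).astype(float))
    if not parts:
        raise ValueError("no usable traits")
    d = np.mean(parts, axis=0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=traits.index, columns=traits.index)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # species × positive axes, scaled by sqrt(eig)
    eigenvalues: np.ndarray  # all, descending
    correction: str  # "none" or "cailliez"
    original_distances: np.ndarray  # condensed, pre-correction

    @property
    def n_positive(self) -> int:
        tol = 1e-8 * max(self.eigenvalues.max(), 1.0)
        return int((self.eigenvalues > tol).sum())

    def r_squared(self, m: int) -> float:
        """Squared correlation of original vs m-axis embedded distances."""
        m = min(m, self.coordinates.shape[1])
        emb = pdist(self.coordinates.to_numpy()[:, :m])
        if self.original_distances.std() == 0 or emb.std() == 0:
            return 1.0 if np.allclose(emb, self.original_distances) else 0.0
        return float(np.corrcoef(self.original_distances, emb)[0, 1] ** 2)


def _double_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest constant c such that d + c (off-diagonal) is Euclidean."""
    n = d.shape[0]
    delta1 = _double_center(d**2)
    delta2 = _double_center(d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    eigs = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(np.max(eigs.real))


def pcoa(d: pd.DataFrame | np.ndarray, negative_tol: float = 1e-8) -> PCoAResult:
    """Principal coordinates analysis with automatic Cailliez correction.

    The distance matrix is double-centred and eigendecomposed;
    coordinates are eigenvectors scaled by the square root of their
    (positive) eigenvalues.  If a meaningfully negative eigenvalue
    appears — the distance is not Euclidean-embeddable, as is common for
    Gower distances — the Cailliez constant is added to all off-diagonal
    distances and the decomposition is redone.
    """
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(len(d))
    dm = np.asarray(d, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    original = squareform(dm, checks=False)

    def decompose(mat):
        eigval, eigvec = np.linalg.eigh(_double_center(mat**2))
        order = np.argsort(eigval)[::-1]
        return eigval[order], eigvec[:, order]

    eigval, eigvec = decompose(dm)
    correction = "none"
    scale = max(abs(eigval).max(), 1.0)
    if eigval.min() < -negative_tol * scale:
        c = _cailliez_constant(dm)
        dm_c = dm + c
        np.fill_diagonal(dm_c, 0.0)
        eigval, eigvec = decompose(dm_c)
        correction = "cailliez"
    tol = negative_tol * max(eigval.max(), 1.0)
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    coord_df = pd.DataFrame(
        coords, index=index, columns=[f"pcoa{i + 1}" for i in range(coords.shape[1])]
    )
    return PCoAResult(coord_df, eigval, correction, original)


def select_axes(result: PCoAResult, quality_threshold: float = 0.75) -> int:
    """Smallest axis count m whose embedding quality R²(m) exceeds the threshold.

    Follows the dbFD-style convention of keeping the number of ordination
    axes that represent the trait space well (the analysis default is
    m = 4 when the quality rule yields it).  If the threshold is not
    reachable the maximum number of positive axes is returned with a
    warning.
    """
    if result.n_positive < 1:
        raise ValueError("no positive PCoA axes")
    for m in range(1, result.n_positive + 1):
        if result.r_squared(m) > quality_threshold:
            return m
    warnings.warn(
        f"embedding quality never exceeds {quality_threshold}; "
        f"using all {result.n_positive} positive axes"
    )
    return result.n_positive


def hull_volume(points: np.ndarray) -> float:
    """Convex hull volume (area in 2-D, length in 1-D); 0 if degenerate."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ndim = pts.shape[1]
    if ndim > 4:
        raise ValueError("hull volumes supported for at most 4 dimensions")
    if ndim == 0 or pts.shape[0] <= ndim:
        return 0.0
    if ndim == 1:
        return float(pts.max() - pts.min())
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return 0.0  # affinely degenerate community


@dataclass
class FricEntry:
    raw: float
    standardized: float
    n_species: int
    n_axes_used: int
    degenerate: bool
    reduced_dimensionality: bool


def fric(
    community: list[str],
    coordinates: pd.DataFrame,
    m: int,
) -> FricEntry:
    """Functional richness of a community in the first m PCoA axes.

    The raw value is the community's convex-hull volume; the
    standardised value divides by the pool hull volume in the same axes,
    so a community equal to the pool scores 1.  Communities with
    richness ≤ m are measured in the first (richness − 1) axes (hull
    volume in the full m axes would be identically zero) and
    standardised against the pool in that same subspace, with a flag.
    """
    unknown = [s for s in community if s not in coordinates.index]
    if unknown:
        raise KeyError(f"community species not in pool: {unknown}")
    n = len(community)
    if m < 1:
        raise ValueError("m must be at least 1")
    if m > 4:
        raise ValueError("FRic supported for at most 4 axes")
    m = min(m, coordinates.shape[1])
    if n < 2:
        return FricEntry(0.0, 0.0, n, 0, True, False)
    reduced = n <= m
    m_used = min(m, n - 1)
    pts = coordinates.loc[community].to_numpy()[:, :m_used]
    pool_pts = coordinates.to_numpy()[:, :m_used]
    raw = hull_volume(pts)
    pool_vol = hull_volume(pool_pts)
    std = raw / pool_vol if pool_vol > 0 else 0.0
    return FricEntry(raw, std, n, m_used, raw == 0.0, reduced)


def fd_loss(
    historical: list[str],
    contemporary: list[str],
    coordinates: pd.DataFrame,
    m: int,
) -> tuple[float, FricEntry, FricEntry]:
    """Standardised FRic(historical) − FRic(contemporary) for one site."""
    h = fric(historical, coordinates, m)
    c = fric(contemporary, coordinates, m)
    return h.standardized - c.standardized, h, c


def fd_site_table(
    historical: pd.DataFrame,
    contemporary: pd.DataFrame,
    traits: pd.DataFrame,
    quality_threshold: float = 0.75,
    m_cap: int = 4,
) -> tuple[pd.DataFrame, PCoAResult, int]:
    """Per-site FD for both periods from raw tables (full FD workflow).

    Computes Gower → PCoA → axis selection (capped at ``m_cap``) on the
    pool, then hull-based FRic per site and period.  Site tables must
    share the ``site_id`` column and species columns.
    """
    d = gower_matrix(traits)
    res = pcoa(d)
    m = min(select_axes(res, quality_threshold), m_cap, res.n_positive)
    sp_cols = [c for c in species_columns(contemporary) if c in traits.index]
    hist = historical.set_index("site_id")
    rows = []
    for _, row in contemporary.iterrows():
        site = row["site_id"]
        comm_c = [s for s in sp_cols if row[s] > 0]
        comm_h = [s for s in sp_cols if hist.loc[site, s] > 0]
        loss, fh, fc = fd_loss(comm_h, comm_c, res.coordinates, m)
        rows.append(
            {
                "site_id": site,
                "fric_raw_hist": fh.raw,
                "fric_std_hist": fh.standardized,
                "fric_raw_cont": fc.raw,
                "fric_std_cont": fc.standardized,
                "fd_loss": loss,
                "richness_hist": fh.n_species,
                "richness_cont": fc.n_species,
                "reduced_axes": fh.reduced_dimensionality or fc.reduced_dimensionality,
            }
        )
    table = pd.DataFrame(rows)
    n_neg = int((table["fd_loss"] < 0).sum())
    if n_neg:
        warnings.warn(f"{n_neg} site(s) show negative FD loss (commission)")
    return table, res, m


def glm_fd(
    fd_loss_values: pd.Series, covariates: pd.DataFrame
) -> tuple[pd.DataFrame, "sm.regression.linear_model.RegressionResultsWrapper"]:
    """Gaussian identity-link GLM (OLS) of FD loss on driver covariates.

    Returns a coefficient table (estimate, std error, t, p) and the
    fitted statsmodels results object for diagnostics.  Rank-deficient
    designs are rejected with the collinear columns named.
    """
    X = covariates.astype(float)
    y = np.asarray(fd_loss_values, dtype=float)
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need more sites than predictors")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = corr.stack().sort_values(ascending=False)
        raise ValueError(
            f"rank-deficient design; most collinear columns: {pairs.index[0]}"
        )
    fit = sm.OLS(y, design).fit()
    table = pd.DataFrame(
        {
            "term": design.columns,
            "estimate": fit.params.to_numpy(),
            "std": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return table, fit
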