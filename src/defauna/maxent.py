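"""Presence-background maximum-entropy species distribution models.

The model is the classic Gibbs form: with features ``f`` over grid
cells, suitability is ``p(cell) ∝ exp(λ·f(cell))`` over the background,
and the weights λ maximise the L1-penalised log-likelihood

    L(λ) = mean_presence(λ·f) − log Σ_background exp(λ·f) − Σ_j β_j|λ_j|

by cyclic coordinate ascent with a soft-thresholded Newton step and
backtracking, so the objective is non-decreasing at every update.  At a
β=0 optimum each feature's expectation under the model matches its
presence mean (the maximum-entropy constraint); with β>0 the mismatch is
bounded by β (KKT condition of the lasso).

Model evaluation follows the common SDM protocol: replicated random
presence splits, test AUC against the background, suitabilities averaged
over replicates, binarisation at the candidate threshold that predicts
the smallest area, and cellwise stacking of the binary maps into a
species-richness surface.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax
from scipy.stats import rankdata

from .raster import EnvStack, RasterGrid

__all__ = [
    "prescreen_predictors",
    "FeatureMatrix",
    "build_features",
    "MaxentSDM",
    "MaxentResults",
    "fit_maxent",
    "auc_score",
    "EvalReport",
    "evaluate_replicates",
    "ThresholdReport",
    "select_threshold",
    "binarize",
    "stack_richness",
    "run_sdm",
]

DEFAULT_CLASSES = ("linear", "quadratic", "product")
# MaxEnt-like per-feature L1 weight: beta_scale * sd_presence(f)/sqrt(n).
# 0.15 tracks MaxEnt's class-specific default multipliers at n ~ 100.
DEFAULT_BETA_SCALE = 0.15


def prescreen_predictors(env: EnvStack, r_max: float = 0.8) -> list[str]:
    """Greedy collinearity filter on the environmental layers.

    Scanning layers in input order, a layer is dropped iff its Pearson
    correlation (over jointly valid cells) with any already-retained
    layer reaches ``r_max`` in absolute value.  Zero-variance layers are
    excluded with a warning (their correlation is undefined).
    """
    if len(env) == 0:
        raise ValueError("empty environment stack")
    mask = env.common_valid_mask()
    retained: list[str] = []
    kept_vals: list[np.ndarray] = []
    for name in env.names:
        v = env[name].values[mask]
        if v.std() == 0:
            warnings.warn(f"layer {name!r} has zero variance; excluded")
            continue
        collinear = False
        for u in kept_vals:
            r = np.corrcoef(u, v)[0, 1]
            if abs(r) >= r_max:
                collinear = True
                break
        if not collinear:
            retained.append(name)
            kept_vals.append(v)
    return retained


@dataclass
class FeatureMatrix:
    """Expanded, [0,1]-scaled MaxEnt features for background + presences.

    Carries enough provenance (layer names, feature classes, scaling
    bounds) to recompute features on any aligned grid for prediction.
    """

    background: np.ndarray  # (n_background, d)
    presence: np.ndarray  # (n_presence, d)
    names: list[str]
    classes: tuple[str, ...]
    layer_names: list[str]
    scale_min: np.ndarray  # per raw feature, before dropping constants
    scale_max: np.ndarray
    keep: np.ndarray  # raw features kept (non-zero range)
    bg_rows: np.ndarray  # background cell row indices in the template grid
    bg_cols: np.ndarray
    template: RasterGrid

    @property
    def n_features(self) -> int:
        return self.background.shape[1]

    def transform_raw(self, layers: np.ndarray) -> np.ndarray:
        """Expand raw layer columns (n, k) into scaled features (n, d)."""
        cols = [layers[:, i] for i in range(layers.shape[1])]
        feats = _expand(cols, self.classes)
        denom = np.where(
            self.scale_max > self.scale_min, self.scale_max - self.scale_min, 1.0
        )
        scaled = (feats - self.scale_min) / denom
        return scaled[:, self.keep]


def _expand(cols: list[np.ndarray], classes) -> np.ndarray:
    feats = []
    if "linear" in classes:
        feats.extend(cols)
    if "quadratic" in classes:
        feats.extend(c**2 for c in cols)
    if "product" in classes:
        feats.extend(a * b for a, b in itertools.combinations(cols, 2))
    return np.column_stack(feats)


def _feature_names(layer_names, classes) -> list[str]:
    names = []
    if "linear" in classes:
        names.extend(layer_names)
    if "quadratic" in classes:
        names.extend(f"{n}^2" for n in layer_names)
    if "product" in classes:
        names.extend(
            f"{a}*{b}" for a, b in itertools.combinations(layer_names, 2)
        )
    return names


def build_features(
    env: EnvStack,
    presences_xy: np.ndarray,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    max_background: int = 10_000,
    seed: int = 0,
) -> FeatureMatrix:
    """Feature matrix over all valid cells (background) plus presences.

    Presence points snap to the cell containing them; points outside the
    raster extent are dropped with a warning.  Features are scaled to
    [0, 1] by the background min/max; zero-range features are dropped.
    If the background exceeds ``max_background`` cells a seeded uniform
    subsample is taken.
    """
    template = env.template
    mask = env.common_valid_mask()
    rows, cols = np.nonzero(mask)
    if rows.size > max_background:
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(rows.size, size=max_background, replace=False))
        rows, cols = rows[pick], cols[pick]
    layer_cols = [env[n].values[rows, cols] for n in env.names]

    xy = np.atleast_2d(np.asarray(presences_xy, dtype=float))
    inside = template.contains(xy[:, 0], xy[:, 1])
    if not inside.all():
        warnings.warn(f"{(~inside).sum()} presence point(s) outside raster extent dropped")
    xy = xy[inside]
    prow, pcol = template.index_of(xy[:, 0], xy[:, 1])
    valid = mask[prow, pcol]
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} presence point(s) on nodata cells dropped")
    prow, pcol = prow[valid], pcol[valid]
    if prow.size == 0:
        raise ValueError("all presence points were dropped")
    pres_cols = [env[n].values[prow, pcol] for n in env.names]

    bg_raw = _expand(layer_cols, classes)
    pr_raw = _expand(pres_cols, classes)
    fmin = bg_raw.min(axis=0)
    fmax = bg_raw.max(axis=0)
    keep = fmax > fmin
    denom = np.where(keep, fmax - fmin, 1.0)
    names = [n for n, k in zip(_feature_names(env.names, classes), keep) if k]
    return FeatureMatrix(
        background=((bg_raw - fmin) / denom)[:, keep],
        presence=np.clip((pr_raw - fmin) / denom, 0.0, 1.0)[:, keep],
        names=names,
        classes=tuple(classes),
        layer_names=list(env.names),
        scale_min=fmin,
        scale_max=fmax,
        keep=keep,
        bg_rows=rows,
        bg_cols=cols,
        template=template,
    )


class MaxentSDM:
    """Maximum-entropy presence-background model (Model object).

    Parameters
    ----------
    features
        :class:`FeatureMatrix` with background and presence rows.
    presence_index
        Optional subset of presence rows to fit on (defaults to all);
        used by the replicate evaluator for train/test splits.
    beta_scale
        Multiplier on the per-feature L1 penalty
        ``β_j = beta_scale · sd_presence(f_j) / √n_presence``.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        presence_index: np.ndarray | None = None,
        beta_scale: float = DEFAULT_BETA_SCALE,
    ):
        self.features = features
        n_pres_all = features.presence.shape[0]
        if presence_index is None:
            presence_index = np.arange(n_pres_all)
        self.presence_index = np.asarray(presence_index, dtype=int)
        if self.presence_index.size < 1:
            raise ValueError("at least one presence is required")
        if features.background.shape[0] < 2:
            raise ValueError("at least two background cells are required")
        self.beta_scale = beta_scale
        Xp = features.presence[self.presence_index]
        n = Xp.shape[0]
        self.beta = beta_scale * Xp.std(axis=0) / np.sqrt(n)

    def _objective(self, eta_pr_mean, log_z, lam):
        return eta_pr_mean - log_z - float(self.beta @ np.abs(lam))

    def fit(
        self,
        max_iter: int = 10_000,
        tol: float = 1e-8,
        start_params: np.ndarray | None = None,
    ) -> "MaxentResults":
        Xb = self.features.background
        Xp = self.features.presence[self.presence_index]
        if np.isnan(Xb).any() or np.isnan(Xp).any():
            raise ValueError("NaN in feature matrix")
        nb, d = Xb.shape
        pbar = Xp.mean(axis=0)
        if start_params is not None:
            lam = np.asarray(start_params, dtype=float).copy()
            eta_b = Xb @ lam
            eta_p_mean = float(pbar @ lam)
            log_z = logsumexp(eta_b)
        else:
            lam = np.zeros(d)
            eta_b = np.zeros(nb)
            eta_p_mean = 0.0
            log_z = np.log(nb)
        obj = self._objective(eta_p_mean, log_z, lam)
        path = [obj]
        converged = False
        for sweep in range(max_iter):
            # active-set acceleration: most sweeps touch only the nonzero
            # coordinates; a full sweep every few iterations (and at the
            # start) lets new features enter the model
            if sweep % 5 == 0 or sweep < 2:
                coords = range(d)
            else:
                coords = np.nonzero(lam)[0]
            improved = obj
            for j in coords:
                p = softmax(eta_b)
                fj = Xb[:, j]
                ef = float(p @ fj)
                var = float(p @ (fj - ef) ** 2)
                g = pbar[j] - ef
                h = max(var, 1e-12)
                # soft-thresholded Newton proposal for the L1 term
                u = lam[j] + g / h
                t = self.beta[j] / h
                new = np.sign(u) * max(abs(u) - t, 0.0)
                delta = new - lam[j]
                if delta == 0.0:
                    continue
                # backtrack until the true penalised objective does not drop
                for _bt in range(40):
                    cand = lam[j] + delta
                    eta_b_new = eta_b + delta * fj
                    log_z_new = logsumexp(eta_b_new)
                    eta_p_new = eta_p_mean + delta * pbar[j]
                    pen_old = self.beta[j] * abs(lam[j])
                    pen_new = self.beta[j] * abs(cand)
                    new_obj = (
                        eta_p_new - log_z_new - float(self.beta @ np.abs(lam))
                        + pen_old - pen_new
                    )
                    if new_obj >= obj - 1e-13:
                        lam[j] = cand
                        eta_b = eta_b_new
                        eta_p_mean = eta_p_new
                        log_z = log_z_new
                        obj = new_obj
                        break
                    delta *= 0.5
            path.append(obj)
            full_sweep = sweep % 5 == 0 or sweep < 2
            if full_sweep and obj - improved < tol:
                converged = True
                break
        if not converged:
            warnings.warn("maxent fit did not converge within max_iter")
        return MaxentResults(self, lam, np.array(path), converged)


@dataclass
class MaxentResults:
    """Fitted MaxEnt model: weights, convergence path, prediction."""

    model: MaxentSDM
    params: np.ndarray
    objective_path: np.ndarray
    converged: bool

    @property
    def feature_names(self) -> list[str]:
        return self.model.features.names

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params

    def background_probabilities(self) -> np.ndarray:
        return softmax(self.linear_predictor(self.model.features.background))

    def suitability(self, X: np.ndarray | None = None) -> np.ndarray:
        """Gibbs density rescaled to max 1 over the background (raw-rescaled)."""
        eta_b = self.linear_predictor(self.model.features.background)
        ref = logsumexp(eta_b)
        peak = eta_b.max() - ref
        eta = eta_b if X is None else self.linear_predictor(X)
        return np.exp(eta - ref - peak)

    def suitability_raster(self) -> RasterGrid:
        f = self.model.features
        out = np.full(f.template.shape, f.template.nodata)
        out[f.bg_rows, f.bg_cols] = self.suitability()
        return f.template.like(out)

    def kkt_gap(self) -> np.ndarray:
        """Per-feature |presence mean − model expectation| (≤ β at optimum)."""
        p = self.background_probabilities()
        ef = p @ self.model.features.background
        pbar = self.model.features.presence[self.model.presence_index].mean(axis=0)
        return np.abs(pbar - ef)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "lambda": self.params,
                "beta": self.model.beta,
                "kkt_gap": self.kkt_gap(),
            }
        )


def fit_maxent(
    features: FeatureMatrix,
    presence_index: np.ndarray | None = None,
    beta_scale: float = DEFAULT_BETA_SCALE,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> MaxentResults:
    """Functional wrapper: build a :class:`MaxentSDM` and fit it."""
    return MaxentSDM(features, presence_index, beta_scale).fit(max_iter, tol)


def auc_score(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formula.

    Ties between a positive and a negative score count one half.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class EvalReport:
    auc_per_replicate: list[float]
    n_replicates: int
    test_fraction: float

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_replicate))


def evaluate_replicates(
    features: FeatureMatrix,
    n_rep: int = 10,
    test_frac: float = 0.10,
    seed: int = 0,
    beta_scale: float = DEFAULT_BETA_SCALE,
    max_iter: int = 100,
    tol: float = 1e-7,
) -> tuple[EvalReport, RasterGrid]:
    """Replicated random-split evaluation and replicate-averaged suitability.

    Each replicate holds out ``test_frac`` of the presences, fits on the
    rest, and scores test presences against the full background by AUC.
    The returned suitability raster is the mean of the replicates'
    rescaled suitability surfaces.
    """
    n = features.presence.shape[0]
    if n < 2:
        raise ValueError("need at least two presences to form a test split")
    n_test = max(1, int(round(test_frac * n)))
    if n_test >= n:
        raise ValueError("test split leaves no training presences")
    rng = np.random.default_rng(seed)
    aucs = []
    mean_suit = None
    warm = None
    for _ in range(n_rep):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        res = MaxentSDM(features, train_idx, beta_scale).fit(
            max_iter=max_iter, tol=tol, start_params=warm
        )
        warm = res.params
        eta_bg = res.linear_predictor(features.background)
        eta_test = res.linear_predictor(features.presence[test_idx])
        aucs.append(auc_score(eta_test, eta_bg))
        s = res.suitability()
        mean_suit = s if mean_suit is None else mean_suit + s
    mean_suit /= n_rep
    out = np.full(features.template.shape, features.template.nodata)
    out[features.bg_rows, features.bg_cols] = mean_suit
    report = EvalReport(aucs, n_rep, test_frac)
    return report, features.template.like(out)


@dataclass
class ThresholdReport:
    """Candidate binarisation thresholds and the minimum-area selection."""

    candidates: dict[str, float]
    predicted_area: dict[str, int]  # cells ≥ candidate
    selected_rule: str
    selected: float

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "predicted_area_cells": self.predicted_area,
            "selected_rule": self.selected_rule,
            "selected_threshold": self.selected,
        }


def select_threshold(
    suitability: RasterGrid, presences_xy: np.ndarray
) -> ThresholdReport:
    """Four standard training thresholds; pick the smallest predicted area.

    Candidates: minimum training presence; 10th-percentile training
    presence; equal training sensitivity and specificity; maximum
    training sensitivity plus specificity.  Predicted area is the count
    of valid cells at or above the candidate; ties on area resolve to
    the larger threshold (the more conservative map).
    """
    xy = np.atleast_2d(np.asarray(presences_xy, dtype=float))
    inside = suitability.contains(xy[:, 0], xy[:, 1])
    row, col = suitability.index_of(xy[inside, 0], xy[inside, 1])
    s_pres = suitability.values[row, col]
    ok = np.isfinite(s_pres) & (s_pres != suitability.nodata)
    s_pres = np.sort(s_pres[ok])
    if s_pres.size == 0:
        raise ValueError("no presence has a valid suitability")
    s_bg = suitability.valid_values()

    m = s_pres.size
    mtp = float(s_pres[0])
    p10 = float(s_pres[int(np.floor(0.1 * m))])
    # scan unique suitability values for the sensitivity/specificity rules
    taus = np.unique(np.concatenate([s_pres, s_bg]))
    sens = (s_pres[None, :] >= taus[:, None]).mean(axis=1)
    spec = (s_bg[None, :] < taus[:, None]).mean(axis=1)
    ess = float(taus[np.argmin(np.abs(sens - spec))])
    mss = float(taus[np.argmax(sens + spec)])
    candidates = {
        "minimum_training_presence": mtp,
        "tenth_percentile_training_presence": p10,
        "equal_training_sensitivity_specificity": ess,
        "maximum_training_sensitivity_plus_specificity": mss,
    }
    area = {name: int((s_bg >= tau).sum()) for name, tau in candidates.items()}
    # minimal predicted area; ties -> larger threshold value
    best = min(candidates, key=lambda k: (area[k], -candidates[k]))
    return ThresholdReport(candidates, area, best, candidates[best])


def binarize(suitability: RasterGrid, tau: float) -> RasterGrid:
    """Binary range map: 1 iff suitability ≥ τ; nodata propagated."""
    mask = suitability.valid_mask()
    out = np.where(mask, (suitability.values >= tau).astype(float), suitability.nodata)
    return suitability.like(out)


def stack_richness(
    binary_maps: list[RasterGrid], template: RasterGrid | None = None
) -> RasterGrid:
    """Cellwise sum of aligned binary species maps (stacked richness).

    An empty species list yields an all-zero raster when a template is
    supplied (richness of an empty pool), otherwise an error.
    """
    if not binary_maps:
        if template is None:
            raise ValueError("no binary maps to stack and no template given")
        return template.like(np.zeros(template.shape))
    template = binary_maps[0]
    total = np.zeros(template.shape)
    any_valid = np.zeros(template.shape, dtype=bool)
    for bm in binary_maps:
        if not bm.aligned_with(template):
            raise ValueError("binary maps are not aligned")
        mask = bm.valid_mask()
        total += np.where(mask, bm.values, 0.0)
        any_valid |= mask
    out = np.where(any_valid, total, template.nodata)
    return template.like(out)


@dataclass
class SpeciesSDM:
    """Per-species artefacts from the historical-distribution stage."""

    species_id: str
    eval_report: EvalReport
    threshold_report: ThresholdReport
    suitability: RasterGrid
    binary: RasterGrid


def run_sdm(
    occurrences: pd.DataFrame,
    env: EnvStack,
    r_max: float = 0.8,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    n_rep: int = 10,
    test_frac: float = 0.10,
    beta_scale: float = DEFAULT_BETA_SCALE,
    max_iter: int = 100,
    seed: int = 0,
    region_mask: RasterGrid | None = None,
) -> tuple[dict[str, SpeciesSDM], RasterGrid, list[str]]:
    """Fit, evaluate, threshold and stack SDMs for every species.

    ``occurrences`` must have columns ``species, x, y``.  Returns the
    per-species artefacts, the stacked historical richness raster and
    the retained predictor names.  If ``region_mask`` is given, binary
    maps are cropped to it (cells outside become 0) before stacking.
    """
    retained = prescreen_predictors(env, r_max)
    env_sub = env.subset(retained)
    results: dict[str, SpeciesSDM] = {}
    binaries = []
    for k, (sp, group) in enumerate(occurrences.groupby("species", sort=True)):
        xy = group[["x", "y"]].to_numpy()
        feats = build_features(env_sub, xy, classes=classes, seed=seed + k)
        report, suit = evaluate_replicates(
            feats,
            n_rep=n_rep,
            test_frac=test_frac,
            seed=seed + k,
            beta_scale=beta_scale,
            max_iter=max_iter,
        )
        thr = select_threshold(suit, xy)
        binary = binarize(suit, thr.selected)
        if region_mask is not None:
            inside = region_mask.values > 0
            vals = np.where(inside, binary.values, 0.0)
            vals[~binary.valid_mask()] = binary.nodata
            binary = binary.like(vals)
        results[sp] = SpeciesSDM(sp, report, thr, suit, binary)
        binaries.append(binary)
    richness = stack_richness(binaries)
    return results, richness, retained
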