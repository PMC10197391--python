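"""Generalized dissimilarity modeling (GDM).

GDM regresses a bounded pairwise dissimilarity (here pairwise FST) on
environmental differences and geographic distance through a monotone
nonlinear link:

    eta = b0 + sum_k |f_k(x_k, site1) - f_k(x_k, site2)|,   mu = 1 - exp(-eta)

with each partial response f_k a non-negative combination of I-splines
(integrated monotone splines), so every fitted f_k is non-decreasing and the
predicted dissimilarity saturates below 1. Fitting minimizes the
binomial-form deviance for continuous response by iteratively reweighted
least squares with a non-negative least-squares inner step (all
coefficients, including the intercept, constrained >= 0).

The maximum height of f_k (the sum of its coefficients, since each basis
function spans [0, 1]) measures predictor importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import nnls

from .core import PairwiseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ISplineBasis",
    "SitePairTable",
    "GDMModel",
    "build_site_pairs",
    "fit_gdm",
    "percent_deviance_explained",
    "predictor_importance",
]

RESPONSE_EPS = 1e-6   # clamp for d and mu in the deviance
GEO_NAME = "Geographic"


@dataclass
class ISplineBasis:
    """Monotone I-spline basis on quantile knots.

    ``n_splines`` basis functions of spline order 3 (quadratic M-splines
    integrated), knots at evenly spaced quantiles of the observed values
    (min/median/max for the default 3). Each basis function is non-decreasing,
    0 at the predictor minimum and 1 at the maximum; evaluation clamps x to
    the knot span, giving flat extension beyond the observed range.
    """

    knots: np.ndarray
    degree: int = 2

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if len(self.knots) < 2 or np.any(np.diff(self.knots) < 0):
            raise ValueError("knots must be a sorted array of length >= 2")

    @classmethod
    def from_values(cls, values: np.ndarray, n_splines: int = 3) -> "ISplineBasis":
        if n_splines < 2:
            raise ValueError("need at least 2 spline basis functions")
        qs = np.linspace(0.0, 1.0, n_splines)
        knots = np.quantile(np.asarray(values, dtype=float), qs)
        return cls(knots=knots)

    @property
    def n_splines(self) -> int:
        return len(self.knots)

    @property
    def degenerate(self) -> bool:
        return bool(self.knots[-1] - self.knots[0] <= 0)

    def design(self, x: np.ndarray) -> np.ndarray:
        """(len(x), n_splines) I-spline design matrix.

        I_j(x) = sum_{m >= j} B_m(x) over the B-spline basis of this knot
        vector — the cumulative-sum identity for monotone splines.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.degenerate:
            return np.zeros((len(x), self.n_splines))
        lo, hi = self.knots[0], self.knots[-1]
        xc = np.clip(x, lo, hi)
        # collapse duplicate interior knots (repeated quantiles)
        interior = [k for k in self.knots[1:-1] if lo < k < hi]
        t = np.r_[[lo] * (self.degree + 1), interior, [hi] * (self.degree + 1)]
        B = BSpline.design_matrix(xc, t, self.degree).toarray()
        ispl = np.cumsum(B[:, ::-1], axis=1)[:, ::-1][:, 1:]
        n_b = ispl.shape[1]
        if n_b < self.n_splines:   # duplicated knots reduced the basis
            ispl = np.hstack([ispl, np.tile(ispl[:, -1:], self.n_splines - n_b)])
        return ispl


@dataclass
class SitePairTable:
    """Site-pair rows: response dissimilarity + predictor values at each site.

    ``env_site1``/``env_site2`` hold environmental values for the two members
    of each pair; ``geo_distance`` (optional) is the pairwise geographic
    distance entering as its own splined predictor.
    """

    response: np.ndarray
    weights: np.ndarray
    pair_labels: list[tuple[str, str]]
    env_site1: pd.DataFrame
    env_site2: pd.DataFrame
    geo_distance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.response)):
            raise ValueError("non-finite response dissimilarities")
        if (self.weights <= 0).any():
            raise ValueError("site-pair weights must be positive")

    @property
    def n_pairs(self) -> int:
        return len(self.response)

    @property
    def predictors(self) -> list[str]:
        names = list(self.env_site1.columns)
        if self.geo_distance is not None:
            names.append(GEO_NAME)
        return names


def build_site_pairs(
    fst_matrix: PairwiseMatrix,
    env_table: pd.DataFrame,
    coords: pd.DataFrame | None = None,
    include_geo: bool = True,
    geo_matrix: PairwiseMatrix | None = None,
) -> SitePairTable:
    """One row per unordered population pair, FST as the response.

    Negative FST estimates are clamped to 0. Geographic distance comes from
    ``geo_matrix`` if supplied, else planar distance between ``coords``
    (x/y columns). Equal weights.
    """
    labels = fst_matrix.labels
    missing = [l for l in labels if l not in env_table.index.astype(str)]
    if missing:
        raise ValueError(f"populations missing from env table: {missing[:5]}")
    env = env_table.loc[[l for l in labels]]
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    d = np.maximum(fst_matrix.values[iu], 0.0)
    pairs = [(labels[i], labels[j]) for i, j in zip(*iu)]
    e1 = env.iloc[iu[0]].reset_index(drop=True)
    e2 = env.iloc[iu[1]].reset_index(drop=True)
    geo = None
    if include_geo:
        if geo_matrix is not None:
            geo = geo_matrix.reindex(labels).values[iu]
        elif coords is not None:
            from .distances import euclidean_matrix

            geo = euclidean_matrix(coords.loc[[l for l in labels]], mode="planar").values[iu]
        else:
            raise ValueError("include_geo=True requires coords or geo_matrix")
    return SitePairTable(
        response=d,
        weights=np.ones(len(d)),
        pair_labels=pairs,
        env_site1=e1,
        env_site2=e2,
        geo_distance=geo,
    )


@dataclass
class GDMModel:
    """Fitted GDM: intercept + non-negative I-spline coefficients per predictor."""

    intercept: float
    coefficients: dict[str, np.ndarray]
    bases: dict[str, ISplineBasis]
    predictors: list[str]
    deviance: float
    null_deviance: float
    converged: bool
    n_iter: int

    def partial_effect(self, predictor: str, x: np.ndarray) -> np.ndarray:
        """Fitted monotone partial response f_k evaluated at x (flat outside knots)."""
        if predictor not in self.coefficients:
            raise KeyError(f"unknown predictor {predictor!r}")
        return self.bases[predictor].design(x) @ self.coefficients[predictor]

    def linear_predictor(self, table: SitePairTable) -> np.ndarray:
        eta = np.full(table.n_pairs, self.intercept)
        for name in self.predictors:
            if name == GEO_NAME:
                eta += self.partial_effect(name, table.geo_distance)
            else:
                eta += np.abs(
                    self.partial_effect(name, table.env_site1[name].to_numpy())
                    - self.partial_effect(name, table.env_site2[name].to_numpy())
                )
        return eta

    def predict(self, table: SitePairTable) -> np.ndarray:
        return 1.0 - np.exp(-self.linear_predictor(table))

    @property
    def percent_deviance_explained(self) -> float:
        return percent_deviance_explained(self)


def _deviance(d: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    d = np.clip(d, RESPONSE_EPS, 1.0 - RESPONSE_EPS)
    mu = np.clip(mu, RESPONSE_EPS, 1.0 - RESPONSE_EPS)
    return float(
        2.0 * np.sum(w * (d * np.log(d / mu) + (1 - d) * np.log((1 - d) / (1 - mu))))
    )


def _feature_blocks(table: SitePairTable, n_splines: int):
    """Per-predictor I-spline bases and pairwise feature columns."""
    bases: dict[str, ISplineBasis] = {}
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for name in table.predictors:
        if name == GEO_NAME:
            vals = table.geo_distance
            basis = ISplineBasis.from_values(vals, n_splines)
            feat = basis.design(vals)
        else:
            x1 = table.env_site1[name].to_numpy(dtype=float)
            x2 = table.env_site2[name].to_numpy(dtype=float)
            basis = ISplineBasis.from_values(np.r_[x1, x2], n_splines)
            feat = np.abs(basis.design(x1) - basis.design(x2))
        if basis.degenerate:
            logger.warning("GDM predictor %s is constant; contributes nothing", name)
        bases[name] = basis
        blocks.append(feat)
        names.append(name)
    return bases, blocks, names


def fit_gdm(
    table: SitePairTable,
    n_splines: int = 3,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> GDMModel:
    """Fit the GDM by IRLS with a non-negative least-squares inner step.

    Converges when the deviance changes by less than ``tol``; a
    non-converged fit is returned with ``converged=False`` and a warning.
    All-zero coefficients are a legal outcome (null-equivalent model).
    """
    bases, blocks, names = _feature_blocks(table, n_splines)
    X = np.hstack([np.ones((table.n_pairs, 1))] + blocks)
    p = X.shape[1]
    if table.n_pairs < p + 1:
        raise ValueError(f"need at least {p + 1} site pairs for {p} coefficients")
    d = np.clip(table.response, RESPONSE_EPS, 1.0 - RESPONSE_EPS)
    w = table.weights
    mu = np.clip((d + d.mean()) / 2.0, 0.01, 0.99)
    eta = -np.log1p(-mu)
    beta = np.zeros(p)
    dev = _deviance(d, mu, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dmu_deta = np.exp(-eta)                        # = 1 - mu
        mu_c = np.clip(mu, RESPONSE_EPS, 1.0 - RESPONSE_EPS)
        var = mu_c * (1.0 - mu_c)
        wt = w * dmu_deta ** 2 / var
        z = eta + (d - mu) / np.maximum(dmu_deta, 1e-10)
        sw = np.sqrt(wt)
        beta, _ = nnls(sw[:, None] * X, sw * z)
        eta = X @ beta
        mu = 1.0 - np.exp(-eta)
        new_dev = _deviance(d, mu, w)
        if abs(dev - new_dev) < tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    if not converged:
        logger.warning("GDM did not converge in %d iterations (deviance %.6g)",
                       max_iter, dev)
    mu_null = float(np.average(d, weights=w))
    null_dev = _deviance(d, np.full_like(d, mu_null), w)
    coefs: dict[str, np.ndarray] = {}
    off = 1
    for name, block in zip(names, blocks):
        k = block.shape[1]
        coefs[name] = beta[off:off + k].copy()
        off += k
    return GDMModel(
        intercept=float(beta[0]),
        coefficients=coefs,
        bases=bases,
        predictors=names,
        deviance=dev,
        null_deviance=null_dev,
        converged=converged,
        n_iter=it,
    )


def percent_deviance_explained(model: GDMModel) -> float:
    """100 * (1 - residual/null deviance); NaN-flagged for zero null deviance."""
    if model.null_deviance <= 0:
        logger.warning("null deviance is zero; percent explained undefined")
        return np.nan
    return 100.0 * (1.0 - model.deviance / model.null_deviance)


def predictor_importance(model: GDMModel) -> pd.DataFrame:
    """Spline heights (sum of coefficients) and their percent of total."""
    heights = {k: float(v.sum()) for k, v in model.coefficients.items()}
    total = sum(heights.values())
    rows = []
    for name, h in heights.items():
        pct = 100.0 * h / total if total > 0 else np.nan
        rows.append({"predictor": name, "height": h, "percent": pct})
    if total <= 0:
        logger.warning("all GDM coefficients are zero; importance undefined")
    df = pd.DataFrame(rows).sort_values("height", ascending=False).reset_index(drop=True)
    return df


def evaluate_splines(model: GDMModel, n_points: int = 100) -> pd.DataFrame:
    """Fitted partial responses on a grid (for I-spline plots/exports)."""
    rows = []
    for name in model.predictors:
        knots = model.bases[name].knots
        xs = np.linspace(knots[0], knots[-1], n_points)
        ys = model.partial_effect(name, xs)
        rows.append(pd.DataFrame({"predictor": name, "x": xs, "f": ys}))
    return pd.concat(rows, ignore_index=True)
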