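"""Permutation Mantel tests and reciprocal causal modeling on distance matrices.

The Mantel statistic correlates the off-diagonal entries of two aligned
symmetric matrices (Spearman by default); the null distribution comes from
simultaneous row/column permutation of the first (genetic) matrix, with a
two-sided p carrying the +1 correction: p = (1 + #{|r*| >= |r|})/(n_perm + 1).

The partial Mantel statistic is the first-order partial correlation

    R_PM = (r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2))

computed on (rank-transformed, under Spearman) off-diagonal vectors; its null
permutes A's labels and recomputes the full statistic each draw
(raw-label permutation, pinned for reproducibility).

Reciprocal causal modeling (RCM) competes every unordered pair of candidate
distance matrices {A, B}: D[A, B] = R_PM(G, A | B) - R_PM(G, B | A). A
positive row for a variable means it out-competes every alternative.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core import PairwiseMatrix, require_aligned

logger = logging.getLogger(__name__)

__all__ = ["MantelResult", "RCMHeatmap", "mantel", "partial_mantel", "rcm_heatmap"]

_TOL = 1e-12


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    seed: int | None = None
    note: str = ""

    @property
    def defined(self) -> bool:
        return math.isfinite(self.r)


@dataclass
class RCMHeatmap:
    """All-pairs reciprocal-causal-modeling summary.

    ``difference[a, b]`` = R_PM(G, A | B) - R_PM(G, B | A) (antisymmetric,
    zero diagonal); ``rpm[a, b]`` and ``pvals[a, b]`` hold the underlying
    partial statistic and permutation p for variable a controlling b.
    """

    variables: list[str]
    difference: np.ndarray
    rpm: np.ndarray
    pvals: np.ndarray
    n_evaluations: int

    def __post_init__(self) -> None:
        d = self.difference
        ok = np.isfinite(d)
        assert np.allclose(np.diag(d), 0.0), "RCM diagonal must be zero"
        assert np.allclose(d[ok & ok.T], -(d.T)[ok & ok.T], atol=1e-10), \
            "RCM difference matrix must be antisymmetric"

    def row(self, variable: str) -> np.ndarray:
        """Off-diagonal D row for one variable (its margin over each rival)."""
        i = self.variables.index(variable)
        return np.delete(self.difference[i], i)


def _rank_square(m: PairwiseMatrix) -> np.ndarray:
    """Square matrix whose off-diagonals are the ranks of the condensed vector.

    Ranking commutes with label permutation, so Spearman Mantel reduces to
    Pearson Mantel on these rank matrices.
    """
    vec = m.condensed()
    from scipy.spatial.distance import squareform

    return squareform(rankdata(vec), checks=False)


def _working(m: PairwiseMatrix, method: str) -> np.ndarray:
    if method == "spearman":
        return _rank_square(m)
    if method == "pearson":
        return m.values.copy()
    raise ValueError("method must be 'spearman' or 'pearson'")


def _condensed(sq: np.ndarray, iu) -> np.ndarray:
    return sq[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc ** 2).sum())
    ny = np.sqrt((yc ** 2).sum())
    if nx == 0 or ny == 0:
        return np.nan
    return float(np.dot(xc, yc) / (nx * ny))


def _permutations(n: int, n_perm: int, exact: bool, seed):
    if exact:
        return [np.array(p) for p in itertools.permutations(range(n))]
    rng = np.random.default_rng(seed)
    return [rng.permutation(n) for _ in range(n_perm)]


def mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    n_perm: int = 999,
    method: str = "spearman",
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """Mantel test of matrix correlation; A (the genetic matrix) is permuted.

    With ``exact=True`` all n! label relabelings are enumerated and
    p = #{|r*| >= |r|}/n! (the identity permutation included), which the
    random-permutation estimator converges to.
    """
    require_aligned(A, B)
    n = A.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 labels")
    Aw = _working(A, method)
    Bw = _working(B, method)
    iu = np.triu_indices(n, k=1)
    avec = _condensed(Aw, iu)
    bvec = _condensed(Bw, iu)
    r_obs = _pearson(avec, bvec)
    if not math.isfinite(r_obs):
        return MantelResult(np.nan, np.nan, 0, method, seed,
                            note="zero variance in off-diagonal entries")
    perms = _permutations(n, n_perm, exact, seed)
    count = 0
    for perm in perms:
        av = Aw[perm[iu[0]], perm[iu[1]]]
        r = _pearson(av, bvec)
        if abs(r) >= abs(r_obs) - _TOL:
            count += 1
    if exact:
        p = count / len(perms)
        n_used = len(perms)
    else:
        p = (1 + count) / (n_perm + 1)
        n_used = n_perm
    return MantelResult(r=r_obs, p=p, n_perm=n_used, method=method, seed=seed)


def _partial_r(r_ab: float, r_ac: float, r_bc: float) -> float:
    denom = (1.0 - r_ac ** 2) * (1.0 - r_bc ** 2)
    if denom <= 0:
        return np.nan
    return (r_ab - r_ac * r_bc) / math.sqrt(denom)


def partial_mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    C: PairwiseMatrix,
    n_perm: int = 999,
    method: str = "spearman",
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel test of A ~ B controlling C; A's labels are permuted."""
    require_aligned(A, B, C)
    n = A.n
    if n < 4:
        raise ValueError("partial Mantel test needs at least 4 labels")
    Aw = _working(A, method)
    iu = np.triu_indices(n, k=1)
    avec = _condensed(Aw, iu)
    bvec = _condensed(_working(B, method), iu)
    cvec = _condensed(_working(C, method), iu)
    r_ab = _pearson(avec, bvec)
    r_ac = _pearson(avec, cvec)
    r_bc = _pearson(bvec, cvec)
    if not all(map(math.isfinite, (r_ab, r_ac, r_bc))):
        return MantelResult(np.nan, np.nan, 0, method, seed,
                            note="zero variance in off-diagonal entries")
    if abs(r_ac) >= 1.0 - _TOL or abs(r_bc) >= 1.0 - _TOL:
        return MantelResult(np.nan, np.nan, 0, method, seed,
                            note="controlling matrix perfectly collinear")
    r_obs = _partial_r(r_ab, r_ac, r_bc)
    if n_perm <= 0:
        return MantelResult(r=r_obs, p=np.nan, n_perm=0, method=method, seed=seed)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        av = Aw[perm[iu[0]], perm[iu[1]]]
        r = _partial_r(_pearson(av, bvec), _pearson(av, cvec), r_bc)
        if math.isfinite(r) and abs(r) >= abs(r_obs) - _TOL:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, method=method, seed=seed)


def rcm_heatmap(
    G: PairwiseMatrix,
    variable_matrices: dict[str, PairwiseMatrix],
    n_perm: int = 999,
    method: str = "spearman",
    seed: int | None = None,
) -> RCMHeatmap:
    """Reciprocal causal modeling over all unordered pairs of candidates.

    For k variables, k(k-1)/2 reciprocal models and k(k-1) partial Mantel
    evaluations are executed (55 and 110 for the canonical 11-variable set).
    Undefined partials (degenerate matrices) leave NaN cells rather than
    silent zeros.
    """
    names = list(variable_matrices)
    if len(names) < 2:
        raise ValueError("RCM needs at least two candidate matrices")
    for m in variable_matrices.values():
        require_aligned(G, m)
    k = len(names)
    diff = np.zeros((k, k))
    rpm = np.full((k, k), np.nan)
    pvals = np.full((k, k), np.nan)
    n_eval = 0
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.generate_state(k * (k - 1)))
    for ia, ib in itertools.combinations(range(k), 2):
        A = variable_matrices[names[ia]]
        B = variable_matrices[names[ib]]
        ra = partial_mantel(G, A, B, n_perm=n_perm, method=method,
                            seed=int(next(child_seeds) % (2 ** 31)))
        rb = partial_mantel(G, B, A, n_perm=n_perm, method=method,
                            seed=int(next(child_seeds) % (2 ** 31)))
        n_eval += 2
        rpm[ia, ib] = ra.r
        rpm[ib, ia] = rb.r
        pvals[ia, ib] = ra.p
        pvals[ib, ia] = rb.p
        if ra.defined and rb.defined:
            diff[ia, ib] = ra.r - rb.r
            diff[ib, ia] = rb.r - ra.r
        else:
            diff[ia, ib] = diff[ib, ia] = np.nan
            logger.warning("RCM cell (%s, %s) undefined: %s / %s",
                           names[ia], names[ib], ra.note, rb.note)
    return RCMHeatmap(variables=names, difference=diff, rpm=rpm, pvals=pvals,
                      n_evaluations=n_eval)
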