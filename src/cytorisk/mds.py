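"""Patient embedding by metric MDS on the squared-rank-difference distance.

For each feature, patients are ranked across the cohort (average ranks for
ties); the distance between patients i and j is the sum over features of the
squared rank difference.  Coordinates are found by SMACOF majorization from a
classical-scaling start, minimizing least-squares stress; the reported stress
is the normalized form

    Stress = sum_{i<j} (d_ij - dhat_ij)^2 / sum_{i<j} d_ij^2,

whose minimizer coincides with raw least-squares stress.  The embedding
dimensionality is chosen from the stress-versus-dimension curve by the elbow
(largest discrete second difference).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .features import OUTCOME_COLUMN

__all__ = [
    "rank_distance",
    "RankMDS",
    "MDSEmbedding",
    "mds_embed",
    "normalized_stress",
    "stress_curve",
    "choose_dimension",
    "align_coordinate_signs",
]

log = logging.getLogger(__name__)


def rank_distance(
    table: pd.DataFrame,
    orientation: str = "across_patients",
) -> pd.DataFrame:
    """Squared-rank-difference distance matrix between patients.

    ``orientation='across_patients'`` (default) ranks each feature across the
    cohort; the alternative ``'within_patient'`` ranks features within each
    patient profile.  Missing values are excluded pairwise (a pair's distance
    sums only over features observed in both patients), with the exclusion
    count logged.
    """
    X = table.drop(columns=[OUTCOME_COLUMN], errors="ignore")
    if len(X) < 2:
        raise ValueError("need at least 2 patients")
    if X.isna().all(axis=0).any():
        bad = list(X.columns[X.isna().all(axis=0)])
        raise ValueError(f"all-missing feature(s): {bad[:5]}")
    vals = X.to_numpy(dtype=float)
    if orientation == "across_patients":
        R = np.full_like(vals, np.nan)
        for k in range(vals.shape[1]):
            col = vals[:, k]
            ok = ~np.isnan(col)
            R[ok, k] = rankdata(col[ok])
    elif orientation == "within_patient":
        R = np.full_like(vals, np.nan)
        for i in range(vals.shape[0]):
            row = vals[i]
            ok = ~np.isnan(row)
            R[i, ok] = rankdata(row[ok])
    else:
        raise ValueError("orientation must be 'across_patients' or 'within_patient'")

    mask = ~np.isnan(R)
    Rz = np.where(mask, R, 0.0)
    sq = Rz**2
    # sum_k (r_ik - r_jk)^2 over features observed in both i and j
    both = mask.astype(float) @ mask.astype(float).T
    cross = Rz @ Rz.T
    si = sq @ mask.astype(float).T
    D = si + si.T - 2.0 * cross
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, 0.0)
    n_excluded = mask.size - int(mask.sum())
    if n_excluded:
        log.info("rank_distance: %d missing values excluded pairwise", n_excluded)
    _ = both  # pair coverage retained for symmetry with the mask computation
    return pd.DataFrame(D, index=X.index, columns=X.index)


def _check_distance(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    return D


def normalized_stress(D: np.ndarray, X: np.ndarray) -> float:
    """Stress = sum (d_ij - dhat_ij)^2 / sum d_ij^2 over unordered pairs."""
    D = np.asarray(D, dtype=float)
    dhat = squareform(_pairwise(X), checks=False)
    d = squareform(D, checks=False)
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0
    return float(np.sum((d - dhat) ** 2) / denom)


def _pairwise(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def _classical_scaling(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    w = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w)


class RankMDS(BaseEstimator):
    """SMACOF least-squares MDS on a precomputed distance matrix.

    Majorization (Guttman transform) from a classical-scaling start (or a
    user initialization); the raw stress sequence is non-increasing by
    construction.  Fitted attributes: ``embedding_`` (n x n_components,
    column-centered), ``stress_`` (normalized stress), ``stress_trace_``
    (normalized stress per iteration), ``n_iter_``.
    """

    def __init__(self, n_components: int = 3, max_iter: int = 1000,
                 tol: float = 1e-8, random_state: int | None = 0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, D, y=None, init: np.ndarray | None = None):
        index = D.index if isinstance(D, pd.DataFrame) else None
        D = _check_distance(D)
        n = D.shape[0]
        if self.n_components >= n:
            raise ValueError("n_components must be smaller than the number of points")

        if init is None:
            X = _classical_scaling(D, self.n_components)
        else:
            X = np.array(init, dtype=float)
            if X.shape != (n, self.n_components):
                raise ValueError("init has the wrong shape")
            # degenerate (e.g. all-zero padded) columns cannot escape the
            # Guttman fixed point; break them with a tiny seeded jitter
            col_norm = np.linalg.norm(X - X.mean(0), axis=0)
            if np.any(col_norm < 1e-12):
                rng = np.random.default_rng(self.random_state)
                X = X + 1e-6 * rng.standard_normal(X.shape)

        denom = float(np.sum(squareform(D, checks=False) ** 2))
        trace = []
        dhat = _pairwise(X)
        raw = float(np.sum((squareform(D, checks=False)
                            - squareform(dhat, checks=False)) ** 2))
        trace.append(raw / denom if denom else 0.0)
        it = 0
        for it in range(1, self.max_iter + 1):
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dhat > 0, D / np.where(dhat > 0, dhat, 1.0), 0.0)
            B = -ratio
            np.fill_diagonal(B, 0.0)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = (B @ X) / n
            dhat = _pairwise(X)
            raw_new = float(np.sum((squareform(D, checks=False)
                                    - squareform(dhat, checks=False)) ** 2))
            trace.append(raw_new / denom if denom else 0.0)
            if raw - raw_new < self.tol * max(raw, 1e-300):
                raw = raw_new
                break
            raw = raw_new

        X = X - X.mean(axis=0, keepdims=True)
        # stress is rotation-invariant; report coordinates on principal
        # axes (variance-ordered) so axis identity is reproducible
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        X = X @ Vt.T
        self.embedding_ = X
        self.index_ = index
        self.stress_trace_ = np.asarray(trace)
        self.stress_ = normalized_stress(D, X)
        self.n_iter_ = it
        self.dissimilarity_matrix_ = D
        return self

    def fit_transform(self, D, y=None, init=None):
        return self.fit(D, init=init).embedding_


@dataclass
class MDSEmbedding:
    """Fitted patient embedding: coordinates, stress, and iteration log."""

    coordinates: pd.DataFrame
    stress: float
    stress_trace: np.ndarray = field(repr=False)
    n_iter: int = 0

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]

    def fitted_distances(self) -> pd.DataFrame:
        d = _pairwise(self.coordinates.to_numpy())
        return pd.DataFrame(d, index=self.coordinates.index,
                            columns=self.coordinates.index)


def mds_embed(
    D: pd.DataFrame | np.ndarray,
    dims: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
    init: np.ndarray | None = None,
) -> MDSEmbedding:
    """Embed a distance matrix in ``dims`` dimensions by SMACOF."""
    model = RankMDS(n_components=dims, max_iter=max_iter, tol=tol,
                    random_state=seed).fit(D, init=init)
    index = model.index_
    if index is None:
        index = pd.RangeIndex(model.embedding_.shape[0])
    coords = pd.DataFrame(
        model.embedding_, index=index,
        columns=[f"coordinate {k + 1}" for k in range(dims)],
    )
    return MDSEmbedding(coords, model.stress_, model.stress_trace_, model.n_iter_)


def stress_curve(
    D: pd.DataFrame | np.ndarray,
    dims_range,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> list[tuple[int, float]]:
    """Stress at each dimensionality, warm-starting each fit from the last.

    Each fit is run both from the previous embedding padded with a jittered
    column and from a classical-scaling start, keeping the lower stress; the
    curve is therefore non-increasing in dimension (violations would only
    arise from optimizer failure and are logged).
    """
    dims = list(dims_range)
    if not dims:
        raise ValueError("empty dimension range")
    out: list[tuple[int, float]] = []
    prev: np.ndarray | None = None
    prev_stress = np.inf
    n = np.shape(D)[0]
    for d in dims:
        cold = RankMDS(d, max_iter, tol, seed).fit(D)
        best = cold
        if prev is not None and d > prev.shape[1]:
            pad = np.zeros((n, d - prev.shape[1]))
            warm = RankMDS(d, max_iter, tol, seed).fit(
                D, init=np.hstack([prev, pad])
            )
            if warm.stress_ < best.stress_:
                best = warm
        if best.stress_ > prev_stress + 1e-12:
            log.warning("stress increased at dims=%d (%.3g -> %.3g)",
                        d, prev_stress, best.stress_)
        out.append((d, best.stress_))
        prev, prev_stress = best.embedding_, best.stress_
    return out


def choose_dimension(curve, override: int | None = None) -> int:
    """Elbow rule: dimension of largest curvature of the stress curve.

    Curvature is the discrete second difference of log stress (the point
    where the *relative* improvement per added dimension collapses).  The
    logarithm matters: least-squares distance fitting loses only
    second-order information when the smallest structural axis is dropped,
    so raw stress drops decay geometrically along a structured curve and
    their plain second difference always peaks one dimension early.  A flat
    or uniformly decaying curve has no positive curvature; the smallest
    dimension is returned with a warning.  ``override`` short-circuits the
    rule (e.g. to pin the study's choice of 3).
    """
    if override is not None:
        return int(override)
    curve = sorted(curve)
    if len(curve) < 3:
        raise ValueError("need a stress curve of length >= 3")
    dims = [c[0] for c in curve]
    s = np.array([c[1] for c in curve], dtype=float)
    ls = np.log(np.maximum(s, 1e-12))
    second = ls[:-2] - 2 * ls[1:-1] + ls[2:]
    if np.all(second <= 1e-9):
        warnings.warn("stress curve has no elbow (flat or uniform decay); "
                      "returning the smallest dimension", stacklevel=2)
        return dims[0]
    return dims[1 + int(np.argmax(second))]


def align_coordinate_signs(
    coords: pd.DataFrame, outcome: pd.Series
) -> pd.DataFrame:
    """Flip each axis so its Spearman correlation with the outcome is >= 0.

    Rigid reflections leave stress unchanged; fixing the sign makes
    downstream reporting reproducible across runs.
    """
    from scipy.stats import spearmanr

    out = coords.copy()
    y = outcome.reindex(coords.index).to_numpy()
    for c in out.columns:
        rho = spearmanr(out[c].to_numpy(), y).statistic
        if np.isfinite(rho) and rho < 0:
            out[c] = -out[c]
    return out
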