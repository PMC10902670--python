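"""Outcome association statistics: AUROC screening with bootstrap CIs,
Spearman correlation with Storey q-values, two-group comparisons, and
univariate logistic odds ratios.

AUROC is the rank statistic (Mann-Whitney identity, ties half-weighted);
its confidence interval is a stratified percentile bootstrap.  The q-value
procedure estimates the null proportion pi0 by the lambda-grid smoother and
applies the step-up transformation; with pi0 fixed at 1 it reduces exactly
to Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "auroc",
    "bootstrap_auroc_ci",
    "spearman",
    "qvalues",
    "group_compare",
    "fisher_exact_test",
    "feature_odds_ratios",
    "screen_coordinates",
    "correlate_features",
    "ScreenResult",
]

log = logging.getLogger(__name__)


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    return (y == classes.max()).astype(int)


def auroc(scores, labels) -> float:
    """Rank-based AUROC: P(random positive outscores random negative),
    ties counted 1/2."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    r = stats.rankdata(s)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _stratified_bootstrap_aurocs(
    s: np.ndarray, y: np.ndarray, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized bootstrap AUROCs resampling within each class.

    Stratified resampling keeps both classes present in every replicate
    (preserving the cohort prevalence), so no degenerate redraws arise.
    """
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = len(pos), len(neg)
    bp = pos[rng.integers(0, n1, size=(reps, n1))]
    bn = neg[rng.integers(0, n0, size=(reps, n0))]
    allv = np.concatenate([bp, bn], axis=1)
    r = stats.rankdata(allv, axis=1)
    u = r[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def bootstrap_auroc_ci(
    scores, labels, reps: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI of the AUROC, stratified by class."""
    if reps < 2:
        raise ValueError("need at least 2 bootstrap replications")
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    boot = _stratified_bootstrap_aurocs(s, y, reps, rng)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("constant vector in Spearman correlation")
    return float((rx * ry).sum() / denom)


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho (Pearson correlation of average ranks) and two-sided p.

    For n <= ``exact_max_n`` the p-value is exact, from the full permutation
    distribution of one margin; otherwise the t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rho = _spearman_rho(x, y)
    if n <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx = rx - rx.mean()
        ry = ry - ry.mean()
        denom = np.sqrt((rx**2).sum() * (ry**2).sum())
        perms = np.array(list(itertools.permutations(ry)))
        rhos = perms @ rx / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def qvalues(p, pi0: float | None = None,
            lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 is estimated on the grid lambda = 0.05..0.95 (step 0.05) with a cubic
    smoother evaluated at the largest lambda, then q_(i) = min_{j>=i}
    pi0 * m * p_(j) / j, clipped to [0, 1].  Passing ``pi0=1`` reproduces
    Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
        if m < 20 or np.allclose(pi0_l, 0):
            pi0 = 1.0
        else:
            coef = np.polyfit(lambdas, pi0_l, deg=3)
            pi0 = float(np.polyval(coef, lambdas.max()))
        pi0 = min(max(pi0, 1e-8), 1.0)
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    q = pi0 * m * ps / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def group_compare(values, labels, exact_max_n: int = 20) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p for a two-group comparison.

    Exact p for combined n <= ``exact_max_n`` without ties; normal
    approximation with tie correction otherwise.
    """
    y = _check_binary(labels)
    v = np.asarray(values, dtype=float)
    a, b = v[y == 1], v[y == 0]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n = len(v)
    has_ties = len(np.unique(v)) < n
    method = "exact" if (n <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_test(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    tables at least as extreme as the observed one."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def feature_odds_ratios(
    features: pd.DataFrame, labels, level: float = 0.95
) -> pd.DataFrame:
    """Univariate logistic regression per feature (IRLS/Newton fits).

    Returns a DataFrame with OR = exp(coefficient), Wald CI and p per
    feature.  Perfectly separating features are flagged: the OR is reported
    as +/-inf with a warning rather than a spuriously finite number.
    """
    import statsmodels.api as sm

    y = _check_binary(labels)
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        X = sm.add_constant(x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta, se = fit.params[1], fit.bse[1]
            separated = (not np.isfinite(se)) or abs(beta) > 15 or se > 50
        except Exception:  # statsmodels raises on perfect separation
            separated = True
            beta = np.nan
        if separated:
            warnings.warn(f"perfect separation for feature {col!r}; "
                          "odds ratio reported as infinite", stacklevel=2)
            sign = np.sign(np.corrcoef(x, y)[0, 1]) if np.std(x) > 0 else 1.0
            rows.append((col, np.inf if sign >= 0 else 0.0,
                         np.nan, np.nan, np.nan, True))
        else:
            rows.append((col, float(np.exp(beta)),
                         float(np.exp(beta - z * se)),
                         float(np.exp(beta + z * se)),
                         float(fit.pvalues[1]), False))
    return pd.DataFrame(
        rows, columns=["feature", "odds_ratio", "ci_lower", "ci_upper",
                       "p_value", "separated"],
    ).set_index("feature")


@dataclass
class ScreenResult:
    """AUROC screen over embedding coordinates."""

    table: pd.DataFrame          # coordinate, auroc, ci_lower, ci_upper
    selected: str                # name of the selected coordinate
    reps: int
    level: float
    seed: int


def screen_coordinates(
    coords: pd.DataFrame,
    outcome: pd.Series,
    reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> ScreenResult:
    """AUROC (with bootstrap CI) of each MDS coordinate against the outcome.

    The coordinate with the largest AUROC is selected; ties break toward
    the lower index (logged).
    """
    y = outcome.reindex(coords.index).to_numpy()
    rows = []
    for i, c in enumerate(coords.columns):
        a = auroc(coords[c].to_numpy(), y)
        lo, hi = bootstrap_auroc_ci(coords[c].to_numpy(), y, reps=reps,
                                    level=level, seed=seed + i)
        rows.append((c, a, lo, hi))
    table = pd.DataFrame(rows, columns=["coordinate", "auroc", "ci_lower",
                                        "ci_upper"]).set_index("coordinate")
    best = table["auroc"].max()
    ties = table.index[table["auroc"] >= best - 1e-12]
    if len(ties) > 1:
        log.info("AUROC tie between %s; selecting %s", list(ties), ties[0])
    return ScreenResult(table, ties[0], reps, level, seed)


def correlate_features(
    features: pd.DataFrame,
    coordinate: pd.Series,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of every feature with one embedding coordinate.

    Returns (feature, rho, p, q, significant), q-values by the Storey
    procedure, significance flagged at q < ``q_threshold``.
    """
    coord = coordinate.reindex(features.index).to_numpy()
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 3 or np.all(x[ok] == x[ok][0]):
            rows.append((col, np.nan, np.nan))
            continue
        rho, p = spearman(x[ok], coord[ok])
        rows.append((col, rho, p))
    out = pd.DataFrame(rows, columns=["feature", "rho", "p_value"]).set_index(
        "feature"
    )
    valid = out["p_value"].notna()
    q = np.full(len(out), np.nan)
    q[valid.to_numpy()] = qvalues(out.loc[valid, "p_value"].to_numpy())
    out["q_value"] = q
    out["significant"] = out["q_value"] < q_threshold
    return out.sort_values("q_value")
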