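"""Per-cell gene-signature scoring and multi-group rank comparisons.

The module score is the binned-control statistic used for single-cell gene
sets (e.g. mitochondrial fatty-acid oxidation, GO:0031998, and mitochondrial
biogenesis, R-HSA-1592230): genes are binned by their average expression
across cells, control genes are drawn from the bins of the signature genes,
and the score is the mean signature expression minus the mean control
expression, per cell.  Group differences are assessed by a tie-corrected
Kruskal-Wallis test with Dunn's post-hoc pairwise comparisons.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["module_score", "ModuleScorer", "kruskal_dunn", "read_gene_set"]


def read_gene_set(path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    with open(path) as fh:
        genes = [ln.strip() for ln in fh
                 if ln.strip() and not ln.lstrip().startswith("#")]
    return genes


def module_score(
    matrix: pd.DataFrame,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control signature score per cell.

    ``matrix`` is cells x genes (counts or log-normalized values).  Genes are
    ranked by their cross-cell average and cut into ``n_bins`` equal-size
    bins; for each signature gene, up to ``n_ctrl`` control genes are drawn
    (without replacement) from its bin, and the per-cell score is the mean
    over signature genes minus the mean over the pooled control genes.
    Signature genes absent from the matrix are dropped with a warning;
    an empty intersection is an error.  Deterministic per seed.
    """
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate gene names in expression matrix")
    # genes with no expression in any cell carry no information; exclude
    # them so scores are invariant to padding the matrix with absent genes
    expressed = matrix.columns[(matrix != 0).any(axis=0)]
    matrix = matrix[expressed]
    gene_set = list(dict.fromkeys(gene_set))
    present = [g for g in gene_set if g in matrix.columns]
    missing = set(gene_set) - set(present)
    if not present:
        raise ValueError("no signature gene present (and expressed) in the matrix")
    if missing:
        warnings.warn(f"{len(missing)} signature gene(s) absent from matrix; "
                      "dropped", stacklevel=2)

    rng = np.random.default_rng(seed)
    avg = matrix.mean(axis=0)
    n_bins = min(n_bins, len(avg))
    # equal-occupancy bins of the gene-average distribution
    order_rank = avg.rank(method="first")
    bins = pd.cut(order_rank, bins=n_bins, labels=False)

    ctrl: set[str] = set()
    for g in present:
        pool = avg.index[bins == bins[g]].to_numpy()
        if len(pool) <= n_ctrl:
            ctrl.update(pool)
        else:
            ctrl.update(rng.choice(pool, size=n_ctrl, replace=False))
    ctrl_genes = sorted(ctrl)

    score = (
        matrix[present].mean(axis=1) - matrix[ctrl_genes].mean(axis=1)
    )
    score.name = "module_score"
    return score


class ModuleScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper: fit learns the expression bins and control
    draw from a reference matrix; transform scores (the same or new) cells.
    """

    def __init__(self, gene_set=(), n_bins: int = 24, n_ctrl: int = 100,
                 random_state: int = 0):
        self.gene_set = gene_set
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        # the control draw is defined by the reference matrix averages
        score = module_score(X, list(self.gene_set), self.n_bins,
                             self.n_ctrl, self.random_state)
        self.reference_score_ = score
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return module_score(X, list(self.gene_set), self.n_bins,
                            self.n_ctrl, self.random_state).to_frame()


def kruskal_dunn(
    scores,
    groups,
    adjust: str = "bonferroni",
) -> dict:
    """Kruskal-Wallis omnibus test plus Dunn pairwise post-hoc comparisons.

    Returns ``{"H", "p", "pairwise"}`` where ``pairwise`` is a DataFrame of
    z statistics with unadjusted and multiplicity-adjusted two-sided p
    (Bonferroni over the pairwise family by default; ``adjust="holm"``
    available).  With fewer than three groups the omnibus test falls back
    to Mann-Whitney with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [scores[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need at least 2 observations per group")
    if len(labels) < 3:
        warnings.warn("fewer than 3 groups; falling back to Mann-Whitney",
                      stacklevel=2)
        res = stats.mannwhitneyu(samples[0], samples[1],
                                 alternative="two-sided")
        return {"H": float(res.statistic), "p": float(res.pvalue),
                "pairwise": None}

    H, p = stats.kruskal(*samples)

    # Dunn z statistics on pooled average ranks, with tie correction
    N = len(scores)
    r = stats.rankdata(scores)
    mean_ranks = {g: r[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        praw = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, z, praw))
    pw = pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw"])
    k = len(pw)
    if adjust == "bonferroni":
        pw["p_adjusted"] = np.minimum(pw["p_raw"] * k, 1.0)
    elif adjust == "holm":
        order = np.argsort(pw["p_raw"].to_numpy())
        adj = np.empty(k)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (k - rank_i) * pw["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        pw["p_adjusted"] = adj
    else:
        raise ValueError("adjust must be 'bonferroni' or 'holm'")
    return {"H": float(H), "p": float(p), "pairwise": pw}
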