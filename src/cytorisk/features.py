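"""Event transformation, manual gating, and per-patient feature assembly.

The analysis scale for all marker intensities is ``asinh(x / cofactor)`` with
cofactor 5.  Events are assigned to immune subsets by a configurable binary
gating tree (marker, threshold, above/below children); per-patient features
are subset abundances (fraction of all gated events), per-subset arcsinh
means of each metabolic regulator, and plasma cytokine levels.  With the
default 21 subsets and 16 regulators the cytometry block is exactly
21 + 21*16 = 357 features.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import panel as P

__all__ = [
    "arcsinh_transform",
    "ArcsinhTransformer",
    "GatingTree",
    "gate_events",
    "build_feature_table",
    "ZTransform",
    "z_normalize",
]

UNGATED = "ungated"
OUTCOME_COLUMN = "infection"


def arcsinh_transform(x, cofactor: float = 5.0):
    """Inverse-hyperbolic-sine transform ``asinh(x / cofactor)``.

    Strictly monotone; defined for negative inputs (which can arise from
    bead-normalised data) but these are flagged with a warning.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        warnings.warn("negative intensities passed to arcsinh_transform",
                      stacklevel=2)
    return np.arcsinh(x / cofactor)


class ArcsinhTransformer(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer applying :func:`arcsinh_transform`."""

    def __init__(self, cofactor: float = 5.0):
        self.cofactor = cofactor

    def fit(self, X, y=None):
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")
        self.n_features_in_ = np.shape(X)[1] if np.ndim(X) == 2 else 1
        return self

    def transform(self, X):
        return arcsinh_transform(X, self.cofactor)


class GatingTree:
    """Binary manual-gating hierarchy.

    Nodes are nested dicts: ``{"marker", "threshold", "above", "below"}``
    for splits (``above`` meaning intensity > threshold on the arcsinh
    scale), and ``{"subset": name-or-None}`` for leaves; a ``None`` subset
    marks ungated events.
    """

    def __init__(self, root: dict):
        self.root = root
        self.leaves = self._collect_leaves(root)
        names = [s for s in self.leaves if s is not None]
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf subset names in gating tree")
        self.markers = self._collect_markers(root)

    @staticmethod
    def _collect_leaves(node, acc=None):
        acc = [] if acc is None else acc
        if "subset" in node:
            acc.append(node["subset"])
            return acc
        for key in ("marker", "threshold", "above", "below"):
            if key not in node:
                raise ValueError(f"malformed gating node (missing {key!r})")
        if np.isnan(node["threshold"]):  # +-inf is a valid catch-all gate
            raise ValueError("gating thresholds must not be NaN")
        GatingTree._collect_leaves(node["above"], acc)
        GatingTree._collect_leaves(node["below"], acc)
        return acc

    @staticmethod
    def _collect_markers(node, acc=None):
        acc = set() if acc is None else acc
        if "subset" in node:
            return acc
        acc.add(node["marker"])
        GatingTree._collect_markers(node["above"], acc)
        GatingTree._collect_markers(node["below"], acc)
        return acc

    @classmethod
    def default(cls) -> "GatingTree":
        return cls(P.default_gating_tree())

    @classmethod
    def from_yaml(cls, path) -> "GatingTree":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.root, fh, sort_keys=False)

    def assign(self, intensities: pd.DataFrame) -> pd.Series:
        """Assign each event (row) to a leaf subset; deterministic.

        ``intensities`` must be arcsinh-transformed and contain every marker
        the tree splits on.
        """
        missing = self.markers - set(intensities.columns)
        if missing:
            raise KeyError(f"gating markers absent from events: {sorted(missing)}")
        labels = np.empty(len(intensities), dtype=object)

        def recurse(node, mask):
            if "subset" in node:
                labels[mask] = node["subset"] if node["subset"] else UNGATED
                return
            above = intensities[node["marker"]].to_numpy() > node["threshold"]
            recurse(node["above"], mask & above)
            recurse(node["below"], mask & ~above)

        recurse(self.root, np.ones(len(intensities), dtype=bool))
        return pd.Series(labels, index=intensities.index, name="subset")


def gate_events(
    events: pd.DataFrame,
    tree: GatingTree | dict | None = None,
    cofactor: float | None = 5.0,
) -> pd.DataFrame:
    """Return ``events`` with an assigned ``subset`` column.

    ``cofactor`` applies the arcsinh transform to the marker columns before
    gating (pass ``None`` if the table is already on the analysis scale).
    """
    if tree is None:
        tree = GatingTree.default()
    elif isinstance(tree, dict):
        tree = GatingTree(tree)
    marker_cols = [c for c in events.columns if c in P.ALL_MARKERS or c in tree.markers]
    intens = events[marker_cols]
    if cofactor is not None:
        intens = pd.DataFrame(
            arcsinh_transform(intens.to_numpy(), cofactor),
            index=events.index, columns=marker_cols,
        )
    out = events.copy()
    out["subset"] = tree.assign(intens)
    return out


#: static parent populations used for the optional fraction-of-parent block
_PARENT_GROUPS: dict[str, tuple[str, ...]] = {
    "CD4T": ("naive CD4T", "central memory CD4T", "effector memory CD4T",
             "TEMRA CD4T", "Treg"),
    "CD8T": ("naive CD8T", "central memory CD8T", "effector memory CD8T",
             "TEMRA CD8T"),
    "innate-like T": ("gdT", "MAIT", "NKT"),
    "NK": P.NK_SUBSETS,
    "B": ("B cells",),
    "monocytes": ("classical monocytes", "intermediate monocytes",
                  "non-classical monocytes"),
    "DC": ("mDC", "pDC"),
}


def abundance_feature(subset: str) -> str:
    return f"{subset} (abundance)"


def marker_feature(marker: str, subset: str) -> str:
    return f"{marker}_{subset}"


def build_feature_table(
    gated_events: pd.DataFrame,
    cytokines: pd.DataFrame | None,
    outcomes: pd.DataFrame | pd.Series,
    subsets: tuple[str, ...] = P.SUBSETS,
    markers: tuple[str, ...] = P.METABOLIC_MARKERS,
    cofactor: float = 5.0,
    parent_fractions: bool = False,
) -> pd.DataFrame:
    """Assemble the patients-by-features table.

    Per subset ``s`` and metabolic regulator ``m`` the feature is the mean of
    per-cell arcsinh intensities of ``m`` over cells gated into ``s`` (mean of
    transformed values, not transform of the mean).  Abundances are fractions
    of all gated (non-ungated) events.  Cytokine columns are appended as
    provided (the 0 pg/mL detection floor is applied upstream).  A subset
    with no cells for a patient yields NaN marker means and abundance 0.
    """
    if "subset" not in gated_events.columns:
        raise ValueError("events must carry a 'subset' column (run gate_events)")
    outcome = (
        outcomes[OUTCOME_COLUMN] if isinstance(outcomes, pd.DataFrame) else outcomes
    )
    event_patients = set(gated_events["patient_id"].unique())
    missing = event_patients - set(outcome.index)
    if missing:
        raise ValueError(f"patients without outcome: {sorted(missing)}")

    gated = gated_events[gated_events["subset"] != UNGATED]
    counts = (
        gated.groupby(["patient_id", "subset"], sort=False).size()
        .unstack(fill_value=0)
        .reindex(columns=list(subsets), fill_value=0)
    )
    totals = counts.sum(axis=1)
    abundances = counts.div(totals, axis=0)
    abundances.columns = [abundance_feature(s) for s in subsets]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # asinh of clipped-0 raw counts is fine
        arc = pd.DataFrame(
            arcsinh_transform(gated[list(markers)].to_numpy(), cofactor),
            index=gated.index, columns=list(markers),
        )
    arc["patient_id"] = gated["patient_id"].to_numpy()
    arc["subset"] = gated["subset"].to_numpy()
    means = arc.groupby(["patient_id", "subset"], sort=False)[list(markers)].mean()

    blocks = [abundances]
    marker_cols = {}
    for s in subsets:
        for m in markers:
            key = (slice(None), s)
            try:
                col = means.loc[key, m].droplevel("subset")
            except KeyError:
                col = pd.Series(np.nan, index=counts.index)
            marker_cols[marker_feature(m, s)] = col
    blocks.append(pd.DataFrame(marker_cols).reindex(counts.index))

    if parent_fractions:
        pf = {}
        for parent, members in _PARENT_GROUPS.items():
            members = [m for m in members if m in subsets]
            if not members:
                continue
            denom = counts[members].sum(axis=1)
            for m in members:
                pf[f"{m} (fraction of {parent})"] = counts[m] / denom.replace(0, np.nan)
        blocks.append(pd.DataFrame(pf))

    if cytokines is not None:
        blocks.append(cytokines.reindex(counts.index))

    table = pd.concat(blocks, axis=1)
    table.index.name = "patient_id"
    table = table.reindex(outcome.index.intersection(table.index))
    table.insert(0, OUTCOME_COLUMN, outcome.reindex(table.index).astype(int))
    if table[OUTCOME_COLUMN].isna().any():
        raise ValueError("missing outcome for some patients")
    return table


class ZTransform(BaseEstimator, TransformerMixin):
    """Column-wise standardization with sample SD (ddof=1).

    Constant columns cannot be standardized and are dropped with a warning.
    Operates on DataFrames and preserves column names, so it composes with
    the feature table directly.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("need at least 2 patients to standardize")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        constant = self.scale_ <= 0
        if constant.any():
            warnings.warn(
                f"dropping {int(constant.sum())} constant feature(s): "
                f"{list(X.columns[constant])[:5]}...",
                stacklevel=2,
            )
        self.columns_ = X.columns[~constant]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        X = pd.DataFrame(X)
        return (X[self.columns_] - self.mean_[self.columns_]) / self.scale_[
            self.columns_
        ]


def z_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-transform every feature column (outcome column passed through)."""
    feats = table.drop(columns=[OUTCOME_COLUMN], errors="ignore")
    zt = ZTransform().fit(feats)
    out = zt.transform(feats)
    if OUTCOME_COLUMN in table.columns:
        out.insert(0, OUTCOME_COLUMN, table[OUTCOME_COLUMN])
    return out
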