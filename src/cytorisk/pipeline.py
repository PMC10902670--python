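"""End-to-end cohort analysis: events -> features -> MDS -> screen -> score.

Mirrors the full risk-stratification workflow: arcsinh transform and manual
gating of events, per-patient feature assembly with cytokines, joint Z
transformation, squared-rank-difference MDS of patients, AUROC screening of
the embedding coordinates against the infection outcome, Spearman/q-value
feature correlation with the selected coordinate, and elastic-net variable
selection over the NK-related candidates to build the predicted risk score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import ScreenResult, correlate_features, screen_coordinates
from .enet import ElasticNetLogit, evaluate_score, fit_elastic_net
from .features import (OUTCOME_COLUMN, GatingTree, build_feature_table,
                       gate_events, z_normalize)
from .mds import (MDSEmbedding, align_coordinate_signs, choose_dimension,
                  mds_embed, rank_distance, stress_curve)

__all__ = ["AnalysisResult", "run_cohort_analysis"]

#: features entering the elastic net by default: NK-related + interleukins
DEFAULT_CANDIDATE_PATTERN = r"NK\(|^IL-"


@dataclass
class AnalysisResult:
    """Everything the cohort analysis produces, in workflow order."""

    feature_table: pd.DataFrame
    z_table: pd.DataFrame
    distance: pd.DataFrame
    stress_curve: list[tuple[int, float]]
    n_dimensions: int
    embedding: MDSEmbedding
    screen: ScreenResult
    correlations: pd.DataFrame
    candidates: list[str]
    model: ElasticNetLogit
    scores: pd.Series
    evaluation: dict = field(default_factory=dict)

    @property
    def selected_coordinate(self) -> str:
        return self.screen.selected

    @property
    def significant_features(self) -> list[str]:
        return list(self.correlations.index[self.correlations["significant"]])


def run_cohort_analysis(
    events: pd.DataFrame,
    cytokines: pd.DataFrame,
    outcomes: pd.DataFrame,
    gating_tree: GatingTree | None = None,
    dims: int | None = 3,
    dims_range=range(1, 7),
    reps: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.05,
    candidate_pattern: str = DEFAULT_CANDIDATE_PATTERN,
    max_candidates: int = 11,
    mixing: float = 0.5,
    cofactor: float = 5.0,
) -> AnalysisResult:
    """Run the complete analysis on raw event/cytokine/outcome tables.

    ``dims`` pins the embedding dimensionality (3, the reference design);
    pass ``None`` to choose it from the stress curve by the elbow rule.
    ``candidate_pattern`` restricts elastic-net candidates among the
    significantly correlated features (NK-related features and interleukins
    by default); if fewer than two significant features match, the
    largest-|rho| matching features are used instead, capped at
    ``max_candidates``.
    """
    gated = gate_events(events, gating_tree, cofactor=cofactor)
    table = build_feature_table(gated, cytokines, outcomes, cofactor=cofactor)
    z_table = z_normalize(table)
    outcome = table[OUTCOME_COLUMN]

    D = rank_distance(z_table)
    curve = stress_curve(D, dims_range, seed=seed)
    n_dim = choose_dimension(curve, override=dims)
    emb = mds_embed(D, n_dim, seed=seed)
    emb.coordinates[:] = align_coordinate_signs(emb.coordinates, outcome)

    screen = screen_coordinates(emb.coordinates, outcome, reps=reps, seed=seed)
    coord = emb.coordinates[screen.selected]
    corr = correlate_features(
        z_table.drop(columns=[OUTCOME_COLUMN]), coord, q_threshold=q_threshold
    )

    pat = re.compile(candidate_pattern)
    sig = corr.index[corr["significant"]]
    candidates = [f for f in sig if pat.search(f)]
    if len(candidates) < 2:
        matching = corr.loc[[f for f in corr.index if pat.search(f)]]
        candidates = list(
            matching.reindex(matching["rho"].abs()
                             .sort_values(ascending=False).index).index
        )
    candidates = candidates[:max_candidates]

    model = fit_elastic_net(z_table[candidates], outcome, mixing=mixing,
                            seed=seed)
    scores = pd.Series(model.predicted_scores(z_table[candidates]),
                       index=z_table.index, name="predicted_score")
    evaluation = evaluate_score(scores.to_numpy(), outcome.to_numpy(),
                                reps=reps, seed=seed)
    return AnalysisResult(
        feature_table=table, z_table=z_table, distance=D, stress_curve=curve,
        n_dimensions=n_dim, embedding=emb, screen=screen, correlations=corr,
        candidates=candidates, model=model, scores=scores,
        evaluation=evaluation,
    )
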