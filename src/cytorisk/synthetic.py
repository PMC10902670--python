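"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a chronic-critical-illness cohort profiled by mass
cytometry: per-patient single-cell event tables over a 42-marker panel
(26 lineage + 16 metabolic regulators), a five-cytokine plasma panel with a
below-detection floor, and a binary nosocomial-infection outcome.

Model, all on the arcsinh(x/5) analysis scale (raw counts are ``5*sinh``):

* lineage markers are bimodal (negative/positive log-normal-type components)
  so each of the 21 subsets is separable by the default gating tree;
* metabolic regulators are Gaussian per (subset, marker) around a marker
  baseline, with three sources of between-patient variation: a global
  activation factor loading on every non-targeted feature, a lymphoid-vs-
  myeloid lineage factor, and idiosyncratic patient noise;
* features named in ``effect_map`` form an infection-responsive program:
  they carry only idiosyncratic patient noise plus, for infected patients,
  a mean shift of ``effect * marker SD`` (exact on the analysis scale);
* cytokines are log-normal per group, partially driven by the global factor,
  floored to 0 pg/mL below the detection limit.

Everything is reproducible bit-for-bit from ``CohortSpec.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import panel as P

__all__ = [
    "CytokineParams",
    "CohortSpec",
    "default_effect_map",
    "default_cytokine_params",
    "generate_cohort",
    "generate_expression",
    "latent_feature_table",
]


@dataclass(frozen=True)
class CytokineParams:
    """Log-normal cytokine model for one analyte (pg/mL).

    ``loc_uninfected``/``loc_infected`` are log-scale locations per outcome
    group, ``scale`` the idiosyncratic log-SD, and ``factor_loading`` the
    loading on the cohort's global inflammation factor.
    """

    loc_uninfected: float
    loc_infected: float
    scale: float = 0.7
    factor_loading: float = 0.5


def default_cytokine_params() -> dict[str, CytokineParams]:
    """IL-10 and IL-15 elevated in the infected group; others group-neutral."""
    return {
        "IL-6": CytokineParams(np.log(20.0), np.log(20.0)),
        "IL-8": CytokineParams(np.log(15.0), np.log(15.0)),
        "IL-10": CytokineParams(np.log(2.0), np.log(2.0) + 0.8),
        "IL-15": CytokineParams(np.log(1.5), np.log(1.5) + 0.6),
        "TNF-a": CytokineParams(np.log(10.0), np.log(10.0), scale=0.6),
    }


def default_effect_map(effect: float = 0.5) -> dict[tuple[str, str], float]:
    """NRF1 down / CPT1a up (in SD units) in every NK subset of infected patients."""
    out: dict[tuple[str, str], float] = {}
    for s in P.NK_SUBSETS:
        out[(s, "NRF1")] = -effect
        out[(s, "CPT1a")] = +effect
    return out


def _metabolic_baselines() -> dict[str, float]:
    # deterministic spread of baseline arcsinh levels across the panel
    lo, hi = 1.2, 2.8
    n = len(P.METABOLIC_MARKERS)
    return {
        m: lo + (hi - lo) * i / (n - 1) for i, m in enumerate(P.METABOLIC_MARKERS)
    }


@dataclass
class CohortSpec:
    """Study design for one synthetic cohort.

    Defaults reproduce the reference design: 37 patients of whom 16 (43.2%)
    develop nosocomial infection, with the NK NRF1/CPT1a program shifted by
    +-0.5 SD in the infected group and IL-10/IL-15 elevated.
    """

    n_patients: int = 37
    infection_rate: float = 16 / 37
    cells_per_patient: int = 5000
    subset_proportions: dict[str, float] = field(
        default_factory=lambda: dict(P.DEFAULT_PROPORTIONS)
    )
    effect_map: dict[tuple[str, str], float] = field(
        default_factory=default_effect_map
    )
    cytokine_params: dict[str, CytokineParams] = field(
        default_factory=default_cytokine_params
    )
    detection_limit: float = 1.0          # pg/mL; below -> reported as 0
    metabolic_sd: float = 0.40            # cell-level SD, arcsinh scale
    global_factor_sd: float = 0.18        # patient global-activation loading
    lineage_factor_sd: float = 0.10       # lymphoid/myeloid patient factor
    patient_noise_sd: float = 0.05        # idiosyncratic per-(subset,marker)
    lineage_jitter_sd: float = 0.05       # patient shift of lineage modes
    composition_factor: float = 0.25      # lineage-factor loading on logits
    composition_noise_sd: float = 0.10    # per-subset abundance logit noise
    lineage_separation: float = P.LINEAGE_POS - P.LINEAGE_NEG
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.infection_rate < 1.0:
            raise ValueError("infection_rate must lie strictly in (0, 1)")
        if self.cells_per_patient < 1:
            raise ValueError("cells_per_patient must be positive")
        total = float(sum(self.subset_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"subset_proportions must sum to 1 (got {total:.12g})"
            )
        if any(v < 0 for v in self.subset_proportions.values()):
            raise ValueError("subset_proportions must be nonnegative")
        unknown = set(self.subset_proportions) - set(P.SUBSET_PHENOTYPES)
        if unknown:
            raise ValueError(f"unknown subsets in proportions: {sorted(unknown)}")
        for (s, m) in self.effect_map:
            if s not in self.subset_proportions:
                raise ValueError(f"effect_map subset not in cohort: {s!r}")
            if m not in P.METABOLIC_MARKERS:
                raise ValueError(f"effect_map marker not in panel: {m!r}")
        for c, cp in self.cytokine_params.items():
            if cp.scale <= 0:
                raise ValueError(f"cytokine scale must be > 0 ({c})")
        for name in ("metabolic_sd", "lineage_separation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


def _assign_outcomes(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n_inf = int(round(spec.n_patients * spec.infection_rate))
    n_inf = min(max(n_inf, 1), spec.n_patients - 1)
    y = np.zeros(spec.n_patients, dtype=int)
    y[rng.permutation(spec.n_patients)[:n_inf]] = 1
    return y


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns ``(events, cytokines, outcomes)``.

    ``events`` has one row per cell: ``patient_id``, ground-truth
    ``subset_label`` and 42 raw (ion-count scale) marker intensities.
    ``cytokines`` and ``outcomes`` are per-patient tables indexed by
    ``patient_id``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    subsets = list(spec.subset_proportions)
    base_props = np.array([spec.subset_proportions[s] for s in subsets])
    patients = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    y = _assign_outcomes(spec, rng)

    baselines = _metabolic_baselines()
    neg = P.LINEAGE_NEG
    pos = neg + spec.lineage_separation
    bright = pos + (P.CD56_BRIGHT - P.LINEAGE_POS)
    level_means = {0: neg, 1: pos, 2: bright}

    # patient-level latent factors
    g_global = rng.standard_normal(spec.n_patients)
    g_lineage = rng.standard_normal(spec.n_patients)
    # idiosyncratic patient effect per (subset, metabolic marker)
    idio = rng.normal(
        0.0, spec.patient_noise_sd,
        size=(spec.n_patients, len(subsets), len(P.METABOLIC_MARKERS)),
    )
    # patient jitter of lineage marker modes
    lin_jitter = rng.normal(
        0.0, spec.lineage_jitter_sd,
        size=(spec.n_patients, len(P.LINEAGE_MARKERS)),
    )

    frames: list[pd.DataFrame] = []
    for p_idx, pid in enumerate(patients):
        logits = np.log(np.maximum(base_props, 1e-12))
        logits = logits + spec.composition_factor * g_lineage[p_idx] * np.array(
            [P.SUBSET_COMPARTMENT[s] for s in subsets]
        )
        logits = logits + rng.normal(0.0, spec.composition_noise_sd, len(subsets))
        props = np.exp(logits - logits.max())
        props /= props.sum()
        counts = rng.multinomial(spec.cells_per_patient, props)

        n_cells = counts.sum()
        X = np.empty((n_cells, len(P.ALL_MARKERS)))
        labels = np.repeat(subsets, counts)

        row = 0
        for s_idx, s in enumerate(subsets):
            c = counts[s_idx]
            if c == 0:
                continue
            pheno = P.SUBSET_PHENOTYPES[s]
            # lineage block
            for m_idx, m in enumerate(P.LINEAGE_MARKERS):
                mu = level_means[pheno.get(m, 0)] + lin_jitter[p_idx, m_idx]
                X[row:row + c, m_idx] = rng.normal(mu, P.LINEAGE_SD, c)
            # metabolic block
            off = len(P.LINEAGE_MARKERS)
            for m_idx, m in enumerate(P.METABOLIC_MARKERS):
                mu = baselines[m] + idio[p_idx, s_idx, m_idx]
                if (s, m) in spec.effect_map:
                    if y[p_idx]:
                        mu += spec.effect_map[(s, m)] * spec.metabolic_sd
                else:
                    mu += spec.global_factor_sd * g_global[p_idx]
                    mu += (
                        spec.lineage_factor_sd
                        * P.SUBSET_COMPARTMENT[s]
                        * g_lineage[p_idx]
                    )
                X[row:row + c, off + m_idx] = rng.normal(mu, spec.metabolic_sd, c)
            row += c

        raw = 5.0 * np.sinh(X)
        np.maximum(raw, 0.0, out=raw)
        df = pd.DataFrame(raw, columns=list(P.ALL_MARKERS))
        df.insert(0, "subset_label", labels)
        df.insert(0, "patient_id", pid)
        frames.append(df)

    events = pd.concat(frames, ignore_index=True)

    # cytokines (pg/mL) with detection floor
    cyto = {}
    for c, cp in spec.cytokine_params.items():
        loc = np.where(y == 1, cp.loc_infected, cp.loc_uninfected)
        logx = loc + cp.factor_loading * g_global + rng.normal(
            0.0, cp.scale, spec.n_patients
        )
        x = np.exp(logx)
        x[x < spec.detection_limit] = 0.0
        cyto[c] = x
    cytokines = pd.DataFrame(cyto, index=pd.Index(patients, name="patient_id"))

    outcomes = pd.DataFrame(
        {"infection": y}, index=pd.Index(patients, name="patient_id")
    )
    return events, cytokines, outcomes


def generate_expression(
    n_cells_per_group: int,
    groups: list[str],
    signature_genes: list[str],
    planted_shift: dict[str, float] | list[float],
    seed: int,
    n_genes: int = 300,
    dispersion: float = 2.0,
    cell_type: str = "NK",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with a gene signature shifted per group.

    Gene means are log-normal across a universe of ``n_genes`` genes named
    ``G0001..``; the signature genes' means are multiplied by
    ``exp(planted_shift[group])`` in each group.  Returns
    ``(counts, cell_meta)`` with cells as rows.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(signature_genes) == 0:
        raise ValueError("signature gene set is empty")
    if len(set(signature_genes)) != len(signature_genes):
        raise ValueError("duplicate gene names in signature")
    gene_names = [f"G{i + 1:04d}" for i in range(n_genes)]
    missing = set(signature_genes) - set(gene_names)
    if missing:
        raise ValueError(f"signature genes outside gene universe: {sorted(missing)}")
    if isinstance(planted_shift, (list, tuple, np.ndarray)):
        if len(planted_shift) != len(groups):
            raise ValueError("planted_shift length must match groups")
        planted_shift = dict(zip(groups, planted_shift))

    rng = np.random.default_rng(seed)
    base_mu = np.exp(rng.normal(0.0, 1.0, n_genes))
    sig_mask = np.isin(gene_names, signature_genes)

    blocks, meta_rows = [], []
    for g in groups:
        mu = base_mu.copy()
        mu[sig_mask] *= np.exp(float(planted_shift.get(g, 0.0)))
        p = dispersion / (dispersion + mu)
        counts = rng.negative_binomial(
            dispersion, p[None, :], size=(n_cells_per_group, n_genes)
        )
        blocks.append(counts)
        meta_rows.extend((g, cell_type) for _ in range(n_cells_per_group))

    cells = [f"cell{i + 1:05d}" for i in range(n_cells_per_group * len(groups))]
    counts = pd.DataFrame(
        np.vstack(blocks), index=pd.Index(cells, name="cell"), columns=gene_names
    )
    meta = pd.DataFrame(
        meta_rows, index=counts.index, columns=["group", "cell_type"]
    )
    return counts, meta


def latent_feature_table(
    n_patients: int = 37,
    latent_dim: int = 3,
    n_features: int = 40,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Patient feature table with a known latent dimensionality.

    Patients occupy ``latent_dim`` orthogonal, equal-variance latent axes
    (orthonormalized Gaussian draws) mapped to features through a random
    orthonormal-row linear map plus Gaussian noise; the equal axis strengths
    make the planted dimensionality the unambiguous elbow of the stress
    curve.  Used to exercise the dimensionality diagnostic against ground
    truth.
    """
    rng = np.random.default_rng(seed)
    Z, _ = np.linalg.qr(rng.standard_normal((n_patients, latent_dim)))
    Z *= np.sqrt(n_patients)
    W, _ = np.linalg.qr(rng.standard_normal((n_features, latent_dim)))
    W = W.T * np.sqrt(n_features)
    X = Z @ W + rng.normal(0.0, noise_sd, (n_patients, n_features))
    idx = pd.Index([f"P{i + 1:02d}" for i in range(n_patients)], name="patient_id")
    cols = [f"f{j + 1:03d}" for j in range(n_features)]
    return pd.DataFrame(X, index=idx, columns=cols), Z
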