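"""Default CyTOF panel, immune-subset definitions, and manual gating hierarchy.

The default panel mirrors a 42-antibody immunometabolic profiling design:
26 lineage markers used for manual gating of 21 peripheral-blood immune
subsets, plus 16 intracellular metabolic regulators (glycolysis, fatty-acid
oxidation, TCA cycle, oxidative phosphorylation, mitochondrial dynamics and
biogenesis) quantified within each subset.

Subsets are encoded as *expression levels* per lineage marker: 0 (negative),
1 (positive / dim for CD56) or 2 (bright, CD56 only).  The default gating
tree thresholds sit in the valley between the negative and positive modes on
the arcsinh(x/5) scale, so simulated events are recoverable by gating.
"""

from __future__ import annotations

LINEAGE_MARKERS: tuple[str, ...] = (
    "CD1c", "CD3", "CD4", "CD8", "CD11c", "CD14", "CD16", "CD19", "CD38",
    "CD39", "CD45", "CD45RA", "CD56", "CD57", "CD66b", "CD86", "CD123",
    "CD141", "CD161", "CD197", "CCR2", "FoxP3", "HLA-DR", "PD1",
    "TCRVa7.2", "TCRgd",
)

METABOLIC_MARKERS: tuple[str, ...] = (
    "ATP5a", "ACADM", "CPT1a", "CS", "CytC", "DRP1", "GAPDH", "GLUT1",
    "HADHA", "HK2", "LDH", "NRF1", "OGDH", "OPA1", "PGC1a", "VDAC",
)

ALL_MARKERS: tuple[str, ...] = LINEAGE_MARKERS + METABOLIC_MARKERS

CYTOKINES: tuple[str, ...] = ("IL-6", "IL-8", "IL-10", "IL-15", "TNF-a")

# Arcsinh-scale component means for lineage markers: negative / positive
# (CD56 carries a third, bright, component).
LINEAGE_NEG = 0.6
LINEAGE_POS = 3.0
CD56_BRIGHT = 5.0
LINEAGE_SD = 0.35

#: per-subset lineage phenotype; markers not listed are negative (level 0)
SUBSET_PHENOTYPES: dict[str, dict[str, int]] = {
    "naive CD4T":            {"CD45": 1, "CD3": 1, "CD4": 1, "CD45RA": 1, "CD197": 1},
    "central memory CD4T":   {"CD45": 1, "CD3": 1, "CD4": 1, "CD197": 1},
    "effector memory CD4T":  {"CD45": 1, "CD3": 1, "CD4": 1},
    "TEMRA CD4T":            {"CD45": 1, "CD3": 1, "CD4": 1, "CD45RA": 1},
    "Treg":                  {"CD45": 1, "CD3": 1, "CD4": 1, "FoxP3": 1, "CD39": 1},
    "naive CD8T":            {"CD45": 1, "CD3": 1, "CD8": 1, "CD45RA": 1, "CD197": 1},
    "central memory CD8T":   {"CD45": 1, "CD3": 1, "CD8": 1, "CD197": 1},
    "effector memory CD8T":  {"CD45": 1, "CD3": 1, "CD8": 1},
    "TEMRA CD8T":            {"CD45": 1, "CD3": 1, "CD8": 1, "CD45RA": 1, "CD57": 1},
    "gdT":                   {"CD45": 1, "CD3": 1, "TCRgd": 1},
    "MAIT":                  {"CD45": 1, "CD3": 1, "TCRVa7.2": 1, "CD161": 1, "CD8": 1},
    "NKT":                   {"CD45": 1, "CD3": 1, "CD56": 1, "CD161": 1},
    "NK(CD56bright)":        {"CD45": 1, "CD56": 2, "CD161": 1},
    "NK(CD56dimCD57-)":      {"CD45": 1, "CD56": 1, "CD16": 1},
    "NK(CD56dimCD57+)":      {"CD45": 1, "CD56": 1, "CD16": 1, "CD57": 1},
    "B cells":               {"CD45": 1, "CD19": 1, "HLA-DR": 1},
    "classical monocytes":   {"CD45": 1, "CD14": 1, "CD11c": 1, "HLA-DR": 1, "CCR2": 1},
    "intermediate monocytes": {"CD45": 1, "CD14": 1, "CD16": 1, "CD11c": 1, "HLA-DR": 1},
    "non-classical monocytes": {"CD45": 1, "CD16": 1, "CD11c": 1, "HLA-DR": 1},
    "mDC":                   {"CD45": 1, "CD11c": 1, "CD1c": 1, "CD141": 1, "HLA-DR": 1},
    "pDC":                   {"CD45": 1, "CD123": 1, "HLA-DR": 1},
}

SUBSETS: tuple[str, ...] = tuple(SUBSET_PHENOTYPES)

NK_SUBSETS: tuple[str, ...] = (
    "NK(CD56bright)", "NK(CD56dimCD57-)", "NK(CD56dimCD57+)",
)

#: lymphoid (+1) vs myeloid (-1) axis used by the composition/lineage factor
SUBSET_COMPARTMENT: dict[str, int] = {
    s: (-1 if ("monocyte" in s or s in ("mDC", "pDC")) else 1) for s in SUBSETS
}

#: resting blood composition (fractions of gated PBMC events, sums to 1)
DEFAULT_PROPORTIONS: dict[str, float] = {
    "naive CD4T": 0.08, "central memory CD4T": 0.10,
    "effector memory CD4T": 0.07, "TEMRA CD4T": 0.03, "Treg": 0.03,
    "naive CD8T": 0.04, "central memory CD8T": 0.04,
    "effector memory CD8T": 0.05, "TEMRA CD8T": 0.05,
    "gdT": 0.03, "MAIT": 0.03, "NKT": 0.02,
    "NK(CD56bright)": 0.015, "NK(CD56dimCD57-)": 0.06,
    "NK(CD56dimCD57+)": 0.055, "B cells": 0.08,
    "classical monocytes": 0.105, "intermediate monocytes": 0.04,
    "non-classical monocytes": 0.04, "mDC": 0.02, "pDC": 0.015,
}

GATE_THRESHOLD = 1.8          # valley between negative and positive modes
CD56_BRIGHT_THRESHOLD = 4.0   # valley between dim and bright CD56


def _leaf(subset: str | None) -> dict:
    return {"subset": subset}


def _split(marker: str, above, below, threshold: float = GATE_THRESHOLD) -> dict:
    return {"marker": marker, "threshold": threshold, "above": above, "below": below}


def default_gating_tree() -> dict:
    """Nested-dict manual gating hierarchy resolving the 21 default subsets.

    Binary splits on arcsinh-transformed lineage intensities; events falling
    outside every terminal phenotype resolve to the ``None`` (ungated) leaf.
    """
    memory_quadrants = lambda prefix: _split(
        "CD45RA",
        _split("CD197", _leaf(f"naive {prefix}"), _leaf(f"TEMRA {prefix}")),
        _split("CD197", _leaf(f"central memory {prefix}"),
               _leaf(f"effector memory {prefix}")),
    )
    cd4_branch = _split("FoxP3", _leaf("Treg"), memory_quadrants("CD4T"))
    t_branch = _split(
        "TCRgd",
        _leaf("gdT"),
        _split(
            "TCRVa7.2",
            _leaf("MAIT"),
            _split(
                "CD56",
                _leaf("NKT"),
                _split("CD4", cd4_branch,
                       _split("CD8", memory_quadrants("CD8T"), _leaf(None))),
            ),
        ),
    )
    nk_branch = _split(
        "CD56",
        _leaf("NK(CD56bright)"),
        _split("CD57", _leaf("NK(CD56dimCD57+)"), _leaf("NK(CD56dimCD57-)")),
        threshold=CD56_BRIGHT_THRESHOLD,
    )
    myeloid_branch = _split(
        "CD14",
        _split("CD16", _leaf("intermediate monocytes"), _leaf("classical monocytes")),
        _split(
            "CD16",
            _leaf("non-classical monocytes"),
            _split("CD123", _leaf("pDC"),
                   _split("CD11c", _leaf("mDC"), _leaf(None))),
        ),
    )
    non_t = _split("CD19", _leaf("B cells"),
                   _split("CD56", nk_branch, myeloid_branch))
    return _split("CD45", _split("CD3", t_branch, non_t), _leaf(None))
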