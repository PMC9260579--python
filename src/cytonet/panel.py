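"""Marker panel and the designed immune-subset catalogue.

The default panel carries 36 surface markers chosen to resolve six major
immune lineages (CD4 T, CD8 T, TCRgd T, innate lymphoid/NK, B, myeloid)
plus activation, maturation and residency markers. A validation-cohort
variant extends it to 39 markers. Forty-four subsets are defined across
the six lineages; each subset is a point in arcsinh-expression space
(mean vector + spread) and carries composition metadata used by the
synthetic-study generator: its latent co-abundance module, its
inflammation effect (enriched / depleted / null) and tissue baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LINEAGES = ("CD4 T", "CD8 T", "TCRgd T", "ILC", "B", "Myeloid")

MODULES = ("network1", "network2", "network3", "none")

#: arcsinh-scale expression levels used by the subset templates.
LOW = 0.5
HIGH = 3.5

_PRIMARY_MARKERS = [
    "CD45", "CD3", "CD4", "CD8a", "TCRgd", "CD7", "CD127", "CD161",
    "CD56", "CD16", "CD27", "CD28", "CD45RA", "CD45RO", "CCR7", "CCR6",
    "CXCR3", "CD25", "CD38", "HLA-DR", "PD-1", "CD103", "CD69", "CD19",
    "CD20", "CD123", "CD11b", "CD11c", "CD14", "CD15", "CD163", "CRTH2",
    "NKp46", "KLRG1", "ICOS", "CD34",
]

#: extra channels on the optimized validation panel.
_VALIDATION_EXTRAS = ["CD117", "Siglec-8", "CD64"]


@dataclass(frozen=True)
class MarkerPanel:
    """Named marker channels plus lineage gating signatures.

    ``lineage_signatures`` maps each lineage to the markers required high
    and required low; lineage assignment scores a cell as
    ``mean(high markers) - mean(low markers)``.
    """

    names: tuple[str, ...]
    lineage_signatures: dict[str, dict[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("marker names must be unique")
        for lin, sig in self.lineage_signatures.items():
            for side in ("high", "low"):
                missing = set(sig[side]) - set(self.names)
                if missing:
                    raise ValueError(f"{lin} signature markers {missing} not in panel")

    @property
    def size(self) -> int:
        return len(self.names)

    def index(self, marker: str) -> int:
        return self.names.index(marker)


_SIGNATURES = {
    "CD4 T": {"high": ("CD3", "CD4"), "low": ("CD8a", "TCRgd", "CD19", "CD11b")},
    "CD8 T": {"high": ("CD3", "CD8a"), "low": ("CD4", "TCRgd", "CD19", "CD11b")},
    "TCRgd T": {"high": ("CD3", "TCRgd"), "low": ("CD19", "CD11b")},
    "ILC": {"high": ("CD7",), "low": ("CD3", "CD14")},
    "B": {"high": ("CD19", "HLA-DR"), "low": ("CD3", "CD7", "CD14")},
    "Myeloid": {"high": ("CD11b",), "low": ("CD3", "CD19", "CD7")},
}


def default_panel(validation: bool = False) -> MarkerPanel:
    """The 36-marker discovery panel, or the 39-marker validation variant."""
    names = list(_PRIMARY_MARKERS) + (_VALIDATION_EXTRAS if validation else [])
    return MarkerPanel(names=tuple(names), lineage_signatures=dict(_SIGNATURES))


@dataclass(frozen=True)
class SubsetDefinition:
    """One designed immune subset.

    ``phenotype`` lists only markers that deviate from the panel-wide
    baseline (``LOW`` everywhere, CD45 bright); ``mean_vector`` realizes
    the full per-marker mean for a given panel. ``baseline_gut`` /
    ``baseline_blood`` are log-abundance offsets of the composition model,
    ``loading`` is the subset's weight on its module latent factor, and
    ``effect``/``effect_size`` encode the inflammation shift.
    """

    subset_id: str
    lineage: str
    phenotype: dict[str, float]
    module: str
    effect: str | None = None
    effect_size: float = 1.0
    loading: float = 0.7
    baseline_gut: float = 0.0
    baseline_blood: float = 0.0
    sd: float = 0.35

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}")
        if self.module not in MODULES:
            raise ValueError(f"unknown module {self.module!r}")
        if self.effect not in (None, "up_in_inflamed", "down_in_inflamed"):
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.sd <= 0:
            raise ValueError("marker spread must be positive")

    def mean_vector(self, panel: MarkerPanel) -> np.ndarray:
        mu = np.full(panel.size, LOW)
        mu[panel.index("CD45")] = 4.5
        for marker, level in self.phenotype.items():
            if marker in panel.names:
                mu[panel.index(marker)] = level
        return mu

    def sd_vector(self, panel: MarkerPanel) -> np.ndarray:
        return np.full(panel.size, self.sd)


def _t4(extra):
    base = {"CD3": 4.0, "CD4": 4.0, "CD7": HIGH, "CD127": 3.0}
    base.update(extra)
    return base


def _t8(extra):
    base = {"CD3": 4.0, "CD8a": 4.0, "CD7": HIGH, "CD127": 2.5}
    base.update(extra)
    return base


def _tgd(extra):
    base = {"CD3": 4.0, "TCRgd": 4.0, "CD7": HIGH}
    base.update(extra)
    return base


def _ilc(extra):
    base = {"CD7": HIGH}
    base.update(extra)
    return base


def _b(extra):
    base = {"CD19": 4.0, "CD20": HIGH, "HLA-DR": 3.0}
    base.update(extra)
    return base


def _my(extra):
    base = {"CD11b": 4.0}
    base.update(extra)
    return base


def _S(sid, lineage, pheno, module, effect=None, loading=0.7, gut=0.0, blood=0.0):
    return SubsetDefinition(
        subset_id=sid, lineage=lineage, phenotype=pheno, module=module,
        effect=effect, loading=loading, baseline_gut=gut, baseline_blood=blood,
    )


def build_default_subsets() -> list[SubsetDefinition]:
    """The 44-subset catalogue used by the synthetic-study generator.

    Module composition mirrors the co-abundance structure the analysis is
    designed to detect: an 11-member module depleted in inflamed tissue
    (10 subsets carry the depletion effect), a 21-member module enriched
    in inflamed tissue (11 carry the enrichment effect), a 9-member
    blood-infiltrate module of naive/central-memory subsets, and 3
    residual subsets outside any qualified module.
    """
    up, down = "up_in_inflamed", "down_in_inflamed"
    S = _S
    subsets = [
        # ---- CD4 T (9) -------------------------------------------------
        S("cd4_naive", "CD4 T", _t4({"CD45RA": HIGH, "CCR7": HIGH, "CD27": HIGH, "CD28": HIGH}),
          "network3", gut=-0.6, blood=1.5),
        S("cd4_cm", "CD4 T", _t4({"CD45RO": HIGH, "CCR7": HIGH, "CD27": HIGH, "CD28": HIGH}),
          "network3", loading=0.8, gut=-0.3, blood=1.2),
        S("cd4_em", "CD4 T", _t4({"CD45RO": HIGH, "CD28": HIGH}),
          "network2", loading=0.65, gut=0.0, blood=0.3),
        S("cd4_temra", "CD4 T", _t4({"CD45RA": HIGH, "KLRG1": HIGH}),
          "network3", loading=0.65, gut=-0.8, blood=0.5),
        S("cd4_th17", "CD4 T", _t4({"CD45RO": HIGH, "CCR6": HIGH, "CD161": HIGH, "CD28": HIGH}),
          "network2", up, loading=0.8, gut=-0.6, blood=0.0),
        S("cd4_th1", "CD4 T", _t4({"CD45RO": HIGH, "CXCR3": HIGH, "CD27": HIGH, "CD28": HIGH}),
          "network2", loading=0.7, gut=-0.3, blood=0.0),
        S("cd4_treg", "CD4 T", _t4({"CD45RO": HIGH, "CD25": 4.0, "ICOS": HIGH, "CD127": LOW}),
          "network2", up, loading=0.75, gut=-0.7, blood=0.0),
        S("cd4_act_em", "CD4 T",
          _t4({"CD45RO": HIGH, "HLA-DR": HIGH, "CD38": HIGH, "PD-1": HIGH, "CD69": HIGH}),
          "network2", up, loading=0.85, gut=-0.9, blood=-1.5),
        S("cd4_trm", "CD4 T", _t4({"CD45RO": HIGH, "CD103": HIGH, "CD69": HIGH, "CD28": HIGH}),
          "network1", down, loading=0.65, gut=0.8, blood=-2.5),
        # ---- CD8 T (8) -------------------------------------------------
        S("cd8_naive", "CD8 T", _t8({"CD45RA": HIGH, "CCR7": HIGH, "CD27": HIGH, "CD28": HIGH}),
          "network3", loading=0.75, gut=-0.6, blood=1.5),
        S("cd8_cm", "CD8 T", _t8({"CD45RO": HIGH, "CCR7": HIGH, "CD27": HIGH, "CD28": HIGH}),
          "network3", loading=0.7, gut=-0.3, blood=1.2),
        S("cd8_em", "CD8 T", _t8({"CD45RO": HIGH, "CD28": HIGH}),
          "network2", loading=0.6, gut=0.0, blood=0.3),
        S("cd8_temra", "CD8 T", _t8({"CD45RA": HIGH, "KLRG1": HIGH}),
          "network3", loading=0.8, gut=-0.6, blood=0.8),
        S("cd8_trm", "CD8 T", _t8({"CD45RO": HIGH, "CD103": HIGH, "CD69": HIGH}),
          "network1", down, loading=0.65, gut=0.8, blood=-2.5),
        S("cd8_act_em", "CD8 T",
          _t8({"CD45RO": HIGH, "HLA-DR": HIGH, "CD38": HIGH, "PD-1": HIGH, "CD69": HIGH}),
          "network2", up, loading=0.8, gut=-1.0, blood=-2.0),
        S("cd8_mait", "CD8 T", _t8({"CD45RO": HIGH, "CD161": 4.0, "CCR6": HIGH, "CD127": HIGH}),
          "network1", down, loading=0.6, gut=0.2, blood=0.0),
        S("cd8_iel", "CD8 T",
          _t8({"CD45RO": HIGH, "CD103": HIGH, "CD69": HIGH, "CD38": HIGH, "CD127": LOW}),
          "network1", down, loading=0.6, gut=0.5, blood=-2.5),
        # ---- TCRgd T (5) -----------------------------------------------
        S("gd_naive", "TCRgd T", _tgd({"CD45RA": HIGH, "CD27": HIGH, "CCR7": HIGH}),
          "network3", loading=0.65, gut=-0.9, blood=0.2),
        S("gd_em", "TCRgd T", _tgd({"CD45RO": HIGH, "CD69": HIGH}),
          "none", gut=0.3, blood=0.0),
        S("gd_cd8", "TCRgd T", _tgd({"CD8a": HIGH, "CD45RO": HIGH, "CD27": HIGH}),
          "network1", loading=0.55, gut=0.1, blood=-2.5),
        S("gd_ccr6", "TCRgd T", _tgd({"CD45RO": HIGH, "CCR6": HIGH, "CD161": HIGH}),
          "network1", down, loading=0.6, gut=0.1, blood=-2.5),
        S("gd_act", "TCRgd T", _tgd({"CD45RO": HIGH, "HLA-DR": HIGH, "CD38": HIGH, "CD69": HIGH}),
          "network2", up, loading=0.7, gut=-1.2, blood=-2.0),
        # ---- ILC / NK (7) ----------------------------------------------
        S("nk_cd56bright", "ILC", _ilc({"CD56": 4.5, "NKp46": HIGH}),
          "network1", down, loading=0.55, gut=-0.1, blood=-0.5),
        S("nk_cd16", "ILC", _ilc({"CD56": 3.0, "CD16": 4.0, "NKp46": HIGH, "KLRG1": HIGH}),
          "network3", loading=0.7, gut=-0.5, blood=1.2),
        S("nk_trm", "ILC", _ilc({"CD56": 4.0, "NKp46": HIGH, "CD69": HIGH, "CD103": HIGH}),
          "network1", down, loading=0.65, gut=0.2, blood=-2.5),
        S("nk_act", "ILC", _ilc({"CD56": 4.0, "NKp46": HIGH, "HLA-DR": HIGH, "CD38": HIGH}),
          "network2", up, loading=0.7, gut=-1.2, blood=-1.5),
        S("ilc1", "ILC", _ilc({"CD127": HIGH, "CD161": HIGH, "CXCR3": HIGH}),
          "network2", loading=0.65, gut=-0.7, blood=-1.0),
        S("ilc2", "ILC", _ilc({"CD127": HIGH, "CRTH2": HIGH, "CD161": HIGH, "CD25": 3.0}),
          "none", gut=-0.7, blood=-0.7),
        S("ilc3", "ILC", _ilc({"CD127": HIGH, "CCR6": HIGH, "NKp46": HIGH}),
          "network1", down, loading=0.6, gut=0.0, blood=-2.5),
        # ---- B (6) ------------------------------------------------------
        S("b_naive", "B", _b({"CD45RA": HIGH}),
          "network3", loading=0.75, gut=-0.4, blood=1.3),
        S("b_memory", "B", _b({"CD27": HIGH}),
          "none", gut=0.2, blood=0.8),
        S("b_activated", "B", _b({"CD27": HIGH, "CD69": HIGH, "CD38": HIGH}),
          "network2", loading=0.7, gut=-0.6, blood=-1.5),
        S("b_tissue_mem", "B", _b({"CD27": HIGH, "CCR6": HIGH, "CD69": HIGH}),
          "network1", down, loading=0.6, gut=0.2, blood=-2.5),
        S("b_plasmablast", "B", _b({"CD27": HIGH, "CD38": 4.5, "CD20": LOW}),
          "network2", up, loading=0.75, gut=-0.9, blood=-1.0),
        S("b_plasma", "B", _b({"CD27": HIGH, "CD38": 4.5, "CD20": LOW, "CD19": 2.5,
                               "HLA-DR": 1.5}),
          "network2", up, loading=0.65, gut=-0.6, blood=-1.5),
        # ---- Myeloid (9) -------------------------------------------------
        S("mono_classical", "Myeloid", _my({"CD14": 4.0, "CD11c": HIGH, "HLA-DR": 3.0}),
          "network2", up, loading=0.75, gut=-0.8, blood=1.2),
        S("mono_nonclassical", "Myeloid",
          _my({"CD16": 4.0, "CD11c": HIGH, "HLA-DR": 3.0, "CD14": 0.8}),
          "network2", loading=0.6, gut=-0.8, blood=0.3),
        S("mac_resident", "Myeloid", _my({"CD14": 4.0, "CD163": HIGH, "HLA-DR": 3.0}),
          "network1", down, loading=0.6, gut=0.4, blood=-3.0),
        S("mono_infl", "Myeloid",
          _my({"CD14": 4.0, "CD11c": HIGH, "HLA-DR": 4.5, "CD38": HIGH}),
          "network2", up, loading=0.85, gut=-1.1, blood=-1.0),
        S("cdc", "Myeloid", _my({"CD11c": 4.0, "HLA-DR": 4.5}),
          "network2", loading=0.65, gut=-0.7, blood=0.0),
        S("pdc", "Myeloid", _my({"CD123": 4.0, "HLA-DR": HIGH}),
          "network2", loading=0.6, gut=-0.9, blood=0.0),
        S("neutrophil", "Myeloid", _my({"CD15": 4.0, "CD16": HIGH, "HLA-DR": LOW}),
          "network2", up, loading=0.8, gut=-0.9, blood=0.3),
        S("eosinophil", "Myeloid", _my({"CD15": HIGH, "CRTH2": HIGH, "HLA-DR": LOW}),
          "network2", loading=0.7, gut=-1.0, blood=-1.0),
        S("basophil", "Myeloid", _my({"CD123": HIGH, "CRTH2": HIGH, "HLA-DR": LOW}),
          "network2", loading=0.6, gut=-1.2, blood=-0.3),
    ]
    return subsets


#: validation-panel extra channels get subset-specific means for a few
#: populations; everything else sits at baseline.
_EXTRA_PHENOTYPES = {
    "CD117": {"ilc2": 3.0, "ilc3": 2.5, "basophil": 2.5},
    "Siglec-8": {"eosinophil": 3.5, "basophil": 3.0},
    "CD64": {"mono_classical": 3.0, "mono_infl": 3.5, "mac_resident": 3.0},
}


def extend_phenotype_for_validation(subset: SubsetDefinition) -> SubsetDefinition:
    """Subset definition with means for the 3 extra validation channels."""
    pheno = dict(subset.phenotype)
    for marker, table in _EXTRA_PHENOTYPES.items():
        if subset.subset_id in table:
            pheno[marker] = table[subset.subset_id]
    return SubsetDefinition(
        subset_id=subset.subset_id, lineage=subset.lineage, phenotype=pheno,
        module=subset.module, effect=subset.effect, effect_size=subset.effect_size,
        loading=subset.loading, baseline_gut=subset.baseline_gut,
        baseline_blood=subset.baseline_blood, sd=subset.sd,
    )


def check_separability(
    subsets: list[SubsetDefinition],
    panel: MarkerPanel,
    min_markers: int = 2,
    min_delta: float = 1.5,
) -> None:
    """Assert every subset pair differs by >= ``min_delta`` arcsinh units in
    >= ``min_markers`` markers; raises ``ValueError`` listing offenders."""
    means = np.stack([s.mean_vector(panel) for s in subsets])
    bad = []
    for i in range(len(subsets)):
        for j in range(i + 1, len(subsets)):
            n_diff = int((np.abs(means[i] - means[j]) >= min_delta).sum())
            if n_diff < min_markers:
                bad.append((subsets[i].subset_id, subsets[j].subset_id, n_diff))
    if bad:
        raise ValueError(f"subset pairs below separability guarantee: {bad}")
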