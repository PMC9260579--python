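"""Synthetic mass-cytometry study generator.

Emulates the statistical structure of a two-cohort IBD tissue study:
per-subject paired intestinal biopsies plus blood, inflamed and
noninflamed samples, latent co-varying subset modules, designed
inflammation effects, and replicate internal-control samples.

The composition model is logistic-normal with latent module factors:

.. math::

    \\log a_{sk} = b_{k,\\text{tissue}} + u_{jk} + \\lambda_k f_{s,m(k)}
                   + \\delta_k \\, [s\\ \\text{inflamed}] + \\epsilon_{sk}

followed by a softmax over subsets ``k``; cell counts are multinomial
and marker intensities per cell are Gaussian around the subset's
arcsinh-scale mean vector, truncated at zero. ``u`` is a subject random
effect shared across a subject's samples, ``f`` a per-sample latent
factor shared within each module, and ``delta_k`` the per-subset
inflammation effect on log-abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CellTable, GroundTruth, Study
from .panel import (
    MarkerPanel,
    SubsetDefinition,
    build_default_subsets,
    check_separability,
    default_panel,
    extend_phenotype_for_validation,
)

COHORTS = ("primary", "validation")


@dataclass(frozen=True, eq=False)
class GeneratorConfig:
    """Fully specifies one synthetic cohort.

    Composition-model parameters (all on the log-abundance scale):
    ``sigma_subj`` subject random effect, ``sigma_mod`` module latent
    factor, ``sigma_res`` the weak latent factor shared by the residual
    (module='none') subsets, ``sigma_noise`` independent per-sample
    noise, ``delta`` the inflammation effect size carried by the
    designed effect subsets, ``module_shift`` an optional inflammation
    shift of the module factor means themselves (+ for the enriched
    module, - for the depleted one).
    """

    cohort: str
    panel: MarkerPanel
    subsets: tuple[SubsetDefinition, ...]
    #: subject table: subject_id, diagnosis in {control, CD, UC}.
    subjects: pd.DataFrame
    cells_per_sample: dict = field(
        default_factory=lambda: {"ileum": 2000, "colon": 1000, "blood": 5000}
    )
    inflamed_count_factor: float = 3.0
    count_dispersion: float = 0.35
    sigma_subj: float = 0.3
    sigma_mod: float = 1.0
    sigma_res: float = 0.8
    sigma_noise: float = 0.3
    delta: float = 1.0
    module_shift: float = 0.0
    #: optional designated high-network2 patient subgroup: the first
    #: ``n_high_n2`` IBD subjects get an extra log-abundance shift of the
    #: enriched-effect subsets in their inflamed samples (off by default;
    #: strong inflamed enrichment in a patient subset already emerges
    #: from the effect shifts alone).
    high_n2_boost: float = 1.5
    n_high_n2: int = 0
    #: log-abundance spike of the activated EM CD4 subset in IBD blood.
    blood_spike: float = 2.0
    blood_spike_subset: str = "cd4_act_em"
    n_internal_controls: int = 7
    batch_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        for name in ("sigma_subj", "sigma_mod", "sigma_res", "sigma_noise",
                     "count_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.cells_per_sample.values()) < 100:
            raise ValueError("cells_per_sample means must be >= 100")
        check_separability(list(self.subsets), self.panel)

    @property
    def subset_ids(self) -> list[str]:
        return [s.subset_id for s in self.subsets]

    def subset_info(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset_id": [s.subset_id for s in self.subsets],
                "lineage": [s.lineage for s in self.subsets],
                "module": [s.module for s in self.subsets],
                "effect": [s.effect for s in self.subsets],
                "effect_size": [s.effect_size for s in self.subsets],
                "loading": [s.loading for s in self.subsets],
            }
        )


def _subject_table(cohort: str) -> pd.DataFrame:
    if cohort == "primary":
        groups = [("control", 11), ("CD", 13), ("UC", 10)]
    else:
        groups = [("control", 15), ("CD", 10), ("UC", 9)]
    rows = []
    for diagnosis, n in groups:
        for i in range(n):
            rows.append({
                "subject_id": f"{cohort[:4]}_{diagnosis}_{i + 1:02d}",
                "diagnosis": diagnosis,
            })
    return pd.DataFrame(rows)


def default_config(cohort: str) -> GeneratorConfig:
    """Deterministic study configuration for the given cohort tag.

    The primary cohort carries 11 controls, 13 CD and 10 UC patients on
    the 36-marker panel; the validation cohort 15 controls and 19 IBD
    patients on the 39-marker panel, so that,
    pooled, 42 IBD patients mirror the cohort structure of the study the
    generator emulates.
    """
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")
    validation = cohort == "validation"
    subsets = build_default_subsets()
    if validation:
        subsets = [extend_phenotype_for_validation(s) for s in subsets]
    return GeneratorConfig(
        cohort=cohort,
        panel=default_panel(validation=validation),
        subsets=tuple(subsets),
        subjects=_subject_table(cohort),
    )


def _sample_plan(config: GeneratorConfig) -> pd.DataFrame:
    """Per-sample metadata rows: paired tissues per subject plus blood.

    Controls contribute noninflamed ileum + colon; IBD patients an
    inflamed sample in the disease-typical tissue (ileum for CD, colon
    for UC), a paired noninflamed sample of the same tissue and a
    noninflamed sample of the other tissue. Every subject contributes
    blood; internal-control replicates are blood aliquots of one
    reference donor.
    """
    rows = []
    for _, subj in config.subjects.iterrows():
        sid, diag = subj["subject_id"], subj["diagnosis"]
        if diag == "control":
            plan = [("ileum", "control"), ("colon", "control")]
        else:
            tis = "ileum" if diag == "CD" else "colon"
            other = "colon" if tis == "ileum" else "ileum"
            plan = [(tis, "inflamed"), (tis, "noninflamed"), (other, "noninflamed")]
        plan.append(("blood", "control" if diag == "control" else "noninflamed"))
        for tissue, status in plan:
            rows.append({
                "sample_id": f"{sid}_{tissue}_{status}",
                "subject_id": sid,
                "cohort": config.cohort,
                "tissue": tissue,
                "status": status,
                "diagnosis": diag,
                "is_internal_control": False,
            })
    for i in range(config.n_internal_controls):
        rows.append({
            "sample_id": f"IC_{config.cohort[:4]}_{i + 1}",
            "subject_id": "internal_control",
            "cohort": config.cohort,
            "tissue": "blood",
            "status": "control",
            "diagnosis": "control",
            "is_internal_control": True,
        })
    return pd.DataFrame(rows)


def _module_index(subsets) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i, s in enumerate(subsets):
        idx.setdefault(s.module, []).append(i)
    return idx


def simulate_study(config: GeneratorConfig, seed: int) -> Study:
    """Draw one full synthetic study; bit-reproducible for a given seed."""
    rng = np.random.default_rng(seed)
    subsets = list(config.subsets)
    ids = np.array(config.subset_ids)
    K = len(subsets)
    panel = config.panel
    meta = _sample_plan(config)

    base = {
        "ileum": np.array([s.baseline_gut for s in subsets]),
        "colon": np.array([s.baseline_gut for s in subsets]),
        "blood": np.array([s.baseline_blood for s in subsets]),
    }
    loadings = np.array([s.loading for s in subsets])
    # per-subset inflammation shift: global delta scales the subset sizes
    delta = config.delta * np.array(
        [s.effect_size if s.effect == "up_in_inflamed"
         else -s.effect_size if s.effect == "down_in_inflamed" else 0.0
         for s in subsets]
    )
    modules = _module_index(subsets)
    spike = np.zeros(K)
    if config.blood_spike_subset in list(ids):
        spike[list(ids).index(config.blood_spike_subset)] = config.blood_spike

    ibd_subjects = list(config.subjects.loc[
        config.subjects["diagnosis"] != "control", "subject_id"])
    high_n2 = ibd_subjects[: config.n_high_n2]

    # subject random effects, shared across a subject's samples
    subj_eff = {
        sid: rng.normal(0.0, config.sigma_subj, K)
        for sid in config.subjects["subject_id"]
    }

    # one fixed internal-control composition (reference healthy blood)
    ic_log = (base["blood"]
              + rng.normal(0.0, config.sigma_subj, K)
              + rng.normal(0.0, config.sigma_noise, K))
    ic_prop = _softmax(ic_log)

    means = np.stack([s.mean_vector(panel) for s in subsets])
    sds = np.stack([s.sd_vector(panel) for s in subsets])
    if config.batch_shift:
        means = means + config.batch_shift

    all_values, all_samples, all_labels, freq_rows, n_cells_col = [], [], [], [], []
    for _, row in meta.iterrows():
        tissue, status = row["tissue"], row["status"]
        inflamed = status == "inflamed"
        if row["is_internal_control"]:
            prop = ic_prop
        else:
            f = {
                "network1": rng.normal(0.0, config.sigma_mod),
                "network2": rng.normal(0.0, config.sigma_mod),
                "network3": rng.normal(0.0, config.sigma_mod),
                "none": rng.normal(0.0, config.sigma_res),
            }
            if inflamed:
                f["network2"] += config.module_shift
                f["network1"] -= config.module_shift
            log_a = base[tissue] + subj_eff[row["subject_id"]].copy()
            for mod, members in modules.items():
                log_a[members] = log_a[members] + loadings[members] * f[mod]
            if inflamed:
                log_a = log_a + delta
                if row["subject_id"] in high_n2:
                    log_a = log_a + config.high_n2_boost * (delta > 0)
            if tissue == "blood" and row["diagnosis"] != "control":
                log_a = log_a + spike
            log_a = log_a + rng.normal(0.0, config.sigma_noise, K)
            prop = _softmax(log_a)
        mean_n = config.cells_per_sample[tissue] * (
            config.inflamed_count_factor if inflamed else 1.0)
        n_cells = max(100, int(round(
            mean_n * rng.lognormal(0.0, config.count_dispersion))))
        counts = rng.multinomial(n_cells, prop)
        freq_rows.append(prop)
        n_cells_col.append(n_cells)
        labels = np.repeat(np.arange(K), counts)
        expr = rng.normal(means[labels], sds[labels]).astype(np.float32)
        np.clip(expr, 0.0, None, out=expr)
        all_values.append(expr)
        all_samples.append(np.repeat(row["sample_id"], n_cells))
        all_labels.append(ids[labels])

    meta = meta.assign(n_cells=n_cells_col)
    cells = CellTable(
        values=np.concatenate(all_values),
        markers=list(panel.names),
        sample_id=np.concatenate(all_samples),
        label=np.concatenate(all_labels),
    )
    truth = GroundTruth(
        sample_freq=pd.DataFrame(
            np.stack(freq_rows), index=meta["sample_id"], columns=ids),
        subset_info=config.subset_info(),
        high_network2_subjects=high_n2,
    )
    return Study(cells=cells, metadata=meta, truth=truth)


def _softmax(log_a: np.ndarray) -> np.ndarray:
    z = np.exp(log_a - log_a.max())
    return z / z.sum()
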