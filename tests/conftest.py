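"""Shared fixtures: one full-scale synthetic primary cohort reused across
the suite, a cheap scaled-down study for unit tests, and derived
frequency matrices."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import cytonet as cn


@pytest.fixture(scope="session")
def primary_config():
    return cn.default_config("primary")


@pytest.fixture(scope="session")
def primary_study(primary_config):
    """Default-scale primary cohort, seed 42."""
    return cn.simulate_study(primary_config, seed=42)


@pytest.fixture(scope="session")
def small_config(primary_config):
    """Reduced cell counts for fast unit tests (structure unchanged)."""
    return dataclasses.replace(
        primary_config,
        cells_per_sample={"ileum": 500, "colon": 300, "blood": 600},
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return cn.simulate_study(small_config, seed=7)


@pytest.fixture(scope="session")
def subset_ids(primary_study):
    return list(primary_study.truth.sample_freq.columns)


@pytest.fixture(scope="session")
def gut_freq_true(primary_study, subset_ids):
    """Intestinal frequency matrix from ground-truth labels (percent of
    total CD45+)."""
    cells = primary_study.cells_for(primary_study.intestinal_mask())
    return cn.compute_frequencies(
        cells.label, cells.sample_id, metadata=primary_study.metadata,
        mode="total_CD45", all_subsets=subset_ids)


@pytest.fixture(scope="session")
def clustered_primary(primary_study, primary_config):
    """Two-level clustering of the primary cohort's intestinal cells."""
    cells = primary_study.cells_for(primary_study.intestinal_mask())
    lineages = cn.assign_lineages(cells, primary_config.panel)
    labeling = cn.cluster_within_lineage(cells, lineages, seed=42)
    return cells, lineages, labeling


def study_analysis(study, subset_ids):
    """Frequencies (truth labels), DA table and modules for one study."""
    cells = study.cells_for(study.intestinal_mask())
    freq = cn.compute_frequencies(
        cells.label, cells.sample_id, metadata=study.metadata,
        mode="total_CD45", all_subsets=subset_ids)
    groups = cn.inflamed_contrast(study.metadata).loc[freq.samples]
    da = cn.ttest_inflamed_vs_rest(freq, groups)
    rho = cn.spearman_matrix(freq)
    modules = cn.extract_modules(rho, da_table=da)
    return freq, da, modules


@pytest.fixture(scope="session")
def multiseed_networks(primary_config, subset_ids):
    """Qualified-module sizes and within-module DA counts over 20 seeds.

    Shared by the network-structure and differential-abundance recovery
    tests; each entry holds (sorted qualified sizes, up-significant count
    in the largest module, down-significant count in the second-largest).
    """
    out = []
    for i in range(20):
        study = cn.simulate_study(primary_config, seed=1000 + i)
        freq, da, modules = study_analysis(study, subset_ids)
        q = modules.qualified().sort_values("size", ascending=False, kind="stable")
        sizes = sorted(q["size"], reverse=True)
        largest = modules.members(q.iloc[0]["module"])
        second = modules.members(q.iloc[1]["module"]) if len(q) > 1 else []
        n_up = sum(
            da.loc[s, "significant"] and da.loc[s, "direction"] == "up_in_inflamed"
            for s in largest)
        n_down = sum(
            da.loc[s, "significant"] and da.loc[s, "direction"] == "down_in_inflamed"
            for s in second)
        out.append({"sizes": sizes, "n_up": int(n_up), "n_down": int(n_down)})
    return out
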