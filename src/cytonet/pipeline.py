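"""End-to-end pipeline orchestration with a reproducible report.

``run_pipeline`` executes the full analysis from a config: simulate (or
load) both cohorts, gate, cluster the primary cohort's intestinal
cells, run differential abundance and the correlation-network stage,
transfer labels to the validation cohort and to blood, and embed the
samples. Every stage writes tab-separated tables under the report
directory; a ``summary.json`` collects the headline numbers and a log
records the package version, config hash and all seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import inflamed_contrast, ttest_inflamed_vs_rest
from .data import Study
from .embedding import embed_samples_tsne, hotelling_on_pca, replicate_qc
from .network import (
    collective_frequencies,
    edge_list,
    extract_modules,
    spearman_matrix,
    stratify_patients,
)
from .preprocess import compute_frequencies, gate_cd45, preprocess_frequencies
from .simulate import default_config, simulate_study
from .subsets import assign_lineages, cluster_within_lineage, match_to_truth, profile_subsets
from .transfer import (
    fit_lda,
    frequency_concordance,
    match_blood_to_tissue,
    predict_with_rejection,
    predicted_frequencies,
)


@dataclasses.dataclass
class PipelineConfig:
    """Schema-checked pipeline settings; see ``default_pipeline_config``."""

    seed: int = 42
    outdir: str = "cytonet_report"
    cells_scale: float = 1.0          # scales all cells_per_sample means
    gate_threshold: float = 1.0
    cluster: bool = True
    abundance: bool = True
    network: bool = True
    transfer: bool = True
    embed: bool = True
    figures: bool = True
    k_min: int = 1
    k_max: int = 12
    alpha: float = 0.05
    m_min: int = 4
    rho_min: float = 0.3
    edge_threshold: float = 0.4
    taus: tuple = (1.0, 0.95)
    stratify_cutoff: float = 50.0
    tsne_perplexity: float = 15.0
    hotelling_d: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "taus" in raw:
            raw["taus"] = tuple(raw["taus"])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["taus"] = list(d["taus"])
        return yaml.safe_dump(d, sort_keys=True)


def _scaled_study(cohort: str, cfg: PipelineConfig, seed: int) -> Study:
    gen = default_config(cohort)
    if cfg.cells_scale != 1.0:
        scaled = {
            k: max(100, int(v * cfg.cells_scale))
            for k, v in gen.cells_per_sample.items()
        }
        gen = dataclasses.replace(gen, cells_per_sample=scaled)
    return simulate_study(gen, seed=seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the summary dict (also on disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    cfg_yaml = config.to_yaml()
    # hash the analysis settings only: the output location is not part
    # of the result's identity
    hashed = yaml.safe_dump(
        {k: v for k, v in yaml.safe_load(cfg_yaml).items() if k != "outdir"},
        sort_keys=True)
    cfg_hash = hashlib.sha256(hashed.encode()).hexdigest()[:16]
    log.append(f"cytonet {__version__}")
    log.append(f"config sha256: {cfg_hash}")
    log.append(f"seed: {config.seed}")
    summary: dict = {"version": __version__, "config_hash": cfg_hash,
                     "seed": config.seed}
    stage = "simulate"
    try:
        primary = _scaled_study("primary", config, seed=config.seed)
        validation = _scaled_study("validation", config, seed=config.seed + 1)
        log.append(
            f"simulated primary: {len(primary.metadata)} samples, "
            f"{primary.cells.n_cells} cells")
        log.append(
            f"simulated validation: {len(validation.metadata)} samples, "
            f"{validation.cells.n_cells} cells")
        primary.metadata.to_csv(out / "primary_metadata.tsv", sep="\t", index=False)
        validation.metadata.to_csv(
            out / "validation_metadata.tsv", sep="\t", index=False)

        stage = "gate"
        gen_primary = default_config("primary")
        gated, retained = gate_cd45(
            primary.cells, gen_primary.panel, threshold=config.gate_threshold)
        summary["gate_retained_fraction"] = float(
            gated.n_cells / primary.cells.n_cells)
        gut_mask = primary.intestinal_mask()
        gut_ids = set(primary.metadata.loc[gut_mask, "sample_id"])
        gut_cells = gated.subset(np.isin(gated.sample_id, list(gut_ids)))

        stage = "cluster"
        subset_ids = list(primary.truth.sample_freq.columns)
        if config.cluster:
            lineages = assign_lineages(gut_cells, gen_primary.panel)
            labeling = cluster_within_lineage(
                gut_cells, lineages,
                k_range=range(config.k_min, config.k_max + 1), seed=config.seed)
            mapping, ari = match_to_truth(labeling.subset_id, gut_cells.label)
            summary["n_subsets_recovered"] = labeling.n_subsets
            summary["clustering_ari"] = ari
            profile = profile_subsets(gut_cells, labeling)
            profile.to_csv(out / "subset_profiles.tsv", sep="\t")
            # analysis labels: recovered clusters renamed to matched truth IDs
            analysis_labels = np.array(
                [mapping.get(s, s) for s in labeling.subset_id])
            log.append(f"clustering: {labeling.n_subsets} subsets, ARI {ari:.3f}")
        else:
            analysis_labels = gut_cells.label
            log.append("clustering disabled: using ground-truth labels")

        freq = compute_frequencies(
            analysis_labels, gut_cells.sample_id, metadata=primary.metadata,
            mode="total_CD45", all_subsets=subset_ids)
        freq.values.to_csv(out / "frequencies_totalCD45.tsv", sep="\t")

        if config.abundance:
            stage = "abundance"
            groups = inflamed_contrast(primary.metadata).loc[freq.samples]
            da = ttest_inflamed_vs_rest(freq, groups, alpha=config.alpha)
            da.to_csv(out / "differential_abundance.tsv", sep="\t")
            summary["da_n_significant"] = int(da["significant"].sum())
            summary["da_table"] = "differential_abundance.tsv"
        else:
            da = None

        if config.network:
            stage = "network"
            rho = spearman_matrix(freq)
            rho.to_csv(out / "spearman_rho.tsv", sep="\t")
            edge_list(rho, threshold=config.edge_threshold).to_csv(
                out / "network_edges.tsv", sep="\t", index=False)
            modules = extract_modules(
                rho, m_min=config.m_min, rho_min=config.rho_min, da_table=da)
            modules.module_info.to_csv(out / "modules.tsv", sep="\t", index=False)
            modules.assignment.to_frame().to_csv(
                out / "module_assignment.tsv", sep="\t")
            coll = collective_frequencies(freq, modules)
            coll.to_csv(out / "network_collectives.tsv", sep="\t")
            strat = stratify_patients(
                coll, primary.metadata, cutoff_percent=config.stratify_cutoff)
            strat.to_csv(out / "patient_stratification.tsv", sep="\t", index=False)
            summary["n_qualified_networks"] = int(
                modules.qualified().shape[0])
            summary["network_sizes"] = [
                int(x) for x in modules.qualified()["size"]]
            summary["patients_flagged"] = strat.attrs["summary"]
            if da is not None:
                q = modules.qualified().sort_values(
                    "size", ascending=False, kind="stable")
                largest = modules.members(q.iloc[0]["module"])
                summary["up_in_largest_module"] = int(sum(
                    da.loc[s, "significant"]
                    and da.loc[s, "direction"] == "up_in_inflamed"
                    for s in largest))

        if config.transfer:
            stage = "transfer"
            model = fit_lda(gut_cells, analysis_labels)
            val_gut = validation.cells_for(validation.intestinal_mask())
            result = predict_with_rejection(model, val_gut, tau=min(config.taus))
            pred = predicted_frequencies(
                result, metadata=validation.metadata, all_subsets=subset_ids)
            true_val = compute_frequencies(
                val_gut.label, val_gut.sample_id, metadata=validation.metadata,
                mode="total_CD45", all_subsets=subset_ids)
            r = frequency_concordance(true_val, pred)
            summary["transfer_concordance_R"] = r
            log.append(f"label transfer R = {r:.4f}")
            blood = primary.cells_for(primary.metadata["tissue"] == "blood")
            matched = {}
            for tau in config.taus:
                res_b, per_subset = match_blood_to_tissue(
                    model, blood, tau=tau, metadata=primary.metadata,
                    all_subsets=subset_ids)
                matched[str(tau)] = res_b.matched_fraction
                per_subset.to_csv(
                    out / f"blood_matched_tau{tau}.tsv", sep="\t")
            summary["blood_matched_fraction"] = matched

        if config.embed:
            stage = "embed"
            all_freq = compute_frequencies(
                primary.cells.label, primary.cells.sample_id,
                metadata=primary.metadata, mode="total_CD45",
                all_subsets=subset_ids)
            prep = preprocess_frequencies(all_freq)
            emb = embed_samples_tsne(
                prep, seed=config.seed, perplexity=config.tsne_perplexity)
            emb.coordinates.to_csv(out / "tsne_samples.tsv", sep="\t")
            ic_mask = (primary.metadata.set_index("sample_id")
                       .loc[prep.index, "is_internal_control"].to_numpy())
            summary["ic_replicate_silhouette"] = replicate_qc(
                emb.coordinates, ic_mask)
            gut_prep = preprocess_frequencies(freq)
            groups = inflamed_contrast(primary.metadata).loc[freq.samples]
            t2 = hotelling_on_pca(
                gut_prep, groups, "inflamed", "rest", d=config.hotelling_d)
            summary["hotelling"] = {
                "t2": t2.t2, "f": t2.f, "df": [t2.df1, t2.df2], "p": t2.p}
            if config.figures:
                _figures(out, emb.coordinates, ic_mask, freq, da)
    except Exception as exc:  # preserve partial outputs, tag the stage
        (out / "pipeline_log.txt").write_text("\n".join(log) + "\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(cfg_yaml)
    (out / "pipeline_log.txt").write_text("\n".join(log) + "\n")
    return summary


def _figures(out: Path, coords: pd.DataFrame, ic_mask, freq, da) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1],
               c=np.where(ic_mask, "tab:green", "tab:gray"), s=18)
    ax.set_xlabel("t-SNE 1"); ax.set_ylabel("t-SNE 2")
    ax.set_title("Samples (internal controls in green)")
    fig.tight_layout(); fig.savefig(out / "tsne_samples.png", dpi=120)
    plt.close(fig)

    if da is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        x = np.sign(da["t"]) * np.abs(da["t"])
        y = -np.log10(np.clip(da["p"], 1e-300, None))
        ax.scatter(x, y, c=np.where(da["significant"], "tab:red", "tab:gray"), s=14)
        ax.set_xlabel("t statistic (inflamed vs rest)")
        ax.set_ylabel("-log10 p")
        fig.tight_layout(); fig.savefig(out / "volcano.png", dpi=120)
        plt.close(fig)
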