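"""Spearman co-abundance networks over subset frequencies.

Pairwise Spearman correlations of subset frequencies across intestinal
samples are clustered hierarchically (average linkage on 1 - rho, cut
chosen by maximum mean silhouette). Clusters qualify as "networks" when
they have at least ``m_min`` members and mean within-cluster pairwise
rho >= ``rho_min``; a small weakly-correlated residual cluster is thus
detected but left unqualified. Collective network frequencies (summed
percent of CD45+ cells over a network's members) support patient-level
stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .data import FrequencyMatrix


def spearman_matrix(freq: FrequencyMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho (average ranks for ties), diagonal 1.

    Requires >= 5 samples. Constant columns correlate with nothing: their
    off-diagonal entries are set to 0 with a warning.
    """
    values = freq.values if isinstance(freq, FrequencyMatrix) else freq
    x = values.to_numpy(dtype=float)
    if x.shape[0] < 5:
        raise ValueError("need at least 5 samples for a correlation network")
    constant = x.std(axis=0) == 0
    rho = np.zeros((x.shape[1], x.shape[1]))
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s); correlations set to 0")
    keep = np.where(~constant)[0]
    if len(keep) == 2:
        r = stats.spearmanr(x[:, keep[0]], x[:, keep[1]]).statistic
        rho[keep[0], keep[1]] = rho[keep[1], keep[0]] = r
    elif len(keep) > 2:
        sub = np.asarray(stats.spearmanr(x[:, keep]).statistic)
        rho[np.ix_(keep, keep)] = sub
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=values.columns, columns=values.columns)


@dataclass
class CorrelationModules:
    """Module decomposition of a subset correlation matrix."""

    rho: pd.DataFrame
    linkage: np.ndarray
    #: subset_id -> module label (network1/2/3 or module_<i>).
    assignment: pd.Series
    #: one row per module: size, mean within-pair rho, qualification.
    module_info: pd.DataFrame
    m_min: int
    rho_min: float

    def qualified(self) -> pd.DataFrame:
        return self.module_info[self.module_info["is_network"]]

    def members(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])


def _mean_within_rho(rho: np.ndarray, idx: np.ndarray) -> float:
    if len(idx) < 2:
        return np.nan
    sub = rho[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def extract_modules(
    rho: pd.DataFrame,
    m_min: int = 4,
    rho_min: float = 0.3,
    k_range: range = range(2, 9),
    da_table: pd.DataFrame | None = None,
) -> CorrelationModules:
    """Hierarchical module extraction with silhouette-chosen cut.

    Average-linkage clustering on distance 1 - rho; the number of
    clusters maximizes the mean silhouette over ``k_range``. Qualified
    modules (>= ``m_min`` members, mean within-pair rho >= ``rho_min``)
    are named by the differential-abundance direction of their members
    when ``da_table`` is given: predominantly depleted -> network1,
    predominantly enriched -> network2, remaining qualified modules ->
    network3, ... by decreasing size. Without a DA table qualified
    modules are named network1, network2, ... by decreasing size.
    """
    if rho.shape[0] < 3:
        raise ValueError("need at least 3 subsets")
    if m_min < 2:
        raise ValueError("m_min must be >= 2")
    if not 0 < rho_min < 1:
        raise ValueError("rho_min must lie in (0, 1)")
    r = rho.to_numpy(dtype=float)
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    dist = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    best_k, best_sil, best_labels = None, -np.inf, None
    for k in k_range:
        if k >= rho.shape[0]:
            break
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(dist, labels, metric="precomputed")
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels
    if best_labels is None:
        # degenerate tree (e.g. all pairwise distances equal): every cut
        # collapses to one cluster; fall back to singleton modules
        best_labels = np.arange(1, rho.shape[0] + 1)

    info_rows = []
    for c in np.unique(best_labels):
        idx = np.where(best_labels == c)[0]
        mean_rho = _mean_within_rho(r, idx)
        qualified = len(idx) >= m_min and (
            not np.isnan(mean_rho) and mean_rho >= rho_min)
        info_rows.append({
            "cluster": int(c), "size": len(idx), "mean_rho": mean_rho,
            "is_network": qualified,
        })
    info = pd.DataFrame(info_rows)

    names = _name_modules(info, best_labels, rho, da_table)
    info["module"] = info["cluster"].map(names)
    assignment = pd.Series(
        [names[c] for c in best_labels], index=rho.index, name="module")
    info = info[["module", "cluster", "size", "mean_rho", "is_network"]]
    return CorrelationModules(
        rho=rho, linkage=z, assignment=assignment, module_info=info,
        m_min=m_min, rho_min=rho_min,
    )


def _name_modules(
    info: pd.DataFrame,
    labels: np.ndarray,
    rho: pd.DataFrame,
    da_table: pd.DataFrame | None,
) -> dict[int, str]:
    """Network numbering is label metadata: the qualified module whose
    members are predominantly significantly depleted in inflamed tissue
    is network1, predominantly enriched network2; remaining qualified
    modules are numbered on by decreasing size."""
    qualified = info.loc[info["is_network"]].sort_values(
        "size", ascending=False, kind="stable")
    names: dict[int, str] = {}
    remaining = list(qualified["cluster"])
    if da_table is not None and len(remaining):
        score = {}
        for c in remaining:
            members = rho.index[labels == c]
            sig = da_table.loc[da_table.index.intersection(members)]
            sig = sig[sig["significant"]]
            n_up = int((sig["direction"] == "up_in_inflamed").sum())
            n_down = int((sig["direction"] == "down_in_inflamed").sum())
            score[c] = (n_down, n_up)
        down_first = max(remaining, key=lambda c: score[c][0])
        if score[down_first][0] > 0:
            names[down_first] = "network1"
            remaining.remove(down_first)
        up_first = max(remaining, key=lambda c: score[c][1], default=None)
        if up_first is not None and score[up_first][1] > 0:
            names[up_first] = "network2"
            remaining.remove(up_first)
    next_id = len(names) + 1
    for c in remaining:
        names[c] = f"network{next_id}"
        next_id += 1
    unqualified = info.loc[~info["is_network"], "cluster"]
    for i, c in enumerate(sorted(unqualified), start=1):
        names[int(c)] = f"module_{i}"
    return names


def collective_frequencies(
    freq: FrequencyMatrix, modules: CorrelationModules
) -> pd.DataFrame:
    """Per-sample sums of member-subset percentages per qualified module."""
    if freq.mode != "total_CD45":
        raise ValueError("collective frequencies require total_CD45 mode")
    cols = {}
    for module in modules.qualified()["module"]:
        members = modules.members(module)
        missing = set(members) - set(freq.subsets)
        if missing:
            raise KeyError(f"module {module} references unknown subsets {missing}")
        cols[module] = freq.values[members].sum(axis=1)
    return pd.DataFrame(cols, index=freq.samples)


def stratify_patients(
    collectives: pd.DataFrame,
    metadata: pd.DataFrame,
    network: str = "network2",
    cutoff_percent: float = 50.0,
    patients_only: bool = True,
) -> pd.DataFrame:
    """Flag patients with any inflamed sample above the collective cutoff.

    Returns a per-patient table (subject_id, max inflamed collective,
    flagged); patients without an inflamed sample are retained unflagged
    with NaN collective. ``patients_only`` drops control subjects.
    """
    if not 0 < cutoff_percent < 100:
        raise ValueError("cutoff must lie in (0, 100) percent")
    meta = metadata.set_index("sample_id").loc[collectives.index]
    df = pd.DataFrame({
        "subject_id": meta["subject_id"],
        "diagnosis": meta["diagnosis"],
        "inflamed": meta["status"] == "inflamed",
        "collective": collectives[network],
    })
    if patients_only:
        df = df[df["diagnosis"] != "control"]
    rows = []
    for subject, grp in df.groupby("subject_id", sort=True):
        infl = grp.loc[grp["inflamed"], "collective"]
        rows.append({
            "subject_id": subject,
            "max_inflamed_collective": infl.max() if len(infl) else np.nan,
            "flagged": bool(len(infl) and infl.max() > cutoff_percent),
        })
    out = pd.DataFrame(rows)
    out.attrs["summary"] = f"{int(out['flagged'].sum())}/{len(out)}"
    return out


def edge_list(
    rho: pd.DataFrame, threshold: float = 0.4
) -> pd.DataFrame:
    """Edges (subset_i, subset_j, rho) with |rho| >= threshold, i < j."""
    r = rho.to_numpy()
    iu = np.triu_indices(len(rho), k=1)
    mask = np.abs(r[iu]) >= threshold
    return pd.DataFrame({
        "subset_i": rho.index[iu[0][mask]],
        "subset_j": rho.columns[iu[1][mask]],
        "rho": r[iu][mask],
    })
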