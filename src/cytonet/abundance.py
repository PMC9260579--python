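"""Per-subset differential abundance between sample groups.

The main contrast compares inflamed samples with pooled noninflamed/
control samples per subset using Welch two-sample t-tests on
arcsine-square-root transformed percentages, with Benjamini-Hochberg
control of the false discovery rate at 5%. Multi-group figures use the
Kruskal-Wallis test with Dunn's rank-based post-hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import FrequencyMatrix
from .preprocess import arcsine_sqrt


def bh_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and significance flags.

    ``q_i = min_{j >= i} (m * p_(j) / j)`` capped at 1; significant where
    ``q <= alpha``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def ttest_inflamed_vs_rest(
    freq: FrequencyMatrix,
    groups: pd.Series,
    transform: bool = True,
    welch: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subset two-sample t-test of inflamed vs pooled rest.

    ``groups`` maps sample_id -> {"inflamed", "rest"}. With ``transform``
    the test runs on arcsine-sqrt percentages (variance stabilization);
    ``welch=False`` selects the pooled-variance Student variant. Returns
    a DataFrame with direction, t, p, q and significance at ``alpha``.
    Subsets where either group has zero variance with n < 2 are flagged
    untestable (p = NaN, never significant).
    """
    g = pd.Series(groups)
    g = g.reindex(freq.samples)
    if g.isna().any():
        raise ValueError("groups must cover every sample in the matrix")
    if set(g.unique()) - {"inflamed", "rest"}:
        raise ValueError("groups must be 'inflamed' or 'rest'")
    x = freq.values.to_numpy(dtype=float)
    if transform:
        x = arcsine_sqrt(x)
    infl = x[(g == "inflamed").to_numpy()]
    rest = x[(g == "rest").to_numpy()]
    if len(infl) < 2 or len(rest) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for j, subset in enumerate(freq.subsets):
        a, b = infl[:, j], rest[:, j]
        diff = a.mean() - b.mean()
        if a.std() == 0 and b.std() == 0:
            t, p = (0.0, 1.0) if diff == 0 else (np.nan, np.nan)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append({
            "subset_id": subset,
            "direction": "up_in_inflamed" if diff > 0 else "down_in_inflamed",
            "t": float(t), "p": float(p),
        })
    out = pd.DataFrame(rows).set_index("subset_id")
    testable = out["p"].notna()
    q = np.full(len(out), np.nan)
    sig = np.zeros(len(out), dtype=bool)
    if testable.any():
        q_t, sig_t = bh_fdr(out.loc[testable, "p"].to_numpy(), alpha=alpha)
        q[testable.to_numpy()] = q_t
        sig[testable.to_numpy()] = sig_t
    out["q"] = q
    out["significant"] = sig
    return out


def _dunn(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction and
    Bonferroni adjustment over the pairs."""
    ranks = stats.rankdata(values)
    n = len(values)
    # tie correction term: sum(t^3 - t) over tied groups
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    var_factor = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    groups = pd.unique(labels)
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    pairs = list(combinations(groups, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_factor * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({
            "group_a": a, "group_b": b, "z": z, "p_raw": p_raw,
            "p_adj": min(1.0, p_raw * len(pairs)),
        })
    return pd.DataFrame(rows)


def kruskal_dunn(
    freq: FrequencyMatrix | pd.DataFrame,
    groups: pd.Series,
) -> dict[str, dict]:
    """Kruskal-Wallis H (tie-corrected) plus Dunn post-hoc per subset.

    Returns ``{subset_id: {"H": .., "p": .., "dunn": DataFrame}}``. All
    values tied across groups yields H = 0, p = 1.
    """
    values = freq.values if isinstance(freq, FrequencyMatrix) else freq
    g = pd.Series(groups).reindex(values.index)
    if g.isna().any():
        raise ValueError("groups must cover every sample")
    labels = g.to_numpy()
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for u in uniq:
        if (labels == u).sum() < 2:
            raise ValueError(f"group {u!r} has fewer than 2 samples")
    out = {}
    for subset in values.columns:
        v = values[subset].to_numpy(dtype=float)
        if np.all(v == v[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*[v[labels == u] for u in uniq])
        out[subset] = {"H": float(h), "p": float(p),
                       "dunn": _dunn(v, labels)}
    return out


def compare_cell_counts(metadata: pd.DataFrame, groups: pd.Series) -> dict:
    """Kruskal-Wallis + Dunn on per-sample CD45+ cell counts."""
    if (metadata["n_cells"] < 0).any():
        raise ValueError("cell counts must be non-negative")
    counts = metadata.set_index("sample_id")[["n_cells"]]
    return kruskal_dunn(counts, groups)["n_cells"]


@dataclass
class DAResult:
    """Convenience bundle: the t-test table plus the contrast definition."""

    table: pd.DataFrame
    alpha: float
    transform: bool

    def significant(self, direction: str | None = None) -> list[str]:
        t = self.table
        mask = t["significant"]
        if direction is not None:
            mask = mask & (t["direction"] == direction)
        return list(t.index[mask])


def inflamed_contrast(metadata: pd.DataFrame) -> pd.Series:
    """sample_id -> inflamed / rest, pooling noninflamed-IBD with controls."""
    status = metadata.set_index("sample_id")["status"]
    return status.map(lambda s: "inflamed" if s == "inflamed" else "rest")
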