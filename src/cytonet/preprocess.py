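"""Transformation, the automated CD45 gate, and frequency matrices.

Frequencies are computed under the two denominators used throughout the
analysis: percent of all CD45+ cells in a sample (``total_CD45``) and
percent of the subset's parent lineage (``lineage``). Variance-stabilized
and standardized versions of the frequency matrix feed the sample-level
embeddings and t-tests; rank-based statistics are unaffected by these
strictly monotone maps.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import REJECTED, CellTable, FrequencyMatrix
from .panel import MarkerPanel


def arcsinh_transform(raw: np.ndarray, cofactor: float = 5.0) -> np.ndarray:
    """Elementwise ``asinh(x / cofactor)``, the standard CyTOF transform."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.arcsinh(np.asarray(raw, dtype=float) / cofactor)


def gate_cd45(
    cells: CellTable,
    panel: MarkerPanel | None = None,
    threshold: float = 1.0,
) -> tuple[CellTable, pd.Series]:
    """Retain cells with arcsinh CD45 >= threshold.

    Automated stand-in for the manual live/single/CD45+ gate; returns the
    gated table and per-sample retained counts.
    """
    if "CD45" not in cells.markers:
        raise KeyError("CD45 channel absent; cannot gate")
    keep = cells.column("CD45") >= threshold
    gated = cells.subset(keep)
    retained = pd.Series(gated.sample_id).value_counts().sort_index()
    retained.name = "n_retained"
    return gated, retained


def compute_frequencies(
    labels: np.ndarray,
    sample_ids: np.ndarray,
    metadata: pd.DataFrame | None = None,
    mode: str = "total_CD45",
    lineage_map: dict[str, str] | None = None,
    all_subsets: list[str] | None = None,
) -> FrequencyMatrix:
    """Per-sample subset frequencies in percent.

    Cells labeled :data:`~cytonet.data.REJECTED` are excluded from both
    numerator and denominator. Under ``lineage`` mode the denominator of
    each subset is the cell count of its parent lineage (``lineage_map``:
    subset -> lineage). Samples with an empty denominator are dropped
    with a warning.
    """
    labels = np.asarray(labels)
    sample_ids = np.asarray(sample_ids)
    if len(labels) != len(sample_ids):
        raise ValueError("labels and sample_ids differ in length")
    keep = labels != REJECTED
    counts = (
        pd.crosstab(pd.Series(sample_ids[keep], name="sample_id"),
                    pd.Series(labels[keep], name="subset_id"))
    )
    # samples whose cells were all rejected must still surface (and be
    # dropped with a warning) rather than silently vanish
    counts = counts.reindex(index=pd.unique(sample_ids), fill_value=0).sort_index()
    if all_subsets is not None:
        counts = counts.reindex(columns=all_subsets, fill_value=0)
    if mode == "total_CD45":
        denom = counts.sum(axis=1)
        empty = denom == 0
        if empty.any():
            warnings.warn(
                f"dropping {int(empty.sum())} sample(s) with empty denominator")
            counts, denom = counts.loc[~empty], denom[~empty]
        freq = counts.div(denom, axis=0) * 100.0
    elif mode == "lineage":
        if lineage_map is None:
            raise ValueError("lineage mode requires a subset -> lineage map")
        freq = pd.DataFrame(
            0.0, index=counts.index, columns=counts.columns)
        for lin in set(lineage_map.values()):
            cols = [c for c in counts.columns if lineage_map.get(c) == lin]
            denom = counts[cols].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                freq[cols] = (counts[cols].div(denom.replace(0, np.nan), axis=0)
                              * 100.0).fillna(0.0)
    else:
        raise ValueError(f"unknown denominator mode {mode!r}")
    return FrequencyMatrix(values=freq, mode=mode, metadata=metadata)


def arcsine_sqrt(percent: np.ndarray) -> np.ndarray:
    """Variance-stabilizing map ``p(%) -> asin(sqrt(p/100))``."""
    p = np.asarray(percent, dtype=float)
    if np.nanmin(p) < -1e-9 or np.nanmax(p) > 100 + 1e-6:
        raise ValueError("percent values must lie in [0, 100]")
    return np.arcsin(np.sqrt(np.clip(p, 0.0, 100.0) / 100.0))


def zscore_columns(matrix: np.ndarray) -> np.ndarray:
    """Standardize columns to mean 0 / sd 1; constant columns map to 0."""
    x = np.asarray(matrix, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd_safe
    z[:, sd == 0] = 0.0
    return z


def preprocess_frequencies(
    freq: FrequencyMatrix,
    steps: tuple[str, ...] = ("arcsine_sqrt", "zscore_columns"),
) -> pd.DataFrame:
    """Apply the named steps in order; returns a DataFrame aligned to freq."""
    x = freq.values.to_numpy(dtype=float)
    for step in steps:
        if step == "arcsine_sqrt":
            x = arcsine_sqrt(x)
        elif step == "zscore_columns":
            x = zscore_columns(x)
        else:
            raise ValueError(f"unknown preprocessing step {step!r}")
    return pd.DataFrame(x, index=freq.values.index, columns=freq.values.columns)
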