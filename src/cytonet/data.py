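"""Core in-memory containers shared across the pipeline.

The package operates on three levels of data:

* per-cell marker intensities (:class:`CellTable`, arcsinh scale),
* per-sample subset compositions (:class:`FrequencyMatrix`, percent),
* study-level metadata and, for synthetic studies, ground truth
  (:class:`GroundTruth`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Label used for cells abstained on by the rejection-option classifier.
REJECTED = "REJECTED"


@dataclass
class CellTable:
    """Per-cell marker intensity matrix with sample assignment.

    Parameters
    ----------
    values
        ``(n_cells, n_markers)`` float array on arcsinh scale.
    markers
        Column names, one per marker channel.
    sample_id
        Per-cell sample identifier, length ``n_cells``.
    label
        Optional per-cell subset label (ground truth or a clustering result).
    """

    values: np.ndarray
    markers: list[str]
    sample_id: np.ndarray
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.sample_id = np.asarray(self.sample_id)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x markers)")
        if self.values.shape[1] != len(self.markers):
            raise ValueError("marker names do not match matrix width")
        if len(self.sample_id) != self.values.shape[0]:
            raise ValueError("sample_id length does not match cell count")
        if self.label is not None and len(self.label) != self.values.shape[0]:
            raise ValueError("label length does not match cell count")
        if not np.isfinite(self.values).all():
            raise ValueError("cell matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in panel") from None

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, self.marker_index(marker)]

    def subset(self, mask: np.ndarray) -> "CellTable":
        """Row-subset the table (boolean mask or integer index)."""
        return CellTable(
            values=self.values[mask],
            markers=list(self.markers),
            sample_id=self.sample_id[mask],
            label=None if self.label is None else self.label[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.markers)
        df.insert(0, "sample_id", self.sample_id)
        if self.label is not None:
            df["label"] = self.label
        return df


@dataclass
class FrequencyMatrix:
    """Samples x subsets frequency table in percent.

    ``mode`` records the denominator: ``total_CD45`` (percent of all
    assigned cells in the sample) or ``lineage`` (percent of the subset's
    parent lineage).
    """

    values: pd.DataFrame
    mode: str
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("total_CD45", "lineage"):
            raise ValueError(f"unknown denominator mode {self.mode!r}")
        v = self.values.to_numpy(dtype=float)
        if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 100 + 1e-6):
            raise ValueError("frequencies must lie in [0, 100] percent")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def subsets(self) -> pd.Index:
        return self.values.columns

    def aligned_metadata(self) -> pd.DataFrame:
        if self.metadata is None:
            raise ValueError("frequency matrix carries no metadata")
        return self.metadata.set_index("sample_id").loc[self.samples].reset_index()


@dataclass
class GroundTruth:
    """Generator-side record for recovery tests on synthetic studies."""

    #: samples x subsets true composition (proportions, rows sum to 1).
    sample_freq: pd.DataFrame
    #: subset catalogue: subset_id, lineage, module, effect, effect_size.
    subset_info: pd.DataFrame
    #: subjects designated as the high network-2 stratification subgroup.
    high_network2_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        rowsum = self.sample_freq.sum(axis=1).to_numpy()
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError("true per-sample frequencies must sum to 1")

    def subsets_in_module(self, module: str) -> list[str]:
        info = self.subset_info
        return list(info.loc[info["module"] == module, "subset_id"])

    def effect_subsets(self, effect: str) -> list[str]:
        info = self.subset_info
        return list(info.loc[info["effect"] == effect, "subset_id"])


@dataclass
class Study:
    """A simulated (or loaded) study: cells, sample metadata, ground truth."""

    cells: CellTable
    metadata: pd.DataFrame
    truth: GroundTruth | None = None

    def sample_cells(self, sample_id: str) -> CellTable:
        return self.cells.subset(self.cells.sample_id == sample_id)

    def cells_for(self, mask: pd.Series) -> CellTable:
        """Cells belonging to the metadata rows selected by ``mask``."""
        keep = set(self.metadata.loc[mask, "sample_id"])
        return self.cells.subset(np.isin(self.cells.sample_id, list(keep)))

    def intestinal_mask(self) -> pd.Series:
        return self.metadata["tissue"].isin(["ileum", "colon"])
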