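"""Study serialization: one file per sample plus metadata and ground truth.

CSV is the default interchange format. A minimal FCS 3.0 writer/reader
(list-mode, float32, little-endian) is provided for interoperability
with cytometry tooling; it covers exactly the keywords needed for a
lossless round trip of the channel names and the data matrix.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import CellTable, GroundTruth, Study

_FORMATS = ("csv", "fcs")


def write_fcs(path: str | Path, values: np.ndarray, channels: list[str]) -> None:
    """Write a single FCS 3.0 list-mode file ($DATATYPE F, $PnB 32)."""
    values = np.ascontiguousarray(values, dtype="<f4")
    n_events, n_par = values.shape
    data = values.tobytes()

    def text_segment(begin_data: int, end_data: int) -> bytes:
        kw = {
            "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
            "$BEGINDATA": str(begin_data), "$ENDDATA": str(end_data),
            "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
            "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_events),
        }
        for i, name in enumerate(channels, start=1):
            kw[f"$P{i}N"] = name
            kw[f"$P{i}B"] = "32"
            kw[f"$P{i}E"] = "0,0"
            kw[f"$P{i}R"] = "1048576"
        body = "/" + "/".join(f"{k}/{v}" for k, v in kw.items()) + "/"
        return body.encode("ascii")

    # iterate once: offsets depend on the text length which depends on them
    text_begin = 58
    begin_data = end_data = 0
    for _ in range(3):
        text = text_segment(begin_data, end_data)
        new_begin = text_begin + len(text)
        new_end = new_begin + len(data) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = text_segment(begin_data, end_data)
    text_end = text_begin + len(text) - 1
    header = (
        b"FCS3.0    "
        + f"{text_begin:8d}{text_end:8d}".encode()
        + f"{begin_data:8d}{end_data:8d}".encode()
        + f"{0:8d}{0:8d}".encode()
    )
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an FCS 3.0 float32 list-mode file written by :func:`write_fcs`."""
    raw = Path(path).read_bytes()
    if not raw.startswith(b"FCS3"):
        raise ValueError(f"{path}: not an FCS 3.x file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin:text_end + 1].decode("ascii")
    delim = text[0]
    tokens = text.strip(delim).split(delim)
    kw = dict(zip(tokens[::2], tokens[1::2]))
    if kw.get("$DATATYPE") != "F" or kw.get("$MODE") != "L":
        raise ValueError("only float list-mode FCS is supported")
    n_par, n_tot = int(kw["$PAR"]), int(kw["$TOT"])
    begin_data = int(kw["$BEGINDATA"])
    end_data = int(kw["$ENDDATA"])
    order = "<" if kw.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">"
    buf = raw[begin_data:end_data + 1]
    values = np.frombuffer(buf, dtype=f"{order}f4", count=n_par * n_tot)
    channels = [kw[f"$P{i}N"] for i in range(1, n_par + 1)]
    return values.reshape(n_tot, n_par).copy(), channels


def write_study(study: Study, directory: str | Path, format: str = "csv") -> pd.DataFrame:
    """Write one file per sample plus metadata / ground-truth tables.

    Returns the manifest (sample_id, path, n_cells). Round-trips through
    :func:`read_study` at float32 precision.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample_id in study.metadata["sample_id"]:
        table = study.sample_cells(sample_id)
        fname = f"{sample_id}.{format}"
        path = directory / fname
        if format == "csv":
            pd.DataFrame(table.values, columns=table.markers).to_csv(path, index=False)
        else:
            write_fcs(path, table.values, table.markers)
        rows.append({"sample_id": sample_id, "path": fname, "n_cells": table.n_cells})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    study.metadata.to_csv(directory / "metadata.tsv", sep="\t", index=False)
    if study.cells.label is not None:
        pd.DataFrame({
            "sample_id": study.cells.sample_id,
            "subset_id": study.cells.label,
        }).to_csv(directory / "cell_labels.tsv", sep="\t", index=False)
    if study.truth is not None:
        study.truth.sample_freq.to_csv(directory / "true_frequencies.tsv", sep="\t")
        study.truth.subset_info.to_csv(
            directory / "subset_info.tsv", sep="\t", index=False)
        (directory / "high_network2_subjects.txt").write_text(
            "\n".join(study.truth.high_network2_subjects) + "\n")
    return manifest


def read_study(directory: str | Path) -> Study:
    """Load a study written by :func:`write_study` (either format)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    metadata = pd.read_csv(directory / "metadata.tsv", sep="\t")
    values, samples, markers = [], [], None
    for _, row in manifest.iterrows():
        path = directory / row["path"]
        if path.suffix == ".csv":
            df = pd.read_csv(path)
            mat, names = df.to_numpy(dtype=np.float32), list(df.columns)
        else:
            mat, names = read_fcs(path)
        if markers is None:
            markers = names
        elif names != markers:
            raise ValueError(f"{path}: channel names differ across samples")
        values.append(mat)
        samples.append(np.repeat(row["sample_id"], mat.shape[0]))
    label = None
    labels_path = directory / "cell_labels.tsv"
    if labels_path.exists():
        label = pd.read_csv(labels_path, sep="\t")["subset_id"].to_numpy()
    cells = CellTable(
        values=np.concatenate(values) if values else np.empty((0, 0), np.float32),
        markers=markers or [],
        sample_id=np.concatenate(samples) if samples else np.array([]),
        label=label,
    )
    truth = None
    freq_path = directory / "true_frequencies.tsv"
    if freq_path.exists():
        truth = GroundTruth(
            sample_freq=pd.read_csv(freq_path, sep="\t", index_col=0),
            subset_info=pd.read_csv(directory / "subset_info.tsv", sep="\t"),
            high_network2_subjects=[
                s for s in (directory / "high_network2_subjects.txt")
                .read_text().splitlines() if s
            ],
        )
    return Study(cells=cells, metadata=metadata, truth=truth)
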