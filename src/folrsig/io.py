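"""Readers and writers for the flat-file formats the pipeline exchanges.

Expression matrices travel as tab-delimited text (first column = feature id,
header = sample ids) or GCT 1.2; probe maps as two-column TSV
(feature_id, gene_id); clinical annotations as TSV with a ``sample_id``
column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Feature-by-sample matrix from TSV; first column is the feature id."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.index.name = None
    return frame


def write_expression_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index_label="feature_id")


def read_gct(path: str | Path) -> pd.DataFrame:
    """GCT 1.2 matrix. The Description column is discarded."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"unsupported GCT version line: {version!r}")
        n_rows, n_cols = (int(x) for x in fh.readline().split()[:2])
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    frame = frame.drop(columns=["Description"], errors="ignore")
    if frame.shape != (n_rows, n_cols):
        raise ValueError(
            f"GCT header declares {(n_rows, n_cols)} but matrix is {frame.shape}"
        )
    frame.index = frame.index.astype(str)
    frame.index.name = None
    return frame


def write_gct(frame: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{frame.shape[0]}\t{frame.shape[1]}\n")
        out = frame.copy()
        out.insert(0, "Description", "na")
        out.to_csv(fh, sep="\t", index_label="NAME")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: .gct -> GCT 1.2, anything else -> TSV."""
    path = Path(path)
    if path.suffix.lower() == ".gct":
        return read_gct(path)
    return read_expression_tsv(path)


def read_probe_map(path: str | Path) -> pd.Series:
    """Two-column TSV (feature_id, gene_id) -> Series feature_id -> gene_id."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("probe map needs two columns: feature_id, gene_id")
    return pd.Series(frame.iloc[:, 1].values, index=frame.iloc[:, 0].values)


def read_clinical(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "sample_id" not in frame.columns:
        raise ValueError("clinical table must have a 'sample_id' column")
    return frame.set_index("sample_id")


def write_clinical(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index_label="sample_id")
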