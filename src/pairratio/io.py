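"""Readers and writers for count tables, metadata and result tables.

The canonical dialect is TSV (tab-separated, UTF-8, "." decimal); CSV input
is accepted via delimiter sniffing on the file extension and content.
"""

from __future__ import annotations

import csv
import json
import sys
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError
from .pairwise import CountTable, SignificanceGrid, TaxonRanking

__all__ = ["RunConfig", "read_count_table", "read_metadata", "write_table",
           "write_grid", "write_ranking", "write_manifest"]


@dataclass
class RunConfig:
    """Validated options for one CLI run; echoed into the run manifest."""

    counts_path: str = ""
    metadata_path: str = ""
    transpose: bool = False
    group_col: str = "group"
    include_study: bool | None = None
    zero_policy: str = "impute"
    pseudocount: float = 1.0
    q_threshold: float = 0.05
    min_informative: int = 5
    methods: list = field(default_factory=lambda: ["bbglm"])
    n_perm: int = 10000
    seed: int = 0
    out_dir: str = "."


def _sniff_sep(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    if path.suffix.lower() in (".tsv", ".tab", ".txt"):
        with open(path, newline="") as fh:
            head = fh.readline()
        if "\t" not in head and "," in head:
            return ","
        return "\t"
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_count_table(counts_path, metadata_path=None, transpose: bool = False) -> CountTable:
    """Read a taxa-by-samples count table (and optional metadata).

    The file must have a header row of sample ids and a first column of
    taxon ids; ``transpose=True`` reads the samples-as-rows orientation.
    Non-integer or negative cells raise an error naming the offending
    taxon/sample. When metadata is given, every sample must be covered.
    """
    counts_path = Path(counts_path)
    raw = pd.read_csv(counts_path, sep=_sniff_sep(counts_path), index_col=0)
    if transpose:
        raw = raw.T
    for taxon in raw.index:
        row = raw.loc[taxon]
        bad = row[(row != np.floor(row)) | row.isna() | (row < 0)]
        if len(bad):
            sample = bad.index[0]
            raise DomainError(
                f"non-integer or negative count at (taxon {taxon!r}, sample {sample!r}): "
                f"{bad.iloc[0]!r}"
            )
    counts = raw.astype(np.int64)
    if metadata_path is None:
        metadata = pd.DataFrame({"group": ["unknown"] * counts.shape[1]},
                                index=counts.columns)
    else:
        metadata = read_metadata(metadata_path)
        missing = [s for s in counts.columns if s not in metadata.index]
        if missing:
            raise DomainError(f"metadata is missing samples: {missing}")
        extra = [s for s in metadata.index if s not in counts.columns]
        if extra:
            print(f"note: metadata has {len(extra)} samples absent from the count table",
                  file=sys.stderr)
    return CountTable(counts=counts, metadata=metadata)


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata with columns sample_id, group and optional study."""
    path = Path(path)
    meta = pd.read_csv(path, sep=_sniff_sep(path))
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise DomainError("metadata needs 'sample_id' and 'group' columns")
    if meta["sample_id"].duplicated().any():
        raise DomainError("duplicate sample_id in metadata")
    return meta.set_index("sample_id")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_counts(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="taxon_id")


def write_grid(grid: SignificanceGrid, path) -> None:
    grid.matrix.astype(int).to_csv(path, sep="\t", index_label="taxon_id")


def write_ranking(ranking: TaxonRanking, path) -> None:
    ranking.to_frame().to_csv(path, sep="\t", index=False)


def write_manifest(config: RunConfig, path, extra: dict | None = None) -> None:
    """Machine-readable record of a run: config, seed and library versions."""
    import pairratio
    import scipy

    manifest = {
        "config": asdict(config),
        "versions": {
            "pairratio": pairratio.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
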