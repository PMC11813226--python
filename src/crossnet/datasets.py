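"""Count-level data container and plain-text I/O.

A :class:`CountDataset` holds one tissue's gene-by-sample count matrix
together with sample metadata (animal id, group) and gene lengths, the
inputs the differential-expression and network stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("control", "sucrose", "JNK_D1", "JNK_D2")


@dataclass
class CountDataset:
    """Gene x sample integer counts for one tissue.

    Attributes
    ----------
    counts : DataFrame, genes x samples, nonnegative integers
    gene_lengths : Series indexed like ``counts`` rows, lengths in bp
    meta : DataFrame indexed by sample id with columns
        ``animal_id``, ``tissue``, ``group``
    tissue : tissue label
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    meta: pd.DataFrame
    tissue: str = field(default="tissue")

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if not self.counts.columns.equals(self.meta.index):
            raise ValueError("metadata index must match count columns")
        if not self.counts.index.equals(self.gene_lengths.index):
            raise ValueError("gene_lengths index must match count rows")
        if (pd.Series(self.gene_lengths).to_numpy() <= 0).any():
            raise ValueError("gene lengths must be positive")
        missing = self.meta["group"].isna()
        if missing.any():
            raise ValueError(f"samples without group: {list(self.meta.index[missing])}")

    @property
    def gene_ids(self):
        return self.counts.index

    @property
    def sample_ids(self):
        return self.counts.columns

    def samples_in_group(self, group: str) -> pd.Index:
        return self.meta.index[self.meta["group"] == group]

    def equals(self, other: "CountDataset") -> bool:
        return (
            self.tissue == other.tissue
            and self.counts.equals(other.counts)
            and self.gene_lengths.astype(float).equals(other.gene_lengths.astype(float))
            and self.meta.equals(other.meta)
        )


def write_dataset(ds: CountDataset, out_dir) -> dict:
    """Write counts / metadata / gene-length TSVs; returns the paths written.

    Files are ``<tissue>_counts.tsv`` (genes as rows, header = sample ids),
    ``<tissue>_meta.tsv`` and ``<tissue>_gene_lengths.tsv``. A read with
    :func:`read_dataset` reproduces the dataset exactly.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": out_dir / f"{ds.tissue}_counts.tsv",
            "meta": out_dir / f"{ds.tissue}_meta.tsv",
            "gene_lengths": out_dir / f"{ds.tissue}_gene_lengths.tsv",
        }
        ds.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
        ds.meta.to_csv(paths["meta"], sep="\t", index_label="sample_id")
        ds.gene_lengths.rename("length_bp").to_csv(
            paths["gene_lengths"], sep="\t", index_label="gene_id"
        )
    except OSError as exc:
        raise OSError(f"cannot write dataset under {out_dir}: {exc}") from exc
    return paths


def read_dataset(out_dir, tissue: str) -> CountDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    out_dir = Path(out_dir)
    counts = pd.read_csv(out_dir / f"{tissue}_counts.tsv", sep="\t", index_col="gene_id")
    meta = pd.read_csv(out_dir / f"{tissue}_meta.tsv", sep="\t", index_col="sample_id")
    lengths = pd.read_csv(
        out_dir / f"{tissue}_gene_lengths.tsv", sep="\t", index_col="gene_id"
    )["length_bp"]
    # header-only files round-trip as empty frames with the right axes
    counts.index = counts.index.astype(str)
    meta = meta.astype({c: str for c in ("animal_id", "tissue", "group") if c in meta})
    return CountDataset(counts=counts, gene_lengths=lengths, meta=meta, tissue=tissue)
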