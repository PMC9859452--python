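"""Core data model and I/O for longitudinal microbiome count tables.

The central container is :class:`LongitudinalMicrobiomeTable`: a taxa x
samples matrix of non-negative integer read counts together with per-sample
metadata (subject, collection time in days, and the *original* read depth,
which is frozen at ingest so that rarefied tables keep their provenance).
Derived views — relative abundances ``p``, pseudocount-adjusted abundances
``p~`` and study-wide mean abundances — live here as free functions.

Trees for phylogeny-aware dissimilarities are read into scikit-bio
``TreeNode`` objects via :func:`read_tree`.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "LongitudinalMicrobiomeTable",
    "read_count_table",
    "write_count_table",
    "relative_abundances",
    "pseudocount_relative_abundances",
    "mean_taxon_abundance",
    "read_tree",
]

METADATA_COLUMNS = ("subject", "time_days", "original_read_depth")


@dataclass
class LongitudinalMicrobiomeTable:
    """Taxon counts over repeatedly sampled subjects.

    Parameters
    ----------
    counts
        DataFrame of shape (n_taxa, n_samples) with unique taxon ids as the
        index, unique sample ids as the columns, and non-negative integer
        entries.  Column sums are the *current* (possibly rarefied) depths.
    metadata
        DataFrame indexed by sample id with columns ``subject`` (str),
        ``time_days`` (float, >= 0) and ``original_read_depth`` (int, the
        pre-rarefaction column sum).  ``original_read_depth`` may be omitted,
        in which case it is filled from the current column sums.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.metadata = self.metadata.copy()
        if "original_read_depth" not in self.metadata.columns:
            self.metadata["original_read_depth"] = self.counts.sum(axis=0).astype(
                np.int64
            )
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        counts, meta = self.counts, self.metadata
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate taxon id {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if not counts.columns.equals(meta.index):
            missing = set(counts.columns).symmetric_difference(meta.index)
            raise ValueError(
                f"metadata samples do not match count columns (mismatch: {sorted(missing)[:5]})"
            )
        for col in ("subject", "time_days"):
            if col not in meta.columns:
                raise ValueError(f"metadata is missing required column {col!r}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (values < 0).any():
            sample = counts.columns[np.argwhere(values < 0)[0, 1]]
            raise ValueError(f"negative count in sample {sample!r}")
        if not np.allclose(values, np.round(values)):
            sample = counts.columns[
                np.argwhere(~np.isclose(values, np.round(values)))[0, 1]
            ]
            raise ValueError(f"fractional count in sample {sample!r}")
        self.counts = counts.astype(np.int64)
        times = pd.to_numeric(meta["time_days"], errors="coerce")
        if times.isna().any():
            bad = meta.index[times.isna()][0]
            raise ValueError(f"non-numeric time for sample {bad!r}")
        if (times < 0).any():
            bad = meta.index[times < 0][0]
            raise ValueError(f"negative time for sample {bad!r}")
        self.metadata["time_days"] = times.astype(float)
        key = meta[["subject", "time_days"]].apply(tuple, axis=1)
        if key.duplicated().any():
            subj, t = key[key.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate (subject, time) pair ({subj!r}, {t}) — samples "
                f"{list(meta.index[key == (subj, t)])}"
            )
        depth = pd.to_numeric(meta["original_read_depth"], errors="coerce")
        if depth.isna().any() or (depth <= 0).any():
            bad = meta.index[depth.isna() | (depth <= 0)][0]
            raise ValueError(f"invalid original_read_depth for sample {bad!r}")
        self.metadata["original_read_depth"] = depth.astype(np.int64)
        current = self.counts.sum(axis=0)
        too_deep = current > self.metadata["original_read_depth"]
        if too_deep.any():
            bad = current.index[too_deep][0]
            raise ValueError(
                f"current depth exceeds original_read_depth for sample {bad!r}"
            )

    # -- convenience -----------------------------------------------------
    @property
    def taxon_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_depths(self) -> pd.Series:
        """Current (possibly rarefied) per-sample totals."""
        return self.counts.sum(axis=0)

    def subjects(self) -> list:
        return sorted(self.metadata["subject"].unique())

    def samples_for_subject(self, subject: str) -> pd.DataFrame:
        """Metadata rows for one subject, sorted by collection time."""
        sub = self.metadata[self.metadata["subject"] == subject]
        return sub.sort_values("time_days")

    def with_counts(self, counts: pd.DataFrame) -> "LongitudinalMicrobiomeTable":
        """New table with replaced counts; metadata (incl. original depth) kept."""
        return LongitudinalMicrobiomeTable(counts, self.metadata.loc[counts.columns])

    def drop_samples(self, sample_ids) -> "LongitudinalMicrobiomeTable":
        keep = [s for s in self.counts.columns if s not in set(sample_ids)]
        return LongitudinalMicrobiomeTable(
            self.counts[keep], self.metadata.loc[keep]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LongitudinalMicrobiomeTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.metadata[
            list(METADATA_COLUMNS)
        ].equals(other.metadata[list(METADATA_COLUMNS)])


# ---------------------------------------------------------------------------
# derived views
# ---------------------------------------------------------------------------

def relative_abundances(table: LongitudinalMicrobiomeTable) -> pd.DataFrame:
    """Per-sample relative abundances p (no pseudocount).

    Each column is count / column sum and sums to 1; a zero-depth sample is
    an error (there is no composition to speak of).
    """
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total reads")
    return table.counts / totals


def pseudocount_relative_abundances(
    table: LongitudinalMicrobiomeTable, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Zero-replaced relative abundances p~.

    Adds ``pseudocount`` to every count before closing each sample to 1, so
    every entry is strictly positive: entry = (count + c) / (total + c * T)
    with T the number of taxa.  A taxon with zero count in a sample of total
    R therefore gets p~ = c / (R + c*T) — for the default c = 1 that is
    1 / (R + T), the value every absent taxon shares in a rarefied sample.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    adjusted = table.counts + pseudocount
    return adjusted / adjusted.sum(axis=0)


def mean_taxon_abundance(table: LongitudinalMicrobiomeTable) -> pd.Series:
    """Arithmetic mean of p over all samples, per taxon (sums to 1)."""
    if table.n_samples == 0:
        raise ValueError("table has no samples")
    return relative_abundances(table).mean(axis=1)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_count_table(
    path: Union[str, Path],
    metadata_path: Union[str, Path, None] = None,
    format: str = "tsv",
) -> LongitudinalMicrobiomeTable:
    """Read a count table plus sample metadata.

    ``format='tsv'``: tab-delimited, taxa as rows, first column the taxon id;
    ``metadata_path`` points to a tab-delimited table with columns
    sample_id / subject / time_days [/ read_depth].  ``format='biom'``: a
    BIOM 1.0-style JSON file (dense or sparse) whose column metadata may
    carry subject/time_days/read_depth, otherwise supply ``metadata_path``.
    """
    path = Path(path)
    if format == "tsv":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        meta = _read_metadata(metadata_path) if metadata_path else None
    elif format == "biom":
        counts, meta = _read_biom_json(path)
        if metadata_path is not None:
            meta = _read_metadata(metadata_path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if meta is None:
        raise ValueError("sample metadata (subject, time_days) is required")
    meta = meta.reindex(counts.columns)
    if meta["subject"].isna().any():
        bad = meta.index[meta["subject"].isna()][0]
        raise ValueError(f"no metadata for sample {bad!r}")
    return LongitudinalMicrobiomeTable(counts, meta)


def _read_metadata(path: Union[str, Path]) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject": str})
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a sample_id column")
    meta = meta.set_index("sample_id")
    if "read_depth" in meta.columns:
        meta = meta.rename(columns={"read_depth": "original_read_depth"})
    return meta


def _read_biom_json(path: Path):
    with open(path) as handle:
        doc = json.load(handle)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    data = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type", "dense") == "sparse":
        for i, j, v in doc["data"]:
            data[int(i), int(j)] = v
    else:
        data[:] = np.asarray(doc["data"])
    counts = pd.DataFrame(data, index=taxa, columns=samples)
    meta = None
    col_meta = [c.get("metadata") for c in doc["columns"]]
    if all(m and "subject" in m and "time_days" in m for m in col_meta):
        meta = pd.DataFrame(col_meta, index=samples)
        if "read_depth" in meta.columns:
            meta = meta.rename(columns={"read_depth": "original_read_depth"})
    return counts, meta


def write_count_table(
    table: LongitudinalMicrobiomeTable,
    path: Union[str, Path],
    metadata_path: Union[str, Path],
) -> None:
    """Write the tab-delimited count table and its companion metadata."""
    out = table.counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")
    meta = table.metadata[list(METADATA_COLUMNS)].copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


def read_tree(path: Union[str, Path, io.StringIO]) -> TreeNode:
    """Read a rooted newick tree and validate it for dissimilarity use.

    Every leaf must be named and every branch length finite and
    non-negative (absent lengths are treated as 0).
    """
    tree = TreeNode.read(path, format="newick")
    for node in tree.traverse(include_self=False):
        if node.is_tip() and not node.name:
            raise ValueError("tree contains an unnamed leaf")
        if node.length is not None:
            if not np.isfinite(node.length):
                raise ValueError(f"non-finite branch length at {node.name!r}")
            if node.length < 0:
                raise ValueError(f"negative branch length at {node.name!r}")
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("tree leaf names are not unique")
    return tree
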