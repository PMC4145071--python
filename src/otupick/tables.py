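"""OTU tables (OTU x sample count matrices) and their transformations."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "build_table",
    "filter_min_count",
    "rarefy",
    "collapse_taxonomy",
    "merge_tables",
    "lineage_prefix",
]


class OtuTable:
    """An OTU x sample matrix of non-negative integer read counts.

    Thin wrapper over a pandas DataFrame (rows = OTU ids, columns = sample
    ids) plus an optional ``otu_id -> semicolon-delimited lineage`` map.
    """

    def __init__(self, counts, otu_ids, sample_ids, taxonomy=None):
        mat = np.asarray(counts)
        if mat.size and (mat < 0).any():
            raise ValueError("OTU table counts must be non-negative")
        if mat.size and not np.issubdtype(mat.dtype, np.integer):
            if not np.all(mat == np.round(mat)):
                raise ValueError("OTU table counts must be integral")
        mat = mat.astype(np.int64).reshape(len(otu_ids), len(sample_ids))
        if len(set(otu_ids)) != len(list(otu_ids)):
            raise ValueError("duplicate OTU ids")
        if len(set(sample_ids)) != len(list(sample_ids)):
            raise ValueError("duplicate sample ids")
        self.data = pd.DataFrame(mat, index=list(otu_ids),
                                 columns=list(sample_ids))
        self.taxonomy = dict(taxonomy) if taxonomy is not None else None

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self):
        return self.data.shape

    def total(self) -> int:
        return int(self.data.to_numpy().sum())

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def otu_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def sample_counts(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]

    def select_samples(self, sample_ids) -> "OtuTable":
        sub = self.data[list(sample_ids)]
        return OtuTable(sub.to_numpy(), list(sub.index), list(sub.columns),
                        taxonomy=self.taxonomy)

    def __eq__(self, other):
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.data.equals(other.data) and self.taxonomy == other.taxonomy

    def __repr__(self):
        return f"<OtuTable: {self.shape[0]} OTUs x {self.shape[1]} samples>"


def build_table(otu_map, samples, taxonomy=None) -> OtuTable:
    """Count reads per (OTU, sample) from an OTU map and sample assignment.

    OTUs appear in map order; samples in first-appearance order over the
    mapped reads. A read without a sample assignment is a hard error.
    """
    otu_ids = otu_map.otu_ids
    sample_index: dict[str, int] = {}
    cells: dict[tuple[int, int], int] = {}
    for i, (otu_id, members) in enumerate(otu_map.items()):
        for rid in members:
            sid = samples.sample_of(rid)
            j = sample_index.setdefault(sid, len(sample_index))
            cells[i, j] = cells.get((i, j), 0) + 1
    mat = np.zeros((len(otu_ids), len(sample_index)), dtype=np.int64)
    for (i, j), v in cells.items():
        mat[i, j] = v
    if taxonomy is not None:
        taxonomy = {o: taxonomy[o] for o in otu_ids if o in taxonomy}
    return OtuTable(mat, otu_ids, list(sample_index), taxonomy=taxonomy)


def filter_min_count(table: OtuTable, c: int) -> OtuTable:
    """Drop OTUs whose total count across samples is below ``c``.

    ``c = 2`` removes exactly the singleton OTUs ("observed at least
    twice"); ``c = 0`` is the identity. Kept counts are never modified.
    """
    if c < 0:
        raise ValueError("min count must be >= 0")
    keep = table.otu_totals() >= c
    sub = table.data.loc[keep]
    tax = None
    if table.taxonomy is not None:
        tax = {o: l for o, l in table.taxonomy.items() if o in sub.index}
    return OtuTable(sub.to_numpy(), list(sub.index), table.sample_ids,
                    taxonomy=tax)


def rarefy(table: OtuTable, depth: int, seed) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning
    (never padded). Sampling is multivariate hypergeometric per sample,
    deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept_cols = []
    dropped = []
    out = []
    for sid in table.sample_ids:
        col = table.data[sid].to_numpy()
        total = int(col.sum())
        if total < depth:
            dropped.append(sid)
            continue
        out.append(rng.multivariate_hypergeometric(col, depth))
        kept_cols.append(sid)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below rarefaction depth "
            f"{depth}: {dropped}", stacklevel=2)
    mat = (np.column_stack(out) if out
           else np.zeros((len(table.otu_ids), 0), dtype=np.int64))
    return OtuTable(mat, table.otu_ids, kept_cols, taxonomy=table.taxonomy)


def lineage_prefix(lineage: str, level: int) -> str:
    """First ``level`` ranks of a semicolon-delimited lineage string."""
    ranks = [r.strip() for r in lineage.split(";") if r.strip()]
    return ";".join(ranks[:level]) if ranks else "Unassigned"


def collapse_taxonomy(table: OtuTable, level: int) -> pd.DataFrame:
    """Relative-abundance profile at a taxonomic rank depth.

    Rank depth is 1-indexed from kingdom (1) to species (7). OTUs without a
    lineage are pooled into ``"Unassigned"``. Columns of the result sum to 1
    for every sample with at least one read.
    """
    if level < 1:
        raise ValueError("taxonomic level must be >= 1")
    taxonomy = table.taxonomy or {}
    groups: dict[str, np.ndarray] = {}
    for otu_id in table.otu_ids:
        lineage = taxonomy.get(otu_id)
        key = lineage_prefix(lineage, level) if lineage else "Unassigned"
        row = table.data.loc[otu_id].to_numpy()
        if key in groups:
            groups[key] = groups[key] + row
        else:
            groups[key] = row.astype(np.float64)
    if not groups:
        return pd.DataFrame(index=[], columns=table.sample_ids, dtype=float)
    df = pd.DataFrame(groups).T
    df.columns = table.sample_ids
    totals = df.sum(axis=0)
    nonzero = totals > 0
    df.loc[:, nonzero] = df.loc[:, nonzero] / totals[nonzero]
    return df


def merge_tables(tables) -> OtuTable:
    """Union of OTU and sample ids; overlapping cells are summed.

    Ids keep first-appearance order across the input tables. Taxonomy maps
    are merged (later tables never overwrite an existing lineage).
    """
    tables = list(tables)
    if not tables:
        return OtuTable(np.zeros((0, 0), dtype=np.int64), [], [])
    otu_ids: dict[str, int] = {}
    sample_ids: dict[str, int] = {}
    for t in tables:
        for o in t.otu_ids:
            otu_ids.setdefault(o, len(otu_ids))
        for s in t.sample_ids:
            sample_ids.setdefault(s, len(sample_ids))
    mat = np.zeros((len(otu_ids), len(sample_ids)), dtype=np.int64)
    for t in tables:
        ridx = [otu_ids[o] for o in t.otu_ids]
        cidx = [sample_ids[s] for s in t.sample_ids]
        mat[np.ix_(ridx, cidx)] += t.data.to_numpy()
    tax: dict[str, str] = {}
    any_tax = False
    for t in tables:
        if t.taxonomy is not None:
            any_tax = True
            for o, l in t.taxonomy.items():
                tax.setdefault(o, l)
    return OtuTable(mat, list(otu_ids), list(sample_ids),
                    taxonomy=tax if any_tax else None)
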